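"""Validation of flow estimates against reported migration statistics.

Reported flow collections are annual; the estimates are five-year
transitions.  The comparison therefore (a) builds equivalent five-year
reported flows — five times the mean of the annual flows available within
the period — and (b) correlates estimated against reported values for six
migration measures rather than scoring absolute accuracy, since reported
statistics vary in definition and coverage:

* count — the bilateral flow itself;
* log_count — its natural log (pairs with a zero on either side dropped,
  or log1p if configured);
* proportion_in / proportion_out — the corridor's share of its
  destination's inflows / origin's outflows;
* imm_rate / emi_rate — country inflow / outflow totals over the
  start-of-period population;
* net_count — country inflows minus outflows.

Also provides the summary statistics of discrepancies between
total-stock-based estimates and summed sex-specific estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PERIOD_LENGTH, DemographicPanel, ValidationError

logger = logging.getLogger("migflows")

MEASURES = (
    "count",
    "log_count",
    "proportion_in",
    "proportion_out",
    "imm_rate",
    "emi_rate",
    "net_count",
)

REPORTED_COLUMNS = ["orig", "dest", "year", "flow"]


def read_reported(path) -> pd.DataFrame:
    """Read an annual reported-flow CSV ([sex,] orig, dest, year, flow)."""
    df = pd.read_csv(path)
    missing = [c for c in REPORTED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"reported-flow CSV missing columns {missing}")
    if (df["flow"] < 0).any():
        raise ValidationError("reported flows must be non-negative")
    return df


def five_year_equivalent(reported: pd.DataFrame, period: int) -> pd.DataFrame:
    """Equivalent five-year flows for one period.

    equivalent = mean(annual flows reported in calendar years t..t+4) * 5.
    Corridors with no annual data inside the period are omitted, not failed.
    """
    keys = ["orig", "dest"] + (["sex"] if "sex" in reported.columns else [])
    sub = reported[
        (reported["year"] >= period) & (reported["year"] < period + PERIOD_LENGTH)
    ]
    if sub.empty:
        return pd.DataFrame(columns=keys + ["period", "flow"])
    out = (
        sub.groupby(keys, as_index=False)["flow"]
        .mean()
        .assign(flow=lambda d: d["flow"] * PERIOD_LENGTH, period=period)
    )
    return out[keys + ["period", "flow"]]


@dataclass
class MeasureVector:
    """Paired (estimated, reported) values of one migration measure."""

    measure: str
    estimated: np.ndarray
    reported: np.ndarray
    keys: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.estimated) != len(self.reported):
            raise ValidationError("estimated and reported vectors differ in length")


def _country_totals(df: pd.DataFrame, value: str, by: str) -> pd.DataFrame:
    """Inflow (by='dest') or outflow (by='orig') totals per sex-period-country."""
    keys = [c for c in ("sex", "period") if c in df.columns] + [by]
    out = df.groupby(keys, as_index=False)[value].sum()
    return out.rename(columns={by: "country"})


def compute_measures(
    est: pd.DataFrame,
    method: str,
    ref: pd.DataFrame,
    demo: DemographicPanel,
    log_zero: str = "drop",
) -> list[MeasureVector]:
    """The six migration measures, paired over the matched corridor keys.

    ``est`` carries column ``method``; ``ref`` carries five-year equivalent
    reported flows in column ``flow``.  Corridor measures are computed on
    the inner join of the two key sets; country measures (rates, net
    counts) aggregate over that join.  Rates use start-of-period
    populations; countries with a zero population denominator are dropped
    with a warning.
    """
    if log_zero not in ("drop", "add1"):
        raise ValidationError("log_zero must be 'drop' or 'add1'")
    keys = ["orig", "dest", "period"] + (
        ["sex"] if "sex" in est.columns and "sex" in ref.columns else []
    )
    joined = est[keys + [method]].merge(
        ref[keys + ["flow"]], on=keys, how="inner", validate="one_to_one"
    )
    if joined.empty:
        raise ValidationError("no matched corridors between estimates and reports")
    e = joined[method].to_numpy(dtype=float)
    r = joined["flow"].to_numpy(dtype=float)
    out = [MeasureVector("count", e, r, joined[keys])]

    if log_zero == "drop":
        pos = (e > 0) & (r > 0)
        out.append(
            MeasureVector("log_count", np.log(e[pos]), np.log(r[pos]), joined[keys][pos])
        )
    else:
        out.append(MeasureVector("log_count", np.log1p(e), np.log1p(r), joined[keys]))

    for measure, by in (("proportion_in", "dest"), ("proportion_out", "orig")):
        group = [c for c in ("sex", "period") if c in joined.columns] + [by]
        e_tot = joined.groupby(group)[method].transform("sum").to_numpy()
        r_tot = joined.groupby(group)["flow"].transform("sum").to_numpy()
        ok = (e_tot > 0) & (r_tot > 0)
        out.append(
            MeasureVector(measure, e[ok] / e_tot[ok], r[ok] / r_tot[ok], joined[keys][ok])
        )

    # country-level totals over the matched corridors
    ctry_keys = [c for c in ("sex", "period") if c in joined.columns] + ["country"]
    e_in = _country_totals(joined, method, "dest").rename(columns={method: "est_in"})
    r_in = _country_totals(joined, "flow", "dest").rename(columns={"flow": "ref_in"})
    e_out = _country_totals(joined, method, "orig").rename(columns={method: "est_out"})
    r_out = _country_totals(joined, "flow", "orig").rename(columns={"flow": "ref_out"})

    def with_population(df: pd.DataFrame) -> pd.DataFrame:
        pops = []
        for _, row in df.iterrows():
            sexes = [row["sex"]] if "sex" in df.columns else list(
                demo.data["sex"].unique()
            )
            p = 0.0
            for s in sexes:
                series = demo.population(int(row["period"]), s)
                p += float(series.get(row["country"], np.nan))
            pops.append(p)
        df = df.assign(pop_start=pops)
        bad = df["pop_start"].isna() | (df["pop_start"] <= 0)
        for _, row in df[bad].iterrows():
            logger.warning(
                "dropping %s (period %s): zero or missing start population",
                row["country"],
                row["period"],
            )
        return df[~bad]

    for measure, e_df, r_df, e_col, r_col in (
        ("imm_rate", e_in, r_in, "est_in", "ref_in"),
        ("emi_rate", e_out, r_out, "est_out", "ref_out"),
    ):
        m = with_population(e_df.merge(r_df, on=ctry_keys))
        out.append(
            MeasureVector(
                measure,
                (m[e_col] / m["pop_start"]).to_numpy(),
                (m[r_col] / m["pop_start"]).to_numpy(),
                m[ctry_keys],
            )
        )

    net = e_in.merge(e_out, on=ctry_keys, how="outer")
    net = net.merge(r_in, on=ctry_keys, how="outer")
    net = net.merge(r_out, on=ctry_keys, how="outer").fillna(0.0)
    out.append(
        MeasureVector(
            "net_count",
            (net["est_in"] - net["est_out"]).to_numpy(),
            (net["ref_in"] - net["ref_out"]).to_numpy(),
            net[ctry_keys],
        )
    )
    return out


def pearson(v: MeasureVector) -> float:
    """Product-moment correlation of a measure pair; NaN when degenerate."""
    if len(v.estimated) < 2:
        logger.warning("measure %s: fewer than 2 pairs, correlation undefined", v.measure)
        return float("nan")
    if np.std(v.estimated) == 0 or np.std(v.reported) == 0:
        logger.warning("measure %s: zero variance, correlation undefined", v.measure)
        return float("nan")
    return float(stats.pearsonr(v.estimated, v.reported).statistic)


def correlate(
    est: pd.DataFrame,
    methods: list[str],
    ref: pd.DataFrame,
    demo: DemographicPanel,
    source: str = "reported",
    log_zero: str = "drop",
) -> pd.DataFrame:
    """Tidy correlation table: source, sex, method, measure, r, n_pairs."""
    rows = []
    sexes = sorted(est["sex"].unique()) if "sex" in est.columns else [None]
    for sex in sexes:
        est_s = est if sex is None else est[est["sex"] == sex]
        ref_s = ref if sex is None or "sex" not in ref.columns else ref[ref["sex"] == sex]
        for method in methods:
            for v in compute_measures(est_s, method, ref_s, demo, log_zero=log_zero):
                rows.append(
                    {
                        "source": source,
                        "sex": sex if sex is not None else "total",
                        "method": method,
                        "measure": v.measure,
                        "r": pearson(v),
                        "n_pairs": len(v.estimated),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Discrepancies between total-based and sex-summed estimates
# ---------------------------------------------------------------------------

def sum_sexes(est: pd.DataFrame, methods: list[str]) -> pd.DataFrame:
    """Sum per-sex flow estimates into sexless corridor totals."""
    return est.groupby(["orig", "dest", "period"], as_index=False)[list(methods)].sum()


def discrepancy_summary(
    total_based: pd.DataFrame,
    sex_summed: pd.DataFrame,
    methods: list[str] | None = None,
) -> pd.DataFrame:
    """Distribution statistics of (total-based − sex-summed) per method.

    IQR = p75 − p25, IDR = p90 − p10, IPR99 = p99.5 − p0.5, all with linear
    interpolation between order statistics.  The two estimate sets must
    cover identical corridor keys.
    """
    if methods is None:
        methods = [c for c in total_based.columns if c in sex_summed.columns
                   and c not in ("sex", "orig", "dest", "period")]
    keys = ["orig", "dest", "period"]
    t = total_based[keys + list(methods)].sort_values(keys).reset_index(drop=True)
    s = sex_summed[keys + list(methods)].sort_values(keys).reset_index(drop=True)
    if len(t) != len(s) or not t[keys].equals(s[keys]):
        raise ValidationError("total-based and sex-summed corridor sets differ")
    rows = []
    for method in methods:
        d = t[method].to_numpy(dtype=float) - s[method].to_numpy(dtype=float)
        q = np.percentile(d, [0.5, 10, 25, 75, 90, 99.5])
        rows.append(
            {
                "method": method,
                "mean": d.mean(),
                "median": float(np.median(d)),
                "sd": d.std(ddof=1) if len(d) > 1 else 0.0,
                "iqr": q[3] - q[2],  # p75 - p25
                "idr": q[4] - q[1],  # p90 - p10
                "ipr99": q[5] - q[0],  # p99.5 - p0.5
                "min": d.min(),
                "max": d.max(),
            }
        )
    return pd.DataFrame(rows).set_index("method")
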