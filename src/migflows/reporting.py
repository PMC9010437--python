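"""Pipeline orchestration, output files and summary statistics.

Runs the requested estimators over every harmonised period and sex and
writes the two study-schema output files:

* file 1 — one row per (sex, orig, dest, period) with a column per
  estimation method;
* file 2 — one row per (sex, move_type, orig, dest, period) with columns
  for the three demographic-accounting methods.

By default both files store the full origin x destination grid (orig = dest
rows carry zero flows), which makes the row counts exact functions of the
country panel: 2 x sum_p n_p^2 for file 1 and three times that for file 2.
A ``corridor`` layout storing only orig != dest rows is available.

Stock-differencing estimates are written as integers (their inputs are
integer stocks); the other methods are written with two decimals.  Rounding
happens only at serialisation, never inside the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accounting, differencing, rates
from .core import (
    INTEGER_METHODS,
    METHOD_KEYS,
    SEXES,
    BilateralStockPanel,
    CountryPanel,
    DemographicPanel,
    ValidationError,
    derive_net_migration,
    harmonize,
    read_demographics,
    read_stocks,
)

logger = logging.getLogger("migflows")

FLOW_KEYS = ["sex", "orig", "dest", "period"]


@dataclass
class RunConfig:
    """Configuration of an estimation run."""

    stocks_path: str | Path | None = None
    demo_path: str | Path | None = None
    out_dir: str | Path = "."
    methods: tuple[str, ...] = METHOD_KEYS
    pb_weight: float = accounting.PB_WEIGHT
    ipf_tol: float = accounting.IPF_TOL
    ipf_max_iter: int = accounting.IPF_MAX_ITER
    halve_rates_total: bool = False
    layout: str = "grid"
    seed: int = 42
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = [m for m in self.methods if m not in METHOD_KEYS]
        if bad:
            raise ValidationError(f"unknown method keys {bad}")
        if not 0.0 <= self.pb_weight <= 1.0:
            raise ValidationError("pb_weight must lie in [0, 1]")
        if self.layout not in ("grid", "corridor"):
            raise ValidationError("layout must be 'grid' or 'corridor'")


def run_estimators(
    stocks: BilateralStockPanel,
    demo: DemographicPanel,
    panel: CountryPanel,
    cfg: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All requested estimators over every period of a harmonised world.

    Returns (flow table, move-type table); the move-type table is empty
    unless at least one demographic-accounting method is requested.
    """
    cfg = cfg or RunConfig()
    if "net_migration" not in demo.data.columns:
        demo = derive_net_migration(demo)
    want_da = [m for m in cfg.methods if m in accounting.DA_METHODS]
    flow_parts, mt_parts = [], []
    for period, countries in sorted(panel.periods.items()):
        try:
            flows = None
            if {"sd_drop_neg", "sd_rev_neg"} & set(cfg.methods):
                diffs = differencing.difference_stocks(stocks, period, countries)
                if "sd_drop_neg" in cfg.methods:
                    flows = differencing.drop_negative(diffs)
                if "sd_rev_neg" in cfg.methods:
                    rev = differencing.reverse_negative(diffs)
                    flows = rev if flows is None else flows.merge(rev, on=FLOW_KEYS)
            if "mig_rate" in cfg.methods:
                mr = rates.estimate_rates(
                    stocks, demo, period, countries, cfg.halve_rates_total
                )
                flows = mr if flows is None else flows.merge(mr, on=FLOW_KEYS)
            if want_da:
                da_flows, da_mt = accounting.estimate_accounting(
                    stocks,
                    demo,
                    period,
                    countries,
                    pb=accounting.PseudoBayesConfig(cfg.pb_weight),
                    tol=cfg.ipf_tol,
                    max_iter=cfg.ipf_max_iter,
                )
                keep = FLOW_KEYS + want_da
                da_flows = da_flows[keep]
                flows = da_flows if flows is None else flows.merge(da_flows, on=FLOW_KEYS)
                mt_parts.append(da_mt[["move_type"] + FLOW_KEYS + want_da])
        except ValidationError as exc:
            raise ValidationError(f"period {period}: {exc}") from exc
        flow_parts.append(flows)
    flows = pd.concat(flow_parts, ignore_index=True)
    move_types = (
        pd.concat(mt_parts, ignore_index=True)
        if mt_parts
        else pd.DataFrame(columns=["move_type"] + FLOW_KEYS)
    )
    return flows, move_types


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

def file1_row_count(panel: CountryPanel, n_sexes: int = 2, layout: str = "grid") -> int:
    """Exact row count of the flow file for a given country panel."""
    if layout == "grid":
        return n_sexes * panel.n_corridor_cells()
    return n_sexes * sum(len(c) * (len(c) - 1) for c in panel.periods.values())


def file2_row_count(panel: CountryPanel, n_sexes: int = 2, layout: str = "grid") -> int:
    """Exact row count of the move-type file (three move types per corridor)."""
    return 3 * file1_row_count(panel, n_sexes, layout)


def _expand_grid(
    df: pd.DataFrame, panel: CountryPanel, extra_keys: list[str]
) -> pd.DataFrame:
    """Add orig == dest rows (zero flows) so each period covers its full grid."""
    value_cols = [c for c in df.columns if c not in FLOW_KEYS + extra_keys]
    extras = (
        df[extra_keys + ["sex"]].drop_duplicates()
        if extra_keys
        else df[["sex"]].drop_duplicates()
    )
    parts = [df]
    for period, countries in panel.periods.items():
        diag = pd.DataFrame({"orig": countries, "dest": countries, "period": period})
        diag = extras.merge(diag, how="cross")
        for c in value_cols:
            diag[c] = 0.0
        parts.append(diag[df.columns])
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["sex"] + extra_keys + ["period", "orig", "dest"]).reset_index(
        drop=True
    )


def _format_values(df: pd.DataFrame) -> pd.DataFrame:
    """Serialise method columns: integers for differencing, two decimals else."""
    out = df.copy()
    for col in out.columns:
        if col not in METHOD_KEYS:
            continue
        v = out[col].to_numpy(dtype=float)
        if col in INTEGER_METHODS and np.allclose(v, np.round(v)):
            out[col] = np.round(v).astype(np.int64)
        else:
            out[col] = [f"{x:.2f}" for x in v]
    return out


def write_flow_file(
    flows: pd.DataFrame, path, panel: CountryPanel, layout: str = "grid"
) -> None:
    """Write file 1: sex, orig, dest, year0 plus one column per method."""
    df = flows if layout == "corridor" else _expand_grid(flows, panel, [])
    df = _format_values(df).rename(columns={"period": "year0"})
    df.to_csv(path, index=False)


def write_move_type_file(
    move_types: pd.DataFrame, path, panel: CountryPanel, layout: str = "grid"
) -> None:
    """Write file 2: sex, move_type, orig, dest, year0 plus the da_* columns."""
    df = (
        move_types
        if layout == "corridor"
        else _expand_grid(move_types, panel, ["move_type"])
    )
    df = _format_values(df).rename(columns={"period": "year0"})
    cols = ["sex", "move_type", "orig", "dest", "year0"] + [
        c for c in df.columns if c in METHOD_KEYS
    ]
    df[cols].to_csv(path, index=False)


def estimate_all(cfg: RunConfig) -> tuple[Path, Path | None]:
    """Read inputs, harmonise, run estimators and write the output files.

    Returns the paths of the flow file and (when any accounting method is
    requested) the move-type file.
    """
    stocks = read_stocks(cfg.stocks_path)
    demo = read_demographics(cfg.demo_path)
    stocks, demo, panel = harmonize(stocks, demo)
    demo = derive_net_migration(demo)
    flows, move_types = run_estimators(stocks, demo, panel, cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flow_path = out / "migration_flow_estimates.csv"
    write_flow_file(flows, flow_path, panel, cfg.layout)
    mt_path = None
    if not move_types.empty:
        mt_path = out / "migration_flow_estimates_by_move_type.csv"
        write_move_type_file(move_types, mt_path, panel, cfg.layout)
    return flow_path, mt_path


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _grid_values(
    flows: pd.DataFrame, panel: CountryPanel, sex: str, period: int, method: str
) -> np.ndarray:
    """Flow values over the full origin x destination grid (diagonal zeros)."""
    sub = flows[(flows["sex"] == sex) & (flows["period"] == period)]
    n = len(panel.periods[period])
    return np.concatenate([sub[method].to_numpy(dtype=float), np.zeros(n)])


def summarise(
    flows: pd.DataFrame, demo: DemographicPanel, panel: CountryPanel
) -> pd.DataFrame:
    """Totals, crude rates, sex shares and distribution stats per sex/period/method.

    Crude rates divide each sex's total flows by that sex's total population
    at the start of the period, per thousand.  Distribution statistics run
    over the full origin x destination key grid (orig = dest keys count as
    zero flows), matching how corridor counts are reported with N equal to
    the squared country count.
    """
    methods = [c for c in flows.columns if c in METHOD_KEYS]
    rows = []
    for period in sorted(panel.periods):
        sexes = sorted(flows["sex"].unique())
        pop = {
            s: float(demo.population(period, s).reindex(panel.periods[period]).sum())
            for s in sexes
        }
        totals = {
            (s, m): float(
                flows[(flows["sex"] == s) & (flows["period"] == period)][m].sum()
            )
            for s in sexes
            for m in methods
        }
        for s in sexes:
            for m in methods:
                v = _grid_values(flows, panel, s, period, m)
                all_total = sum(totals[(s2, m)] for s2 in sexes)
                nz = v[v > 0]
                rows.append(
                    {
                        "sex": s,
                        "period": period,
                        "method": m,
                        "total": totals[(s, m)],
                        "crude_rate_per_1000": 1000.0 * totals[(s, m)] / pop[s]
                        if pop[s] > 0
                        else np.nan,
                        "sex_share": totals[(s, m)] / all_total
                        if all_total > 0
                        else np.nan,
                        "n": len(v),
                        "min": v.min(),
                        "median": float(np.median(v)),
                        "mean": v.mean(),
                        "max": v.max(),
                        "sd": v.std(ddof=1),
                        "prop_zero": float((v == 0).mean()),
                        "mean_nonzero": nz.mean() if len(nz) else np.nan,
                        "sd_nonzero": nz.std(ddof=1) if len(nz) > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def table1_stats(
    flows: pd.DataFrame, panel: CountryPanel
) -> pd.DataFrame:
    """Distribution statistics pooled over all periods, per sex and method.

    N is the full corridor key-space size (sum over periods of the squared
    country count).
    """
    methods = [c for c in flows.columns if c in METHOD_KEYS]
    rows = []
    for s in sorted(flows["sex"].unique()):
        for m in methods:
            v = np.concatenate(
                [_grid_values(flows, panel, s, p, m) for p in sorted(panel.periods)]
            )
            nz = v[v > 0]
            rows.append(
                {
                    "sex": s,
                    "method": m,
                    "n": len(v),
                    "min": v.min(),
                    "median": float(np.median(v)),
                    "mean": v.mean(),
                    "max": v.max(),
                    "sd": v.std(ddof=1),
                    "prop_zero": float((v == 0).mean()),
                    "mean_nonzero": nz.mean() if len(nz) else np.nan,
                    "sd_nonzero": nz.std(ddof=1) if len(nz) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def summarise_move_types(
    move_types: pd.DataFrame, demo: DemographicPanel, panel: CountryPanel
) -> pd.DataFrame:
    """Totals, crude rates and move-type shares per sex, period and method."""
    methods = [c for c in move_types.columns if c in METHOD_KEYS]
    rows = []
    for period in sorted(move_types["period"].unique()):
        for s in sorted(move_types["sex"].unique()):
            pop = float(demo.population(period, s).reindex(panel.periods[period]).sum())
            sub = move_types[
                (move_types["sex"] == s) & (move_types["period"] == period)
            ]
            for m in methods:
                grand = float(sub[m].sum())
                for mt in accounting.MOVE_TYPES:
                    total = float(sub[sub["move_type"] == mt][m].sum())
                    rows.append(
                        {
                            "sex": s,
                            "period": period,
                            "method": m,
                            "move_type": mt,
                            "total": total,
                            "crude_rate_per_1000": 1000.0 * total / pop
                            if pop > 0
                            else np.nan,
                            "type_share": total / grand if grand > 0 else np.nan,
                        }
                    )
    return pd.DataFrame(rows)
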