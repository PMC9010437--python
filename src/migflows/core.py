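"""Core data model for bilateral migration-flow estimation.

Holds the two input panels every estimator consumes — bilateral migrant
stocks by sex, birthplace and residence at five-year time points, and
per-country demographic components (populations, deaths, births, sex ratio
at birth) per five-year period — together with CSV I/O, country/period
harmonisation and the demographic derivations (sex-specific births, net
migration, native-born home-cell stocks) shared by all methods.

Conventions
-----------
* Country codes are opaque 3-letter strings (the study's country list
  includes non-ISO entities, so no ISO validation is attempted).
* Periods are labelled by their start year; a period spans [t, t+5).
  Time points are mid-year instants on the five-year grid.
* The sex ratio at birth (``srb``) is male births per female birth.
* Corridors absent from the input stock table are treated as stock 0
  (dense completion over the harmonised country set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("migflows")

#: sexes the estimators are run for
SEXES = ("female", "male")

#: the six estimation-method column keys used in the output files
METHOD_KEYS = (
    "sd_drop_neg",
    "sd_rev_neg",
    "mig_rate",
    "da_min_open",
    "da_min_closed",
    "da_pb_closed",
)

#: method columns whose estimates are integer counts
INTEGER_METHODS = ("sd_drop_neg", "sd_rev_neg")

#: length of an estimation period in years
PERIOD_LENGTH = 5

STOCK_COLUMNS = ["sex", "birthplace", "residence", "year", "stock"]
DEMO_COLUMNS = [
    "country",
    "period",
    "sex",
    "pop_start",
    "pop_end",
    "deaths",
    "births_total",
    "srb",
]


class ValidationError(ValueError):
    """An input table violates a schema invariant."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing columns {missing}")


@dataclass
class BilateralStockPanel:
    """Bilateral migrant stocks s_ij^t by sex, birthplace i and residence j.

    ``data`` is a long-format frame with columns
    ``sex, birthplace, residence, year, stock``.  Only foreign-born cells
    (birthplace != residence) are stored; native home cells are derivable
    from population totals via :func:`native_home_stock`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.data, STOCK_COLUMNS, "stock panel")
        df = self.data.loc[:, STOCK_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["stock"] = pd.to_numeric(df["stock"], errors="raise")
        if not np.isfinite(df["stock"].to_numpy()).all():
            raise ValidationError("stock panel contains non-finite stocks")
        neg = df.index[df["stock"] < 0]
        if len(neg):
            raise ValidationError(f"negative stock at row {neg[0]}")
        home = df.index[df["birthplace"] == df["residence"]]
        if len(home):
            raise ValidationError(
                f"home cell (birthplace == residence) at row {home[0]}; "
                "home cells are derived, not supplied"
            )
        keys = df[["sex", "birthplace", "residence", "year"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].to_dict()
            raise ValidationError(f"duplicate stock key {dup}")
        self.data = df.reset_index(drop=True)

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def sexes(self) -> list[str]:
        return sorted(self.data["sex"].unique())

    def countries(self, year: int | None = None) -> list[str]:
        """Codes appearing as birthplace or residence (optionally in one year)."""
        df = self.data if year is None else self.data[self.data["year"] == year]
        return sorted(set(df["birthplace"]) | set(df["residence"]))

    def matrix(self, sex: str, year: int, countries: list[str]) -> np.ndarray:
        """Dense birthplace x residence stock matrix over ``countries``.

        Missing corridors are 0; the diagonal (home cells) is 0.
        """
        idx = {c: i for i, c in enumerate(countries)}
        out = np.zeros((len(countries), len(countries)))
        sub = self.data[(self.data["sex"] == sex) & (self.data["year"] == year)]
        sub = sub[sub["birthplace"].isin(idx) & sub["residence"].isin(idx)]
        out[
            sub["birthplace"].map(idx).to_numpy(),
            sub["residence"].map(idx).to_numpy(),
        ] = sub["stock"].to_numpy()
        return out

    def subset(self, countries: list[str]) -> "BilateralStockPanel":
        keep = self.data["birthplace"].isin(countries) & self.data[
            "residence"
        ].isin(countries)
        return BilateralStockPanel(self.data[keep].reset_index(drop=True))


def combine_sexes(stocks: BilateralStockPanel, label: str = "total") -> BilateralStockPanel:
    """Sum the per-sex stocks into a single-'sex' panel (e.g. sex-aggregated runs)."""
    df = (
        stocks.data.groupby(["birthplace", "residence", "year"], as_index=False)["stock"]
        .sum()
        .assign(sex=label)
    )
    return BilateralStockPanel(df[STOCK_COLUMNS])


@dataclass
class DemographicPanel:
    """Per country, period and sex: populations, deaths, births and SRB.

    ``data`` columns: ``country, period, sex, pop_start, pop_end, deaths,
    births_total, srb`` plus, after :func:`derive_net_migration`, the derived
    ``births_sex`` and ``net_migration``.  ``births_total`` counts both sexes;
    ``srb`` is male births per female birth.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.data, DEMO_COLUMNS, "demographic panel")
        df = self.data.copy()
        df["period"] = df["period"].astype(int)
        for col in ("pop_start", "pop_end", "deaths", "births_total"):
            if (df[col] < 0).any():
                bad = df.loc[df[col] < 0].iloc[0]
                raise ValidationError(
                    f"negative {col} for {bad['country']} period {bad['period']}"
                )
        if (df["srb"] <= 0).any():
            bad = df.loc[df["srb"] <= 0].iloc[0]
            raise ValidationError(
                f"non-positive srb for {bad['country']} period {bad['period']}"
            )
        keys = df[["country", "period", "sex"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].to_dict()
            raise ValidationError(f"duplicate demographic key {dup}")
        self.data = df.reset_index(drop=True)

    @property
    def periods(self) -> list[int]:
        return sorted(self.data["period"].unique())

    def countries(self, period: int | None = None) -> list[str]:
        df = self.data if period is None else self.data[self.data["period"] == period]
        return sorted(df["country"].unique())

    def subset(self, panel: "CountryPanel") -> "DemographicPanel":
        parts = [
            self.data[
                (self.data["period"] == p) & (self.data["country"].isin(codes))
            ]
            for p, codes in panel.periods.items()
        ]
        return DemographicPanel(pd.concat(parts, ignore_index=True))

    def population(self, time_point: int, sex: str) -> pd.Series:
        """Population per country at a mid-year time point.

        Uses ``pop_start`` of the period starting at ``time_point`` when
        available, else ``pop_end`` of the preceding period.
        """
        df = self.data[self.data["sex"] == sex]
        start = df[df["period"] == time_point].set_index("country")["pop_start"]
        prev = df[df["period"] == time_point - PERIOD_LENGTH].set_index("country")[
            "pop_end"
        ]
        pop = start.combine_first(prev)
        if pop.empty:
            raise ValidationError(
                f"no population data at time point {time_point} for sex {sex}"
            )
        return pop


@dataclass
class CountryPanel:
    """Ordered country lists active in each period (period start year -> codes)."""

    periods: dict[int, list[str]]

    def __post_init__(self) -> None:
        for p, codes in self.periods.items():
            if len(set(codes)) != len(codes):
                raise ValidationError(f"duplicate country codes in period {p}")
            self.periods[p] = sorted(codes)

    def n_corridor_cells(self) -> int:
        """Origin x destination x period key-space size (includes orig == dest)."""
        return sum(len(c) ** 2 for c in self.periods.values())

    def n_country_periods(self) -> int:
        return sum(len(c) for c in self.periods.values())


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_stocks(path) -> BilateralStockPanel:
    """Read a bilateral stock CSV (columns sex, birthplace|orig, residence, year, stock)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed stock CSV {path}: {exc}") from exc
    if "orig" in df.columns and "birthplace" not in df.columns:
        df = df.rename(columns={"orig": "birthplace"})
    return BilateralStockPanel(df)


def write_stocks(stocks: BilateralStockPanel, path) -> None:
    stocks.data.to_csv(path, index=False)


def read_demographics(path) -> DemographicPanel:
    """Read a demographic CSV (country, period|period_start, sex, pop_start, ...)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"malformed demographic CSV {path}: {exc}") from exc
    if "period_start" in df.columns and "period" not in df.columns:
        df = df.rename(columns={"period_start": "period"})
    return DemographicPanel(df)


def write_demographics(demo: DemographicPanel, path) -> None:
    df = demo.data.rename(columns={"period": "period_start"})
    df.to_csv(path, index=False)


def read_country_list(path) -> pd.DataFrame:
    """Read a code,name country list CSV."""
    df = pd.read_csv(path)
    _require_columns(df, ["code", "name"], "country list")
    return df


# ---------------------------------------------------------------------------
# Harmonisation
# ---------------------------------------------------------------------------

def harmonize(
    stocks: BilateralStockPanel, demo: DemographicPanel
) -> tuple[BilateralStockPanel, DemographicPanel, CountryPanel]:
    """Clean both inputs to a common set of countries in each period.

    A country is retained in period [t, t+5) when it appears in the stock
    table at both time points and in the demographic panel for the period.
    Countries whose bilateral stocks are all zero at either time point are
    dropped (they make several estimators degenerate), with a log message
    per drop.
    """
    stock_years = set(stocks.years)
    periods = [
        p for p in demo.periods if p in stock_years and p + PERIOD_LENGTH in stock_years
    ]
    if not periods:
        raise ValidationError("no period is covered by both stocks and demographics")

    kept: dict[int, list[str]] = {}
    for p in periods:
        t0, t1 = p, p + PERIOD_LENGTH
        present = set(stocks.countries(t0)) & set(stocks.countries(t1))
        in_demo = set(demo.countries(p))
        keep = present & in_demo
        if not keep:
            raise ValidationError(f"no common countries for period {p}")
        for year in (t0, t1):
            sub = stocks.data[stocks.data["year"] == year]
            totals = {c: 0.0 for c in keep}
            for col in ("birthplace", "residence"):
                agg = sub.groupby(col)["stock"].sum()
                for c in keep & set(agg.index):
                    totals[c] += agg[c]
            all_zero = {c for c, tot in totals.items() if tot == 0}
            for c in sorted(all_zero):
                logger.warning(
                    "dropping %s from period %d: all bilateral stocks zero at %d",
                    c,
                    p,
                    year,
                )
            keep -= all_zero
        if not keep:
            raise ValidationError(f"no usable countries for period {p}")
        kept[p] = sorted(keep)

    panel = CountryPanel(kept)

    # a stock year serves the period starting there and the one ending there
    year_codes: dict[int, set[str]] = {}
    for p, codes in panel.periods.items():
        for year in (p, p + PERIOD_LENGTH):
            year_codes.setdefault(year, set()).update(codes)
    keep_rows = pd.Series(False, index=stocks.data.index)
    for year, codes in year_codes.items():
        sub = stocks.data["year"] == year
        keep_rows |= (
            sub
            & stocks.data["birthplace"].isin(codes)
            & stocks.data["residence"].isin(codes)
        )
    stocks_h = BilateralStockPanel(stocks.data[keep_rows].reset_index(drop=True))
    demo_h = demo.subset(panel)
    return stocks_h, demo_h, panel


# ---------------------------------------------------------------------------
# Demographic derivations
# ---------------------------------------------------------------------------

def split_births_by_sex(births_total, srb):
    """Split total births into (female, male) using the sex ratio at birth.

    male = births_total * srb / (1 + srb); female is the remainder, so the
    two always sum exactly to ``births_total``.
    """
    births_total = np.asarray(births_total, dtype=float)
    srb = np.asarray(srb, dtype=float)
    if np.any(srb <= 0):
        raise ValidationError("sex ratio at birth must be positive")
    male = births_total * srb / (1.0 + srb)
    female = births_total - male
    return female, male


def derive_net_migration(demo: DemographicPanel) -> DemographicPanel:
    """Add sex-specific births and accounting-equation net migration.

    net_migration = pop_end - pop_start - births_sex + deaths, per country,
    period and sex.
    """
    df = demo.data.copy()
    for col in ("pop_start", "pop_end", "deaths", "births_total", "srb"):
        if df[col].isna().any():
            bad = df.loc[df[col].isna()].iloc[0]
            raise ValidationError(
                f"missing {col} for {bad['country']} period {bad['period']} "
                f"sex {bad['sex']}"
            )
    female, male = split_births_by_sex(df["births_total"], df["srb"])
    df["births_sex"] = np.where(df["sex"] == "male", male, female)
    df["net_migration"] = (
        df["pop_end"] - df["pop_start"] - df["births_sex"] + df["deaths"]
    )
    return DemographicPanel(df)


def native_home_stock(
    stocks: BilateralStockPanel,
    demo: DemographicPanel,
    time_point: int,
    countries: list[str] | None = None,
) -> pd.DataFrame:
    """Native-born home-cell stocks s_kk at a time point, per sex.

    s_kk = population of k minus its foreign-born residents.  A negative
    value signals inconsistent inputs; it is clamped to 0 with a warning
    rather than aborting a batch run.

    Returns a frame with columns ``sex, country, stock``.
    """
    rows = []
    for sex in sorted(set(stocks.sexes) & set(demo.data["sex"].unique())):
        pop = demo.population(time_point, sex)
        codes = countries if countries is not None else sorted(pop.index)
        sub = stocks.data[
            (stocks.data["sex"] == sex)
            & (stocks.data["year"] == time_point)
            & stocks.data["birthplace"].isin(codes)
        ]
        foreign_in = sub.groupby("residence")["stock"].sum()
        for c in codes:
            if c not in pop.index:
                raise ValidationError(
                    f"no population for {c} at time point {time_point} (sex {sex})"
                )
            home = pop[c] - foreign_in.get(c, 0.0)
            if home < 0:
                logger.warning(
                    "negative native home stock for %s at %d (sex %s): "
                    "%.1f clamped to 0",
                    c,
                    time_point,
                    sex,
                    home,
                )
                home = 0.0
            rows.append({"sex": sex, "country": c, "stock": home})
    return pd.DataFrame(rows, columns=["sex", "country", "stock"])
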