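"""Synthetic migration worlds with known true flows.

The real inputs to the estimators — sex-specific bilateral migrant stocks
and demographic components — come from large external compilations that are
not bundled here.  This module generates small worlds with the same
statistical structure so every estimator and validation routine can be
exercised against a known ground truth:

* true five-year flows are sampled first (log-normal gravity-like
  intensities), and the stocks are propagated from them, so transition-based
  estimators have an unambiguous target;
* populations, births, deaths and stocks satisfy the demographic accounting
  equation exactly by construction, for every country, period and sex;
* deaths are removed proportionally over birthplace within the country of
  residence at the start of the period — the same allocation the accounting
  estimators assume — so closed-system recovery is clean.  The
  ``perturb_mortality`` flag applies mortality after migration instead, to
  stress-test that assumption;
* births are added to the home cell of the birth country and are split into
  sexes by the sampled sex ratio at birth.

Within a period, events therefore unfold as deaths -> moves -> births.
All randomness flows from one master seed via independent streams per
(sex, period), so identical configs give identical worlds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    PERIOD_LENGTH,
    SEXES,
    STOCK_COLUMNS,
    BilateralStockPanel,
    DemographicPanel,
    ValidationError,
)

TRUE_FLOW_COLUMNS = ["sex", "orig", "dest", "period", "flow"]

# stream tags keeping the per-purpose RNG streams disjoint
_INIT_STREAM, _FLOW_STREAM, _VITAL_STREAM = 3, 7, 11


@dataclass
class WorldConfig:
    """Configuration of a synthetic world.

    Rates are per five-year period.  ``migration_intensity`` is the expected
    fraction of a country's residents who move abroad during a period;
    ``flow_sigma`` is the log-scale spread of the gravity-like corridor
    weights.  ``initial_foreign_share`` sets the foreign-born fraction of
    each country at the first time point.
    """

    n_countries: int = 10
    n_periods: int = 3
    seed: int = 42
    start_year: int = 1990
    base_pop_range: tuple[float, float] = (500_000.0, 5_000_000.0)
    migration_intensity: float = 0.02
    birth_rate: float = 0.11
    death_rate: float = 0.08
    srb_range: tuple[float, float] = (1.03, 1.07)
    initial_foreign_share: float = 0.05
    flow_sigma: float = 0.8
    perturb_mortality: bool = False

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ValidationError("need at least 2 countries")
        if self.n_periods < 1:
            raise ValidationError("need at least 1 period")
        for name in ("migration_intensity", "birth_rate", "death_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValidationError(f"{name} must lie in [0, 1)")
        if self.base_pop_range[0] <= 0 or self.base_pop_range[1] < self.base_pop_range[0]:
            raise ValidationError("base_pop_range must be a positive interval")
        if self.srb_range[0] <= 0 or self.srb_range[1] < self.srb_range[0]:
            raise ValidationError("srb_range must be a positive interval")
        if not 0.0 <= self.initial_foreign_share < 0.5:
            raise ValidationError("initial_foreign_share must lie in [0, 0.5)")

    @property
    def countries(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_countries)]

    @property
    def time_points(self) -> list[int]:
        return [
            self.start_year + PERIOD_LENGTH * i for i in range(self.n_periods + 1)
        ]


def _move_probabilities(cfg: WorldConfig, rng: np.random.Generator, attract: np.ndarray) -> np.ndarray:
    """Per-origin move probabilities p[i, j], rows summing to migration_intensity."""
    n = cfg.n_countries
    w = attract[None, :] * rng.lognormal(0.0, cfg.flow_sigma, size=(n, n))
    np.fill_diagonal(w, 0.0)
    if cfg.migration_intensity == 0.0 or n == 1:
        return np.zeros((n, n))
    return cfg.migration_intensity * w / w.sum(axis=1, keepdims=True)


def generate_world(
    cfg: WorldConfig,
) -> tuple[BilateralStockPanel, DemographicPanel, pd.DataFrame]:
    """Simulate a world and return (stocks, demographics, true flows).

    The true-flow frame has columns ``sex, orig, dest, period, flow``.
    """
    n = cfg.n_countries
    codes = cfg.countries
    rng0 = np.random.default_rng([cfg.seed, _INIT_STREAM])

    # initial resident-by-birthplace matrices S[k (birthplace), j (residence)]
    pop = rng0.uniform(*cfg.base_pop_range, size=n)
    female_share = rng0.uniform(0.49, 0.51, size=n)
    attract = rng0.lognormal(0.0, 0.5, size=n)
    diaspora_w = pop * rng0.lognormal(0.0, 0.5, size=n)

    state: dict[str, np.ndarray] = {}
    for s_idx, sex in enumerate(SEXES):
        pop_sex = pop * (female_share if sex == "female" else 1.0 - female_share)
        S = np.zeros((n, n))
        for j in range(n):
            foreign = cfg.initial_foreign_share * pop_sex[j]
            w = diaspora_w.copy()
            w[j] = 0.0
            if w.sum() > 0 and foreign > 0:
                S[:, j] = foreign * w / w.sum()
            S[j, j] = pop_sex[j] - S[:, j].sum()
        state[sex] = S

    stock_rows: list[pd.DataFrame] = []
    demo_rows: list[dict] = []
    flow_rows: list[pd.DataFrame] = []

    def emit_stocks(year: int) -> None:
        for sex in SEXES:
            S = state[sex]
            k, j = np.nonzero(~np.eye(n, dtype=bool))
            stock_rows.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "birthplace": np.array(codes)[k],
                        "residence": np.array(codes)[j],
                        "year": year,
                        "stock": S[k, j],
                    }
                )
            )

    emit_stocks(cfg.time_points[0])

    oi, di = np.nonzero(~np.eye(n, dtype=bool))
    for p_idx, year in enumerate(cfg.time_points[:-1]):
        vital = np.random.default_rng([cfg.seed, _VITAL_STREAM, p_idx])
        srb = vital.uniform(*cfg.srb_range, size=n)
        birth_rate = cfg.birth_rate * vital.uniform(0.9, 1.1, size=n)
        death_rate = cfg.death_rate * vital.uniform(0.9, 1.1, size=n)

        pop_start = {sex: state[sex].sum(axis=0) for sex in SEXES}
        births_total = birth_rate * (pop_start["female"] + pop_start["male"])
        births_male = births_total * srb / (1.0 + srb)
        births = {"female": births_total - births_male, "male": births_male}

        for s_idx, sex in enumerate(SEXES):
            rng = np.random.default_rng([cfg.seed, _FLOW_STREAM, p_idx, s_idx])
            S = state[sex]
            deaths = death_rate * pop_start[sex]
            if np.any(deaths > pop_start[sex]):
                raise ValidationError(
                    f"death rate drains a country negative in period {year}"
                )

            if not cfg.perturb_mortality:
                S = S * (1.0 - death_rate)[None, :]

            prob = _move_probabilities(cfg, rng, attract)
            # moved[k, i, j]: k-born residents moving i -> j
            moved = S[:, :, None] * prob[None, :, :]
            S = S - moved.sum(axis=2) + moved.sum(axis=1)
            flows = moved.sum(axis=0)  # corridor totals over birthplaces

            if cfg.perturb_mortality:
                col = S.sum(axis=0)
                scale = np.divide(
                    col - deaths, col, out=np.ones_like(col), where=col > 0
                )
                S = S * scale[None, :]

            S[np.arange(n), np.arange(n)] += births[sex]
            state[sex] = S

            flow_rows.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "orig": np.array(codes)[oi],
                        "dest": np.array(codes)[di],
                        "period": year,
                        "flow": flows[oi, di],
                    }
                )
            )
            pop_end = S.sum(axis=0)
            for c in range(n):
                demo_rows.append(
                    {
                        "country": codes[c],
                        "period": year,
                        "sex": sex,
                        "pop_start": pop_start[sex][c],
                        "pop_end": pop_end[c],
                        "deaths": deaths[c],
                        "births_total": births_total[c],
                        "srb": srb[c],
                    }
                )
        emit_stocks(year + PERIOD_LENGTH)

    stocks = BilateralStockPanel(
        pd.concat(stock_rows, ignore_index=True)[STOCK_COLUMNS]
    )
    demo = DemographicPanel(pd.DataFrame(demo_rows))
    true_flows = pd.concat(flow_rows, ignore_index=True)[TRUE_FLOW_COLUMNS]
    return stocks, demo, true_flows


def puerto_rico_fixture() -> tuple[BilateralStockPanel, DemographicPanel]:
    """Two-country fixture embedding the documented 2010-2015 corridor changes.

    The Puerto Rico -> USA stock changes are real reported values: the total
    corridor stock fell by 15,028 while the female stock fell by 119,357 and
    the male stock rose by 104,329 — opposite-signed sex-specific changes
    that make stock differencing of the total disagree with the sum of the
    sex-specific estimates.  Stock levels, the reverse corridor and the
    demographic panel are synthetic but plausibly scaled.
    """
    rows = [
        # sex, birthplace, residence, year, stock
        ("female", "PRI", "USA", 2010, 1_700_000),
        ("female", "PRI", "USA", 2015, 1_700_000 - 119_357),
        ("male", "PRI", "USA", 2010, 1_500_000),
        ("male", "PRI", "USA", 2015, 1_500_000 + 104_329),
        ("female", "USA", "PRI", 2010, 110_000),
        ("female", "USA", "PRI", 2015, 110_000),
        ("male", "USA", "PRI", 2010, 100_000),
        ("male", "USA", "PRI", 2015, 100_000),
    ]
    stocks = BilateralStockPanel(pd.DataFrame(rows, columns=STOCK_COLUMNS))
    demo_rows = [
        # country, period, sex, pop_start, pop_end, deaths, births_total, srb
        ("PRI", 2010, "female", 1_920_000, 1_790_000, 80_000, 180_000, 1.05),
        ("PRI", 2010, "male", 1_800_000, 1_680_000, 85_000, 180_000, 1.05),
        ("USA", 2010, "female", 157_000_000, 160_500_000, 6_300_000, 19_800_000, 1.05),
        ("USA", 2010, "male", 152_000_000, 155_600_000, 6_500_000, 19_800_000, 1.05),
    ]
    demo = DemographicPanel(
        pd.DataFrame(
            demo_rows,
            columns=[
                "country",
                "period",
                "sex",
                "pop_start",
                "pop_end",
                "deaths",
                "births_total",
                "srb",
            ],
        )
    )
    return stocks, demo
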