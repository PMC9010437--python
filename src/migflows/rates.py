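"""Migration-rates flow estimator.

Allocates an (unobserved) global total of migrant flows proportionally to
the bilateral stock pattern at the start of the period:

    flow i->j = (s_ij^t / sum_hk s_hk^t) * G

where the global total G is approximated by the sum over countries of the
absolute net migration flows derived from the demographic accounting
equation.  Both G and the allocation are computed per sex.

Whether each mover should count once or twice in the sum of absolute nets
(every move adds to one positive and one negative net) is left open by the
method's description; the formula is implemented as stated, with a
``halve_total`` switch for the halved variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import BilateralStockPanel, DemographicPanel, ValidationError


def global_total(
    demo: DemographicPanel, period: int, sex: str, halve_total: bool = False
) -> float:
    """Global flow total G = sum over countries of |net migration|."""
    if "net_migration" not in demo.data.columns:
        raise ValidationError(
            "net_migration not derived; run derive_net_migration first"
        )
    sub = demo.data[(demo.data["period"] == period) & (demo.data["sex"] == sex)]
    if sub.empty or sub["net_migration"].isna().any():
        raise ValidationError(f"missing net migration for period {period} sex {sex}")
    G = float(np.abs(sub["net_migration"].to_numpy()).sum())
    return G / 2.0 if halve_total else G


def rate_allocate(
    stocks: BilateralStockPanel,
    period: int,
    sex: str,
    G: float,
    countries: list[str],
) -> pd.DataFrame:
    """Allocate G over corridors proportionally to start-of-period stocks.

    The denominator is the sum of all bilateral foreign-born stocks at the
    period start over the harmonised country set (home cells excluded).
    Returns a flow table with column ``mig_rate``.
    """
    if G < 0:
        raise ValidationError("global flow total must be non-negative")
    s = stocks.matrix(sex, period, countries)
    np.fill_diagonal(s, 0.0)
    total = s.sum()
    if total == 0 and G > 0:
        raise ValidationError(
            f"all start-of-period stocks are zero in period {period} (sex {sex}); "
            "proportional allocation is undefined"
        )
    flow = s / total * G if total > 0 else np.zeros_like(s)
    n = len(countries)
    i, j = np.nonzero(~np.eye(n, dtype=bool))
    return pd.DataFrame(
        {
            "sex": sex,
            "orig": np.array(countries)[i],
            "dest": np.array(countries)[j],
            "period": period,
            "mig_rate": flow[i, j],
        }
    )


def estimate_rates(
    stocks: BilateralStockPanel,
    demo: DemographicPanel,
    period: int,
    countries: list[str],
    halve_total: bool = False,
) -> pd.DataFrame:
    """Run the rates estimator for every sex in one period."""
    parts = [
        rate_allocate(
            stocks, period, sex, global_total(demo, period, sex, halve_total), countries
        )
        for sex in stocks.sexes
        if sex in set(demo.data["sex"])
    ]
    return pd.concat(parts, ignore_index=True)
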