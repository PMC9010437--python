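"""Stock-differencing flow estimators.

The simplest way to turn two bilateral migrant-stock tables into a flow
estimate is to difference them: y_ij = s_ij^{t+1} - s_ij^t, where i is the
birthplace (taken as origin) and j the residence (taken as destination).
Differences can be negative, and the two estimators here differ only in how
they treat that sign:

* ``drop_negative``  — negative differences are set to zero (``sd_drop_neg``);
* ``reverse_negative`` — a negative difference i->j is re-read as a return
  flow j->i of the same size, added to any positive difference already on
  that corridor (``sd_rev_neg``).  Simultaneous positive y_ij and negative
  y_ji are summed, not netted.

Both operate on the bilateral table alone: no demographic data enters, and
flows are reported only for ordered pairs of the harmonised country set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PERIOD_LENGTH, BilateralStockPanel, ValidationError


@dataclass
class StockDiffTable:
    """Signed stock differences per (sex, birthplace, residence, period).

    Columns: ``sex, birthplace, residence, period, diff``; ``countries``
    records the dense corridor grid the differences cover.
    """

    data: pd.DataFrame
    countries: list[str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.data["diff"].to_numpy()).all():
            raise ValidationError("non-finite stock difference")
        keys = self.data[["sex", "birthplace", "residence", "period"]]
        if keys.duplicated().any():
            raise ValidationError("duplicate keys in stock-difference table")

    def matrix(self, sex: str, period: int) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.countries)}
        out = np.zeros((len(idx), len(idx)))
        sub = self.data[(self.data["sex"] == sex) & (self.data["period"] == period)]
        out[
            sub["birthplace"].map(idx).to_numpy(),
            sub["residence"].map(idx).to_numpy(),
        ] = sub["diff"].to_numpy()
        return out


def difference_stocks(
    stocks: BilateralStockPanel,
    period: int,
    countries: list[str] | None = None,
) -> StockDiffTable:
    """End-of-period minus start-of-period stocks per corridor and sex.

    The table is dense over ``countries`` (missing corridors count as stock
    0); home cells are excluded.
    """
    t0, t1 = period, period + PERIOD_LENGTH
    years = set(stocks.years)
    if t0 not in years or t1 not in years:
        raise ValidationError(
            f"stocks missing at an endpoint of period {period} ({t0} or {t1})"
        )
    if countries is None:
        countries = sorted(
            set(stocks.countries(t0)) & set(stocks.countries(t1))
        )
    n = len(countries)
    off = ~np.eye(n, dtype=bool)
    k, j = np.nonzero(off)
    frames = []
    for sex in stocks.sexes:
        diff = stocks.matrix(sex, t1, countries) - stocks.matrix(sex, t0, countries)
        frames.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "birthplace": np.array(countries)[k],
                    "residence": np.array(countries)[j],
                    "period": period,
                    "diff": diff[k, j],
                }
            )
        )
    return StockDiffTable(pd.concat(frames, ignore_index=True), list(countries))


def drop_negative(diffs: StockDiffTable) -> pd.DataFrame:
    """Flows with negative differences set to zero (column ``sd_drop_neg``)."""
    df = diffs.data.rename(columns={"birthplace": "orig", "residence": "dest"})
    out = df[["sex", "orig", "dest", "period"]].copy()
    out["sd_drop_neg"] = np.maximum(df["diff"].to_numpy(), 0.0)
    return out


def reverse_negative(diffs: StockDiffTable) -> pd.DataFrame:
    """Flows with negative differences reversed as return flows (``sd_rev_neg``).

    flow i->j = max(diff_ij, 0) + max(-diff_ji, 0).
    """
    n = len(diffs.countries)
    k, j = np.nonzero(~np.eye(n, dtype=bool))
    frames = []
    for (sex, period), _ in diffs.data.groupby(["sex", "period"], sort=True):
        d = diffs.matrix(sex, period)
        flow = np.maximum(d, 0.0) + np.maximum(-d.T, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "orig": np.array(diffs.countries)[k],
                    "dest": np.array(diffs.countries)[j],
                    "period": period,
                    "sd_rev_neg": flow[k, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
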