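"""Demographic-accounting flow estimators.

These estimators embed the two stock tables bounding a period into a
birthplace-specific origin-destination flow array y_ijk (origin i,
destination j, birthplace k, with stayers on the diagonal y_iik) and impute
its cells subject to margin constraints:

* the stocks at the *start* of the period, adjusted for deaths, give the
  outflow margins (row sums over destinations) for each birthplace;
* the stocks at the *end* of the period, adjusted for births, give the
  inflow margins (column sums over origins).

Adjustment subtracts each country's period deaths from its start-of-period
residents, allocated proportionally over birthplace (mortality assumed
birthplace-neutral), and subtracts its sex-specific births from the
end-of-period native home cell (newborns assumed non-migrant within the
period).

Per birthplace the two margin totals need not agree.  The *open* system
absorbs the discrepancy with an extra outside origin/destination (OUT); the
*closed* system scales both tables to the mid-point of their totals, which
constrains the implied bilateral flows to sum to each country's net
migration from the accounting equation.

Imputation comes in two flavours:

* minimisation — stayers y_iik are first set to their maximum feasible
  value min(row_i, col_i), minimising total migration, then off-diagonal
  cells are fitted by iterative proportional fitting (IPF) under a
  quasi-independent log-linear model with the diagonal held fixed;
* independent — all cells, diagonal included, follow the independence fit
  row_i * col_j / total (the closed form of the IPF limit with full
  margins).

The pseudo-Bayesian estimator is a cellwise weighted combination of the
two, with weight 0.87 on the minimisation imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    PERIOD_LENGTH,
    BilateralStockPanel,
    DemographicPanel,
    ValidationError,
    native_home_stock,
    split_births_by_sex,
)

logger = logging.getLogger("migflows")

#: default absolute IPF margin tolerance, in persons
IPF_TOL = 1e-6
IPF_MAX_ITER = 1000

#: pseudo-Bayesian weight on the minimisation imputation
PB_WEIGHT = 0.87

MOVE_TYPES = ("outward", "return", "transit")


@dataclass
class PseudoBayesConfig:
    """Weights of the pseudo-Bayesian combination (w1 on minimisation)."""

    w1: float = PB_WEIGHT

    def __post_init__(self) -> None:
        if not 0.0 <= self.w1 <= 1.0:
            raise ValidationError("pseudo-Bayes weight must lie in [0, 1]")

    @property
    def w2(self) -> float:
        return 1.0 - self.w1


@dataclass
class AdjustedStockPair:
    """Margin pairs per birthplace for one sex and period.

    ``row[k, i]`` — adjusted start-of-period stock of k-born residents of i
    (outflow margin of origin i for birthplace k); ``col[k, j]`` — adjusted
    end-of-period stock (inflow margin of destination j).  ``out_row`` /
    ``out_col`` hold the per-birthplace OUT-origin / OUT-destination margins
    after :func:`balance_open`.
    """

    sex: str
    period: int
    countries: list[str]
    row: np.ndarray
    col: np.ndarray
    out_row: np.ndarray | None = None
    out_col: np.ndarray | None = None

    @property
    def has_out(self) -> bool:
        return self.out_row is not None

    def margins(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Full (row, col) margin vectors for birthplace index k, OUT last."""
        r, c = self.row[k], self.col[k]
        if self.has_out:
            r = np.append(r, self.out_row[k])
            c = np.append(c, self.out_col[k])
        return r, c


@dataclass
class BirthplaceFlowArray:
    """Imputed y_ijk array for one sex and period.

    ``array`` has shape (m, m, n) with m = n countries (+1 when ``has_out``,
    the OUT origin/destination occupying the last index of the first two
    axes).  The birthplace axis always covers the n real countries.
    """

    sex: str
    period: int
    countries: list[str]
    array: np.ndarray
    has_out: bool = False

    def total_migration(self) -> float:
        """Total off-diagonal mass (migrants of any birthplace and corridor)."""
        m = self.array.shape[0]
        off = ~np.eye(m, dtype=bool)
        return float(self.array[off].sum())


# ---------------------------------------------------------------------------
# Stock adjustment and balancing
# ---------------------------------------------------------------------------

def adjust_stocks(
    stocks: BilateralStockPanel,
    demo: DemographicPanel,
    period: int,
    sex: str,
    countries: list[str],
) -> AdjustedStockPair:
    """Demographically adjusted start/end stock tables with home cells.

    Deaths are subtracted from the start table proportionally over
    birthplace within each residence; sex-specific births are subtracted
    from the end table's native home cells.  Negative cells are clamped to
    zero with a warning.
    """
    t0, t1 = period, period + PERIOD_LENGTH
    n = len(countries)

    def full_matrix(year: int) -> np.ndarray:
        S = stocks.matrix(sex, year, countries)
        home = native_home_stock(stocks, demo, year, countries)
        home = home[home["sex"] == sex].set_index("country")["stock"]
        S[np.arange(n), np.arange(n)] = home.reindex(countries).to_numpy()
        return S

    S0, S1 = full_matrix(t0), full_matrix(t1)

    sub = demo.data[(demo.data["period"] == period) & (demo.data["sex"] == sex)]
    sub = sub.set_index("country")
    missing = [c for c in countries if c not in sub.index]
    if missing:
        raise ValidationError(
            f"no demographic components for {missing[0]} in period {period} (sex {sex})"
        )
    deaths = sub["deaths"].reindex(countries).to_numpy(dtype=float)
    if "births_sex" in sub.columns:
        births = sub["births_sex"].reindex(countries).to_numpy(dtype=float)
    else:
        f, m = split_births_by_sex(
            sub["births_total"].reindex(countries), sub["srb"].reindex(countries)
        )
        births = m if sex == "male" else f

    col_tot = S0.sum(axis=0)
    scale = np.ones(n)
    for j in range(n):
        if deaths[j] > col_tot[j]:
            logger.warning(
                "deaths (%.1f) exceed residents (%.1f) in %s, period %d, sex %s; "
                "start stocks clamped to 0",
                deaths[j],
                col_tot[j],
                countries[j],
                period,
                sex,
            )
            scale[j] = 0.0
        elif col_tot[j] > 0:
            scale[j] = (col_tot[j] - deaths[j]) / col_tot[j]
    S0 = S0 * scale[None, :]

    diag = S1[np.arange(n), np.arange(n)] - births
    for k in range(n):
        if diag[k] < 0:
            logger.warning(
                "births exceed end-of-period home stock for %s, period %d, sex %s; "
                "cell clamped to 0 (deficit %.1f)",
                countries[k],
                period,
                sex,
                -diag[k],
            )
            diag[k] = 0.0
    S1[np.arange(n), np.arange(n)] = diag

    # row[k, i]: k-born residing i at start -> outflow margin of origin i
    return AdjustedStockPair(sex, period, list(countries), S0, S1)


def balance_open(pair: AdjustedStockPair) -> AdjustedStockPair:
    """Absorb per-birthplace margin discrepancies into an OUT origin/destination.

    For birthplace k with row total R and column total C, the OUT origin
    receives margin max(0, C - R) and the OUT destination max(0, R - C);
    the OUT x OUT cell is structurally zero, so the extended totals balance
    exactly.
    """
    R = pair.row.sum(axis=1)
    C = pair.col.sum(axis=1)
    return AdjustedStockPair(
        pair.sex,
        pair.period,
        pair.countries,
        pair.row.copy(),
        pair.col.copy(),
        out_row=np.maximum(0.0, C - R),
        out_col=np.maximum(0.0, R - C),
    )


def balance_closed(pair: AdjustedStockPair) -> AdjustedStockPair:
    """Scale both margin tables to the mid-point of their totals per birthplace.

    With totals R and C, the target is T = (R + C) / 2: start margins are
    scaled by T/R and end margins by T/C, after which both total exactly T.
    """
    row = pair.row.copy()
    col = pair.col.copy()
    R = row.sum(axis=1)
    C = col.sum(axis=1)
    for k, (r_tot, c_tot) in enumerate(zip(R, C)):
        if r_tot == 0 and c_tot == 0:
            continue
        if r_tot == 0 or c_tot == 0:
            raise ValidationError(
                f"cannot close birthplace {pair.countries[k]} in period "
                f"{pair.period} (sex {pair.sex}): one margin total is zero "
                f"(start {r_tot}, end {c_tot})"
            )
        target = (r_tot + c_tot) / 2.0
        row[k] *= target / r_tot
        col[k] *= target / c_tot
    return AdjustedStockPair(pair.sex, pair.period, pair.countries, row, col)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def ipf(
    seed: np.ndarray,
    row_targets: np.ndarray,
    col_targets: np.ndarray,
    tol: float = IPF_TOL,
    max_iter: int = IPF_MAX_ITER,
) -> np.ndarray:
    """Iterative proportional fitting of a non-negative seed to target margins.

    Structural zeros are encoded as zero seed cells.  Convergence requires
    the maximum absolute deviation of both margins to fall below ``tol``
    (absolute, persons).
    """
    if abs(row_targets.sum() - col_targets.sum()) > max(
        tol, 1e-9 * max(row_targets.sum(), 1.0)
    ):
        raise ValidationError(
            "IPF margin totals disagree "
            f"({row_targets.sum():.6f} vs {col_targets.sum():.6f})"
        )
    M = seed.astype(float).copy()
    for _ in range(max_iter):
        rs = M.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            M *= np.where(rs > 0, row_targets / np.where(rs > 0, rs, 1.0), 0.0)[:, None]
        cs = M.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            M *= np.where(cs > 0, col_targets / np.where(cs > 0, cs, 1.0), 0.0)[None, :]
        dev = max(
            np.abs(M.sum(axis=1) - row_targets).max(),
            np.abs(M.sum(axis=0) - col_targets).max(),
        )
        if dev < tol:
            return M
    raise ValidationError(
        f"IPF did not converge in {max_iter} sweeps "
        f"(worst margin deviation {dev:.3e})"
    )


def impute_min(
    pair: AdjustedStockPair,
    tol: float = IPF_TOL,
    max_iter: int = IPF_MAX_ITER,
) -> BirthplaceFlowArray:
    """Two-stage minimisation imputation of the y_ijk array.

    Stage 1 fixes each stayer cell y_iik at its maximum feasible value
    min(row_i, col_i) — jointly feasible because after it every index has a
    zero residual on at least one margin.  Stage 2 fits the off-diagonal
    cells by IPF (flat seed of 1 in permitted cells, diagonal excluded) to
    the residual margins.
    """
    n = len(pair.countries)
    m = n + 1 if pair.has_out else n
    array = np.zeros((m, m, n))
    off_seed = 1.0 - np.eye(m)
    for k in range(n):
        r, c = pair.margins(k)
        d = np.minimum(r, c)
        M = ipf(off_seed, r - d, c - d, tol=tol, max_iter=max_iter)
        M[np.arange(m), np.arange(m)] = d
        array[:, :, k] = M
    return BirthplaceFlowArray(
        pair.sex, pair.period, list(pair.countries), array, pair.has_out
    )


def impute_indep(pair: AdjustedStockPair) -> BirthplaceFlowArray:
    """Independence imputation y_ijk = row_i * col_j / total, diagonal included.

    This is the closed form of the IPF limit under an independent
    log-linear model constrained only by the row and column margins.
    """
    n = len(pair.countries)
    m = n + 1 if pair.has_out else n
    array = np.zeros((m, m, n))
    for k in range(n):
        r, c = pair.margins(k)
        total = r.sum()
        if total > 0:
            array[:, :, k] = np.outer(r, c) / total
    return BirthplaceFlowArray(
        pair.sex, pair.period, list(pair.countries), array, pair.has_out
    )


def pseudo_bayes(
    arr_min: BirthplaceFlowArray,
    arr_indep: BirthplaceFlowArray,
    cfg: PseudoBayesConfig | None = None,
) -> BirthplaceFlowArray:
    """Cellwise weighted combination w1 * minimisation + w2 * independent."""
    cfg = cfg or PseudoBayesConfig()
    if arr_min.array.shape != arr_indep.array.shape:
        raise ValidationError(
            f"shape mismatch {arr_min.array.shape} vs {arr_indep.array.shape}"
        )
    return BirthplaceFlowArray(
        arr_min.sex,
        arr_min.period,
        list(arr_min.countries),
        cfg.w1 * arr_min.array + cfg.w2 * arr_indep.array,
        arr_min.has_out,
    )


# ---------------------------------------------------------------------------
# Flow extraction
# ---------------------------------------------------------------------------

def flows_from_array(arr: BirthplaceFlowArray, method_key: str) -> pd.DataFrame:
    """Bilateral flows: sum y_ijk over birthplace, off-diagonal, OUT excluded."""
    n = len(arr.countries)
    flow = arr.array[:n, :n, :].sum(axis=2)
    i, j = np.nonzero(~np.eye(n, dtype=bool))
    return pd.DataFrame(
        {
            "sex": arr.sex,
            "orig": np.array(arr.countries)[i],
            "dest": np.array(arr.countries)[j],
            "period": arr.period,
            method_key: flow[i, j],
        }
    )


def move_type_decompose(arr: BirthplaceFlowArray, method_key: str) -> pd.DataFrame:
    """Split each corridor's flow into outward, return and transit moves.

    outward: birthplace = origin; return: birthplace = destination;
    transit: any other birthplace.  The three parts partition the corridor
    total exactly.
    """
    n = len(arr.countries)
    a = arr.array[:n, :n, :]
    total = a.sum(axis=2)
    outward = a.diagonal(axis1=0, axis2=2).T  # y_ij,k=i
    ret = a.diagonal(axis1=1, axis2=2)  # y_ij,k=j
    transit = total - outward - ret
    i, j = np.nonzero(~np.eye(n, dtype=bool))
    frames = []
    for name, values in (("outward", outward), ("return", ret), ("transit", transit)):
        frames.append(
            pd.DataFrame(
                {
                    "sex": arr.sex,
                    "move_type": name,
                    "orig": np.array(arr.countries)[i],
                    "dest": np.array(arr.countries)[j],
                    "period": arr.period,
                    method_key: values[i, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

DA_METHODS = ("da_min_open", "da_min_closed", "da_pb_closed")


def accounting_arrays(
    stocks: BilateralStockPanel,
    demo: DemographicPanel,
    period: int,
    sex: str,
    countries: list[str],
    pb: PseudoBayesConfig | None = None,
    tol: float = IPF_TOL,
    max_iter: int = IPF_MAX_ITER,
) -> dict[str, BirthplaceFlowArray]:
    """Imputed arrays for the three accounting estimators, one sex and period."""
    adjusted = adjust_stocks(stocks, demo, period, sex, countries)
    open_pair = balance_open(adjusted)
    closed_pair = balance_closed(adjusted)
    arr_min_closed = impute_min(closed_pair, tol=tol, max_iter=max_iter)
    return {
        "da_min_open": impute_min(open_pair, tol=tol, max_iter=max_iter),
        "da_min_closed": arr_min_closed,
        "da_pb_closed": pseudo_bayes(arr_min_closed, impute_indep(closed_pair), pb),
    }


def estimate_accounting(
    stocks: BilateralStockPanel,
    demo: DemographicPanel,
    period: int,
    countries: list[str],
    pb: PseudoBayesConfig | None = None,
    tol: float = IPF_TOL,
    max_iter: int = IPF_MAX_ITER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accounting flows and move-type decomposition for every sex in a period.

    Returns (flow table with the three ``da_*`` columns, move-type table).
    """
    keys = ["sex", "orig", "dest", "period"]
    flow_parts, mt_parts = [], []
    for sex in stocks.sexes:
        arrays = accounting_arrays(
            stocks, demo, period, sex, countries, pb=pb, tol=tol, max_iter=max_iter
        )
        flows = None
        mts = None
        for method, arr in arrays.items():
            f = flows_from_array(arr, method)
            m = move_type_decompose(arr, method)
            flows = f if flows is None else flows.merge(f, on=keys)
            mts = m if mts is None else mts.merge(m, on=["move_type"] + keys)
        flow_parts.append(flows)
        mt_parts.append(mts)
    return (
        pd.concat(flow_parts, ignore_index=True),
        pd.concat(mt_parts, ignore_index=True),
    )
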