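"""Demographic-accounting estimators: adjustment, balancing, imputation."""

import logging

import numpy as np
import pandas as pd
import pytest

import migflows as mf
from migflows.accounting import AdjustedStockPair
from migflows.core import STOCK_COLUMNS

from _oracles import quasi_independent_oracle, random_balanced_margins


def demo_frame(rows):
    return mf.DemographicPanel(
        pd.DataFrame(
            rows,
            columns=[
                "country", "period", "sex", "pop_start", "pop_end",
                "deaths", "births_total", "srb",
            ],
        )
    )


def slice_pair(row, col, sex="female", period=1990):
    """Pair with the given margins in slice k=0 and empty other slices."""
    n = len(row)
    countries = [chr(ord("A") + i) for i in range(n)]
    rows = np.zeros((n, n))
    cols = np.zeros((n, n))
    rows[0], cols[0] = row, col
    return AdjustedStockPair(sex, period, countries, rows, cols)


class TestAdjustStocks:
    def _toy(self, deaths_a=0.0, births_total_a=0.0):
        rows = [
            ("female", "B", "A", 1990, 40),
            ("female", "A", "B", 1990, 5),
            ("female", "B", "A", 1995, 40),
            ("female", "A", "B", 1995, 5),
        ]
        stocks = mf.BilateralStockPanel(pd.DataFrame(rows, columns=STOCK_COLUMNS))
        demo = demo_frame(
            [
                ("A", 1990, "female", 100, 100, deaths_a, births_total_a, 1.0),
                ("B", 1990, "female", 200, 200, 0, 0, 1.0),
            ]
        )
        return stocks, demo

    def test_zero_births_and_deaths_is_identity(self):
        stocks, demo = self._toy()
        pair = mf.adjust_stocks(stocks, demo, 1990, "female", ["A", "B"])
        # home cells: A = 100 - 40 = 60, B = 200 - 5 = 195
        expected = np.array([[60.0, 5.0], [40.0, 195.0]])
        assert np.allclose(pair.row, expected)
        assert np.allclose(pair.col, expected)

    def test_deaths_allocated_proportionally_over_birthplace(self):
        stocks, demo = self._toy(deaths_a=10)
        pair = mf.adjust_stocks(stocks, demo, 1990, "female", ["A", "B"])
        # residence A holds {A-born: 60, B-born: 40}; 10 deaths -> {54, 36}
        assert pair.row[0, 0] == pytest.approx(54)
        assert pair.row[1, 0] == pytest.approx(36)
        # end margins untouched by deaths
        assert pair.col[0, 0] == pytest.approx(60)

    def test_births_subtracted_from_end_home_cell(self):
        # srb 1.0 and 40 total births -> 20 female births in A
        stocks, demo = self._toy(births_total_a=40)
        pair = mf.adjust_stocks(stocks, demo, 1990, "female", ["A", "B"])
        assert pair.col[0, 0] == pytest.approx(60 - 20)
        assert pair.row[0, 0] == pytest.approx(60)

    def test_excess_births_clamp_with_warning(self, caplog):
        stocks, demo = self._toy(births_total_a=200)
        with caplog.at_level(logging.WARNING, logger="migflows"):
            pair = mf.adjust_stocks(stocks, demo, 1990, "female", ["A", "B"])
        assert pair.col[0, 0] == 0
        assert any("clamped" in r.message for r in caplog.records)


class TestBalanceOpen:
    def test_balanced_slice_gets_zero_out_margins(self):
        pair = mf.balance_open(slice_pair([50.0, 50.0], [60.0, 40.0]))
        assert pair.out_row[0] == 0 and pair.out_col[0] == 0

    def test_column_surplus_becomes_out_origin(self):
        pair = mf.balance_open(slice_pair([40.0, 50.0], [60.0, 50.0]))
        assert pair.out_row[0] == 20  # colS 110 - rowS 90
        assert pair.out_col[0] == 0

    def test_row_surplus_becomes_out_destination(self):
        pair = mf.balance_open(slice_pair([60.0, 50.0], [40.0, 50.0]))
        assert pair.out_row[0] == 0
        assert pair.out_col[0] == 20

    def test_extended_totals_balance_exactly(self):
        rng = np.random.default_rng(0)
        row, col = rng.uniform(0, 100, (2, 4, 4))
        pair = mf.balance_open(
            AdjustedStockPair("female", 1990, list("ABCD"), row, col)
        )
        for k in range(4):
            r, c = pair.margins(k)
            assert r.sum() == pytest.approx(c.sum(), rel=1e-12)


class TestBalanceClosed:
    def test_equal_totals_identity(self):
        pair = slice_pair([50.0, 50.0], [60.0, 40.0])
        out = mf.balance_closed(pair)
        assert np.allclose(out.row, pair.row)
        assert np.allclose(out.col, pair.col)

    def test_midpoint_scaling(self):
        out = mf.balance_closed(slice_pair([40.0, 50.0], [60.0, 50.0]))
        assert np.allclose(out.row[0], np.array([40.0, 50.0]) * 100 / 90)
        assert np.allclose(out.col[0], np.array([60.0, 50.0]) * 100 / 110)
        assert out.row[0].sum() == pytest.approx(100)
        assert out.col[0].sum() == pytest.approx(100)

    def test_scaled_totals_agree_on_random_pairs(self):
        rng = np.random.default_rng(1)
        row, col = rng.uniform(0, 100, (2, 5, 5))
        out = mf.balance_closed(
            AdjustedStockPair("female", 1990, list("ABCDE"), row, col)
        )
        assert np.allclose(out.row.sum(axis=1), out.col.sum(axis=1), rtol=1e-12)

    def test_single_zero_total_errors(self):
        with pytest.raises(mf.ValidationError, match="one margin total is zero"):
            mf.balance_closed(slice_pair([0.0, 0.0], [60.0, 40.0]))


class TestImputeMin:
    def test_forced_residual_case(self):
        arr = mf.impute_min(slice_pair([50.0, 30.0, 20.0], [40.0, 40.0, 20.0]))
        y = arr.array[:, :, 0]
        assert np.allclose(np.diag(y), [40, 30, 20])
        assert y[0, 1] == pytest.approx(10)
        off = y - np.diag(np.diag(y))
        assert off.sum() == pytest.approx(10)

    def test_equal_margins_put_everyone_on_diagonal(self):
        arr = mf.impute_min(slice_pair([50.0, 30.0], [50.0, 30.0]))
        y = arr.array[:, :, 0]
        assert np.allclose(np.diag(y), [50, 30])
        assert arr.total_migration() == pytest.approx(0)

    @pytest.mark.parametrize("seed", range(5))
    def test_margins_reproduced_on_random_balanced_slices(self, seed):
        rng = np.random.default_rng(seed)
        row, col = random_balanced_margins(rng, 4)
        arr = mf.impute_min(slice_pair(list(row), list(col)))
        y = arr.array[:, :, 0]
        assert np.abs(y.sum(axis=1) - row).max() < 1e-6
        assert np.abs(y.sum(axis=0) - col).max() < 1e-6

    @pytest.mark.parametrize("m", [3, 4])
    def test_matches_brute_force_quasi_independent_fit(self, m):
        rng = np.random.default_rng(m)
        for _ in range(10):
            row, col = random_balanced_margins(rng, m)
            arr = mf.impute_min(slice_pair(list(row), list(col)))
            oracle = quasi_independent_oracle(list(row), list(col))
            scale = max(oracle.max(), 1.0)
            assert np.abs(arr.array[:, :, 0] - oracle).max() / scale < 1e-5

    def test_diagonal_fixed_at_stage_one_value(self):
        row, col = [70.0, 10.0, 20.0], [40.0, 30.0, 30.0]
        arr = mf.impute_min(slice_pair(row, col))
        assert np.allclose(
            np.diag(arr.array[:, :, 0]), np.minimum(row, col)
        )

    def test_non_convergence_reports_deviation(self):
        # zero diagonal forces each row into a single cell; these margins are
        # infeasible under that mask, so the fit cannot converge
        with pytest.raises(mf.ValidationError, match="converge"):
            mf.ipf(
                1.0 - np.eye(2),
                np.array([10.0, 5.0]),
                np.array([4.0, 11.0]),
                max_iter=50,
            )


class TestImputeIndep:
    def test_outer_product_closed_form(self):
        arr = mf.impute_indep(slice_pair([10.0, 0.0], [5.0, 5.0]))
        assert np.allclose(arr.array[:, :, 0], [[5.0, 5.0], [0.0, 0.0]])

    def test_zero_slice_stays_zero(self):
        arr = mf.impute_indep(slice_pair([0.0, 0.0], [0.0, 0.0]))
        assert np.all(arr.array == 0)

    def test_ipf_from_flat_seed_matches_closed_form(self):
        rng = np.random.default_rng(2)
        row, col = random_balanced_margins(rng, 4)
        fitted = mf.ipf(np.ones((4, 4)), row, col)
        assert np.allclose(fitted, np.outer(row, col) / row.sum(), atol=1e-6)


class TestPseudoBayes:
    def test_identical_arrays_unchanged(self):
        arr = mf.impute_indep(slice_pair([10.0, 5.0], [8.0, 7.0]))
        combo = mf.pseudo_bayes(arr, arr)
        assert np.allclose(combo.array, arr.array)

    def test_weighted_combination_value(self):
        a = mf.impute_indep(slice_pair([10.0, 5.0], [8.0, 7.0]))
        b = mf.impute_indep(slice_pair([10.0, 5.0], [8.0, 7.0]))
        a.array[:] = 100.0
        b.array[:] = 200.0
        combo = mf.pseudo_bayes(a, b, mf.PseudoBayesConfig(0.87))
        assert np.allclose(combo.array, 113.0)

    def test_weight_one_returns_first_imputation(self):
        a = mf.impute_min(slice_pair([10.0, 5.0], [8.0, 7.0]))
        b = mf.impute_indep(slice_pair([10.0, 5.0], [8.0, 7.0]))
        combo = mf.pseudo_bayes(a, b, mf.PseudoBayesConfig(1.0))
        assert np.allclose(combo.array, a.array)

    def test_shape_mismatch_errors(self):
        a = mf.impute_indep(slice_pair([10.0, 5.0], [8.0, 7.0]))
        b = mf.impute_indep(slice_pair([10.0, 5.0, 1.0], [8.0, 7.0, 1.0]))
        with pytest.raises(mf.ValidationError, match="shape"):
            mf.pseudo_bayes(a, b)

    def test_invalid_weight_rejected(self):
        with pytest.raises(mf.ValidationError):
            mf.PseudoBayesConfig(1.5)


def hand_array():
    """2 countries, 2 birthplaces: A->B carries 3 A-born and 2 B-born."""
    arr = np.zeros((2, 2, 2))
    arr[0, 1, 0] = 3.0  # A->B, born A (outward)
    arr[0, 1, 1] = 2.0  # A->B, born B (return)
    arr[1, 0, 1] = 4.0  # B->A, born B (outward)
    arr[0, 0, 0] = 50.0  # stayers
    return mf.BirthplaceFlowArray("female", 1990, ["A", "B"], arr)


class TestFlowExtraction:
    def test_diagonal_only_array_gives_zero_flows(self):
        arr = mf.impute_min(slice_pair([50.0, 30.0], [50.0, 30.0]))
        flows = mf.flows_from_array(arr, "da_min_closed")
        assert (flows["da_min_closed"] == 0).all()

    def test_hand_built_array_sums(self):
        flows = mf.flows_from_array(hand_array(), "da_min_open")
        f = flows.set_index(["orig", "dest"])["da_min_open"]
        assert f.loc[("A", "B")] == 5.0
        assert f.loc[("B", "A")] == 4.0

    def test_pseudo_bayes_flows_are_linear_combination(self):
        pair = slice_pair([50.0, 30.0, 20.0], [40.0, 40.0, 20.0])
        a_min = mf.impute_min(pair)
        a_ind = mf.impute_indep(pair)
        pb = mf.pseudo_bayes(a_min, a_ind)
        f_pb = mf.flows_from_array(pb, "v")["v"]
        combo = (
            0.87 * mf.flows_from_array(a_min, "v")["v"]
            + 0.13 * mf.flows_from_array(a_ind, "v")["v"]
        )
        assert np.allclose(f_pb, combo)


class TestMoveTypes:
    def test_outward_and_return_by_definition(self):
        mt = mf.move_type_decompose(hand_array(), "v")
        v = mt.set_index(["move_type", "orig", "dest"])["v"]
        assert v.loc[("outward", "A", "B")] == 3.0
        assert v.loc[("return", "A", "B")] == 2.0
        assert v.loc[("transit", "A", "B")] == 0.0
        assert v.loc[("outward", "B", "A")] == 4.0

    def test_partition_sums_to_total_flow(self):
        rng = np.random.default_rng(3)
        arr = mf.BirthplaceFlowArray(
            "female", 1990, ["A", "B", "C"], rng.uniform(0, 10, (3, 3, 3))
        )
        mt = mf.move_type_decompose(arr, "v")
        total = mt.groupby(["orig", "dest"])["v"].sum()
        flows = mf.flows_from_array(arr, "v").set_index(["orig", "dest"])["v"]
        assert np.allclose(total.sort_index(), flows.sort_index(), atol=1e-9)


class TestWorldLevel:
    def test_closed_net_constraint(self, harmonized_world):
        """Closed-system flows sum to each country's accounting-equation net."""
        stocks, demo, panel = harmonized_world
        flows, _ = mf.run_estimators(stocks, demo, panel)
        for method in ("da_min_closed", "da_pb_closed"):
            inflow = flows.groupby(["sex", "period", "dest"])[method].sum()
            outflow = flows.groupby(["sex", "period", "orig"])[method].sum()
            net = (inflow - outflow).rename("implied").reset_index()
            net = net.rename(columns={"dest": "country"}).merge(
                demo.data[["sex", "period", "country", "net_migration"]]
            )
            assert np.abs(net["implied"] - net["net_migration"]).max() < 1e-3

    def test_pseudo_bayes_total_dominates_minimisation(self, harmonized_world):
        stocks, demo, panel = harmonized_world
        for period, countries in panel.periods.items():
            for sex in mf.SEXES:
                arrays = mf.accounting_arrays(stocks, demo, period, sex, countries)
                assert (
                    arrays["da_pb_closed"].total_migration()
                    >= arrays["da_min_closed"].total_migration() - 1e-9
                )

    def test_open_out_cell_structurally_zero(self, harmonized_world):
        stocks, demo, panel = harmonized_world
        period, countries = next(iter(sorted(panel.periods.items())))
        arrays = mf.accounting_arrays(stocks, demo, period, "female", countries)
        arr = arrays["da_min_open"]
        assert arr.has_out
        assert np.all(arr.array[-1, -1, :] == 0)
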