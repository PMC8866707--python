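"""Closed-form estimators and the adjustable-factor strata table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ldlkit import (
    LipidPanel,
    PanelValidationError,
    StrataTable,
    friedewald,
    martin_adjustable,
    sampson_nih,
)
from ldlkit.equations import (
    AdjustableFactorModel,
    default_nonhdl_edges,
    default_tg_edges,
    derive_strata_table,
)
from ldlkit.simulate import CohortParams, FactorModel, generate_cohort


class TestFriedewald:
    def test_printed_formula(self):
        assert friedewald(LipidPanel(200, 50, 100)) == pytest.approx(130.0)

    def test_zero_tg_equals_non_hdl(self):
        assert friedewald(LipidPanel(200, 50, 0)) == pytest.approx(150.0)

    def test_validity_flag_at_tg_400(self):
        est, ok = friedewald(LipidPanel(260, 50, 400), return_flag=True)
        assert not ok and est == pytest.approx(130.0)  # value still returned
        _, ok2 = friedewald(LipidPanel(260, 50, 399), return_flag=True)
        assert ok2

    @pytest.mark.parametrize(
        "tc,hdl,tg,bad_field",
        [(-5, 50, 100, "tc"), (200, 0, 100, "hdl"), (200, 50, -1, "tg"), (200, 200, 100, "hdl")],
    )
    def test_invalid_panel_names_field(self, tc, hdl, tg, bad_field):
        with pytest.raises(PanelValidationError) as exc:
            friedewald(LipidPanel(tc, hdl, tg))
        assert exc.value.field == bad_field

    def test_matches_bruteforce_oracle(self, random_panels):
        est = friedewald(random_panels)
        oracle = np.array(
            [r.tc - r.hdl - r.tg / 5 for r in random_panels.itertuples()]
        )
        np.testing.assert_allclose(est, oracle, atol=1e-9)


class TestSampsonNih:
    def test_hand_arithmetic(self):
        # 210.9705 - 51.4933 - (17.5234 + 10.5140 - 1.3975) - 9.44
        assert sampson_nih(LipidPanel(200, 50, 150)) == pytest.approx(123.40, abs=0.01)

    def test_tc_equal_hdl_rejected(self):
        with pytest.raises(PanelValidationError):
            sampson_nih(LipidPanel(100, 100, 50))

    def test_matches_bruteforce_oracle(self, random_panels):
        est = sampson_nih(random_panels)
        oracle = np.array(
            [
                r.tc / 0.948
                - r.hdl / 0.971
                - (r.tg / 8.56 + r.tg * (r.tc - r.hdl) / 2140 - r.tg**2 / 16100)
                - 9.44
                for r in random_panels.itertuples()
            ]
        )
        np.testing.assert_allclose(est, oracle, atol=1e-9)


class TestMartinAdjustable:
    def test_all_fives_table_equals_friedewald(self, random_panels):
        table = StrataTable.uniform(5.0)
        np.testing.assert_array_equal(
            martin_adjustable(random_panels, table), friedewald(random_panels)
        )

    def test_direct_arithmetic_with_factor_8(self):
        table = StrataTable.uniform(8.0)
        assert martin_adjustable(LipidPanel(200, 50, 100), table) == pytest.approx(137.5)

    def test_matches_linear_scan_oracle(self, random_panels, rng):
        tg_edges = np.sort(rng.uniform(20, 500, 7))
        nh_edges = np.sort(rng.uniform(60, 250, 4))
        factors = rng.uniform(3, 12, (8, 5))
        table = StrataTable(tg_edges, nh_edges, factors)
        est = martin_adjustable(random_panels, table)

        def scan(edges, v):
            # explicit linear scan over left-closed right-open strata
            for k, e in enumerate(edges):
                if v < e:
                    return k
            return len(edges)

        oracle = np.array(
            [
                r.tc - r.hdl - r.tg / factors[scan(tg_edges, r.tg), scan(nh_edges, r.tc - r.hdl)]
                for r in random_panels.itertuples()
            ]
        )
        np.testing.assert_allclose(est, oracle, atol=1e-9)

    def test_out_of_range_clamps_to_edge_strata(self):
        table = StrataTable(np.array([100.0]), np.array([150.0]), np.array([[4.0, 6.0], [8.0, 10.0]]))
        # tg far above every stratum, non-HDL far below: clamps to (last, first)
        est = martin_adjustable(LipidPanel(120, 40, 5000), table)
        assert est == pytest.approx(120 - 40 - 5000 / 8.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    tc=st.floats(100, 400),
    hdl_frac=st.floats(0.1, 0.6),
    tg=st.floats(0, 390),
    dtg=st.floats(0.5, 10),
)
def test_estimators_strictly_decreasing_in_tg(tc, hdl_frac, tg, dtg):
    hdl = tc * hdl_frac
    lo, hi = LipidPanel(tc, hdl, tg), LipidPanel(tc, hdl, tg + dtg)
    table = StrataTable.uniform(6.5)
    assert friedewald(hi) < friedewald(lo)
    assert sampson_nih(hi) < sampson_nih(lo)  # over the TG in [0, 400] applicability range
    assert martin_adjustable(hi, table) < martin_adjustable(lo, table)


class TestStrataTable:
    def test_default_geometry_is_180_cells(self):
        assert StrataTable.uniform(5.0).cell_count == 180

    def test_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            StrataTable(np.array([100.0]), np.array([150.0]), np.array([[5.0, -1.0], [5.0, 5.0]]))

    def test_roundtrip_bit_identical(self, tmp_path, rng):
        table = StrataTable(
            default_tg_edges(), default_nonhdl_edges(), rng.uniform(3, 12, (30, 6))
        )
        path = tmp_path / "table.csv"
        table.to_file(path)
        back = StrataTable.from_file(path)
        np.testing.assert_array_equal(back.factors, table.factors)
        np.testing.assert_array_equal(back.tg_edges, table.tg_edges)
        np.testing.assert_array_equal(back.nonhdl_edges, table.nonhdl_edges)


class TestDeriveStrataTable:
    def test_constant_factor_recovered(self):
        fm = FactorModel(base=5.0, amplitude=0.0, nonhdl_slope=0.0)
        df = generate_cohort(CohortParams(n=20_000, seed=11, factor_model=fm, assay_noise_sd=0.0))
        table = derive_strata_table(df)
        np.testing.assert_allclose(table.factors, 5.0, atol=0.05)

    def test_piecewise_factors_recovered(self):
        # true divisor 4 below TG 150, 8 at or above; edges aligned with the truth
        n_per = 5_000
        rng = np.random.default_rng(202)
        tg = np.concatenate([rng.uniform(40, 149, n_per), rng.uniform(151, 380, n_per)])
        f = np.where(tg < 150, 4.0, 8.0)
        tc = rng.normal(200, 25, 2 * n_per)
        hdl = rng.uniform(35, 70, 2 * n_per)
        ldl = tc - hdl - tg / f
        df = pd.DataFrame({"tc": tc, "hdl": hdl, "tg": tg, "ldl_measured": ldl})
        table = derive_strata_table(df, tg_edges=[150.0], nonhdl_edges=[140.0])
        np.testing.assert_allclose(table.factors[0], 4.0, atol=0.1)
        np.testing.assert_allclose(table.factors[1], 8.0, atol=0.1)

    def test_single_record_fills_all_cells(self):
        df = pd.DataFrame({"tc": [160.0], "hdl": [40.0], "tg": [100.0], "ldl_measured": [100.0]})
        table = derive_strata_table(df)  # vldl = 20 -> factor 5
        np.testing.assert_allclose(table.factors, 5.0)

    def test_all_nonpositive_vldl_is_error(self):
        df = pd.DataFrame({"tc": [160.0], "hdl": [40.0], "tg": [100.0], "ldl_measured": [130.0]})
        with pytest.raises(ValueError):
            derive_strata_table(df)

    def test_derived_table_beats_friedewald_when_factor_varies(self, small_cohort):
        results = AdjustableFactorModel(small_cohort).fit()
        martin = martin_adjustable(small_cohort, results.table)
        fw = friedewald(small_cohort)
        meas = small_cohort["ldl_measured"].to_numpy()
        assert np.sqrt(np.mean((martin - meas) ** 2)) < np.sqrt(np.mean((fw - meas) ** 2))

    def test_record_order_invariance(self, small_cohort):
        shuffled = small_cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        t1 = derive_strata_table(small_cohort)
        t2 = derive_strata_table(shuffled)
        np.testing.assert_allclose(t1.factors, t2.factors)
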