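import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lifetab as lt
from lifetab.errors import ScheduleValidationError
from lifetab.lifetable import (
    assign_ax,
    build_life_table,
    chiang_variance,
    greville_smooth,
    mx_to_qx,
    with_se,
)
from oracles import constant_q_e0, local_cubic_graduation, step_hazard_le


class TestRateToProbability:
    def test_zero_rate(self):
        assert mx_to_qx(np.array([0.0]), 0.5)[0] == 0.0

    def test_small_rate_formula(self):
        q = mx_to_qx(np.array([0.01]), 0.5)[0]
        assert q == pytest.approx(0.01 / (1 + 0.5 * 0.01), rel=1e-12)
        assert q == pytest.approx(0.00995024875, abs=1e-9)

    def test_large_rate_capped_at_one(self):
        # uncapped limit is 1/(1-ax) = 2 for ax = 0.5
        assert mx_to_qx(np.array([1e9]), 0.5)[0] == 1.0

    def test_round_trip_inverse(self):
        mx = np.array([0.001, 0.05, 0.4])
        ax = np.array([0.1, 0.5, 0.5])
        np.testing.assert_allclose(lt.qx_to_mx(mx_to_qx(mx, ax), ax), mx, rtol=1e-12)


class TestSeparationFactors:
    @pytest.mark.parametrize("sex,a0", [("male", 0.05), ("female", 0.13)])
    def test_infant_value(self, sex, a0):
        ax = assign_ax(sex, np.array([0, 1, 40]))
        assert ax[0] == a0
        assert ax[1] == 0.5 and ax[2] == 0.5

    def test_no_infant_row_when_first_age_positive(self):
        assert np.all(assign_ax("male", np.arange(12, 20)) == 0.5)

    def test_unknown_sex(self):
        with pytest.raises(ScheduleValidationError):
            assign_ax("other", np.array([0]))


class TestGrevilleGraduation:
    def test_constant_series_unchanged(self):
        q = np.full(30, 0.01)
        np.testing.assert_allclose(greville_smooth(q, 9), q, atol=1e-12)

    def test_exact_on_cubics(self):
        x = np.arange(30, dtype=float)
        q = 1e-4 + 1e-6 * x + 2e-8 * x**2 + 1e-9 * x**3
        sm = greville_smooth(q, 9)
        np.testing.assert_allclose(sm, q, rtol=1e-8)
        np.testing.assert_allclose(sm, local_cubic_graduation(q, 9), rtol=1e-8)

    def test_spike_attenuated(self):
        x = np.arange(60, dtype=float)
        cubic = 1e-3 + 1e-5 * x + 1e-7 * x**3 / 50
        q = cubic.copy()
        q[30] += 0.05
        sm = greville_smooth(q, 9)
        # graduation spreads the spike: smaller squared residual vs the cubic,
        # and the peak itself is attenuated
        assert np.sum((sm - cubic) ** 2) < np.sum((q - cubic) ** 2)
        assert sm[30] - cubic[30] < 0.5 * 0.05

    def test_short_series_passes_through_with_warning(self):
        q = np.array([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning, match="shorter"):
            out = greville_smooth(q, 9)
        np.testing.assert_array_equal(out, q)

    def test_even_order_rejected(self):
        with pytest.raises(ValueError):
            greville_smooth(np.full(30, 0.1), 8)

    def test_custom_weights_hook(self):
        q = np.full(20, 0.02)
        w = np.full(9, 1 / 9)
        np.testing.assert_allclose(greville_smooth(q, 9, weights=w), q, atol=1e-14)


class TestLifeTableConstruction:
    def test_certain_death_collapses_immediately(self):
        ages = np.arange(50, 53)
        tab = build_life_table(ages, np.ones(3), np.full(3, 0.5), closure_mx=2.0)
        assert tab.lx[1] == 0.0
        # everyone dies in the first year, living ax of it on average
        assert tab.ex[0] == pytest.approx(0.5)

    def test_constant_q_matches_brute_force(self):
        q = 0.07
        n = 40
        ages = np.arange(n + 1)
        qx = np.full(n + 1, q)
        ax = np.full(n + 1, 0.5)
        tab = build_life_table(ages, qx, ax, closure_mx=0.9)
        oracle = constant_q_e0(q, n, ax=0.5, closure_mx=0.9)
        assert tab.ex[0] == pytest.approx(oracle, rel=1e-9)

    def test_huge_exposure_recovers_analytic_le(self, scenario):
        # deaths set to their expectation: the infinite-exposure limit
        ages = np.arange(0, 101)
        mu = scenario.hazard(ages.astype(float))
        expo = np.full(ages.shape, 1e10)
        sched = lt.MortalitySchedule("ref", "male", ages, expo, expo * mu)
        res = lt.LifeTableModel(sched, smooth_order=None).fit()
        truth = step_hazard_le(mu)
        assert res.e0 == pytest.approx(truth, abs=0.1)

    def test_radix_must_be_positive(self):
        with pytest.raises(ValueError):
            build_life_table(np.array([0]), np.array([1.0]), np.array([0.5]), radix=0.0)

    def test_smoothing_neutrality_on_well_behaved_schedule(self, reference_schedule):
        smooth = lt.LifeTableModel(reference_schedule, smooth_order=9).fit()
        raw = lt.LifeTableModel(reference_schedule, smooth_order=None).fit()
        assert abs(smooth.e0 - raw.e0) < 0.5

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        qx=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=40),
        closure_mx=st.floats(0.05, 3.0),
    )
    def test_invariants_hold_for_any_probabilities(self, qx, closure_mx):
        qx = np.asarray(qx)
        ages = np.arange(len(qx))
        ax = assign_ax("male", ages)
        tab = build_life_table(ages, qx, ax, closure_mx=closure_mx)
        # survivorship monotone and non-negative
        assert np.all(np.diff(tab.lx) <= 1e-9)
        assert np.all(tab.lx >= 0)
        # conservation: all radix deaths accounted for
        assert np.sum(tab.dx) == pytest.approx(tab.radix, rel=1e-12)
        # recursion consistency, bit for bit
        np.testing.assert_array_equal(np.cumsum(tab.Lx[::-1])[::-1], tab.Tx)
        alive = tab.lx > 0
        np.testing.assert_array_equal(tab.ex[alive], tab.Tx[alive] / tab.lx[alive])
        # one year of age costs at most one year of expectation
        alive_pair = alive[:-1] & alive[1:]
        assert np.all(tab.ex[:-1][alive_pair] <= tab.ex[1:][alive_pair] + 1 + 1e-9)


class TestChiangVariance:
    @staticmethod
    def toy_table():
        ages = np.array([50, 51])
        tab = build_life_table(
            ages, np.array([0.2, 1.0]), np.array([0.5, 0.5]), closure_mx=0.5
        )
        return tab

    def test_degenerate_probabilities_give_zero_variance(self):
        ages = np.arange(3)
        tab = build_life_table(
            ages, np.array([0.0, 1.0, 1.0]), np.full(3, 0.5), closure_mx=1.0
        )
        s2 = chiang_variance(tab, np.array([0.0, 50.0, 0.0]))
        np.testing.assert_array_equal(s2, np.zeros(3))

    def test_toy_table_hand_computation(self):
        # l = [1e5, 8e4]; L = [9e4, 1.6e5]; T = [2.5e5, 1.6e5]; e = [2.5, 2.0]
        # S2_p0 = 0.2^2 * 0.8 / 100 = 3.2e-4; bracket = (0.5 + 2.0)^2 = 6.25
        # S2_e50 = 6.25 * 3.2e-4 = 2.0e-3  =>  se = 0.0447213...
        tab = self.toy_table()
        assert tab.ex[0] == pytest.approx(2.5)
        assert tab.ex[1] == pytest.approx(2.0)
        ci = lt.chiang_ci(tab, np.array([100.0, np.nan]))[0]
        assert ci.se_ex == pytest.approx(np.sqrt(2.0e-3), rel=1e-12)
        assert ci.lo95 == pytest.approx(2.5 - 1.96 * np.sqrt(2.0e-3), rel=1e-12)
        assert ci.hi95 == pytest.approx(2.5 + 1.96 * np.sqrt(2.0e-3), rel=1e-12)

    def test_quadrupled_deaths_halve_the_se(self, deterministic_schedule):
        mx = 0.002 * 1.09 ** np.arange(60)
        s1 = deterministic_schedule(mx, exposure=1e4)
        s4 = deterministic_schedule(mx, exposure=4e4)
        r1 = lt.LifeTableModel(s1, smooth_order=None).fit()
        r4 = lt.LifeTableModel(s4, smooth_order=None).fit()
        np.testing.assert_allclose(r4.se_ex[:-1], 0.5 * r1.se_ex[:-1], rtol=1e-9)

    def test_unsquared_bracket_flag_changes_result(self):
        tab = self.toy_table()
        s2_sq = chiang_variance(tab, np.array([100.0, np.nan]), square_bracket=True)
        s2_lit = chiang_variance(tab, np.array([100.0, np.nan]), square_bracket=False)
        assert s2_lit[0] == pytest.approx(2.5 * 3.2e-4, rel=1e-12)
        assert s2_sq[0] > s2_lit[0]

    def test_zero_deaths_contribute_zero_with_warning(self, caplog):
        tab = self.toy_table()
        with caplog.at_level("WARNING", logger="lifetab.lifetable"):
            s2 = chiang_variance(tab, np.array([0.0, np.nan]))
        assert s2[0] == 0.0
        assert "variance contribution" in caplog.text
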