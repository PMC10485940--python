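import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lifetab as lt
from lifetab.errors import PrevalenceCoverageError, ScheduleValidationError
from lifetab.lifetable import build_life_table, with_se
from lifetab.sullivan import expand_prevalence, sullivan, sullivan_ci, sullivan_variance


def simple_table(n=61, first=0, q=None):
    ages = np.arange(first, first + n)
    if q is None:
        mx = 0.002 * 1.09 ** np.arange(n)
        q = lt.mx_to_qx(mx, 0.5)
    ax = lt.assign_ax("male", ages)
    tab = build_life_table(ages, q, ax, closure_mx=0.6)
    deaths = np.full(n, 500.0)
    return with_se(tab, deaths), deaths


class TestExpandPrevalence:
    def test_single_group_covers_everything(self):
        sched = lt.PrevalenceSchedule("DF", [0], [100], [0.1])
        np.testing.assert_array_equal(
            expand_prevalence(sched, np.arange(101)), np.full(101, 0.1)
        )

    def test_two_groups_step_at_boundary(self):
        sched = lt.PrevalenceSchedule("PH", [0, 50], [49, 100], [0.05, 0.20])
        pi = expand_prevalence(sched, np.arange(101))
        assert pi[49] == 0.05 and pi[50] == 0.20

    def test_ages_below_first_group_carry_down(self):
        sched = lt.PrevalenceSchedule("NHIS", [20], [100], [0.3])
        pi = expand_prevalence(sched, np.arange(0, 101))
        assert np.all(pi[:20] == 0.3)

    def test_uncovered_old_ages_raise(self):
        sched = lt.PrevalenceSchedule("NHIS", [0], [79], [0.1])
        with pytest.raises(PrevalenceCoverageError, match="ends at age 79"):
            expand_prevalence(sched, np.arange(101))

    def test_interior_gap_raises(self):
        sched = lt.PrevalenceSchedule("NHIS", [0, 60], [49, 100], [0.1, 0.2])
        with pytest.raises(PrevalenceCoverageError, match="age 50"):
            expand_prevalence(sched, np.arange(101))

    def test_spline_expansion_stays_in_bounds_and_near_step(self):
        sched = lt.PrevalenceSchedule(
            "DF", [0, 30, 60], [29, 59, 100], [0.05, 0.15, 0.40]
        )
        pi = expand_prevalence(sched, np.arange(101), method="spline")
        assert np.all((pi >= 0) & (pi <= 1))
        assert np.all(np.diff(pi) >= -1e-12)  # monotone for monotone groups

    def test_grouped_step_hale_close_to_smooth_truth(self, scenario):
        # 5-year grouping of a smooth logistic prevalence curve shifts HALE
        # at birth by only a fraction of a year
        tab, deaths = simple_table(n=101)
        curve = lt.PrevalenceCurve(floor=0.05, ceiling=0.5, midpoint=75, slope=0.1)
        exact = np.clip(curve(tab.ages), 0, 1)
        starts = np.arange(0, 101, 5)
        glo, ghi = starts, np.append(starts[1:] - 1, 100)
        grouped = lt.PrevalenceSchedule(
            "NHIS", glo, ghi, np.clip(curve((glo + ghi) / 2), 0, 1)
        )
        pi_step = expand_prevalence(grouped, tab.ages)
        h_exact = sullivan(tab, exact).hale[0]
        h_step = sullivan(tab, pi_step).hale[0]
        assert abs(h_exact - h_step) < 0.3


class TestSullivanEstimator:
    def test_zero_prevalence_reproduces_le(self):
        tab, _ = simple_table()
        h = sullivan(tab, np.zeros(len(tab.ages)))
        np.testing.assert_allclose(h.hale, tab.ex, atol=1e-12)

    def test_constant_prevalence_scales_le(self):
        tab, _ = simple_table()
        c = 0.23
        h = sullivan(tab, np.full(len(tab.ages), c))
        np.testing.assert_allclose(h.hale, (1 - c) * tab.ex, atol=1e-12)

    def test_total_prevalence_gives_zero(self):
        tab, _ = simple_table()
        h = sullivan(tab, np.ones(len(tab.ages)))
        np.testing.assert_allclose(h.hale, 0.0, atol=1e-12)

    def test_unhealthy_le_identity(self):
        tab, _ = simple_table()
        rng = np.random.default_rng(2)
        pi = np.sort(rng.uniform(0.05, 0.6, len(tab.ages)))
        h = sullivan(tab, pi)
        unhealthy = np.cumsum((tab.Lx * pi)[::-1])[::-1] / tab.lx
        np.testing.assert_allclose(tab.ex - h.hale, unhealthy, atol=1e-9)
        assert np.all(tab.ex - h.hale >= 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_dominance_in_prevalence(self, seed):
        tab, _ = simple_table(n=30)
        rng = np.random.default_rng(seed)
        p1 = rng.uniform(0, 0.9, 30)
        p2 = np.clip(p1 + rng.uniform(0, 0.1, 30), 0, 1)
        h1 = sullivan(tab, p1).hale
        h2 = sullivan(tab, p2).hale
        assert np.all(h1 >= h2 - 1e-12)

    def test_hale_never_exceeds_le(self):
        tab, _ = simple_table()
        pi = np.linspace(0.0, 0.8, len(tab.ages))
        assert np.all(sullivan(tab, pi).hale <= tab.ex + 1e-12)


class TestSullivanIntervals:
    def test_zero_prevalence_interval_equals_le_interval(self):
        tab, deaths = simple_table()
        h = sullivan_ci(tab, np.zeros(len(tab.ages)), deaths)
        np.testing.assert_allclose(h.se_hale, tab.se_ex, atol=1e-12)

    def test_quadrupled_deaths_halve_the_se(self):
        n = 61
        ages = np.arange(n)
        mx = 0.002 * 1.09 ** np.arange(n)
        q = lt.mx_to_qx(mx, 0.5)
        ax = lt.assign_ax("male", ages)
        tab = build_life_table(ages, q, ax, closure_mx=0.6)
        pi = np.linspace(0.05, 0.5, n)
        s1 = sullivan_variance(tab, pi, np.full(n, 200.0))
        s4 = sullivan_variance(tab, pi, np.full(n, 800.0))
        np.testing.assert_allclose(np.sqrt(s4[:-1]), 0.5 * np.sqrt(s1[:-1]), rtol=1e-9)

    def test_toy_two_age_hand_computation(self):
        # table: q = [0.2, 1], ax = 0.5, closure m = 0.5, D0 = 100, pi = [0.1, 0.4]
        # l = [1e5, 8e4]; L = [9e4, 1.6e5]
        # hale1 = 1.6e5*0.6/8e4 = 1.2
        # hale0 = (9e4*0.9 + 1.6e5*0.6)/1e5 = 1.77
        # S2_p0 = 0.04*0.8/100 = 3.2e-4
        # bracket0 = (0.5*0.9 + 1.2)^2 = 1.65^2 = 2.7225
        # S2_hale0 = 2.7225 * 3.2e-4 = 8.712e-4
        ages = np.array([50, 51])
        tab = build_life_table(
            ages, np.array([0.2, 1.0]), np.array([0.5, 0.5]), closure_mx=0.5
        )
        pi = np.array([0.1, 0.4])
        h = sullivan_ci(tab, pi, np.array([100.0, np.nan]))
        assert h.hale[1] == pytest.approx(1.2, rel=1e-12)
        assert h.hale[0] == pytest.approx(1.77, rel=1e-12)
        assert h.se_hale[0] == pytest.approx(np.sqrt(8.712e-4), rel=1e-12)

    def test_prevalence_variance_needs_denominators(self):
        tab, deaths = simple_table()
        with pytest.raises(ScheduleValidationError, match="denominators"):
            sullivan_variance(
                tab, np.full(len(tab.ages), 0.2), deaths, prevalence_variance=True
            )

    def test_prevalence_variance_term_widens_interval(self):
        tab, deaths = simple_table()
        pi = np.full(len(tab.ages), 0.2)
        base = sullivan_variance(tab, pi, deaths)
        wide = sullivan_variance(
            tab, pi, deaths, prevalence_variance=True,
            denom=np.full(len(tab.ages), 500.0),
        )
        assert np.all(wide[:-1] > base[:-1])


class TestSullivanModelSurface:
    def test_model_over_results_object(self, reference_results, scenario):
        prev = lt.simulate_prevalence(scenario, "reference", "NHIS")
        res = lt.SullivanModel(reference_results, prev).fit()
        assert res.definition == "NHIS"
        assert np.all(res.hale <= reference_results.ex + 1e-12)
        assert np.all(res.unhealthy_le() >= -1e-12)
        summ = res.summary(report_ages=[0, 65])
        assert list(summ["age"]) == [0, 65]
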