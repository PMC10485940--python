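import numpy as np
import pytest

import lifetab as lt
from lifetab.errors import ExtensionFitError
from lifetab.extension import (
    FAMILIES,
    ExtensionConfig,
    extend_and_blend,
    fit_extension_model,
    select_extension_model,
)
from conftest import make_schedule

GOMPERTZ = {"B": 2.27e-5, "c": 1.11}


def gompertz_schedule(exposure=1e9):
    ages = np.arange(30, 85)
    mx = FAMILIES["gompertz"].predict(ages.astype(float), GOMPERTZ)
    return make_schedule(mx, ages=ages, exposure=exposure)


class TestFamilyFits:
    def test_gompertz_parameter_recovery(self):
        fit = fit_extension_model(gompertz_schedule(), "gompertz")
        assert fit.params["B"] == pytest.approx(GOMPERTZ["B"], rel=1e-6)
        assert fit.params["c"] == pytest.approx(GOMPERTZ["c"], rel=1e-6)

    def test_makeham_degenerates_to_constant(self):
        ages = np.arange(30, 85)
        sched = make_schedule(np.full(len(ages), 0.015), ages=ages)
        fit = fit_extension_model(sched, "makeham")
        assert fit.params["A"] == pytest.approx(0.015, rel=1e-3)
        # senescent term negligible over the window
        senescent = fit.params["B"] * fit.params["c"] ** 84
        assert senescent < 1e-4

    def test_wrong_family_fits_worse(self):
        ages = np.arange(30, 85)
        u = 2.27e-5 * 1.11 ** ages.astype(float)
        sched = make_schedule(u / (1 + u), ages=ages)  # kannisto truth
        kan = fit_extension_model(sched, "kannisto")
        gom = fit_extension_model(sched, "gompertz")
        assert gom.criterion_value > kan.criterion_value

    def test_extrapolated_rates_strictly_positive(self):
        fit = fit_extension_model(gompertz_schedule(), "gompertz", max_age=110)
        assert np.all(fit.extended_mx > 0)
        assert list(fit.extended_ages) == list(range(85, 111))

    def test_window_too_short(self):
        sched = gompertz_schedule().restrict(30, 67)
        with pytest.raises(ExtensionFitError, match="usable ages"):
            fit_extension_model(sched, "gompertz", fit_window=(65, 84))

    def test_unknown_family(self):
        with pytest.raises(ExtensionFitError, match="unknown"):
            fit_extension_model(gompertz_schedule(), "thiele")


class TestSelection:
    def test_single_candidate_returned(self):
        sel = select_extension_model(gompertz_schedule(), families=("weibull",))
        assert sel.family == "weibull"

    def test_tie_broken_by_priority_not_input_order(self):
        # log-quadratic nests the Gompertz truth (c = 0): both fit exactly,
        # and the fixed priority prefers gompertz even when listed last
        sel = select_extension_model(
            gompertz_schedule(), families=("log_quadratic", "gompertz")
        )
        assert sel.family == "gompertz"

    def test_selection_invariant_to_exposure_scaling(self):
        ages = np.arange(30, 85)
        mx = 0.008 + FAMILIES["gompertz"].predict(ages.astype(float), GOMPERTZ)
        rng = np.random.default_rng(3)
        noisy = mx * np.exp(rng.normal(0, 0.02, len(mx)))
        s1 = make_schedule(noisy, ages=ages, exposure=1e4)
        s2 = make_schedule(noisy, ages=ages, exposure=1e9)
        assert select_extension_model(s1).family == select_extension_model(s2).family

    def test_selection_table_lists_every_candidate(self):
        _, table = select_extension_model(gompertz_schedule(), return_table=True)
        assert len(table) == len(lt.FAMILY_PRIORITY)
        assert set(table["family"]) == set(lt.FAMILY_PRIORITY)

    def test_all_failed_raises(self):
        sched = gompertz_schedule().restrict(30, 67)
        with pytest.raises(ExtensionFitError, match="all families failed"):
            select_extension_model(sched, families=("gompertz", "makeham"),
                                   fit_window=(65, 84))


class TestSpliceAndBlend:
    def test_pure_extrapolation_beyond_data(self):
        sched = gompertz_schedule()
        fit = fit_extension_model(sched, "gompertz")
        rates = extend_and_blend(sched, fit, splice_age=85, max_age=100, blend_width=0)
        np.testing.assert_array_equal(rates.mx[:55], sched.mx)  # observed untouched
        model = fit.predict(np.arange(85, 101, dtype=float))
        np.testing.assert_allclose(rates.mx[55:], model, rtol=1e-12)

    def test_zero_blend_equals_model_inside_data(self):
        sched = gompertz_schedule()
        fit = fit_extension_model(sched, "gompertz", fit_window=(60, 79))
        rates = extend_and_blend(sched, fit, splice_age=80, max_age=95, blend_width=0)
        model = fit.predict(np.arange(80, 96, dtype=float))
        np.testing.assert_allclose(rates.mx[50:], model, rtol=1e-12)

    def test_blend_tapers_the_jump(self):
        ages = np.arange(30, 85)
        mx = FAMILIES["gompertz"].predict(ages.astype(float), GOMPERTZ)
        mx_off = mx.copy()
        mx_off[-1] *= 1.5  # discontinuity vs the fitted curve at the splice
        sched = make_schedule(mx_off, ages=ages)
        fit = fit_extension_model(sched, "gompertz", fit_window=(60, 83))
        hard = extend_and_blend(sched, fit, splice_age=85, max_age=100, blend_width=0)
        soft = extend_and_blend(sched, fit, splice_age=85, max_age=100, blend_width=5)
        # blended first extrapolated rate sits between the hard splice value and
        # the fully offset model curve (offset = observed/model jump, ~1.5)
        assert hard.mx[55] < soft.mx[55] < hard.mx[55] * 1.5
        # far from the splice the blend has decayed away
        np.testing.assert_allclose(soft.mx[-5:], hard.mx[-5:], rtol=1e-12)

    def test_observed_counts_carried_for_variance(self):
        sched = gompertz_schedule(exposure=1e6)
        fit = fit_extension_model(sched, "gompertz", fit_window=(60, 79))
        rates = extend_and_blend(sched, fit, splice_age=80, max_age=100, blend_width=0)
        # replaced-but-observed ages keep their death counts; extrapolated are NaN
        np.testing.assert_allclose(rates.deaths[50:55], sched.deaths[50:55])
        assert np.all(np.isnan(rates.deaths[55:]))


class TestModelSurface:
    def test_results_surface(self):
        res = lt.OldAgeExtension(gompertz_schedule(), ExtensionConfig()).fit()
        assert res.family == "gompertz"
        assert res.summary().shape[0] == len(lt.FAMILY_PRIORITY)
        rates = res.spliced_rates()
        assert rates.ages[-1] == 100

    def test_family_override_forces_fit(self):
        cfg = ExtensionConfig(family_override="coale_kisker")
        res = lt.OldAgeExtension(gompertz_schedule(), cfg).fit()
        assert res.family == "coale_kisker"

    def test_le_insensitive_to_extension_when_model_is_true(self, scenario):
        # large-exposure truth to 100 vs extension from 85 with the true family class
        ages = np.arange(0, 101)
        mu = scenario.hazard(ages.astype(float))
        sched = make_schedule(mu, ages=ages, exposure=1e10)
        full = lt.LifeTableModel(sched, smooth_order=None).fit()
        ext = lt.LifeTableModel(
            sched, smooth_order=None,
            extension=ExtensionConfig(fit_window=(65, 84), max_age=100),
        ).fit()
        assert abs(ext.e0 - full.e0) < 0.05
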