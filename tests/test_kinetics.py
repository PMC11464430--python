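"""Depletion kinetics: window selection, rate fitting, clearance chain, liver models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from microstab import kinetics as kin
from tests.conftest import ols_normal_equations


def prefix_scan_oracle(times, lnx, threshold=0.98, min_points=4):
    """Independent window oracle: longest prefix whose linregress r^2 meets the threshold."""
    best = None
    for end in range(min_points, len(times) + 1):
        r2 = sps.linregress(times[:end], lnx[:end]).rvalue ** 2
        if r2 >= threshold:
            best = (times[0], times[end - 1])
    return best


class TestPercentRemaining:
    def test_reference_course_percentages(self, depletion_course):
        x = kin.percent_remaining(depletion_course)
        t = np.asarray(depletion_course.times)
        assert x[t == 0.0][0] == 100.0
        assert x[t == 2.5][0] == pytest.approx(91.18, abs=0.005)
        assert x[t == 30.0][0] == pytest.approx(37.45, abs=0.005)
        assert x[t == 40.0][0] == pytest.approx(25.15, abs=0.005)

    def test_constant_course_stays_at_100(self):
        course = kin.DepletionTimeCourse(times=(0.0, 10.0, 20.0), mean_conc=(5.0, 5.0, 5.0))
        np.testing.assert_allclose(kin.percent_remaining(course), 100.0)

    def test_invariant_to_concentration_rescaling(self, depletion_course):
        scaled = kin.DepletionTimeCourse(
            times=depletion_course.times,
            mean_conc=tuple(3.7 * c for c in depletion_course.mean_conc),
        )
        np.testing.assert_allclose(
            kin.percent_remaining(scaled), kin.percent_remaining(depletion_course), rtol=1e-12
        )

    @pytest.mark.parametrize(
        "times,conc",
        [((0.0, 5.0), (0.0, 1.0)), ((5.0, 10.0), (1.0, 1.0)), ((0.0, 5.0, 5.0), (1.0, 1.0, 1.0))],
    )
    def test_invalid_courses_rejected(self, times, conc):
        with pytest.raises(ValueError):
            kin.DepletionTimeCourse(times=times, mean_conc=conc)


class TestLnRemaining:
    def test_reference_values(self):
        assert kin.ln_remaining(100.0) == pytest.approx(4.6052, abs=5e-5)
        # printed column reports these to 2 decimals as 3.62 and 4.51
        assert round(kin.ln_remaining(37.45), 2) == 3.62
        assert kin.ln_remaining(37.45) == pytest.approx(3.6230, abs=5e-4)
        assert round(kin.ln_remaining(91.18), 2) == 4.51
        assert kin.ln_remaining(91.18) == pytest.approx(4.5128, abs=5e-4)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            kin.ln_remaining(0.0)


class TestWindowSelection:
    def test_manual_window_passes_through(self):
        w = kin.select_linear_window(np.arange(5.0), np.zeros(5), mode="manual", manual_window=(0, 40))
        assert w == (0.0, 40.0)

    def test_pure_exponential_selects_the_full_range(self):
        t = np.array([0, 5, 10, 20, 40, 60.0])
        lnx = math.log(100) - 0.03 * t
        assert kin.select_linear_window(t, lnx) == (0.0, 60.0)

    def test_reference_course_auto_window_matches_prefix_scan_oracle(self, depletion_course):
        # printed ln-column: the plateau past 50 min breaks log-linearity
        t = np.asarray(depletion_course.times)
        lnx = np.array([4.61, 4.51, 4.45, 4.36, 4.18, 3.97, 3.62, 3.22, 3.08, 3.06])
        assert kin.select_linear_window(t, lnx) == prefix_scan_oracle(t, lnx) == (0.0, 50.0)

    def test_no_linear_prefix_advises_manual_mode(self):
        rng = np.random.default_rng(0)
        t = np.arange(10.0)
        with pytest.raises(ValueError, match="manual"):
            kin.select_linear_window(t, rng.normal(0, 5, 10), r2_threshold=0.999)


class TestFitDepletion:
    def test_exact_line(self):
        t = np.array([0, 10, 20, 30.0])
        slope, intercept, r2 = kin.fit_depletion(t, -0.03 * t + 4.6, (0, 30))
        assert slope == pytest.approx(-0.03, abs=1e-12)
        assert intercept == pytest.approx(4.6, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_reference_course_printed_column_over_0_40(self, depletion_course):
        t = np.asarray(depletion_course.times)
        lnx = np.array([4.61, 4.51, 4.45, 4.36, 4.18, 3.97, 3.62, 3.22, 3.08, 3.06])
        slope, _, r2 = kin.fit_depletion(t, lnx, (0, 40))
        a, b = ols_normal_equations(t[t <= 40], lnx[t <= 40])
        assert slope == pytest.approx(a, abs=1e-10)
        assert slope == pytest.approx(-0.0340, abs=5e-4)
        assert r2 == pytest.approx(0.995, abs=5e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 60, 5))
        y = rng.normal(0, 1, 5)
        slope, intercept, _ = kin.fit_depletion(t, y, (t.min(), t.max()))
        a, b = ols_normal_equations(t, y)
        assert slope == pytest.approx(a, abs=1e-10)
        assert intercept == pytest.approx(b, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kin.fit_depletion(np.array([0, 1, 2, 3.0]), np.zeros(4), (0, 1))


class TestClearanceChain:
    def test_half_life_arithmetic_and_scaling_law(self):
        assert kin.half_life(-0.0693) == pytest.approx(10.0, abs=0.005)
        assert kin.half_life(-0.0297) == pytest.approx(23.34, abs=0.005)
        assert kin.half_life(-0.015) == pytest.approx(2 * kin.half_life(-0.03), rel=1e-12)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            kin.half_life(0.01)

    def test_intrinsic_clearance_from_anchored_slope(self):
        # chain anchored on the reported depletion slope
        cl = kin.intrinsic_clearance(kin.half_life(-0.0297))
        assert cl == pytest.approx(34.74, abs=0.01)

    def test_intrinsic_clearance_from_reported_half_life(self):
        assert kin.intrinsic_clearance(23.24) == pytest.approx(34.89, abs=0.01)

    def test_linearity_in_scaling_factors(self):
        base = kin.intrinsic_clearance(20.0)
        doubled = kin.intrinsic_clearance(20.0, kin.ScalingFactors(liver_mass=52.0))
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_ln2_cancels_in_slope_composition(self):
        # Clint(half_life(slope)) = |slope| * product of scaling factors, exactly
        s = kin.ScalingFactors()
        for slope in (-0.01, -0.0297, -0.2):
            assert kin.intrinsic_clearance(kin.half_life(slope), s) == pytest.approx(
                abs(slope) * s.product, rel=1e-12
            )

    @pytest.mark.parametrize(
        "cl,expected",
        [(34.74, "moderate"), (0.0, "low"), (8.6, "low"), (47.0, "moderate"), (47.1, "high")],
    )
    def test_clearance_classification_with_boundary_tie_breaks(self, cl, expected):
        assert kin.classify_clearance(cl) == expected

    def test_negative_clearance_rejected(self):
        with pytest.raises(ValueError):
            kin.classify_clearance(-1.0)


class TestHepaticModels:
    def test_zero_clearance_gives_zero_extraction_everywhere(self):
        out = kin.hepatic_models(0.0)
        for model in out.values():
            assert model["extraction_ratio"] == pytest.approx(0.0, abs=1e-12)

    def test_very_large_clearance_approaches_complete_extraction(self):
        out = kin.hepatic_models(1e7)
        for model in out.values():
            assert model["extraction_ratio"] == pytest.approx(1.0, abs=1e-4)

    def test_reported_clearance_sits_in_the_moderate_extraction_band(self):
        e_h = kin.hepatic_models(34.74)["well_stirred"]["extraction_ratio"]
        assert e_h == pytest.approx(0.627, abs=0.005)
        assert 0.3 < e_h < 0.7

    @settings(derandomize=True, max_examples=40)
    @given(cl=st.floats(0.1, 500.0))
    def test_model_ordering_well_stirred_below_dispersion_below_parallel_tube(self, cl):
        out = kin.hepatic_models(cl)
        assert (
            out["well_stirred"]["extraction_ratio"]
            <= out["dispersion"]["extraction_ratio"]
            <= out["parallel_tube"]["extraction_ratio"]
        )

    @settings(derandomize=True, max_examples=20)
    @given(cl=st.floats(0.1, 200.0))
    def test_extraction_strictly_increasing_in_clearance(self, cl):
        lo, hi = kin.hepatic_models(cl), kin.hepatic_models(cl * 1.1)
        for name in lo:
            assert hi[name]["extraction_ratio"] > lo[name]["extraction_ratio"]

    def test_dispersion_limits_recover_the_other_two_models(self):
        cl = 34.74
        pt = kin.hepatic_models(cl)["parallel_tube"]["extraction_ratio"]
        ws = kin.hepatic_models(cl)["well_stirred"]["extraction_ratio"]
        near_pt = kin.hepatic_models(cl, kin.HepaticModelConfig(dispersion_number=1e-4))
        near_ws = kin.hepatic_models(cl, kin.HepaticModelConfig(dispersion_number=1e4))
        assert near_pt["dispersion"]["extraction_ratio"] == pytest.approx(pt, abs=1e-3)
        assert near_ws["dispersion"]["extraction_ratio"] == pytest.approx(ws, abs=1e-3)

    def test_cl_h_is_q_times_extraction(self):
        out = kin.hepatic_models(34.74)
        for model in out.values():
            assert model["cl_h"] == pytest.approx(20.7 * model["extraction_ratio"], rel=1e-12)


class TestCsl:
    @pytest.mark.parametrize(
        "rates,kw,expected",
        [((0.0,), 1.0, 0.0), ((1.0, 2.0), 0.0, 1.0), ((1.0, 2.0), 1.0, 0.75)],
    )
    def test_composite_site_lability(self, rates, kw, expected):
        assert kin.csl_combine(kin.LabilitySites(rates, kw)) == pytest.approx(expected)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            kin.csl_combine(kin.LabilitySites((0.0,), 0.0))


class TestAnalyzeTimecourse:
    def test_reference_course_manual_window_chain(self, depletion_course):
        result = kin.analyze_timecourse(depletion_course, window_mode="manual", manual_window=(0, 40))
        assert result.window == (0.0, 40.0)
        assert result.slope == pytest.approx(-0.034, abs=1e-3)
        assert result.clearance_class == "moderate"
        assert result.t_half == pytest.approx(kin.LN2 / abs(result.slope), rel=1e-12)

    def test_auto_window_excludes_plateau(self, depletion_course):
        result = kin.analyze_timecourse(depletion_course)
        assert result.window[1] < max(depletion_course.times)
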