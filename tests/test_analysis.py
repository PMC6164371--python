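"""Inverse-radius regression, classification, Schram domain estimation."""

import numpy as np
import pytest

from vrfrap.analysis import (
    RegressionResult,
    VrFitSeries,
    alpha_crossover_radius,
    build_series,
    classify_motion,
    extrapolate_parameter,
    regress_vs_inverse_radius,
    schram_domain_size,
)
from vrfrap.fitting import FitResult


def fake_fit(model_key, params, R, stderr=None):
    return FitResult(model_key=model_key, params=params,
                     stderr=stderr or {k: 0.01 for k in params},
                     chi2=1.0, chi2_reduced=1.0, residuals=np.zeros(3),
                     converged=True, n_terms=19, bleach_radius=R,
                     sigma=0.03, sigma_source="given")


def rbm_series(Mp=0.75, L=0.09, radii=(0.32, 0.37, 0.44, 0.74), jitter=0.0,
               seed=0):
    rng = np.random.default_rng(seed)
    entries = []
    for R in radii:
        M = Mp + 0.63 * L / R + (rng.normal(0, jitter) if jitter else 0.0)
        entries.append((R, fake_fit("rbm", {"D": 0.2, "K": 1.0, "M": M}, R)))
    return VrFitSeries(entries=entries, model_key="rbm", length_unit="um")


class TestRegression:
    def test_constant_parameter_gives_flat_line(self):
        fits = [fake_fit("adm", {"K": 1.0, "D_alpha": 0.3, "alpha": 0.66}, R)
                for R in (1.0, 2.0, 3.0)]
        series = build_series(fits, "adm")
        reg = regress_vs_inverse_radius(series, "alpha")
        assert reg.slope == pytest.approx(0.0, abs=1e-12)
        assert reg.intercept == pytest.approx(0.66)

    def test_schram_generated_line_recovered_exactly(self):
        reg = regress_vs_inverse_radius(rbm_series(), "M")
        assert reg.slope == pytest.approx(0.63 * 0.09, rel=1e-10)
        assert reg.intercept == pytest.approx(0.75, rel=1e-10)
        assert reg.r_squared == pytest.approx(1.0)

    def test_permutation_invariance(self):
        s1 = rbm_series(jitter=0.01, seed=3)
        s2 = VrFitSeries(entries=list(reversed(s1.entries)), model_key="rbm",
                         length_unit="um")
        r1 = regress_vs_inverse_radius(s1, "M")
        r2 = regress_vs_inverse_radius(s2, "M")
        assert r1.slope == pytest.approx(r2.slope)
        assert r1.intercept == pytest.approx(r2.intercept)

    def test_radius_filter_and_minimum_points(self):
        series = rbm_series()
        with pytest.raises(ValueError):
            regress_vs_inverse_radius(series, "M", R_min=0.4)

    def test_model_parameter_mismatch(self):
        with pytest.raises(ValueError):
            regress_vs_inverse_radius(rbm_series(), "alpha")

    def test_needs_three_distinct_radii(self):
        fits = [fake_fit("rbm", {"D": 1, "K": 1, "M": 0.9}, 1.0)] * 3
        with pytest.raises(ValueError):
            VrFitSeries(entries=[(1.0, f) for f in fits], model_key="rbm")


def test_extrapolation_returns_intercept_and_error():
    reg = regress_vs_inverse_radius(rbm_series(), "M")
    value, err = extrapolate_parameter(reg)
    assert value == reg.intercept
    assert err == reg.intercept_stderr


class TestClassification:
    def reg(self, name, slope, stderr, intercept=0.7):
        return RegressionResult(parameter_name=name, slope=slope,
                                intercept=intercept, slope_stderr=stderr,
                                intercept_stderr=0.01, r_squared=0.9,
                                n_points=5, R_min_used=1.0)

    def test_negative_alpha_slope_is_ctrw(self):
        assert classify_motion(self.reg("alpha", -0.1, 0.02)) == "ctrw_like"

    def test_positive_slopes_are_domain_confined(self):
        assert classify_motion(self.reg("alpha", +0.1, 0.02)) == "domain_confined"
        assert classify_motion(
            M_regression=self.reg("M", +0.05, 0.01, intercept=0.75)
        ) == "domain_confined"

    def test_flat_and_unity_is_brownian(self):
        a = self.reg("alpha", 0.001, 0.01, intercept=1.0)
        m = self.reg("M", 0.0005, 0.01, intercept=0.99)
        assert classify_motion(a, m) == "brownian"

    def test_insignificant_nonunity_is_inconclusive(self):
        a = self.reg("alpha", 0.01, 0.05, intercept=0.6)
        assert classify_motion(a) == "inconclusive"

    def test_nothing_is_inconclusive(self):
        assert classify_motion() == "inconclusive"


class TestSchram:
    def reg_m(self, slope, intercept, R_min=0.32):
        return RegressionResult(parameter_name="M", slope=slope,
                                intercept=intercept, slope_stderr=0.001,
                                intercept_stderr=0.001, r_squared=0.99,
                                n_points=4, R_min_used=R_min,
                                length_unit="um")

    def test_arithmetic_inverse(self):
        est = schram_domain_size(self.reg_m(0.063, 0.80))
        assert est.L == pytest.approx(0.1)
        assert est.confined_fraction == pytest.approx(0.20)
        assert est.valid

    def test_free_fraction_three_quarters(self):
        est = schram_domain_size(self.reg_m(0.63 * 0.09, 0.75))
        assert est.Mp == pytest.approx(0.75)
        assert est.confined_fraction == pytest.approx(0.25)

    def test_pure_free_diffusion(self):
        est = schram_domain_size(self.reg_m(0.0, 1.0))
        assert est.L == 0.0
        assert est.confined_fraction == 0.0

    def test_negative_slope_invalid(self):
        est = schram_domain_size(self.reg_m(-0.02, 0.9))
        assert not est.valid

    def test_domain_larger_than_smallest_radius_invalid(self):
        est = schram_domain_size(self.reg_m(0.63 * 0.5, 0.8, R_min=0.32))
        assert est.L == pytest.approx(0.5)
        assert not est.valid

    def test_requires_mobile_fraction_regression(self):
        bad = RegressionResult(parameter_name="alpha", slope=0.1,
                               intercept=0.7, slope_stderr=0.01,
                               intercept_stderr=0.01, r_squared=0.9,
                               n_points=4, R_min_used=1.0)
        with pytest.raises(ValueError):
            schram_domain_size(bad)


class TestCrossover:
    def reg_a(self, slope, intercept):
        return RegressionResult(parameter_name="alpha", slope=slope,
                                intercept=intercept, slope_stderr=0.001,
                                intercept_stderr=0.001, r_squared=0.99,
                                n_points=5, R_min_used=0.3, length_unit="um")

    def test_subdiffusion_to_normal_transition_radius(self):
        cross = alpha_crossover_radius(self.reg_a(-0.032, 1.2))
        assert cross.radius == pytest.approx(0.16)
        assert cross.physical

    def test_intercept_exactly_one_infinite_radius(self):
        cross = alpha_crossover_radius(self.reg_a(-0.05, 1.0))
        assert np.isinf(cross.radius)

    def test_no_positive_crossover_flagged(self):
        cross = alpha_crossover_radius(self.reg_a(-0.05, 0.8))
        assert not cross.physical

    def test_zero_slope_error(self):
        with pytest.raises(ValueError):
            alpha_crossover_radius(self.reg_a(0.0, 0.9))
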