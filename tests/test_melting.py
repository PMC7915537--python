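"""Two-transition melting model: evaluation, transitions, fitting."""

import numpy as np
import pytest

from meiboquant.melting import (
    FitResult,
    HillParams,
    MeltingCurve,
    SOAT1_NULL_PARAMS,
    WILD_TYPE_PARAMS,
    _naive_hill,
    fit_melting,
    hill_model,
    melt_fraction_at,
    spline_transitions,
)
from meiboquant.synthetic_data import MeltSimSpec, default_melt_grid, simulate_melting_curve

# frozen oracle values computed with arbitrary-precision arithmetic
# (40-digit evaluation of the two-term Hill expression and bisection)
HILL_NULL_AT_304 = 0.746008974977043
MELT50_NULL_K = 326.3425166666
MELT50_WT_K = 297.8640629549


class TestHillModel:
    def test_low_temperature_limit(self):
        p = SOAT1_NULL_PARAMS
        assert hill_model(p.T1 / 10, p) == pytest.approx(p.A, abs=1e-6)

    def test_half_saturation_at_t1_with_single_term(self):
        p = HillParams(A=1.0, B=0.4, C=0.0, T1=300.0, T2=400.0, k=25.0, m=25.0)
        assert hill_model(300.0, p) == pytest.approx(1.0 - 0.2, abs=1e-15)

    def test_value_at_t1_matches_high_precision_oracle(self):
        assert hill_model(304.0, SOAT1_NULL_PARAMS) == pytest.approx(
            HILL_NULL_AT_304, abs=1e-12)

    def test_matches_naive_form_where_finite(self):
        p = HillParams(A=1.0, B=0.5, C=0.5, T1=290.0, T2=350.0, k=15.0, m=20.0)
        T = np.linspace(200.0, 400.0, 401)
        assert np.max(np.abs(hill_model(T, p) - _naive_hill(T, p))) < 1e-12

    def test_finite_at_extreme_cooperativity(self):
        p = HillParams(A=1.0, B=0.5, C=0.5, T1=289.0, T2=307.0, k=200.0, m=200.0)
        values = hill_model(np.linspace(250.0, 400.0, 500), p)
        assert np.all(np.isfinite(values))

    def test_monotonically_non_increasing(self):
        for p in (SOAT1_NULL_PARAMS, WILD_TYPE_PARAMS):
            values = hill_model(np.linspace(210.0, 450.0, 3000), p)
            assert np.all(np.diff(values) <= 1e-15)

    def test_high_temperature_limit(self):
        p = SOAT1_NULL_PARAMS
        assert hill_model(5000.0, p) == pytest.approx(p.A - p.B - p.C, abs=1e-6)

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError):
            hill_model(-10.0, SOAT1_NULL_PARAMS)

    @pytest.mark.parametrize("kwargs", [
        dict(A=0.0), dict(B=-0.1), dict(T1=400.0, T2=300.0), dict(k=0.0),
    ])
    def test_invalid_params_rejected(self, kwargs):
        base = dict(A=1.0, B=0.5, C=0.5, T1=300.0, T2=350.0, k=30.0, m=30.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            HillParams(**base)


class TestSplineTransitions:
    def test_two_transitions_near_t1_t2(self):
        curve = simulate_melting_curve(MeltSimSpec(SOAT1_NULL_PARAMS, noise_sd=0.0))
        trans = spline_transitions(curve)
        assert len(trans) == 2
        assert trans[0] == pytest.approx(SOAT1_NULL_PARAMS.T1, abs=2.0)
        assert trans[1] == pytest.approx(SOAT1_NULL_PARAMS.T2, abs=2.0)

    def test_flat_curve_has_none(self):
        curve = MeltingCurve(np.linspace(250.0, 400.0, 50), np.ones(50))
        assert spline_transitions(curve) == []

    def test_single_transition_when_one_term(self):
        p = HillParams(A=1.0, B=0.8, C=0.0, T1=310.0, T2=400.0, k=40.0, m=40.0)
        grid = np.linspace(250.0, 370.0, 150)
        curve = simulate_melting_curve(MeltSimSpec(p, grid, noise_sd=0.0))
        trans = spline_transitions(curve)
        assert len(trans) == 1
        assert trans[0] == pytest.approx(310.0, abs=2.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            MeltingCurve(np.linspace(250.0, 400.0, 5), np.ones(5))


class TestFitting:
    @pytest.mark.parametrize("truth", [SOAT1_NULL_PARAMS, WILD_TYPE_PARAMS],
                             ids=["soat1_null", "wild_type"])
    def test_noiseless_self_consistency(self, truth):
        curve = simulate_melting_curve(MeltSimSpec(truth, noise_sd=0.0))
        fit = fit_melting(curve)
        assert fit.converged
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.params.T1 == pytest.approx(truth.T1, abs=0.5)
        assert fit.params.T2 == pytest.approx(truth.T2, abs=0.5)
        assert fit.params.k == pytest.approx(truth.k, rel=0.05)
        assert fit.params.m == pytest.approx(truth.m, rel=0.05)

    def test_transition_bias_under_noise(self):
        # median bias over replicates stays below 1 K at noise SD 0.01
        t1s, t2s = [], []
        for seed in range(50):
            curve = simulate_melting_curve(
                MeltSimSpec(SOAT1_NULL_PARAMS, noise_sd=0.01, seed=seed))
            fit = fit_melting(curve)
            t1s.append(fit.params.T1)
            t2s.append(fit.params.T2)
        assert abs(np.mean(t1s) - SOAT1_NULL_PARAMS.T1) < 1.0
        assert abs(np.mean(t2s) - SOAT1_NULL_PARAMS.T2) < 1.0

    def test_steep_wild_type_curve_fits_without_overflow(self):
        curve = simulate_melting_curve(
            MeltSimSpec(WILD_TYPE_PARAMS, noise_sd=0.01, seed=3))
        fit = fit_melting(curve)
        assert fit.converged
        assert np.all(np.isfinite(fit.residuals))
        assert fit.r_squared > 0.99

    def test_result_ordering_t1_below_t2(self):
        init = HillParams(A=1.0, B=0.5, C=0.5, T1=360.0, T2=361.0, k=30.0, m=30.0)
        curve = simulate_melting_curve(MeltSimSpec(SOAT1_NULL_PARAMS, noise_sd=0.0))
        fit = fit_melting(curve, init=init)
        assert fit.params.T1 < fit.params.T2

    def test_non_convergence_is_flagged_not_raised(self):
        curve = simulate_melting_curve(
            MeltSimSpec(SOAT1_NULL_PARAMS, noise_sd=0.02, seed=1))
        fit = fit_melting(curve, max_nfev=2)
        assert isinstance(fit, FitResult)
        assert not fit.converged


class TestMeltFraction:
    def test_half_melt_is_t1_for_single_term(self):
        p = HillParams(A=1.0, B=0.5, C=0.0, T1=305.0, T2=400.0, k=30.0, m=30.0)
        assert melt_fraction_at(p, 0.5) == pytest.approx(305.0, abs=1e-6)

    def test_null_params_match_bisection_oracle(self):
        assert melt_fraction_at(SOAT1_NULL_PARAMS, 0.5) == pytest.approx(
            MELT50_NULL_K, abs=1e-6)

    def test_wild_type_params_match_bisection_oracle(self):
        assert melt_fraction_at(WILD_TYPE_PARAMS, 0.5) == pytest.approx(
            MELT50_WT_K, abs=1e-6)

    def test_small_fraction_is_below_t1(self):
        assert melt_fraction_at(SOAT1_NULL_PARAMS, 0.01) < SOAT1_NULL_PARAMS.T1

    def test_zero_contributions_rejected(self):
        p = HillParams(A=1.0, B=0.0, C=0.0, T1=300.0, T2=350.0, k=30.0, m=30.0)
        with pytest.raises(ValueError):
            melt_fraction_at(p, 0.5)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_fraction_bounds(self, bad):
        with pytest.raises(ValueError):
            melt_fraction_at(SOAT1_NULL_PARAMS, bad)
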