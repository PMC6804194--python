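"""Parameter surfaces, isotherm, batch equilibrium solver and Langmuir fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pasorption import (
    BatchSystem,
    Condition,
    LangmuirParameters,
    RationalSurfaceCoefficients,
    DEFAULT_KEQ_COEFFS,
    DEFAULT_SCWM_COEFFS,
    evaluate_surface,
    fit_langmuir,
    isotherm_q,
    langmuir_parameters,
    solve_batch_equilibrium,
)
from pasorption.errors import (
    DegenerateSystemError,
    ExtrapolationWarning,
    FitFailureError,
    InvalidParameterError,
    SingularSurfaceError,
)

# An alternative surface parameterization used to exercise the rational
# evaluation against independently hand-computed values.
ALT_KEQ = RationalSurfaceCoefficients(
    numerator=(1.21e-3, -2.69e-3, 0.0), denominator=(0.0, -9.01, -1.25e2, 1.0), label="Keq"
)
ALT_SCWM = RationalSurfaceCoefficients(
    numerator=(4.57e-1, 0.0, 2.04e1), denominator=(0.0, 4.57e-1, -6.69, 1.0), label="Scwm"
)


class TestCondition:
    def test_celsius_round_trip(self):
        cond = Condition.from_celsius(35.0, 15.0)
        assert cond.temperature_K == pytest.approx(308.15)
        assert cond.temperature_C == pytest.approx(35.0)

    @pytest.mark.parametrize("t_c,e,extrapolated", [
        (15.0, 0.0, False), (35.0, 15.0, False), (25.0, 7.5, False),
        (10.0, 0.0, True), (40.0, 0.0, True), (20.0, 20.0, True),
    ])
    def test_extrapolation_flag(self, t_c, e, extrapolated):
        assert Condition.from_celsius(t_c, e).is_extrapolated is extrapolated

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            Condition(temperature_K=0.0, ethanol_pct=0.0)
        with pytest.raises(ValueError):
            Condition(temperature_K=300.0, ethanol_pct=-1.0)


class TestEvaluateSurface:
    def test_direct_ratio(self):
        coeffs = RationalSurfaceCoefficients(numerator=(2.0, 0.0, 0.0),
                                             denominator=(0.0, 1.0, 0.0, 0.0))
        assert evaluate_surface(coeffs, Condition(2.0, 0.0)) == pytest.approx(1.0)

    @pytest.mark.parametrize("coeffs,expected", [
        # hand-evaluated: (1.21e-3 - 2.69e-3*308.15) / (-9.01*308.15 - 125*15 + 308.15*15)
        (ALT_KEQ, 0.0283643),
        # hand-evaluated: (0.457 + 20.4*15) / (-6.69*15 + 0.457*308.15 + 308.15*15)
        (ALT_SCWM, 0.0657249),
    ])
    def test_hand_evaluated_rational(self, coeffs, expected, finished_wine):
        assert evaluate_surface(coeffs, finished_wine) == pytest.approx(expected, rel=1e-4)

    @given(
        num=st.tuples(*[st.floats(-10, 10) for _ in range(3)]),
        den=st.tuples(*[st.floats(0.5, 10) for _ in range(4)]),
        t=st.floats(1.0, 400.0),
        e=st.floats(0.0, 20.0),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_matches_direct_arithmetic(self, num, den, t, e):
        coeffs = RationalSurfaceCoefficients(numerator=num, denominator=den)
        expected = (num[0] + num[1] * t + num[2] * e) / (
            den[0] + den[1] * t + den[2] * e + den[3] * t * e
        )
        assert evaluate_surface(coeffs, Condition(t, e)) == pytest.approx(expected)

    def test_singular_denominator_names_condition(self):
        coeffs = RationalSurfaceCoefficients(numerator=(1.0, 0.0, 0.0),
                                             denominator=(-300.0, 1.0, 0.0, 0.0),
                                             label="Keq")
        with pytest.raises(SingularSurfaceError, match="Keq"):
            evaluate_surface(coeffs, Condition(300.0, 0.0))


class TestLangmuirParameters:
    def test_defaults_positive_on_calibrated_grid(self):
        """K and S are strictly positive over the full calibrated envelope."""
        for t_c in np.arange(15.0, 35.0 + 1e-9, 0.5):
            for e in (0.0, 7.5, 12.0, 15.0):
                p = langmuir_parameters(Condition.from_celsius(t_c, e))
                assert p.keq > 0 and p.scwm > 0

    def test_deterministic(self, finished_wine):
        a = langmuir_parameters(finished_wine)
        b = langmuir_parameters(finished_wine)
        assert (a.keq, a.scwm) == (b.keq, b.scwm)

    def test_override_coefficients_used(self, finished_wine):
        p_default = langmuir_parameters(finished_wine)
        p_alt = langmuir_parameters(finished_wine, ALT_KEQ, ALT_SCWM)
        assert p_alt.keq == pytest.approx(0.0283643, rel=1e-4)
        assert p_alt.scwm == pytest.approx(0.0657249, rel=1e-4)
        assert p_alt.keq != p_default.keq

    def test_extrapolation_warns(self):
        with pytest.warns(ExtrapolationWarning):
            langmuir_parameters(Condition.from_celsius(40.0, 0.0))

    def test_nonpositive_surface_rejected(self, finished_wine):
        negative = RationalSurfaceCoefficients(numerator=(-1.0, 0.0, 0.0),
                                               denominator=(1.0, 0.0, 0.0, 0.0))
        with pytest.raises(InvalidParameterError):
            langmuir_parameters(finished_wine, negative, DEFAULT_SCWM_COEFFS)


class TestIsotherm:
    def test_empty_solution(self, simple_params):
        assert isotherm_q(0.0, simple_params) == 0.0

    def test_half_saturation(self, simple_params):
        # K*C = 1 sits exactly at half the capacity
        assert isotherm_q(1.0, simple_params) == pytest.approx(0.2)

    def test_saturation_asymptote(self, simple_params):
        assert isotherm_q(1e9, simple_params) == pytest.approx(0.4, abs=1e-6)

    def test_negative_concentration_rejected(self, simple_params):
        with pytest.raises(ValueError):
            isotherm_q(-1.0, simple_params)

    @given(c=st.lists(st.floats(0, 1e5), min_size=2, max_size=20),
           k=st.floats(1e-4, 10), s=st.floats(1e-3, 1.0))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_bounded_and_monotone(self, c, k, s):
        params = LangmuirParameters(k, s)
        q = isotherm_q(np.sort(np.asarray(c)), params)
        assert np.all(q >= 0) and np.all(q < s)
        assert np.all(np.diff(q) >= -1e-12 * s)  # non-decreasing up to roundoff


def _bisect_equilibrium(system, params, tol=1e-14):
    """Independent oracle: bisection on the mass-balance residual in C."""
    V, m, total = system.liquid_volume_L, system.cwm_mass_mg, system.total_pa_mg

    def residual(c):
        return c * V + isotherm_q(c, params) * m - total

    lo, hi = 0.0, total / V
    if residual(hi) <= 0:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo <= tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


class TestBatchEquilibrium:
    def test_no_adsorbent(self, simple_params):
        state = solve_batch_equilibrium(BatchSystem(1.0, 0.0, 100.0), simple_params)
        assert state.c_pa_mg_per_L == pytest.approx(100.0)
        assert state.q_pa_mg_per_mg == 0.0

    def test_forward_substitution(self, simple_params):
        # with C = 1: q = 1*0.4/2 = 0.2, so total = 1*1 + 1000*0.2 = 201
        state = solve_batch_equilibrium(BatchSystem(1.0, 1000.0, 201.0), simple_params)
        assert state.c_pa_mg_per_L == pytest.approx(1.0, rel=1e-12)
        assert state.q_pa_mg_per_mg == pytest.approx(0.2, rel=1e-12)

    def test_zero_volume_rejected(self, simple_params):
        with pytest.raises(DegenerateSystemError):
            solve_batch_equilibrium(BatchSystem(0.0, 10.0, 5.0), simple_params)

    def test_zero_total_is_empty_state(self, simple_params):
        state = solve_batch_equilibrium(BatchSystem(1.0, 10.0, 0.0), simple_params)
        assert state.c_pa_mg_per_L == 0.0 and state.adsorbed_mg == 0.0

    def test_matches_bisection_oracle(self, rng):
        for _ in range(200):
            system = BatchSystem(10 ** rng.uniform(-3, 1),
                                 10 ** rng.uniform(0, 4),
                                 10 ** rng.uniform(-1, 4))
            params = LangmuirParameters(10 ** rng.uniform(-4, 1), 10 ** rng.uniform(-3, 0))
            state = solve_batch_equilibrium(system, params)
            oracle = _bisect_equilibrium(system, params)
            assert state.c_pa_mg_per_L == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    @given(v=st.floats(1e-3, 10), m=st.floats(1e-2, 1e4), total=st.floats(0, 1e4),
           k=st.floats(1e-4, 10), s=st.floats(1e-3, 1.0))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_mass_conservation_and_bounds(self, v, m, total, k, s):
        system = BatchSystem(v, m, total)
        params = LangmuirParameters(k, s)
        state = solve_batch_equilibrium(system, params)
        assert state.mass_residual <= 1e-9 * max(total, 1.0)
        assert state.c_pa_mg_per_L >= 0
        assert 0 <= state.q_pa_mg_per_mg < s


class TestFitLangmuir:
    def test_exact_recovery_on_noise_free_data(self):
        truth = LangmuirParameters(0.01, 0.3)
        c = np.array([10.0, 50.0, 100.0, 300.0, 700.0, 1500.0])
        pts = np.column_stack([c, isotherm_q(c, truth)])
        fit = fit_langmuir(pts)
        assert fit.converged
        assert fit.params.keq == pytest.approx(truth.keq, rel=1e-6)
        assert fit.params.scwm == pytest.approx(truth.scwm, rel=1e-6)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-10)

    def test_null_isotherm_degenerate(self):
        pts = [(10.0, 0.0), (100.0, 0.0), (1000.0, 0.0)]
        with pytest.raises(FitFailureError, match="null isotherm"):
            fit_langmuir(pts)

    @pytest.mark.parametrize("pts", [
        [(1.0, 0.1), (2.0, 0.2)],                      # too few
        [(5.0, 0.1), (5.0, 0.1), (5.0, 0.1)],          # one distinct c
        [(1.0, -0.1), (2.0, 0.2), (3.0, 0.3)],         # negative q
    ])
    def test_degenerate_designs_rejected(self, pts):
        with pytest.raises(FitFailureError):
            fit_langmuir(pts)
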