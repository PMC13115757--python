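"""Binding-equilibrium solvers, isotherm fits and stoichiometry selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from dclkit import (
    DomainError,
    Titration,
    ValidationError,
    complex_fraction_1to1,
    complex_fraction_1to2,
    fit_binding_isotherm,
    linearized_fit_1to1,
    predict_anisotropy,
    select_stoichiometry,
)
from dclkit.binding import BindingFit
from dclkit import synth


def bisection_fraction(K, G, H):
    """Independent oracle: bisection on the 1:1 mass-balance polynomial."""
    if K == 0 or H == 0 or G == 0:
        return 0.0

    def g(c):
        return K * c * c - (K * G + K * H + 1.0) * c + K * G * H

    c = brentq(g, 0.0, min(G, H), xtol=1e-300, rtol=8.9e-16, maxiter=200)
    return c / G


class TestComplexFraction1to1:
    def test_zero_constant_gives_no_binding(self):
        assert complex_fraction_1to1(0.0, 1e-6, 5e-3, mode="exact") == 0.0
        assert complex_fraction_1to1(0.0, 1e-6, 5e-3, mode="host_excess") == 0.0

    def test_half_saturation_in_host_excess(self):
        # K*H = 1 puts the guest exactly half bound
        assert complex_fraction_1to1(200.0, 1e-6, 5e-3,
                                     mode="host_excess") == pytest.approx(0.5)

    def test_exact_agrees_with_host_excess_in_excess_regime(self):
        f_ex = complex_fraction_1to1(200.0, 1e-6, 5e-3, mode="exact")
        f_he = complex_fraction_1to1(200.0, 1e-6, 5e-3, mode="host_excess")
        assert f_ex == pytest.approx(f_he, rel=1e-3)

    def test_exact_matches_bisection_oracle_on_random_grid(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            K = 10 ** rng.uniform(0, 4)
            G = 10 ** rng.uniform(-7, -3)
            H = rng.uniform(0, 0.02)
            f = complex_fraction_1to1(K, G, H, mode="exact")
            assert f == pytest.approx(bisection_fraction(K, G, H), abs=1e-9)

    def test_excess_approximation_within_half_percent_at_100x(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            K = 10 ** rng.uniform(0, 3)
            G = 10 ** rng.uniform(-7, -5)
            H = rng.uniform(100 * G, 0.02)
            f_ex = complex_fraction_1to1(K, G, H, mode="exact")
            f_he = complex_fraction_1to1(K, G, H, mode="host_excess")
            assert abs(f_ex - f_he) <= 0.005 * max(f_he, 1e-12) + 1e-12

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            complex_fraction_1to1(-1.0, 1e-6, 1e-3)
        with pytest.raises(DomainError):
            complex_fraction_1to1(100.0, 1e-6, -1e-3)


class TestComplexFraction1to2:
    def test_zero_constant(self):
        assert complex_fraction_1to2(0.0, 1e-3) == 0.0

    def test_half_saturation_at_inverse_sqrt_K(self):
        K = 3.7e7
        assert complex_fraction_1to2(K, K ** -0.5) == pytest.approx(0.5)

    def test_high_saturation_value(self):
        # K H^2 = 100 -> f = 100/101
        assert complex_fraction_1to2(1e8, 1e-3) == pytest.approx(100 / 101)

    @given(st.floats(1e2, 1e12), st.floats(0, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_fraction_bounded_and_monotone(self, K, H):
        f = complex_fraction_1to2(K, H)
        assert 0.0 <= f <= 1.0
        assert complex_fraction_1to2(K, H * 2) >= f


class TestPredictAnisotropy:
    def test_limits_and_midpoint(self):
        fit = BindingFit("1:1", K=200.0, r_free=0.005, r_inf=0.047)
        assert predict_anisotropy(fit, 0.0) == pytest.approx(0.005)
        assert predict_anisotropy(fit, 1e3) == pytest.approx(0.047, rel=1e-4)
        # f_bound = 0.5 at K*H = 1
        assert predict_anisotropy(fit, 1 / 200.0) == pytest.approx(0.026)

    def test_monotone_in_host_concentration(self):
        for stoich, K in (("1:1", 150.0), ("1:2", 5e7)):
            fit = BindingFit(stoich, K=K, r_free=0.004, r_inf=0.05)
            h = np.linspace(0, 0.02, 200)
            r = predict_anisotropy(fit, h)
            assert np.all(np.diff(r) >= -1e-15)


class TestIsothermFit:
    def test_noiseless_round_trip(self, noiseless_titration):
        t, truth = noiseless_titration
        fit = fit_binding_isotherm(t, "1:1")
        assert fit.K == pytest.approx(truth["K"], rel=1e-3)
        assert fit.r_free == pytest.approx(truth["r_free"], rel=1e-3)
        assert fit.r_inf == pytest.approx(truth["r_inf"], rel=1e-3)
        assert fit.residual_ss < 1e-12

    def test_noisy_K_within_confidence_interval(self):
        from scipy import stats
        hits = 0
        for seed in range(40):
            t, truth = synth.make_titration(K=200.0, sigma_r=0.001, seed=seed)
            fit = fit_binding_isotherm(t, "1:1")
            tq = stats.t.ppf(0.975, len(t) - 3)
            if abs(fit.K - truth["K"]) <= tq * fit.std_errors["K"]:
                hits += 1
        assert hits >= 32  # ~95% nominal coverage, generous floor

    def test_flat_series_flags_unidentifiable_K(self):
        t = Titration(host_conc=np.linspace(0, 0.01, 8),
                      r_obs=np.full(8, 0.02), temperature=298.15,
                      medium="PBS_pH7.4", guest_total=1e-6)
        fit = fit_binding_isotherm(t, "1:1")
        assert "K_unidentifiable" in fit.warnings

    def test_too_few_points_rejected(self):
        t = Titration(host_conc=[0, 1e-3, 2e-3, 3e-3],
                      r_obs=[0.005, 0.01, 0.013, 0.016],
                      temperature=298.15, medium="water_pH7.4",
                      guest_total=1e-6)
        with pytest.raises(ValidationError):
            fit_binding_isotherm(t, "1:1")

    def test_1to2_round_trip(self):
        t, truth = synth.make_titration(K=1e8, stoichiometry="1:2",
                                        host_max=1e-3, sigma_r=0.0)
        fit = fit_binding_isotherm(t, "1:2")
        assert fit.K == pytest.approx(1e8, rel=1e-3)
        assert fit.K_sqrt ** 2 == pytest.approx(fit.K, rel=1e-9)


class TestLinearizedFit:
    def test_matches_nonlinear_fit_on_noiseless_data(self, noiseless_titration):
        t, truth = noiseless_titration
        lin = linearized_fit_1to1(t)
        nl = fit_binding_isotherm(t, "1:1")
        assert lin.K == pytest.approx(nl.K, rel=1e-3)
        assert lin.r_inf == pytest.approx(nl.r_inf, rel=1e-3)
        assert lin.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_point_series_passes_through(self):
        t = Titration(host_conc=[0, 2e-3, 6e-3],
                      r_obs=[0.005, 0.0150, 0.0264],
                      temperature=298.15, medium="citrate_pH3.5",
                      guest_total=1e-6)
        lin = linearized_fit_1to1(t)
        assert lin.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_worse_fit_on_sigmoidal_1to2_data(self):
        t, _ = synth.make_titration(K=1e8, stoichiometry="1:2",
                                    host_max=1e-3, sigma_r=0.0)
        lin = linearized_fit_1to1(t)
        fit12 = fit_binding_isotherm(t, "1:2")
        # the 1:2 model nails the data; the reciprocal line cannot
        assert fit12.residual_ss < 1e-12
        assert lin.r_squared < 0.98


class TestStoichiometrySelection:
    @pytest.mark.parametrize("stoich,K,host_max", [
        ("1:1", 200.0, 12e-3),
        ("1:2", 1e8, 1e-3),
    ])
    def test_noiseless_selection_with_decisive_gap(self, stoich, K, host_max):
        t, _ = synth.make_titration(K=K, stoichiometry=stoich,
                                    host_max=host_max, sigma_r=0.0)
        rep = select_stoichiometry(t)
        assert rep.selected == stoich
        assert rep.delta_aicc > 10

    def test_selection_accuracy_on_noisy_grid(self):
        correct = 0
        n = 0
        for seed in range(30):
            for stoich, K, hmax in (("1:1", 200.0, 12e-3),
                                    ("1:2", 1e8, 1e-3)):
                t, _ = synth.make_titration(K=K, stoichiometry=stoich,
                                            host_max=hmax, sigma_r=0.001,
                                            seed=seed)
                correct += select_stoichiometry(t).selected == stoich
                n += 1
        assert correct / n >= 0.95


class TestTitrationValidation:
    def test_requires_zero_host_point(self):
        with pytest.raises(ValidationError):
            Titration(host_conc=[1e-3, 2e-3, 3e-3, 4e-3, 5e-3],
                      r_obs=[0.01] * 5, temperature=298.15,
                      medium="PBS_pH7.4", guest_total=1e-6)

    def test_rejects_unknown_medium_and_bad_anisotropy(self):
        with pytest.raises(ValidationError):
            Titration(host_conc=[0, 1e-3], r_obs=[0.01, 0.02],
                      temperature=298.15, medium="DMSO", guest_total=1e-6)
        with pytest.raises(ValidationError):
            Titration(host_conc=[0, 1e-3], r_obs=[0.01, 0.6],
                      temperature=298.15, medium="PBS_pH7.4",
                      guest_total=1e-6)
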