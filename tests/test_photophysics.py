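"""Anisotropy arithmetic, decay fitting, mean lifetimes and quenching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dclkit import (
    DecayTrace,
    DomainError,
    FitError,
    QuenchSeries,
    ValidationError,
    anisotropy_from_intensities,
    emission_peak_nm,
    fit_decay,
    stern_volmer_fit,
    weighted_mean_lifetime,
)
from dclkit import synth


class TestAnisotropyFromIntensities:
    @pytest.mark.parametrize("ivv,ivh,g,expected", [
        (3.0, 3.0, 1.0, 0.0),     # fully depolarized: I_VV = G I_VH
        (5.0, 0.0, 1.0, 1.0),     # no perpendicular component
        (2.0, 1.0, 1.0, 0.25),
    ])
    def test_known_values(self, ivv, ivh, g, expected):
        assert anisotropy_from_intensities(ivv, ivh, g) == pytest.approx(expected)

    @given(st.floats(-0.19, 0.39), st.floats(1e2, 1e7), st.floats(0.5, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_inverts_polarized_intensity_synthesis(self, r, total, G):
        # forward synthesis: I_VV = (1+2r)/3 * total, I_VH = (1-r)/(3G) * total
        I_VV = (1 + 2 * r) / 3 * total
        I_VH = (1 - r) / (3 * G) * total
        assert anisotropy_from_intensities(I_VV, I_VH, G) == pytest.approx(
            r, abs=1e-12)

    def test_zero_intensity_rejected(self):
        with pytest.raises(DomainError):
            anisotropy_from_intensities(0.0, 0.0, 1.0)


class TestWeightedMeanLifetime:
    def test_single_component_is_identity(self):
        assert weighted_mean_lifetime([1.0], [4.2]) == pytest.approx(4.2)

    def test_two_component_hand_value(self):
        # sum(A tau^2)/sum(A tau) = (2+8)/(1+2) = 10/3
        assert weighted_mean_lifetime([0.5, 0.5], [2.0, 4.0]) == pytest.approx(
            10 / 3)

    @given(st.lists(st.tuples(st.floats(0.01, 10), st.floats(0.1, 50)),
                    min_size=1, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_extreme_lifetimes_and_scale_invariant(self, comps):
        A = [a for a, _ in comps]
        tau = [t for _, t in comps]
        m = weighted_mean_lifetime(A, tau)
        assert min(tau) - 1e-12 <= m <= max(tau) + 1e-12
        assert weighted_mean_lifetime([3.7 * a for a in A], tau) == \
            pytest.approx(m, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            weighted_mean_lifetime([0.0, 0.0], [1.0, 2.0])
        with pytest.raises(DomainError):
            weighted_mean_lifetime([1.0], [1.0, 2.0])


class TestFitDecay:
    def test_noiseless_monoexponential_round_trip(self):
        trace, _ = synth.make_decay(poisson=False)
        fit = fit_decay(trace, 1)
        assert fit.lifetimes[0] == pytest.approx(4.2, rel=1e-3)
        assert fit.mean_lifetime == pytest.approx(4.2, rel=1e-3)

    def test_poisson_noised_recovery_and_chi_square(self):
        trace, _ = synth.make_decay(seed=2)
        fit = fit_decay(trace, 1)
        assert fit.lifetimes[0] == pytest.approx(4.2, rel=0.02)
        assert 0.8 <= fit.reduced_chisq <= 1.2

    def test_biexponential_components_recovered(self):
        trace, _ = synth.make_decay(lifetimes=(1.5, 8.0),
                                    amplitudes=(0.6, 0.4), poisson=False)
        fit = fit_decay(trace, 2)
        assert fit.lifetimes[0] == pytest.approx(1.5, rel=0.02)
        assert fit.lifetimes[1] == pytest.approx(8.0, rel=0.02)

    def test_background_only_trace_raises(self):
        t = np.linspace(0, 100, 1024, endpoint=False)
        rng = np.random.default_rng(0)
        trace = DecayTrace(channel_time=t, counts=rng.poisson(5.0, t.size))
        with pytest.raises(FitError):
            fit_decay(trace, 1)

    def test_counts_must_be_integral(self):
        t = np.linspace(0, 100, 256, endpoint=False)
        with pytest.raises(ValidationError):
            DecayTrace(channel_time=t, counts=np.full(t.size, 1.5))


class TestSternVolmer:
    def test_linear_series_hand_values(self):
        # slope 120 dm^3/mol, tau0 4.2 ns -> k_q = 2.857e10 dm^3/mol/s
        s, _ = synth.make_quench(K_SV=120.0, tau0=4.2, sigma_frac=0.0)
        res = stern_volmer_fit(s)
        assert res.K_SV == pytest.approx(120.0, rel=1e-9)
        assert res.k_q == pytest.approx(120.0 / 4.2e-9, rel=1e-9)
        assert res.linear_mask.all()

    def test_intensity_and_lifetime_routes_agree_when_dynamic(self):
        s, _ = synth.make_quench(sigma_frac=0.0)
        ki = stern_volmer_fit(s, use="intensity").K_SV
        kl = stern_volmer_fit(s, use="lifetime").K_SV
        assert ki == pytest.approx(kl, rel=0.01)

    def test_curved_series_masks_tail_and_recovers_dynamic_slope(self):
        s, truth = synth.make_quench(static_beta=1500.0, seed=1)
        res = stern_volmer_fit(s)
        assert res.warnings  # curvature flagged
        assert res.linear_mask.sum() < len(s)  # high-[Q] tail excluded
        assert not res.linear_mask[-3:].any()
        assert res.K_SV == pytest.approx(truth["K_SV"], rel=0.05)

    def test_series_without_zero_point_rejected(self):
        with pytest.raises(ValidationError):
            QuenchSeries(quencher_conc=[0.01, 0.02, 0.03, 0.04],
                         intensity_ratio=[2.2, 3.4, 4.6, 5.8], tau0=4.2)

    def test_ratio_below_unity_rejected(self):
        with pytest.raises(ValidationError):
            QuenchSeries(quencher_conc=[0.0, 0.01, 0.02, 0.03],
                         intensity_ratio=[1.0, 0.8, 2.0, 3.0], tau0=4.2)


class TestEmissionPeak:
    def test_band_positions_and_red_shift(self):
        wl_l, I_l, _ = synth.make_emission_spectrum("lactone")
        wl_c, I_c, _ = synth.make_emission_spectrum("carboxylate")
        p_l = emission_peak_nm(wl_l, I_l)
        p_c = emission_peak_nm(wl_c, I_c)
        assert p_l == pytest.approx(431.0, abs=0.5)
        assert p_c - p_l == pytest.approx(14.0, abs=0.5)
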