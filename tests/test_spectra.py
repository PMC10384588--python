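"""Solvent spectrum models, friction/viscosity conversions, classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vaspipe as vp
from vaspipe.constants import KB

T = 298.15
KT = KB * T


# ------------------------------------------------------------- water model

class TestWaterVAS:
    def test_zero_frequency_plateau(self):
        p = vp.CoupledLEParams(gamma=2e-12, k=1e-8, n=3, T=T)
        assert vp.eval_water_vas(0.0, p) == pytest.approx(KT / (3 * p.gamma))

    def test_single_neighbour_is_flat(self):
        p = vp.CoupledLEParams(gamma=2e-12, k=1e-8, n=1, T=T)
        w = np.logspace(0, 8, 30)
        assert vp.eval_water_vas(w, p) == pytest.approx(KT / p.gamma, rel=1e-14)

    def test_known_point_n2(self):
        # omega*tau_c = sqrt(2), n=2: (n+x)/(n^2+x) = 4/6
        p = vp.CoupledLEParams(gamma=2e-12, k=1e-8, n=2, T=T)
        w = np.sqrt(2.0) / p.tau_c
        assert vp.eval_water_vas(w, p) == pytest.approx(
            (2.0 / 3.0) * KT / p.gamma, rel=1e-12)

    @given(loggamma=st.floats(-14, -10), logtau=st.floats(-6, -2),
           n=st.integers(1, 8))
    def test_limits_and_monotonicity(self, loggamma, logtau, n):
        gamma, tau = 10.0**loggamma, 10.0**logtau
        p = vp.CoupledLEParams.from_tau(gamma=gamma, tau_c=tau, n=n, T=T)
        assert vp.eval_water_vas(0.0, p) * n * gamma / KT == pytest.approx(1.0, rel=1e-9)
        w_hi = 1e6 / tau
        assert vp.eval_water_vas(w_hi, p) * gamma / KT == pytest.approx(1.0, rel=1e-6)
        w = np.logspace(np.log10(1e-3 / tau), np.log10(1e3 / tau), 200)
        D = vp.eval_water_vas(w, p)
        assert np.all(np.diff(D) >= -1e-14 * D[:-1])  # ulp slack for n=1

    def test_rejects_invalid_input(self):
        p = vp.CoupledLEParams(gamma=2e-12, k=1e-8, n=2, T=T)
        with pytest.raises(ValueError):
            vp.eval_water_vas(np.array([1.0, np.nan]), p)
        with pytest.raises(ValueError):
            vp.eval_water_vas(-1.0, p)
        with pytest.raises(ValueError):
            vp.CoupledLEParams(gamma=2e-12, k=1e-8, n=0, T=T)

    def test_matches_complete_graph_oracle(self):
        # the n-molecule model is exactly the per-particle VAS of K_n
        gamma, k, n = 2e-12, 4e-9, 4
        p = vp.CoupledLEParams(gamma=gamma, k=k, n=n, T=T)
        K = -k * np.ones((n, n))
        np.fill_diagonal(K, k * (n - 1))
        net = vp.LangevinNetwork(masses=np.zeros(n),
                                 frictions=np.full(n, gamma), K=K, T=T)
        w = 2 * np.pi * np.logspace(1, 4, 12)
        assert vp.oracle_vas(net, w, 0) == pytest.approx(
            vp.eval_water_vas(w, p), rel=1e-12)


# ----------------------------------------------------------- mixture model

class TestMixtureVAS:
    def test_no_clusters_reduces_to_water_model(self):
        # star of 1 + n_w waters == single-species model with n = n_w + 1
        m = vp.MixtureLEParams(gamma=4e-12, k=2e-7, omega_o=1e4, T=T,
                               n_w=2, n_c=0)
        p = vp.CoupledLEParams(gamma=4e-12, k=2e-7, n=3, T=T)
        w = np.logspace(1, 6, 50)
        assert vp.eval_mixture_vas(w, m) == pytest.approx(
            vp.eval_water_vas(w, p), rel=1e-12)

    def test_matches_network_oracle(self, mixture_params):
        m = mixture_params
        net = vp.build_mixture_motif(m.n_w, m.n_c, 0.0, m.M_cluster,
                                     m.gamma, m.k, m.T)
        rng = np.random.default_rng(0)
        w = 2 * np.pi * 10 ** rng.uniform(0, 5, size=100)
        w.sort()
        Dc = vp.eval_mixture_vas(w, m)
        Do = vp.oracle_vas(net, w, 0)
        assert Dc == pytest.approx(Do, rel=1e-8)

    def test_monotone_decreasing_on_band(self, mixture_spectrum):
        assert np.all(np.diff(mixture_spectrum.D) < 0)

    def test_zero_frequency_is_com_diffusivity(self, mixture_params):
        m = mixture_params
        expect = KB * m.T / ((1 + m.n_w + m.n_c) * m.gamma)
        assert vp.eval_mixture_vas(0.0, m) == pytest.approx(expect, rel=1e-12)

    def test_tau_override_must_be_consistent(self):
        with pytest.raises(ValueError):
            vp.MixtureLEParams(gamma=4e-12, k=2e-7, omega_o=1e4, T=T,
                               tau=1.0)
        m = vp.MixtureLEParams(gamma=4e-12, k=2e-7, omega_o=1e4, T=T,
                               tau=4e-12 / 2e-7)
        assert m.tau == pytest.approx(m.gamma / m.k)


# ------------------------------------------------ friction and viscosity

class TestConversions:
    def test_friction_value(self):
        spec = vp.VelocitySpectrum(freq=[50.0, 100.0], D=[2.0e-9, 2.0e-9])
        fric = vp.friction_from_vas(spec, T)
        assert fric.gamma == pytest.approx(KT / 2.0e-9, rel=1e-12)
        assert fric.gamma[0] == pytest.approx(2.058e-12, rel=1e-3)

    def test_round_trip_identity(self, water_spectrum):
        back = vp.vas_from_friction(vp.friction_from_vas(water_spectrum, T), T)
        assert back.D == pytest.approx(water_spectrum.D, rel=1e-15)
        assert back.freq == pytest.approx(water_spectrum.freq)

    def test_monotonicity_reversal(self, water_spectrum):
        fric = vp.friction_from_vas(water_spectrum, T)
        assert np.all(np.diff(water_spectrum.D) > 0)
        assert np.all(np.diff(fric.gamma) < 0)

    def test_viscosity_value_and_linearity(self):
        fric = vp.FrictionSpectrum(freq=[50.0, 100.0],
                                   gamma=[1.884e-12, 3.768e-12], T=T)
        vpar = vp.ViscosityParams(R=1e-10, s_factor=6)
        eta = vp.viscosity_from_friction(fric, vpar)
        assert eta[0] == pytest.approx(1.0e-3, rel=1e-3)
        assert eta[1] == pytest.approx(2 * eta[0], rel=1e-12)

    def test_rejects_nonpositive_diffusivity(self):
        with pytest.raises(ValueError):
            vp.VelocitySpectrum(freq=[1.0, 2.0], D=[1e-9, -1e-9])


# ------------------------------------------------------------ classification

class TestClassifyRheology:
    def test_water_is_thinning(self, water_spectrum):
        assert vp.classify_rheology(water_spectrum) == "thinning"

    def test_mixture_is_thickening(self, mixture_spectrum):
        assert vp.classify_rheology(mixture_spectrum) == "thickening"

    def test_flat_is_newtonian(self):
        spec = vp.VelocitySpectrum(freq=np.logspace(1.7, 3.5, 20),
                                   D=np.full(20, 1e-9))
        assert vp.classify_rheology(spec) == "newtonian"

    def test_dip_is_mixed(self):
        f = np.logspace(1.7, 3.5, 41)
        u = np.linspace(-1, 1, 41)
        D = 1e-9 * np.exp(2.0 * u**2)  # falls then rises
        spec = vp.VelocitySpectrum(freq=f, D=D)
        assert vp.classify_rheology(spec) == "mixed"

    @given(logscale=st.floats(-2, 2), logfshift=st.floats(-1, 1))
    def test_invariant_under_rescaling(self, water_spectrum, logscale,
                                       logfshift):
        scaled = vp.VelocitySpectrum(
            freq=water_spectrum.freq * 10.0**logfshift,
            D=water_spectrum.D * 10.0**logscale)
        assert vp.classify_rheology(scaled) == "thinning"

    def test_requires_three_points(self):
        spec = vp.VelocitySpectrum(freq=[1.0, 2.0], D=[1e-9, 1e-9])
        with pytest.raises(ValueError):
            vp.classify_rheology(spec)


class TestLogBinning:
    def test_preserves_flat_level_and_shrinks_sigma(self):
        f = np.linspace(100.0, 10000.0, 300)
        rng = np.random.default_rng(1)
        D = 1e-9 * np.exp(rng.normal(0, 0.1, 300))
        spec = vp.VelocitySpectrum(freq=f, D=D, sigma=np.full(300, 1e-10))
        binned = vp.log_bin_spectrum(spec, bins_per_decade=6)
        assert len(binned) < len(spec)
        assert binned.D.mean() == pytest.approx(1e-9, rel=0.05)
        assert np.all(binned.sigma[:-1] < 1e-10)
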