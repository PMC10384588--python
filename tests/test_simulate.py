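"""Time-domain simulators, colored noise, spectral estimation, sampler."""

import numpy as np
import pytest

import vaspipe as vp
from vaspipe.constants import KB

REDUCED_T = 1.0 / KB  # kB*T = 1
T = 298.15
GAMMA = 2e-12


def _free_net():
    return vp.LangevinNetwork(masses=[0.0], frictions=[GAMMA], K=[[0.0]], T=T)


class TestSimulateNetwork:
    def test_determinism(self):
        net = _free_net()
        a = vp.simulate_network(net, dt=1e-5, n_steps=2000, seed=9)
        b = vp.simulate_network(net, dt=1e-5, n_steps=2000, seed=9)
        assert np.array_equal(a.positions, b.positions)
        c = vp.simulate_network(net, dt=1e-5, n_steps=2000, seed=10)
        assert not np.array_equal(a.positions, c.positions)

    def test_free_particle_diffusion(self):
        traj = vp.simulate_network(_free_net(), dt=1e-5, n_steps=200_000,
                                   seed=1)
        x = traj.positions[:, 0]
        lag = 100
        inc = x[lag::lag] - x[:-lag:lag]
        D_est = inc.var() / (2 * lag * traj.dt)
        assert D_est == pytest.approx(KB * T / GAMMA, rel=0.05)

    def test_inertial_equipartition(self):
        M = 3e-15
        net = vp.LangevinNetwork(masses=[M], frictions=[GAMMA], K=[[0.0]],
                                 T=T)
        _, vel = vp.simulate_network(net, dt=1e-5, n_steps=400_000, seed=2,
                                     store_velocities=True)
        assert vel[:, 0].var() * M / (KB * T) == pytest.approx(1.0, rel=0.02)

    def test_stability_rule_enforced(self):
        net = vp.LangevinNetwork(masses=[0.0], frictions=[GAMMA],
                                 K=[[4e-9]], T=T)
        with pytest.raises(ValueError, match="stability"):
            vp.simulate_network(net, dt=1.0, n_steps=100, seed=0)


class TestColoredNoise:
    def test_white_kernel_uncorrelated(self):
        kern = vp.PronyKernel(gamma_inf=GAMMA)
        f = vp.colored_noise(kern, dt=1e-4, n_steps=100_000, T=T, seed=3)
        fm = f - f.mean()
        r1 = np.dot(fm[:-1], fm[1:]) / np.dot(fm, fm)
        assert abs(r1) < 3 / np.sqrt(f.size)
        assert f.var() == pytest.approx(2 * KB * T * GAMMA / 1e-4, rel=0.05)

    def test_single_term_autocovariance(self):
        c1, lam1 = 0.8, 1.0
        kern = vp.PronyKernel(c=[c1], lam=[lam1])
        dt, n = 5e-3, 1_000_000
        f = vp.colored_noise(kern, dt=dt, n_steps=n, T=REDUCED_T, seed=4)
        fm = f - f.mean()
        for t_lag in (0.0, 0.5, 1.5, 3.0):
            lag = int(round(t_lag / dt))
            acov = np.dot(fm[:n - lag], fm[lag:]) / (n - lag)
            ref = c1 * np.exp(-lam1 * t_lag)  # kB*T = 1
            assert abs(acov - ref) <= 0.05 * c1

    def test_variance_linear_in_temperature(self):
        kern = vp.PronyKernel(c=[0.5], lam=[2.0])
        f1 = vp.colored_noise(kern, dt=1e-2, n_steps=200_000, T=REDUCED_T,
                              seed=5)
        f2 = vp.colored_noise(kern, dt=1e-2, n_steps=200_000, T=4 * REDUCED_T,
                              seed=5)
        assert f2.var() / f1.var() == pytest.approx(4.0, rel=1e-9)


class TestPronyFit:
    def test_flat_target_white_only(self):
        f = np.logspace(np.log10(50), np.log10(3000), 30)
        fr = vp.FrictionSpectrum(freq=f, gamma=np.full(30, GAMMA), T=T)
        kern, ok = vp.prony_fit(fr, 3)
        assert ok and kern.n_terms == 0
        assert kern.gamma_inf == pytest.approx(GAMMA)

    def test_single_exponential_recovery(self):
        f = np.logspace(np.log10(50), np.log10(3000), 30)
        kern0 = vp.PronyKernel(c=[1e-9], lam=[2 * np.pi * 500],
                               gamma_inf=1e-12)
        fr = vp.FrictionSpectrum(freq=f,
                                 gamma=kern0.re_gamma_omega(2 * np.pi * f),
                                 T=T)
        kern, ok = vp.prony_fit(fr, 1)
        assert ok
        assert kern.c[0] == pytest.approx(1e-9, rel=1e-6)
        assert kern.lam[0] == pytest.approx(2 * np.pi * 500, rel=1e-6)

    def test_thinning_friction_fit_within_tolerance(self, water_spectrum):
        fr = vp.friction_from_vas(water_spectrum, T)
        kern, ok = vp.prony_fit(fr, 3)
        assert ok
        rel = np.abs(kern.re_gamma_omega(fr.omega) / fr.gamma - 1)
        assert rel.max() <= 0.05

    def test_rising_friction_flagged_not_silent(self, mixture_spectrum):
        # a completely monotone kernel cannot produce a rising friction
        # spectrum; the fit must come back flagged
        fr = vp.friction_from_vas(mixture_spectrum, T)
        kern, ok = vp.prony_fit(fr, 3)
        assert not ok
        assert kern.n_terms <= 3  # still a valid kernel


class TestRouseSimulation:
    def test_determinism(self):
        rp = vp.RouseParams(N=8, b=1.0, T=REDUCED_T)
        kern = vp.PronyKernel(gamma_inf=1.0)
        a = vp.simulate_rouse_gle(rp, kern, dt=5e-4, n_steps=5000, seed=6)
        b = vp.simulate_rouse_gle(rp, kern, dt=5e-4, n_steps=5000, seed=6)
        assert np.array_equal(a.positions, b.positions)

    def test_com_diffusion_white(self):
        rp = vp.RouseParams(N=16, b=1.0, T=REDUCED_T)
        kern = vp.PronyKernel(gamma_inf=1.0)
        traj = vp.simulate_rouse_gle(rp, kern, dt=8e-4, n_steps=600_000,
                                     seed=7)
        com = traj.positions.mean(axis=1)
        lag = 100
        inc = com[lag::lag] - com[:-lag:lag]
        D_est = inc.var() / (2 * lag * traj.dt)
        assert D_est == pytest.approx(1.0 / 16.0, rel=0.10)

    def test_com_diffusion_with_memory(self):
        # long-lag COM diffusivity feels the full kernel gamma(0)
        rp = vp.RouseParams(N=8, b=1.0, T=REDUCED_T)
        kern = vp.PronyKernel(c=[6.0], lam=[3.0], gamma_inf=1.0)
        traj = vp.simulate_rouse_gle(rp, kern, dt=8e-4, n_steps=1_200_000,
                                     seed=8)
        com = traj.positions.mean(axis=1)
        lag = 8_000  # ~6.4 s >> 1/lambda
        inc = com[lag::lag] - com[:-lag:lag]
        D_est = inc.var() / (2 * lag * traj.dt)
        assert D_est == pytest.approx(1.0 / (8 * kern.gamma_zero), rel=0.30)

    def test_memory_requires_white_component(self):
        rp = vp.RouseParams(N=8, b=1.0, T=REDUCED_T)
        with pytest.raises(ValueError, match="gamma_inf"):
            vp.simulate_rouse_gle(rp, vp.PronyKernel(c=[1.0], lam=[1.0]),
                                  dt=1e-4, n_steps=100, seed=0)


class TestEstimateVAS:
    def test_free_particle_flat_level(self):
        traj = vp.simulate_network(_free_net(), dt=1e-5, n_steps=200_000,
                                   seed=11)
        spec = vp.estimate_vas(traj, n_segments=50)
        binned = vp.log_bin_spectrum(spec, bins_per_decade=4)
        sel = (binned.freq > 200) & (binned.freq < 20000)
        assert binned.D[sel] == pytest.approx(KB * T / GAMMA, rel=0.10)

    def test_pinned_particle_matches_oracle(self):
        net = vp.LangevinNetwork(masses=[0.0], frictions=[GAMMA],
                                 K=[[4e-9]], T=T)
        traj = vp.simulate_network(net, dt=2e-6, n_steps=1_000_000, seed=12)
        spec = vp.estimate_vas(traj, n_segments=100)
        binned = vp.log_bin_spectrum(spec, bins_per_decade=8)
        sel = (binned.freq >= 200) & (binned.freq <= 2000)  # one decade
        ref = vp.oracle_vas(net, 2 * np.pi * binned.freq[sel], 0)
        assert binned.D[sel] == pytest.approx(ref, rel=0.15)

    def test_sigma_shrinks_with_segments(self):
        traj = vp.simulate_network(_free_net(), dt=1e-5, n_steps=160_000,
                                   seed=13)
        s1 = vp.estimate_vas(traj, n_segments=20)
        s2 = vp.estimate_vas(traj, n_segments=40)
        # doubling the segment count: sigma ~ sqrt(2) smaller at matched
        # frequencies (compare band medians; bin sets differ)
        m1 = np.median(s1.sigma / s1.D)
        m2 = np.median(s2.sigma / s2.D)
        assert m2 / m1 == pytest.approx(1 / np.sqrt(2), rel=0.2)

    def test_too_short_trajectory_raises(self):
        traj = vp.simulate_network(_free_net(), dt=1e-5, n_steps=100, seed=0)
        with pytest.raises(ValueError, match="too short"):
            vp.estimate_vas(traj, n_segments=64)


class TestMGSESample:
    def test_noiseless_matches_model(self, water_params):
        design = vp.MGSEDesign(noise_cv=0.0, seed=0)
        spec = vp.mgse_sample(lambda w: vp.eval_water_vas(w, water_params),
                              design, T=T)
        assert spec.D == pytest.approx(
            vp.eval_water_vas(spec.omega, water_params), rel=1e-15)
        assert spec.sigma is None

    def test_seeded_reproducibility(self, water_params):
        model = lambda w: vp.eval_water_vas(w, water_params)
        a = vp.mgse_sample(model, vp.MGSEDesign(seed=42), T=T)
        b = vp.mgse_sample(model, vp.MGSEDesign(seed=42), T=T)
        c = vp.mgse_sample(model, vp.MGSEDesign(seed=43), T=T)
        assert np.array_equal(a.D, b.D)
        assert not np.array_equal(a.D, c.D)

    def test_noise_level_and_sigma(self, water_params):
        design = vp.MGSEDesign(n_points=200, f_max=1e5, noise_cv=0.05,
                               seed=1)
        spec = vp.mgse_sample(lambda w: vp.eval_water_vas(w, water_params),
                              design, T=T)
        true = vp.eval_water_vas(spec.omega, water_params)
        eps = np.log(spec.D / true)
        assert eps.std() == pytest.approx(0.05, rel=0.2)
        assert spec.sigma == pytest.approx(0.05 * spec.D)
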