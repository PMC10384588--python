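"""Time-domain simulators and the MGSE-style measurement emulator.

This module generates the package's synthetic data:

* :func:`simulate_network` -- Brownian/Langevin dynamics of small linear
  bead--spring networks (overdamped particles by Euler--Maruyama, inertial
  ones by a BAOAB splitting), the time-domain counterpart of the
  frequency-domain oracle.
* :func:`simulate_rouse_gle` -- a one-dimensional Rouse chain, optionally
  with retarded friction represented by a Prony-series memory kernel via
  Markovian embedding (one auxiliary Ornstein--Uhlenbeck variable per Prony
  term per mode), so dissipation and thermal noise share the same kernel and
  the fluctuation--dissipation theorem holds by construction.
* :func:`colored_noise` -- stationary Gaussian forces with autocovariance
  kB*T*gamma(t) for a given kernel.
* :func:`estimate_vas` -- segmented-periodogram VAS estimation from
  trajectories (central-difference velocities, non-overlapping rectangular
  windows).
* :func:`mgse_sample` -- log-spaced noisy sampling of an analytic or fitted
  solvent model on the spin-echo measurement band (default 50--3000 Hz),
  with multiplicative log-normal noise.

All randomness flows from explicit integer seeds; identical configurations
produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, signal

from .constants import KB
from .network import LangevinNetwork
from .rouse import RouseParams, _solvent_eval
from .spectra import FrictionSpectrum, VelocitySpectrum, _check_positive

__all__ = [
    "Trajectory",
    "PronyKernel",
    "MGSEDesign",
    "simulate_network",
    "simulate_rouse_gle",
    "colored_noise",
    "prony_fit",
    "estimate_vas",
    "mgse_sample",
]


@dataclass(frozen=True)
class Trajectory:
    """Simulated particle paths: positions is (n_steps, n_particles), m."""

    dt: float
    positions: np.ndarray
    seed: int
    scheme: str
    labels: Optional[tuple] = None
    T: float = np.nan

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        pos = np.asarray(self.positions)
        if pos.ndim != 2:
            raise ValueError("positions must be (n_steps, n_particles)")
        if not np.all(np.isfinite(pos[-1])):
            raise ValueError("trajectory contains non-finite values")
        object.__setattr__(self, "positions", pos)

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt


@dataclass(frozen=True)
class PronyKernel:
    """Sum-of-exponentials friction kernel

        gamma(t) = 2 gamma_inf delta(t) + sum_i c_i exp(-lambda_i t),

    with amplitudes c_i >= 0 (kg/s^2), rates lambda_i > 0 (1/s) and an
    optional instantaneous (white) component gamma_inf (kg/s).  Complete
    monotonicity (non-negative c_i) guarantees a positive friction spectrum.
    """

    c: np.ndarray = field(default_factory=lambda: np.zeros(0))
    lam: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma_inf: float = 0.0

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.c, dtype=float))
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "lam", lam)
        if c.size != lam.size:
            raise ValueError("c and lam must have the same length")
        if np.any(c < 0):
            raise ValueError("Prony amplitudes must be non-negative")
        if np.any(lam <= 0):
            raise ValueError("Prony rates must be positive")
        if self.gamma_inf < 0:
            raise ValueError("gamma_inf must be non-negative")
        if self.gamma_inf == 0 and c.size == 0:
            raise ValueError("kernel must have a white part or Prony terms")

    @property
    def n_terms(self) -> int:
        return self.c.size

    def gamma_of_t(self, t):
        """Continuous (non-delta) part of the kernel, kg/s^2."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t1 = np.atleast_1d(t)
        if self.n_terms == 0:
            out = np.zeros_like(t1)
        else:
            out = (self.c[:, None] * np.exp(-np.outer(self.lam, t1))).sum(axis=0)
        return float(out[0]) if scalar else out

    def re_gamma_omega(self, omega) -> np.ndarray:
        """Real part of the one-sided transform of the kernel, kg/s:
        gamma'(omega) = gamma_inf + sum_i c_i lambda_i / (lambda_i^2 + omega^2)."""
        w = np.asarray(omega, dtype=float)
        out = np.full_like(w, self.gamma_inf, dtype=float)
        for ci, li in zip(self.c, self.lam):
            out = out + ci * li / (li**2 + w**2)
        return out

    @property
    def gamma_zero(self) -> float:
        """Zero-frequency friction gamma_inf + sum c_i/lambda_i, kg/s."""
        return self.gamma_inf + float(np.sum(self.c / self.lam)) \
            if self.n_terms else self.gamma_inf


@dataclass(frozen=True)
class MGSEDesign:
    """Measurement design of the spin-echo emulator: ``n_points`` log-spaced
    frequencies on [f_min, f_max] Hz with relative (multiplicative) noise
    level ``noise_cv``."""

    f_min: float = 50.0
    f_max: float = 3000.0
    n_points: int = 30
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    @property
    def freq(self) -> np.ndarray:
        return np.logspace(np.log10(self.f_min), np.log10(self.f_max),
                           self.n_points)


def _stability_dt(net: LangevinNetwork) -> float:
    """Largest admissible step: 0.01 * min(gamma/k, M/gamma) over particles,
    with k the coupling-constant scale (largest spring magnitude in K)."""
    offdiag = net.K - np.diag(np.diag(net.K))
    k_scale = float(np.max(np.abs(offdiag))) if net.n_particles > 1 else \
        float(np.max(np.abs(net.K)))
    scales = []
    for i in range(net.n_particles):
        if k_scale > 0:
            scales.append(net.frictions[i] / k_scale)
        if net.masses[i] > 0:
            scales.append(net.masses[i] / net.frictions[i])
    return 0.01 * min(scales) if scales else np.inf


def _step_matrices(net: LangevinNetwork, dt: float):
    """One-step affine update s' = A s + W xi for the mixed EM/BAOAB scheme.

    State s stacks all positions and the velocities of inertial particles;
    xi is one standard normal per particle per step.  The matrices are
    assembled by pushing basis vectors through the update, so the loop body
    is a single matrix--vector product.
    """
    n = net.n_particles
    inertial = np.flatnonzero(net.masses > 0)
    over = np.flatnonzero(net.masses == 0)
    nv = inertial.size
    dim = n + nv
    kT = KB * net.T
    g = net.frictions

    # coefficient matrices: S maps old state -> value, W maps noise -> value
    X = np.zeros((n, dim));  X[:, :n] = np.eye(n)
    V = np.zeros((nv, dim)); V[:, n:] = np.eye(nv)
    WX = np.zeros((n, n))
    WV = np.zeros((nv, n))

    F = -net.K @ X                                  # force at step start
    # overdamped: Euler-Maruyama with start-of-step force
    Xn, WXn = X.copy(), WX.copy()
    if over.size:
        Xn[over] = X[over] + (dt / g[over])[:, None] * F[over]
        WXn[over, over] = np.sqrt(2.0 * kT * dt / g[over])
    if nv:
        Mi = net.masses[inertial]
        gi = g[inertial]
        cO = np.exp(-gi * dt / Mi)
        sO = np.sqrt((1.0 - cO**2) * kT / Mi)
        # B: half kick, A: half drift, O: exact OU on velocity, A, B
        Vh = V + (0.5 * dt / Mi)[:, None] * F[inertial]
        Xh = X.copy(); Xh[inertial] = X[inertial] + 0.5 * dt * Vh
        Vo = cO[:, None] * Vh
        WVo = np.zeros((nv, n)); WVo[np.arange(nv), inertial] = sO
        Xn[inertial] = Xh[inertial] + 0.5 * dt * Vo
        WXn[inertial] = WXn[inertial] + 0.5 * dt * WVo
        F1 = -net.K @ Xn
        WF1 = -net.K @ WXn
        Vn = Vo + (0.5 * dt / Mi)[:, None] * F1[inertial]
        WVn = WVo + (0.5 * dt / Mi)[:, None] * WF1[inertial]
    A = np.zeros((dim, dim))
    W = np.zeros((dim, n))
    A[:n] = Xn; W[:n] = WXn
    if nv:
        A[n:] = Vn; W[n:] = WVn
    return A, W, inertial


def simulate_network(net: LangevinNetwork, dt: float, n_steps: int,
                     seed: int, store_velocities: bool = False):
    """Simulate a bead--spring network; returns a :class:`Trajectory`.

    Overdamped particles (mass 0) advance by Euler--Maruyama with white
    noise variance 2 kB T gamma dt; inertial particles by a BAOAB splitting
    with an exact Ornstein--Uhlenbeck velocity sub-step.  The time step must
    satisfy dt <= 0.01 * min(gamma_i/K_ii, M_i/gamma_i); violating it raises
    with a suggested dt.  Reproducible: same seed, same trajectory.
    """
    _check_positive(dt=dt)
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    dt_max = _stability_dt(net)
    if dt > dt_max:
        raise ValueError(f"dt={dt:g} s violates the stability rule; "
                         f"use dt <= {dt_max:g} s")
    A, W, inertial = _step_matrices(net, dt)
    n = net.n_particles
    dim = A.shape[0]
    rng = np.random.default_rng(seed)
    pos = np.empty((n_steps, n), dtype=float)
    vel = np.empty((n_steps, inertial.size), dtype=float) if store_velocities else None
    s = np.zeros(dim)
    # equilibrium (Gibbs) start: internal spring modes at kB*T/kappa, free
    # modes at the origin, inertial velocities at equipartition
    kappa, modes = np.linalg.eigh(net.K)
    scale = max(np.max(np.abs(net.K)), 1.0)
    bound = kappa > 1e-10 * scale
    amp = np.zeros(n)
    amp[bound] = rng.normal(0.0, np.sqrt(KB * net.T / kappa[bound]))
    s[:n] = modes @ amp
    if inertial.size:
        s[n:] = rng.normal(0.0, np.sqrt(KB * net.T / net.masses[inertial]))
    chunk = 65536
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        xi = rng.standard_normal((m, n))
        for j in range(m):
            s = A @ s + W @ xi[j]
            pos[done + j] = s[:n]
            if store_velocities:
                vel[done + j] = s[n:]
        done += m
    traj = Trajectory(dt=dt, positions=pos, seed=seed, scheme="em+baoab",
                      labels=net.labels, T=net.T)
    return (traj, vel) if store_velocities else traj


def colored_noise(kernel: PronyKernel, dt: float, n_steps: int, T: float,
                  seed: int) -> np.ndarray:
    """Stationary Gaussian force series with autocovariance kB*T*gamma(t).

    Each Prony term is an exact-update Ornstein--Uhlenbeck process of
    variance kB*T*c_i and rate lambda_i; the white part contributes variance
    2*kB*T*gamma_inf/dt per sample (a discretized delta).  Initial states
    are drawn from the stationary distribution, so the series is stationary
    from the first sample.
    """
    _check_positive(dt=dt, T=T)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.zeros(n_steps)
    for ci, li in zip(kernel.c, kernel.lam):
        a = np.exp(-li * dt)
        sig = np.sqrt(KB * T * ci)
        innov = rng.standard_normal(n_steps) * (sig * np.sqrt(1.0 - a * a))
        innov[0] = rng.normal(0.0, sig)  # stationary start
        out += signal.lfilter([1.0], [1.0, -a], innov)
    if kernel.gamma_inf > 0:
        out += rng.standard_normal(n_steps) * np.sqrt(
            2.0 * KB * T * kernel.gamma_inf / dt)
    return out


def simulate_rouse_gle(rp: RouseParams, kernel: PronyKernel, dt: float,
                       n_steps: int, seed: int,
                       dtype=np.float64) -> Trajectory:
    """One-dimensional free-ended Rouse chain with (optional) memory friction.

    Springs: k = 3 kB T / b^2 (entropic Kuhn spring).  The chain is evolved
    in normal-mode space (the modes decouple because all beads share the
    same kernel): each mode obeys an overdamped Euler--Maruyama step driven
    by the instantaneous friction gamma_inf, plus one auxiliary OU variable
    per Prony term supplying both the retarded drag and its matching colored
    noise (fluctuation--dissipation by construction).  A kernel with Prony
    terms requires gamma_inf > 0 to carry the instantaneous response.

    Stability: dt <= 0.01 * gamma_inf / max_p k_p, where k_p are the chain
    eigenvalues (k_max < 4k); violations raise with a suggested dt.
    """
    _check_positive(dt=dt)
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if kernel.n_terms > 0 and kernel.gamma_inf <= 0:
        raise ValueError("memory kernels need gamma_inf > 0 for the "
                         "instantaneous response")
    N = rp.N
    kT = KB * rp.T
    k_spring = 3.0 * kT / rp.b**2
    g0 = kernel.gamma_inf
    # free-chain (Neumann) normal modes: eigenvalues 4k sin^2(p pi / 2N)
    p = np.arange(N)
    k_p = 4.0 * k_spring * np.sin(np.pi * p / (2.0 * N)) ** 2
    dt_max = 0.01 * g0 / k_p.max()
    if dt > dt_max:
        raise ValueError(f"dt={dt:g} s violates the stability rule; "
                         f"use dt <= {dt_max:g} s")
    j = np.arange(N)
    # orthonormal DCT-II-style mode shapes
    phi = np.sqrt(2.0 / N) * np.cos(np.outer(np.pi * p, (j + 0.5)) / N)
    phi[0] = np.sqrt(1.0 / N)
    rng = np.random.default_rng(seed)
    sig_white = np.sqrt(2.0 * kT * dt / g0)
    if kernel.n_terms == 0:
        # pure white friction: each mode is an independent AR(1); run the
        # exact same EM recursion through a C-loop linear filter per mode,
        # started from the stationary distribution of the discrete chain.
        # Chunked along time to bound memory for long runs.
        a = 1.0 - dt * k_p / g0
        pos = np.empty((n_steps, N), dtype=dtype)
        zi = np.zeros(N)
        chunk = 1 << 20
        done = 0
        while done < n_steps:
            mlen = min(chunk, n_steps - done)
            xi = rng.standard_normal((mlen, N)) * sig_white
            if done == 0:
                xi[0, 1:] = rng.normal(
                    0.0, sig_white / np.sqrt(1.0 - a[1:] ** 2))
                xi[0, 0] = 0.0
            Z = np.empty((mlen, N))
            for q in range(N):
                Z[:, q], zf = signal.lfilter([1.0], [1.0, -a[q]], xi[:, q],
                                             zi=np.array([a[q] * zi[q]]))
                zi[q] = Z[-1, q]
            pos[done:done + mlen] = Z @ phi
            done += mlen
        return Trajectory(dt=dt, positions=pos, seed=seed, scheme="em-modes",
                          T=rp.T)
    # memory case: per-mode auxiliary OU variables z_i (force units); EM on x
    c, lam = kernel.c, kernel.lam
    aO = np.exp(-lam * dt)
    sigz = np.sqrt(kT * c * (1.0 - aO**2))
    Z = np.zeros((kernel.n_terms, N))
    for i in range(kernel.n_terms):
        Z[i] = rng.normal(0.0, np.sqrt(kT * c[i]), size=N)
    x = np.zeros(N)
    x[1:] = rng.normal(0.0, np.sqrt(kT / k_p[1:]))  # Gibbs start
    modes = np.empty((n_steps, N), dtype=dtype)
    for step in range(n_steps):
        xi = rng.standard_normal(N)
        force = -k_p * x + Z.sum(axis=0)
        x_new = x + (dt / g0) * force + sig_white * xi
        dx = x_new - x
        eta = rng.standard_normal((kernel.n_terms, N))
        Z = aO[:, None] * Z - c[:, None] * dx + sigz[:, None] * eta
        x = x_new
        modes[step] = x
    return Trajectory(dt=dt, positions=modes @ phi, seed=seed,
                      scheme="em-modes-gle", T=rp.T)


def prony_fit(target: FrictionSpectrum, n_terms: int,
              rtol: float = 0.05) -> Tuple[PronyKernel, bool]:
    """Fit a Prony kernel's friction spectrum to a target gamma(omega).

    Matches gamma_inf + sum_i c_i lambda_i/(lambda_i^2 + omega^2) to the
    target in relative log terms, with c_i >= 0 enforced by log
    parametrization.  Returns (kernel, ok); ``ok`` is False when the maximum
    relative error on the band exceeds ``rtol`` (returned anyway, never
    silently dropped).
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    w = target.omega
    g = target.gamma
    if np.allclose(g, g[0], rtol=1e-12, atol=0.0):
        return PronyKernel(gamma_inf=float(g[0])), True
    lam0 = np.logspace(np.log10(w[0]), np.log10(w[-1]), n_terms + 2)[1:-1]
    span = max(g.max() - g.min(), 1e-3 * g.min())
    theta0 = np.concatenate([
        np.log(np.full(n_terms, span * lam0.mean() / n_terms)),  # c_i
        np.log(lam0),
        [np.log(max(g.min(), 1e-6 * g.max()))],
    ])

    def unpack(theta):
        c = np.exp(theta[:n_terms])
        lam = np.exp(theta[n_terms:2 * n_terms])
        ginf = np.exp(theta[-1])
        return PronyKernel(c=c, lam=lam, gamma_inf=ginf)

    def resid(theta):
        return np.log(unpack(theta).re_gamma_omega(w)) - np.log(g)

    res = optimize.least_squares(resid, theta0, method="lm", xtol=1e-14,
                                 ftol=1e-14, max_nfev=20000)
    kernel = unpack(res.x)
    rel = np.abs(kernel.re_gamma_omega(w) / g - 1.0)
    return kernel, bool(np.max(rel) <= rtol)


def estimate_vas(traj: Trajectory, particles: Optional[Sequence[int]] = None,
                 n_segments: int = 16) -> VelocitySpectrum:
    """Segmented-periodogram VAS estimate from a trajectory.

    Velocities by central finite differences, split into ``n_segments``
    non-overlapping rectangular windows; the one-sided estimate is
    D(f) = S_v(f)/2 with the per-segment periodogram averaged over segments
    and the selected particles.  The central-difference transfer bias is
    removed by dividing by cos^2(omega dt / 2) (exact for free diffusion,
    O((omega dt)^2) accurate otherwise).  ``sigma`` is the cross-segment
    (and cross-particle) standard error.  Frequencies are returned in Hz;
    the zero-frequency and Nyquist bins are dropped.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    idx = np.arange(traj.n_particles) if particles is None \
        else np.asarray(list(particles), dtype=int)
    x = traj.positions[:, idx].astype(np.float64, copy=False)
    v = (x[2:] - x[:-2]) / (2.0 * traj.dt)
    seg_len = v.shape[0] // n_segments
    if seg_len < 8:
        need = 8 * n_segments + 2
        raise ValueError(f"trajectory too short for {n_segments} segments; "
                         f"need at least {need} steps, have {traj.n_steps}")
    v = v[:seg_len * n_segments]
    v = v.reshape(n_segments, seg_len, idx.size)
    P = np.abs(np.fft.rfft(v, axis=1)) ** 2 * (traj.dt / seg_len)
    D_samples = 0.5 * P[:, 1:-1, :]              # drop DC and Nyquist bins
    freq = np.fft.rfftfreq(seg_len, traj.dt)[1:-1]
    gain = np.cos(np.pi * freq * traj.dt) ** 2   # central-difference bias
    D_samples = D_samples / gain[None, :, None]
    n_avg = n_segments * idx.size
    D = D_samples.mean(axis=(0, 2))
    sigma = D_samples.std(axis=(0, 2), ddof=1) / np.sqrt(n_avg) \
        if n_avg > 1 else None
    return VelocitySpectrum(freq=freq, D=D, sigma=sigma,
                            label=f"periodogram estimate ({n_segments} segments)")


def mgse_sample(model, design: MGSEDesign, T: float = 298.15,
                label: str = "") -> VelocitySpectrum:
    """Noisy spin-echo-style sampling of a solvent model.

    ``model`` is anything :func:`vaspipe.rouse.polymer_vas_from_solvent`
    accepts (a FitResult, a callable D(omega), or analytic params via a
    lambda).  Observations are D_obs = D_true * exp(eps) with
    eps ~ N(0, noise_cv^2) i.i.d. from the design's seed, and the reported
    sigma is noise_cv * D_obs.
    """
    freq = design.freq
    omega = 2.0 * np.pi * freq
    D_true = _solvent_eval(model, omega)
    rng = np.random.default_rng(design.seed)
    if design.noise_cv > 0:
        eps = rng.normal(0.0, design.noise_cv, size=freq.size)
        D_obs = D_true * np.exp(eps)
        sigma = design.noise_cv * D_obs
    else:
        D_obs, sigma = D_true.copy(), None
    return VelocitySpectrum(freq=freq, D=D_obs, sigma=sigma,
                            label=label or "synthetic MGSE sample")
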