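r"""Analytic solvent velocity-autocorrelation spectra and rheology helpers.

The central quantity throughout the package is the velocity autocorrelation
spectrum (VAS)

    D(omega) = (1/2) * \int_{-inf}^{inf} <v(t) v(0)> e^{i omega t} dt ,

the one-sided cosine transform of the velocity autocorrelation function, so
that ``D(0)`` equals the long-time self-diffusion coefficient.  Two analytic
solvent models are provided:

* ``eval_water_vas`` -- a molecule harmonically coupled to ``n`` mutually
  interacting neighbours, all overdamped (single-species liquid, e.g. pure
  water).  The spectrum rises with frequency: shear thinning.
* ``eval_mixture_vas`` -- a water molecule coupled to ``n_w`` overdamped
  water neighbours and ``n_c`` heavy inertial clusters (glycerol/water-like
  mixtures).  For cluster-dominated parameters the spectrum falls across the
  measurement band: shear thickening.

The generalized Einstein--Smoluchowski relation ``D(omega) = kB*T/gamma(omega)``
converts between diffusion and friction spectra, and the Stokes relation
``gamma(omega) = s*pi*R*eta(omega)`` yields a frequency-dependent viscosity.

Conventions: all formulas work in angular frequency omega (rad/s); every
array container and file interface stores ordinary frequency in Hz.  The
factor ``2*pi`` is applied exactly once at the interface boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .constants import KB

__all__ = [
    "VelocitySpectrum",
    "FrictionSpectrum",
    "CoupledLEParams",
    "MixtureLEParams",
    "ViscosityParams",
    "eval_water_vas",
    "eval_mixture_vas",
    "friction_from_vas",
    "vas_from_friction",
    "viscosity_from_friction",
    "classify_rheology",
    "log_bin_spectrum",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class VelocitySpectrum:
    """Sampled diffusion spectrum D(f).

    Parameters
    ----------
    freq : array
        Sample frequencies in Hz, strictly increasing, non-negative.
    D : array
        Diffusivities in m^2/s, strictly positive.
    sigma : array, optional
        One-sigma uncertainties on ``D`` (m^2/s), strictly positive.
    label : str
        Free-text provenance (e.g. "water fit", "synthetic 33 vol% G/W").
    """

    freq: np.ndarray
    D: np.ndarray
    sigma: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        freq = _as_1d(self.freq, "freq")
        D = _as_1d(self.D, "D")
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "D", D)
        if freq.size != D.size:
            raise ValueError("freq and D must have the same length")
        if freq.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if np.any(freq < 0):
            raise ValueError("frequencies must be non-negative")
        if np.any(np.diff(freq) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(D <= 0):
            raise ValueError("diffusivities must be strictly positive")
        if self.sigma is not None:
            sigma = _as_1d(self.sigma, "sigma")
            object.__setattr__(self, "sigma", sigma)
            if sigma.size != D.size:
                raise ValueError("sigma must match D in length")
            if np.any(sigma <= 0):
                raise ValueError("sigma must be strictly positive")

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies, rad/s."""
        return 2.0 * np.pi * self.freq

    def __len__(self) -> int:
        return self.freq.size


@dataclass(frozen=True)
class FrictionSpectrum:
    """Frequency-dependent friction gamma(f), kg/s, with the temperature it
    was derived at."""

    freq: np.ndarray
    gamma: np.ndarray
    T: float

    def __post_init__(self):
        freq = _as_1d(self.freq, "freq")
        gamma = _as_1d(self.gamma, "gamma")
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "gamma", gamma)
        if freq.size != gamma.size:
            raise ValueError("freq and gamma must have the same length")
        if np.any(np.diff(freq) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(gamma <= 0):
            raise ValueError("friction must be strictly positive")
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.freq


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class CoupledLEParams:
    """Parameters of the single-species coupled-Langevin liquid.

    gamma : molecular friction coefficient, kg/s.
    k     : harmonic coupling constant, N/m.
    n     : number of mutually coupled molecules in the transient cage
            (integer >= 1); n=1 means a free molecule.
    T     : temperature, K.
    M     : molecular mass, kg (optional; only used to check the overdamped
            validity window omega << gamma/M).
    """

    gamma: float
    k: float
    n: int
    T: float
    M: Optional[float] = None

    def __post_init__(self):
        _check_positive(gamma=self.gamma, k=self.k, T=self.T)
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be an integer >= 1, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))
        if self.M is not None:
            _check_positive(M=self.M)

    @property
    def tau_c(self) -> float:
        """Correlation time gamma/k, s."""
        return self.gamma / self.k

    @classmethod
    def from_tau(cls, gamma: float, tau_c: float, n: int, T: float,
                 M: Optional[float] = None) -> "CoupledLEParams":
        _check_positive(tau_c=tau_c)
        return cls(gamma=gamma, k=gamma / tau_c, n=n, T=T, M=M)


@dataclass(frozen=True)
class MixtureLEParams:
    """Parameters of the two-species (water + heavy cluster) model.

    A tagged water molecule is harmonically coupled (constant ``k``) to
    ``n_w`` overdamped water neighbours and ``n_c`` heavy inertial clusters;
    clusters do not interact with each other, and all particles share the
    friction ``gamma``.  The cluster resonance ``omega_o = sqrt(k/M_cluster)``
    parametrizes the cluster mass.

    The correlation time is structurally tied to the couplings,
    ``tau = gamma/k``; passing an inconsistent ``tau`` raises.
    """

    gamma: float
    k: float
    omega_o: float
    T: float
    n_w: int = 2
    n_c: int = 1
    tau: Optional[float] = None

    def __post_init__(self):
        _check_positive(gamma=self.gamma, k=self.k, omega_o=self.omega_o, T=self.T)
        for name in ("n_w", "n_c"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n_w + self.n_c < 1:
            raise ValueError("need at least one neighbour (n_w + n_c >= 1)")
        derived = self.gamma / self.k
        if self.tau is None:
            object.__setattr__(self, "tau", derived)
        elif not np.isclose(self.tau, derived, rtol=1e-9):
            raise ValueError(
                "tau must equal gamma/k in the reconstructed two-species model "
                f"(got tau={self.tau!r}, gamma/k={derived!r})"
            )

    @property
    def M_cluster(self) -> float:
        """Cluster mass implied by the resonance, kg."""
        return self.k / self.omega_o**2

    @classmethod
    def from_rates(cls, gamma: float, tau: float, omega_o: float, T: float,
                   n_w: int = 2, n_c: int = 1) -> "MixtureLEParams":
        _check_positive(tau=tau)
        return cls(gamma=gamma, k=gamma / tau, omega_o=omega_o, T=T,
                   n_w=n_w, n_c=n_c)


@dataclass(frozen=True)
class ViscosityParams:
    """Stokes boundary-condition factor s (6 = stick, 4 = slip) and
    hydrodynamic radius R (m) for gamma = s*pi*R*eta."""

    R: float
    s_factor: float = 6.0

    def __post_init__(self):
        _check_positive(R=self.R, s_factor=self.s_factor)


def _check_omega(omega) -> np.ndarray:
    w = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("omega contains non-finite values")
    if np.any(w < 0):
        raise ValueError("omega must be non-negative")
    return w


def eval_water_vas(omega, params: CoupledLEParams):
    """VAS of an overdamped molecule in a cage of ``n`` coupled molecules.

    D(omega) = (kB*T/gamma) * (n + tau_c^2 omega^2) / (n^2 + tau_c^2 omega^2),
    with tau_c = gamma/k.  Limits: D(0) = kB*T/(n*gamma) (caged diffusion) and
    D(inf) = kB*T/gamma (free Einstein--Smoluchowski coefficient).  This is
    exactly the per-molecule spectrum of a complete graph of ``n`` overdamped
    particles with uniform coupling ``k``.

    Parameters: ``omega`` in rad/s (scalar or array).  Returns m^2/s.
    """
    w = _check_omega(omega)
    x = (params.tau_c * w) ** 2
    n = params.n
    out = (KB * params.T / params.gamma) * (n + x) / (n**2 + x)
    return out if out.shape else float(out)


def _mixture_vas_complex(w: np.ndarray, n_w: int, n_c: int, Mc: float,
                         gamma: float, k: float, T: float) -> np.ndarray:
    """Arrowhead closed form for the tagged water of the star motif.

    The response matrix A = K - omega^2 diag(M) - i omega diag(Gamma) of the
    star (central water, n_w water leaves, n_c cluster leaves) is an arrowhead
    matrix, so its inverse row is available in closed form; the position
    spectral density follows from the white-force spectral density
    2 kB T diag(Gamma).
    """
    dw = k - 1j * w * gamma                 # water leaf diagonal
    dc = k - w**2 * Mc - 1j * w * gamma     # cluster leaf diagonal
    d0 = (n_w + n_c) * k - 1j * w * gamma   # central water diagonal
    delta = d0 - n_w * k**2 / dw - n_c * k**2 / dc
    num = 1.0 + n_w * k**2 / np.abs(dw) ** 2 + n_c * k**2 / np.abs(dc) ** 2
    return KB * T * gamma * w**2 * num / np.abs(delta) ** 2


def eval_mixture_vas(omega, params: MixtureLEParams):
    """VAS of the tagged water in the water+cluster motif (closed form).

    Exact frequency-domain solution of the coupled Langevin system: the
    tagged (overdamped) water coupled with constant ``k`` to ``n_w``
    overdamped waters and ``n_c`` inertial clusters of mass
    ``M_cluster = k/omega_o^2``, all sharing friction ``gamma``, with no
    cluster--cluster springs.  Identical (to machine precision) to the
    brute-force network solution of :func:`vaspipe.network.oracle_vas` on
    the motif built by :func:`vaspipe.network.build_mixture_motif`.

    With ``n_c = 0`` the motif is a star of ``1 + n_w`` waters, whose tagged
    spectrum reduces exactly to :func:`eval_water_vas` with ``n = n_w + 1``
    (the zero-frequency limit kB*T/((1+n_w)*gamma) fixes the count).

    Parameters: ``omega`` in rad/s (scalar or array).  Returns m^2/s.
    """
    w = _check_omega(omega)
    scalar = w.ndim == 0
    w = np.atleast_1d(w)
    out = np.empty_like(w)
    nz = w > 0
    out[nz] = _mixture_vas_complex(w[nz], params.n_w, params.n_c,
                                   params.M_cluster, params.gamma,
                                   params.k, params.T)
    # omega -> 0: centre-of-mass diffusion of the whole motif.
    out[~nz] = KB * params.T / ((1 + params.n_w + params.n_c) * params.gamma)
    return float(out[0]) if scalar else out


def friction_from_vas(spec: VelocitySpectrum, T: float) -> FrictionSpectrum:
    """Generalized Einstein--Smoluchowski relation: gamma(omega) = kB*T/D(omega)."""
    _check_positive(T=T)
    return FrictionSpectrum(freq=spec.freq.copy(), gamma=KB * T / spec.D, T=T)


def vas_from_friction(fric: FrictionSpectrum, T: Optional[float] = None,
                      label: str = "") -> VelocitySpectrum:
    """Inverse direction of :func:`friction_from_vas`: D = kB*T/gamma(omega)."""
    T = fric.T if T is None else T
    _check_positive(T=T)
    return VelocitySpectrum(freq=fric.freq.copy(), D=KB * T / fric.gamma,
                            label=label or "from friction spectrum")


def viscosity_from_friction(fric: FrictionSpectrum, vp: ViscosityParams) -> np.ndarray:
    """Frequency-dependent shear viscosity eta(omega) = gamma(omega)/(s*pi*R), Pa*s."""
    return fric.gamma / (vp.s_factor * np.pi * vp.R)


def log_bin_spectrum(spec: VelocitySpectrum,
                     bins_per_decade: int = 12) -> VelocitySpectrum:
    """Average a (typically periodogram) spectrum into logarithmic
    frequency bins.

    Bins are geometric with ``bins_per_decade`` per decade; each output
    point is the arithmetic mean of the member diffusivities at the
    geometric-mean frequency, with the standard error reduced by the member
    count.  Useful for comparing noisy estimates against smooth models.
    """
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    f, D = spec.freq, spec.D
    if f[0] <= 0:
        raise ValueError("log binning requires positive frequencies")
    n_bins = int(np.ceil(np.log10(f[-1] / f[0]) * bins_per_decade)) + 1
    edges = f[0] * 10 ** (np.arange(n_bins + 1) / bins_per_decade)
    idx = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, n_bins - 1)
    fo, Do, so = [], [], []
    for b in range(n_bins):
        sel = idx == b
        m = int(sel.sum())
        if m == 0:
            continue
        fo.append(np.exp(np.mean(np.log(f[sel]))))
        Do.append(np.mean(D[sel]))
        if spec.sigma is not None:
            so.append(np.sqrt(np.sum(spec.sigma[sel] ** 2)) / m)
    sigma = np.array(so) if spec.sigma is not None else None
    return VelocitySpectrum(freq=np.array(fo), D=np.array(Do), sigma=sigma,
                            label=f"{spec.label} [log-binned]")


def _trend_change(logf: np.ndarray, logD: np.ndarray) -> float:
    """Predicted relative change of D across the band from a robust
    (Theil--Sen) log-log slope."""
    slope = stats.theilslopes(logD, logf)[0]
    return float(np.expm1(slope * (logf[-1] - logf[0])))


def classify_rheology(spec: VelocitySpectrum, slope_tol: float = 0.05) -> str:
    """Classify a diffusion spectrum as thinning / thickening / newtonian / mixed.

    Since eta(omega) is proportional to 1/D(omega), a rising D means the
    viscosity falls with frequency (shear thinning, pure-water-like) and a
    falling D means thickening (glycerol-rich-mixture-like).  The decision
    statistic is the Theil--Sen median-of-pairwise-slopes of log D versus
    log f, robust to multiplicative measurement noise; the band is declared
    newtonian when the implied total relative change of D is within
    ``slope_tol``.  "mixed" flags bands whose two halves trend in opposite
    directions beyond tolerance (e.g. a resonance dip inside the band).
    """
    if len(spec) < 3:
        raise ValueError("classification requires at least 3 points")
    if slope_tol < 0:
        raise ValueError("slope_tol must be non-negative")
    logf = np.log(spec.freq) if spec.freq[0] > 0 else np.log(spec.freq + spec.freq[1])
    logD = np.log(spec.D)
    half = len(spec) // 2
    if half >= 3:
        c1 = _trend_change(logf[:half + 1], logD[:half + 1])
        c2 = _trend_change(logf[half:], logD[half:])
        if c1 > slope_tol and c2 < -slope_tol:
            return "mixed"
        if c1 < -slope_tol and c2 > slope_tol:
            return "mixed"
    change = _trend_change(logf, logD)
    if abs(change) <= slope_tol:
        return "newtonian"
    return "thinning" if change > 0 else "thickening"
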