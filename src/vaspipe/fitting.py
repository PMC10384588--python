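"""Weighted nonlinear least-squares fitting of the solvent VAS models.

Both solvent models (single-species "water" model and two-species
water+cluster "mixture" model) are fitted in log space -- residuals of
log D -- matching the multiplicative noise of the measurement emulator.
Parameters are optimized as logarithms (automatic positivity), with a
scale-free data-driven starting point and a small deterministic multi-start
to escape the mixture model's local minima.  Neighbour counts are treated
as small fixed integers (they are counts, not continuous parameters); the
water model's ``n`` can alternatively be profiled over 1..6.

Model choice between the two is by AIC (:func:`select_model`), with ties
(delta AIC < 2) reported as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy import optimize

from .constants import KB
from .spectra import (CoupledLEParams, MixtureLEParams, VelocitySpectrum,
                      eval_mixture_vas, eval_water_vas)

__all__ = ["FitResult", "fit_water_model", "fit_mixture_model",
           "select_model", "fitted_spectrum"]

_N_STARTS = 5
_JITTER_SEED = 20230719  # deterministic multi-start jitter


@dataclass(frozen=True)
class FitResult:
    """Outcome of a solvent-model fit.

    ``params`` satisfies its own type invariants; ``covariance`` is the
    parameter covariance (linear scale, order as ``param_names``) from the
    log-space Gauss--Newton approximation; ``rss`` is the residual sum of
    squares of weighted log residuals.  ``flags`` collects soft warnings
    (bound-hugging parameters, unidentifiable resonance, ...).
    """

    model_id: str
    params: Union[CoupledLEParams, MixtureLEParams]
    covariance: Optional[np.ndarray]
    rss: float
    n_points: int
    fixed: Dict[str, float] = field(default_factory=dict)
    param_names: Tuple[str, ...] = ()
    aic: float = np.nan
    converged: bool = True
    flags: Tuple[str, ...] = ()

    def evaluate(self, omega):
        """Model D(omega), rad/s -> m^2/s; valid at any frequency
        (parametric extrapolation)."""
        if self.model_id == "water_eq2":
            return eval_water_vas(omega, self.params)
        return eval_mixture_vas(omega, self.params)

    def stderr(self) -> Optional[np.ndarray]:
        if self.covariance is None:
            return None
        return np.sqrt(np.diag(self.covariance))


def _weights(spec: VelocitySpectrum) -> np.ndarray:
    """Log-residual weights: with reported sigma, 1/(sigma/D) (delta-method
    relative error); otherwise unit weight (constant relative error)."""
    if spec.sigma is not None:
        return spec.D / spec.sigma
    return np.ones(len(spec))


def _ls_multistart(resid, theta0: np.ndarray, rng: np.ndarray) -> optimize.OptimizeResult:
    """Bounded least squares from 5 jittered starts; best rss wins, ties
    broken by the smaller parameter norm."""
    best = None
    starts = [theta0] + [theta0 + rng.normal(0.0, 0.5, size=theta0.size)
                         for _ in range(_N_STARTS - 1)]
    lb, ub = theta0 - 25.0, theta0 + 25.0
    for s in starts:
        try:
            res = optimize.least_squares(resid, np.clip(s, lb, ub),
                                         bounds=(lb, ub), method="trf",
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost * (1 - 1e-12) or (
                abs(res.cost - best.cost) <= 1e-12 * max(best.cost, 1e-300)
                and np.linalg.norm(res.x) < np.linalg.norm(best.x)):
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")
    return best


def _finish(model_id: str, res, names: Tuple[str, ...], spec: VelocitySpectrum,
            make_params, fixed: Dict[str, float], extra_flags=()) -> FitResult:
    n = len(spec)
    p = res.x.size
    rss = float(2.0 * res.cost)
    flags = list(extra_flags)
    theta = np.exp(res.x)
    # covariance in log space via the Gauss-Newton Hessian, then delta method
    cov = None
    if n > p:
        J = res.jac
        try:
            cov_log = rss / (n - p) * np.linalg.inv(J.T @ J)
            cov = cov_log * np.outer(theta, theta)
            cov = 0.5 * (cov + cov.T)
        except np.linalg.LinAlgError:
            flags.append("singular_jacobian")
    aic = n * np.log(max(rss, 1e-300) / n) + 2.0 * p
    if not res.success:
        flags.append("optimizer_not_converged")
    return FitResult(model_id=model_id, params=make_params(theta),
                     covariance=cov, rss=rss, n_points=n, fixed=dict(fixed),
                     param_names=names, aic=float(aic),
                     converged=bool(res.success), flags=tuple(flags))


def fit_water_model(spec: VelocitySpectrum, T: float = 298.15,
                    n_fixed: Optional[int] = None) -> FitResult:
    """Fit the single-species model (free: gamma, tau_c; n fixed or profiled).

    When ``n_fixed`` is None, the neighbour count is profiled over 1..6 and
    the best-rss value kept.  Requires at least 4 points.
    """
    if len(spec) < 4:
        raise ValueError("water-model fit requires at least 4 points")
    w = _weights(spec)
    omega = spec.omega
    logD = np.log(spec.D)
    kT = KB * T

    def make_resid(n):
        def resid(theta):
            gamma, tau = np.exp(theta)
            x = (tau * omega) ** 2
            model = np.log(kT / gamma * (n + x) / (n**2 + x))
            return w * (model - logD)
        return resid

    gamma0 = kT / np.median(spec.D)
    f_geo = np.exp(np.mean(np.log(spec.freq[spec.freq > 0])))
    tau0 = 1.0 / (2.0 * np.pi * f_geo)
    theta0 = np.log([gamma0, tau0])
    if n_fixed is not None:
        if int(n_fixed) != n_fixed or n_fixed < 1:
            raise ValueError("n_fixed must be an integer >= 1")
        n_candidates = [int(n_fixed)]
    else:
        n_candidates = list(range(1, 7))
    best = None
    for n in n_candidates:
        rng = np.random.default_rng(_JITTER_SEED)
        res = _ls_multistart(make_resid(n), theta0, rng)
        if best is None or res.cost < best[1].cost:
            best = (n, res)
    n, res = best
    fixed = {"n": n} if n_fixed is not None else {}
    flags = [] if n_fixed is not None else [f"n_profiled:{n}"]
    if np.any(np.abs(res.x - theta0) > 24.0):
        flags.append("parameter_at_bounds")
    return _finish(
        "water_eq2", res, ("gamma", "tau_c"), spec,
        lambda th: CoupledLEParams(gamma=th[0], k=th[0] / th[1], n=n, T=T),
        fixed, flags)


def fit_mixture_model(spec: VelocitySpectrum, T: float = 298.15,
                      n_w_fixed: int = 2, n_c_fixed: int = 1) -> FitResult:
    """Fit the two-species model (free: gamma, tau, omega_o; counts fixed).

    Requires at least 6 points.  A resonance pushed far outside the sampled
    band or with an enormous standard error is flagged
    ``omega_o_unidentifiable`` (typical for thinning, water-like input).
    """
    if len(spec) < 6:
        raise ValueError("mixture-model fit requires at least 6 points")
    w = _weights(spec)
    omega = spec.omega
    logD = np.log(spec.D)
    kT = KB * T
    n_w, n_c = int(n_w_fixed), int(n_c_fixed)
    if n_w < 0 or n_c < 1:
        raise ValueError("n_w_fixed must be >= 0 and n_c_fixed >= 1 "
                         "(with no clusters, fit the water model)")

    def resid(theta):
        gamma, tau, omega_o = np.exp(theta)
        params = MixtureLEParams.from_rates(gamma=gamma, tau=tau,
                                            omega_o=omega_o, T=T,
                                            n_w=n_w, n_c=n_c)
        return w * (np.log(eval_mixture_vas(omega, params)) - logD)

    gamma0 = kT / np.median(spec.D)
    f_geo = np.exp(np.mean(np.log(spec.freq[spec.freq > 0])))
    tau0 = 1.0 / (2.0 * np.pi * f_geo)
    # steepest descending slope of log D locates the resonance start
    dlogD = np.diff(np.log(spec.D)) / np.diff(np.log(spec.freq))
    i_steep = int(np.argmin(dlogD))
    f_steep = np.sqrt(spec.freq[i_steep] * spec.freq[i_steep + 1])
    omega_o0 = 2.0 * np.pi * f_steep
    theta0 = np.log([gamma0, tau0, omega_o0])
    rng = np.random.default_rng(_JITTER_SEED + 1)
    res = _ls_multistart(resid, theta0, rng)
    flags = []
    gamma, tau, omega_o = np.exp(res.x)
    band = 2.0 * np.pi * np.array([spec.freq[0], spec.freq[-1]])
    if not (band[0] / 30.0 <= omega_o <= band[1] * 30.0):
        flags.append("omega_o_unidentifiable")
    fit = _finish(
        "mixture_eq3", res, ("gamma", "tau", "omega_o"), spec,
        lambda th: MixtureLEParams.from_rates(gamma=th[0], tau=th[1],
                                              omega_o=th[2], T=T,
                                              n_w=n_w, n_c=n_c),
        {"n_w": n_w, "n_c": n_c}, flags)
    se = fit.stderr()
    if (se is not None and np.isfinite(se[2]) and se[2] > omega_o
            and "omega_o_unidentifiable" not in fit.flags):
        fit = FitResult(**{**fit.__dict__,
                           "flags": fit.flags + ("omega_o_unidentifiable",)})
    return fit


def select_model(spec: VelocitySpectrum, T: float = 298.15
                 ) -> Tuple[str, Dict[str, FitResult], Dict[str, float]]:
    """Fit both solvent models and pick the AIC-minimizing one.

    Returns (model_id, {model_id: FitResult}, {model_id: AIC}); a delta AIC
    below 2 yields model_id ``"ambiguous"``.
    """
    fits: Dict[str, FitResult] = {}
    errors = []
    for name, fn in (("water_eq2", fit_water_model),
                     ("mixture_eq3", fit_mixture_model)):
        try:
            fits[name] = fn(spec, T=T)
        except Exception as exc:  # propagate only if both fail
            errors.append(f"{name}: {exc}")
    if not fits:
        raise RuntimeError("both model fits failed: " + "; ".join(errors))
    aics = {name: fit.aic for name, fit in fits.items()}
    best = min(aics, key=aics.get)
    if len(aics) == 2:
        # both numerically perfect (e.g. a flat spectrum): AIC is noise
        # rms weighted log-residual below 1e-4 (0.01% of D) counts as exact
        perfect = all(f.rss / f.n_points < 1e-8 for f in fits.values())
        if perfect or abs(aics["water_eq2"] - aics["mixture_eq3"]) < 2.0:
            return "ambiguous", fits, aics
    return best, fits, aics


def fitted_spectrum(fit: FitResult, band_hz: Tuple[float, float] = (50.0, 3000.0),
                    grid_size: int = 200) -> VelocitySpectrum:
    """Evaluate a converged fit on a log grid (model-based extrapolation is
    allowed outside the original data band)."""
    if not fit.converged:
        raise ValueError("refusing to evaluate an unconverged fit")
    lo, hi = band_hz
    if not (0 < lo < hi):
        raise ValueError(f"invalid band {band_hz!r}")
    freq = np.logspace(np.log10(lo), np.log10(hi), int(grid_size))
    D = fit.evaluate(2.0 * np.pi * freq)
    return VelocitySpectrum(freq=freq, D=np.asarray(D, float),
                            label=f"fitted {fit.model_id}")
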