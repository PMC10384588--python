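"""File formats, pipeline configuration and the end-to-end demo pipeline.

Formats
-------
* Spectrum CSV: header ``freq_hz,D_m2s,sigma_m2s`` (sigma optional), UTF-8,
  '.' decimal, ``#`` comment lines tolerated.
* Fit JSON: model id, parameters with SI units in the key names, covariance,
  rss, AIC, fixed parameters, package version and input checksum.
* Network JSON: masses, frictions, dense row-major K, temperature, labels.
* Trajectory container: HDF5 (default) or CSV, with dt/seed/scheme metadata.

The demo pipeline (:func:`run_pipeline`) reproduces the full analysis chain
on synthetic data for two solvents -- a thinning water-like branch and a
thickening 33 vol% glycerol/water-like branch: noisy band-limited sampling
-> model fit -> friction spectrum -> polymer segmental VAS -> peak metrics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .fitting import (FitResult, fit_mixture_model, fit_water_model,
                      select_model)
from .network import LangevinNetwork
from .presets import DEFAULT_T, mixture_preset, polymer_preset, water_preset
from .rouse import (PolymerVAS, RouseParams, peak_metrics,
                    polymer_vas_from_solvent)
from .simulate import MGSEDesign, Trajectory, mgse_sample
from .spectra import (CoupledLEParams, MixtureLEParams, VelocitySpectrum,
                      classify_rheology, eval_mixture_vas, eval_water_vas)

__all__ = [
    "read_spectrum_csv", "write_spectrum_csv",
    "write_fit_json", "read_fit_json",
    "write_network_json", "read_network_json",
    "write_trajectory", "read_trajectory",
    "PipelineConfig", "run_pipeline",
]


# ---------------------------------------------------------------- spectrum CSV

def write_spectrum_csv(spec: VelocitySpectrum, path) -> None:
    path = Path(path)
    cols = {"freq_hz": spec.freq, "D_m2s": spec.D}
    if spec.sigma is not None:
        cols["sigma_m2s"] = spec.sigma
    with open(path, "w", encoding="utf-8") as fh:
        if spec.label:
            fh.write(f"# {spec.label}\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_spectrum_csv(path, label: str = "") -> VelocitySpectrum:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", encoding="utf-8")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in ("freq_hz", "D_m2s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in [c for c in ("freq_hz", "D_m2s", "sigma_m2s") if c in df.columns]:
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col!r}, "
                             f"row {int(bad[0]) + 2}")
        if col != "freq_hz":
            neg = df.index[df[col] <= 0]
            if len(neg):
                raise ValueError(f"{path}: non-positive {col!r} in row "
                                 f"{int(neg[0]) + 2}")
    sigma = df["sigma_m2s"].to_numpy() if "sigma_m2s" in df.columns else None
    return VelocitySpectrum(freq=df["freq_hz"].to_numpy(),
                            D=df["D_m2s"].to_numpy(), sigma=sigma,
                            label=label or path.stem)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# -------------------------------------------------------------------- fit JSON

_PARAM_KEYS = {
    "water_eq2": {"gamma": "gamma_kg_per_s", "k": "k_N_per_m", "n": "n",
                  "T": "T_K"},
    "mixture_eq3": {"gamma": "gamma_kg_per_s", "k": "k_N_per_m",
                    "omega_o": "omega_o_rad_per_s", "n_w": "n_w",
                    "n_c": "n_c", "T": "T_K"},
}


def write_fit_json(fit: FitResult, path, input_checksum: str = "") -> None:
    keys = _PARAM_KEYS[fit.model_id]
    params = {json_key: getattr(fit.params, attr)
              for attr, json_key in keys.items()}
    doc = {
        "model_id": fit.model_id,
        "params": params,
        "param_names": list(fit.param_names),
        "covariance": None if fit.covariance is None else fit.covariance.tolist(),
        "rss": fit.rss,
        "aic": fit.aic,
        "n_points": fit.n_points,
        "fixed": fit.fixed,
        "converged": fit.converged,
        "flags": list(fit.flags),
        "software_version": __version__,
        "input_checksum": input_checksum,
    }
    Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")


def read_fit_json(path) -> FitResult:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    model_id = doc["model_id"]
    p = doc["params"]
    if model_id == "water_eq2":
        params = CoupledLEParams(gamma=p["gamma_kg_per_s"], k=p["k_N_per_m"],
                                 n=p["n"], T=p["T_K"])
    elif model_id == "mixture_eq3":
        params = MixtureLEParams(gamma=p["gamma_kg_per_s"], k=p["k_N_per_m"],
                                 omega_o=p["omega_o_rad_per_s"],
                                 n_w=p["n_w"], n_c=p["n_c"], T=p["T_K"])
    else:
        raise ValueError(f"{path}: unknown model_id {model_id!r}")
    cov = doc.get("covariance")
    return FitResult(model_id=model_id, params=params,
                     covariance=None if cov is None else np.asarray(cov),
                     rss=doc["rss"], n_points=doc["n_points"],
                     fixed=doc.get("fixed", {}),
                     param_names=tuple(doc.get("param_names", ())),
                     aic=doc.get("aic", np.nan),
                     converged=doc.get("converged", True),
                     flags=tuple(doc.get("flags", ())))


# ---------------------------------------------------------------- network JSON

def write_network_json(net: LangevinNetwork, path) -> None:
    doc = {
        "masses_kg": net.masses.tolist(),
        "frictions_kg_per_s": net.frictions.tolist(),
        "K_N_per_m": net.K.tolist(),
        "T_K": net.T,
        "labels": None if net.labels is None else list(net.labels),
    }
    Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")


def read_network_json(path) -> LangevinNetwork:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return LangevinNetwork(masses=np.asarray(doc["masses_kg"]),
                           frictions=np.asarray(doc["frictions_kg_per_s"]),
                           K=np.asarray(doc["K_N_per_m"]), T=doc["T_K"],
                           labels=doc.get("labels"))


# ---------------------------------------------------------- trajectory storage

def write_trajectory(traj: Trajectory, path, fmt: str = "hdf5") -> None:
    path = Path(path)
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("positions", data=traj.positions)
            ds.attrs["dt_s"] = traj.dt
            ds.attrs["seed"] = traj.seed
            ds.attrs["scheme"] = traj.scheme
            ds.attrs["T_K"] = traj.T
            if traj.labels is not None:
                ds.attrs["labels"] = list(traj.labels)
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# dt_s={traj.dt!r} seed={traj.seed} "
                     f"scheme={traj.scheme} T_K={traj.T!r}\n")
            cols = (traj.labels if traj.labels is not None
                    else [f"x{i}" for i in range(traj.n_particles)])
            pd.DataFrame(traj.positions,
                         columns=[f"{c}_{i}" for i, c in enumerate(cols)]
                         ).to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    import h5py
    with h5py.File(path, "r") as fh:
        ds = fh["positions"]
        labels = ds.attrs.get("labels")
        return Trajectory(dt=float(ds.attrs["dt_s"]), positions=ds[...],
                          seed=int(ds.attrs["seed"]),
                          scheme=str(ds.attrs["scheme"]),
                          T=float(ds.attrs["T_K"]),
                          labels=None if labels is None else tuple(labels))


# ------------------------------------------------------------------- pipeline

_CONFIG_KEYS = {"seed", "f_min_hz", "f_max_hz", "n_points", "noise_cv",
                "T_K", "N_segments_polymer", "b_m", "polymer_band_hz",
                "polymer_grid", "fit_mode"}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the end-to-end demo; round-trips losslessly through
    JSON and rejects unknown keys."""

    seed: int = 0
    f_min_hz: float = 50.0
    f_max_hz: float = 3000.0
    n_points: int = 30
    noise_cv: float = 0.05
    T_K: float = DEFAULT_T
    N_segments_polymer: int = 5000
    b_m: float = 5.0e-9
    polymer_band_hz: tuple = (50.0, 3000.0)
    polymer_grid: int = 200
    fit_mode: str = "known"   # "known": fit each branch's own model; "auto": AIC

    def __post_init__(self):
        if self.fit_mode not in ("known", "auto"):
            raise ValueError("fit_mode must be 'known' or 'auto'")
        object.__setattr__(self, "polymer_band_hz",
                           tuple(float(v) for v in self.polymer_band_hz))

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        text = Path(source).read_text(encoding="utf-8") \
            if isinstance(source, (str, Path)) and str(source).endswith(".json") \
            else str(source)
        doc = json.loads(text)
        unknown = set(doc) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @property
    def checksum(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Execute sample -> fit -> polymer for the water-like and mixture-like
    branches; writes spectra CSVs, fit JSONs, polymer CSVs and a summary
    JSON (including every seed used) into ``outdir``.  Returns the summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    T = config.T_K
    rp = RouseParams(N=config.N_segments_polymer, b=config.b_m, T=T)
    branches = {
        "water": (water_preset(T), eval_water_vas, fit_water_model),
        "mixture": (mixture_preset(T), eval_mixture_vas, fit_mixture_model),
    }
    summary: Dict = {"config": json.loads(config.to_json()),
                     "config_checksum": config.checksum,
                     "software_version": __version__, "branches": {}}
    for i, (name, (params, model_fn, fit_fn)) in enumerate(branches.items()):
        stage = f"{name} branch"
        try:
            design = MGSEDesign(f_min=config.f_min_hz, f_max=config.f_max_hz,
                                n_points=config.n_points,
                                noise_cv=config.noise_cv,
                                seed=config.seed + i)
            sample = mgse_sample(lambda w, p=params, fn=model_fn: fn(w, p),
                                 design, T=T, label=f"synthetic {name} sample")
            csv_path = outdir / f"{name}_spectrum.csv"
            write_spectrum_csv(sample, csv_path)
            if config.fit_mode == "auto":
                _, fits, _ = select_model(sample, T=T)
                fit = min(fits.values(), key=lambda f: f.aic)
            else:
                if name == "water":
                    fit = fit_fn(sample, T=T, n_fixed=params.n)
                else:
                    fit = fit_fn(sample, T=T, n_w_fixed=params.n_w,
                                 n_c_fixed=params.n_c)
            write_fit_json(fit, outdir / f"{name}_fit.json",
                           input_checksum=_checksum(csv_path))
            pv = polymer_vas_from_solvent(fit, rp,
                                          band_hz=config.polymer_band_hz,
                                          grid_size=config.polymer_grid,
                                          label=f"{name} fit")
            write_spectrum_csv(pv.spectrum, outdir / f"{name}_polymer.csv")
            pm = peak_metrics(pv)
            D = pv.spectrum.D
            summary["branches"][name] = {
                "sample_seed": design.seed,
                "solvent_class": classify_rheology(sample),
                "fit_model": fit.model_id,
                "fit_rss": fit.rss,
                "fit_flags": list(fit.flags),
                "polymer_monotone_nondecreasing": bool(np.all(np.diff(D) >= 0)),
                "polymer_has_interior_peak": pm is not None,
                "peak_metrics": None if pm is None else asdict(pm),
            }
        except Exception as exc:
            raise RuntimeError(f"pipeline failed in {stage}: {exc}") from exc
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2),
                                         encoding="utf-8")
    return summary
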