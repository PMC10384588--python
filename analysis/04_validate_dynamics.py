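#!/usr/bin/env python
"""Cross-validation of the time-domain simulators against exact results.

Smaller-scale counterparts of the checks in tests/test_acceptance.py:
(i) Brownian dynamics of the 4-particle water+cluster motif against the
frequency-domain oracle, (ii) a constant-friction Rouse chain against the
mode-sum spectrum, and (iii) the fluctuation--dissipation pairing of the
colored-noise generator.  Writes validation_report.json.
"""

import json
from pathlib import Path

import numpy as np

import vaspipe as vp
from vaspipe.constants import KB

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 7
REDUCED_T = 1.0 / KB


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}

    m = vp.mixture_preset()
    net = vp.build_mixture_motif(m.n_w, m.n_c, 0.0, m.M_cluster, m.gamma,
                                 m.k, m.T)
    traj = vp.simulate_network(net, dt=2e-7, n_steps=4_000_000, seed=SEED)
    spec = vp.estimate_vas(traj, particles=[0], n_segments=80)
    binned = vp.log_bin_spectrum(spec, bins_per_decade=8)
    sel = (binned.freq >= 100.0) & (binned.freq <= 1000.0)
    ref = vp.oracle_vas(net, 2 * np.pi * binned.freq[sel], 0)
    report["motif_sim_vs_oracle_max_rel_err"] = float(
        np.max(np.abs(binned.D[sel] / ref - 1)))

    rp = vp.RouseParams(N=32, b=1.0, T=REDUCED_T)
    traj = vp.simulate_rouse_gle(rp, vp.PronyKernel(gamma_inf=1.0), dt=8e-4,
                                 n_steps=1_500_000, seed=SEED,
                                 dtype=np.float32)
    spec = vp.estimate_vas(traj, particles=range(0, 32, 2), n_segments=40)
    binned = vp.log_bin_spectrum(spec, bins_per_decade=6)
    sel = (binned.freq >= 0.1) & (binned.freq <= 0.6)
    ref = vp.rouse_vas_sum(2 * np.pi * binned.freq[sel], 32,
                           vp.rouse_tau_c(1.0, 1.0, REDUCED_T),
                           vp.rouse_Dc(1.0, 32, REDUCED_T))
    report["rouse_sim_vs_mode_sum_max_rel_err"] = float(
        np.max(np.abs(binned.D[sel] / ref - 1)))

    kern = vp.PronyKernel(c=[0.8, 0.4], lam=[1.0, 5.0])
    f = vp.colored_noise(kern, dt=5e-3, n_steps=1_000_000, T=REDUCED_T,
                         seed=SEED)
    fm = f - f.mean()
    n = f.size
    lags = np.arange(0, 601, 5)
    acov = np.array([np.dot(fm[:n - l], fm[l:]) / (n - l) for l in lags])
    report["fdt_autocov_max_dev_frac_of_c0"] = float(
        np.max(np.abs(acov - kern.gamma_of_t(lags * 5e-3)))
        / kern.gamma_of_t(0.0))

    (OUT / "validation_report.json").write_text(json.dumps(report, indent=2))
    for k, v in report.items():
        print(f"{k}: {v:.3f}")
    print(f"wrote validation_report.json to {OUT}")


if __name__ == "__main__":
    main()
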