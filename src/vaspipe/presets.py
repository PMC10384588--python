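"""Canonical synthetic study conditions.

These parameter sets define the solvents the synthetic measurement emulator
produces and the polymer used in the end-to-end demonstration.  They are
chosen once to be physically plausible stand-ins for the measured systems:

* ``water_preset`` -- a thinning, pure-water-like solvent.  The
  high-frequency limit kB*T/gamma matches the room-temperature self-diffusion
  coefficient of water (~2.3e-9 m^2/s); n = 3 coupled molecules gives a
  zero-frequency plateau a factor 3 lower; tau_c = 5e-4 s places the rise
  inside the 50--3000 Hz spin-echo band, as the measured water spectra show.
* ``mixture_preset`` -- a thickening, 33 vol% glycerol/water-like solvent:
  higher friction (lower diffusivities), a short coupling time and a cluster
  resonance at the top of the band, which makes the spectrum monotonically
  decreasing across the whole band by roughly a factor ~2.7.
* ``polymer_preset`` -- a long flexible chain (N = 5000 Kuhn segments of
  b = 5 nm) whose segmental spectrum responds visibly to the solvent's
  rheology inside the measurement band.
"""

from __future__ import annotations

from .rouse import RouseParams
from .spectra import CoupledLEParams, MixtureLEParams

__all__ = ["DEFAULT_T", "water_preset", "mixture_preset", "polymer_preset"]

#: Default temperature for all presets, K.
DEFAULT_T: float = 298.15


def water_preset(T: float = DEFAULT_T) -> CoupledLEParams:
    """Thinning single-species solvent (pure-water-like)."""
    gamma = 1.8e-12           # kg/s -> kB*T/gamma ~ 2.3e-9 m^2/s
    tau_c = 5.0e-4            # s
    return CoupledLEParams.from_tau(gamma=gamma, tau_c=tau_c, n=3, T=T)


def mixture_preset(T: float = DEFAULT_T) -> MixtureLEParams:
    """Thickening two-species solvent (33 vol% glycerol/water-like)."""
    gamma = 4.0e-12           # kg/s
    tau = 2.0e-5              # s
    omega_o = 2.0 * 3.141592653589793 * 3000.0  # rad/s, resonance at band top
    return MixtureLEParams.from_rates(gamma=gamma, tau=tau, omega_o=omega_o,
                                      T=T, n_w=2, n_c=1)


def polymer_preset(T: float = DEFAULT_T) -> RouseParams:
    """Long flexible chain for the polymer-in-solvent demonstration."""
    return RouseParams(N=5000, b=5.0e-9, T=T)
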