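"""Exact frequency-domain VAS of linear Langevin bead--spring networks.

This is the brute-force oracle of the package: for any network of particles
with masses ``M_i`` (zero marks an overdamped particle), frictions
``gamma_i`` and a symmetric positive semi-definite spring matrix ``K``,
driven by white thermal forces of spectral density ``2 kB T gamma_i``, the
position spectral density is

    S_x(omega) = G (2 kB T diag(Gamma)) G^dagger,
    G(omega)   = [K - omega^2 diag(M) - i omega diag(Gamma)]^{-1},

and the per-particle VAS is ``D_i(omega) = omega^2 Re S_x,ii / 2``.  Dense
linear algebra only; intended for networks of at most ~100 particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .constants import KB

__all__ = ["LangevinNetwork", "build_mixture_motif", "oracle_vas"]


@dataclass(frozen=True)
class LangevinNetwork:
    """A linear bead--spring network in one dimension.

    masses    : per-particle masses, kg; 0 marks an overdamped particle.
    frictions : per-particle frictions, kg/s; strictly positive.
    K         : symmetric positive semi-definite spring matrix, N/m
                (a graph Laplacian times k for uniform coupling).
    T         : temperature, K.
    labels    : per-particle species tags, e.g. "water"/"cluster".
    """

    masses: np.ndarray
    frictions: np.ndarray
    K: np.ndarray
    T: float
    labels: Optional[tuple] = None

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=float)
        g = np.asarray(self.frictions, dtype=float)
        K = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "frictions", g)
        object.__setattr__(self, "K", K)
        n = m.size
        if g.size != n or K.shape != (n, n):
            raise ValueError("inconsistent dimensions between masses, frictions and K")
        if np.any(m < 0):
            raise ValueError("masses must be non-negative")
        if np.any(g <= 0):
            raise ValueError("frictions must be strictly positive")
        if not np.allclose(K, K.T, rtol=1e-12, atol=0):
            raise ValueError("K must be symmetric")
        scale = np.max(np.abs(K)) if n else 0.0
        if scale > 0 and np.min(np.linalg.eigvalsh(K)) < -1e-10 * scale:
            raise ValueError("K must be positive semi-definite")
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != n:
                raise ValueError("labels must match the number of particles")
            object.__setattr__(self, "labels", labels)
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_particles(self) -> int:
        return self.masses.size


def build_mixture_motif(n_w: int, n_c: int, M_w: float, M_c: float,
                        gamma: float, k: float, T: float) -> LangevinNetwork:
    """Star motif of the two-species mixture model.

    A central water particle (mass ``M_w``, typically 0 for overdamped) is
    coupled with spring constant ``k`` to ``n_w`` water neighbours and
    ``n_c`` clusters of mass ``M_c``; there are no cluster--cluster or
    neighbour--neighbour springs.  Every row of K sums to zero (translation
    invariance), so the network diffuses as a whole.
    """
    if int(n_w) != n_w or int(n_c) != n_c or n_w < 0 or n_c < 0:
        raise ValueError("n_w and n_c must be non-negative integers")
    n_w, n_c = int(n_w), int(n_c)
    if n_w + n_c < 1:
        raise ValueError("the motif needs at least one neighbour (n_w + n_c >= 1)")
    if gamma <= 0 or k <= 0 or T <= 0 or M_w < 0 or M_c < 0:
        raise ValueError("gamma, k, T must be positive; masses non-negative")
    n = 1 + n_w + n_c
    K = np.zeros((n, n))
    for j in range(1, n):
        K[0, 0] += k
        K[j, j] += k
        K[0, j] = K[j, 0] = -k
    masses = np.zeros(n)
    masses[0] = M_w
    masses[1:1 + n_w] = M_w
    masses[1 + n_w:] = M_c
    labels = ("water",) * (1 + n_w) + ("cluster",) * n_c
    return LangevinNetwork(masses=masses, frictions=np.full(n, gamma), K=K,
                           T=T, labels=labels)


def _dc_limit(net: LangevinNetwork, i: int) -> float:
    """omega -> 0 limit of D_i.

    The zero-frequency diffusivity is carried entirely by the free
    (zero-eigenvalue) modes: for the connected component containing particle
    ``i`` it equals kB*T / sum(gamma_j) over that component if the component
    is free (its restricted K has a zero mode, i.e. zero row sums), and 0 if
    the component is pinned.
    """
    n = net.n_particles
    adj = csr_matrix((np.abs(net.K) > 0) & ~np.eye(n, dtype=bool))
    _, comp = connected_components(adj, directed=False)
    members = comp == comp[i]
    Kc = net.K[np.ix_(members, members)]
    scale = max(np.max(np.abs(net.K)), 1.0)
    if np.all(np.abs(Kc.sum(axis=1)) <= 1e-10 * scale):
        return KB * net.T / float(net.frictions[members].sum())
    return 0.0


def oracle_vas(net: LangevinNetwork, omega, particle_index: int = 0):
    """Exact VAS of one particle of a linear Langevin network, m^2/s.

    ``omega`` in rad/s, scalar or array.  The omega = 0 value is the analytic
    limit (centre-of-mass diffusivity of the particle's free component).
    Raises if the response matrix is singular at a nonzero frequency.
    """
    w = np.asarray(omega, dtype=float)
    scalar = w.ndim == 0
    w = np.atleast_1d(w)
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError("omega must be finite and non-negative")
    i = particle_index
    if not 0 <= i < net.n_particles:
        raise IndexError(f"particle_index {i} out of range")
    G2 = 2.0 * KB * net.T * net.frictions
    out = np.empty_like(w)
    for j, wj in enumerate(w):
        if wj == 0.0:
            out[j] = _dc_limit(net, i)
            continue
        A = (net.K - wj**2 * np.diag(net.masses)
             - 1j * wj * np.diag(net.frictions))
        try:
            row = np.linalg.solve(A.T, np.eye(net.n_particles)[i])  # i-th row of A^-1
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular response matrix at omega={wj!r} rad/s") from exc
        S_ii = np.sum(G2 * np.abs(row) ** 2)
        out[j] = 0.5 * wj**2 * S_ii
    return float(out[0]) if scalar else out
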