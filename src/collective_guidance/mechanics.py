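"""Short-range physical interactions between cells.

Cells are pointlike particles with a preferred (equilibrium) separation of
one cell diameter.  Pairs closer than that repel with a spring of strength
``v_r``; pairs between the equilibrium separation and the interaction range
``D0`` attract with a spring of strength ``v_a``; beyond ``D0`` the force
vanishes.  The same range ``D0`` defines "contact": cells within ``D0`` of
each other are neighbors, and contact inhibition of locomotion (CIL) biases
each cell's polarity away from its neighbors, along

    q_i = sum_{j ~ i} rhat_ij ,

the sum of unit vectors pointing from each contacting neighbor j toward i.
Interior cells of a symmetric cluster have q ~ 0; edge cells point outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactGraph",
    "pair_force",
    "pairwise_geometry",
    "net_forces",
    "contact_graph",
    "cil_bias_vectors",
]

#: Default interaction / contact range in cell diameters.
DEFAULT_D0 = 1.2


class DegenerateOverlapError(ValueError):
    """Two cells coincide; pair interactions are undefined at zero distance."""


@dataclass
class ContactGraph:
    """Symmetric contact network of a cell configuration.

    ``adj`` is a boolean adjacency matrix (no self edges); ``degree`` the
    per-cell neighbor count n_i; ``cutoff`` the contact range used.
    """

    adj: np.ndarray
    cutoff: float
    degree: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adj, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("self-edges are not allowed")
        self.adj = adj
        self.degree = adj.sum(axis=1).astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.adj.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adj[i])

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian L = diag(n_i) - adj as a dense float matrix."""
        return np.diag(self.degree).astype(float) - self.adj.astype(float)


def pair_force(d, v_r: float, v_a: float, D0: float = DEFAULT_D0):
    """Signed radial force between a pair at separation ``d`` (diameters).

    Positive values push the cells apart (repulsion), negative pull them
    together (adhesion):

        F(d) = +v_r (1 - d)            d < 1
             = -v_a (d - 1)/(D0 - 1)   1 <= d < D0
             = 0                       d >= D0

    Continuous at d = 1 (both branches vanish); drops discontinuously to
    zero at d = D0.  Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0.0):
        raise DegenerateOverlapError("pair separation must be positive")
    if D0 <= 1.0:
        raise ValueError("D0 must exceed the equilibrium separation of 1")
    out = np.where(
        d < 1.0,
        v_r * (1.0 - d),
        np.where(d < D0, -v_a * (d - 1.0) / (D0 - 1.0), 0.0),
    )
    return out if out.ndim else float(out)


def pairwise_geometry(positions: np.ndarray):
    """Pairwise displacement tensor, distance matrix and unit vectors.

    Returns ``(diff, dist, rhat)`` where ``diff[i, j] = r_i - r_j``,
    ``dist[i, j] = |r_i - r_j|`` (diagonal set to inf so it never counts as
    a contact) and ``rhat[i, j]`` the unit vector from j toward i.
    Raises on coincident distinct cells.
    """
    pos = np.asarray(positions, dtype=float)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    n = pos.shape[0]
    idx = np.arange(n)
    dist[idx, idx] = np.inf
    if np.any(dist <= 0.0):
        raise DegenerateOverlapError("coincident cells in configuration")
    rhat = diff / dist[:, :, None]
    return diff, dist, rhat


def net_forces(
    positions: np.ndarray, v_r: float, v_a: float, D0: float = DEFAULT_D0
) -> np.ndarray:
    """Total intercellular force on each cell, sum_j F_ij.

    F_ij acts on i along rhat_ij (from j toward i) with magnitude given by
    :func:`pair_force`; action--reaction holds pairwise, so the forces sum
    to zero over the cluster.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] < 2:
        return np.zeros_like(pos)
    _, dist, rhat = pairwise_geometry(pos)
    mag = np.zeros_like(dist)
    m_rep = dist < 1.0
    mag[m_rep] = v_r * (1.0 - dist[m_rep])
    m_adh = (dist >= 1.0) & (dist < D0)
    mag[m_adh] = -v_a * (dist[m_adh] - 1.0) / (D0 - 1.0)
    return np.einsum("ij,ijk->ik", mag, rhat)


def contact_graph(positions: np.ndarray, cutoff: float = DEFAULT_D0) -> ContactGraph:
    """Contact network: an edge for every pair with distance < ``cutoff``."""
    pos = np.asarray(positions, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    if pos.shape[0] < 2:
        return ContactGraph(np.zeros((pos.shape[0], pos.shape[0]), dtype=bool), cutoff)
    _, dist, _ = pairwise_geometry(pos)
    return ContactGraph(dist < cutoff, cutoff)


def cil_bias_vectors(positions: np.ndarray, graph: ContactGraph) -> np.ndarray:
    """CIL bias q_i = sum over contacting neighbors of rhat_ij.

    Not normalized: a cell with more one-sided contact gets a stronger
    outward bias.  Isolated cells get the zero vector.
    """
    pos = np.asarray(positions, dtype=float)
    if graph.n_cells != pos.shape[0]:
        raise ValueError("graph does not match positions")
    if pos.shape[0] < 2:
        return np.zeros_like(pos)
    _, _, rhat = pairwise_geometry(pos)
    return np.einsum("ij,ijk->ik", graph.adj.astype(float), rhat)
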