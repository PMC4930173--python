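"""Cluster-level measurements and the rigid-cluster steady-state predictor.

The key observables of chemotaxing clusters are the mean velocity along
the gradient <V_x>, the chemotactic index CI = <V_x>/<|V|> over an
ensemble of trajectories, and the mean angular speed <|Omega|>.  Velocity
is always measured as centroid displacement over a time window divided by
the window duration; the natural velocity scale is V0 = beta_bar tau S1.

For rigid, strongly adherent clusters the mean velocity can be predicted
without stochastic simulation: with the polarity dynamics at steady state,
<V>_c = (1/N) sum_i beta_i q_i at fixed configuration, averaged over the
cluster's orientation.  Fluctuations about this mean are Gaussian with
per-component variance sigma^2 tau / N, which fixes the predicted CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import i0e

from .chemo_signal import (
    LegiRates,
    SignalField,
    legi_steady_state,
    signal_at,
    susceptibility_from_response,
    susceptibility_minimal,
)
from .dynamics import ModelParams, TrajectoryRecord
from .mechanics import cil_bias_vectors, contact_graph

__all__ = [
    "EnsembleSummary",
    "cluster_velocity",
    "chemotactic_index",
    "angular_speed",
    "fragmentation_count",
    "rigid_steady_prediction",
    "chirality_drift",
    "summarize_ensemble",
]


def _window_frames(times: np.ndarray, window: tuple[float, float] | None):
    if window is None:
        return 0, len(times) - 1
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must have positive duration")
    i0_ = int(np.argmin(np.abs(times - lo)))
    i1_ = int(np.argmin(np.abs(times - hi)))
    if i1_ <= i0_:
        raise ValueError("window narrower than the snapshot cadence")
    return i0_, i1_


def cluster_velocity(
    traj: TrajectoryRecord, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Centroid displacement over the window divided by its duration."""
    i0_, i1_ = _window_frames(traj.times, window)
    cm = traj.centroid()
    return (cm[i1_] - cm[i0_]) / (traj.times[i1_] - traj.times[i0_])


def chemotactic_index(velocities: np.ndarray) -> float:
    """CI = <V_x> / <|V|> over an ensemble of trajectory velocities."""
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    if v.shape[0] < 1:
        raise ValueError("need at least one velocity")
    speeds = np.linalg.norm(v, axis=1)
    mean_speed = speeds.mean()
    if mean_speed == 0:
        return 0.0
    return float(v[:, 0].mean() / mean_speed)


def angular_speed(
    traj: TrajectoryRecord,
    window: tuple[float, float] | None = None,
    min_radius: float = 1e-9,
) -> tuple[float, float]:
    """Signed mean angular velocity of the cluster and its absolute value.

    Per frame, each cell's angular velocity about the centroid is
    omega_i = [(r_i - r_cm) x (v_i - v_cm)]_z / |r_i - r_cm|^2 with
    central-finite-difference velocities; cells at the centroid are
    excluded.  The cell average is then averaged over the window.
    """
    if traj.n_cells < 2:
        raise ValueError("angular speed requires at least two cells")
    i0_, i1_ = _window_frames(traj.times, window)
    pos = traj.positions[i0_ : i1_ + 1]
    t = traj.times[i0_ : i1_ + 1]
    if len(t) < 3:
        raise ValueError("need at least three frames for central differences")
    v = (pos[2:] - pos[:-2]) / (t[2:] - t[:-2])[:, None, None]
    mid = pos[1:-1]
    rel = mid - mid.mean(axis=1, keepdims=True)
    vrel = v - v.mean(axis=1, keepdims=True)
    r2 = np.einsum("fik,fik->fi", rel, rel)
    cross = rel[:, :, 0] * vrel[:, :, 1] - rel[:, :, 1] * vrel[:, :, 0]
    valid = r2 > min_radius**2
    omega_cells = np.where(valid, cross / np.where(valid, r2, 1.0), np.nan)
    omega_frames = np.nanmean(omega_cells, axis=1)
    omega = float(np.mean(omega_frames))
    return omega, abs(omega)


def fragmentation_count(positions: np.ndarray, D0: float) -> int:
    """Number of connected components of the contact graph (1 = intact)."""
    g = contact_graph(positions, D0)
    n, _ = connected_components(csr_matrix(g.adj), directed=False)
    return int(n)


def _rice_mean(nu: float, s: float) -> float:
    """E|V| for a 2D isotropic Gaussian with mean magnitude nu and std s.

    Computed as the mean of the Rice distribution by adaptive quadrature;
    the exponentially scaled Bessel i0e keeps the integrand finite.
    """
    if s == 0:
        return abs(nu)

    def integrand(r):
        return (r * r / (s * s)) * np.exp(-((r - nu) ** 2) / (2 * s * s)) * i0e(
            r * nu / (s * s)
        )

    hi = nu + 12.0 * s
    val, _ = quad(integrand, 0.0, hi, points=[max(nu, 0.0)], limit=200)
    return float(val)


@dataclass
class RigidPrediction:
    """Orientation-averaged steady-state prediction for a rigid cluster."""

    mean_velocity: np.ndarray  # orientation-averaged (Vx, Vy)
    speed: float  # |orientation-averaged velocity|
    ci: float
    per_orientation: np.ndarray  # (n_orientations, 2)
    n_cells: int


def rigid_steady_prediction(
    positions: np.ndarray,
    params: ModelParams,
    fieldspec: SignalField,
    n_orientations: int = 64,
) -> RigidPrediction:
    """Steady-state drift of a rigid cluster, averaged over orientation.

    For each equally spaced rotation of the configuration about its
    centroid: evaluate the signal per cell, the response beta_i (minimal or
    via the LEGI steady state), the CIL bias q_i, and the rigid-body drift
    <V>_c = (1/N) sum_i beta_i q_i.  The chemotactic index follows from the
    mixture of 2D Gaussians centered at the per-orientation drifts with
    per-component variance sigma^2 tau / N.
    """
    pos = np.asarray(positions, dtype=float)
    pos = pos - pos.mean(axis=0)
    n = pos.shape[0]
    thetas = np.linspace(0.0, 2.0 * np.pi, n_orientations, endpoint=False)
    vels = np.empty((n_orientations, 2))
    for k, th in enumerate(thetas):
        c, s_ = np.cos(th), np.sin(th)
        rot = pos @ np.array([[c, s_], [-s_, c]])
        if n == 1:
            vels[k] = 0.0
            continue
        graph = contact_graph(rot, params.D0)
        q = cil_bias_vectors(rot, graph)
        S = np.atleast_1d(signal_at(fieldspec, rot, 0.0))
        if params.response_mode == "minimal":
            beta = np.asarray(susceptibility_minimal(S, params.beta_bar))
        else:
            rates: LegiRates = params.legi
            ss = legi_steady_state(S, graph, rates)
            mode = "linear" if params.response_mode == "legi_linear" else "switch"
            beta = np.atleast_1d(
                susceptibility_from_response(ss.R, rates, params.beta_bar, mode, params.lam)
            )
        vels[k] = (beta[:, None] * q).sum(axis=0) / n
    mean_v = vels.mean(axis=0)
    s = params.sigma * np.sqrt(params.tau / n)
    mean_speed = float(np.mean([_rice_mean(np.linalg.norm(v), s) for v in vels]))
    ci = float(mean_v[0] / mean_speed) if mean_speed > 0 else 0.0
    return RigidPrediction(
        mean_velocity=mean_v,
        speed=float(np.linalg.norm(mean_v)),
        ci=ci,
        per_orientation=vels,
        n_cells=n,
    )


def chirality_drift(omegas: np.ndarray, v_y: np.ndarray) -> dict:
    """Per-trajectory (Omega, V_y) pairs and branch-averaged drifts.

    The branch means are the mean perpendicular drift of the clusters
    rotating counterclockwise (Omega > 0) and clockwise (Omega < 0); a
    rotation-drift coupling shows up as branch means of opposite sign.
    """
    omegas = np.asarray(omegas, dtype=float)
    v_y = np.asarray(v_y, dtype=float)
    if omegas.shape != v_y.shape:
        raise ValueError("omega and V_y arrays must match")
    pos_branch = v_y[omegas > 0]
    neg_branch = v_y[omegas < 0]
    return {
        "pairs": np.column_stack([omegas, v_y]),
        "vy_positive_branch": float(pos_branch.mean()) if pos_branch.size else np.nan,
        "vy_negative_branch": float(neg_branch.mean()) if neg_branch.size else np.nan,
        "n_positive": int(pos_branch.size),
        "n_negative": int(neg_branch.size),
    }


@dataclass
class EnsembleSummary:
    """Per-trajectory and aggregate observables for an ensemble."""

    velocities: np.ndarray  # (n_traj, 2)
    omegas: np.ndarray  # signed, per trajectory
    window: tuple[float, float] | None
    mean_velocity: np.ndarray
    sem_velocity: np.ndarray
    ci: float
    mean_abs_omega: float
    v0: float | None = None

    @property
    def n_traj(self) -> int:
        return self.velocities.shape[0]


def summarize_ensemble(
    trajectories,
    window: tuple[float, float] | None = None,
    v0: float | None = None,
    with_rotation: bool = True,
) -> EnsembleSummary:
    """Measure velocity, CI and rotation for an ensemble of trajectories."""
    vels = np.array([cluster_velocity(tr, window) for tr in trajectories])
    if with_rotation and trajectories[0].n_cells >= 2:
        omegas = np.array([angular_speed(tr, window)[0] for tr in trajectories])
    else:
        omegas = np.zeros(len(trajectories))
    nt = len(trajectories)
    return EnsembleSummary(
        velocities=vels,
        omegas=omegas,
        window=window,
        mean_velocity=vels.mean(axis=0),
        sem_velocity=vels.std(axis=0, ddof=1) / np.sqrt(nt) if nt > 1 else np.zeros(2),
        ci=chemotactic_index(vels),
        mean_abs_omega=float(np.abs(omegas).mean()),
        v0=v0,
    )
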