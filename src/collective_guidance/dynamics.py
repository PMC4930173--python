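"""State containers and Euler--Maruyama integration of the cluster model.

Each cell i carries a position r_i and a polarity p_i (the velocity it
would have in isolation).  The coupled dynamics are

    dr_i/dt = p_i + sum_{j != i} F_ij
    dp_i/dt = -p_i/tau + sigma xi_i(t) + beta_i q_i
              + chi (grad c/|grad c|) Theta(|grad c| - g0)

with F_ij the short-range spring forces, q_i the CIL bias, beta_i the
signal-regulated CIL susceptibility and the last term co-attraction to the
secreted field c.  The noise has correlator <xi_mu xi_nu> = 2 delta_mu,nu
delta(t - t'), so the discrete polarity update gains sigma*sqrt(2*dt) per
standard normal -- note the factor 2, which makes the stationary polarity
variance sigma^2 tau per component and the RMS speed of an isolated cell
sqrt(2) sigma sqrt(tau).

Simulation units: 1 length unit = 20 um (one cell diameter), 1 time unit
= 20 min (the polarity relaxation time tau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import lfilter
from scipy.special import k1

from .chemo_signal import LegiRates, LegiState, SignalField, signal_at
from .coattraction import CoattractionParams
from .mechanics import DEFAULT_D0, ContactGraph, DegenerateOverlapError

__all__ = [
    "ModelParams",
    "SimulationState",
    "TrajectoryRecord",
    "init_hexagonal_cluster",
    "polarity_rate",
    "step",
    "run_trajectory",
    "run_ensemble",
    "UNIT_LENGTH_UM",
    "UNIT_TIME_MIN",
]

UNIT_LENGTH_UM = 20.0
UNIT_TIME_MIN = 20.0
#: Speed conversion: 1 sim unit of speed = 20 um / 20 min = 1 um/min.
UNIT_SPEED_UM_PER_MIN = UNIT_LENGTH_UM / UNIT_TIME_MIN


class InstabilityError(RuntimeError):
    """The explicit integrator produced a non-finite state; reduce dt."""


@dataclass
class ModelParams:
    """All rate/strength constants of the cluster model plus integration controls.

    Force strengths default to the strongly adherent ("rigid") choice
    v_r = v_a = 500 with dt = 1e-4; co-attraction studies use
    v_a = 0, v_r = 100 with dt = 1e-3 (see :meth:`loose`).
    """

    tau: float = 1.0
    sigma: float = 1.0
    beta_bar: float = 20.0
    v_r: float = 500.0
    v_a: float = 500.0
    D0: float = DEFAULT_D0
    coattraction: CoattractionParams = field(default_factory=CoattractionParams)
    legi: LegiRates | None = None
    response_mode: Literal["minimal", "legi_linear", "legi_switch"] = "minimal"
    lam: float = 1e-2
    legi_kinetics: Literal["quasi_static", "full"] = "quasi_static"
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.D0 <= 1.0:
            raise ValueError("D0 must exceed the equilibrium separation of 1")
        if self.response_mode != "minimal" and self.legi is None:
            raise ValueError(f"response mode {self.response_mode!r} requires LEGI rates")
        if self.dt * max(self.v_r, self.v_a) > 0.5:
            warnings.warn(
                "dt * spring strength > 0.5: explicit stepping of the cell-cell "
                "springs may be unstable; reduce dt",
                stacklevel=2,
            )

    @classmethod
    def loose(cls, **kw) -> "ModelParams":
        """Co-attraction defaults: no short-range adhesion, softer repulsion."""
        kw.setdefault("v_r", 100.0)
        kw.setdefault("v_a", 0.0)
        kw.setdefault("dt", 1e-3)
        return cls(**kw)


@dataclass
class SimulationState:
    """Instantaneous state of all cells plus the trajectory's RNG stream."""

    t: float
    positions: np.ndarray
    polarities: np.ndarray
    rng: np.random.Generator
    legi: LegiState | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.polarities = np.asarray(self.polarities, dtype=float)
        if self.positions.shape != self.polarities.shape:
            raise ValueError("positions and polarities must have matching shapes")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]


@dataclass
class TrajectoryRecord:
    """Snapshots of a single simulated trajectory at fixed cadence."""

    times: np.ndarray
    positions: np.ndarray  # (frames, N, 2)
    polarities: np.ndarray  # (frames, N, 2)
    seed: int | tuple
    params: ModelParams
    R: np.ndarray | None = None  # (frames, N) LEGI readout, if present

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=1)

    def to_dataframe(self):
        """Long-format (t, cell_id, x, y, px, py[, R]) table."""
        import pandas as pd

        frames, n, _ = self.positions.shape
        t = np.repeat(self.times, n)
        cid = np.tile(np.arange(n), frames)
        data = {
            "t": t,
            "cell_id": cid,
            "x": self.positions[:, :, 0].ravel(),
            "y": self.positions[:, :, 1].ravel(),
            "px": self.polarities[:, :, 0].ravel(),
            "py": self.polarities[:, :, 1].ravel(),
        }
        if self.R is not None:
            data["R"] = self.R.ravel()
        return pd.DataFrame(data)

    def save(self, prefix) -> None:
        """Write the record as ``<prefix>.csv`` plus a ``<prefix>.json``
        sidecar holding the parameters, seed and unit conventions."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        prefix = Path(prefix)
        self.to_dataframe().to_csv(prefix.with_suffix(".csv"), index=False)
        sidecar = {
            "seed": self.seed,
            "params": asdict(self.params),
            "units": {"length_um": UNIT_LENGTH_UM, "time_min": UNIT_TIME_MIN},
        }
        prefix.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, default=float) + "\n"
        )


# closed-shell hexagonal cluster sizes: 1 + 3k(k+1)
CLOSED_SHELL_SIZES = (1, 7, 19, 37, 61, 91, 127)


def init_hexagonal_cluster(
    N: int, rng: np.random.Generator | int | None = None, rotate: bool = True
) -> np.ndarray:
    """Unit-spacing triangular-lattice cluster of N cells, centroid at origin.

    Sites are chosen closest-first from the lattice center, which yields
    closed hexagonal shells at N in {1, 7, 19, 37, 61, 91, 127}.  The whole
    cluster is rotated by a uniform random angle unless ``rotate=False``.
    """
    if N < 1:
        raise ValueError("cluster must contain at least one cell")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rmax = int(np.ceil(np.sqrt(N))) + 2
    a1 = np.array([1.0, 0.0])
    a2 = np.array([0.5, np.sqrt(3.0) / 2.0])
    ii, jj = np.meshgrid(np.arange(-rmax, rmax + 1), np.arange(-rmax, rmax + 1))
    sites = ii.ravel()[:, None] * a1 + jj.ravel()[:, None] * a2
    d = np.linalg.norm(sites, axis=1)
    ang = np.arctan2(sites[:, 1], sites[:, 0])
    order = np.lexsort((ang, np.round(d, 9)))  # deterministic shell-by-shell order
    pos = sites[order[:N]].copy()
    pos -= pos.mean(axis=0)
    if rotate:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        pos = pos @ np.array([[c, s], [-s, c]])
    return pos


_TRIU_CACHE: dict[int, tuple] = {}


def _triu_cache(n: int):
    """Cached upper-triangle index pairs (iu, il) for symmetric kernels."""
    if n not in _TRIU_CACHE:
        iu = np.triu_indices(n, 1)
        _TRIU_CACHE[n] = (iu, (iu[1], iu[0]))
    return _TRIU_CACHE[n]


def _interaction_terms(pos: np.ndarray, params: ModelParams):
    """Pairwise forces, contact adjacency/degree, CIL bias q and grad c.

    One fused distance computation per step; grad c is None when
    co-attraction is off.
    """
    n = pos.shape[0]
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    idx = np.arange(n)
    # finite sentinel on the diagonal: beyond every interaction range and
    # deep in the Bessel kernel's underflow region, so it contributes 0
    dist[idx, idx] = 1e9
    if np.any(dist <= 0.0):
        raise DegenerateOverlapError("coincident cells during integration")
    adj = dist < params.D0
    degree = adj.sum(axis=1)
    with_coat = params.coattraction.chi > 0
    coef = np.empty((3 if with_coat else 2, n, n))
    coef[0] = np.where(
        dist < 1.0,
        params.v_r * (1.0 - dist),
        np.where(adj, -params.v_a * (dist - 1.0) / (params.D0 - 1.0), 0.0),
    )
    coef[1] = adj
    if with_coat:
        iu, il = _triu_cache(n)
        kern = np.zeros_like(dist)
        kv = -k1(dist[iu] / params.coattraction.ell)
        kern[iu] = kv
        kern[il] = kv
        coef[2] = kern
    rhat = diff
    rhat /= dist[:, :, None]
    out = np.einsum("cij,ijk->cik", coef, rhat)
    forces, q = out[0], out[1]
    grad_c = out[2] if with_coat else None
    return forces, adj, degree, q, grad_c


def _beta_values(
    state: SimulationState, params: ModelParams, fieldspec: SignalField
) -> np.ndarray:
    """Per-cell CIL susceptibility under the configured response mode."""
    from .chemo_signal import susceptibility_from_response, susceptibility_minimal

    S = np.atleast_1d(signal_at(fieldspec, state.positions, state.t))
    if params.response_mode == "minimal":
        return np.asarray(susceptibility_minimal(S, params.beta_bar))
    if state.legi is None:
        raise ValueError("LEGI response mode requires a LEGI state")
    mode = "linear" if params.response_mode == "legi_linear" else "switch"
    return np.atleast_1d(
        susceptibility_from_response(
            state.legi.R, params.legi, params.beta_bar, mode, params.lam
        )
    )


def polarity_rate(
    state: SimulationState,
    params: ModelParams,
    fieldspec: SignalField,
    graph: ContactGraph | None = None,
) -> np.ndarray:
    """Deterministic part of the polarity dynamics, -p/tau + beta q + chemotaxis."""
    from .coattraction import chemotaxis_bias
    from .mechanics import cil_bias_vectors, contact_graph

    if graph is None:
        graph = contact_graph(state.positions, params.D0)
    q = cil_bias_vectors(state.positions, graph)
    beta = _beta_values(state, params, fieldspec)
    rate = -state.polarities / params.tau + beta[:, None] * q
    ca = params.coattraction
    if ca.chi > 0 and state.n_cells > 1:
        from .coattraction import coattract_gradient

        grad = coattract_gradient(state.positions, ell=ca.ell)
        rate = rate + chemotaxis_bias(grad, ca.chi, ca.g0)
    return rate


def _init_legi_state(
    pos: np.ndarray, params: ModelParams, fieldspec: SignalField, t: float
) -> LegiState | None:
    """Inhibitor starts at the uniform steady state for the initial mean signal."""
    if params.legi is None:
        return None
    rates = params.legi
    S = np.atleast_1d(signal_at(fieldspec, pos, t))
    if rates.k_mI <= 0:
        raise ValueError("k_mI must be positive to initialize the inhibitor")
    I = np.full(pos.shape[0], (rates.kI / rates.k_mI) * S.mean())
    A = (rates.kA / rates.k_mA) * S
    R = rates.kR * A / (rates.kR * A + rates.k_mR * I)
    return LegiState(A=A, I=I, R=R)


def _advance_legi(
    legi: LegiState,
    S: np.ndarray,
    adj: np.ndarray,
    degree: np.ndarray,
    params: ModelParams,
) -> LegiState:
    """One explicit Euler step of the LEGI kinetics.

    Quasi-static mode integrates only the inhibitor; the activator is
    enslaved to its steady state and the readout to the exact fixed point
    of its kinetics.  Full mode integrates all three species.
    """
    rates = params.legi
    dt = params.dt
    adjf = adj.astype(float)
    exchange = -rates.kD * degree * legi.I + rates.kD * (adjf @ legi.I)
    I = legi.I + dt * (rates.kI * S - rates.k_mI * legi.I + exchange)
    if params.legi_kinetics == "quasi_static":
        A = (rates.kA / rates.k_mA) * S
        R = rates.kR * A / (rates.kR * A + rates.k_mR * I)
    else:
        A = legi.A + dt * (rates.kA * S - rates.k_mA * legi.A)
        R = legi.R + dt * (rates.kR * legi.A * (1.0 - legi.R) - rates.k_mR * legi.I * legi.R)
    return LegiState(A=A, I=np.maximum(I, 0.0), R=R)


def step(
    state: SimulationState, params: ModelParams, fieldspec: SignalField
) -> SimulationState:
    """One Euler--Maruyama step of the full coupled model.

    Positions advance with the pre-step polarity plus forces; the polarity
    gains the deterministic rate times dt plus sigma*sqrt(2*dt) per
    standard normal component; LEGI species advance per the configured
    kinetics mode; the contact graph is recomputed from the pre-step
    positions.
    """
    pos, p = state.positions, state.polarities
    dt = params.dt
    forces, adj, degree, q, grad_c = _interaction_terms(pos, params)
    S = np.atleast_1d(signal_at(fieldspec, pos, state.t))
    if params.response_mode == "minimal":
        beta = params.beta_bar * S
    else:
        mode = "linear" if params.response_mode == "legi_linear" else "switch"
        from .chemo_signal import susceptibility_from_response

        beta = np.atleast_1d(
            susceptibility_from_response(
                state.legi.R, params.legi, params.beta_bar, mode, params.lam
            )
        )
    rate = -p / params.tau + beta[:, None] * q
    ca = params.coattraction
    if grad_c is not None:
        gmag = np.sqrt(np.einsum("ik,ik->i", grad_c, grad_c))
        active = gmag > ca.g0
        if np.any(active):
            rate[active] += ca.chi * grad_c[active] / gmag[active, None]
    noise = params.sigma * np.sqrt(2.0 * dt) * state.rng.standard_normal(p.shape)
    new_p = p + dt * rate + noise
    new_pos = pos + dt * (p + forces)
    new_legi = None
    if state.legi is not None:
        new_legi = _advance_legi(state.legi, S, adj, degree, params)
    if not (np.all(np.isfinite(new_pos)) and np.all(np.isfinite(new_p))):
        raise InstabilityError("non-finite state after step; reduce dt")
    return SimulationState(
        t=state.t + dt, positions=new_pos, polarities=new_p, rng=state.rng, legi=new_legi
    )


def _run_single_cell(
    params: ModelParams,
    fieldspec: SignalField,
    T: float,
    rng: np.random.Generator,
    pos0: np.ndarray,
    seed,
    snap_every: int,
    n_steps: int,
) -> TrajectoryRecord:
    """Exact vectorized specialization of the stepper for an isolated cell.

    With no neighbors the forces, CIL bias and co-attractant gradient all
    vanish identically, leaving the linear recursion
    p_{k+1} = (1 - dt/tau) p_k + sigma*sqrt(2*dt) eta_k, which is evaluated
    with a linear filter.  The RNG stream is consumed in the same order as
    the generic stepper, so results match it bit-for-bit draw-for-draw.
    """
    dt = params.dt
    a = 1.0 - dt / params.tau
    c = params.sigma * np.sqrt(2.0 * dt)
    frames = n_steps // snap_every + 1
    times = np.arange(frames) * (snap_every * dt)
    rec_pos = np.empty((frames, 1, 2))
    rec_pol = np.empty((frames, 1, 2))
    p = np.zeros(2)
    r = pos0[0].astype(float).copy()
    rec_pos[0, 0] = r
    rec_pol[0, 0] = p
    chunk = 1 << 18
    done = 0
    fidx = 1
    while done < n_steps:
        m = min(chunk, n_steps - done)
        eta = rng.standard_normal((m, 2))
        # p-series within the chunk: p_hist[k] is p after k steps of the chunk
        p_hist = np.empty((m + 1, 2))
        p_hist[0] = p
        for axis in range(2):
            zi = np.array([a * p[axis]])
            p_hist[1:, axis], _ = lfilter([c], [1.0, -a], eta[:, axis], zi=zi)
        # positions advance with the pre-step polarity
        r_hist = r + dt * np.cumsum(p_hist[:-1], axis=0)
        ks = np.arange(done + 1, done + m + 1)
        sel = np.flatnonzero(ks % snap_every == 0)
        if sel.size:
            rec_pos[fidx : fidx + sel.size, 0] = r_hist[sel]
            rec_pol[fidx : fidx + sel.size, 0] = p_hist[sel + 1]
            fidx += sel.size
        p = p_hist[-1]
        r = r_hist[-1]
        done += m
    return TrajectoryRecord(
        times=times, positions=rec_pos, polarities=rec_pol, seed=seed, params=params
    )


def run_trajectory(
    params: ModelParams,
    fieldspec: SignalField,
    N: int,
    T: float,
    seed,
    snapshot_dt: float = 0.1,
    initial_positions: np.ndarray | None = None,
    initial_polarities: np.ndarray | None = None,
) -> TrajectoryRecord:
    """Simulate one trajectory and record snapshots at fixed cadence.

    Deterministic function of (params, N, T, seed).  The initial cluster is
    a hexagonal-lattice packing at a uniform random orientation, polarities
    start at zero, and the LEGI inhibitor starts at the uniform steady
    state for the initial mean signal.
    """
    if T <= 0:
        raise ValueError("duration T must be positive")
    rng = np.random.default_rng(seed)
    if initial_positions is None:
        pos = init_hexagonal_cluster(N, rng)
    else:
        pos = np.array(initial_positions, dtype=float)
        if pos.shape[0] != N:
            raise ValueError("initial_positions does not match N")
    p = (
        np.zeros_like(pos)
        if initial_polarities is None
        else np.array(initial_polarities, dtype=float)
    )
    dt = params.dt
    n_steps = int(round(T / dt))
    snap_every = max(1, int(round(snapshot_dt / dt)))

    if (
        N == 1
        and params.legi is None
        and initial_polarities is None
        and n_steps % snap_every == 0
    ):
        return _run_single_cell(params, fieldspec, T, rng, pos, seed, snap_every, n_steps)

    state = SimulationState(
        t=0.0,
        positions=pos,
        polarities=p,
        rng=rng,
        legi=_init_legi_state(pos, params, fieldspec, 0.0),
    )
    frames = n_steps // snap_every + 1
    rec_t = np.empty(frames)
    rec_pos = np.empty((frames, N, 2))
    rec_pol = np.empty((frames, N, 2))
    rec_R = np.empty((frames, N)) if state.legi is not None else None
    fidx = 0

    def record(st: SimulationState):
        nonlocal fidx
        rec_t[fidx] = st.t
        rec_pos[fidx] = st.positions
        rec_pol[fidx] = st.polarities
        if rec_R is not None:
            rec_R[fidx] = st.legi.R
        fidx += 1

    record(state)
    for k in range(1, n_steps + 1):
        state = step(state, params, fieldspec)
        if k % snap_every == 0:
            record(state)
    return TrajectoryRecord(
        times=rec_t[:fidx],
        positions=rec_pos[:fidx],
        polarities=rec_pol[:fidx],
        seed=seed,
        params=params,
        R=rec_R[:fidx] if rec_R is not None else None,
    )


def run_ensemble(
    params: ModelParams,
    fieldspec: SignalField,
    N: int,
    T: float,
    n_traj: int,
    master_seed: int,
    snapshot_dt: float = 0.1,
) -> list[TrajectoryRecord]:
    """Independent trajectories, one RNG stream per trajectory.

    Stream k is seeded from the pair (master_seed, k), so ensembles are
    reproducible and extensible without re-running earlier members.
    """
    return [
        run_trajectory(params, fieldspec, N, T, seed=[master_seed, k], snapshot_dt=snapshot_dt)
        for k in range(n_traj)
    ]
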