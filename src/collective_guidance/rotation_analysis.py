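"""Reduced rotation model, pitchfork fit, and pair-scattering theory.

A tightly packed, co-attraction-bound cluster can rotate persistently.
In a rigid circular cluster with purely radial polarity biases Gamma_i,
projecting the polarity dynamics on the collective rotation angle theta
gives two coupled ODEs for the angular velocity Omega = d(theta)/dt and
the radial polarity moment W:

    dW/dt = Omega^2 - W/tau + W0/tau
    dOmega/dt = -(1/tau + W) Omega

where W0 = mu_theta tau sum_i R_i Gamma_i collects the net radial bias
(negative when co-attraction polarizes cells inward).  For W0 tau > -1 the
only steady state is the non-rotating one; at W0 tau = -1 it loses
stability in a pitchfork bifurcation to a mirror pair of rotating states
Omega = +/- (1/tau) sqrt(-1 - W0 tau).  In the full model the inward bias
is supplied by the co-attraction strength chi, so the cluster's angular
velocity follows

    |Omega|(chi) = 0                         chi <= chi_c
                 = Omega_0 sqrt(chi - chi_c) chi >  chi_c

whose parameters (Omega_0, chi_c) are extracted by least squares from
sweep data.  The pair-scattering results quantify how a colliding pair of
cells with graded CIL susceptibilities beta_i, beta_j exchanges polarity:
the relative polarity reverses almost elastically while the total polarity
gains a term set by the *relative* difference (beta_i - beta_j)/(beta_i +
beta_j) -- which is why graded CIL adapts to the overall signal level even
without a dedicated adaptation circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .chemo_signal import SignalField
from .dynamics import ModelParams, SimulationState, step

__all__ = [
    "ReducedModelParams",
    "PitchforkFit",
    "reduced_steady_states",
    "integrate_reduced",
    "fit_pitchfork",
    "pair_scattering_theory",
    "pair_scattering_numeric",
]


@dataclass
class ReducedModelParams:
    """Parameters of the reduced rotation model: relaxation time and net radial bias."""

    tau: float = 1.0
    W0: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class PitchforkFit:
    """Square-root pitchfork fit |Omega|(chi) = Omega0 sqrt(chi - chi_c)."""

    Omega0: float
    chi_c: float
    residual: float
    n_points: int

    def __call__(self, chi):
        chi = np.asarray(chi, dtype=float)
        out = self.Omega0 * np.sqrt(np.maximum(chi - self.chi_c, 0.0))
        return float(out) if out.ndim == 0 else out


def reduced_steady_states(params: ReducedModelParams):
    """Steady states (Omega, W, stable) of the reduced rotation ODEs.

    Always contains the non-rotating state (0, W0), stable iff
    W0 tau > -1; below the bifurcation the mirror pair of rotating states
    Omega = +/- (1/tau) sqrt(-1 - W0 tau), W = -1/tau appears, both stable.
    """
    tau, W0 = params.tau, params.W0
    states = [(0.0, W0, W0 * tau > -1.0)]
    if W0 * tau < -1.0:
        om = np.sqrt(-1.0 - W0 * tau) / tau
        states.append((om, -1.0 / tau, True))
        states.append((-om, -1.0 / tau, True))
    return states


def integrate_reduced(
    params: ReducedModelParams,
    W_init: float,
    Omega_init: float,
    T: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Integrate the reduced (W, Omega) ODEs; returns (t, W(t), Omega(t))."""
    if T <= 0:
        raise ValueError("T must be positive")
    tau, W0 = params.tau, params.W0

    def rhs(_t, y):
        W, Om = y
        return [Om * Om - W / tau + W0 / tau, -(1.0 / tau + W) * Om]

    sol = solve_ivp(
        rhs, (0.0, T), [W_init, Omega_init], method="LSODA",
        rtol=rtol, atol=atol, dense_output=True,
    )
    return sol.t, sol.y[0], sol.y[1]


def _pitchfork_residual(chi, omega, chi_c):
    """Best Omega0 for fixed chi_c (linear in Omega0) and the residual norm."""
    f = np.sqrt(np.maximum(chi - chi_c, 0.0))
    denom = np.dot(f, f)
    omega0 = max(np.dot(f, omega) / denom, 0.0) if denom > 0 else 0.0
    r = omega - omega0 * f
    return omega0, float(np.dot(r, r))


def fit_pitchfork(
    chi_values, omega_means, zero_tol: float = 1e-12, n_starts: int = 200
) -> PitchforkFit:
    """Least-squares fit of branch-averaged |Omega| data to the pitchfork form.

    Joint fit over (Omega0, chi_c): for each chi_c the optimal Omega0 is a
    linear projection, and chi_c is located by a deterministic fine-grid
    multi-start (the objective is non-smooth at the data points) followed
    by bounded local refinement.  Ties break toward the smallest residual,
    then the smallest chi_c.
    """
    chi = np.asarray(chi_values, dtype=float)
    omega = np.abs(np.asarray(omega_means, dtype=float))
    if chi.ndim != 1 or chi.shape != omega.shape:
        raise ValueError("chi and omega arrays must be 1-D and matching")
    if chi.size < 3:
        raise ValueError("need at least three chi values")
    if np.any(np.diff(chi) <= 0):
        raise ValueError("chi values must be strictly increasing")
    if np.all(omega <= zero_tol):
        raise ValueError(
            "all angular velocities are ~0: chi_c is not identifiable "
            f"(lower bound {chi[-1]})"
        )
    lo, hi = chi[0] - (chi[-1] - chi[0]), chi[-1] - 1e-9
    grid = np.linspace(lo, hi, n_starts)
    best = None
    for cc in grid:
        om0, res = _pitchfork_residual(chi, omega, cc)
        key = (res, cc)
        if best is None or key < best[0]:
            best = (key, om0, cc)
    (_, _), om0, cc = best
    # local refinement around the best grid point
    span = (hi - lo) / (n_starts - 1)
    try:
        opt = minimize_scalar(
            lambda c: _pitchfork_residual(chi, omega, c)[1],
            bounds=(cc - 2 * span, min(cc + 2 * span, hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if opt.fun <= _pitchfork_residual(chi, omega, cc)[1]:
            cc = float(opt.x)
    except ValueError:
        pass
    om0, res = _pitchfork_residual(chi, omega, cc)
    return PitchforkFit(Omega0=om0, chi_c=float(cc), residual=res, n_points=chi.size)


def pair_scattering_theory(
    delta0: float, sigma0: float, beta_i: float, beta_j: float
) -> tuple[float, float]:
    """Outgoing polarity projections after a strongly CIL-driven pair collision.

    With Delta = p_i - p_j and Sigma = p_i + p_j projected on the contact
    axis rhat_ij, the collision is almost elastic in the relative channel
    and shifts the total channel by the relative susceptibility contrast:

        Delta_out = -Delta_in
        Sigma_out = Sigma_in - 2 Delta_in (beta_i - beta_j)/(beta_i + beta_j)
    """
    if beta_i + beta_j <= 0:
        raise ValueError("scattering requires beta_i + beta_j > 0")
    delta_out = -delta0
    sigma_out = sigma0 - 2.0 * delta0 * (beta_i - beta_j) / (beta_i + beta_j)
    return delta_out, sigma_out


def pair_scattering_shallow(delta0: float, sigma0: float, S1: float, D0: float) -> float:
    """Shallow-exponential-gradient limit of the total-polarity shift.

    For beta_i = beta_bar S0 exp(S1 x_i) with S1 D0 << 1 the susceptibility
    contrast is S1 D0 / 2 regardless of S0, giving
    Sigma_out = Sigma_in - Delta_in * S1 * D0.
    """
    return sigma0 - delta0 * S1 * D0


def pair_scattering_numeric(
    p_i0,
    p_j0,
    beta_bar: float,
    fieldspec: SignalField,
    params: ModelParams | None = None,
    d_init: float | None = None,
    T_max: float = 50.0,
) -> dict:
    """Deterministic two-cell collision; projections at the separation time.

    Two cells are placed on the x axis at separation ``d_init`` (default:
    just inside the interaction range D0, i.e. the moment contact begins)
    with the given initial polarities, and integrated with sigma = 0 until
    their distance exceeds D0.  Returns the incoming and outgoing
    Delta.rhat and Sigma.rhat plus the separation time t*.
    """
    if params is None:
        params = ModelParams.loose(beta_bar=beta_bar, dt=1e-5)
    else:
        params = replace(params, beta_bar=beta_bar)
    params = replace(params, sigma=0.0)
    if d_init is None:
        d_init = params.D0 * (1.0 - 1e-9)
    if d_init >= params.D0:
        raise ValueError("cells must start within the interaction range D0")
    pos = np.array([[d_init / 2.0, 0.0], [-d_init / 2.0, 0.0]])
    pol = np.array([np.asarray(p_i0, float), np.asarray(p_j0, float)])
    rhat0 = (pos[0] - pos[1]) / np.linalg.norm(pos[0] - pos[1])
    delta_in = float((pol[0] - pol[1]) @ rhat0)
    sigma_in = float((pol[0] + pol[1]) @ rhat0)
    state = SimulationState(
        t=0.0, positions=pos, polarities=pol, rng=np.random.default_rng(0)
    )
    n_max = int(round(T_max / params.dt))
    for _ in range(n_max):
        state = step(state, params, fieldspec)
        sep = np.linalg.norm(state.positions[0] - state.positions[1])
        if sep > params.D0:
            rhat = (state.positions[0] - state.positions[1]) / sep
            p = state.polarities
            return {
                "delta_in": delta_in,
                "sigma_in": sigma_in,
                "delta_out": float((p[0] - p[1]) @ rhat),
                "sigma_out": float((p[0] + p[1]) @ rhat),
                "t_star": state.t,
            }
    raise RuntimeError(f"cells did not separate within T_max = {T_max}")


def rotation_sweep(
    chi_values,
    N: int = 37,
    beta_bar: float = 35.0,
    n_traj: int = 10,
    T: float = 25.0,
    master_seed: int = 0,
    window: tuple[float, float] | None = None,
    snapshot_dt: float = 0.05,
    fieldspec: SignalField | None = None,
    ell: float = 5.0,
    dt: float = 1e-3,
    progress: bool = False,
):
    """Sweep the co-attraction strength and measure each trajectory's rotation.

    For every chi, ``n_traj`` independent loose-cluster trajectories
    (v_a = 0, v_r = 100) are simulated for time T and their window-averaged
    velocity and signed angular velocity recorded.  Returns a tidy
    DataFrame with one row per (chi, trajectory).
    """
    import pandas as pd

    from .coattraction import CoattractionParams
    from .dynamics import run_trajectory
    from .observables import angular_speed, cluster_velocity

    if fieldspec is None:
        fieldspec = SignalField(kind="uniform", S0=1.0)
    if window is None:
        window = (T / 2.0, T)
    rows = []
    for ci, chi in enumerate(chi_values):
        params = ModelParams.loose(
            beta_bar=beta_bar,
            coattraction=CoattractionParams(chi=float(chi), ell=ell),
            dt=dt,
        )
        for k in range(n_traj):
            seed = [int(master_seed), ci, k]
            traj = run_trajectory(
                params, fieldspec, N, T, seed=seed, snapshot_dt=snapshot_dt
            )
            v = cluster_velocity(traj, window)
            om, _ = angular_speed(traj, window)
            rows.append(
                {
                    "chi": float(chi),
                    "beta_bar": float(beta_bar),
                    "N": N,
                    "traj": k,
                    "seed": "-".join(map(str, seed)),
                    "Vx": v[0],
                    "Vy": v[1],
                    "speed": float(np.linalg.norm(v)),
                    "omega": om,
                }
            )
            if progress:
                print(f"chi={chi:g} traj={k} omega={om:+.3f}", flush=True)
    return pd.DataFrame(rows)


def branch_averaged_omega(sweep_table):
    """Per-chi branch-averaged angular speed from a rotation sweep table.

    Trajectories are split by the sign of their mean angular velocity; the
    two branch means are magnitude-averaged with their trajectory counts,
    which equals the per-chi mean of |Omega|.  Returns (chi, omega_mean)
    arrays sorted by chi, plus the per-branch means as a DataFrame.
    """
    import pandas as pd

    df = sweep_table
    out = []
    for chi, grp in df.groupby("chi"):
        om = grp["omega"].to_numpy()
        pos, neg = om[om > 0], om[om < 0]
        n_pos, n_neg = pos.size, neg.size
        m_pos = pos.mean() if n_pos else np.nan
        m_neg = neg.mean() if n_neg else np.nan
        pooled = np.abs(om).mean()
        out.append(
            {
                "chi": chi,
                "omega_mean": pooled,
                "omega_pos_branch": m_pos,
                "omega_neg_branch": m_neg,
                "n_pos": n_pos,
                "n_neg": n_neg,
            }
        )
    table = pd.DataFrame(out).sort_values("chi").reset_index(drop=True)
    return table["chi"].to_numpy(), table["omega_mean"].to_numpy(), table


def pitchfork_protocol(
    master_seed: int = 0,
    chi_values=(5.0, 20.0, 35.0, 50.0, 65.0, 80.0, 95.0),
    N: int = 37,
    beta_bar: float = 35.0,
    n_traj: int = 10,
    T: float = 25.0,
    progress: bool = False,
):
    """Scaled-down rotation-bifurcation protocol: sweep, branch-average, fit.

    Sweeps the co-attraction strength with no external signal gradient,
    branch-averages each chi's trajectory angular velocities, and fits the
    square-root pitchfork.  Returns (fit, sweep_table).
    """
    df = rotation_sweep(
        chi_values, N=N, beta_bar=beta_bar, n_traj=n_traj, T=T,
        master_seed=master_seed, progress=progress,
    )
    chi, omega_mean, _ = branch_averaged_omega(df)
    return fit_pitchfork(chi, omega_mean), df
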