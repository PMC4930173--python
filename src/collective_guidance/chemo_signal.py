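"""External chemoattractant signal and its intracellular processing.

The external signal S(r, t) regulates each cell's susceptibility to
contact inhibition of locomotion, beta_i.  Three response modes:

* ``minimal``      -- beta_i = beta_bar * S(r_i): direct transduction.
* ``legi_linear``  -- beta_i = beta_bar * R_i / R0, with R the readout of a
  local-excitation / global-inhibition (LEGI) network.
* ``legi_switch``  -- beta_i = beta_bar * g(R_i / R0), a switchlike
  amplification g(x) = (1/2)[1 + tanh((x - 1)/lambda)].

In the LEGI network the signal produces a cell-local activator A and an
inhibitor I that is exchanged between contacting cells at rate kD
(e.g. through gap junctions); A up- and I down-regulate the readout R.
Because A tracks the local signal while I tends toward the cluster
average, R develops a profile proportional to the *relative* signal
variation across the cluster, and adapts perfectly to uniform signals:

    dA_i/dt = kA S_i - k_mA A_i
    dI_i/dt = kI S_i - k_mI I_i - kD n_i I_i + kD sum_{j~i} I_j
    dR_i/dt = kR A_i (1 - R_i) - k_mR I_i R_i

The ratio alpha = k_mI / kD controls sensing quality: for alpha << 1/N the
inhibitor equilibrates over the cluster and R_i -> R0 S_i / S_bar (ideal
collective sensing); at larger alpha the R profile flattens in big
clusters, which is what makes cluster speed non-monotonic in size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .mechanics import ContactGraph

__all__ = [
    "SignalField",
    "LegiRates",
    "LegiState",
    "signal_at",
    "susceptibility_minimal",
    "legi_rhs",
    "legi_steady_state",
    "amplification_g",
    "susceptibility_from_response",
]


@dataclass
class SignalField:
    """External signal S(r, t).

    kinds: ``uniform`` S0; ``linear`` S0 + S1*(axis . r); ``exponential``
    S0*exp(S1*(axis . r)); ``step_in_time`` uniform S_before until
    ``step_time``, then S_after.
    """

    kind: Literal["uniform", "linear", "exponential", "step_in_time"] = "uniform"
    S0: float = 1.0
    S1: float = 0.0
    axis: tuple[float, float] = (1.0, 0.0)
    step_time: float = 0.0
    S_before: float = 1.0
    S_after: float = 2.0

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(ax)
        if norm == 0:
            raise ValueError("gradient axis must be a nonzero vector")
        self.axis = tuple(ax / norm)
        if self.kind in ("uniform", "linear", "exponential") and self.S0 <= 0:
            raise ValueError("S0 must be positive")

    def __call__(self, r: np.ndarray, t: float = 0.0):
        return signal_at(self, r, t)


def signal_at(fieldspec: SignalField, r: np.ndarray, t: float = 0.0):
    """Evaluate S at positions ``r`` ((..., 2) array) and time ``t``."""
    r = np.asarray(r, dtype=float)
    x = r @ np.asarray(fieldspec.axis)
    if fieldspec.kind == "uniform":
        out = np.full_like(x, fieldspec.S0, dtype=float)
    elif fieldspec.kind == "linear":
        out = fieldspec.S0 + fieldspec.S1 * x
        if np.any(out <= 0):
            raise ValueError("linear signal non-positive at a sampled point")
    elif fieldspec.kind == "exponential":
        out = fieldspec.S0 * np.exp(fieldspec.S1 * x)
    elif fieldspec.kind == "step_in_time":
        level = fieldspec.S_before if t < fieldspec.step_time else fieldspec.S_after
        out = np.full_like(x, level, dtype=float)
    else:  # pragma: no cover - guarded by dataclass typing
        raise ValueError(f"unknown signal kind {fieldspec.kind!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class LegiRates:
    """First-order rate constants of the LEGI network, in units of 1/tau.

    Defaults: kI = k_mI = 1 and kD = 4 (so alpha = 0.25, the
    gap-junction-plausible value); kA = k_mA = 1 (only their ratio matters
    at steady state); kR/k_mR = 1e-3 so that the readout steady state is
    well approximated by (kR/k_mR) A/I.
    """

    kA: float = 1.0
    k_mA: float = 1.0
    kI: float = 1.0
    k_mI: float = 1.0
    kR: float = 1e-3
    k_mR: float = 1.0
    kD: float = 4.0

    def __post_init__(self) -> None:
        for name in ("kA", "k_mA", "kI", "k_mI", "kR", "k_mR", "kD"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def alpha(self) -> float:
        """Inhibitor degradation / intercellular transfer ratio k_mI/kD."""
        if self.kD == 0:
            return np.inf
        return self.k_mI / self.kD

    @property
    def R0(self) -> float:
        """Scale of the readout, (kR/k_mR)(kA/k_mA)(k_mI/kI)."""
        return (self.kR / self.k_mR) * (self.kA / self.k_mA) * (self.k_mI / self.kI)


@dataclass
class LegiState:
    """Per-cell concentrations of activator A, inhibitor I and readout R."""

    A: np.ndarray
    I: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if not (self.A.shape == self.I.shape == self.R.shape):
            raise ValueError("A, I, R must have matching shapes")
        if np.any(self.A < 0) or np.any(self.I < 0) or np.any(self.R < 0):
            raise ValueError("concentrations must be non-negative")


def susceptibility_minimal(S, beta_bar: float):
    """Minimal response: beta = beta_bar * S, elementwise."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("signal must be non-negative")
    out = beta_bar * S
    return float(out) if out.ndim == 0 else out


def legi_rhs(state: LegiState, S_i: np.ndarray, graph: ContactGraph, rates: LegiRates):
    """Time derivatives (dA, dI, dR) of the LEGI network on the contact graph.

    The exchange terms -kD n_i I_i + kD sum_{j~i} I_j are -kD (L I)_i with
    L the graph Laplacian, so total inhibitor is conserved by exchange.
    """
    A, I, R = state.A, state.I, state.R
    S_i = np.asarray(S_i, dtype=float)
    if graph.n_cells != A.shape[0]:
        raise ValueError("graph does not match state size")
    adj = graph.adj.astype(float)
    dA = rates.kA * S_i - rates.k_mA * A
    dI = rates.kI * S_i - rates.k_mI * I - rates.kD * graph.degree * I + rates.kD * (adj @ I)
    dR = rates.kR * A * (1.0 - R) - rates.k_mR * I * R
    return dA, dI, dR


def legi_steady_state(
    S_i: np.ndarray, graph: ContactGraph, rates: LegiRates
) -> LegiState:
    """Exact steady state of the LEGI network for fixed signal and contacts.

    A_i = (kA/k_mA) S_i; the inhibitor solves the symmetric positive
    definite linear system (k_mI Id + kD L) I = kI S; the readout is the
    exact fixed point R_i = kR A_i / (kR A_i + k_mR I_i), which reduces to
    (kR/k_mR) A_i/I_i when k_mR >> kR.
    """
    S_i = np.atleast_1d(np.asarray(S_i, dtype=float))
    n = S_i.shape[0]
    if graph.n_cells != n:
        raise ValueError("graph does not match signal size")
    if rates.k_mA <= 0:
        raise ValueError("k_mA must be positive for a steady state")
    A = (rates.kA / rates.k_mA) * S_i
    M = rates.k_mI * np.eye(n) + rates.kD * graph.laplacian()
    try:
        I = np.linalg.solve(M, rates.kI * S_i)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular inhibitor system (k_mI = 0 with a disconnected graph?)"
        ) from exc
    if not np.all(np.isfinite(I)):
        raise ValueError("inhibitor system is singular or ill-conditioned")
    denom = rates.kR * A + rates.k_mR * I
    if np.any(denom <= 0):
        raise ValueError("degenerate readout steady state (zero production and decay)")
    R = rates.kR * A / denom
    return LegiState(A=A, I=I, R=R)


def relax_legi(
    S_i: np.ndarray,
    graph: ContactGraph,
    rates: LegiRates,
    T: float,
    state0: LegiState | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> LegiState:
    """Integrate the full LEGI kinetics for time T (ODE-relaxation oracle)."""
    S_i = np.atleast_1d(np.asarray(S_i, dtype=float))
    n = S_i.shape[0]
    if state0 is None:
        state0 = LegiState(np.zeros(n), np.zeros(n), np.zeros(n))

    def rhs(_t, y):
        st = LegiState(y[:n], np.maximum(y[n : 2 * n], 0.0), y[2 * n :])
        dA, dI, dR = legi_rhs(st, S_i, graph, rates)
        return np.concatenate([dA, dI, dR])

    y0 = np.concatenate([state0.A, state0.I, state0.R])
    sol = solve_ivp(rhs, (0.0, T), y0, method="LSODA", rtol=rtol, atol=atol)
    y = sol.y[:, -1]
    return LegiState(y[:n], y[n : 2 * n], y[2 * n :])


def amplification_g(x, lam: float = 1e-2):
    """Switchlike amplification g(x) = (1/2)[1 + tanh((x-1)/lam)]."""
    if lam <= 0:
        raise ValueError("switch width lam must be positive")
    x = np.asarray(x, dtype=float)
    out = 0.5 * (1.0 + np.tanh((x - 1.0) / lam))
    return float(out) if out.ndim == 0 else out


def susceptibility_from_response(
    R,
    rates: LegiRates,
    beta_bar: float,
    mode: Literal["linear", "switch"] = "linear",
    lam: float = 1e-2,
):
    """CIL susceptibility from the LEGI readout.

    ``linear``: beta = beta_bar * R/R0.  ``switch``: beta = beta_bar *
    g(R/R0, lam), with R0 the uniform-signal readout scale.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("readout must be non-negative")
    x = R / rates.R0
    if mode == "linear":
        out = np.asarray(beta_bar * x)
    elif mode == "switch":
        out = np.asarray(beta_bar * amplification_g(x, lam))
    else:
        raise ValueError(f"unknown response mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def legi_profile_table(
    positions: np.ndarray,
    fieldspec: SignalField,
    rates: LegiRates,
    beta_bar: float = 1.0,
    mode: Literal["linear", "switch"] = "linear",
    lam: float = 1e-2,
    cutoff: float | None = None,
    t: float = 0.0,
):
    """Steady-state per-cell profile as a tidy table.

    Columns: cell_id, x, y, S, A, I, R, beta.  Useful for exporting the
    response profile of a fixed configuration (CSV via ``.to_csv``).
    """
    import pandas as pd

    from .mechanics import DEFAULT_D0, contact_graph

    pos = np.asarray(positions, dtype=float)
    graph = contact_graph(pos, DEFAULT_D0 if cutoff is None else cutoff)
    S = np.atleast_1d(signal_at(fieldspec, pos, t))
    ss = legi_steady_state(S, graph, rates)
    beta = np.atleast_1d(
        susceptibility_from_response(ss.R, rates, beta_bar, mode, lam)
    )
    return pd.DataFrame(
        {
            "cell_id": np.arange(pos.shape[0]),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "S": S,
            "A": ss.A,
            "I": ss.I,
            "R": ss.R,
            "beta": beta,
        }
    )
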