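"""TOML run configuration: parsing, validation, round-trip and hashing.

A run configuration has sections [model], [signal], [ensemble] and
[output]; the optional [model.legi] subtable holds the LEGI rates and the
optional [sweep] section a parameter grid.  Configurations are fully
validated before any simulation starts, and every run writes its resolved
configuration (plus a content hash) beside its outputs.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .chemo_signal import LegiRates, SignalField
from .coattraction import CoattractionParams
from .dynamics import ModelParams

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash", "scenario_config"]


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    scenario: str = "custom"
    model: ModelParams = field(default_factory=ModelParams)
    signal: SignalField = field(default_factory=SignalField)
    N: int = 37
    n_traj: int = 10
    T: float = 25.0
    window: tuple[float, float] | None = None
    master_seed: int = 0
    snapshot_dt: float = 0.1
    outdir: str = "runs"
    sweep: dict | None = None  # e.g. {"chi": [...], "beta_bar": [...]}

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if self.n_traj < 1:
            raise ValueError("n_traj must be at least 1")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.snapshot_dt <= 0:
            raise ValueError("snapshot_dt must be positive")
        if self.window is not None:
            lo, hi = self.window
            if not (0 <= lo < hi <= self.T):
                raise ValueError("window must lie within [0, T]")

    def resolved(self) -> dict:
        """Plain-dict form used for serialization and hashing."""
        d = {
            "scenario": self.scenario,
            "model": asdict(self.model),
            "signal": asdict(self.signal),
            "ensemble": {
                "N": self.N,
                "n_traj": self.n_traj,
                "T": self.T,
                "window": list(self.window) if self.window else None,
                "master_seed": self.master_seed,
                "snapshot_dt": self.snapshot_dt,
            },
            "output": {"dir": self.outdir},
        }
        if self.sweep:
            d["sweep"] = self.sweep
        return d


def _model_from_dict(m: dict) -> ModelParams:
    m = dict(m)
    co = CoattractionParams(
        chi=m.pop("chi", 0.0), ell=m.pop("ell", 5.0), g0=m.pop("g0", 1e-5)
    )
    legi = None
    if "legi" in m:
        legi = LegiRates(**m.pop("legi"))
    allowed = {
        "tau", "sigma", "beta_bar", "v_r", "v_a", "D0",
        "response_mode", "lam", "legi_kinetics", "dt",
    }
    unknown = set(m) - allowed
    if unknown:
        raise ValueError(f"unknown [model] keys: {sorted(unknown)}")
    return ModelParams(coattraction=co, legi=legi, **m)


def _signal_from_dict(s: dict) -> SignalField:
    s = dict(s)
    if "axis" in s:
        s["axis"] = tuple(s["axis"])
    return SignalField(**s)


def config_from_dict(data: dict, scenario: str = "custom") -> RunConfig:
    ens = dict(data.get("ensemble", {}))
    window = ens.pop("window", None)
    return RunConfig(
        scenario=data.get("scenario", scenario),
        model=_model_from_dict(data.get("model", {})),
        signal=_signal_from_dict(data.get("signal", {})),
        window=tuple(window) if window else None,
        outdir=data.get("output", {}).get("dir", "runs"),
        sweep=data.get("sweep"),
        **ens,
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return repr(int(v))
    if isinstance(v, float):  # also covers numpy float scalars
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _emit_table(name: str, table: dict, lines: list[str]) -> None:
    subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
    scalars = {k: v for k, v in table.items() if not isinstance(v, dict) and v is not None}
    if scalars or not subtables:
        lines.append(f"[{name}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    for k, v in subtables.items():
        _emit_table(f"{name}.{k}", v, lines)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration as TOML (round-trips via load_config)."""
    d = cfg.resolved()
    lines = [f'scenario = {_toml_value(d.pop("scenario"))}', ""]
    # flatten model: coattraction params are flat keys, legi is a subtable
    model = dict(d.pop("model"))
    co = model.pop("coattraction")
    legi = model.pop("legi")
    model.update(co)
    _emit_table("model", model, lines)
    if legi is not None:
        _emit_table("model.legi", legi, lines)
    _emit_table("signal", d.pop("signal"), lines)
    _emit_table("ensemble", d.pop("ensemble"), lines)
    _emit_table("output", d.pop("output"), lines)
    if "sweep" in d:
        _emit_table("sweep", d.pop("sweep"), lines)
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def config_hash(cfg: RunConfig) -> str:
    """Stable content hash of the resolved configuration."""
    payload = json.dumps(cfg.resolved(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --- bundled scenarios: representative parameter regimes ------------------

_SCENARIOS: dict[str, dict] = {
    # rigid LEGI-adapting clusters in a shallow exponential gradient
    "rigid_adaptation": {
        "model": {
            "beta_bar": 20.0, "v_r": 500.0, "v_a": 500.0, "dt": 1e-4,
            "response_mode": "legi_linear",
            "legi": {"kI": 1.0, "k_mI": 1.0, "kD": 4.0},
        },
        "signal": {"kind": "exponential", "S0": 1.0, "S1": 0.025},
        "ensemble": {"N": 19, "n_traj": 20, "T": 6.0, "snapshot_dt": 0.1},
    },
    # switchlike amplification; weak beta_bar to stay near steady state
    "rigid_amplified": {
        "model": {
            "beta_bar": 0.2, "v_r": 500.0, "v_a": 500.0, "dt": 1e-4,
            "response_mode": "legi_switch", "lam": 1e-2,
            "legi": {"kI": 1.0, "k_mI": 1.0, "kD": 4.0},
        },
        "signal": {"kind": "exponential", "S0": 1.0, "S1": 0.025},
        "ensemble": {"N": 19, "n_traj": 20, "T": 6.0, "snapshot_dt": 0.1},
    },
    # loosely bound co-attracting cluster, strong CIL
    "loose_chemotaxis": {
        "model": {
            "beta_bar": 70.0, "v_r": 100.0, "v_a": 0.0, "dt": 1e-3,
            "chi": 15.0, "ell": 5.0,
        },
        "signal": {"kind": "exponential", "S0": 1.0, "S1": 0.025},
        "ensemble": {
            "N": 37, "n_traj": 10, "T": 50.0, "window": [12.5, 50.0],
            "snapshot_dt": 0.1,
        },
    },
    # tightly packed rotating cluster
    "tight_rotating": {
        "model": {
            "beta_bar": 37.2, "v_r": 100.0, "v_a": 0.0, "dt": 1e-3,
            "chi": 83.3, "ell": 5.0,
        },
        "signal": {"kind": "exponential", "S0": 1.0, "S1": 0.025},
        "ensemble": {
            "N": 37, "n_traj": 10, "T": 50.0, "window": [12.5, 50.0],
            "snapshot_dt": 0.05,
        },
    },
    # rotation bifurcation sweep: no external gradient
    "rotation_sweep": {
        "model": {
            "beta_bar": 35.0, "v_r": 100.0, "v_a": 0.0, "dt": 1e-3,
            "ell": 5.0, "chi": 0.0,
        },
        "signal": {"kind": "uniform", "S0": 1.0},
        "ensemble": {
            "N": 37, "n_traj": 10, "T": 25.0, "window": [12.5, 25.0],
            "snapshot_dt": 0.05,
        },
        "sweep": {"chi": [5.0, 20.0, 35.0, 50.0, 65.0, 80.0, 95.0]},
    },
    # signal-level dependence with and without adaptation
    "signal_level_sweep": {
        "model": {
            "beta_bar": 70.0, "v_r": 100.0, "v_a": 0.0, "dt": 1e-3,
            "chi": 15.0, "ell": 5.0,
        },
        "signal": {"kind": "exponential", "S0": 1.0, "S1": 0.02},
        "ensemble": {
            "N": 37, "n_traj": 10, "T": 50.0, "window": [12.5, 50.0],
            "snapshot_dt": 0.1,
        },
        "sweep": {"S0": [0.5, 1.0, 2.0, 4.0]},
    },
}


def scenario_config(name: str) -> RunConfig:
    """A bundled named scenario as a fully resolved configuration."""
    if name not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(_SCENARIOS)}")
    return config_from_dict(_SCENARIOS[name], scenario=name)


def available_scenarios() -> list[str]:
    return sorted(_SCENARIOS)
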