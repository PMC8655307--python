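"""File formats, configuration, and run manifests.

Trajectory files are comma-separated with header
``t,theta,theta_dot,tau,tau_floor,phi`` (SI units, radians, one row per
sample); marker files use ``t,<landmark>_x,<landmark>_y,...`` in meters at
the motion-capture rate.  Configuration is a single TOML file with
``[body]``, ``[floor]``, ``[controller]``, ``[sim]`` and ``[ga]`` sections;
unspecified fields fall back to the study defaults (m = 0.404 kg,
h = 0.107 m, 40 ms delay, 8.8 degree / 0.25 s ramp, dt = 1 ms, identified
mean gains).  Every CLI run writes a JSON manifest with the configuration
hash, the seeds, and the artifact paths so deterministic stages can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .controllers import MPCConfig, PDConfig
from .identification import GAConfig, ParameterBounds
from .kinematics import LANDMARKS, MarkerFrames
from .model import FloorProfile, PendulumParams, SimulationConfig, Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "ParseError",
    "ConfigError",
    "AppConfig",
    "read_trajectory",
    "write_trajectory",
    "read_markers",
    "write_markers",
    "load_config",
    "config_hash",
    "RunManifest",
]

TRAJECTORY_COLUMNS = ("t", "theta", "theta_dot", "tau", "tau_floor", "phi")


class ParseError(ValueError):
    """A data file does not match its declared dialect."""


class ConfigError(ValueError):
    """A configuration file failed validation; lists every violation."""


def _check_uniform(times: np.ndarray, what: str) -> None:
    if len(times) < 2:
        raise ParseError(f"{what}: need at least two rows")
    dts = np.diff(times)
    ref = dts[0]
    bad = np.nonzero(np.abs(dts - ref) > 1e-9)[0]
    if bad.size:
        row = int(bad[0]) + 2  # +1 for 0-base, +1 for the preceding row
        raise ParseError(
            f"{what}: non-uniform sampling at data row {row} "
            f"(dt {dts[bad[0]]:.6g} s vs {ref:.6g} s)"
        )


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV; columns are matched by name."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    times = df["t"].to_numpy(dtype=float)
    _check_uniform(times, str(path))
    return Trajectory(
        times=times,
        theta=df["theta"].to_numpy(dtype=float),
        theta_dot=df["theta_dot"].to_numpy(dtype=float),
        tau=df["tau"].to_numpy(dtype=float),
        tau_floor=df["tau_floor"].to_numpy(dtype=float),
        phi=df["phi"].to_numpy(dtype=float),
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory CSV at full float precision (round-trip exact)."""
    df = pd.DataFrame(
        {
            "t": traj.times,
            "theta": traj.theta,
            "theta_dot": traj.theta_dot,
            "tau": traj.tau,
            "tau_floor": traj.tau_floor,
            "phi": traj.phi,
        }
    )
    df.to_csv(path, index=False)


def read_markers(path) -> MarkerFrames:
    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns:
        raise ParseError(f"{path}: missing column 't'")
    times = df["t"].to_numpy(dtype=float)
    _check_uniform(times, str(path))
    coords = {}
    for name in LANDMARKS:
        cx, cy = f"{name}_x", f"{name}_y"
        if cx not in df.columns or cy not in df.columns:
            raise ParseError(f"{path}: missing columns for landmark {name!r}")
        coords[name] = np.column_stack(
            [df[cx].to_numpy(dtype=float), df[cy].to_numpy(dtype=float)]
        )
    return MarkerFrames(times=times, coords=coords)


def write_markers(frames: MarkerFrames, path) -> None:
    data = {"t": frames.times}
    for name in LANDMARKS:
        data[f"{name}_x"] = frames.coords[name][:, 0]
        data[f"{name}_y"] = frames.coords[name][:, 1]
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class AppConfig:
    """Validated full configuration with study defaults."""

    params: PendulumParams
    profile: FloorProfile
    sim: SimulationConfig
    mpc: MPCConfig
    pd: PDConfig
    ga: GAConfig
    bounds: ParameterBounds
    controller: str = "mpc"
    raw: dict = field(default_factory=dict)


def _section(data: dict, name: str) -> dict:
    sec = data.get(name, {})
    if not isinstance(sec, dict):
        raise ConfigError(f"section [{name}] must be a table")
    return dict(sec)


def load_config(path=None) -> AppConfig:
    """Load a TOML config; absent fields take the study defaults.

    Gains in ``[body]`` are given as multiples of m*g*h (``kp_mgh``,
    ``kd_mgh``) and the noise in mN.m (``sigma_mnm``); they are converted to
    SI internally and m*g*h is recomputed whenever the body constants are
    overridden.  All violations are reported together.
    """
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)

    errors: list[str] = []
    body = _section(data, "body")
    floor = _section(data, "floor")
    ctrl = _section(data, "controller")
    sim = _section(data, "sim")
    ga = _section(data, "ga")

    def build(factory, kwargs, label):
        try:
            return factory(**kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(f"[{label}] {exc}")
            return None

    params = build(
        PendulumParams.rat,
        {
            "m": body.get("m", 0.404),
            "h": body.get("h", 0.107),
            "g": body.get("g", 9.81),
            "J": body.get("J"),
            "kp_mgh": body.get("kp_mgh", 0.34),
            "kd_mgh": body.get("kd_mgh", 0.03),
            "sigma_mnm": body.get("sigma_mnm", 0.50),
        },
        "body",
    )
    profile = build(
        FloorProfile,
        {
            "onset": floor.get("onset", 0.0),
            "duration": floor.get("duration", 0.25),
            "amplitude": math.radians(floor.get("amplitude_deg", 8.8)),
        },
        "floor",
    )
    sim_cfg = build(
        SimulationConfig,
        {
            k: sim[k]
            for k in ("dt", "t_start", "t_end", "noise_seed", "noise_scaling_mode")
            if k in sim
        },
        "sim",
    )
    mpc_kwargs = {
        k: ctrl[k]
        for k in (
            "hp", "hu", "delay", "state_weight", "move_weight",
            "input_regularizer", "preview", "delay_compensation",
        )
        if k in ctrl
    }
    mpc_kwargs["dt"] = sim.get("dt", 1e-3)
    mpc = build(MPCConfig, mpc_kwargs, "controller")
    pd_cfg = build(
        PDConfig,
        {
            "variant": ctrl.get("pd_variant", "linear"),
            "kp_lin": ctrl.get("kp_lin", 1.46),
            "kd_lin": ctrl.get("kd_lin", 0.30),
            "kp2": ctrl.get("kp2", 196.0),
            "kp0": ctrl.get("kp0", 0.88),
            "kd_nl": ctrl.get("kd_nl", 0.11),
        },
        "controller",
    )
    ga_cfg = build(
        GAConfig,
        {
            k: ga[k]
            for k in (
                "population", "generations", "elite", "tournament",
                "crossover_rate", "blend_alpha", "mutation_rate",
                "mutation_scale", "n_rep", "stall_generations",
            )
            if k in ga
        },
        "ga",
    )
    bounds = build(
        ParameterBounds,
        {
            k: tuple(ga[f"bounds_{k}"])
            for k in ("hp", "hu", "kp_mgh", "kd_mgh", "sigma_mnm")
            if f"bounds_{k}" in ga
        },
        "ga",
    )
    controller = ctrl.get("type", "mpc")
    if controller not in ("mpc", "pd", "nlpd"):
        errors.append(f"[controller] unknown type {controller!r}")

    if errors:
        raise ConfigError("; ".join(errors))
    return AppConfig(
        params=params, profile=profile, sim=sim_cfg, mpc=mpc, pd=pd_cfg,
        ga=ga_cfg, bounds=bounds, controller=controller, raw=data,
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(cfg: AppConfig) -> str:
    """SHA-256 of the canonical JSON form of the effective configuration."""
    payload = {
        k: _jsonable(getattr(cfg, k))
        for k in ("params", "profile", "sim", "mpc", "pd", "ga", "bounds",
                  "controller")
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one CLI run."""

    command: str
    config_hash: str
    seeds: list
    artifacts: list
    version: str
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(_jsonable(self), indent=2) + "\n")
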