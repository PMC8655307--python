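"""Synthetic study data with the statistical structure the analysis assumes.

The original recordings (rat CoM-angle traces and marker trajectories) are
not deposited, so every pipeline input is regenerated here:

* post-learning trials — the MPC closed loop at the identified mean
  parameters (Hp = 0.96 s, Hu = 24.4 ms, k_P = 0.34 mgh, k_D = 0.03 mgh,
  sigma = 0.50 mN.m) under the 8.8 degree / 0.25 s ramp, sampled at 1 kHz
  over [-0.35, 0.45] s;
* naive (pre-learning) trials — the same loop with a short prediction
  horizon (the cue--tilt association, and with it deep prediction, not yet
  acquired), or a PD baseline;
* marker motion — forward kinematics of the five-segment chain with
  prescribed joint-angle functions, so segment angular velocities are known
  by construction.

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .controllers import MPCConfig, PDController, mpc_rollout
from .identification import IdentificationTarget
from .kinematics import MarkerFrames, SegmentModel
from .model import (
    FloorProfile,
    PendulumParams,
    SimulationConfig,
    SimulationError,
    Trajectory,
    simulate,
)

__all__ = [
    "SyntheticTrialSpec",
    "DEFAULT_SEGMENT_LENGTHS",
    "synth_trial",
    "synth_naive_trial",
    "synth_targets",
    "synth_marker_motion",
]

#: default sagittal chain lengths, m (plausible for a ~0.4 kg rat standing
#: upright; the whole-body CoM height they imply is near the measured 0.107 m)
DEFAULT_SEGMENT_LENGTHS = {
    "foot": 0.035,
    "leg": 0.10,
    "lower_trunk": 0.045,
    "upper_trunk": 0.045,
    "neck": 0.025,
    "head": 0.030,
}


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Generator settings; defaults are the study conditions (identified
    mean parameters, measured body constants, experimental tilt ramp, and
    18 sequences mirroring the identified experimental set)."""

    params: PendulumParams = field(default_factory=PendulumParams.rat)
    mpc: MPCConfig = field(default_factory=MPCConfig)
    profile: FloorProfile = field(default_factory=FloorProfile)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_sequences: int = 18
    seed: int = 0


def _trial_seed(spec: SyntheticTrialSpec, index: int) -> int:
    return int(np.random.SeedSequence((spec.seed, index)).generate_state(1)[0]) % 2**31


def _rollout_trajectory(spec, mpc_config, seed) -> Trajectory:
    res = mpc_rollout(spec.params, mpc_config, spec.profile, spec.sim, [seed])
    if res.fell.any() or np.max(np.abs(res.theta)) > np.pi / 2:
        raise SimulationError("generator configuration is unstable (body fell)")
    theta = res.theta[:, 0]
    theta_dot = res.theta_dot[:, 0]
    phi = np.asarray(spec.profile.angle(res.times), dtype=float)
    phi_dot = np.asarray(spec.profile.rate(res.times), dtype=float)
    p = spec.params
    tf = -p.k_p * (theta - phi) - p.k_d * (theta_dot - phi_dot)
    return Trajectory(
        times=res.times, theta=theta, theta_dot=theta_dot,
        tau=res.tau[:, 0], tau_floor=tf, phi=phi, seed=seed,
    )


def synth_trial(spec: SyntheticTrialSpec, index: int = 0) -> Trajectory:
    """One post-learning trial: the identified MPC under the tilt ramp."""
    return _rollout_trajectory(spec, spec.mpc, _trial_seed(spec, index))


#: prediction depth of the pre-learning surrogate, s: deep enough to stand
#: on a level floor, far too shallow to manage the tilt
NAIVE_HP = 0.05


def synth_naive_trial(
    spec: SyntheticTrialSpec, index: int = 0, mode: str = "short-horizon"
) -> Trajectory:
    """One pre-learning surrogate trial.

    ``mode='short-horizon'`` (default) keeps the MPC but shrinks its
    prediction horizon to ``NAIVE_HP`` — learning is interpreted as
    acquiring the prediction depth that the cue--tilt association makes
    possible, the axis the study's horizon sweep probes.  The response is
    several times the trained one, as in naive animals.
    ``mode='pd'`` / ``mode='nlpd'`` use the conventional feedback baselines
    instead.
    """
    seed = _trial_seed(spec, index)
    if mode == "short-horizon":
        naive = replace(
            spec.mpc, hp=NAIVE_HP, hu=min(spec.mpc.hu, NAIVE_HP)
        )
        return _rollout_trajectory(spec, naive, seed)
    if mode in ("pd", "nlpd"):
        from .controllers import PDConfig

        cfg = PDConfig(variant="linear" if mode == "pd" else "nonlinear")
        ctrl = PDController(
            spec.params, cfg, delay=spec.mpc.delay, dt=spec.sim.dt
        )
        sim_cfg = replace(spec.sim, noise_seed=seed)
        traj = simulate(spec.params, ctrl, spec.profile, sim_cfg)
        if np.max(np.abs(traj.theta)) > np.pi / 2:
            raise SimulationError("generator configuration is unstable (body fell)")
        return traj
    raise ValueError(f"unknown naive-trial mode {mode!r}")


def synth_targets(spec: SyntheticTrialSpec, n: int | None = None) -> list:
    """Identification targets from ``n`` (default ``spec.n_sequences``)
    post-learning trials with distinct seeds."""
    n = spec.n_sequences if n is None else n
    return [
        IdentificationTarget.from_trajectory(
            synth_trial(spec, i), spec.profile, spec.params, label=f"seq{i}"
        )
        for i in range(n)
    ]


def _direction(angle: np.ndarray) -> np.ndarray:
    # unit vector of a segment line at angle-from-vertical (backward positive)
    return np.column_stack([-np.sin(angle), np.cos(angle)])


def synth_marker_motion(
    model: SegmentModel,
    angle_funcs: dict[str, Callable],
    duration: float = 0.5,
    fs: float = 200.0,
    lengths: dict | None = None,
    base: tuple[float, float] = (0.0, 0.0),
) -> MarkerFrames:
    """Forward-kinematic marker motion with prescribed segment angles.

    ``angle_funcs`` maps each segment name (foot, leg, lower_trunk,
    upper_trunk, head) to a callable t -> absolute angle from vertical in
    radians; segments not listed stay vertical.  The chain runs MTP ->
    ankle -> (knee on the leg line) -> hip -> (iliac crest on the lower
    trunk line) -> mid-trunk -> scapula, and the head segment (TMJ -> nose)
    hangs from the scapula by a neck link that rotates with the head.
    Angular velocities of every segment are therefore known analytically.
    """
    lengths = {**DEFAULT_SEGMENT_LENGTHS, **(lengths or {})}
    for name, L in lengths.items():
        if L <= 0:
            raise ValueError(f"segment length {name!r} must be positive")
    n = round(duration * fs)
    times = np.arange(n + 1) / fs

    def ang(name):
        f = angle_funcs.get(name)
        if f is None:
            return np.zeros_like(times)
        return np.asarray([float(f(t)) for t in times])

    a_foot, a_leg = ang("foot"), ang("leg")
    a_low, a_up, a_head = ang("lower_trunk"), ang("upper_trunk"), ang("head")

    mtp = np.broadcast_to(np.asarray(base, dtype=float), (n + 1, 2)).copy()
    ankle = mtp + lengths["foot"] * _direction(a_foot)
    hip = ankle + lengths["leg"] * _direction(a_leg)
    knee = ankle + 0.5 * lengths["leg"] * _direction(a_leg)
    mid_trunk = hip + lengths["lower_trunk"] * _direction(a_low)
    iliac = hip + 0.5 * lengths["lower_trunk"] * _direction(a_low)
    scapula = mid_trunk + lengths["upper_trunk"] * _direction(a_up)
    tmj = scapula + lengths["neck"] * _direction(a_head)
    nose = tmj + lengths["head"] * _direction(a_head)

    return MarkerFrames(
        times=times,
        coords={
            "mtp": mtp, "ankle": ankle, "knee": knee, "hip": hip,
            "iliac_crest": iliac, "mid_trunk": mid_trunk,
            "scapula": scapula, "tmj": tmj, "nose": nose,
        },
    )
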