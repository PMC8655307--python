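"""Controllers for the tilting-floor stance task.

Three control laws are provided:

* :class:`MPCController` — receding-horizon model-predictive control.  At
  every sampling instant the controller forecasts the body angle over a
  prediction horizon ``Hp`` using a linear internal copy of the pendulum and
  floor dynamics, lets the planned torque vary freely for ``Hu`` steps and
  holds it constant afterwards (move blocking), minimizes the sum of squared
  predicted angles plus an input-increment penalty, and applies only the
  first planned move.  What the forecast assumes about the floor is a
  policy (:class:`MPCConfig.preview`): unknown, sensed-and-held, or fully
  previewed (the learned cue--tilt association).  Because the problem is an
  unconstrained quadratic, the optimal first move is a precomputable linear
  gain on the state estimate, the previous torque, and the floor preview.
* :class:`PDController` — proportional-derivative feedback on the delayed
  measurement, with the gains of Peterka's human-stance model
  (k_P = 1.46 mgh, k_D = 0.3 mgh).
* nonlinear PD — adds a quadratic stiffness term (k_P2 = 196 mgh,
  k_P0 = 0.88 mgh, k_D = 0.11 mgh), the feedback law previously identified
  for bipedally standing rats.  The quadratic term is implemented with odd
  symmetry (-k_P2*mgh*theta*|theta|) so it always opposes the displacement.

A 40 ms sensory delay applies to all controllers; the MPC compensates it by
forward-propagating the delayed measurement through its internal model with
the stored torque and floor histories (predictor structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import cont2discrete

from .model import FloorProfile, PendulumParams

__all__ = [
    "MPCConfig",
    "PDConfig",
    "InternalModel",
    "MPCGains",
    "linearize_internal_model",
    "mpc_gain",
    "mpc_control",
    "delay_compensate",
    "pd_control",
    "nonlinear_pd_control",
    "MPCController",
    "PDController",
    "horizon_steps",
]

#: sensory delay of the rat postural loop, s
DEFAULT_DELAY = 0.040


def horizon_steps(horizon_s: float, dt: float) -> int:
    """Horizon in seconds -> whole step count (nearest, minimum 1)."""
    return max(1, round(horizon_s / dt))


@dataclass(frozen=True)
class MPCConfig:
    """Receding-horizon controller settings.

    ``hp`` and ``hu`` are the prediction and control horizons in seconds
    (rounded to whole steps of ``dt``); ``delay`` the sensory delay.
    ``move_weight`` penalizes squared input increments between consecutive
    planned moves (including the increment from the previously applied
    torque), the manipulated-variable-rate term of the standard industrial
    MPC cost.  Because the weight acts on unscaled physical units it is only
    meaningful together with a variable scaling; the default 1e4 is
    calibrated so that the closed loop at the identified parameters
    reproduces the few-degree tilt response observed in trained animals
    (without a substantial rate penalty the optimizer cancels the tilt
    almost perfectly and the loop degenerates).  ``input_regularizer`` is a
    tiny penalty on input magnitude kept solely for numerical conditioning.

    ``preview`` selects what the forecast assumes about the floor:

    * ``"none"`` (default) — the floor state is unknown to the controller;
      the internal floor model assumes a level floor and the tilt is felt
      only through the body.  This is the default reactive regime: the
      control torque rises only after the floor torque does.
    * ``"measured"`` — the currently sensed floor angle and rate are held
      constant over the horizon, the standard treatment of a measured
      disturbance without future preview.
    * ``"full"`` — the exact future floor trajectory over the horizon is
      known (a perfectly learned cue--tilt association), giving anticipatory
      torque before the tilt reaches the body.

    The optimal gains are identical across policies; only the preview
    content supplied to them differs.

    With ``delay_compensation`` (default on) the controller forward-
    propagates the delayed measurement through the internal model using the
    stored torque history (and floor history when the floor is sensed), the
    standard predictor treatment of a known sensory delay.  When disabled,
    stale measurements are treated as current and the resulting phase lag
    destabilizes the loop at these gains.
    """

    hp: float = 0.96
    hu: float = 0.0244
    dt: float = 1e-3
    delay: float = DEFAULT_DELAY
    state_weight: float = 1.0
    move_weight: float = 1e4
    input_regularizer: float = 1e-8
    preview: str = "none"
    delay_compensation: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.hu:
            raise ValueError("hu must be strictly positive")
        if self.hu > self.hp:
            raise ValueError("hu must not exceed hp")
        if not self.dt > 0.0:
            raise ValueError("dt must be strictly positive")
        if self.delay < 0.0:
            raise ValueError("delay must be non-negative")
        steps = self.delay / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("delay must be a whole number of steps")
        if self.state_weight <= 0.0:
            raise ValueError("state_weight must be strictly positive")
        if self.move_weight < 0.0:
            raise ValueError("move_weight must be non-negative")
        if self.input_regularizer < 0.0:
            raise ValueError("input_regularizer must be non-negative")
        if self.preview not in ("full", "measured", "none"):
            raise ValueError("preview must be 'full', 'measured' or 'none'")

    @property
    def hp_steps(self) -> int:
        return horizon_steps(self.hp, self.dt)

    @property
    def hu_steps(self) -> int:
        return min(horizon_steps(self.hu, self.dt), self.hp_steps)

    @property
    def delay_steps(self) -> int:
        return round(self.delay / self.dt)


@dataclass(frozen=True)
class PDConfig:
    """Gains of the conventional feedback baselines, as multiples of mgh."""

    variant: str = "linear"
    kp_lin: float = 1.46
    kd_lin: float = 0.30
    kp2: float = 196.0
    kp0: float = 0.88
    kd_nl: float = 0.11

    def __post_init__(self) -> None:
        if self.variant not in ("linear", "nonlinear"):
            raise ValueError("variant must be 'linear' or 'nonlinear'")
        for name in ("kp_lin", "kd_lin", "kp2", "kp0", "kd_nl"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class InternalModel:
    """Zero-order-hold discretization of the linearized stance dynamics.

    Continuous form (sin(theta) -> theta):

        theta'' = a*theta + b*theta_dot + tau/J + (k_p/J)*phi + (k_d/J)*phi_dot

    with a = (mgh - k_p)/J and b = -k_d/J.  ``A`` (2x2), ``B`` (2,) and
    ``E`` (2x2, columns for phi and phi_dot) propagate the state
    (theta, theta_dot) over one step of ``dt`` with held inputs.
    """

    A: np.ndarray
    B: np.ndarray
    E: np.ndarray
    dt: float


def linearize_internal_model(params: PendulumParams, dt: float) -> InternalModel:
    """Linearize the pendulum + floor dynamics about upright and discretize
    by zero-order hold at step ``dt``."""
    if not dt > 0.0:
        raise ValueError("dt must be strictly positive")
    J = params.J
    a = (params.mgh - params.k_p) / J
    b = -params.k_d / J
    Ac = np.array([[0.0, 1.0], [a, b]])
    # inputs: [tau, phi, phi_dot]
    Bc = np.array([[0.0, 0.0, 0.0], [1.0 / J, params.k_p / J, params.k_d / J]])
    Ad, Bd, *_ = cont2discrete((Ac, Bc, np.eye(2), np.zeros((2, 3))), dt)
    return InternalModel(A=Ad, B=Bd[:, 0].copy(), E=Bd[:, 1:].copy(), dt=dt)


@dataclass(frozen=True)
class MPCGains:
    """Preview-gain form of the receding-horizon control law.

    The first optimal move is the linear map

        tau = k_state . x_est + k_u_prev * tau_prev
              + k_phi . phi_preview + k_phi_dot . phi_dot_preview

    with previews sampled at the current time and the following
    ``hp_steps - 1`` steps, and ``tau_prev`` the previously applied torque
    (it enters through the move penalty on the first input increment).
    """

    k_state: np.ndarray
    k_u_prev: float
    k_phi: np.ndarray
    k_phi_dot: np.ndarray
    hp_steps: int
    hu_steps: int
    dt: float


def _prediction_operators(model: InternalModel, hp: int):
    """Stacked one-step maps: CA[k] = [1, 0] A^k for k = 0..hp."""
    CA = np.empty((hp + 1, 2))
    row = np.array([1.0, 0.0])
    for k in range(hp + 1):
        CA[k] = row
        row = row @ model.A
    return CA


def _correlate_lower(m0: np.ndarray, h: np.ndarray) -> np.ndarray:
    """y[j] = sum_{k>=j} m0[k] * h[k-j]: product with a lower-triangular
    Toeplitz matrix built from the impulse response ``h``, without forming
    the Hp x Hp matrix."""
    n = len(m0)
    return np.correlate(m0, h, mode="full")[n - 1 :]


def mpc_gain(model: InternalModel, config: MPCConfig) -> MPCGains:
    """Solve the finite-horizon quadratic problem in closed form.

    Cost over the prediction horizon (target angle always zero):

        state_weight * sum_{k=1..Hp} theta_k^2
        + move_weight * sum_i (u_i - u_{i-1})^2      (u_{-1} = applied torque)
        + input_regularizer * sum_i u_i^2

    with the input free for the first Hu steps and held constant afterwards
    (move blocking).  Unconstrained and quadratic, so the first move is an
    exact linear gain on (state estimate, previous torque, floor preview).
    """
    hp, hu = config.hp_steps, config.hu_steps
    CA = _prediction_operators(model, hp)
    F = CA[1:]                      # (hp, 2) free response of theta
    g = CA[:hp] @ model.B           # impulse response of theta to tau
    h_phi = CA[:hp] @ model.E[:, 0]
    h_phid = CA[:hp] @ model.E[:, 1]

    # move blocking: theta_pred = F x + Phi_u u + (floor terms); the last
    # free input also drives all steps beyond Hu
    Phi_u = np.zeros((hp, hu))
    for i in range(hu - 1):
        Phi_u[i:, i] = g[: hp - i]
    cs = np.cumsum(g)
    Phi_u[hu - 1 :, hu - 1] = cs[: hp - hu + 1]

    w = config.state_weight
    # D u - e0*u_prev stacks the input increments of the free moves
    DtD = (
        np.diag(np.r_[np.full(hu - 1, 2.0), 1.0])
        + np.diag(np.full(hu - 1, -1.0), 1)
        + np.diag(np.full(hu - 1, -1.0), -1)
    ) if hu > 1 else np.array([[1.0]])
    H = (
        w * (Phi_u.T @ Phi_u)
        + config.move_weight * DtD
        + config.input_regularizer * np.eye(hu)
    )
    e0 = np.zeros(hu)
    e0[0] = 1.0
    try:
        y = np.linalg.solve(H, e0)  # first row of H^{-1}
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"degenerate MPC normal equations (hp={hp}, hu={hu}, "
            f"move_weight={config.move_weight:g}, "
            f"regularizer={config.input_regularizer:g}): {exc}"
        ) from exc
    m0 = w * (Phi_u @ y)            # (hp,) row mapping predicted theta -> u0
    return MPCGains(
        k_state=-(m0 @ F),
        k_u_prev=float(config.move_weight * y[0]),
        k_phi=-_correlate_lower(m0, h_phi),
        k_phi_dot=-_correlate_lower(m0, h_phid),
        hp_steps=hp,
        hu_steps=hu,
        dt=config.dt,
    )


def mpc_control(
    gains: MPCGains,
    state_estimate,
    phi_preview: np.ndarray,
    phi_dot_preview: np.ndarray,
    tau_prev: float = 0.0,
) -> float:
    """First optimal move for the given state estimate and floor preview.

    Pure function of its arguments; previews must have exactly ``hp_steps``
    samples starting at the current instant.  ``tau_prev`` is the torque
    applied at the previous step (the first move increment is penalized
    relative to it).
    """
    phi_preview = np.asarray(phi_preview, dtype=float)
    phi_dot_preview = np.asarray(phi_dot_preview, dtype=float)
    if phi_preview.shape != (gains.hp_steps,) or phi_dot_preview.shape != (
        gains.hp_steps,
    ):
        raise ValueError(
            f"previews must have length {gains.hp_steps}, got "
            f"{phi_preview.shape} and {phi_dot_preview.shape}"
        )
    x = np.asarray(state_estimate, dtype=float)
    return float(
        gains.k_state @ x
        + gains.k_u_prev * tau_prev
        + gains.k_phi @ phi_preview
        + gains.k_phi_dot @ phi_dot_preview
    )


def delay_compensate(
    model: InternalModel,
    delayed_measurement,
    input_history: np.ndarray,
    phi_history: np.ndarray,
    phi_dot_history: np.ndarray,
) -> np.ndarray:
    """Predict the current state from a measurement ``d`` steps old.

    The measurement is propagated forward through the internal model using
    the torques actually applied during the delay window and the (known)
    floor trajectory over the same window; histories are ordered oldest
    first and must span exactly the delay.
    """
    u = np.atleast_1d(np.asarray(input_history, dtype=float))
    ph = np.atleast_1d(np.asarray(phi_history, dtype=float))
    pd = np.atleast_1d(np.asarray(phi_dot_history, dtype=float))
    if u.size == 0 and ph.size == 0:
        return np.asarray(delayed_measurement, dtype=float)
    if not (u.shape == ph.shape == pd.shape):
        raise ValueError("histories must share one length (the delay)")
    x = np.asarray(delayed_measurement, dtype=float)
    for j in range(u.size):
        x = model.A @ x + model.B * u[j] + model.E @ np.array([ph[j], pd[j]])
    return x


def pd_control(
    config: PDConfig, params: PendulumParams, theta: float, theta_dot: float
) -> float:
    """Linear PD feedback -k_P*mgh*theta - k_D*mgh*theta_dot."""
    if config.variant != "linear":
        raise ValueError("pd_control requires the linear variant")
    mgh = params.mgh
    return float(-config.kp_lin * mgh * theta - config.kd_lin * mgh * theta_dot)


def nonlinear_pd_control(
    config: PDConfig, params: PendulumParams, theta: float, theta_dot: float
) -> float:
    """Nonlinear PD feedback with odd-symmetric quadratic stiffness:
    -k_P2*mgh*theta*|theta| - k_P0*mgh*theta - k_D*mgh*theta_dot."""
    if config.variant != "nonlinear":
        raise ValueError("nonlinear_pd_control requires the nonlinear variant")
    mgh = params.mgh
    return float(
        -config.kp2 * mgh * theta * abs(theta)
        - config.kp0 * mgh * theta
        - config.kd_nl * mgh * theta_dot
    )


class _DelayOps:
    """Precomputed linear maps for the delay predictor."""

    def __init__(self, model: InternalModel, d: int):
        self.d = d
        self.A_d = np.linalg.matrix_power(model.A, d)
        # x_now = A^d x_meas + sum_j A^(d-1-j) (B u_j + E d_j), j oldest first
        self.WB = np.empty((max(d, 1), 2)) if d else np.zeros((0, 2))
        self.WE = np.empty((max(d, 1), 2, 2)) if d else np.zeros((0, 2, 2))
        P = np.eye(2)
        for j in range(d - 1, -1, -1):
            self.WB[j] = P @ model.B
            self.WE[j] = P @ model.E
            P = P @ model.A


class MPCController:
    """Receding-horizon preview controller bound to a body model.

    Satisfies the controller protocol of :func:`tiltstand.model.simulate`.
    With ``preview_enabled=False`` the controller has no knowledge of the
    floor trajectory at all (neither preview nor delay-window history): it
    reacts purely to what the delayed measurements reveal.
    """

    def __init__(self, params: PendulumParams, config: MPCConfig):
        self.params = params
        self.config = config
        self.model = linearize_internal_model(params, config.dt)
        self.gains = mpc_gain(self.model, config)
        self.delay_steps = config.delay_steps
        self._delay_ops = _DelayOps(self.model, self.delay_steps)
        self._tau_prev = 0.0

    def reset(self) -> None:
        # the only internal state is the previously applied torque, which
        # enters the first-move increment penalty
        self._tau_prev = 0.0

    def estimate_state(self, t, theta_meas, theta_dot_meas, tau_history, profile):
        d = self.delay_steps
        x = np.array([theta_meas, theta_dot_meas], dtype=float)
        if d == 0:
            return x
        ops = self._delay_ops
        if self.config.preview != "none":
            # the floor angle is sensed in real time; its past over the
            # delay window is available to the predictor
            ht = t + self.config.dt * (np.arange(d) - d)
            ph = np.asarray(profile.angle(ht), dtype=float)
            pd = np.asarray(profile.rate(ht), dtype=float)
            dist = ops.WB.T @ tau_history + np.einsum("jab,bj->a", ops.WE,
                                                      np.vstack([ph, pd]))
        else:
            dist = ops.WB.T @ tau_history
        return ops.A_d @ x + dist

    def control(self, t, theta_meas, theta_dot_meas, tau_history, profile) -> float:
        tau_history = np.asarray(tau_history, dtype=float)
        if tau_history.shape != (self.delay_steps,):
            raise ValueError("tau_history must span exactly the delay")
        if self.config.delay_compensation:
            x_est = self.estimate_state(
                t, theta_meas, theta_dot_meas, tau_history, profile
            )
            t_sense = t
        else:
            # stale measurements treated as current
            x_est = np.array([theta_meas, theta_dot_meas], dtype=float)
            t_sense = t - self.config.delay
        hp = self.gains.hp_steps
        mode = self.config.preview
        if mode == "full":
            pt = t + self.config.dt * np.arange(hp)
            phi_prev = np.asarray(profile.angle(pt), dtype=float)
            phid_prev = np.asarray(profile.rate(pt), dtype=float)
        elif mode == "measured":
            phi_prev = np.full(hp, float(profile.angle(t_sense)))
            phid_prev = np.full(hp, float(profile.rate(t_sense)))
        else:
            phi_prev = np.zeros(hp)
            phid_prev = np.zeros(hp)
        u = mpc_control(self.gains, x_est, phi_prev, phid_prev, self._tau_prev)
        self._tau_prev = u
        return u


class PDController:
    """PD feedback (linear or nonlinear variant) on the delayed measurement.

    The physiological sensory delay applies but is not compensated: these
    baselines have no internal model.
    """

    def __init__(
        self,
        params: PendulumParams,
        config: PDConfig | None = None,
        *,
        delay: float = DEFAULT_DELAY,
        dt: float = 1e-3,
    ):
        self.params = params
        self.config = config if config is not None else PDConfig()
        steps = delay / dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("delay must be a whole number of steps")
        self.delay_steps = round(steps)

    def reset(self) -> None:
        pass

    def control(self, t, theta_meas, theta_dot_meas, tau_history, profile) -> float:
        if self.config.variant == "linear":
            return pd_control(self.config, self.params, theta_meas, theta_dot_meas)
        return nonlinear_pd_control(
            self.config, self.params, theta_meas, theta_dot_meas
        )


@dataclass
class RolloutResult:
    """Batched closed-loop MPC simulation: one column per noise realization."""

    times: np.ndarray
    theta: np.ndarray       # (n_samples, n_rep)
    theta_dot: np.ndarray
    tau: np.ndarray
    fell: np.ndarray        # (n_rep,) bool, angle passed the fall limit

    def mean_theta(self) -> np.ndarray:
        return self.theta.mean(axis=1)

    def max_abs_theta(self) -> np.ndarray:
        return np.max(np.abs(self.theta), axis=0)

    def max_abs_tau(self) -> np.ndarray:
        return np.max(np.abs(self.tau), axis=0)


def mpc_rollout(
    params: PendulumParams,
    mpc_config: MPCConfig,
    profile: FloorProfile,
    sim_config,
    seeds,
) -> RolloutResult:
    """Simulate the MPC closed loop for several noise seeds at once.

    Numerically equivalent to :func:`tiltstand.model.simulate` with an
    :class:`MPCController` (verified in the test suite), but vectorized over
    noise realizations and with the preview and delay-window floor terms,
    which do not depend on the realization, computed once per run.  This is
    the engine behind GA identification and the parameter sweeps.
    """
    from .model import FALL_ANGLE  # local import to avoid a cycle

    dt = sim_config.dt
    n = sim_config.n_steps
    times = sim_config.times
    d = mpc_config.delay_steps
    hp = mpc_config.hp_steps

    model = linearize_internal_model(params, dt)
    gains = mpc_gain(model, mpc_config)
    ops = _DelayOps(model, d)

    # floor grids on the extended lattice t_start + dt*(-d .. n + hp)
    ext = sim_config.t_start + dt * np.arange(-d, n + hp + 1)
    phi_g = np.asarray(profile.angle(ext), dtype=float)
    phid_g = np.asarray(profile.rate(ext), dtype=float)
    phi_half = np.asarray(profile.angle(times[:-1] + 0.5 * dt), dtype=float)
    phid_half = np.asarray(profile.rate(times[:-1] + 0.5 * dt), dtype=float)

    win = np.lib.stride_tricks.sliding_window_view
    if mpc_config.preview == "full":
        # preview feedforward c[k] = k_phi . phi(t_k .. t_k + (hp-1)dt) + ...
        c_prev = win(phi_g[d:], hp)[: n + 1] @ gains.k_phi + win(phid_g[d:], hp)[
            : n + 1
        ] @ gains.k_phi_dot
    elif mpc_config.preview == "measured":
        # sensed floor state held constant over the horizon; without delay
        # compensation the sensed value is the delayed one
        off = 0 if mpc_config.delay_compensation else -d
        c_prev = (
            gains.k_phi.sum() * phi_g[d + off : d + off + n + 1]
            + gains.k_phi_dot.sum() * phid_g[d + off : d + off + n + 1]
        )
    else:
        c_prev = np.zeros(n + 1)
    if mpc_config.delay_compensation and mpc_config.preview != "none" and d > 0:
        # delay-window floor contribution to the state estimate
        dist = np.stack([win(phi_g, d)[: n + 1], win(phid_g, d)[: n + 1]], axis=2)
        e_k = np.einsum("jab,kjb->ka", ops.WE, dist)  # (n+1, 2)
    else:
        e_k = np.zeros((n + 1, 2))

    seeds = list(seeds)
    S = len(seeds)
    eta = np.stack(
        [np.random.default_rng(s).standard_normal(n) for s in seeds], axis=1
    )
    noise = params.sigma * sim_config.noise_gain() * eta  # (n, S)

    theta = np.zeros((n + 1, S))
    theta_dot = np.zeros((n + 1, S))
    tau = np.zeros((n + 1, S))
    tau_hist = np.zeros((d, S))
    u_prev = np.zeros(S)
    alive = np.ones(S, dtype=bool)
    mgh, J, k_p, k_d = params.mgh, params.J, params.k_p, params.k_d

    for k in range(n + 1):
        if k >= d:
            x_meas = np.vstack([theta[k - d], theta_dot[k - d]])
        else:
            x_meas = np.zeros((2, S))
        if mpc_config.delay_compensation:
            x_est = ops.A_d @ x_meas + e_k[k][:, None]
            if d > 0:
                x_est += ops.WB.T @ tau_hist
        else:
            x_est = x_meas
        u = gains.k_state @ x_est + gains.k_u_prev * u_prev + c_prev[k]
        u_prev = u
        tau[k] = u
        if k == n:
            break
        tt = u + noise[k]
        th, om = theta[k], theta_dot[k]
        # mid-interval floor rate is exact over the whole step (see rk4_step)
        p0, rr, ph_, p1 = (
            phi_g[d + k], phid_half[k], phi_half[k], phi_g[d + k + 1],
        )

        def f(th_, om_, p, r):
            tf = -k_p * (th_ - p) - k_d * (om_ - r)
            return om_, (mgh * np.sin(th_) + tt + tf) / J

        k1t, k1o = f(th, om, p0, rr)
        k2t, k2o = f(th + 0.5 * dt * k1t, om + 0.5 * dt * k1o, ph_, rr)
        k3t, k3o = f(th + 0.5 * dt * k2t, om + 0.5 * dt * k2o, ph_, rr)
        k4t, k4o = f(th + dt * k3t, om + dt * k3o, p1, rr)
        th1 = th + dt / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t)
        om1 = om + dt / 6.0 * (k1o + 2 * k2o + 2 * k3o + k4o)
        just_fell = alive & (np.abs(th1) > FALL_ANGLE)
        alive = alive & ~just_fell
        keep = alive | just_fell  # record the fall sample itself, then freeze
        theta[k + 1] = np.where(keep, th1, theta[k])
        theta_dot[k + 1] = np.where(keep, om1, theta_dot[k])
        if d > 0:
            tau_hist = np.roll(tau_hist, -1, axis=0)
            tau_hist[-1] = u
    return RolloutResult(
        times=times, theta=theta, theta_dot=theta_dot, tau=tau,
        fell=~alive,
    )
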