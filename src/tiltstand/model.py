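"""Single-link inverted-pendulum stance dynamics under floor tilt.

The standing animal is reduced to one rigid link pivoting at the
metatarsophalangeal (MTP) joint, with the body angle ``theta`` measured from
the vertical (backward rotation positive).  The equation of motion is

    J * theta'' = m*g*h * sin(theta) + tau + tau_floor + noise_torque

where ``tau`` is the active control torque, ``noise_torque`` is additive
Gaussian torque noise of magnitude ``sigma``, and the passive ankle/MTP
visco-elasticity couples the body to the floor angle ``phi``:

    tau_floor = -k_p*(theta - phi) - k_d*(theta_dot - phi_dot)

On a level floor (phi = 0) this stiffness stabilizes stance; during a tilt
it injects a disturbance torque proportional to the floor angle.

All internal quantities are SI (radians, seconds, N.m); degrees appear only
at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GRAVITY",
    "RAT_MASS",
    "RAT_COM_HEIGHT",
    "FALL_ANGLE",
    "PendulumParams",
    "FloorProfile",
    "SimulationConfig",
    "Trajectory",
    "SimulationError",
    "make_floor_profile",
    "floor_torque",
    "pendulum_accel",
    "simulate",
    "is_stable",
]

GRAVITY = 9.81
#: mean body mass (kg) and MTP-to-CoM length (m) of the study animals
RAT_MASS = 0.404
RAT_COM_HEIGHT = 0.107

#: beyond this angle the body has unambiguously fallen; integration freezes
#: there to avoid floating overflow in divergent closed loops
FALL_ANGLE = 2.0 * math.pi


class SimulationError(RuntimeError):
    """Raised when a closed-loop integration cannot proceed."""


@dataclass(frozen=True)
class PendulumParams:
    """Physical constants of the single-link body model.

    Parameters
    ----------
    m : body mass, kg
    h : MTP-to-CoM length, m
    g : gravitational acceleration, m/s^2
    J : moment of inertia about the MTP joint, kg.m^2; defaults to the
        point-mass value ``m*h**2`` consistent with the single-link
        MTP-to-CoM reduction
    k_p : passive MTP elastic coefficient, N.m/rad
    k_d : passive MTP viscous coefficient, N.m.s/rad
    sigma : torque-noise magnitude, N.m.  Under the default ``per-sample``
        noise scaling this is the SD of the torque noise held over each
        1 ms step; under the continuous-time ``sqrt-dt`` scaling the
        per-step SD is ``sigma/sqrt(dt)``.
    """

    m: float = RAT_MASS
    h: float = RAT_COM_HEIGHT
    g: float = GRAVITY
    J: float | None = None
    k_p: float = 0.0
    k_d: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.J is None:
            object.__setattr__(self, "J", self.m * self.h**2)
        for name in ("m", "h", "g", "J"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("k_p", "k_d", "sigma"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def mgh(self) -> float:
        """Gravitational toppling stiffness m*g*h, N.m/rad."""
        return self.m * self.g * self.h

    @classmethod
    def rat(
        cls,
        kp_mgh: float = 0.34,
        kd_mgh: float = 0.03,
        sigma_mnm: float = 0.50,
        *,
        m: float = RAT_MASS,
        h: float = RAT_COM_HEIGHT,
        g: float = GRAVITY,
        J: float | None = None,
    ) -> "PendulumParams":
        """Body at the identified mean passive parameters.

        Stiffness and viscosity are given as dimensionless multiples of
        ``m*g*h``, the noise magnitude in mN.m.
        """
        mgh = m * g * h
        return cls(
            m=m, h=h, g=g, J=J,
            k_p=kp_mgh * mgh, k_d=kd_mgh * mgh, sigma=sigma_mnm * 1e-3,
        )

    def with_normalized(
        self,
        kp_mgh: float | None = None,
        kd_mgh: float | None = None,
        sigma_mnm: float | None = None,
    ) -> "PendulumParams":
        kwargs = {}
        if kp_mgh is not None:
            kwargs["k_p"] = kp_mgh * self.mgh
        if kd_mgh is not None:
            kwargs["k_d"] = kd_mgh * self.mgh
        if sigma_mnm is not None:
            kwargs["sigma"] = sigma_mnm * 1e-3
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FloorProfile:
    """Floor tilt ramp: zero before ``onset``, linear rise to ``amplitude``
    over ``duration``, constant thereafter.  Positive angle = toes-up
    (backward) rotation."""

    onset: float = 0.0
    duration: float = 0.25
    amplitude: float = math.radians(8.8)

    def __post_init__(self) -> None:
        if not self.duration > 0.0:
            raise ValueError("duration must be strictly positive")

    def angle(self, t):
        """Floor angle phi(t), rad (scalar or array)."""
        t = np.asarray(t, dtype=float)
        frac = np.clip((t - self.onset) / self.duration, 0.0, 1.0)
        out = self.amplitude * frac
        return out if out.ndim else float(out)

    def rate(self, t):
        """Floor angular velocity phi_dot(t), rad/s: amplitude/duration on
        the ramp, zero elsewhere.  Right-continuous at the corners (the
        value at a corner belongs to the interval it starts)."""
        t = np.asarray(t, dtype=float)
        on = (t >= self.onset) & (t < self.onset + self.duration)
        out = np.where(on, self.amplitude / self.duration, 0.0)
        return out if out.ndim else float(out)


def make_floor_profile(
    onset: float, duration: float, amplitude_deg: float
) -> FloorProfile:
    """Build a tilt ramp from an amplitude given in degrees."""
    return FloorProfile(
        onset=onset, duration=duration, amplitude=math.radians(amplitude_deg)
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Fixed-step simulation window settings.

    The default window [-0.35, 0.45] s brackets the tilt onset at t = 0 and
    matches the identification window; dt = 1 ms is the shared sampling time
    of the plant and the controller.
    """

    dt: float = 1e-3
    t_start: float = -0.35
    t_end: float = 0.45
    noise_seed: int | None = None
    noise_scaling_mode: str = "per-sample"

    def __post_init__(self) -> None:
        if not self.dt > 0.0:
            raise ValueError("dt must be strictly positive")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        n = (self.t_end - self.t_start) / self.dt
        if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
            raise ValueError("window length must be divisible by dt")
        if self.noise_scaling_mode not in ("per-sample", "sqrt-dt"):
            raise ValueError("noise_scaling_mode must be 'per-sample' or 'sqrt-dt'")

    @property
    def n_steps(self) -> int:
        return round((self.t_end - self.t_start) / self.dt)

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_steps + 1)

    def noise_gain(self) -> float:
        """Multiplier converting sigma into the per-step noise torque SD."""
        if self.noise_scaling_mode == "sqrt-dt":
            return 1.0 / math.sqrt(self.dt)
        return 1.0


@dataclass
class Trajectory:
    """Uniformly sampled closed-loop record (SI units, backward positive)."""

    times: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    tau: np.ndarray
    tau_floor: np.ndarray
    phi: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("theta", "theta_dot", "tau", "tau_floor", "phi"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name!r} length differs from times")
        if n >= 2:
            dts = np.diff(self.times)
            if np.ptp(dts) > 1e-12:
                raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def max_abs_theta(self) -> float:
        return float(np.max(np.abs(self.theta)))


def floor_torque(params: PendulumParams, theta, theta_dot, phi, phi_dot):
    """Passive MTP torque -k_p*(theta-phi) - k_d*(theta_dot-phi_dot), N.m."""
    args = (theta, theta_dot, phi, phi_dot)
    if not all(np.all(np.isfinite(a)) for a in args):
        raise ValueError("floor_torque requires finite inputs")
    return -params.k_p * (np.asarray(theta) - phi) - params.k_d * (
        np.asarray(theta_dot) - phi_dot
    )


def pendulum_accel(params: PendulumParams, theta, tau, tau_floor, noise_torque=0.0):
    """Angular acceleration (m*g*h*sin(theta) + tau + tau_floor + noise)/J."""
    return (params.mgh * np.sin(theta) + tau + tau_floor + noise_torque) / params.J


def _drift(params, theta, theta_dot, tau_total, phi, phi_dot):
    tf = -params.k_p * (theta - phi) - params.k_d * (theta_dot - phi_dot)
    acc = (params.mgh * np.sin(theta) + tau_total + tf) / params.J
    return theta_dot, acc


def rk4_step(params, theta, theta_dot, tau_total, profile, t, dt):
    """One classical RK4 step of the drift with the torque held constant over
    the step and the floor ramp evaluated at the substep times."""
    th, om = theta, theta_dot
    # the floor rate is piecewise constant with corners on the step grid, so
    # the mid-interval value is exact for the whole open interval; using it
    # at every stage keeps the discontinuity out of the integrator
    rr = profile.rate(t + 0.5 * dt)
    p0 = profile.angle(t)
    ph = profile.angle(t + 0.5 * dt)
    p1 = profile.angle(t + dt)
    k1t, k1o = _drift(params, th, om, tau_total, p0, rr)
    k2t, k2o = _drift(params, th + 0.5 * dt * k1t, om + 0.5 * dt * k1o, tau_total, ph, rr)
    k3t, k3o = _drift(params, th + 0.5 * dt * k2t, om + 0.5 * dt * k2o, tau_total, ph, rr)
    k4t, k4o = _drift(params, th + dt * k3t, om + dt * k3o, tau_total, p1, rr)
    return (
        th + dt / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t),
        om + dt / 6.0 * (k1o + 2 * k2o + 2 * k3o + k4o),
    )


def simulate(
    params: PendulumParams,
    controller,
    profile: FloorProfile,
    config: SimulationConfig,
) -> Trajectory:
    """Fixed-step closed-loop integration over the simulation window.

    ``controller`` follows the protocol of :mod:`tiltstand.controllers`:
    an integer attribute ``delay_steps`` and a method
    ``control(t, theta_meas, theta_dot_meas, tau_history, profile) -> float``
    receiving the sensory-delayed state and the applied-torque history over
    the delay window.  The body is assumed at rest (theta = theta_dot = 0)
    at and before ``t_start``.

    With a fixed ``noise_seed`` the output is reproducible bit-for-bit.
    Trajectories whose angle passes ``FALL_ANGLE`` are frozen at the fall
    state for the remaining samples (the body is on the floor; continuing
    the integration would only overflow).
    """
    n = config.n_steps
    times = config.times
    rng = np.random.default_rng(config.noise_seed)
    eta = rng.standard_normal(n)
    noise = params.sigma * config.noise_gain() * eta

    d = int(getattr(controller, "delay_steps", 0))
    if hasattr(controller, "reset"):
        controller.reset()

    theta = np.zeros(n + 1)
    theta_dot = np.zeros(n + 1)
    tau = np.zeros(n + 1)
    # applied-torque history over the delay window, oldest first
    tau_hist = np.zeros(d)
    fallen = False
    for k in range(n + 1):
        t = float(times[k])
        if fallen:
            theta[k] = theta[k - 1]
            theta_dot[k] = theta_dot[k - 1]
            tau[k] = tau[k - 1]
            continue
        if k >= d:
            th_m, om_m = theta[k - d], theta_dot[k - d]
        else:  # at rest before the window start
            th_m, om_m = 0.0, 0.0
        u = controller.control(t, th_m, om_m, tau_hist, profile)
        if not np.isfinite(u):
            raise SimulationError(
                f"controller returned non-finite torque at step {k} (t={t:.3f} s)"
            )
        tau[k] = u
        if k == n:
            break
        th1, om1 = rk4_step(
            params, theta[k], theta_dot[k], u + noise[k], profile, t, config.dt
        )
        theta[k + 1], theta_dot[k + 1] = th1, om1
        if d > 0:
            tau_hist = np.roll(tau_hist, -1)
            tau_hist[-1] = u
        if abs(th1) > FALL_ANGLE:
            fallen = True

    phi = profile.angle(times)
    phi_dot = profile.rate(times)
    tf = -params.k_p * (theta - phi) - params.k_d * (theta_dot - phi_dot)
    return Trajectory(
        times=times,
        theta=theta,
        theta_dot=theta_dot,
        tau=tau,
        tau_floor=tf,
        phi=np.asarray(phi, dtype=float),
        seed=config.noise_seed,
    )


def is_stable(traj: Trajectory, angle_limit: float = math.pi / 2) -> bool:
    """True unless |theta| exceeds ``angle_limit`` at any sample."""
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    return bool(traj.max_abs_theta() <= angle_limit)
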