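"""Independent numerical oracles used by several test modules."""

import math

import numpy as np


def _qp_oracle_first_move(model, config, x0, phi_prev, phid_prev, u_prev):
    """Independent solution of the finite-horizon problem: the cost is
    evaluated by forward-simulating the internal model; the exact Hessian
    and gradient of the quadratic are extracted by finite differences and
    the normal equations solved directly."""
    hp, hu = config.hp_steps, config.hu_steps

    def cost(u_free):
        u = np.concatenate([u_free, np.full(hp - hu, u_free[-1])])
        x = np.asarray(x0, dtype=float)
        c = 0.0
        prev = u_prev
        for k in range(hp):
            x = model.A @ x + model.B * u[k] + model.E @ np.array(
                [phi_prev[k], phid_prev[k]]
            )
            c += config.state_weight * x[0] ** 2
        for i in range(hu):
            c += config.move_weight * (u_free[i] - prev) ** 2
            prev = u_free[i]
            c += config.input_regularizer * u_free[i] ** 2
        return c

    e = np.eye(hu)
    c0 = cost(np.zeros(hu))
    grad = np.array(
        [(cost(e[i]) - cost(-e[i])) / 2.0 for i in range(hu)]
    )
    H = np.empty((hu, hu))
    ci = [cost(e[i]) for i in range(hu)]
    # exact for a quadratic: central second differences with unit steps
    for i in range(hu):
        H[i, i] = cost(e[i]) + cost(-e[i]) - 2 * c0
        for j in range(i + 1, hu):
            H[i, j] = H[j, i] = cost(e[i] + e[j]) - ci[i] - ci[j] + c0
    u = np.linalg.solve(H, -grad)
    return float(u[0])


def _reference_closed_loop(params, controller, profile, config):
    """Oracle: same discrete control law, but the plant is propagated over
    each 1 ms hold interval by a high-order adaptive integrator."""
    from scipy.integrate import solve_ivp

    n = config.n_steps
    times = config.times
    d = controller.delay_steps
    controller.reset()
    theta = np.zeros(n + 1)
    theta_dot = np.zeros(n + 1)
    tau_hist = np.zeros(d)
    for k in range(n):
        t = float(times[k])
        th_m, om_m = (theta[k - d], theta_dot[k - d]) if k >= d else (0.0, 0.0)
        u = controller.control(t, th_m, om_m, tau_hist, profile)
        # within one hold interval the floor rate is constant (corners lie
        # on the sampling grid); freezing it keeps the rhs smooth
        rate = profile.rate(t + 0.5 * config.dt)

        def rhs(s, y):
            tf = -params.k_p * (y[0] - profile.angle(s)) - params.k_d * (
                y[1] - rate
            )
            return [y[1], (params.mgh * math.sin(y[0]) + u + tf) / params.J]

        sol = solve_ivp(
            rhs, (t, t + config.dt), [theta[k], theta_dot[k]],
            method="DOP853", rtol=1e-11, atol=1e-13,
        )
        theta[k + 1], theta_dot[k + 1] = sol.y[:, -1]
        if d > 0:
            tau_hist = np.roll(tau_hist, -1)
            tau_hist[-1] = u
    return theta
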