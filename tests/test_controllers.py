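"""Receding-horizon controller: internal model, closed-form gains vs an
independent quadratic-program oracle, delay predictor, PD baselines."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from tiltstand.controllers import (
    MPCConfig,
    MPCController,
    PDConfig,
    PDController,
    delay_compensate,
    linearize_internal_model,
    mpc_control,
    mpc_gain,
    mpc_rollout,
    nonlinear_pd_control,
    pd_control,
)
from tiltstand.model import FloorProfile, PendulumParams, SimulationConfig, simulate

from _oracles import _qp_oracle_first_move

MGH = 0.404 * 9.81 * 0.107


class TestInternalModel:
    def test_stiffness_cancels_at_unit_normalized_kp(self):
        p = PendulumParams.rat(kp_mgh=1.0, kd_mgh=0.0, sigma_mnm=0.0)
        m = linearize_internal_model(p, 1e-3)
        # continuous stiffness (mgh - k_p)/J = 0: theta'' has no theta term,
        # so over one step A[1, 0] stays 0 to first order
        assert abs(m.A[1, 0]) < 1e-12

    def test_identified_stiffness_coefficient(self):
        p = PendulumParams.rat(sigma_mnm=0.0)
        assert (p.mgh - p.k_p) / p.J == pytest.approx(60.51, abs=0.05)

    def test_zoh_step_matches_matrix_exponential(self, rat):
        m = linearize_internal_model(rat, 1e-3)
        # oracle: exponential of the augmented (state + held input) system
        J = rat.J
        a = (rat.mgh - rat.k_p) / J
        b = -rat.k_d / J
        Ac = np.array([[0.0, 1.0], [a, b]])
        Bc = np.array([[0.0, 0.0, 0.0], [1 / J, rat.k_p / J, rat.k_d / J]])
        aug = np.zeros((5, 5))
        aug[:2, :2] = Ac
        aug[:2, 2:] = Bc
        M = expm(aug * 1e-3)
        assert np.allclose(m.A, M[:2, :2], atol=1e-10)
        assert np.allclose(np.column_stack([m.B, m.E]), M[:2, 2:], atol=1e-10)


class TestMPCGainVsQPOracle:
    @pytest.mark.parametrize(
        "hp_steps,hu_steps",
        [(1, 1), (5, 2), (30, 10), (120, 24), (200, 24), (200, 1)],
    )
    def test_first_move_matches_numeric_qp(self, rat, hp_steps, hu_steps):
        cfg = MPCConfig(
            hp=hp_steps * 1e-3, hu=hu_steps * 1e-3, move_weight=3.0,
            input_regularizer=1e-8,
        )
        model = linearize_internal_model(rat, cfg.dt)
        gains = mpc_gain(model, cfg)
        rng = np.random.default_rng(hp_steps * 100 + hu_steps)
        x0 = rng.normal(scale=0.05, size=2)
        phi = rng.normal(scale=0.05, size=hp_steps)
        phid = rng.normal(scale=0.2, size=hp_steps)
        u_prev = rng.normal(scale=0.01)
        closed = mpc_control(gains, x0, phi, phid, u_prev)
        oracle = _qp_oracle_first_move(model, cfg, x0, phi, phid, u_prev)
        assert closed == pytest.approx(oracle, abs=1e-8)

    def test_zero_state_zero_preview_gives_zero(self, rat, mpc_config):
        model = linearize_internal_model(rat, mpc_config.dt)
        gains = mpc_gain(model, mpc_config)
        hp = gains.hp_steps
        assert mpc_control(gains, [0.0, 0.0], np.zeros(hp), np.zeros(hp)) == 0.0

    def test_single_step_horizon_hand_solution(self, rat):
        # Hp = Hu = 1, no move penalty: minimize (CAx + CBu)^2 + eps*u^2
        cfg = MPCConfig(hp=1e-3, hu=1e-3, move_weight=0.0, input_regularizer=1e-12)
        model = linearize_internal_model(rat, cfg.dt)
        gains = mpc_gain(model, cfg)
        x0 = np.array([0.02, -0.1])
        cb = model.B[0]
        ca = (model.A @ x0)[0]
        expected = -ca * cb / (cb * cb + 1e-12)
        got = mpc_control(gains, x0, np.zeros(1), np.zeros(1))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_wrong_preview_length_rejected(self, rat, mpc_config):
        model = linearize_internal_model(rat, mpc_config.dt)
        gains = mpc_gain(model, mpc_config)
        with pytest.raises(ValueError, match="length"):
            mpc_control(gains, [0.0, 0.0], np.zeros(3), np.zeros(3))

    def test_statelessness_of_gain_map(self, rat, mpc_config):
        model = linearize_internal_model(rat, mpc_config.dt)
        gains = mpc_gain(model, mpc_config)
        hp = gains.hp_steps
        rng = np.random.default_rng(0)
        args = (rng.normal(size=2), rng.normal(size=hp), rng.normal(size=hp), 0.3)
        assert mpc_control(gains, *args) == mpc_control(gains, *args)

    def test_anticipatory_torque_with_future_preview(self, rat):
        # zero state, a ramp entering the preview window: the controller
        # moves before the disturbance reaches the plant
        cfg = MPCConfig(preview="full")
        model = linearize_internal_model(rat, cfg.dt)
        gains = mpc_gain(model, cfg)
        hp = gains.hp_steps
        prof = FloorProfile()
        pt = -0.3 + cfg.dt * np.arange(hp)  # onset at 0 enters the window
        tau = mpc_control(
            gains, [0.0, 0.0], prof.angle(pt), prof.rate(pt)
        )
        assert tau != 0.0


class TestDelayCompensate:
    def test_zero_delay_identity(self, rat):
        m = linearize_internal_model(rat, 1e-3)
        x = np.array([0.1, -0.2])
        out = delay_compensate(m, x, np.zeros(0), np.zeros(0), np.zeros(0))
        assert np.array_equal(out, x)

    def test_zero_histories_zero_state(self, rat):
        m = linearize_internal_model(rat, 1e-3)
        out = delay_compensate(
            m, [0.0, 0.0], np.zeros(40), np.zeros(40), np.zeros(40)
        )
        assert np.allclose(out, 0.0)

    def test_history_length_mismatch_rejected(self, rat):
        m = linearize_internal_model(rat, 1e-3)
        with pytest.raises(ValueError):
            delay_compensate(m, [0.0, 0.0], np.zeros(40), np.zeros(39), np.zeros(40))

    def test_closed_loop_estimate_tracks_true_state(self):
        """On a small-amplitude noise-free tilt (where the linearization is
        essentially exact) the compensated estimate equals the true plant
        state to 1e-6 rad."""
        p = PendulumParams.rat(sigma_mnm=0.0)
        prof = FloorProfile(amplitude=math.radians(1.0))
        cfg = SimulationConfig()
        mpc = MPCConfig(preview="measured", delay_compensation=True)
        ctrl = MPCController(p, mpc)
        traj = simulate(p, ctrl, prof, cfg)
        model = ctrl.model
        d = ctrl.delay_steps
        worst = 0.0
        for k in range(d, cfg.n_steps + 1, 25):
            t = traj.times[k]
            ht = t + cfg.dt * (np.arange(d) - d)
            est = delay_compensate(
                model,
                [traj.theta[k - d], traj.theta_dot[k - d]],
                traj.tau[k - d : k],
                prof.angle(ht),
                prof.rate(ht),
            )
            worst = max(worst, abs(est[0] - traj.theta[k]))
        assert worst < 1e-6


class TestPDControllers:
    def test_zero_state_zero_torque(self, rat):
        assert pd_control(PDConfig(), rat, 0.0, 0.0) == 0.0
        assert nonlinear_pd_control(PDConfig(variant="nonlinear"), rat, 0.0, 0.0) == 0.0

    def test_peterka_proportional_value(self, rat):
        tq = pd_control(PDConfig(), rat, 0.1, 0.0)
        assert tq == pytest.approx(-0.06191, abs=2e-5)

    def test_peterka_derivative_value(self, rat):
        tq = pd_control(PDConfig(), rat, 0.0, 0.1)
        assert tq == pytest.approx(-0.012722, abs=2e-6)

    def test_nonlinear_value(self, rat):
        tq = nonlinear_pd_control(PDConfig(variant="nonlinear"), rat, 0.05, 0.0)
        assert tq == pytest.approx(-0.22645, abs=2e-5)

    def test_nonlinear_odd_symmetry(self, rat):
        cfg = PDConfig(variant="nonlinear")
        for th in (0.01, 0.05, 0.3):
            assert nonlinear_pd_control(cfg, rat, -th, 0.0) == pytest.approx(
                -nonlinear_pd_control(cfg, rat, th, 0.0), rel=1e-12
            )

    def test_variant_mismatch_rejected(self, rat):
        with pytest.raises(ValueError):
            pd_control(PDConfig(variant="nonlinear"), rat, 0.1, 0.0)
        with pytest.raises(ValueError):
            nonlinear_pd_control(PDConfig(), rat, 0.1, 0.0)


class TestRolloutEquivalence:
    @pytest.mark.parametrize("preview", ["none", "measured", "full"])
    def test_batch_rollout_matches_generic_loop(self, rat_noisy, ramp, preview):
        cfg = MPCConfig(hp=0.3, preview=preview)
        sim_cfg = SimulationConfig(noise_seed=17)
        traj = simulate(rat_noisy, MPCController(rat_noisy, cfg), ramp, sim_cfg)
        roll = mpc_rollout(rat_noisy, cfg, ramp, SimulationConfig(), [17])
        # full preview samples the piecewise-constant floor rate at times
        # computed by two float routes, which may land on opposite sides of
        # a ramp corner; the looser bound covers that one-sample ambiguity
        tol = 2e-5 if preview == "full" else 1e-9
        assert np.max(np.abs(roll.theta[:, 0] - traj.theta)) < tol
        assert np.max(np.abs(roll.tau[:, 0] - traj.tau)) < max(tol, 1e-8)

    def test_columns_are_independent_realizations(self, rat_noisy, ramp):
        roll = mpc_rollout(
            rat_noisy, MPCConfig(hp=0.2), ramp, SimulationConfig(), [1, 2, 1]
        )
        assert np.array_equal(roll.theta[:, 0], roll.theta[:, 2])
        assert not np.array_equal(roll.theta[:, 0], roll.theta[:, 1])


class TestConfigValidation:
    def test_hu_exceeding_hp_rejected(self):
        with pytest.raises(ValueError):
            MPCConfig(hp=0.01, hu=0.02)

    def test_fractional_delay_rejected(self):
        with pytest.raises(ValueError):
            MPCConfig(delay=0.0405 / 81)

    def test_horizon_rounding_minimum_one_step(self):
        cfg = MPCConfig(hp=0.0004, hu=0.0004)
        assert cfg.hp_steps == 1
        assert cfg.hu_steps == 1
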