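"""Environments: curl field, delay bookkeeping, condition sampling
statistics, observation layout, and determinism."""

import numpy as np
import pytest

from diffeffector import tasks
from diffeffector.autodiff import data_of
from diffeffector.tasks import (CentreOutReach, FeedbackConfig, Postural,
                                RandomReach, TrialCondition, curl_field_force,
                                make_environment)


class TestCurlField:
    def test_unit_rightward_velocity(self):
        f = curl_field_force(np.array([[1.0, 0.0]]), b=8.0)
        np.testing.assert_allclose(np.asarray(f), [[0.0, 8.0]])

    def test_zero_strength(self, rng):
        v = rng.normal(size=(4, 2))
        np.testing.assert_array_equal(np.asarray(curl_field_force(v, 0.0)), 0.0)

    def test_orthogonality_and_magnitude(self, rng):
        v = rng.normal(size=(50, 2))
        f = np.asarray(curl_field_force(v, 8.0))
        np.testing.assert_allclose(np.einsum("ij,ij->i", f, v), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(f, axis=1),
                                   8.0 * np.linalg.norm(v, axis=1), rtol=1e-12)


class TestFeedbackConfig:
    def test_delay_steps(self):
        cfg = FeedbackConfig(delta_p=0.02, delta_v=0.05)
        assert cfg.steps(0.01) == (2, 5)

    def test_non_multiple_rejected(self):
        with pytest.raises(ValueError):
            FeedbackConfig(delta_v=0.053).steps(0.01)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            FeedbackConfig(sigma_v=-0.1).steps(0.01)


class TestObservation:
    def test_layout_size(self, arm26):
        env = RandomReach(arm26)
        obs, _ = env.reset(seed=0, batch_size=3)
        assert data_of(obs).shape == (3, 5 + 2 + 2 * 6)

    def test_visual_block_lags_by_delay(self, arm26, rng):
        """With noise off, the visual block at step t equals the true
        endpoint at t - 5 (50 ms / 10 ms steps)."""
        env = CentreOutReach(arm26, FeedbackConfig(), horizon=0.5)
        obs, info = env.reset(seed=1)
        true_positions = [info["cartesian_position"].copy()]
        observed = []
        for t in range(50):
            action = rng.uniform(0, 0.5, (8, 6))
            obs, _, _, _, info = env.step(action)
            true_positions.append(info["cartesian_position"].copy())
            observed.append(data_of(obs)[:, 5:7].copy())
        for t in range(5, 50):
            np.testing.assert_allclose(observed[t], true_positions[t + 1 - 5],
                                       atol=1e-12)

    def test_pre_delay_padding(self, arm26):
        env = CentreOutReach(arm26, FeedbackConfig())
        obs, info = env.reset(seed=0)
        start = info["cartesian_position"].copy()
        for t in range(4):
            obs, *_ = env.step(np.full((8, 6), 0.5))
            np.testing.assert_allclose(data_of(obs)[:, 5:7], start, atol=1e-12)

    def test_gocue_channel_flips_after_visual_delay(self, arm26):
        env = CentreOutReach(arm26, gocue_time=0.1, horizon=0.5)
        obs, _ = env.reset(seed=0)
        flips = []
        for t in range(1, 30):
            obs, *_ = env.step(np.zeros((8, 6)))
            flips.append(data_of(obs)[0, 4])
        # cue at step 10, visual delay 5 -> channel drops at step 15
        assert flips[13] == 1.0 and flips[14] == 0.0

    def test_desired_position_switches_instantly(self, arm26):
        env = CentreOutReach(arm26, gocue_time=0.1, horizon=0.3)
        env.reset(seed=0)
        for t in range(1, 30):
            _, _, _, _, info = env.step(np.zeros((8, 6)))
            expected = (env.conditions.target_pos if t >= 10 else env._start_pos)
            np.testing.assert_allclose(info["desired_position"], expected)

    def test_visual_noise_reproducible(self, arm26):
        cfg = FeedbackConfig(sigma_v=0.01)

        def first_obs(seed):
            env = RandomReach(arm26, cfg)
            env.reset(seed=seed, batch_size=2)
            obs, *_ = env.step(np.zeros((2, 6)))
            return data_of(obs).copy()

        np.testing.assert_array_equal(first_obs(7), first_obs(7))
        assert not np.array_equal(first_obs(7), first_obs(8))


class TestConditionSampling:
    def test_catch_fraction(self, arm26):
        env = RandomReach(arm26)
        cond = env.sample_condition(10_000, np.random.default_rng(0))
        frac = cond.is_catch.mean()
        # binomial 99% CI around 0.5 at n = 10^4
        assert abs(frac - 0.5) < 2.58 * 0.5 / np.sqrt(10_000)

    def test_perturbation_magnitudes(self, arm26):
        env = RandomReach(arm26, perturbations=True)
        cond = env.sample_condition(10_000, np.random.default_rng(1))
        mag = cond.pert_magnitude
        non_catch = mag[(~cond.is_catch) & (mag > 0)]
        on_catch = mag[cond.is_catch & (mag > 0)]
        assert non_catch.max() <= 4.0
        assert on_catch.max() <= 8.0
        assert on_catch.max() > 4.0  # the wider distribution is exercised
        np.testing.assert_allclose(non_catch.mean(), 2.0, atol=0.1)

    def test_catch_trial_desired_is_start_forever(self, arm26):
        env = RandomReach(arm26, horizon=0.3)
        env.reset(seed=5, batch_size=16)
        catch = env.conditions.is_catch
        assert catch.any()
        truncated = False
        while not truncated:
            _, _, _, truncated, info = env.step(np.zeros((16, 6)))
            np.testing.assert_allclose(info["desired_position"][catch],
                                       env._start_pos[catch])

    def test_gocue_uniform_over_window(self, arm26):
        env = RandomReach(arm26, catch_prob=0.0, horizon=0.8)
        cond = env.sample_condition(5000, np.random.default_rng(2))
        g = cond.gocue_time
        assert g.min() >= 0 and g.max() <= 0.8
        np.testing.assert_allclose(g.mean(), 0.4, atol=0.03)


class TestEnvStep:
    def test_horizon_truncation(self, arm26):
        env = CentreOutReach(arm26, horizon=1.0)
        env.reset(seed=0)
        steps = 0
        truncated = False
        while not truncated:
            _, reward, terminated, truncated, _ = env.step(np.zeros((8, 6)))
            assert reward == 0.0 and not terminated
            steps += 1
        assert steps == 100
        with pytest.raises(RuntimeError):
            env.step(np.zeros((8, 6)))

    def test_info_is_instantaneous(self, arm26):
        env = CentreOutReach(arm26, horizon=0.3)
        env.reset(seed=0)
        for _ in range(10):
            obs, _, _, _, info = env.step(np.full((8, 6), 0.3))
        state_pos = data_of(env._state.cartesian.pos)
        np.testing.assert_array_equal(info["cartesian_position"], state_pos)
        assert not np.allclose(data_of(obs)[:, 5:7], state_pos)

    def test_deterministic_replay(self, arm26):
        def run(seed):
            env = RandomReach(arm26, horizon=0.2)
            env.reset(seed=seed, batch_size=4)
            traj = []
            truncated = False
            while not truncated:
                _, _, _, truncated, info = env.step(np.full((4, 6), 0.2))
                traj.append(info["cartesian_position"].copy())
            return np.stack(traj)

        np.testing.assert_array_equal(run(3), run(3))

    def test_perturbation_impulse_accounting(self, arm26):
        """The integral of the applied external force equals magnitude x
        100 ms along the perturbation direction."""
        cond = TrialCondition(
            start_joint=np.deg2rad([[45.0, 90.0]]),
            target_pos=[[0.3, 0.4]], gocue_time=[np.inf],
            pert_magnitude=[4.0], pert_direction=[np.pi / 3],
            pert_onset=[0.1], pert_duration=[0.1])
        env = RandomReach(arm26, horizon=0.4)
        env.reset(conditions=cond)
        impulse = np.zeros(2)
        truncated = False
        while not truncated:
            force = env._external_force()
            if force is not None:
                impulse += data_of(force)[0] * env.dt
            _, _, _, truncated, _ = env.step(np.zeros((1, 6)))
        expected = 4.0 * 0.1 * np.array([np.cos(np.pi / 3), np.sin(np.pi / 3)])
        np.testing.assert_allclose(impulse, expected, rtol=1e-9)

    def test_curl_power_is_zero_each_step(self, arm26, rng):
        env = CentreOutReach(arm26, horizon=0.3, curl_b=8.0)
        env.reset(seed=0)
        for _ in range(25):
            vel = data_of(env._state.cartesian.vel)
            force = env._external_force()
            power = np.einsum("ij,ij->i", data_of(force), vel)
            np.testing.assert_allclose(power, 0.0, atol=1e-12)
            env.step(rng.uniform(0, 0.4, (8, 6)))

    def test_delay_cross_correlation_peak(self, arm26):
        """Cross-correlation between true endpoint and the observed
        visual block peaks at exactly delta_v / dt steps."""
        env = CentreOutReach(arm26, horizon=0.8)
        obs, info = env.reset(seed=0)
        true_x, obs_x = [], []
        truncated = False
        while not truncated:
            obs, _, _, truncated, info = env.step(np.full((8, 6), 0.4))
            true_x.append(info["cartesian_position"][0, 0])
            obs_x.append(data_of(obs)[0, 5])
        true_x = np.array(true_x) - np.mean(true_x)
        obs_x = np.array(obs_x) - np.mean(obs_x)
        lags = range(0, 12)
        corr = [np.corrcoef(true_x[:len(true_x) - k], obs_x[k:])[0, 1]
                for k in lags]
        assert int(np.argmax(corr)) == 5


class TestConditionCSV:
    def test_round_trip(self, arm26, tmp_path):
        env = RandomReach(arm26, perturbations=True)
        cond = env.sample_condition(20, np.random.default_rng(0))
        path = tmp_path / "conditions.csv"
        cond.to_csv(path)
        back = TrialCondition.from_csv(path)
        for name in ("start_joint", "target_pos", "gocue_time", "pert_magnitude",
                     "pert_direction", "pert_onset", "pert_duration"):
            np.testing.assert_allclose(getattr(back, name), getattr(cond, name))


class TestPresets:
    def test_registry(self, arm26):
        for name in ("RandomReach", "DelayedReach", "CentreOutReach", "Postural"):
            env = make_environment(name, arm26)
            assert env.effector is arm26
        with pytest.raises(ValueError):
            make_environment("NoSuchTask", arm26)

    def test_postural_defaults(self, arm26):
        env = Postural(arm26, pert_magnitude=6.0, pert_direction=np.pi)
        env.reset(seed=0)
        cond = env.conditions
        assert cond.is_catch.all()
        np.testing.assert_allclose(cond.pert_onset, 0.17 + 0.05)
        np.testing.assert_allclose(cond.target_pos, env._start_pos)
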