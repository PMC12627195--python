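"""Synthetic experiment generator."""

import numpy as np
import pandas as pd
import pytest

import serialbias as sb
from serialbias.simulate import BiasProfile, STEP_OFFSETS


class TestTargetSequence:
    def test_one_random_trial_per_period(self):
        rng = np.random.default_rng(0)
        _, is_random = sb.generate_target_sequence(10, 10, rng)
        assert is_random.sum() == 1

    def test_offsets_on_step_grid(self):
        rng = np.random.default_rng(1)
        targets, is_random = sb.generate_target_sequence(400, 10, rng)
        x = sb.wrap_signed(targets[1:] - targets[:-1])
        ok = ~is_random[1:]
        assert set(np.round(x[ok], 9)) <= set(float(s) for s in STEP_OFFSETS)

    def test_step_conditions_roughly_balanced(self):
        rng = np.random.default_rng(1)
        targets, is_random = sb.generate_target_sequence(400, 10, rng)
        x = sb.wrap_signed(targets[1:] - targets[:-1])[~is_random[1:]]
        counts = pd.Series(np.round(x)).value_counts()
        assert len(counts) == 9
        assert counts.min() >= 0.8 * counts.mean()
        assert counts.max() <= 1.2 * counts.mean()

    def test_validation(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sb.generate_target_sequence(1, 10, rng)
        with pytest.raises(ValueError):
            sb.generate_target_sequence(100, 1, rng)


class TestReportErrors:
    def test_noise_free_limit_matches_dog(self):
        cfg = sb.SimConfig(n_participants=1, kappa=1e8, include_trajectories=False)
        rng = np.random.default_rng(2)
        targets, is_random = sb.generate_target_sequence(200, 10, rng)
        df = sb.simulate_errors(targets, is_random, "retrieval", cfg, rng)
        err = sb.signed_difference(df.response_deg[1:], df.target_deg[1:])
        x = sb.signed_difference(df.prev_target_deg[1:], df.target_deg[1:])
        expected = sb.dog(x, cfg.alpha_true["retrieval"], cfg.w_true, cfg.beta_true)
        np.testing.assert_allclose(err, expected, atol=0.1)

    def test_unbiased_case_has_zero_bin_means(self):
        cfg = sb.SimConfig(
            n_participants=1,
            alpha_true={"perceptual": 0, "consolidation": 0, "retrieval": 0},
            include_trajectories=False,
        )
        rng = np.random.default_rng(3)
        targets, is_random = sb.generate_target_sequence(4000, 10, rng)
        df = sb.simulate_errors(targets, is_random, "consolidation", cfg, rng)
        assigned = sb.assign_condition(df)
        means = assigned[assigned.included].groupby("condition_bin")["error_deg"].mean()
        # ~400 trials/bin at circular SD ~9 degrees -> MC error ~0.5 degrees
        assert np.abs(means).max() < 1.5

    def test_attraction_sign_at_pm36(self):
        cfg = sb.SimConfig(n_participants=1, kappa=1e6, include_trajectories=False)
        rng = np.random.default_rng(4)
        targets, is_random = sb.generate_target_sequence(400, 10, rng)
        df = sb.simulate_errors(targets, is_random, "retrieval", cfg, rng)
        assigned = sb.assign_condition(df)
        means = assigned[assigned.included].groupby("condition_bin")["error_deg"].mean()
        assert means.loc[-36.0] < 0 < means.loc[36.0]

    def test_unknown_report_type(self):
        cfg = sb.SimConfig(n_participants=1)
        with pytest.raises(ValueError, match="report type"):
            sb.simulate_errors([0, 36], [False, False], "recall", cfg,
                               np.random.default_rng(0))


class TestTrajectories:
    def _noise_free(self, **over):
        traj = sb.TrajectoryConfig(motor_noise_sd_px=0.0, pre_onset_jitter_px=0.0,
                                   move_duration_sigma=0.0, **over)
        return sb.SimConfig(n_participants=1, trajectory=traj)

    def test_unbiased_path_is_straight(self):
        cfg = self._noise_free(
            profiles={"perceptual": BiasProfile(0.0, 0.0)},
        )
        rng = np.random.default_rng(0)
        traj = sb.simulate_trajectory(36.0, 90.0, 0.0, "perceptual", 300.0, cfg, rng)
        aligned = sb.preprocess_trajectory(traj)
        np.testing.assert_allclose(aligned.h, 0.0, atol=1e-9)

    def test_constant_profile_endpoint_matches_dog(self):
        # early_mid == late_mid makes the two ramps sum to a constant amplitude
        const = BiasProfile(5.0, 5.0, early_mid=0.5, late_mid=0.5)
        cfg = self._noise_free(profiles={"retrieval": const})
        err = sb.dog(36.0, 5.0, cfg.w_true, 0.0)
        rng = np.random.default_rng(0)
        traj = sb.simulate_trajectory(36.0, 200.0, err, "retrieval", 250.0, cfg, rng)
        click = np.rad2deg(np.arctan2(traj.xs[-1], traj.ys[-1]))
        assert sb.signed_difference(click, 200.0) == pytest.approx(err, abs=1e-9)

    def test_consolidation_crossover_profile(self):
        cfg = self._noise_free()
        x = 72.0
        # endpoint error equal to the late amplitude's prediction: no homing ramp
        err = sb.dog(x, cfg.trajectory.profiles["consolidation"].late_amp, cfg.w_true, 0)
        rng = np.random.default_rng(0)
        traj = sb.simulate_trajectory(x, 0.0, err, "consolidation", 250.0, cfg, rng)
        aligned = sb.preprocess_trajectory(traj)
        h_02 = aligned.h[np.argmin(np.abs(aligned.t_norm - 0.2))]
        h_09 = aligned.h[np.argmin(np.abs(aligned.t_norm - 0.9))]
        assert h_02 < 0 < h_09


class TestExperiment:
    def test_default_wm_trial_count(self):
        cfg = sb.SimConfig(n_participants=2, include_trajectories=False)
        ds = sb.simulate_experiment(cfg)
        per = ds.trials.groupby(["participant", "report_type"]).size()
        assert (per.xs("consolidation", level=1) == 400).all()
        assert (per.xs("retrieval", level=1) == 400).all()
        assert (per.xs("perceptual", level=1) == 150).all()

    def test_determinism(self):
        cfg = sb.SimConfig(n_participants=2, n_perceptual_trials=30,
                           n_wm_trials=40, seed=5)
        d1 = sb.simulate_experiment(cfg)
        d2 = sb.simulate_experiment(cfg)
        pd.testing.assert_frame_equal(d1.trials, d2.trials)
        for key in d1.trajectories:
            np.testing.assert_array_equal(d1.trajectories[key].xs,
                                          d2.trajectories[key].xs)

    def test_bookkeeping(self, small_dataset):
        trials = small_dataset.trials
        assert trials.participant.nunique() == 4
        assert set(trials.report_type) == set(sb.REPORT_TYPES)
        # one trajectory per trial record
        assert len(small_dataset.trajectories) == len(trials)

    def test_excluding_random_leaves_only_step_conditions(self, small_dataset):
        assigned = sb.assign_condition(small_dataset.trials)
        kept = assigned[assigned.included]
        assert set(kept.condition_bin) == set(float(s) for s in STEP_OFFSETS)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sb.SimConfig(n_participants=0)
        with pytest.raises(ValueError):
            sb.SimConfig(random_trial_period=1)
        with pytest.raises(ValueError):
            sb.SimConfig(alpha_true={"perceptual": 0.0})
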