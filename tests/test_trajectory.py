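"""Trajectory preprocessing, AUC statistics, deviation profiles, median split."""

import numpy as np
import pandas as pd
import pytest

import serialbias as sb
from serialbias.trajectory import AlignedTrajectory


def make_traj(points, target=0.0, dt=10.0):
    pts = np.asarray(points, dtype=float)
    return sb.TrajectorySamples(
        timestamps=np.arange(len(pts)) * dt, xs=pts[:, 0], ys=pts[:, 1],
        target_angle=target,
    )


def ramp_aligned(h_fn, n=101):
    t = np.linspace(0, 1, n)
    return AlignedTrajectory(t_norm=t, h=h_fn(t), onset_latency_ms=100.0)


class TestOnset:
    def test_strict_threshold(self):
        # distances 0, 5, 10, 15: the 10-px sample does not trigger (strict >)
        traj = make_traj([(0, 0), (0, 5), (0, 10), (0, 15)])
        idx, latency = sb.detect_onset(traj)
        assert idx == 3
        assert latency == 30.0

    def test_immediate_movement(self):
        traj = make_traj([(0, 0), (20, 0), (40, 0)])
        idx, _ = sb.detect_onset(traj)
        assert idx == 1

    def test_never_moves_is_unusable(self):
        traj = make_traj([(0, 0), (3, 3), (5, 5), (7, 0)])
        with pytest.raises(sb.UnusableTrajectoryError):
            sb.detect_onset(traj)


class TestNormalizeTime:
    def test_midpoint_interpolation(self):
        traj = make_traj([(0, 0), (0, 20), (0, 100)])
        t, x, y = sb.normalize_time(traj, onset_index=1, n_grid=3)
        assert y[1] == pytest.approx(60.0)

    def test_endpoints_exact(self):
        traj = make_traj([(0, 0), (5, 30), (17, 90), (23, 150)])
        _, x, y = sb.normalize_time(traj, onset_index=1)
        assert (x[0], y[0]) == (5.0, 30.0)
        assert (x[-1], y[-1]) == (23.0, 150.0)

    def test_idempotent_on_grid(self):
        t = np.linspace(0, 1, 101)
        traj = sb.TrajectorySamples(timestamps=t * 500 + 100, xs=np.sin(t),
                                    ys=t * 200, target_angle=0.0)
        _, x, y = sb.normalize_time(traj, onset_index=0)
        np.testing.assert_allclose(x, np.sin(t), atol=1e-12)
        np.testing.assert_allclose(y, t * 200, atol=1e-12)

    def test_onset_equals_click_rejected(self):
        traj = make_traj([(0, 0), (0, 5), (0, 20)])
        with pytest.raises(sb.UnusableTrajectoryError):
            sb.normalize_time(traj, onset_index=2)  # onset at the click


class TestRotation:
    def test_on_target_ray_has_zero_h(self):
        rad = np.deg2rad(73.0)
        h, v = sb.rotate_to_target(50 * np.sin(rad), 50 * np.cos(rad), 73.0)
        assert h == pytest.approx(0.0, abs=1e-9)
        assert v == pytest.approx(50.0)

    def test_quarter_turn_clockwise(self):
        target = 30.0
        rad = np.deg2rad(target + 90.0)
        h, _ = sb.rotate_to_target(80 * np.sin(rad), 80 * np.cos(rad), target)
        assert h == pytest.approx(80.0)

    def test_radius_preserved(self):
        rng = np.random.default_rng(0)
        xs, ys = rng.normal(0, 50, 20), rng.normal(0, 50, 20)
        h, v = sb.rotate_to_target(xs, ys, 211.0)
        np.testing.assert_allclose(np.hypot(h, v), np.hypot(xs, ys), rtol=1e-12)


class TestAUC:
    def test_constant_offset(self):
        a = ramp_aligned(lambda t: np.full_like(t, 10.0))
        assert sb.compute_auc(a, include_endpoint=True) == pytest.approx(10.0)
        assert sb.compute_auc(a, include_endpoint=False) == pytest.approx(5.0)

    def test_straight_drift_has_no_path_bias(self):
        a = ramp_aligned(lambda t: 10.0 * t)
        assert sb.compute_auc(a, include_endpoint=True) == pytest.approx(5.0)
        assert sb.compute_auc(a, include_endpoint=False) == pytest.approx(0.0, abs=1e-12)

    def test_sine_bump_endpoint_free(self):
        a = ramp_aligned(lambda t: 10.0 * np.sin(np.pi * t))
        expected = 20.0 / np.pi
        assert sb.compute_auc(a, True) == pytest.approx(expected, abs=1e-3)
        assert sb.compute_auc(a, False) == pytest.approx(expected, abs=1e-3)

    def test_decomposition_identity(self, small_dataset):
        # AUC_with - AUC_without = h(1)/2 exactly under the trapezoid rule
        for key in list(small_dataset.trajectories)[::37]:
            aligned = sb.preprocess_trajectory(small_dataset.trajectories[key])
            res = sb.auc_result(aligned)
            assert (
                res.auc_with_endpoint - res.auc_without_endpoint
                == pytest.approx(res.endpoint_offset / 2.0, abs=1e-9)
            )

    def test_mirror_symmetry(self, small_dataset):
        key = list(small_dataset.trajectories)[3]
        traj = small_dataset.trajectories[key]
        aligned = sb.preprocess_trajectory(traj)
        # reflect the path about the target axis: h -> -h, v unchanged
        rad = np.deg2rad(traj.target_angle)
        h, v = sb.rotate_to_target(traj.xs, traj.ys, traj.target_angle)
        xs = -h * np.cos(rad) + v * np.sin(rad)
        ys = h * np.sin(rad) + v * np.cos(rad)
        mirrored = sb.TrajectorySamples(timestamps=traj.timestamps, xs=xs, ys=ys,
                                        target_angle=traj.target_angle)
        m_aligned = sb.preprocess_trajectory(mirrored)
        np.testing.assert_allclose(m_aligned.h, -aligned.h, atol=1e-9)
        assert sb.compute_auc(m_aligned, True) == pytest.approx(
            -sb.compute_auc(aligned, True))


class TestFeatureTables:
    def test_profile_node_100_is_endpoint(self, small_dataset):
        feats = sb.trajectory_features(small_dataset.trajectories)
        usable = feats[feats.usable]
        np.testing.assert_allclose(usable["h_100"], usable["endpoint"], atol=1e-9)

    def test_straight_paths_give_zero_tables(self):
        trials = []
        trajectories = {}
        rng = np.random.default_rng(0)
        targets, is_random = sb.generate_target_sequence(120, 10, rng)
        cfg = sb.SimConfig(
            n_participants=1,
            trajectory=sb.TrajectoryConfig(motor_noise_sd_px=0.0,
                                           pre_onset_jitter_px=0.0),
        )
        df = sb.simulate_errors(targets, is_random, "perceptual", cfg, rng)
        df["response_deg"] = df["target_deg"]  # force unbiased endpoints
        for i in range(120):
            trajectories[(0, "perceptual", i)] = sb.simulate_trajectory(
                np.nan, df.target_deg[i], 0.0, "perceptual", 300.0, cfg, rng
            )
        feats = sb.trajectory_features(trajectories)
        aucs = sb.auc_condition_summaries(feats, df)
        assert np.allclose(aucs.auc_with, 0.0, atol=1e-9)
        prof = sb.deviation_profiles(feats, df)
        assert np.allclose(prof.mean_dev, 0.0, atol=1e-9)

    def test_auc_sign_tracks_configured_bias(self, small_dataset):
        feats = sb.trajectory_features(small_dataset.trajectories)
        aucs = sb.auc_condition_summaries(feats, small_dataset.trials)
        ret = aucs[aucs.report_type == "retrieval"].groupby("bin_center").auc_with.mean()
        assert ret.loc[-36.0] < 0 < ret.loc[36.0]

    def test_cell_counts_match_included_trials(self, small_dataset):
        feats = sb.trajectory_features(small_dataset.trajectories)
        aucs = sb.auc_condition_summaries(feats, small_dataset.trials)
        assigned = sb.assign_condition(small_dataset.trials)
        merged = assigned[assigned.included & (assigned.report_type == "perceptual")]
        n_expected = merged[merged.participant == 0].shape[0]
        nine = aucs[(aucs.participant == 0) & (aucs.report_type == "perceptual")
                    & (aucs.bin_center < 180)]
        assert nine.n_trials.sum() == n_expected


class TestMedianSplit:
    def _features(self, latencies, participant=0):
        return pd.DataFrame({
            "participant": participant, "report_type": "consolidation",
            "trial_index": range(len(latencies)),
            "usable": True, "onset_latency_ms": latencies,
        })

    def test_even_split(self):
        out = sb.median_split_by_onset(self._features([100, 200, 300, 400]))
        assert out.onset_half.tolist() == ["early", "early", "late", "late"]
        assert out.onset_split_ok.all()

    def test_median_element_goes_early(self):
        out = sb.median_split_by_onset(self._features([100, 200, 300]))
        assert out.onset_half.tolist() == ["early", "early", "late"]

    def test_all_tied_flagged(self):
        out = sb.median_split_by_onset(self._features([250, 250, 250]))
        assert (out.onset_half == "early").all()
        assert not out.onset_split_ok.any()
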