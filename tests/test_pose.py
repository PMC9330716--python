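"""Frame-tensor preprocessing, ground-truth alignment, the 25->19 joint
reduction and the pose regressor."""

import numpy as np
import pytest

from mmgait.kinematics import (GaitScenario, K25, KINECT25_JOINTS,
                               SubjectSpec, synth_skeleton_trajectory)
from mmgait.pointcloud import PointCloudFrame
from mmgait.pose import (FrameTensor, align_ground_truth, build_pose_net,
                         predict_joints, predict_joints_batch,
                         preprocess_frame, reduce_25_to_19,
                         skeleton25_wrist_targets, train_pose)


def _frame(xyz, inten=None, ts=0.0):
    n = len(xyz)
    f = PointCloudFrame(timestamp=ts, xyz=np.asarray(xyz, float),
                        doppler=np.zeros(n),
                        intensity=np.ones(n) if inten is None else inten,
                        rng=np.linalg.norm(np.asarray(xyz, float)
                                           - [0, 0, 2], axis=1))
    f.track_id[:] = 0
    return f


class TestPreprocess:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        xyz = rng.uniform(0, 3, (30, 3))
        inten = rng.random(30)
        t1 = preprocess_frame(_frame(xyz, inten))
        perm = rng.permutation(30)
        t2 = preprocess_frame(_frame(xyz[perm], inten[perm]))
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-12)

    def test_empty_frame_gives_zero_tensor(self):
        t = preprocess_frame(_frame(np.zeros((0, 3))))
        assert t.values.shape == (64, 5)
        assert not np.any(t.values)

    def test_truncation_keeps_highest_intensity(self):
        rng = np.random.default_rng(1)
        xyz = rng.uniform(0, 1.5, (100, 3)) + [0, 2, 0]
        inten = rng.random(100)
        t = preprocess_frame(_frame(xyz, inten), n_points_max=64)
        kept = np.sort(t.values[:, 4])[::-1]
        expected = np.sort(inten)[::-1][:64]   # brute-force top-k oracle
        np.testing.assert_allclose(kept, expected, atol=1e-6)

    def test_outliers_dropped(self):
        xyz = np.vstack([np.tile([0, 3, 1], (20, 1)),
                         [[0, 30.0, 1.0]]])          # one far outlier
        t = preprocess_frame(_frame(xyz), outlier_radius=3.0)
        assert np.count_nonzero(t.values[:, 4]) == 20

    def test_padding_rows_all_zero(self):
        t = preprocess_frame(_frame(np.tile([0.5, 3, 1], (5, 1))))
        assert not np.any(t.values[5:])


class TestAlignGroundTruth:
    def _setup(self, offset=0.0, skew=0.0, n=40):
        rng = np.random.default_rng(2)
        ts = np.arange(n) * 0.055
        spine = np.stack([0.2 * np.sin(ts), 3 + 0.5 * ts, 0.9 * np.ones(n)],
                         axis=1)
        joints = np.tile(spine[:, None, :], (1, 25, 1))
        frames = []
        for i in range(n):
            pts = spine[i] + rng.normal(0, 0.05, (15, 3))
            frames.append(_frame(pts, ts=float(ts[i])))
        kinect = joints.copy()
        kinect[:, :, 0] += offset
        return frames, ts + skew, kinect

    def test_injected_offset_recovered(self):
        frames, kts, kinect = self._setup(offset=0.30)
        _, aligned, offset = align_ground_truth(frames, kts, kinect)
        assert offset == pytest.approx(0.30, abs=0.01)

    def test_zero_offset_identity(self):
        frames, kts, kinect = self._setup(offset=0.0)
        idx, aligned, offset = align_ground_truth(frames, kts, kinect)
        assert idx == list(range(len(frames)))
        assert abs(offset) < 0.01

    def test_clock_skew_within_tolerance_keeps_all_pairs(self):
        frames, kts, kinect = self._setup(skew=0.010)
        idx, _, _ = align_ground_truth(frames, kts, kinect)
        assert len(idx) == len(frames)

    def test_disjoint_recordings_rejected(self):
        frames, kts, kinect = self._setup()
        with pytest.raises(ValueError, match="overlap"):
            align_ground_truth(frames, kts + 1000.0, kinect)


class TestReduce25To19:
    def test_output_order_and_shape(self):
        rng = np.random.default_rng(3)
        sk = rng.normal(size=(25, 3))
        out = reduce_25_to_19(sk)
        assert out.shape == (19, 3)
        np.testing.assert_array_equal(out[0], sk[K25["Head"]])
        np.testing.assert_array_equal(out[10], sk[K25["SpineBase"]])

    def test_no_confidence_passes_canonical_wrist(self):
        rng = np.random.default_rng(4)
        sk = rng.normal(size=(25, 3))
        out = reduce_25_to_19(sk)
        np.testing.assert_array_equal(out[7], sk[K25["WristLeft"]])
        np.testing.assert_array_equal(out[8], sk[K25["WristRight"]])

    def test_confidence_argmax_selects_candidate(self):
        sk = np.zeros((25, 3))
        for j, name in enumerate(KINECT25_JOINTS):
            sk[j] = [j, 0, 0]
        conf = np.array([0.1, 0.9, 0.2, 0.3, 0.1, 0.2])
        out = reduce_25_to_19(sk, conf)
        # left candidates beyond the canonical wrist: hand, hand-tip, thumb;
        # scores (canonical 0.5, 0.1, 0.9, 0.2) -> hand-tip wins
        np.testing.assert_array_equal(out[7], sk[K25["HandTipLeft"]])
        # right: (0.5, 0.3, 0.1, 0.2) -> canonical wrist wins
        np.testing.assert_array_equal(out[8], sk[K25["WristRight"]])

    def test_coincident_candidates_trivial(self):
        sk = np.ones((25, 3))
        out = reduce_25_to_19(sk, np.array([0.4, 0.1, 0.9, 0.2, 0.5, 0.6]))
        np.testing.assert_array_equal(out[7], [1, 1, 1])

    def test_wrist_targets_mark_nearest_candidate(self):
        spec = SubjectSpec()
        sc = GaitScenario(subjects=(spec,), duration=1.0, seed=0)
        traj = synth_skeleton_trajectory(spec, sc, np.random.default_rng(0))
        t = skeleton25_wrist_targets(traj.joints)
        assert t.shape == (traj.n_frames, 6)
        assert np.all(t.sum(axis=1) == 2)   # one winner per side


class TestPoseNetwork:
    def test_overfits_small_sample(self):
        """Capacity sanity: with regularization off, a handful of pairs is
        memorized to sub-cm MAE."""
        from mmgait import nn
        rng = np.random.default_rng(5)
        tensors = [FrameTensor(values=rng.normal(size=(64, 5)).astype(np.float32),
                               centroid=np.zeros(3), timestamp=0.0)
                   for _ in range(16)]
        targets = rng.normal(0, 0.3, size=(16, 19, 3))
        model = build_pose_net(seed=0)
        for layer in model.layers:
            if isinstance(layer, nn.Dropout):
                layer.p = 0.0
        train_pose(model, tensors, targets, epochs=300, seed=0,
                   val_fraction=0.0, patience=300, lr=2e-3)
        pred = predict_joints_batch(model, tensors)
        mae = np.mean(np.abs(pred - targets))
        assert mae < 0.01    # 1 cm

    def test_mismatched_pair_counts_rejected(self):
        t = [FrameTensor(values=np.zeros((64, 5), np.float32),
                         centroid=np.zeros(3), timestamp=0.0)]
        with pytest.raises(ValueError):
            train_pose(build_pose_net(), t, np.zeros((2, 19, 3)))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_pose(build_pose_net(), [], np.zeros((0, 19, 3)))

    def test_seeded_training_is_deterministic(self):
        rng = np.random.default_rng(6)
        tensors = [FrameTensor(values=rng.normal(size=(64, 5)).astype(np.float32),
                               centroid=np.zeros(3), timestamp=0.0)
                   for _ in range(8)]
        targets = rng.normal(size=(8, 19, 3))
        preds = []
        for _ in range(2):
            m = build_pose_net(seed=3)
            train_pose(m, tensors, targets, epochs=5, seed=3,
                       val_fraction=0.0)
            preds.append(predict_joints_batch(m, tensors))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_prediction_shape_and_determinism(self, pose_trained):
        model, _ = pose_trained
        t = FrameTensor(values=np.random.default_rng(7).normal(
            size=(64, 5)).astype(np.float32), centroid=np.array([0, 3, 0.9]),
            timestamp=0.0)
        a = predict_joints(model, t)
        b = predict_joints(model, t)
        assert a.shape == (19, 3)
        np.testing.assert_array_equal(a, b)


class TestTrainedPoseQuality:
    def test_beats_mean_skeleton_baseline(self, pose_trained, pose_dataset):
        """Held-out MAE must beat predicting the training-mean skeleton
        (each in centroid-relative coordinates)."""
        model, _ = pose_trained
        d = pose_dataset
        val = d.val_mask
        cents = np.stack([t.centroid for t in d.tensors])
        rel = d.targets19 - cents[:, None, :]
        baseline = rel[~val].mean(axis=0)
        base_mae = np.mean(np.abs(rel[val] - baseline))
        pred = predict_joints_batch(model, [t for t, v in
                                            zip(d.tensors, val) if v])
        mae = np.mean(np.abs(pred - d.targets19[val]))
        assert mae < base_mae

    def test_head_above_ankles(self, pose_trained, pose_dataset):
        """Anatomical sanity on held-out frames."""
        model, _ = pose_trained
        d = pose_dataset
        val_t = [t for t, v in zip(d.tensors, d.val_mask) if v]
        pred = predict_joints_batch(model, val_t)
        head_z = pred[:, 0, 2]
        ankle_z = pred[:, 15:17, 2].mean(axis=1)
        assert np.mean(head_z > ankle_z) >= 0.95

    def test_axis_error_ordering_mirrors_radar_geometry(self, pose_trained,
                                                        pose_dataset):
        """On lateral walks the horizontal (x) error is the largest axis and
        depth (y, measured by precise ranging) beats it."""
        from mmgait.evaluate import joint_error_table
        model, _ = pose_trained
        d = pose_dataset
        sel = d.val_mask & (d.paths == "perpendicular")
        assert sel.any()
        val_t = [t for t, s in zip(d.tensors, sel) if s]
        pred = predict_joints_batch(model, val_t)
        table = joint_error_table(pred, d.targets19[sel])
        avg = table.loc["19 points Average"]
        assert avg["MAE_x"] > avg["MAE_y"]
        assert avg["MAE_x"] > avg["MAE_z"]

    def test_wrists_hardest_joints(self, pose_trained, pose_dataset):
        """Sparse arm returns make the wrists the least accurate joints."""
        from mmgait.evaluate import joint_error_table
        model, _ = pose_trained
        d = pose_dataset
        val_t = [t for t, v in zip(d.tensors, d.val_mask) if v]
        pred = predict_joints_batch(model, val_t)
        table = joint_error_table(pred, d.targets19[d.val_mask])
        mae = table[["MAE_x", "MAE_y", "MAE_z"]].mean(axis=1)
        wrists = mae[["Wrist Left", "Wrist Right"]].mean()
        others = mae.drop(["Wrist Left", "Wrist Right",
                           "19 points Average"]).mean()
        assert wrists > others
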