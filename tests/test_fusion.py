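"""Skeleton-branch features, probability fusion and the end-to-end pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmgait.datasets import (make_transition_frames, simulate_subject)
from mmgait.fusion import (FusionConfig, fuse_predict, skeleton_class_probabilities,
                           skeleton_features, run_pipeline)
from mmgait.har import ActivityPrediction
from mmgait.kinematics import (GAIT_CLASSES, GaitScenario, SubjectSpec,
                               sample_subject, synth_skeleton_trajectory)
from mmgait.pose import reduce_25_to_19


def _simplex(k=5):
    return st.lists(st.floats(0.01, 1.0), min_size=k, max_size=k).map(
        lambda v: np.array(v) / np.sum(v))


class TestFusePredict:
    def test_doppler_only_reduces_to_doppler_branch(self):
        pd = np.array([0.7, 0.1, 0.1, 0.05, 0.05])
        ps = np.array([0.2] * 5)
        out = fuse_predict(pd, ps, FusionConfig(weight_doppler=1.0))
        np.testing.assert_allclose(out.probabilities, pd)
        assert out.predicted_class == "W1"

    def test_identical_branches_idempotent(self):
        p = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        out = fuse_predict(p, p)
        np.testing.assert_allclose(out.probabilities, p, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_predict(np.ones(4) / 4, np.ones(5) / 5)

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            fuse_predict(np.array([0.5, 0.5, 0.5, -0.25, -0.25]),
                         np.ones(5) / 5)

    def test_tie_breaks_toward_doppler_argmax(self):
        pd = np.array([0.4, 0.6, 0.0, 0.0, 0.0])
        ps = np.array([0.6, 0.4, 0.0, 0.0, 0.0])
        out = fuse_predict(pd, ps)     # fused ties W1/W2 at 0.5
        assert out.predicted_class == "W2"

    @given(pd=_simplex(), ps=_simplex(),
           w=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_always_valid_probability(self, pd, ps, w):
        out = fuse_predict(pd, ps, FusionConfig(weight_doppler=w))
        assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(out.probabilities >= 0)

    def test_monotone_along_segment(self):
        pd = np.array([0.6, 0.1, 0.1, 0.1, 0.1])
        ps = np.array([0.1, 0.6, 0.1, 0.1, 0.1])
        for w in np.linspace(0, 1, 11):
            out = fuse_predict(pd, ps, FusionConfig(weight_doppler=w)).probabilities
            expect = w * pd + (1 - w) * ps
            np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(weight_doppler=1.5)


class TestSkeletonFeatures:
    def _joints(self, cls="W1", duration=4.0, **kw):
        # start near the walk-area corner so short walks have no turnaround
        spec = SubjectSpec(gait_class=cls, start_position=(-2.5, 3.0),
                           heading=0.0, **kw)
        sc = GaitScenario(subjects=(spec,), duration=duration, seed=4)
        traj = synth_skeleton_trajectory(spec, sc, np.random.default_rng(4))
        return reduce_25_to_19(traj.joints), traj.timestamps

    def test_stoop_angle_recovered_within_ten_percent(self):
        j, ts = self._joints("W2", stoop_pitch=0.35)
        feats = skeleton_features(j, ts)
        assert feats[0] == pytest.approx(0.35, rel=0.10)

    def test_limp_asymmetry_recovered_within_ten_percent(self):
        j, ts = self._joints("W3", limp_asymmetry=0.6)
        feats = skeleton_features(j, ts)
        assert feats[1] == pytest.approx(0.6, rel=0.10)

    def test_walking_speed_feature(self):
        j, ts = self._joints("W1", walking_speed=1.1)
        feats = skeleton_features(j, ts)
        assert feats[5] == pytest.approx(1.1, rel=0.15)

    def test_frozen_skeleton_warns_but_returns(self):
        j = np.tile(np.random.default_rng(5).normal(size=(1, 19, 3)), (10, 1, 1))
        with pytest.warns(RuntimeWarning, match="frozen"):
            feats = skeleton_features(j, np.arange(10) * 0.055)
        assert np.all(np.isfinite(feats))

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            skeleton_features(np.zeros((1, 19, 3)), np.zeros(1))

    def test_probabilities_sum_to_one(self, skeleton_clf_trained):
        j, ts = self._joints("W2", stoop_pitch=0.3)
        p = skeleton_class_probabilities(skeleton_clf_trained, j, ts)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_stooped_windows_classified_as_stooped(self, skeleton_clf_trained):
        """The skeleton branch recognizes a class-typical stooped walker on
        held-out ground-truth skeleton windows."""
        spec = sample_subject("W2", np.random.default_rng(44),
                              stoop_pitch=0.35, start_position=(-2.5, 3.0),
                              heading=0.0)
        sc = GaitScenario(subjects=(spec,), duration=8.0, seed=4,
                          path_type="parallel")
        traj = synth_skeleton_trajectory(spec, sc, np.random.default_rng(4))
        j, ts = reduce_25_to_19(traj.joints), traj.timestamps
        w = 36
        hits = 0
        windows = range(0, len(j) - w, 9)
        for s in windows:
            p = skeleton_class_probabilities(skeleton_clf_trained,
                                             j[s:s + w], ts[s:s + w])
            hits += GAIT_CLASSES[int(np.argmax(p))] == "W2"
        assert hits / len(list(windows)) >= 0.9


class TestPipeline:
    def test_empty_input_empty_timeline(self, har_trained, pose_trained,
                                        skeleton_clf_trained, config):
        results, skeletons = run_pipeline([], har_trained[0], pose_trained[0],
                                          skeleton_clf_trained, config)
        assert results == [] and skeletons == {}

    def test_missing_model_named(self, config):
        with pytest.raises(ValueError, match="pose_net"):
            run_pipeline([], object(), None, object(), config)

    def test_transition_detected_within_two_windows(
            self, har_trained, pose_trained, skeleton_clf_trained, config):
        """A walk that changes from normal to limping mid-recording flips
        the predicted label near the true switch time."""
        frames, _, _ = make_transition_frames("W1", "W3", switch_time=6.0,
                                              duration=12.0, seed=5,
                                              config=config)
        results, _ = run_pipeline(frames, har_trained[0], pose_trained[0],
                                  skeleton_clf_trained, config,
                                  stride=4 * config.frame_period)
        labels = [(r.t_end, r.prediction.predicted_class) for r in results]
        before = [l for t, l in labels if t < 5.5]
        after = [l for t, l in labels if t > 8.5]
        assert before and after
        frac_w1_before = np.mean([l == "W1" for l in before])
        frac_w3_after = np.mean([l == "W3" for l in after])
        assert frac_w1_before >= 0.7
        assert frac_w3_after >= 0.7

    def test_two_subject_scene_labeled_per_track(
            self, har_trained, pose_trained, skeleton_clf_trained, config):
        """Concurrent walker + stooped subjects get separate tracks with
        mostly correct per-track labels."""
        from mmgait.datasets import make_multi_subject_frames
        from mmgait.dsp import cluster_points, track_subjects
        frames, trajs = make_multi_subject_frames(("W4", "W2"), duration=10.0,
                                                  seed=6, config=config)
        frames = [cluster_points(f, eps=0.5, min_points=4) for f in frames]
        frames, tracks = track_subjects(frames, gate=1.0)
        results, _ = run_pipeline(frames, har_trained[0], pose_trained[0],
                                  skeleton_clf_trained, config,
                                  stride=4 * config.frame_period)
        by_track = {}
        for r in results:
            by_track.setdefault(r.track_id, []).append(
                r.prediction.predicted_class)
        assert len(by_track) == 2
        # map tracks to subjects by mean position; lanes differ in x
        majorities = sorted(
            max(set(v), key=v.count) for v in by_track.values())
        assert majorities == ["W2", "W4"]
        accs = [np.mean([x == max(set(v), key=v.count) for x in v])
                for v in by_track.values()]
        assert min(accs) >= 0.9
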