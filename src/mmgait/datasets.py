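"""Labeled synthetic datasets for training and evaluating the gait system.

These helpers run the simulator end to end at desk scale: subjects sampled
from the study-population ranges walk for a few seconds per recording, the
fast point-cloud path produces sparse detections, and windows become
(micro-Doppler image, skeleton-feature vector, label) triples.  Splits are
by subject so evaluation is on walkers never seen in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import (GAIT_CLASSES, GaitScenario, JointTrajectory,
                         SubjectSpec, sample_subject)
from .pointcloud import PointCloudFrame, ScattererSet, scatterers_from_skeleton, \
    synth_point_clouds
from .pose import FrameTensor, preprocess_frames, reduce_25_to_19, \
    skeleton25_wrist_targets
from .radar import RadarConfig, RadarMount
from .spectrogram import accumulate_spectrogram, log_compress, \
    resample_spectrogram
from .fusion import device_point_fraction, skeleton_features


def simulate_subject(spec: SubjectSpec, duration: float, seed: int,
                     config: RadarConfig, mount: RadarMount | None = None,
                     dropout_prob: float = 0.35, jitter_std: float = 0.04,
                     path_type: str = "perpendicular"
                     ) -> tuple[list[PointCloudFrame], JointTrajectory]:
    """One subject's point-cloud frames (track id 0) with ground truth."""
    scenario = GaitScenario(subjects=(spec,), duration=duration,
                            frame_period=config.frame_period, seed=seed,
                            path_type=path_type)
    rng = np.random.default_rng(seed)
    from .kinematics import synth_skeleton_trajectory
    traj = synth_skeleton_trajectory(spec, scenario, rng)
    scat = scatterers_from_skeleton(traj, spec)
    frames = synth_point_clouds(scat, config, dropout_prob=dropout_prob,
                                jitter_std=jitter_std, seed=rng,
                                mount=mount or RadarMount())
    for f in frames:
        f.track_id[:] = 0
    return frames, traj


@dataclass
class GaitWindowDataset:
    """Per-window spectrogram images, skeleton features and labels.

    ``features_truth`` always comes from the ground-truth skeletons;
    ``features`` comes from pose-estimated skeletons when the dataset was
    built with a pose model (the stream the fusion stage actually consumes)
    and equals ``features_truth`` otherwise.  Training the skeleton branch
    on both domains makes it robust to estimation error without losing the
    clean-skeleton signal.
    """

    images: np.ndarray            # (n, 64, 64)
    features: np.ndarray          # (n, 8) skeleton-branch features
    labels: np.ndarray            # (n,) int class index 0..4
    subject_ids: np.ndarray       # (n,) global subject index
    val_mask: np.ndarray          # (n,) bool: held-out subjects
    features_truth: np.ndarray = None  # (n, 8) from ground-truth skeletons

    def training_features(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Both-domain training set for the skeleton branch:
        (features, labels, train-row count per domain)."""
        tr = ~self.val_mask
        if self.features_truth is None or \
                self.features_truth is self.features:
            return self.features[tr], self.labels[tr], tr
        x = np.vstack([self.features_truth[tr], self.features[tr]])
        y = np.concatenate([self.labels[tr], self.labels[tr]])
        return x, y, tr

    @property
    def class_names(self):
        return GAIT_CLASSES


def make_gait_window_dataset(n_subjects_per_class: int = 8,
                             duration: float = 8.0, seed: int = 0,
                             config: RadarConfig | None = None,
                             window: float = 2.0, stride_frames: int = 4,
                             val_subjects_per_class: int = 2,
                             path_type: str = "parallel",
                             pose_model=None) -> GaitWindowDataset:
    """Simulate all five classes and window the recordings.

    The last ``val_subjects_per_class`` subjects of each class form the
    held-out split.  Every window yields the resampled 64x64 micro-Doppler
    image and the skeleton-branch feature vector — computed from the pose
    model's estimated skeletons when ``pose_model`` is given (matching what
    the fusion stage sees at run time), else from the paired ground-truth
    skeletons.
    """
    config = config or RadarConfig()
    val_subjects_per_class = min(val_subjects_per_class,
                                 n_subjects_per_class - 1)
    rng = np.random.default_rng(seed)
    images, feats, feats_gt, labels, sids, val = [], [], [], [], [], []
    w_frames = max(int(round(window / config.frame_period)), 1)
    sid = 0
    for ci, cls in enumerate(GAIT_CLASSES):
        for k in range(n_subjects_per_class):
            spec = sample_subject(cls, rng, subject_id=sid)
            frames, traj = simulate_subject(
                spec, duration, int(rng.integers(2 ** 31)), config,
                path_type=path_type)
            specs = accumulate_spectrogram(
                frames, 0, config, window=window,
                stride=stride_frames * config.frame_period)
            j19_gt = reduce_25_to_19(traj.joints)
            if pose_model is not None:
                from .pose import predict_joints_batch
                j19 = predict_joints_batch(
                    pose_model, preprocess_frames(frames, track_id=0))
            else:
                j19 = j19_gt
            ts = traj.timestamps
            is_val = k >= n_subjects_per_class - val_subjects_per_class
            for wi, sp in enumerate(specs):
                start = wi * stride_frames
                sl = slice(start, start + w_frames)
                images.append(log_compress(resample_spectrogram(sp)))
                devf = device_point_fraction(frames[sl], 0, j19[sl])
                feats.append(skeleton_features(j19[sl], ts[sl], devf))
                if pose_model is not None:
                    devg = device_point_fraction(frames[sl], 0, j19_gt[sl])
                    feats_gt.append(skeleton_features(j19_gt[sl], ts[sl],
                                                      devg))
                labels.append(ci)
                sids.append(sid)
                val.append(is_val)
            sid += 1
    features = np.asarray(feats)
    return GaitWindowDataset(images=np.asarray(images, np.float32),
                             features=features,
                             labels=np.asarray(labels, int),
                             subject_ids=np.asarray(sids, int),
                             val_mask=np.asarray(val, bool),
                             features_truth=(np.asarray(feats_gt)
                                             if feats_gt else features))


@dataclass
class PoseDataset:
    tensors: list[FrameTensor]
    targets19: np.ndarray         # (n, 19, 3)
    wrist_targets: np.ndarray     # (n, 6)
    val_mask: np.ndarray
    paths: np.ndarray = None      # (n,) collection walk per sample


def make_pose_dataset(n_subjects: int = 10, duration: float = 6.0,
                      seed: int = 0, config: RadarConfig | None = None,
                      dropout_prob: float = 0.25, jitter_std: float = 0.03,
                      val_subjects: int = 2,
                      classes: tuple = GAIT_CLASSES) -> PoseDataset:
    """Paired (frame tensor, 19-joint skeleton) samples across gait classes.

    Subjects cycle through the collection walks — two lateral crossings for
    every toward/away walk — so the regressor sees both geometries with the
    lateral crossing dominant, as in the emulated recording campaign.
    """
    config = config or RadarConfig()
    rng = np.random.default_rng(seed)
    paths = ("perpendicular", "parallel", "perpendicular")
    tensors, targets, wrists, val, path_of = [], [], [], [], []
    for k in range(n_subjects):
        cls = classes[k % len(classes)]
        spec = sample_subject(cls, rng, subject_id=k)
        frames, traj = simulate_subject(
            spec, duration, int(rng.integers(2 ** 31)), config,
            dropout_prob=dropout_prob, jitter_std=jitter_std,
            path_type=paths[k % 3])
        tens = preprocess_frames(frames, track_id=0)
        j19 = reduce_25_to_19(traj.joints)
        wt = skeleton25_wrist_targets(traj.joints)
        is_val = k >= n_subjects - val_subjects
        for t, y, w in zip(tens, j19, wt):
            if not np.any(t.values):
                continue
            tensors.append(t)
            targets.append(y)
            wrists.append(w)
            val.append(is_val)
            path_of.append(paths[k % 3])
    return PoseDataset(tensors=tensors, targets19=np.asarray(targets),
                       wrist_targets=np.asarray(wrists, np.float32),
                       val_mask=np.asarray(val, bool),
                       paths=np.asarray(path_of))


def make_transition_frames(class_a: str, class_b: str, switch_time: float,
                           duration: float, seed: int,
                           config: RadarConfig | None = None
                           ) -> tuple[list[PointCloudFrame], JointTrajectory,
                                      JointTrajectory]:
    """Within-subject activity transition: class_a until switch_time, then
    class_b continuing from the same position/heading."""
    config = config or RadarConfig()
    rng = np.random.default_rng(seed)
    spec_a = sample_subject(class_a, rng, subject_id=0)
    frames_a, traj_a = simulate_subject(spec_a, switch_time, seed, config,
                                        path_type="parallel")
    end_xy = tuple(traj_a.joints[-1, 0, :2])   # spine base ~ root
    spec_b = sample_subject(class_b, rng, subject_id=0,
                            start_position=end_xy, height=spec_a.height)
    frames_b, traj_b = simulate_subject(spec_b, duration - switch_time,
                                        seed + 1, config,
                                        path_type="parallel")
    shift = frames_a[-1].timestamp + config.frame_period
    for f in frames_b:
        f.timestamp += shift
    traj_b.timestamps = traj_b.timestamps + shift
    return frames_a + frames_b, traj_a, traj_b


def make_multi_subject_frames(classes: tuple, duration: float, seed: int,
                              config: RadarConfig | None = None
                              ) -> tuple[list[PointCloudFrame],
                                         list[JointTrajectory]]:
    """Concurrent subjects in one scene (distinct walking lanes), merged
    per-frame without track labels — tracking must separate them."""
    config = config or RadarConfig()
    rng = np.random.default_rng(seed)
    lanes = np.linspace(-2.0, 2.0, len(classes))
    all_frames: list[list[PointCloudFrame]] = []
    trajs = []
    for i, cls in enumerate(classes):
        spec = sample_subject(cls, rng, subject_id=i,
                              start_position=(float(lanes[i]), 3.0 + 0.7 * i),
                              heading=np.pi / 2)
        frames, traj = simulate_subject(spec, duration,
                                        int(rng.integers(2 ** 31)), config,
                                        path_type="parallel")
        all_frames.append(frames)
        trajs.append(traj)
    merged = []
    for fi in range(len(all_frames[0])):
        parts = [s[fi] for s in all_frames]
        merged.append(PointCloudFrame(
            timestamp=parts[0].timestamp,
            xyz=np.concatenate([p.xyz for p in parts]),
            doppler=np.concatenate([p.doppler for p in parts]),
            intensity=np.concatenate([p.intensity for p in parts]),
            rng=np.concatenate([p.rng for p in parts]),
        ))
    return merged, trajs
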