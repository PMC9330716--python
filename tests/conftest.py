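"""Shared fixtures.

The expensive trained models (micro-Doppler CNN, pose regressor, skeleton
branch) are session-scoped and shared between the unit, integration and
acceptance tests so the whole suite trains each network once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mmgait import (RadarConfig, RadarMount, build_classifier,
                    build_pose_net, derive_quantities, train_classifier)
from mmgait.datasets import (make_gait_window_dataset, make_pose_dataset)
from mmgait.fusion import SkeletonBranchClassifier
from mmgait.kinematics import GAIT_CLASSES
from mmgait.pose import train_pose


@pytest.fixture(scope="session")
def config() -> RadarConfig:
    return RadarConfig()


@pytest.fixture(scope="session")
def derived(config):
    return derive_quantities(config)


@pytest.fixture(scope="session")
def mount() -> RadarMount:
    return RadarMount()


@pytest.fixture(scope="session")
def pose_dataset(config):
    return make_pose_dataset(n_subjects=10, duration=6.0, seed=1,
                             config=config)


@pytest.fixture(scope="session")
def pose_trained(pose_dataset):
    model = build_pose_net(seed=0)
    history = train_pose(model, pose_dataset.tensors, pose_dataset.targets19,
                         wrist_targets=pose_dataset.wrist_targets,
                         epochs=40, seed=0, patience=6)
    return model, history


@pytest.fixture(scope="session")
def window_dataset(config, pose_trained):
    """Five-class simulated windows: >= 200 spectrograms per class, split by
    held-out subjects; skeleton features from pose-estimated joints."""
    return make_gait_window_dataset(n_subjects_per_class=8, duration=8.0,
                                    seed=0, config=config,
                                    pose_model=pose_trained[0])


@pytest.fixture(scope="session")
def har_trained(window_dataset):
    model = build_classifier(seed=0)
    history = train_classifier(model, window_dataset.images,
                               window_dataset.labels, epochs=20, seed=0,
                               val_mask=window_dataset.val_mask, patience=4)
    return model, history


@pytest.fixture(scope="session")
def skeleton_clf_trained(window_dataset):
    x, y, _ = window_dataset.training_features()
    clf = SkeletonBranchClassifier(seed=0)
    clf.fit(x, np.array(GAIT_CLASSES)[y])
    return clf
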