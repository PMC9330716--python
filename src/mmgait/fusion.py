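"""Late fusion of the micro-Doppler classifier and the skeleton stream.

The skeleton branch summarizes a window of 19-joint skeletons into gait
features (trunk pitch, step-length asymmetry, per-arm swing, gait-cycle
period, speed, sway, leading device points) and scores them with a softmax
classifier; the final walking-posture probabilities are a convex
combination of the two branch probability vectors, the argmax breaking
ties toward the micro-Doppler branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .har import ActivityPrediction, classify
from .kinematics import GAIT_CLASSES, J19, trunk_pitch, step_length_ratio
from .pointcloud import PointCloudFrame
from .pose import preprocess_frames, predict_joints_batch
from .spectrogram import accumulate_spectrogram

SKELETON_FEATURES = (
    "trunk_pitch", "step_asymmetry", "arm_swing_left", "arm_swing_right",
    "gait_period", "walking_speed", "lateral_sway", "device_fraction",
)


@dataclass(frozen=True)
class FusionConfig:
    """Branch weights (sum to one) and the skeleton feature window."""

    weight_doppler: float = 0.5
    skeleton_window: float = 2.0    # s

    def __post_init__(self):
        if not 0.0 <= self.weight_doppler <= 1.0:
            raise ValueError("weight_doppler must lie in [0, 1]")

    @property
    def weight_skeleton(self) -> float:
        return 1.0 - self.weight_doppler


def _forward_axis(joints19: np.ndarray) -> np.ndarray:
    """Dominant horizontal motion axis of the pelvis (unit 2-vector)."""
    sb = joints19[:, J19["Spine Base"], :2]
    d = sb - sb.mean(axis=0)
    if np.allclose(d, 0):
        return np.array([0.0, 1.0])
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return vt[0]


def _p2p(x: np.ndarray) -> float:
    return float(np.percentile(x, 97.5) - np.percentile(x, 2.5))


def skeleton_features(joints19: np.ndarray, timestamps: np.ndarray,
                      device_fraction: float = 0.0) -> np.ndarray:
    """Gait features of one skeleton window ((n, 19, 3), n >= 2)."""
    joints19 = np.asarray(joints19, dtype=float)
    ts = np.asarray(timestamps, dtype=float)
    if len(joints19) < 2:
        raise ValueError("a feature window needs at least 2 frames")
    if np.allclose(joints19.std(axis=0), 0.0):
        warnings.warn("frozen skeleton window: features are degenerate",
                      RuntimeWarning)
    pitch = float(np.mean(trunk_pitch(joints19)))
    ratio = step_length_ratio(joints19)
    asym = min(ratio, 1.0 / ratio) if np.isfinite(ratio) and ratio > 0 else 1.0
    u = _forward_axis(joints19)
    ss = joints19[:, J19["Spine Shoulder"], :2]
    swings = []
    for w in ("Wrist Left", "Wrist Right"):
        rel = (joints19[:, J19[w], :2] - ss) @ u
        swings.append(_p2p(rel))
    # gait-cycle period from the left-foot forward excursion autocorrelation
    rel_foot = (joints19[:, J19["Foot Left"], :2]
                - joints19[:, J19["Spine Base"], :2]) @ u
    period = _autocorr_period(rel_foot - rel_foot.mean(), ts)
    sb = joints19[:, J19["Spine Base"], :2]
    dur = ts[-1] - ts[0]
    speed = float(np.linalg.norm(sb[-1] - sb[0]) / dur) if dur > 0 else 0.0
    nvec = np.array([-u[1], u[0]])
    sway = _p2p((sb - sb.mean(axis=0)) @ nvec)
    return np.array([pitch, asym, swings[0], swings[1], period, speed, sway,
                     device_fraction])


def _autocorr_period(x: np.ndarray, ts: np.ndarray) -> float:
    if len(x) < 4 or np.allclose(x, 0):
        return 0.0
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    # unbiased: compensate the shrinking overlap at large lags
    ac = ac / np.arange(len(x), 0, -1)
    ac /= max(ac[0], 1e-12)
    # first local maximum after the zero-lag peak
    for lag in range(2, len(ac) - 1):
        if ac[lag] >= ac[lag - 1] and ac[lag] >= ac[lag + 1] and ac[lag] > 0.25:
            return float(lag * np.median(np.diff(ts)))
    return 0.0


def device_point_fraction(frames: list[PointCloudFrame], track_id: int,
                          joints19_seq: np.ndarray) -> float:
    """Fraction of track points low and ahead of the body — the signature of
    a leading walker frame or planted cane."""
    u = _forward_axis(joints19_seq)
    total = dev = 0
    for f, j19 in zip(frames, joints19_seq):
        sel = f.track_id == track_id
        if not np.any(sel):
            continue
        pts = f.xyz[sel]
        sb = j19[J19["Spine Base"]]
        ahead = (pts[:, :2] - sb[:2]) @ u
        low = pts[:, 2] < 1.0
        total += len(pts)
        dev += int(np.sum((ahead > 0.25) & low))
    return dev / total if total else 0.0


class SkeletonBranchClassifier:
    """Softmax layer over the gait features (multinomial logistic model).

    Moderate regularization (C = 1) keeps the branch's probabilities
    calibrated rather than saturated, so a fused decision cannot be
    overturned by overconfident skeleton evidence on atypical windows.
    """

    def __init__(self, seed: int = 0, C: float = 1.0):
        self.scaler = StandardScaler()
        self.model = LogisticRegression(max_iter=2000, C=C,
                                        random_state=seed)
        self.classes_: list[str] = list(GAIT_CLASSES)

    def fit(self, features: np.ndarray, labels: np.ndarray
            ) -> "SkeletonBranchClassifier":
        y = np.asarray(labels)
        self.model.fit(self.scaler.fit_transform(features), y)
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """(n, 5) probabilities in W1..W5 order."""
        feats = np.atleast_2d(features)
        p = self.model.predict_proba(self.scaler.transform(feats))
        out = np.zeros((len(feats), len(GAIT_CLASSES)))
        for i, cls in enumerate(self.model.classes_):
            out[:, GAIT_CLASSES.index(cls)] = p[:, i]
        return out

    def save(self, path) -> None:
        import joblib
        joblib.dump({"scaler": self.scaler, "model": self.model}, path)

    @classmethod
    def load(cls, path) -> "SkeletonBranchClassifier":
        import joblib
        data = joblib.load(path)
        obj = cls()
        obj.scaler, obj.model = data["scaler"], data["model"]
        return obj


def skeleton_class_probabilities(clf: SkeletonBranchClassifier,
                                 joints19: np.ndarray, timestamps: np.ndarray,
                                 device_fraction: float = 0.0) -> np.ndarray:
    """Length-5 probability vector for one skeleton window."""
    feats = skeleton_features(joints19, timestamps, device_fraction)
    return clf.predict_proba(feats[None])[0]


def fuse_predict(p_doppler: np.ndarray, p_skeleton: np.ndarray,
                 cfg: FusionConfig = FusionConfig()) -> ActivityPrediction:
    """Convex combination of the branch probabilities; ties break toward the
    micro-Doppler branch's argmax."""
    pd = np.asarray(p_doppler, dtype=float)
    ps = np.asarray(p_skeleton, dtype=float)
    if pd.shape != (len(GAIT_CLASSES),) or ps.shape != (len(GAIT_CLASSES),):
        raise ValueError("branch probability vectors must have length 5")
    for v, name in ((pd, "doppler"), (ps, "skeleton")):
        if abs(v.sum() - 1.0) > 1e-6 or np.any(v < 0):
            raise ValueError(f"{name} branch probabilities are not a "
                             "probability vector")
    fused = cfg.weight_doppler * pd + cfg.weight_skeleton * ps
    fused = fused / fused.sum()
    best = np.flatnonzero(np.isclose(fused, fused.max(), rtol=0, atol=1e-12))
    pick = int(best[0])
    if len(best) > 1 and int(np.argmax(pd)) in best:
        pick = int(np.argmax(pd))
    return ActivityPrediction(probabilities=fused,
                              predicted_class=GAIT_CLASSES[pick])


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class WindowPrediction:
    track_id: int
    t_start: float
    t_end: float
    prediction: ActivityPrediction
    p_doppler: np.ndarray
    p_skeleton: np.ndarray


def run_pipeline(frames: list[PointCloudFrame], har_model, pose_model,
                 skeleton_clf: SkeletonBranchClassifier, config,
                 fusion_cfg: FusionConfig = FusionConfig(),
                 window: float = 2.0, stride: float | None = None,
                 min_track_frames: int = 10
                 ) -> tuple[list[WindowPrediction], dict[int, np.ndarray]]:
    """Tracked point clouds -> per-track fused activity timeline + skeletons.

    For cube input, run :func:`mmgait.dsp.process_cubes` first; frames here
    must already carry track ids.  Returns the window predictions and a
    {track_id: (n_frames, 19, 3)} dict of per-frame skeleton estimates.
    """
    if har_model is None or pose_model is None or skeleton_clf is None:
        missing = [n for n, m in (("har_cnn", har_model),
                                  ("pose_net", pose_model),
                                  ("skeleton_classifier", skeleton_clf))
                   if m is None]
        raise ValueError(f"missing trained model(s): {', '.join(missing)}")
    if not frames:
        return [], {}
    stride = stride or config.frame_period
    track_ids = sorted({int(t) for f in frames
                        for t in np.unique(f.track_id) if t >= 0})
    results: list[WindowPrediction] = []
    skeletons: dict[int, np.ndarray] = {}
    ts = np.array([f.timestamp for f in frames])
    for tid in track_ids:
        present = np.array([bool(np.any(f.track_id == tid)) for f in frames])
        if present.sum() < min_track_frames:
            continue
        tensors = preprocess_frames(frames, track_id=tid)
        joints = predict_joints_batch(pose_model, tensors)
        skeletons[tid] = joints
        specs = accumulate_spectrogram(frames, tid, config, window=window,
                                       stride=stride)
        w_frames = max(int(round(window / config.frame_period)), 1)
        s_frames = max(int(round(stride / config.frame_period)), 1)
        for wi, spec in enumerate(specs):
            start = wi * s_frames
            sl = slice(start, start + w_frames)
            if present[sl].sum() < 2:
                continue
            p_d = classify(har_model, spec).probabilities
            devf = device_point_fraction(frames[sl], tid, joints[sl])
            p_s = skeleton_class_probabilities(skeleton_clf, joints[sl],
                                               ts[sl], devf)
            pred = fuse_predict(p_d, p_s, fusion_cfg)
            results.append(WindowPrediction(
                track_id=tid, t_start=float(ts[sl][0]),
                t_end=float(ts[sl][-1]), prediction=pred,
                p_doppler=p_d, p_skeleton=p_s))
    return results, skeletons
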