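"""Skeletal pose regression from sparse 5D point-cloud frames.

A frame's variable-size cloud is canonicalized into a fixed 64-point x
5-channel tensor (sorted by intensity, range, x; truncated or zero-padded),
centred on the cloud centroid.  A small network — two 1-D convolutions (16
and 32 channels) with batch normalization and dropout, then 512-unit and
57-unit dense layers — regresses the 19 joint coordinates relative to that
centroid; an auxiliary 6-unit sigmoid head scores the per-hand wrist
candidates used when collapsing 25-joint Kinect ground truth to the
19-joint space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .kinematics import (JOINTS19, JOINTS19_TO_KINECT25, K25,
                         WRIST_CANDIDATES_LEFT, WRIST_CANDIDATES_RIGHT)
from .pointcloud import PointCloudFrame

N_JOINTS19 = 19
N_OUT = N_JOINTS19 * 3          # 57 joint coordinates
N_CONF = 6                      # wrist-candidate confidence head


@dataclass(frozen=True)
class PoseNetSpec:
    conv_channels: tuple = (16, 32)
    conv_dropouts: tuple = (0.3, 0.4)
    fc_sizes: tuple = (512, N_OUT)
    fc_dropout: float = 0.2
    n_points_max: int = 64
    outlier_radius: float = 3.0     # m from frame centroid


@dataclass
class FrameTensor:
    """Fixed-shape (n_points_max, 5) frame representation.

    Channels: x, y, z (centroid-relative, m), Doppler (m/s), intensity.
    ``centroid`` restores absolute coordinates after regression.
    """

    values: np.ndarray
    centroid: np.ndarray
    timestamp: float


def preprocess_frame(frame: PointCloudFrame, n_points_max: int = 64,
                     outlier_radius: float = 3.0,
                     track_id: int | None = None) -> FrameTensor:
    """Canonicalize one frame: outlier cull, sort, truncate/zero-pad.

    Sorting (intensity desc, range asc, x asc) makes the tensor invariant
    to the arrival order of detections; truncation keeps the strongest
    ``n_points_max`` points.  An empty frame maps to the all-zero tensor.
    """
    if n_points_max < 1:
        raise ValueError("n_points_max must be >= 1")
    sel = np.ones(len(frame), bool)
    if track_id is not None:
        sel &= frame.track_id == track_id
    xyz = frame.xyz[sel]
    dop = frame.doppler[sel]
    inten = frame.intensity[sel]
    rng_m = frame.rng[sel]
    if len(xyz):
        centroid = xyz.mean(axis=0)
        keep = np.linalg.norm(xyz - centroid, axis=1) <= outlier_radius
        xyz, dop, inten, rng_m = xyz[keep], dop[keep], inten[keep], rng_m[keep]
    if len(xyz) == 0:
        return FrameTensor(values=np.zeros((n_points_max, 5), np.float32),
                           centroid=np.zeros(3), timestamp=frame.timestamp)
    centroid = xyz.mean(axis=0)
    rng_sort = np.where(np.isfinite(rng_m), rng_m, np.inf)
    order = np.lexsort((xyz[:, 0], rng_sort, -inten))
    order = order[:n_points_max]
    vals = np.zeros((n_points_max, 5), np.float32)
    k = len(order)
    vals[:k, :3] = xyz[order] - centroid
    vals[:k, 3] = dop[order]
    vals[:k, 4] = inten[order]
    return FrameTensor(values=vals, centroid=centroid,
                       timestamp=frame.timestamp)


def preprocess_frames(frames: list[PointCloudFrame], n_points_max: int = 64,
                      outlier_radius: float = 3.0,
                      track_id: int | None = None) -> list[FrameTensor]:
    return [preprocess_frame(f, n_points_max, outlier_radius, track_id)
            for f in frames]


# ---------------------------------------------------------------------------
# ground-truth alignment and the 25 -> 19 joint reduction
# ---------------------------------------------------------------------------

def align_ground_truth(radar_frames: list[PointCloudFrame],
                       kinect_timestamps: np.ndarray,
                       kinect_joints25: np.ndarray,
                       tolerance: float | None = None
                       ) -> tuple[list[int], np.ndarray, float]:
    """Pair radar frames with Kinect skeletons and remove the x offset.

    Nearest-timestamp pairing within ``tolerance`` (default: half the median
    radar frame period); the constant x-axis mounting offset is the
    least-squares fit between cloud centroid x and the spine-mid x
    trajectory and is subtracted from the returned skeletons.

    Returns (radar frame indices, aligned (n, 25, 3) skeletons, offset).
    """
    rt = np.array([f.timestamp for f in radar_frames])
    kt = np.asarray(kinect_timestamps, dtype=float)
    if len(rt) == 0 or len(kt) == 0 or rt.max() < kt.min() or kt.max() < rt.min():
        raise ValueError("radar and Kinect recordings do not overlap in time")
    if tolerance is None:
        tolerance = 0.5 * float(np.median(np.diff(rt))) if len(rt) > 1 else 0.05
    pairs_r, pairs_k = [], []
    for i, t in enumerate(rt):
        j = int(np.argmin(np.abs(kt - t)))
        if abs(kt[j] - t) <= tolerance:
            pairs_r.append(i)
            pairs_k.append(j)
    if not pairs_r:
        raise ValueError("no radar/Kinect frame pairs within tolerance")
    skel = np.asarray(kinect_joints25, dtype=float)[pairs_k].copy()
    cent_x = np.array([radar_frames[i].xyz[:, 0].mean()
                       if len(radar_frames[i]) else np.nan for i in pairs_r])
    spine_x = skel[:, K25["SpineMid"], 0]
    ok = np.isfinite(cent_x)
    # least squares for a constant offset = mean residual
    offset = float(np.mean(spine_x[ok] - cent_x[ok])) if ok.any() else 0.0
    skel[:, :, 0] -= offset
    return pairs_r, skel, offset


def reduce_25_to_19(skel25: np.ndarray,
                    confidences: np.ndarray | None = None) -> np.ndarray:
    """Collapse Kinect's 25 joints to the 19-joint reporting space.

    The four per-hand wrist candidates (wrist, hand, hand tip, thumb) reduce
    to a single wrist per side: the highest-confidence candidate when
    ``confidences`` (length 6: 3 alternates per side beyond the canonical
    wrist, ordered left hand/tip/thumb then right) plus the canonical wrist
    are scored, else the canonical wrist entry.
    """
    skel25 = np.asarray(skel25, dtype=float)
    squeeze = skel25.ndim == 2
    sk = skel25[None] if squeeze else skel25
    out = sk[:, JOINTS19_TO_KINECT25, :].copy()
    if confidences is not None:
        conf = np.asarray(confidences, dtype=float)
        if conf.ndim == 1:
            conf = conf[None]
        for side, cands, col in (("left", WRIST_CANDIDATES_LEFT, 7),
                                 ("right", WRIST_CANDIDATES_RIGHT, 8)):
            # candidate scores: canonical wrist then the three alternates
            base = 0 if side == "left" else 3
            scores = np.concatenate(
                [np.full((len(sk), 1), 0.5), conf[:, base:base + 3]], axis=1)
            pick = np.argmax(scores, axis=1)
            for n in range(len(sk)):
                out[n, col] = sk[n, cands[pick[n]]]
    return out[0] if squeeze else out


def skeleton25_wrist_targets(skel25: np.ndarray) -> np.ndarray:
    """Training targets for the confidence head: 1 for the candidate closest
    to the canonical wrist, else 0 (per side, alternates only)."""
    sk = np.asarray(skel25, dtype=float)
    if sk.ndim == 2:
        sk = sk[None]
    out = np.zeros((len(sk), N_CONF), np.float32)
    for base, cands, wrist in ((0, WRIST_CANDIDATES_LEFT, K25["WristLeft"]),
                               (3, WRIST_CANDIDATES_RIGHT, K25["WristRight"])):
        d = np.linalg.norm(sk[:, cands[1:], :] - sk[:, [wrist], :], axis=2)
        out[np.arange(len(sk)), base + np.argmin(d, axis=1)] = 1.0
    return out


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def build_pose_net(spec: PoseNetSpec = PoseNetSpec(),
                   seed: int = 0) -> nn.Sequential:
    """conv1d(16)+BN+drop(0.3) -> conv1d(32)+BN+drop(0.4) -> fc(512)+BN+drop
    -> fc(57 + 6): joint offsets plus wrist-candidate confidence logits."""
    rng = np.random.default_rng(seed)
    c1, c2 = spec.conv_channels
    d1, d2 = spec.conv_dropouts
    fc1, out = spec.fc_sizes
    layers = [
        nn.Conv1D(5, c1, rng=rng), nn.BatchNorm(c1), nn.LeakyReLU(0.01),
        nn.Dropout(d1),
        nn.Conv1D(c1, c2, rng=rng), nn.BatchNorm(c2), nn.LeakyReLU(0.01),
        nn.Dropout(d2),
        nn.Flatten(),
        nn.Dense(c2 * spec.n_points_max, fc1, rng=rng), nn.BatchNorm(fc1),
        nn.LeakyReLU(0.01), nn.Dropout(spec.fc_dropout),
        nn.Dense(fc1, out + N_CONF, rng=rng),
    ]
    return nn.Sequential(layers)


def _tensor_batch(tensors: list[FrameTensor]) -> np.ndarray:
    return np.stack([t.values.T for t in tensors]).astype(np.float32)  # (n,5,64)


def train_pose(model: nn.Sequential, tensors: list[FrameTensor],
               targets19: np.ndarray, wrist_targets: np.ndarray | None = None,
               epochs: int = 60, seed: int = 0, batch_size: int = 32,
               lr: float = 1e-3, conf_weight: float = 0.1,
               val_fraction: float = 0.2, patience: int = 8) -> dict:
    """Minimize MSE on the 57 centroid-relative outputs (+ BCE on the
    confidence head when wrist targets are given)."""
    if len(tensors) != len(targets19):
        raise ValueError("tensors and targets must pair one-to-one")
    if len(tensors) == 0:
        raise ValueError("training needs at least one paired sample")
    x = _tensor_batch(tensors)
    cents = np.stack([t.centroid for t in tensors])
    y = (np.asarray(targets19, np.float32).reshape(len(x), N_OUT)
         - np.tile(cents, (1, N_JOINTS19)).astype(np.float32))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(x))
    n_val = max(int(round(val_fraction * len(x))), 1) if val_fraction > 0 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    opt = nn.Adam(model.params(), lr=lr)
    history = {"train_loss": [], "val_loss": []}
    best, best_state, bad = np.inf, None, 0
    for epoch in range(epochs):
        order = rng.permutation(len(tr_idx))
        losses = []
        for s in range(0, len(tr_idx), batch_size):
            idx = tr_idx[order[s:s + batch_size]]
            out = model.forward(x[idx], train=True, rng=rng)
            loss, grad = nn.mse_loss(out[:, :N_OUT], y[idx])
            g = np.zeros_like(out)
            g[:, :N_OUT] = grad
            if wrist_targets is not None:
                closs, cgrad = nn.bce_with_logits(out[:, N_OUT:],
                                                  wrist_targets[idx])
                loss += conf_weight * closs
                g[:, N_OUT:] = conf_weight * cgrad
            model.backward(g)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if n_val:
            out = model.forward(x[val_idx], train=False)
            vl, _ = nn.mse_loss(out[:, :N_OUT], y[val_idx])
        else:
            vl = history["train_loss"][-1]
        history["val_loss"].append(float(vl))
        if vl < best - 1e-7:
            best, bad = vl, 0
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        else:
            bad += 1
            if bad >= patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return history


def predict_joints(model: nn.Sequential, tensor: FrameTensor) -> np.ndarray:
    """One frame's (19, 3) joint positions (absolute world coordinates)."""
    return predict_joints_batch(model, [tensor])[0]


def predict_joints_batch(model: nn.Sequential,
                         tensors: list[FrameTensor]) -> np.ndarray:
    x = _tensor_batch(tensors)
    out = model.forward(x, train=False)[:, :N_OUT].astype(float)
    cents = np.stack([t.centroid for t in tensors])
    return out.reshape(len(x), N_JOINTS19, 3) + cents[:, None, :]


def predict_wrist_confidences(model: nn.Sequential,
                              tensors: list[FrameTensor]) -> np.ndarray:
    x = _tensor_batch(tensors)
    logits = model.forward(x, train=False)[:, N_OUT:]
    return 1.0 / (1.0 + np.exp(-logits.astype(float)))
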