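"""Joint-localization error tables and activity confusion matrices.

Joint errors are reported per joint and axis as MAE and RMSE in cm, with a
19-point average row; confusion matrices are row-normalized percentages
(rows = true class).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinematics import GAIT_CLASSES, JOINTS19

AVERAGE_ROW = "19 points Average"
_COLS = ["MAE_x", "RMSE_x", "MAE_y", "RMSE_y", "MAE_z", "RMSE_z"]


def aggregate_joint_errors(per_joint: pd.DataFrame) -> pd.DataFrame:
    """Append the 19-point average row (arithmetic mean per column)."""
    missing = [c for c in _COLS if c not in per_joint.columns]
    if missing:
        raise ValueError(f"missing error columns: {missing}")
    body = per_joint.loc[[j for j in per_joint.index if j != AVERAGE_ROW]]
    avg = body[_COLS].mean(axis=0)
    out = body.copy()
    out.loc[AVERAGE_ROW] = avg
    return out


def joint_error_table(pred: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Per-joint, per-axis MAE/RMSE (cm) between predicted and true skeletons.

    ``pred`` and ``truth``: (n_frames, 19, 3) in metres, matched frame by
    frame.  The returned table has the 19 joint rows plus the average row.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction {pred.shape} and truth {truth.shape} "
                         "must have equal shapes")
    if pred.ndim != 3 or pred.shape[1:] != (19, 3):
        raise ValueError("expected (n_frames, 19, 3) skeleton sequences")
    err = (pred - truth) * 100.0                    # cm
    mae = np.mean(np.abs(err), axis=0)              # (19, 3)
    rmse = np.sqrt(np.mean(err ** 2, axis=0))
    data = {
        "MAE_x": mae[:, 0], "RMSE_x": rmse[:, 0],
        "MAE_y": mae[:, 1], "RMSE_y": rmse[:, 1],
        "MAE_z": mae[:, 2], "RMSE_z": rmse[:, 2],
    }
    table = pd.DataFrame(data, index=list(JOINTS19))
    return aggregate_joint_errors(table)


def confusion_matrix(true_labels, pred_labels) -> pd.DataFrame:
    """5x5 row-normalized percentage confusion matrix (rows = true class)."""
    t = [str(x) for x in true_labels]
    p = [str(x) for x in pred_labels]
    if len(t) == 0:
        raise ValueError("empty label lists")
    if len(t) != len(p):
        raise ValueError("label lists must have equal length")
    bad = sorted({x for x in t + p} - set(GAIT_CLASSES))
    if bad:
        raise ValueError(f"unknown class labels: {bad}")
    counts = pd.DataFrame(0.0, index=list(GAIT_CLASSES),
                          columns=list(GAIT_CLASSES))
    for a, b in zip(t, p):
        counts.loc[a, b] += 1
    sums = counts.sum(axis=1)
    pct = counts.div(sums.replace(0, np.nan), axis=0) * 100.0
    return pct.fillna(0.0)


def diagonally_dominant(cm: pd.DataFrame) -> bool:
    """Every diagonal entry strictly exceeds every off-diagonal in its row
    (rows with no samples are ignored)."""
    for cls in cm.index:
        row = cm.loc[cls]
        if row.sum() == 0:
            continue
        off = row.drop(cls)
        if not (row[cls] > off).all():
            return False
    return True


def accuracy(true_labels, pred_labels) -> float:
    t = np.asarray([str(x) for x in true_labels])
    p = np.asarray([str(x) for x in pred_labels])
    return float(np.mean(t == p))
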