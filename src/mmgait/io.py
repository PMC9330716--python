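"""Readers and writers: the 17-column point-cloud CSV dialect, skeleton
files, scenario configurations and shipped reference data.

The point-cloud dialect (one row per detection)::

    time, target_idx, x, y, z, range, velocity, doppler_bin, bearing,
    intensity, elevation, posX, posY, posZ, velX, velY, velZ

``time`` is seconds since capture start; ``velocity`` the radial Doppler
(m/s, approaching positive); ``bearing``/``elevation`` degrees (bearing
positive to the radar's left); ``pos*/vel*`` the tracker's state for the
point's track (NaN when untracked).  Parsing is header-keyed, so column
order does not matter and extra columns are tolerated.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import GaitScenario, JOINTS19, SubjectSpec
from .pointcloud import PointCloudFrame
from .radar import RadarConfig, RadarMount, derive_quantities

logger = logging.getLogger("mmgait")

POINTCLOUD_COLUMNS = [
    "time", "target_idx", "x", "y", "z", "range", "velocity", "doppler_bin",
    "bearing", "intensity", "elevation", "posX", "posY", "posZ",
    "velX", "velY", "velZ",
]


def pointcloud_to_dataframe(frames: list[PointCloudFrame],
                            config: RadarConfig | None = None,
                            mount: RadarMount | None = None) -> pd.DataFrame:
    """Flatten frames into the 17-column dialect (one row per point)."""
    config = config or RadarConfig()
    mount = mount or RadarMount()
    dq = derive_quantities(config)
    rows = []
    for f in frames:
        n = len(f)
        if n == 0:
            continue
        r, az, el = mount.world_to_spherical(f.xyz)
        rng_m = np.where(np.isfinite(f.rng), f.rng, r)
        rows.append(pd.DataFrame({
            "time": np.full(n, f.timestamp),
            "target_idx": f.track_id,
            "x": f.xyz[:, 0], "y": f.xyz[:, 1], "z": f.xyz[:, 2],
            "range": rng_m,
            "velocity": f.doppler,
            "doppler_bin": np.round(f.doppler / dq.doppler_resolution
                                    ).astype(int),
            "bearing": az, "intensity": f.intensity, "elevation": el,
            "posX": f.track_state[:, 0], "posY": f.track_state[:, 1],
            "posZ": f.track_state[:, 2], "velX": f.track_state[:, 3],
            "velY": f.track_state[:, 4], "velZ": f.track_state[:, 5],
        }))
    if not rows:
        return pd.DataFrame(columns=POINTCLOUD_COLUMNS)
    return pd.concat(rows, ignore_index=True)[POINTCLOUD_COLUMNS]


def dataframe_to_frames(df: pd.DataFrame) -> list[PointCloudFrame]:
    """Group rows by identical ``time`` into frames (chronological)."""
    frames = []
    for t, g in df.groupby("time", sort=True):
        frames.append(PointCloudFrame(
            timestamp=float(t),
            xyz=g[["x", "y", "z"]].to_numpy(float),
            doppler=g["velocity"].to_numpy(float),
            intensity=g["intensity"].to_numpy(float),
            rng=g["range"].to_numpy(float),
            track_id=g["target_idx"].to_numpy(int),
            track_state=g[["posX", "posY", "posZ",
                           "velX", "velY", "velZ"]].to_numpy(float),
        ))
    return frames


def write_pointcloud_csv(frames_or_df, path,
                         config: RadarConfig | None = None,
                         mount: RadarMount | None = None) -> None:
    df = (frames_or_df if isinstance(frames_or_df, pd.DataFrame)
          else pointcloud_to_dataframe(frames_or_df, config, mount))
    df.to_csv(path, index=False, float_format="%.6f")


def read_pointcloud_csv(path) -> pd.DataFrame:
    """Read and validate the dialect; errors name the missing column or the
    offending row."""
    df = pd.read_csv(path)
    missing = [c for c in POINTCLOUD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in POINTCLOUD_COLUMNS]
    if extra:
        logger.info("ignoring extra columns: %s", ", ".join(extra))
    for col in POINTCLOUD_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() \
            & ~df[col].astype(str).str.strip().str.lower().isin(("nan", ""))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, row {row + 2}")   # +2: header + 1-based
        df[col] = coerced
    return df[POINTCLOUD_COLUMNS + extra]


# ---------------------------------------------------------------------------
# skeleton files: per-frame rows `timestamp, joint_name, x, y, z`
# ---------------------------------------------------------------------------

def write_skeleton_csv(timestamps: np.ndarray, joints: np.ndarray, path,
                       joint_names: tuple = JOINTS19) -> None:
    """One file per subject; joints (n_frames, n_joints, 3) in metres."""
    joints = np.asarray(joints, dtype=float)
    n, j, _ = joints.shape
    if j != len(joint_names):
        raise ValueError(f"{j} joints but {len(joint_names)} names")
    df = pd.DataFrame({
        "timestamp": np.repeat(np.asarray(timestamps, float), j),
        "joint_name": list(joint_names) * n,
        "x": joints[:, :, 0].ravel(),
        "y": joints[:, :, 1].ravel(),
        "z": joints[:, :, 2].ravel(),
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_skeleton_csv(path) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Returns (timestamps (n,), joints (n, j, 3), joint names)."""
    df = pd.read_csv(path)
    for col in ("timestamp", "joint_name", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    names = tuple(df["joint_name"].drop_duplicates())
    j = len(names)
    ts = df["timestamp"].to_numpy(float)[::j]
    joints = df[["x", "y", "z"]].to_numpy(float).reshape(-1, j, 3)
    return ts, joints, names


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

def scenario_to_yaml(scenario: GaitScenario, path) -> None:
    from dataclasses import asdict
    data = {
        "duration": scenario.duration,
        "frame_period": scenario.frame_period,
        "seed": scenario.seed,
        "path_type": scenario.path_type,
        "subjects": [asdict(s) for s in scenario.subjects],
    }
    for s in data["subjects"]:
        s["start_position"] = list(s["start_position"])
        s["device_offset"] = list(s["device_offset"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def scenario_from_yaml(path) -> GaitScenario:
    data = yaml.safe_load(Path(path).read_text())
    subjects = []
    for s in data.pop("subjects"):
        s["start_position"] = tuple(s["start_position"])
        s["device_offset"] = tuple(s.get("device_offset", (0.0, 0.45, 0.9)))
        subjects.append(SubjectSpec(**s))
    return GaitScenario(subjects=tuple(subjects), **data)


# ---------------------------------------------------------------------------
# shipped data
# ---------------------------------------------------------------------------

def default_config() -> RadarConfig:
    """The shipped 60 GHz ODS waveform configuration."""
    with resources.as_file(resources.files("mmgait.data")
                           / "iwr6843_ods.yaml") as p:
        return RadarConfig.from_yaml(p)


def load_reference_joint_errors() -> pd.DataFrame:
    """Published per-joint MAE/RMSE (cm) of a Kinect-supervised radar pose
    regressor; used as the input for aggregate-error checks."""
    with resources.as_file(resources.files("mmgait.data")
                           / "reference_joint_errors.csv") as p:
        return pd.read_csv(p, index_col=0)
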