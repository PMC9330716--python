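"""5D radar point clouds and the scatterer stand-in for body reflections.

A detection carries (x, y, z, Doppler, intensity) plus cluster/track ids.
Frames hold points as parallel numpy arrays for vectorized processing;
:class:`RadarPoint` is a per-point convenience view.

``scatterers_from_skeleton`` turns a joint trajectory into a physical
stand-in for the body's reflection centres: one scatterer per joint plus
limb/torso midpoints, torso points more reflective than extremities, with
velocities by finite differencing.  ``synth_point_clouds`` is the fast
simulation path: it emulates the sparse, jittery clouds a real detector
produces without synthesizing echoes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .kinematics import K25, JointTrajectory, SubjectSpec
from .radar import RadarConfig, RadarMount, derive_quantities


@dataclass(frozen=True)
class RadarPoint:
    x: float
    y: float
    z: float
    range: float
    doppler: float
    intensity: float
    frame_time: float = 0.0
    cluster_id: int | None = None
    track_id: int | None = None


@dataclass
class PointCloudFrame:
    """One frame of 5D detections (parallel arrays, one row per point)."""

    timestamp: float
    xyz: np.ndarray                      # (n, 3) world m
    doppler: np.ndarray                  # (n,) m/s, approaching > 0
    intensity: np.ndarray                # (n,) >= 0
    rng: np.ndarray | None = None        # (n,) m from the sensor
    cluster_id: np.ndarray = None        # (n,) int, -1 = noise/unassigned
    track_id: np.ndarray = None          # (n,) int, -1 = unassigned
    track_state: np.ndarray = None       # (n, 6) tracker pos+vel, NaN if none

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float)).reshape(-1, 3)
        n = len(self.xyz)
        self.doppler = np.asarray(self.doppler, dtype=float).reshape(n)
        self.intensity = np.asarray(self.intensity, dtype=float).reshape(n)
        if self.rng is None:
            self.rng = np.full(n, np.nan)
        else:
            self.rng = np.asarray(self.rng, dtype=float).reshape(n)
        if self.cluster_id is None:
            self.cluster_id = np.full(n, -1, dtype=int)
        if self.track_id is None:
            self.track_id = np.full(n, -1, dtype=int)
        if self.track_state is None:
            self.track_state = np.full((n, 6), np.nan)

    def __len__(self) -> int:
        return len(self.xyz)

    def __iter__(self) -> Iterator[RadarPoint]:
        for i in range(len(self)):
            yield self.point(i)

    def point(self, i: int) -> RadarPoint:
        cid, tid = int(self.cluster_id[i]), int(self.track_id[i])
        return RadarPoint(
            x=float(self.xyz[i, 0]), y=float(self.xyz[i, 1]), z=float(self.xyz[i, 2]),
            range=float(self.rng[i]), doppler=float(self.doppler[i]),
            intensity=float(self.intensity[i]), frame_time=self.timestamp,
            cluster_id=None if cid < 0 else cid, track_id=None if tid < 0 else tid,
        )

    def subset(self, mask: np.ndarray) -> "PointCloudFrame":
        return PointCloudFrame(
            timestamp=self.timestamp, xyz=self.xyz[mask],
            doppler=self.doppler[mask], intensity=self.intensity[mask],
            rng=self.rng[mask], cluster_id=self.cluster_id[mask],
            track_id=self.track_id[mask], track_state=self.track_state[mask],
        )


@dataclass
class ScattererSet:
    """Per-frame reflection centres: (n_frames, n_scat, 3) positions and
    velocities plus per-scatterer reflectivity (constant over time)."""

    timestamps: np.ndarray
    positions: np.ndarray      # (n_frames, n_scat, 3) m
    velocities: np.ndarray     # (n_frames, n_scat, 3) m/s
    reflectivity: np.ndarray   # (n_scat,)
    subject_id: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[1]

    @staticmethod
    def merge(sets: Sequence["ScattererSet"]) -> "ScattererSet":
        """Concatenate scatterers of several subjects sharing timestamps."""
        first = sets[0]
        return ScattererSet(
            timestamps=first.timestamps,
            positions=np.concatenate([s.positions for s in sets], axis=1),
            velocities=np.concatenate([s.velocities for s in sets], axis=1),
            reflectivity=np.concatenate([s.reflectivity for s in sets]),
            subject_id=-1,
        )


# reflectivity by body region: the torso presents a far larger cross-section
# than distal limb segments
_TORSO = {"SpineBase", "SpineMid", "SpineShoulder", "Neck", "Head",
          "ShoulderLeft", "ShoulderRight", "HipLeft", "HipRight"}
_LIMB = {"ElbowLeft", "ElbowRight", "KneeLeft", "KneeRight"}

_MIDPOINT_SEGMENTS = (
    ("HipLeft", "KneeLeft"), ("KneeLeft", "AnkleLeft"),
    ("HipRight", "KneeRight"), ("KneeRight", "AnkleRight"),
    ("ShoulderLeft", "ElbowLeft"), ("ElbowLeft", "WristLeft"),
    ("ShoulderRight", "ElbowRight"), ("ElbowRight", "WristRight"),
    ("SpineBase", "SpineMid"), ("SpineMid", "SpineShoulder"),
)


def _joint_reflectivity(name: str) -> float:
    if name in _TORSO:
        return 1.0
    if name in _LIMB:
        return 0.35
    return 0.18


def scatterers_from_skeleton(traj: JointTrajectory,
                             spec: SubjectSpec | None = None) -> ScattererSet:
    """Build the reflection-centre set for one subject's trajectory.

    One scatterer per joint, one per limb/torso segment midpoint, plus the
    assistive-device anchors (walker frame corners / cane grip+tip) when
    present.  Velocities are central finite differences of position.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    from .kinematics import KINECT25_JOINTS

    joints = traj.joints                                   # (T, 25, 3)
    mids = np.stack(
        [0.5 * (joints[:, K25[a]] + joints[:, K25[b]])
         for a, b in _MIDPOINT_SEGMENTS], axis=1)
    parts = [joints, mids]
    refl = ([_joint_reflectivity(nm) for nm in KINECT25_JOINTS]
            + [0.45] * len(_MIDPOINT_SEGMENTS))
    if traj.device_points.shape[1]:
        parts.append(traj.device_points)
        refl += [0.8] * traj.device_points.shape[1]        # metal frame/shaft
    pos = np.concatenate(parts, axis=1)

    dt = np.gradient(traj.timestamps)
    vel = np.gradient(pos, axis=0) / dt[:, None, None]
    return ScattererSet(timestamps=traj.timestamps.copy(), positions=pos,
                        velocities=vel, reflectivity=np.asarray(refl, float),
                        subject_id=traj.subject_id)


def radial_doppler(positions: np.ndarray, velocities: np.ndarray,
                   mount: RadarMount) -> tuple[np.ndarray, np.ndarray]:
    """Range and Doppler (approaching > 0) of world points w.r.t. the sensor."""
    rel = positions - mount.position
    r = np.linalg.norm(rel, axis=-1)
    los = rel / np.maximum(r, 1e-12)[..., None]
    dop = -np.sum(los * velocities, axis=-1)
    return r, dop


def synth_point_clouds(scatterers: ScattererSet, config: RadarConfig,
                       dropout_prob: float = 0.35, jitter_std: float = 0.06,
                       radial_jitter_std: float = 0.02,
                       doppler_noise_std: float = 0.04,
                       seed: int | np.random.Generator = 0,
                       mount: RadarMount | None = None) -> list[PointCloudFrame]:
    """Fast simulation path: sparse, noisy detections without echo synthesis.

    Each scatterer is independently dropped with ``dropout_prob``; survivors
    get anisotropic positional jitter — ``radial_jitter_std`` along the line
    of sight (range is measured precisely) and the larger ``jitter_std``
    across it (angles are coarse with a small aperture; the elevation-like
    tangent gets n_rx/n_tx times more, mirroring the smaller elevation
    aperture) — plus Doppler = radial velocity + noise and intensity
    proportional to reflectivity/r^2.
    """
    if not 0.0 <= dropout_prob < 1.0:
        raise ValueError("dropout_prob must lie in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mount = mount or RadarMount()
    frames: list[PointCloudFrame] = []
    for f in range(scatterers.n_frames):
        pos = scatterers.positions[f]
        vel = scatterers.velocities[f]
        keep = rng.random(len(pos)) >= dropout_prob
        pos = pos[keep]
        if jitter_std > 0 or radial_jitter_std > 0:
            rel = pos - mount.position
            u = rel / np.maximum(np.linalg.norm(rel, axis=1, keepdims=True),
                                 1e-12)
            t1 = np.cross(u, [0.0, 0.0, 1.0])
            t1 /= np.maximum(np.linalg.norm(t1, axis=1, keepdims=True), 1e-12)
            t2 = np.cross(u, t1)
            n = len(pos)
            elev_factor = config.n_rx / config.n_tx
            pos = (pos + u * rng.normal(0, radial_jitter_std, (n, 1))
                   + t1 * rng.normal(0, jitter_std, (n, 1))
                   + t2 * rng.normal(0, elev_factor * jitter_std, (n, 1)))
        vel = vel[keep]
        r, dop = radial_doppler(pos, vel, mount)
        if doppler_noise_std > 0:
            dop = dop + rng.normal(0.0, doppler_noise_std, len(dop))
        inten = scatterers.reflectivity[keep] / np.maximum(r, 0.3) ** 2
        frames.append(PointCloudFrame(
            timestamp=float(scatterers.timestamps[f]), xyz=pos,
            doppler=dop, intensity=inten, rng=r,
        ))
    return frames
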