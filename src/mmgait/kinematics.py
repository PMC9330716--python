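"""Parametric gait kinematics: 25-joint skeleton trajectories for five gait classes.

The model is a rigid-segment kinematic chain driven by phase-offset sinusoidal
oscillators (thigh swing, knee flexion, arm swing, pelvic sway and bob), not a
biomechanical simulator.  It exists to produce class-discriminable radar
signatures and paired Kinect-style ground truth:

* W1 normal      — symmetric swing, upright trunk.
* W2 stooped     — trunk pitched forward, reduced arm swing, slower.
* W3 limp        — one leg's swing amplitude scaled down (shorter step) with
                   exaggerated lateral trunk sway.
* W4 walker      — slow, both arms reaching forward to the frame, a 4-point
                   rolling-walker rigid body leading the subject.
* W5 cane        — one arm holds a 2-point cane tracking that hand to the
                   ground, its swing suppressed.

Joint order follows the Kinect V2 convention (25 joints); the 19-joint
reporting order used for pose regression lives alongside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

GAIT_CLASSES = ("W1", "W2", "W3", "W4", "W5")
GAIT_CLASS_NAMES = {
    "W1": "walking normal",
    "W2": "walking with stooped posture",
    "W3": "walking with limp",
    "W4": "walking with a walker",
    "W5": "walking with a cane",
}

# Kinect V2 joint order.
KINECT25_JOINTS = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)
K25 = {name: i for i, name in enumerate(KINECT25_JOINTS)}

# 19-joint reporting order (head-to-foot), the pose-regression target space.
JOINTS19 = (
    "Head", "Neck", "Spine Shoulder", "Shoulder Left", "Shoulder Right",
    "Elbow Left", "Elbow Right", "Wrist Left", "Wrist Right",
    "Spine Mid", "Spine Base", "Hip Left", "Hip Right",
    "Knee Left", "Knee Right", "Ankle Left", "Ankle Right",
    "Foot Left", "Foot Right",
)
J19 = {name: i for i, name in enumerate(JOINTS19)}

# Kinect-order index of each 19-joint entry (the 6 dropped joints are the
# per-hand duplicates: Hand, HandTip, Thumb on each side).
JOINTS19_TO_KINECT25 = (
    K25["Head"], K25["Neck"], K25["SpineShoulder"],
    K25["ShoulderLeft"], K25["ShoulderRight"],
    K25["ElbowLeft"], K25["ElbowRight"],
    K25["WristLeft"], K25["WristRight"],
    K25["SpineMid"], K25["SpineBase"],
    K25["HipLeft"], K25["HipRight"],
    K25["KneeLeft"], K25["KneeRight"],
    K25["AnkleLeft"], K25["AnkleRight"],
    K25["FootLeft"], K25["FootRight"],
)

# Per-hand wrist candidates ("recorded twice" by Kinect): wrist, hand,
# hand-tip, thumb.
WRIST_CANDIDATES_LEFT = (K25["WristLeft"], K25["HandLeft"],
                         K25["HandTipLeft"], K25["ThumbLeft"])
WRIST_CANDIDATES_RIGHT = (K25["WristRight"], K25["HandRight"],
                          K25["HandTipRight"], K25["ThumbRight"])


@dataclass(frozen=True)
class SubjectSpec:
    """One walking subject: gait class plus kinematic parameters."""

    gait_class: str = "W1"
    height: float = 1.70            # m
    walking_speed: float = 1.2      # m/s
    cadence: float = 1.9            # steps/s
    start_position: tuple = (0.0, 4.0)   # (x, y) m on the floor
    heading: float = math.pi / 2.0  # rad, 0 = +x, pi/2 = +y (away from radar)
    hip_amplitude: float = 0.35     # rad, thigh swing half-angle
    knee_amplitude: float = 0.45    # rad, swing-phase knee flexion
    arm_amplitude: float = 0.35     # rad, arm swing half-angle
    sway_amplitude: float = 0.025   # m, lateral pelvic sway
    bob_amplitude: float = 0.02     # m, vertical pelvic bob
    limp_asymmetry: float = 1.0     # affected/unaffected step-length ratio (W3)
    limp_side: str = "left"
    stoop_pitch: float = 0.0        # rad, forward trunk pitch (W2)
    device_offset: tuple = (0.0, 0.45, 0.9)  # m, device anchor rel. pelvis (W4/W5)
    subject_id: int = 0

    def __post_init__(self) -> None:
        if self.gait_class not in GAIT_CLASSES:
            raise ValueError(f"unknown gait class {self.gait_class!r}; "
                             f"expected one of {GAIT_CLASSES}")
        if self.walking_speed < 0:
            raise ValueError("walking_speed must be >= 0")
        if not 0.0 <= self.limp_asymmetry <= 1.0:
            raise ValueError("limp_asymmetry must lie in [0, 1]")

    def replace(self, **kw) -> "SubjectSpec":
        return replace(self, **kw)


# Class-typical parameter adjustments applied by `sample_subject`.
_CLASS_DEFAULTS = {
    "W1": dict(walking_speed=1.25, cadence=1.9),
    "W2": dict(walking_speed=0.9, cadence=1.7, stoop_pitch=0.35,
               arm_amplitude=0.12, hip_amplitude=0.28),
    "W3": dict(walking_speed=0.9, cadence=1.7, limp_asymmetry=0.55,
               sway_amplitude=0.07),
    "W4": dict(walking_speed=0.55, cadence=1.3, arm_amplitude=0.0,
               hip_amplitude=0.22, device_offset=(0.0, 0.45, 0.9)),
    "W5": dict(walking_speed=0.85, cadence=1.6, arm_amplitude=0.30,
               device_offset=(0.25, 0.15, 0.0)),
}

# Study-population height distribution (cm -> m): 170 +- 5.55.
_HEIGHT_MEAN, _HEIGHT_SD = 1.70, 0.0555


def sample_subject(gait_class: str, rng: np.random.Generator,
                   subject_id: int = 0, **overrides) -> SubjectSpec:
    """Draw a subject of the given class with population-typical variation."""
    if gait_class not in GAIT_CLASSES:
        raise ValueError(f"unknown gait class {gait_class!r}")
    base = dict(_CLASS_DEFAULTS[gait_class])
    height = float(np.clip(rng.normal(_HEIGHT_MEAN, _HEIGHT_SD), 1.50, 1.90))
    base["walking_speed"] *= float(rng.uniform(0.85, 1.15))
    base["cadence"] *= float(rng.uniform(0.9, 1.1))
    if gait_class == "W2":
        base["stoop_pitch"] *= float(rng.uniform(0.8, 1.25))
    if gait_class == "W3":
        base["limp_asymmetry"] = float(rng.uniform(0.4, 0.7))
        base["limp_side"] = "left" if rng.random() < 0.5 else "right"
    start = (float(rng.uniform(-1.5, 1.5)), float(rng.uniform(2.5, 6.0)))
    spec = SubjectSpec(gait_class=gait_class, height=height,
                       start_position=start, subject_id=subject_id, **base)
    return spec.replace(**overrides) if overrides else spec


@dataclass(frozen=True)
class GaitScenario:
    """A recording session: subjects, duration and the walk-path scenario."""

    subjects: Sequence[SubjectSpec] = field(default_factory=lambda: (SubjectSpec(),))
    duration: float = 10.0          # s
    frame_period: float = 55e-3     # s
    seed: int = 0
    path_type: str = "perpendicular"   # perpendicular | parallel | free

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.subjects:
            raise ValueError("a scenario needs at least one subject")
        if self.path_type not in ("perpendicular", "parallel", "free"):
            raise ValueError(f"unknown path_type {self.path_type!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_period))

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period


@dataclass
class JointTrajectory:
    """Per-frame 25-joint skeletons for one subject, plus device anchors.

    ``joints`` has shape (n_frames, 25, 3) in world coordinates (m);
    ``device_points`` is (n_frames, k, 3) with k = 0 unless the subject uses
    a walker (4 frame corners) or cane (grip + tip).
    """

    timestamps: np.ndarray
    joints: np.ndarray
    device_points: np.ndarray
    subject_id: int = 0
    gait_class: str = "W1"

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def joints19(self) -> np.ndarray:
        """(n_frames, 19, 3) view in the reporting joint order."""
        return self.joints[:, JOINTS19_TO_KINECT25, :]


# Segment lengths as fractions of standing height.
_PROP = dict(
    hip_height=0.50, spine_base=0.55, spine_mid=0.70, spine_shoulder=0.80,
    neck=0.84, head=0.93, shoulder_halfwidth=0.11, hip_halfwidth=0.09,
    thigh=0.245, shank=0.246, foot=0.10, upper_arm=0.186, forearm=0.146,
)

# Walk-area bounds for turnarounds (m).
_XLIM = (-3.0, 3.0)
_YLIM = (1.5, 7.5)


def _path(spec: SubjectSpec, scenario: GaitScenario,
          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Root path (n,2) and unit forward direction (n,2) with turnarounds."""
    n = scenario.n_frames
    dt = scenario.frame_period
    # "perpendicular": path perpendicular to the boresight (a lateral
    # crossing, the dominant depth-displacement-free collection walk);
    # "parallel": along the boresight (toward/away from the sensor)
    if scenario.path_type == "perpendicular":
        heading = 0.0 if abs(spec.heading) <= math.pi / 2 else math.pi
    elif scenario.path_type == "parallel":
        heading = math.pi / 2.0 if math.sin(spec.heading) >= 0 else -math.pi / 2
    else:
        heading = spec.heading
    pos = np.array(spec.start_position, dtype=float)
    hd = float(heading)
    hd_target = hd
    max_turn = 2.5 * dt           # rad per frame: smooth U-turns
    margin = 0.6
    out_p = np.empty((n, 2))
    out_u = np.empty((n, 2))
    for i in range(n):
        u = np.array([math.cos(hd), math.sin(hd)])
        out_p[i] = pos
        out_u[i] = u
        step = spec.walking_speed * dt
        # command a turn-back when approaching the walk-area boundary
        # while still moving toward it (forward-and-back collection)
        if (pos[0] > _XLIM[1] - margin and math.cos(hd_target) > 0) or \
                (pos[0] < _XLIM[0] + margin and math.cos(hd_target) < 0):
            hd_target = math.pi - hd_target
        if (pos[1] > _YLIM[1] - margin and math.sin(hd_target) > 0) or \
                (pos[1] < _YLIM[0] + margin and math.sin(hd_target) < 0):
            hd_target = -hd_target
        if scenario.path_type == "free":
            hd_target += float(rng.normal(0.0, 0.06))
        diff = math.remainder(hd_target - hd, math.tau)
        hd += float(np.clip(diff, -max_turn, max_turn))
        pos = pos + np.array([math.cos(hd), math.sin(hd)]) * step
    return out_p, out_u


def synth_skeleton_trajectory(spec: SubjectSpec, scenario: GaitScenario,
                              rng: np.random.Generator | None = None) -> JointTrajectory:
    """Generate one subject's rigid-segment 25-joint walking trajectory.

    Limb oscillators run at the stride frequency (cadence / 2); the two legs
    are anti-phase, each arm anti-phase with its ipsilateral leg.  Bone
    lengths are constant over time by construction (forward kinematics from
    joint angles).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 7919 * spec.subject_id)
    h = spec.height
    L = {k: v * h for k, v in _PROP.items()}
    n = scenario.n_frames
    ts = scenario.timestamps
    root_xy, fwd_xy = _path(spec, scenario, rng)

    f_stride = spec.cadence / 2.0
    phi = 2.0 * math.pi * f_stride * ts            # stride phase
    joints = np.zeros((n, 25, 3))

    u = np.concatenate([fwd_xy, np.zeros((n, 1))], axis=1)       # forward
    nvec = np.stack([-fwd_xy[:, 1], fwd_xy[:, 0], np.zeros(n)], axis=1)  # left
    zhat = np.array([0.0, 0.0, 1.0])

    # pelvis with lateral sway (stride-rate) and vertical bob (step-rate)
    sway = spec.sway_amplitude * np.sin(phi)
    bob = spec.bob_amplitude * np.cos(2.0 * phi)
    pelvis = (np.concatenate([root_xy, np.zeros((n, 1))], axis=1)
              + nvec * sway[:, None] + zhat[None, :] * (L["hip_height"] + bob)[:, None])

    # trunk axis pitched forward by stoop_pitch about the lateral axis
    pitch = spec.stoop_pitch
    t_axis = math.cos(pitch) * zhat[None, :] + math.sin(pitch) * u

    sb = pelvis + (L["spine_base"] - L["hip_height"]) * t_axis
    joints[:, K25["SpineBase"]] = sb
    joints[:, K25["SpineMid"]] = sb + (L["spine_mid"] - L["spine_base"]) * t_axis
    ss = sb + (L["spine_shoulder"] - L["spine_base"]) * t_axis
    joints[:, K25["SpineShoulder"]] = ss
    joints[:, K25["Neck"]] = sb + (L["neck"] - L["spine_base"]) * t_axis
    joints[:, K25["Head"]] = sb + (L["head"] - L["spine_base"]) * t_axis

    # --- legs -----------------------------------------------------------
    amp = {"left": spec.hip_amplitude, "right": spec.hip_amplitude}
    kamp = {"left": spec.knee_amplitude, "right": spec.knee_amplitude}
    if spec.gait_class == "W3":
        amp[spec.limp_side] *= spec.limp_asymmetry
        kamp[spec.limp_side] *= spec.limp_asymmetry
    leg_phase = {"left": phi, "right": phi + math.pi}
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        ph = leg_phase[side]
        alpha = amp[side] * np.sin(ph)                       # thigh vs vertical
        beta = kamp[side] * np.maximum(0.0, np.sin(ph))      # knee flexion
        hip = pelvis + sgn * L["hip_halfwidth"] * nvec
        sa, ca = np.sin(alpha)[:, None], np.cos(alpha)[:, None]
        knee = hip + L["thigh"] * (sa * u - ca * zhat[None, :])
        th2 = alpha - beta
        s2, c2 = np.sin(th2)[:, None], np.cos(th2)[:, None]
        ankle = knee + L["shank"] * (s2 * u - c2 * zhat[None, :])
        foot = ankle + L["foot"] * (c2 * u + s2 * zhat[None, :])
        cap = side.capitalize()
        joints[:, K25[f"Hip{cap}"]] = hip
        joints[:, K25[f"Knee{cap}"]] = knee
        joints[:, K25[f"Ankle{cap}"]] = ankle
        joints[:, K25[f"Foot{cap}"]] = foot

    # --- arms -----------------------------------------------------------
    arm_amp = {"left": spec.arm_amplitude, "right": spec.arm_amplitude}
    arm_bias = {"left": 0.0, "right": 0.0}     # constant forward reach, rad
    if spec.gait_class == "W4":
        arm_amp = {"left": 0.02, "right": 0.02}
        arm_bias = {"left": 0.55, "right": 0.55}   # hands forward on the frame
    elif spec.gait_class == "W5":
        cane_side = "right"
        arm_amp[cane_side] = 0.05                  # grip arm barely swings
        arm_bias[cane_side] = 0.25
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        ph = leg_phase[side] + math.pi              # anti-phase with own leg
        gamma = arm_bias[side] + arm_amp[side] * np.sin(ph)
        shoulder = ss + sgn * L["shoulder_halfwidth"] * nvec
        sg, cg = np.sin(gamma)[:, None], np.cos(gamma)[:, None]
        elbow = shoulder + L["upper_arm"] * (sg * u - cg * zhat[None, :])
        ge = gamma + 0.25                           # slight constant elbow flexion
        sge, cge = np.sin(ge)[:, None], np.cos(ge)[:, None]
        fdir = sge * u - cge * zhat[None, :]
        wrist = elbow + L["forearm"] * fdir
        cap = side.capitalize()
        joints[:, K25[f"Shoulder{cap}"]] = shoulder
        joints[:, K25[f"Elbow{cap}"]] = elbow
        joints[:, K25[f"Wrist{cap}"]] = wrist
        # hand-region duplicates cluster just beyond the wrist
        joints[:, K25[f"Hand{cap}"]] = wrist + 0.04 * fdir
        joints[:, K25[f"HandTip{cap}"]] = wrist + 0.10 * fdir
        joints[:, K25[f"Thumb{cap}"]] = wrist + 0.04 * fdir + sgn * 0.03 * nvec

    # --- assistive device anchors --------------------------------------
    if spec.gait_class == "W4":
        off = np.asarray(spec.device_offset)
        base = (np.concatenate([root_xy, np.zeros((n, 1))], axis=1)
                + off[0] * nvec + off[1] * u)
        wob = 0.01 * np.sin(phi)[:, None] * u
        hw = 0.25
        device = np.stack([
            base + hw * nvec + off[2] * zhat[None, :] + wob,   # left handle
            base - hw * nvec + off[2] * zhat[None, :] + wob,   # right handle
            base + hw * nvec + 0.05 * zhat[None, :] + wob,     # left leg/wheel
            base - hw * nvec + 0.05 * zhat[None, :] + wob,     # right leg/wheel
        ], axis=1)
    elif spec.gait_class == "W5":
        grip = joints[:, K25["WristRight"]]
        tip = grip.copy()
        tip[:, 2] = 0.0
        tip[:, :2] += 0.15 * fwd_xy                     # planted ahead of the hand
        device = np.stack([grip + 0.02 * zhat[None, :], tip], axis=1)
    else:
        device = np.zeros((n, 0, 3))

    return JointTrajectory(timestamps=ts.copy(), joints=joints,
                           device_points=device, subject_id=spec.subject_id,
                           gait_class=spec.gait_class)


# ---------------------------------------------------------------------------
# feature extraction used for validation and the skeleton branch of fusion
# ---------------------------------------------------------------------------

def trunk_pitch(joints19: np.ndarray) -> np.ndarray:
    """Forward trunk pitch (rad) per frame from spine-base -> neck."""
    vec = joints19[:, J19["Neck"]] - joints19[:, J19["Spine Base"]]
    horiz = np.linalg.norm(vec[:, :2], axis=1)
    return np.arctan2(horiz, vec[:, 2])


def step_length_ratio(joints19: np.ndarray) -> float:
    """Left/right step-length ratio from foot excursions relative to the pelvis.

    Step length scales with a foot's fore-aft excursion about the trunk; the
    peak-to-peak excursion of each foot relative to the spine base, projected
    on the instantaneous heading (smoothed spine-base velocity direction),
    is a robust stand-in that needs no event detection.
    """
    sb = joints19[:, J19["Spine Base"], :2]
    vel = np.gradient(sb, axis=0)
    # smooth the heading over ~half a stride to suppress sway
    k = min(9, len(vel))
    kernel = np.ones(k) / k
    vs = np.stack([np.convolve(vel[:, i], kernel, mode="same")
                   for i in range(2)], axis=1)
    norm = np.linalg.norm(vs, axis=1, keepdims=True)
    u = np.divide(vs, norm, out=np.tile(np.array([[0.0, 1.0]]),
                                        (len(vs), 1)), where=norm > 1e-9)
    ratios = []
    for foot in ("Foot Left", "Foot Right"):
        rel = joints19[:, J19[foot], :2] - sb
        proj = np.sum(rel * u, axis=1)
        ratios.append(np.percentile(proj, 97.5) - np.percentile(proj, 2.5))
    if ratios[1] < 1e-9:
        return float("inf")
    return float(ratios[0] / ratios[1])
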