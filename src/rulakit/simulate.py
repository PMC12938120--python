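"""Synthetic lifting-task sessions with known ground-truth angles.

Emulates a standardized load-lifting trial recorded frontally at 30 FPS: a
60 s session with an initiation/acceleration phase (0-5 s), a loaded peak
(5-35 s), sustained elevation (35-50 s) and recovery (50-60 s).  Joint-angle
targets follow raised-cosine ramps between phase plateaus (C1 trajectories
with bounded derivatives), and an articulated kinematic chain with
anthropometric segment lengths converts them to the 33-landmark layout the
rest of the pipeline consumes.  Isotropic Gaussian landmark jitter and
random visibility dropouts emulate pose-estimator noise and occlusion.

Every generated session carries a per-frame :class:`GroundTruth`: trunk,
neck, lateral-tilt and elbow angles are exact by construction; arm flexion
and abduction under combined rotations are evaluated from the generator's
own direction vectors, independently of the landmark-parsing and kinematics
path under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import ANGLE_CHANNELS, JointAngles, KinematicsConfig
from .landmarks import LandmarkFrame, SessionStream, frames_from_arrays
from .rula import RulaConfig, SubScores, evaluate_frame


@dataclass
class LiftingProfile:
    """Parameters of one synthetic lifting trial.

    Peak angles are the plateau targets reached during the loaded-peak phase
    (degrees; trunk is the raw, pre-correction flexion).  ``sustained_level``
    scales the plateau during the sustained-elevation phase.  ``noise_sd`` is
    the isotropic per-coordinate landmark jitter in metres (the ~5 mm default
    corresponds to the few-pixel pre-filter jitter of markerless estimators
    at a ~2 m working distance).  Segment lengths are anthropometric round
    numbers for an average-stature adult.
    """

    fps: float = 30.0
    phase_durations: dict[str, float] = field(
        default_factory=lambda: {"initiation": 5.0, "peak": 30.0, "sustained": 15.0, "recovery": 10.0}
    )
    peak_trunk_flexion: float = 48.0
    peak_arm_flexion: float = 87.0
    peak_neck_flexion: float = 44.0
    peak_abduction: float = 30.0
    tilt_amplitude: float = 5.0
    elbow_baseline: float = 170.0
    elbow_peak: float = 90.0
    sustained_level: float = 0.75
    noise_sd: float = 0.005
    dropout_prob: float = 0.0
    seed: int = 0
    segment_lengths: dict[str, float] = field(
        default_factory=lambda: {
            "trunk": 0.5,
            "upper_arm": 0.3,
            "forearm": 0.27,
            "neck": 0.18,
            "shoulder_width": 0.4,
            "hip_width": 0.3,
            "ear_width": 0.15,
        }
    )

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.phase_durations.values()):
            raise ValueError("phase durations must be > 0")
        for name in ("peak_trunk_flexion", "peak_arm_flexion", "peak_neck_flexion",
                     "peak_abduction", "tilt_amplitude", "elbow_baseline", "elbow_peak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ValueError(f"{name}={v} outside [0, 180]")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def duration(self) -> float:
        return sum(self.phase_durations.values())


PRESETS: dict[str, LiftingProfile] = {
    "neutral": LiftingProfile(
        peak_trunk_flexion=0.0, peak_arm_flexion=0.0, peak_neck_flexion=0.0,
        peak_abduction=0.0, tilt_amplitude=0.0, elbow_peak=170.0, elbow_baseline=170.0,
    ),
    "moderate_lift": LiftingProfile(
        peak_trunk_flexion=30.0, peak_arm_flexion=50.0, peak_neck_flexion=20.0,
        peak_abduction=20.0, tilt_amplitude=4.0,
    ),
    "severe_lift": LiftingProfile(
        peak_trunk_flexion=60.0, peak_arm_flexion=95.0, peak_neck_flexion=40.0,
        peak_abduction=50.0, tilt_amplitude=12.0, elbow_peak=120.0,
    ),
}


def preset(name: str, **overrides) -> LiftingProfile:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


@dataclass
class GroundTruth:
    """Noise-free truth aligned with the generated frames."""

    angles: list[JointAngles]               # true post-convention angles (trunk corrected)
    raw_trunk: list[float]                  # pre-correction trunk flexion
    sub_scores: list[SubScores]             # expected under the given RulaConfig
    final_scores: list[int]
    envelope: np.ndarray                    # activation profile in [0, 1]

    def max_final(self) -> int:
        return max(self.final_scores)

    def is_critical(self, threshold: int = 5) -> bool:
        return self.max_final() >= threshold


def phase_envelope(t: np.ndarray, durations: dict[str, float], sustained_level: float,
                   transition_s: float = 2.0) -> np.ndarray:
    """Raised-cosine activation profile over the four task phases.

    0 -> 1 across initiation; 1 during the loaded peak; easing to
    ``sustained_level`` over the first ``transition_s`` of the sustained
    phase; back to 0 across recovery.
    """
    d1 = durations["initiation"]
    d2 = durations["peak"]
    d3 = durations["sustained"]
    d4 = durations["recovery"]
    tr = min(transition_s, d3 / 2.0)
    b1, b2, b3 = d1, d1 + d2, d1 + d2 + d3
    end = b3 + d4
    env = np.zeros_like(t, dtype=float)
    s = sustained_level

    m = t < b1
    env[m] = 0.5 * (1.0 - np.cos(np.pi * t[m] / d1))
    m = (t >= b1) & (t < b2)
    env[m] = 1.0
    m = (t >= b2) & (t < b2 + tr)
    env[m] = s + (1.0 - s) * 0.5 * (1.0 + np.cos(np.pi * (t[m] - b2) / tr))
    m = (t >= b2 + tr) & (t < b3)
    env[m] = s
    m = (t >= b3) & (t < end)
    env[m] = s * 0.5 * (1.0 + np.cos(np.pi * (t[m] - b3) / d4))
    env[t >= end] = 0.0
    return env


# -- small self-contained vector helpers (ground truth must not depend on the
#    kinematics module it is used to test) ----------------------------------

def _rot_z(deg: float) -> np.ndarray:
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cos = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cos))))


def _rotate_about(v: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    r = math.radians(deg)
    return (
        v * math.cos(r)
        + np.cross(axis, v) * math.sin(r)
        + axis * float(np.dot(axis, v)) * (1.0 - math.cos(r))
    )


def _pitch_forward(v: np.ndarray, deg: float) -> np.ndarray:
    """Rotate about the lateral (x) axis so +deg tips a vertical vector
    toward the camera (-z)."""
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    x, y, z = v
    return np.array([x, c * y + s * z, -s * y + c * z])


_SIDE_SIGN = {"left": -1.0, "right": 1.0}


def _chain_positions(profile: LiftingProfile, trunk: float, neck: float, arm: float,
                     abd: float, elbow: float, tilt: float) -> tuple[np.ndarray, dict]:
    """Landmark positions (33, 3) for one set of instantaneous joint angles.

    Returns the positions and the internal direction vectors used for the
    ground-truth arm angles.
    """
    L = profile.segment_lengths
    hip_center = np.array([0.0, 1.0, 2.0])
    x_hat = np.array([1.0, 0.0, 0.0])

    trunk_up = _pitch_forward(np.array([0.0, 1.0, 0.0]), trunk)
    shoulder_center = hip_center + L["trunk"] * trunk_up
    tilt_dir = _rot_z(tilt) @ x_hat                      # left->right shoulder direction
    neck_up = _pitch_forward(np.array([0.0, 1.0, 0.0]), trunk + neck)
    ear_center = shoulder_center + L["neck"] * neck_up

    pos = np.zeros((33, 3))
    hips = {}
    shoulders = {}
    internals: dict[str, np.ndarray] = {}
    for side, idx_hip, idx_sh in (("left", 23, 11), ("right", 24, 12)):
        sgn = _SIDE_SIGN[side]
        hips[side] = hip_center + sgn * 0.5 * L["hip_width"] * x_hat
        shoulders[side] = shoulder_center + sgn * 0.5 * L["shoulder_width"] * tilt_dir
        pos[idx_hip] = hips[side]
        pos[idx_sh] = shoulders[side]
    pos[7] = ear_center - 0.5 * L["ear_width"] * tilt_dir   # left ear
    pos[8] = ear_center + 0.5 * L["ear_width"] * tilt_dir   # right ear

    for side, idx_el, idx_wr in (("left", 13, 15), ("right", 14, 16)):
        sgn = _SIDE_SIGN[side]
        ref = hips[side] - shoulders[side]
        ref_dir = ref / np.linalg.norm(ref)
        d_arm = _pitch_forward(ref_dir, -arm)             # sagittal flexion: elbow swings toward the camera
        d_arm = _rot_z(sgn * abd) @ d_arm                 # outward frontal abduction
        elbow_pos = shoulders[side] + L["upper_arm"] * d_arm
        axis = np.cross(d_arm, x_hat)
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(d_arm, np.array([0.0, 0.0, 1.0]))
        d_fore = _rotate_about(d_arm, axis, 180.0 - elbow)
        wrist_pos = elbow_pos + L["forearm"] * d_fore
        pos[idx_el] = elbow_pos
        pos[idx_wr] = wrist_pos
        internals[f"ref_{side}"] = ref
        internals[f"arm_{side}"] = d_arm
        # hands (pinky/index/thumb) ride just beyond the wrist
        hand_base = wrist_pos + 0.08 * d_fore
        for k, idx in enumerate((17, 19, 21) if side == "left" else (18, 20, 22)):
            pos[idx] = hand_base + 0.01 * k * x_hat * _SIDE_SIGN[side]

    # face: nose and eyes ahead of the ear line, mouth below
    forward = np.array([0.0, 0.0, -1.0])
    pos[0] = ear_center + 0.10 * forward
    for k, idx in enumerate((1, 2, 3)):          # left eye landmarks
        pos[idx] = ear_center + 0.09 * forward - (0.02 + 0.01 * k) * tilt_dir + 0.02 * neck_up
    for k, idx in enumerate((4, 5, 6)):          # right eye landmarks
        pos[idx] = ear_center + 0.09 * forward + (0.02 + 0.01 * k) * tilt_dir + 0.02 * neck_up
    pos[9] = ear_center + 0.09 * forward - 0.02 * tilt_dir - 0.03 * neck_up
    pos[10] = ear_center + 0.09 * forward + 0.02 * tilt_dir - 0.03 * neck_up

    # legs: knees, ankles, heels, feet below the hips
    down = np.array([0.0, -1.0, 0.0])
    for side, (kn, ank, heel, foot) in (("left", (25, 27, 29, 31)), ("right", (26, 28, 30, 32))):
        h = hips[side]
        pos[kn] = h + 0.45 * down
        pos[ank] = h + 0.90 * down
        pos[heel] = pos[ank] + np.array([0.0, -0.05, 0.03])
        pos[foot] = pos[ank] + np.array([0.0, -0.05, -0.12])
    return pos, internals


def _true_joint_angles(profile: LiftingProfile, trunk: float, neck: float, arm: float,
                       abd: float, elbow: float, tilt: float,
                       internals: dict, trunk_correction: float) -> JointAngles:
    ja = JointAngles(
        trunk_flexion=min(180.0, max(0.0, trunk + trunk_correction)),
        neck_flexion=neck,
        lateral_tilt=abs(tilt),
        active_side="right",
        valid={c: True for c in ANGLE_CHANNELS},
    )
    for side in ("left", "right"):
        ref = internals[f"ref_{side}"]
        d_arm = internals[f"arm_{side}"]
        setattr(ja, f"arm_flexion_{side}", _angle_deg(d_arm, ref))
        pa = np.array([d_arm[0], d_arm[1], 0.0])
        pb = np.array([ref[0], ref[1], 0.0])
        setattr(ja, f"arm_abduction_{side}", _angle_deg(pa, pb))
        setattr(ja, f"forearm_angle_{side}", elbow)
    return ja


def generate_session(
    profile: LiftingProfile,
    rula_cfg: RulaConfig | None = None,
    kin_cfg: KinematicsConfig | None = None,
    metadata: dict[str, str] | None = None,
) -> tuple[SessionStream, GroundTruth]:
    """One synthetic lifting trial plus its frame-aligned ground truth.

    Deterministic given ``profile.seed``.  Dropouts set the affected
    landmark's visibility below 0.5 so the downstream gating rule fires.
    """
    rula_cfg = rula_cfg or RulaConfig()
    kin_cfg = kin_cfg or KinematicsConfig()
    rng = np.random.default_rng(profile.seed)
    n = int(round(profile.duration() * profile.fps))
    ts = np.arange(n) / profile.fps
    env = phase_envelope(ts, profile.phase_durations, profile.sustained_level)

    positions = np.zeros((n, 33, 3))
    vis = np.ones((n, 33))
    truth_angles: list[JointAngles] = []
    raw_trunk: list[float] = []
    subs: list[SubScores] = []
    finals: list[int] = []
    for i, e in enumerate(env):
        trunk = profile.peak_trunk_flexion * e
        neck = profile.peak_neck_flexion * e
        arm = profile.peak_arm_flexion * e
        abd = profile.peak_abduction * e
        tilt = profile.tilt_amplitude * e
        elbow = profile.elbow_baseline + (profile.elbow_peak - profile.elbow_baseline) * e
        pos, internals = _chain_positions(profile, trunk, neck, arm, abd, elbow, tilt)
        positions[i] = pos
        ja = _true_joint_angles(profile, trunk, neck, arm, abd, elbow, tilt,
                                internals, kin_cfg.trunk_correction)
        truth_angles.append(ja)
        raw_trunk.append(trunk)
        res = evaluate_frame(ja, rula_cfg)
        subs.append(res.sub_scores)
        finals.append(res.final_score)

    if profile.noise_sd > 0:
        positions = positions + rng.normal(0.0, profile.noise_sd, positions.shape)
    if profile.dropout_prob > 0:
        drop = rng.random((n, 33)) < profile.dropout_prob
        vis[drop] = rng.uniform(0.05, 0.45, int(drop.sum()))

    frames = frames_from_arrays(ts, positions, vis)
    meta = {"condition": "dynamic", "generator": "synthetic_lifting"}
    if metadata:
        meta.update(metadata)
    stream = SessionStream(frames=frames, nominal_fps=profile.fps, metadata=meta)
    truth = GroundTruth(
        angles=truth_angles,
        raw_trunk=raw_trunk,
        sub_scores=subs,
        final_scores=finals,
        envelope=env,
    )
    return stream, truth


@dataclass
class CohortSample:
    sessions: list[SessionStream]
    truths: list[GroundTruth]
    labels: list[bool]  # expected critical-risk classification per session


def generate_cohort(
    n: int,
    profile_sampler=None,
    seed: int = 0,
    rula_cfg: RulaConfig | None = None,
    critical_threshold: int = 5,
) -> CohortSample:
    """Generate ``n`` sessions with per-session seeds derived from ``seed``.

    ``profile_sampler(rng, i)`` returns the i-th participant's profile; the
    default draws peak angles around the task means with inter-participant
    spread.  Each session's expected risk label comes from its ground-truth
    sub-scores pushed through the lookup tables.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rula_cfg = rula_cfg or RulaConfig()
    master = np.random.default_rng(seed)
    if profile_sampler is None:
        profile_sampler = default_profile_sampler

    sessions, truths, labels = [], [], []
    for i in range(n):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        profile = profile_sampler(rng, i)
        profile = replace(profile, seed=sub_seed)
        stream, truth = generate_session(
            profile, rula_cfg=rula_cfg, metadata={"participant": f"P{i + 1:03d}"}
        )
        sessions.append(stream)
        truths.append(truth)
        labels.append(truth.is_critical(critical_threshold))
    return CohortSample(sessions=sessions, truths=truths, labels=labels)


def default_profile_sampler(rng: np.random.Generator, i: int) -> LiftingProfile:
    """Heterogeneous lifting styles around the observed task means."""
    return LiftingProfile(
        peak_trunk_flexion=float(np.clip(rng.normal(48.0, 12.0), 0.0, 90.0)),
        peak_arm_flexion=float(np.clip(rng.normal(87.0, 15.0), 0.0, 175.0)),
        peak_neck_flexion=float(np.clip(rng.normal(44.0, 10.0), 0.0, 90.0)),
        peak_abduction=float(np.clip(rng.normal(40.0, 15.0), 0.0, 120.0)),
        tilt_amplitude=float(np.clip(rng.normal(8.0, 4.0), 0.0, 45.0)),
        elbow_peak=float(np.clip(rng.normal(95.0, 20.0), 20.0, 175.0)),
    )
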