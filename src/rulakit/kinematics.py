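"""Segment vectors and 3D joint angles from a landmark frame.

Body segments are straight lines between landmarks (or landmark midpoints);
the angle between two segments A and B comes directly from the dot product,

    theta = arccos( A . B / (|A| |B|) ),

which uses all three coordinates and is therefore independent of camera
viewpoint, unlike planar 2D projections.  Trunk flexion is measured against
the global gravity vertical [0, -1, 0] and receives a configurable +10
degree correction compensating for typical frontal camera tilt at a
workstation.

Angle conventions (all degrees, neutral upright posture reads ~0):

* trunk_flexion  — angle of the mid-shoulder→mid-hip vector from gravity,
  plus the correction, clamped to [0, 180].
* neck_flexion   — 180 minus the angle between the mid-shoulder→mid-ear
  vector and the trunk vector (the two are antiparallel when upright).
* arm_flexion    — angle between the shoulder→elbow vector and the
  shoulder→ipsilateral-hip reference (a hanging arm reads ~0).
* arm_abduction  — the same pair projected onto the frontal (x-y) plane.
* forearm_angle  — the included elbow angle, 180 minus the angle between the
  upper-arm and forearm vectors (a right-angle elbow reads 90).
* lateral_tilt   — absolute difference between the frontal-plane inclinations
  of the shoulder line and the hip line.

Any angle depending on a visibility-invalidated landmark is flagged invalid
rather than raising; invalidity is data carried downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .landmarks import (
    LEFT_EAR,
    LEFT_ELBOW,
    LEFT_HIP,
    LEFT_SHOULDER,
    LEFT_WRIST,
    RIGHT_EAR,
    RIGHT_ELBOW,
    RIGHT_HIP,
    RIGHT_SHOULDER,
    RIGHT_WRIST,
    LandmarkFrame,
    ValidityMask,
    frame_validity,
)

DEGENERACY_FLOOR = 1e-9  # metres; below this a segment has no direction


class DegenerateGeometryError(ValueError):
    """A segment vector is too short to define a direction."""


@dataclass
class KinematicsConfig:
    gravity_ref: tuple[float, float, float] = (0.0, -1.0, 0.0)
    trunk_correction: float = 10.0
    visibility_threshold: float = 0.5

    def __post_init__(self) -> None:
        if float(np.linalg.norm(self.gravity_ref)) <= DEGENERACY_FLOOR:
            raise ValueError("gravity_ref must be nonzero")
        if not 0.0 <= self.visibility_threshold <= 1.0:
            raise ValueError("visibility_threshold outside [0, 1]")


def vector_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two 3D vectors via the dot product.

    The cosine is clamped to [-1, 1] before arccos to absorb rounding, so the
    result is always in [0, 180].  Near-zero vectors have no direction and
    raise :class:`DegenerateGeometryError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na <= DEGENERACY_FLOOR or nb <= DEGENERACY_FLOOR:
        raise DegenerateGeometryError(f"degenerate vector (norms {na:.3g}, {nb:.3g})")
    cos = float(np.dot(a, b) / (na * nb))
    cos = max(-1.0, min(1.0, cos))
    return math.degrees(math.acos(cos))


@dataclass
class SegmentVectors:
    """The body-segment vectors of one frame plus per-vector validity.

    A vector is valid only if every constituent landmark passed the
    visibility mask and the vector's norm exceeds the degeneracy floor.
    """

    trunk: np.ndarray          # mid-shoulders -> mid-hips
    neck: np.ndarray           # mid-shoulders -> mid-ears
    upper_arm_left: np.ndarray   # shoulder -> elbow
    upper_arm_right: np.ndarray
    forearm_left: np.ndarray     # elbow -> wrist
    forearm_right: np.ndarray
    ref_arm_left: np.ndarray     # shoulder -> ipsilateral hip
    ref_arm_right: np.ndarray
    shoulder_line: np.ndarray    # left shoulder -> right shoulder
    hip_line: np.ndarray         # left hip -> right hip
    valid: dict[str, bool] = field(default_factory=dict)


_VECTOR_LANDMARKS: dict[str, tuple[int, ...]] = {
    "trunk": (LEFT_SHOULDER, RIGHT_SHOULDER, LEFT_HIP, RIGHT_HIP),
    "neck": (LEFT_SHOULDER, RIGHT_SHOULDER, LEFT_EAR, RIGHT_EAR),
    "upper_arm_left": (LEFT_SHOULDER, LEFT_ELBOW),
    "upper_arm_right": (RIGHT_SHOULDER, RIGHT_ELBOW),
    "forearm_left": (LEFT_ELBOW, LEFT_WRIST),
    "forearm_right": (RIGHT_ELBOW, RIGHT_WRIST),
    "ref_arm_left": (LEFT_SHOULDER, LEFT_HIP),
    "ref_arm_right": (RIGHT_SHOULDER, RIGHT_HIP),
    "shoulder_line": (LEFT_SHOULDER, RIGHT_SHOULDER),
    "hip_line": (LEFT_HIP, RIGHT_HIP),
}


def build_segment_vectors(frame: LandmarkFrame, mask: ValidityMask | None = None) -> SegmentVectors:
    """Construct all segment vectors from the frame's landmark positions.

    Midpoints are unweighted averages of the two flanking landmarks.  A
    vector whose constituent landmarks include any invalid one, or whose norm
    is below the degeneracy floor, is marked invalid (no exception).
    """
    if mask is None:
        mask = frame_validity(frame)
    pos = frame.positions()

    def mid(i: int, j: int) -> np.ndarray:
        return 0.5 * (pos[i] + pos[j])

    vecs: dict[str, np.ndarray] = {
        "trunk": mid(LEFT_HIP, RIGHT_HIP) - mid(LEFT_SHOULDER, RIGHT_SHOULDER),
        "neck": mid(LEFT_EAR, RIGHT_EAR) - mid(LEFT_SHOULDER, RIGHT_SHOULDER),
        "upper_arm_left": pos[LEFT_ELBOW] - pos[LEFT_SHOULDER],
        "upper_arm_right": pos[RIGHT_ELBOW] - pos[RIGHT_SHOULDER],
        "forearm_left": pos[LEFT_WRIST] - pos[LEFT_ELBOW],
        "forearm_right": pos[RIGHT_WRIST] - pos[RIGHT_ELBOW],
        "ref_arm_left": pos[LEFT_HIP] - pos[LEFT_SHOULDER],
        "ref_arm_right": pos[RIGHT_HIP] - pos[RIGHT_SHOULDER],
        "shoulder_line": pos[RIGHT_SHOULDER] - pos[LEFT_SHOULDER],
        "hip_line": pos[RIGHT_HIP] - pos[LEFT_HIP],
    }
    valid = {
        name: all(mask[i] for i in deps) and float(np.linalg.norm(vecs[name])) > DEGENERACY_FLOOR
        for name, deps in _VECTOR_LANDMARKS.items()
    }
    return SegmentVectors(**vecs, valid=valid)


ANGLE_CHANNELS = (
    "trunk_flexion",
    "neck_flexion",
    "arm_flexion_left",
    "arm_flexion_right",
    "arm_abduction_left",
    "arm_abduction_right",
    "forearm_angle_left",
    "forearm_angle_right",
    "lateral_tilt",
)


@dataclass
class JointAngles:
    """All RULA-relevant angles of one frame, degrees, with validity flags.

    Invalid fields hold NaN; ``valid`` maps each channel name to whether its
    value may be consumed by scoring.  ``active_side`` is the working side
    selected by shoulder-depth comparison.
    """

    trunk_flexion: float = math.nan
    neck_flexion: float = math.nan
    arm_flexion_left: float = math.nan
    arm_flexion_right: float = math.nan
    arm_abduction_left: float = math.nan
    arm_abduction_right: float = math.nan
    forearm_angle_left: float = math.nan
    forearm_angle_right: float = math.nan
    lateral_tilt: float = math.nan
    valid: dict[str, bool] = field(default_factory=lambda: {c: False for c in ANGLE_CHANNELS})
    active_side: str = "right"

    def get(self, channel: str) -> float:
        return getattr(self, channel)

    def side(self, base: str, side: str | None = None) -> float:
        return getattr(self, f"{base}_{side or self.active_side}")

    def side_valid(self, base: str, side: str | None = None) -> bool:
        return self.valid.get(f"{base}_{side or self.active_side}", False)


def _frontal_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between the frontal-plane (x-y) projections of two vectors."""
    pa = np.array([a[0], a[1], 0.0])
    pb = np.array([b[0], b[1], 0.0])
    return vector_angle_deg(pa, pb)


def _line_inclination(line: np.ndarray) -> float:
    """Signed inclination (degrees) of a left->right body line from the
    horizontal, in the frontal plane, wrapped to [-90, 90]."""
    dx, dy = float(line[0]), float(line[1])
    if math.hypot(dx, dy) <= DEGENERACY_FLOOR:
        raise DegenerateGeometryError("line has no frontal-plane extent")
    ang = math.degrees(math.atan2(dy, dx))
    if ang > 90.0:
        ang -= 180.0
    elif ang < -90.0:
        ang += 180.0
    return ang


def compute_joint_angles(sv: SegmentVectors, cfg: KinematicsConfig | None = None) -> JointAngles:
    """Derive every scored angle from the segment vectors.

    Outputs depending on an invalid vector (or on a degenerate projection)
    are flagged invalid; no exception escapes.
    """
    cfg = cfg or KinematicsConfig()
    gravity = np.asarray(cfg.gravity_ref, dtype=float)
    out = JointAngles()

    def attempt(channel: str, deps: list[str], fn) -> None:
        if all(sv.valid.get(d, False) for d in deps):
            try:
                setattr(out, channel, fn())
                out.valid[channel] = True
                return
            except DegenerateGeometryError:
                pass
        setattr(out, channel, math.nan)
        out.valid[channel] = False

    attempt(
        "trunk_flexion",
        ["trunk"],
        lambda: min(180.0, max(0.0, vector_angle_deg(sv.trunk, gravity) + cfg.trunk_correction)),
    )
    attempt("neck_flexion", ["neck", "trunk"], lambda: 180.0 - vector_angle_deg(sv.neck, sv.trunk))
    for side in ("left", "right"):
        ua = getattr(sv, f"upper_arm_{side}")
        fa = getattr(sv, f"forearm_{side}")
        ref = getattr(sv, f"ref_arm_{side}")
        attempt(
            f"arm_flexion_{side}",
            [f"upper_arm_{side}", f"ref_arm_{side}"],
            lambda ua=ua, ref=ref: vector_angle_deg(ua, ref),
        )
        attempt(
            f"arm_abduction_{side}",
            [f"upper_arm_{side}", f"ref_arm_{side}"],
            lambda ua=ua, ref=ref: _frontal_angle(ua, ref),
        )
        attempt(
            f"forearm_angle_{side}",
            [f"upper_arm_{side}", f"forearm_{side}"],
            lambda ua=ua, fa=fa: 180.0 - vector_angle_deg(ua, fa),
        )
    attempt(
        "lateral_tilt",
        ["shoulder_line", "hip_line"],
        lambda: abs(_line_inclination(sv.shoulder_line) - _line_inclination(sv.hip_line)),
    )
    return out


def active_side(
    frame: LandmarkFrame,
    mask: ValidityMask | None = None,
    previous: str | None = None,
) -> str:
    """The working side: the shoulder nearer the camera (smaller depth z).

    In a sagittal working view the task arm is closest to the camera, so its
    side carries the highest risk profile.  Ties resolve to ``right``; if
    either shoulder is invalid the previous frame's side is kept (``right``
    when there is none).
    """
    if mask is None:
        mask = frame_validity(frame)
    if not (mask[LEFT_SHOULDER] and mask[RIGHT_SHOULDER]):
        return previous if previous in ("left", "right") else "right"
    zl = frame.landmarks[LEFT_SHOULDER].z
    zr = frame.landmarks[RIGHT_SHOULDER].z
    return "left" if zl < zr else "right"
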