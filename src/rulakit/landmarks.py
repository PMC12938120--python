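"""Data model and file I/O for 33-landmark 3D pose sessions.

A session is an ordered sequence of timestamped frames, each carrying the 33
anatomical landmarks of the MediaPipe Holistic body model as metric world
coordinates plus a per-landmark visibility confidence.  Internally frames use
a y-up convention (gravity points along -y); pose estimators that emit y-down
world coordinates are flipped at ingest via ``y_axis="down"``.

Only landmark indices {7, 8, 11, 12, 13, 14, 15, 16, 23, 24} (ears,
shoulders, elbows, wrists, hips) are consumed by the kinematics; the rest are
carried opaquely so sessions round-trip losslessly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

N_LANDMARKS = 33

# MediaPipe Holistic body indices consumed downstream
LEFT_EAR, RIGHT_EAR = 7, 8
LEFT_SHOULDER, RIGHT_SHOULDER = 11, 12
LEFT_ELBOW, RIGHT_ELBOW = 13, 14
LEFT_WRIST, RIGHT_WRIST = 15, 16
LEFT_HIP, RIGHT_HIP = 23, 24


class SessionFormatError(ValueError):
    """Raised when a session file is malformed or violates stream invariants."""


@dataclass(frozen=True)
class Landmark:
    """One anatomical point: metric coordinates plus estimator confidence.

    x is lateral (+ toward the subject's right in the camera frame), y is
    vertical (+ up, so gravity is -y), z is depth (+ away from the camera).
    """

    x: float
    y: float
    z: float
    visibility: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.z)):
            raise ValueError("landmark coordinates must be finite")
        if not 0.0 <= self.visibility <= 1.0:
            raise ValueError(f"visibility {self.visibility} outside [0, 1]")

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class LandmarkFrame:
    """A single timestamped sample of all 33 landmarks."""

    timestamp: float
    landmarks: tuple[Landmark, ...]

    def __post_init__(self) -> None:
        if len(self.landmarks) != N_LANDMARKS:
            raise ValueError(
                f"frame at t={self.timestamp} has {len(self.landmarks)} landmarks, expected {N_LANDMARKS}"
            )

    def positions(self) -> np.ndarray:
        """(33, 3) array of coordinates."""
        return np.array([[p.x, p.y, p.z] for p in self.landmarks], dtype=float)

    def visibilities(self) -> np.ndarray:
        return np.array([p.visibility for p in self.landmarks], dtype=float)


@dataclass
class SessionStream:
    """An ordered landmark-frame sequence with nominal rate and metadata.

    ``nominal_fps`` is advisory metadata (the achieved rate is whatever the
    timestamps say); ``metadata`` typically carries a participant id and a
    condition label (``static`` | ``dynamic``).
    """

    frames: list[LandmarkFrame] = field(default_factory=list)
    nominal_fps: float = 30.0
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nominal_fps <= 0:
            raise ValueError("nominal_fps must be > 0")
        self.validate_timestamps()

    def validate_timestamps(self) -> None:
        ts = [f.timestamp for f in self.frames]
        for i in range(1, len(ts)):
            if ts[i] <= ts[i - 1]:
                raise SessionFormatError(
                    f"timestamps not strictly increasing at frame {i}: {ts[i - 1]} -> {ts[i]}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def duration(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1].timestamp - self.frames[0].timestamp


@dataclass(frozen=True)
class ValidityMask:
    """Per-landmark validity under a visibility threshold.

    ``valid[i]`` is True iff the landmark's visibility is at or above the
    threshold; landmarks below it are treated as occluded or unreliable and
    invalidate every segment vector they participate in.
    """

    valid: tuple[bool, ...]
    threshold: float

    def __getitem__(self, i: int) -> bool:
        return self.valid[i]


def frame_validity(frame: LandmarkFrame, threshold: float = 0.5) -> ValidityMask:
    """Gate landmarks on visibility: valid iff visibility >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return ValidityMask(
        valid=tuple(p.visibility >= threshold for p in frame.landmarks),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# File formats
#
# JSON-lines: first line is a header object {"nominal_fps": .., "metadata":
# {..}}, then one frame per line: {"t": float, "lm": [[x, y, z, vis] * 33]}.
# CSV: columns t, lm00_x, lm00_y, lm00_z, lm00_vis, ..., lm32_vis (133
# columns); nominal fps and metadata ride in "# key: value" comment lines.
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["t"] + [
    f"lm{i:02d}_{c}" for i in range(N_LANDMARKS) for c in ("x", "y", "z", "vis")
]


def _frame_from_flat(t: float, flat: Iterable[float], where: str) -> LandmarkFrame:
    vals = list(flat)
    if len(vals) != 4 * N_LANDMARKS:
        raise SessionFormatError(
            f"{where}: expected {4 * N_LANDMARKS} landmark values, got {len(vals)}"
        )
    try:
        lms = tuple(
            Landmark(vals[4 * i], vals[4 * i + 1], vals[4 * i + 2], vals[4 * i + 3])
            for i in range(N_LANDMARKS)
        )
    except (TypeError, ValueError) as exc:
        raise SessionFormatError(f"{where}: {exc}") from exc
    return LandmarkFrame(timestamp=t, landmarks=lms)


def _flip_y(stream: SessionStream) -> SessionStream:
    frames = [
        LandmarkFrame(
            timestamp=f.timestamp,
            landmarks=tuple(
                Landmark(p.x, -p.y, p.z, p.visibility) for p in f.landmarks
            ),
        )
        for f in stream.frames
    ]
    return SessionStream(frames=frames, nominal_fps=stream.nominal_fps, metadata=dict(stream.metadata))


def read_session(path: str | Path, format: str | None = None, y_axis: str = "up") -> SessionStream:
    """Read a recorded session from a JSON-lines or CSV file.

    ``y_axis="down"`` negates every y coordinate on ingest, converting raw
    estimator output (image-style y-down world coordinates) to the internal
    y-up convention.  Timestamps are checked for strict monotonicity, never
    silently re-sorted.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown session format {format!r}")
    if y_axis not in ("up", "down"):
        raise ValueError(f"y_axis must be 'up' or 'down', got {y_axis!r}")

    if format == "jsonl":
        stream = _read_jsonl(path)
    else:
        stream = _read_csv(path)
    if y_axis == "down":
        stream = _flip_y(stream)
    return stream


def _read_jsonl(path: Path) -> SessionStream:
    frames: list[LandmarkFrame] = []
    nominal_fps = 30.0
    metadata: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SessionFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            if lineno == 1 and "t" not in rec:
                nominal_fps = float(rec.get("nominal_fps", 30.0))
                metadata = {str(k): str(v) for k, v in rec.get("metadata", {}).items()}
                continue
            if "t" not in rec or "lm" not in rec:
                raise SessionFormatError(f"{path}:{lineno}: record missing 't' or 'lm'")
            flat = [v for quad in rec["lm"] for v in quad]
            if any(len(quad) != 4 for quad in rec["lm"]):
                raise SessionFormatError(f"{path}:{lineno}: each landmark needs [x, y, z, vis]")
            frames.append(_frame_from_flat(float(rec["t"]), flat, f"{path}:{lineno}"))
    return SessionStream(frames=frames, nominal_fps=nominal_fps, metadata=metadata)


def _read_csv(path: Path) -> SessionStream:
    nominal_fps = 30.0
    metadata: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if line.startswith("#"):
                pos += len(line)
                key, _, val = line[1:].strip().partition(":")
                key, val = key.strip(), val.strip()
                if key == "nominal_fps":
                    nominal_fps = float(val)
                elif key:
                    metadata[key] = val
            else:
                break
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns) != _CSV_COLUMNS:
        raise SessionFormatError(
            f"{path}: unexpected columns (got {len(df.columns)}, expected {len(_CSV_COLUMNS)})"
        )
    frames = []
    values = df.to_numpy(dtype=float)
    for row_i, row in enumerate(values):
        frames.append(_frame_from_flat(float(row[0]), row[1:], f"{path}: row {row_i}"))
    return SessionStream(frames=frames, nominal_fps=nominal_fps, metadata=metadata)


def write_session(stream: SessionStream, path: str | Path, format: str | None = None) -> None:
    """Write a session so that :func:`read_session` round-trips it losslessly."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with open(path, "w") as fh:
            header = {"nominal_fps": stream.nominal_fps, "metadata": stream.metadata}
            fh.write(json.dumps(header) + "\n")
            for f in stream.frames:
                rec = {
                    "t": f.timestamp,
                    "lm": [[p.x, p.y, p.z, p.visibility] for p in f.landmarks],
                }
                fh.write(json.dumps(rec) + "\n")
    elif format == "csv":
        rows = [
            [f.timestamp] + [v for p in f.landmarks for v in (p.x, p.y, p.z, p.visibility)]
            for f in stream.frames
        ]
        df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        with open(path, "w") as fh:
            fh.write(f"# nominal_fps: {stream.nominal_fps}\n")
            for k, v in stream.metadata.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown session format {format!r}")


def frames_from_arrays(
    timestamps: np.ndarray, positions: np.ndarray, visibilities: np.ndarray
) -> list[LandmarkFrame]:
    """Assemble frames from a (T,) timestamp vector, (T, 33, 3) positions and
    (T, 33) visibilities."""
    frames = []
    for t, pos, vis in zip(timestamps, positions, visibilities):
        lms = tuple(
            Landmark(float(p[0]), float(p[1]), float(p[2]), float(v))
            for p, v in zip(pos, vis)
        )
        frames.append(LandmarkFrame(timestamp=float(t), landmarks=lms))
    return frames
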