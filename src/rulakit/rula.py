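"""Deterministic digitized RULA scoring.

Per-segment threshold scoring followed by lookup through the published RULA
tables (A: upper limb, B: neck/trunk/legs, C: grand score) to a final 1-7
score and action level.  The tables live in a versioned JSON data file and
are frozen by a sha256 checksum so the engine stays mathematically identical
to the manual worksheet method.

Threshold semantics: every breakpoint is a strict lower bound (">30 deg"
means 30.0 stays in the lower band).  The deliberately tolerant defaults —
upper arm stays at 1 until flexion exceeds 30 deg, forearm neutral zone
50-110 deg, trunk transitions at 10/20/60 deg — avoid penalising neutral
task postures.  Wrist, wrist-twist and leg scores default to 1 because
markerless vision cannot resolve them reliably; muscle-use and force/load
additions default to 0 and are exposed in config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

from .kinematics import JointAngles

TABLES_SHA256 = "dead1c5f47ff45e5e95de744bb824f919e51a97746075ff35ce107c4c51b7114"

ACTION_LEVELS = (
    (1, 2, "acceptable"),
    (3, 4, "investigate"),
    (5, 6, "changes_soon"),
    (7, 7, "urgent"),
)


def action_level(final_score: int) -> str:
    """Intervention band implied by a final RULA score."""
    for lo, hi, name in ACTION_LEVELS:
        if lo <= final_score <= hi:
            return name
    raise ValueError(f"final score {final_score} outside 1-7")


@dataclass
class RulaConfig:
    """Scoring thresholds (degrees) and default sub-scores.

    ``arm_thresholds`` = (t1, t2, t3): upper-arm flexion bands <=t1 -> 1,
    (t1,t2] -> 2, (t2,t3] -> 3, >t3 -> 4.  ``trunk_thresholds`` likewise for
    trunk bands 1-4.  ``neck_thresholds`` = (t1, t2) for neck bands 1-3.
    ``forearm_neutral`` = (lo, hi): score 1 inside, 2 outside.  Abduction
    beyond ``abduction_threshold`` adds +1 to the upper arm; lateral tilt
    beyond ``tilt_threshold`` adds +1 to the trunk (both switchable).
    """

    arm_thresholds: tuple[float, float, float] = (30.0, 45.0, 90.0)
    forearm_neutral: tuple[float, float] = (50.0, 110.0)
    trunk_thresholds: tuple[float, float, float] = (10.0, 20.0, 60.0)
    neck_thresholds: tuple[float, float] = (10.0, 30.0)
    abduction_threshold: float = 45.0
    tilt_threshold: float = 10.0
    abduction_adjust: bool = True
    tilt_adjust: bool = True
    default_wrist_score: int = 1
    default_twist_score: int = 1
    default_legs_score: int = 1
    muscle_score: int = 0
    force_score: int = 0

    def __post_init__(self) -> None:
        for name in ("arm_thresholds", "trunk_thresholds", "neck_thresholds", "forearm_neutral"):
            vals = getattr(self, name)
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing, got {vals}")
        if not 1 <= self.default_wrist_score <= 4:
            raise ValueError("default_wrist_score outside 1-4")
        if not 1 <= self.default_twist_score <= 2:
            raise ValueError("default_twist_score outside 1-2")
        if not 1 <= self.default_legs_score <= 2:
            raise ValueError("default_legs_score outside 1-2")
        if self.muscle_score < 0 or self.force_score < 0:
            raise ValueError("muscle/force additions must be >= 0")


@dataclass(frozen=True)
class SubScores:
    upper_arm: int
    lower_arm: int
    wrist: int
    wrist_twist: int
    neck: int
    trunk: int
    legs: int

    _RANGES = {
        "upper_arm": (1, 6),
        "lower_arm": (1, 3),
        "wrist": (1, 4),
        "wrist_twist": (1, 2),
        "neck": (1, 6),
        "trunk": (1, 6),
        "legs": (1, 2),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"sub-score {name}={v} outside [{lo}, {hi}]")


class RulaTables:
    """The three published lookup matrices with checksum verification.

    Indexing clamps scores above the last row/column of Table C to it
    (the worksheet's "8+" convention); sub-score indices into A and B must be
    in range — out-of-range indices are contract violations, not clamped.
    """

    def __init__(self, table_a, table_b, table_c) -> None:
        self.table_a = table_a
        self.table_b = table_b
        self.table_c = table_c

    @classmethod
    def load(cls, verify: bool = True) -> "RulaTables":
        text = resources.files("rulakit").joinpath("data/rula_tables.json").read_text()
        data = json.loads(text)
        obj = cls(data["table_a"], data["table_b"], data["table_c"])
        if verify and obj.checksum() != TABLES_SHA256:
            raise ValueError(
                "RULA table data file does not match its frozen checksum; "
                "the tables must stay identical to the published worksheet"
            )
        return obj

    def checksum(self) -> str:
        canonical = json.dumps(
            {"table_a": self.table_a, "table_b": self.table_b, "table_c": self.table_c},
            sort_keys=True,
            separators=(",", ":"),
        )
        return hashlib.sha256(canonical.encode()).hexdigest()


_DEFAULT_TABLES: RulaTables | None = None


def default_tables() -> RulaTables:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = RulaTables.load()
    return _DEFAULT_TABLES


@dataclass(frozen=True)
class RulaResult:
    sub_scores: SubScores
    score_a: int
    score_b: int
    final_score: int
    action_level: str
    contributing_angles: JointAngles | None = None


class UnscorableFrame:
    """Marker for a frame whose required angles were invalid."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "UnscorableFrame()"


UNSCORABLE = UnscorableFrame()


# ---------------------------------------------------------------------------
# Per-segment threshold scoring
# ---------------------------------------------------------------------------

def _band(value: float, thresholds: tuple[float, ...]) -> int:
    """1 + number of strict threshold exceedances."""
    return 1 + sum(value > t for t in thresholds)


def score_upper_arm(flexion: float, abduction: float = 0.0, cfg: RulaConfig | None = None) -> int:
    cfg = cfg or RulaConfig()
    s = _band(flexion, cfg.arm_thresholds)
    if cfg.abduction_adjust and abduction > cfg.abduction_threshold:
        s += 1
    return min(s, 6)


def score_lower_arm(forearm_angle: float, cfg: RulaConfig | None = None) -> int:
    cfg = cfg or RulaConfig()
    lo, hi = cfg.forearm_neutral
    return 1 if lo <= forearm_angle <= hi else 2


def score_trunk(trunk_flexion: float, lateral_tilt: float = 0.0, cfg: RulaConfig | None = None) -> int:
    cfg = cfg or RulaConfig()
    s = _band(trunk_flexion, cfg.trunk_thresholds)
    if cfg.tilt_adjust and lateral_tilt > cfg.tilt_threshold:
        s += 1
    return min(s, 6)


def score_neck(neck_flexion: float, cfg: RulaConfig | None = None) -> int:
    cfg = cfg or RulaConfig()
    return _band(neck_flexion, cfg.neck_thresholds)


def score_segments(angles: JointAngles, cfg: RulaConfig | None = None) -> SubScores | UnscorableFrame:
    """Threshold-score every segment for the frame's active side.

    Requires valid trunk, neck, lateral tilt and active-side arm flexion,
    abduction and forearm angles; if any is invalid the frame is unscorable
    (returned as a marker, never an exception).
    """
    cfg = cfg or RulaConfig()
    required = ["trunk_flexion", "neck_flexion", "lateral_tilt"]
    side = angles.active_side
    required += [f"arm_flexion_{side}", f"arm_abduction_{side}", f"forearm_angle_{side}"]
    if not all(angles.valid.get(ch, False) for ch in required):
        return UNSCORABLE
    return SubScores(
        upper_arm=score_upper_arm(angles.side("arm_flexion"), angles.side("arm_abduction"), cfg),
        lower_arm=score_lower_arm(angles.side("forearm_angle"), cfg),
        wrist=cfg.default_wrist_score,
        wrist_twist=cfg.default_twist_score,
        neck=score_neck(angles.neck_flexion, cfg),
        trunk=score_trunk(angles.trunk_flexion, angles.lateral_tilt, cfg),
        legs=cfg.default_legs_score,
    )


# ---------------------------------------------------------------------------
# Table lookups
# ---------------------------------------------------------------------------

def lookup_score_a(s: SubScores, tables: RulaTables | None = None) -> int:
    tables = tables or default_tables()
    try:
        return tables.table_a[s.upper_arm - 1][s.lower_arm - 1][s.wrist - 1][s.wrist_twist - 1]
    except IndexError as exc:
        raise IndexError(f"sub-scores {s} out of Table A range") from exc


def lookup_score_b(s: SubScores, tables: RulaTables | None = None) -> int:
    tables = tables or default_tables()
    try:
        return tables.table_b[s.neck - 1][s.trunk - 1][s.legs - 1]
    except IndexError as exc:
        raise IndexError(f"sub-scores {s} out of Table B range") from exc


def final_score(
    score_a: int,
    score_b: int,
    cfg: RulaConfig | None = None,
    tables: RulaTables | None = None,
) -> tuple[int, str]:
    """Grand score via Table C with muscle/force adjustments and clamping.

    Adjusted scores beyond the table's last row/column clamp to it (the
    worksheet's "8+" convention).  Returns (final 1-7, action level).
    """
    cfg = cfg or RulaConfig()
    tables = tables or default_tables()
    if score_a < 1 or score_b < 1:
        raise ValueError("scores A and B must be >= 1")
    a = score_a + cfg.muscle_score + cfg.force_score
    b = score_b + cfg.muscle_score + cfg.force_score
    a = min(a, len(tables.table_c))
    b = min(b, len(tables.table_c[0]))
    final = tables.table_c[a - 1][b - 1]
    return final, action_level(final)


def evaluate_frame(
    angles: JointAngles,
    cfg: RulaConfig | None = None,
    tables: RulaTables | None = None,
) -> RulaResult | UnscorableFrame:
    """Full per-frame evaluation: segment scores -> tables -> final score."""
    cfg = cfg or RulaConfig()
    tables = tables or default_tables()
    sub = score_segments(angles, cfg)
    if isinstance(sub, UnscorableFrame):
        return UNSCORABLE
    a = lookup_score_a(sub, tables)
    b = lookup_score_b(sub, tables)
    final, level = final_score(a, b, cfg, tables)
    return RulaResult(
        sub_scores=sub,
        score_a=a,
        score_b=b,
        final_score=final,
        action_level=level,
        contributing_angles=angles,
    )
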