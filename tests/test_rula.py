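"""Threshold scoring and RULA table lookups."""

import itertools

import numpy as np
import pytest

from rulakit.kinematics import ANGLE_CHANNELS, JointAngles
from rulakit.rula import (
    TABLES_SHA256,
    UNSCORABLE,
    RulaConfig,
    RulaTables,
    SubScores,
    UnscorableFrame,
    action_level,
    evaluate_frame,
    final_score,
    lookup_score_a,
    lookup_score_b,
    score_lower_arm,
    score_neck,
    score_segments,
    score_trunk,
    score_upper_arm,
)


def make_angles(trunk=0.0, neck=0.0, arm=0.0, abduction=0.0, forearm=90.0, tilt=0.0):
    ja = JointAngles(
        trunk_flexion=trunk,
        neck_flexion=neck,
        arm_flexion_left=arm,
        arm_flexion_right=arm,
        arm_abduction_left=abduction,
        arm_abduction_right=abduction,
        forearm_angle_left=forearm,
        forearm_angle_right=forearm,
        lateral_tilt=tilt,
        valid={c: True for c in ANGLE_CHANNELS},
        active_side="right",
    )
    return ja


# ---------------------------------------------------------------------------
# Segment threshold scoring
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "flexion,abduction,expected",
    [
        (25.0, 0.0, 1),   # tolerant band below 30
        (30.0, 0.0, 1),   # strict bound: 30.0 stays low
        (35.0, 0.0, 2),
        (50.0, 0.0, 3),   # interior band (45, 90]
        (90.0, 0.0, 3),
        (95.0, 0.0, 4),   # maximum activates above 90
        (95.0, 50.0, 5),  # abduction beyond 45 adds one
        (25.0, 46.0, 2),
    ],
)
def test_upper_arm_scoring(flexion, abduction, expected):
    assert score_upper_arm(flexion, abduction) == expected


@pytest.mark.parametrize(
    "angle,expected", [(120.0, 2), (80.0, 1), (50.0, 1), (110.0, 1), (49.0, 2), (111.0, 2)]
)
def test_forearm_neutral_zone(angle, expected):
    assert score_lower_arm(angle) == expected


@pytest.mark.parametrize(
    "trunk,tilt,expected",
    [
        (65.0, 0.0, 4),   # severe flexion above 60
        (15.0, 0.0, 2),
        (10.0, 0.0, 1),   # strict bound
        (25.0, 0.0, 3),
        (60.0, 0.0, 3),
        (65.0, 12.0, 5),  # lateral tilt beyond 10 adds one
    ],
)
def test_trunk_scoring(trunk, tilt, expected):
    assert score_trunk(trunk, tilt) == expected


@pytest.mark.parametrize("neck,expected", [(5.0, 1), (10.0, 1), (15.0, 2), (30.0, 2), (35.0, 3)])
def test_neck_scoring(neck, expected):
    assert score_neck(neck) == expected


def test_threshold_sweep_breakpoints_exact():
    """Sub-scores are piecewise constant in 0.5-degree sweeps with steps only
    just past the configured thresholds."""
    grid = np.arange(0.0, 180.5, 0.5)

    def breakpoints(fn):
        vals = [fn(x) for x in grid]
        return {grid[i] for i in range(1, len(vals)) if vals[i] != vals[i - 1]}

    assert breakpoints(lambda x: score_upper_arm(x, 0.0)) == {30.5, 45.5, 90.5}
    assert breakpoints(score_lower_arm) == {50.0, 110.5}
    assert breakpoints(lambda x: score_trunk(x, 0.0)) == {10.5, 20.5, 60.5}
    assert breakpoints(score_neck) == {10.5, 30.5}


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def test_tables_checksum_frozen():
    tables = RulaTables.load(verify=True)
    assert tables.checksum() == TABLES_SHA256
    # a mutated copy no longer matches
    mutated = RulaTables([list(map(list, r)) for r in tables.table_a], tables.table_b, tables.table_c)
    mutated.table_a[0][0][0] = [2, 2]
    assert mutated.checksum() != TABLES_SHA256


def test_table_extreme_cells():
    assert lookup_score_a(SubScores(1, 1, 1, 1, 1, 1, 1)) == 1
    assert lookup_score_a(SubScores(6, 3, 4, 2, 1, 1, 1)) == 9
    assert lookup_score_b(SubScores(1, 1, 1, 1, 1, 1, 1)) == 1
    assert lookup_score_b(SubScores(1, 1, 1, 1, 6, 6, 2)) == 9
    assert final_score(1, 1) == (1, "acceptable")
    assert final_score(8, 7) == (7, "urgent")


def test_final_score_clamps_beyond_table():
    assert final_score(9, 9) == final_score(8, 7)


def test_tables_monotone_exhaustive():
    """Full index-domain check: +1 in any single sub-score never decreases
    Score A, Score B or the final score."""
    tables = RulaTables.load()
    A = np.array(tables.table_a)
    B = np.array(tables.table_b)
    C = np.array(tables.table_c)
    for arr in (A, B, C):
        for axis in range(arr.ndim):
            assert np.all(np.diff(arr, axis=axis) >= 0)
    # composite: final score over the complete SubScores domain
    ranges = [range(1, 7), range(1, 4), range(1, 5), range(1, 3), range(1, 7), range(1, 7), range(1, 3)]
    finals = {}
    for combo in itertools.product(*ranges):
        s = SubScores(*combo)
        f, _ = final_score(lookup_score_a(s), lookup_score_b(s))
        assert 1 <= f <= 7
        finals[combo] = f
    for combo, f in finals.items():
        for i in range(7):
            up = list(combo)
            up[i] += 1
            if tuple(up) in finals:
                assert finals[tuple(up)] >= f


def test_action_level_bands():
    assert [action_level(s) for s in range(1, 8)] == [
        "acceptable", "acceptable", "investigate", "investigate",
        "changes_soon", "changes_soon", "urgent",
    ]


def test_out_of_range_subscores_rejected():
    with pytest.raises(ValueError):
        SubScores(7, 1, 1, 1, 1, 1, 1)
    with pytest.raises(ValueError):
        SubScores(1, 1, 5, 1, 1, 1, 1)


# ---------------------------------------------------------------------------
# Frame evaluation
# ---------------------------------------------------------------------------

def test_evaluate_neutral_frame_acceptable():
    res = evaluate_frame(make_angles())
    assert res.final_score <= 2
    assert res.action_level == "acceptable"


def test_evaluate_deep_lift_frame_critical():
    res = evaluate_frame(make_angles(trunk=65.0, neck=35.0, arm=95.0, forearm=120.0))
    assert res.sub_scores.upper_arm == 4
    assert res.sub_scores.lower_arm == 2
    assert res.sub_scores.trunk == 4
    assert res.sub_scores.neck == 3
    assert res.final_score >= 5
    assert res.action_level in ("changes_soon", "urgent")


def test_invalid_required_angle_yields_unscorable():
    ja = make_angles(trunk=65.0)
    ja.valid["arm_flexion_right"] = False  # active side arm missing
    assert isinstance(score_segments(ja), UnscorableFrame)
    assert isinstance(evaluate_frame(ja), UnscorableFrame)
    # inactive side invalidity does not block scoring
    ja2 = make_angles()
    ja2.valid["arm_flexion_left"] = False
    assert not isinstance(evaluate_frame(ja2), UnscorableFrame)


def test_determinism_pure_lookup():
    ja = make_angles(trunk=40.0, neck=20.0, arm=60.0, forearm=70.0)
    r1 = evaluate_frame(ja)
    r2 = evaluate_frame(ja)
    assert r1.final_score == r2.final_score and r1.sub_scores == r2.sub_scores
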