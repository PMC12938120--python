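"""End-to-end scoring of recorded sessions and cohort aggregation.

Per frame the pipeline runs: visibility gating -> segment vectors -> joint
angles -> exponential smoothing -> RULA scoring -> alert decision, exactly
the loop a live monitor executes, applied offline to a finite recording.
Outputs are a structured JSON report (carrying the effective configuration,
software version and table checksum for provenance) and an events CSV with
one row per alert.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .alerts import AlertEvent, AlertState, process_frame
from .analytics import (
    ScoreSeries,
    SessionSummary,
    cohens_h,
    cohort_distribution,
    mcnemar_exact,
    paired_risk_table,
    summarize_session,
)
from .config import PipelineConfig
from .kinematics import (
    ANGLE_CHANNELS,
    JointAngles,
    active_side,
    build_segment_vectors,
    compute_joint_angles,
)
from .landmarks import (
    Landmark,
    LandmarkFrame,
    SessionStream,
    frame_validity,
    read_session,
)
from .rula import TABLES_SHA256, UNSCORABLE, UnscorableFrame, evaluate_frame
from .stabilizer import Stabilizer

# angle channel -> stabilizer channel
_SMOOTH_CHANNEL = {
    "trunk_flexion": "trunk",
    "neck_flexion": "neck",
    "arm_flexion_left": "arm_left",
    "arm_flexion_right": "arm_right",
    "arm_abduction_left": "abduction_left",
    "arm_abduction_right": "abduction_right",
    "forearm_angle_left": "forearm_left",
    "forearm_angle_right": "forearm_right",
    "lateral_tilt": "tilt",
}


def _smooth_coordinates(stream: SessionStream, alpha: float, threshold: float) -> SessionStream:
    """Coordinate-mode smoothing: EMA over raw landmark positions.

    Landmarks below the visibility threshold hold their last smoothed
    position (visibility is passed through untouched).
    """
    last: np.ndarray | None = None
    frames = []
    for f in stream.frames:
        pos = f.positions()
        vis = f.visibilities()
        if last is None:
            sm = pos.copy()
        else:
            sm = np.where(
                (vis >= threshold)[:, None], alpha * pos + (1 - alpha) * last, last
            )
        last = sm
        frames.append(
            LandmarkFrame(
                timestamp=f.timestamp,
                landmarks=tuple(
                    Landmark(float(p[0]), float(p[1]), float(p[2]), float(v))
                    for p, v in zip(sm, vis)
                ),
            )
        )
    return SessionStream(frames=frames, nominal_fps=stream.nominal_fps, metadata=dict(stream.metadata))


def score_stream(stream: SessionStream, config: PipelineConfig | None = None):
    """Run the full scoring loop over a session.

    Returns (ScoreSeries, list[AlertEvent]).  Angle channels invalidated by
    visibility gating hold the last smoothed value but are flagged stale and
    excluded from scoring, so such frames come out unscorable.
    """
    config = config or PipelineConfig()
    if config.stabilizer.mode == "coordinates":
        stream = _smooth_coordinates(
            stream, config.stabilizer.coordinate_alpha, config.kinematics.visibility_threshold
        )
        smooth_angles = False
    else:
        smooth_angles = True

    stab = Stabilizer(config.stabilizer)
    alert_state = AlertState()
    side_prev: str | None = None
    timestamps, scores, angles_list, subs_list, events = [], [], [], [], []

    for frame in stream.frames:
        mask = frame_validity(frame, config.kinematics.visibility_threshold)
        sv = build_segment_vectors(frame, mask)
        raw = compute_joint_angles(sv, config.kinematics)
        side = active_side(frame, mask, previous=side_prev)
        side_prev = side

        smoothed = JointAngles(active_side=side)
        for ch in ANGLE_CHANNELS:
            sc = _SMOOTH_CHANNEL[ch]
            if raw.valid.get(ch, False):
                val = stab.update(sc, raw.get(ch)) if smooth_angles else raw.get(ch)
                setattr(smoothed, ch, val)
                smoothed.valid[ch] = True
            else:
                held = stab.last(sc)
                setattr(smoothed, ch, held if held is not None else math.nan)
                smoothed.valid[ch] = False  # stale: held, not scorable

        result = evaluate_frame(smoothed, config.rula)
        if isinstance(result, UnscorableFrame):
            scores.append(UNSCORABLE)
            subs_list.append(UNSCORABLE)
            ev = process_frame(UNSCORABLE, frame.timestamp, alert_state, config.alerts)
        else:
            scores.append(result.final_score)
            subs_list.append(result.sub_scores)
            ev = process_frame(result.final_score, frame.timestamp, alert_state, config.alerts)
        if ev is not None:
            events.append(ev)
        timestamps.append(frame.timestamp)
        angles_list.append(smoothed)

    series = ScoreSeries(
        timestamps=timestamps, scores=scores, angles=angles_list, sub_scores=subs_list
    )
    return series, events


def _summary_to_dict(s: SessionSummary) -> dict:
    d = asdict(s)
    if d["risk_alert_r"] is None:
        d["risk_alert_r"] = None  # explicit undefined marker in JSON
    return d


def run_score(
    input_path: str | Path,
    config: PipelineConfig | None = None,
    report_path: str | Path | None = None,
    events_path: str | Path | None = None,
    y_axis: str = "up",
    include_series: bool = False,
) -> dict:
    """Score one recorded session file; write report JSON and events CSV.

    Returns the report dictionary.  Outputs are only written after the whole
    session scored successfully, so failures leave no partial files.
    """
    config = config or PipelineConfig()
    stream = read_session(input_path, y_axis=y_axis)
    series, events = score_stream(stream, config)
    summary = summarize_session(series, events, config.analytics, config.alerts)

    report = {
        "software": {"name": "rulakit", "version": __version__, "tables_sha256": TABLES_SHA256},
        "config": config.to_dict(),
        "session": {
            "input": str(input_path),
            "metadata": stream.metadata,
            "nominal_fps": stream.nominal_fps,
            "n_frames": len(stream.frames),
        },
        "summary": _summary_to_dict(summary),
    }
    if include_series:
        report["series"] = {
            "timestamps": series.timestamps,
            "scores": [None if isinstance(s, UnscorableFrame) else s for s in series.scores],
        }
    if report_path is not None:
        Path(report_path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    if events_path is not None:
        write_events_csv(events, events_path)
    return report


def write_events_csv(events: list[AlertEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp_s", "score", "frequency_hz", "duration_ms"])
        for e in events:
            w.writerow([f"{e.timestamp:.6f}", e.score_at_trigger, e.frequency, e.duration_ms])


def read_events_csv(path: str | Path) -> list[AlertEvent]:
    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(
                AlertEvent(
                    timestamp=float(row["timestamp_s"]),
                    score_at_trigger=int(row["score"]),
                    frequency=float(row["frequency_hz"]),
                    duration_ms=float(row["duration_ms"]),
                )
            )
    return events


def run_cohort(
    manifest_path: str | Path,
    config: PipelineConfig | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Aggregate paired static/dynamic session reports into cohort statistics.

    The manifest is a CSV with columns ``participant, static_report,
    dynamic_report`` naming report JSON files produced by :func:`run_score`
    (paths relative to the manifest).  Participants whose files are missing
    are excluded from the paired tests with a warning entry.
    """
    config = config or PipelineConfig()
    manifest_path = Path(manifest_path)
    thr = config.analytics.critical_threshold

    pairs, excluded = [], []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            pid = row.get("participant", "").strip()
            entry = {}
            ok = True
            for cond in ("static_report", "dynamic_report"):
                rel = (row.get(cond) or "").strip()
                p = (manifest_path.parent / rel) if rel else None
                if not rel or not p.exists():
                    excluded.append({"participant": pid, "reason": f"missing {cond}"})
                    ok = False
                    break
                entry[cond] = json.loads(p.read_text())
            if ok:
                pairs.append((pid, entry))

    if not pairs:
        result = {"n_pairs": 0, "excluded": excluded, "mcnemar_p": None, "cohens_h": None,
                  "note": "insufficient data for paired tests"}
        if out_path is not None:
            Path(out_path).write_text(json.dumps(result, sort_keys=True, indent=2) + "\n")
        return result

    def max_score(rep: dict) -> int | None:
        return rep["summary"]["max_score"]

    static_crit = [max_score(e["static_report"]) is not None and max_score(e["static_report"]) >= thr
                   for _, e in pairs]
    dynamic_crit = [max_score(e["dynamic_report"]) is not None and max_score(e["dynamic_report"]) >= thr
                    for _, e in pairs]
    table = paired_risk_table(static_crit, dynamic_crit)

    def to_summary(rep: dict) -> SessionSummary:
        return SessionSummary(**rep["summary"])

    dyn_summaries = [to_summary(e["dynamic_report"]) for _, e in pairs]
    stat_summaries = [to_summary(e["static_report"]) for _, e in pairs]
    dist_dyn = cohort_distribution(dyn_summaries, condition="dynamic", critical_threshold=thr)
    dist_stat = cohort_distribution(stat_summaries, condition="static", critical_threshold=thr)

    if len(pairs) < 2:
        p_mcnemar = None
        h = None
        note = "insufficient data for paired tests"
    else:
        p_mcnemar = mcnemar_exact(table)
        h = cohens_h(table.p_dynamic, table.p_static)
        note = None

    result = {
        "n_pairs": len(pairs),
        "excluded": excluded,
        "paired_table": {"n11": table.n11, "n10": table.n10, "n01": table.n01, "n00": table.n00},
        "p_critical_static": table.p_static,
        "p_critical_dynamic": table.p_dynamic,
        "mcnemar_p": p_mcnemar,
        "cohens_h": h,
        "distribution_dynamic": asdict(dist_dyn),
        "distribution_static": asdict(dist_stat),
    }
    if note:
        result["note"] = note
    if out_path is not None:
        Path(out_path).write_text(json.dumps(result, sort_keys=True, indent=2) + "\n")
    return result
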