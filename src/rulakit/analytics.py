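"""Session-level risk metrics and cohort-level paired statistics.

Per session: maximum and mean RULA score, time spent in the critical zone
(score >= 5), alert count, the Pearson correlation between the binary risk
indicator and alert coverage, false-alarm and missed-alert rates, which
anatomical segments contributed to critical risk, and the static-baseline
score.

Per cohort: the score distribution over action-level bands, the percentage
of participants at critical risk, and — for paired static/dynamic designs —
McNemar's exact test on discordant pairs plus Cohen's h effect size for the
difference of proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .alerts import AlertConfig, AlertEvent
from .kinematics import JointAngles
from .rula import SubScores, UnscorableFrame


@dataclass
class AnalyticsConfig:
    critical_threshold: int = 5    # final score defining the critical zone
    baseline_s: float = 3.0        # leading window treated as static baseline
    # minimum sub-score for a segment to count as contributing to risk
    segment_flag_min: dict[str, int] = field(
        default_factory=lambda: {"trunk": 2, "neck": 2, "upper_arm": 2, "lower_arm": 2}
    )


@dataclass
class ScoreSeries:
    """Aligned per-frame outputs of the scoring pipeline."""

    timestamps: list[float]
    scores: list  # int or UnscorableFrame per frame
    angles: list[JointAngles] | None = None
    sub_scores: list | None = None  # SubScores or UnscorableFrame per frame

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if len(self.scores) != n:
            raise ValueError("scores and timestamps must align")
        for attr in (self.angles, self.sub_scores):
            if attr is not None and len(attr) != n:
                raise ValueError("per-frame series must align with timestamps")
        for a, b in zip(self.timestamps, self.timestamps[1:]):
            if b <= a:
                raise ValueError("timestamps must be strictly increasing")

    def scorable(self) -> list[tuple[int, float, int]]:
        """(index, timestamp, score) for frames that produced a score."""
        return [
            (i, t, s)
            for i, (t, s) in enumerate(zip(self.timestamps, self.scores))
            if not isinstance(s, UnscorableFrame)
        ]


@dataclass
class SessionSummary:
    max_score: int | None
    mean_score: float | None
    time_critical: float
    alert_count: int
    risk_alert_r: float | None
    false_alarm_rate: float
    missed_rate: float
    segment_flags: dict[str, bool]
    static_score: int | None
    duration: float
    n_frames: int
    n_scorable: int


def _frame_durations(timestamps: list[float]) -> np.ndarray:
    """Per-frame duration: gap to the next timestamp; the last frame gets the
    median gap (a single frame gets 0)."""
    ts = np.asarray(timestamps, dtype=float)
    if len(ts) < 2:
        return np.zeros(len(ts))
    gaps = np.diff(ts)
    return np.append(gaps, float(np.median(gaps)))


def _critical_runs(series: ScoreSeries, threshold: int) -> list[tuple[float, float]]:
    """Maximal runs of consecutive scorable frames with score >= threshold,
    as (start_t, end_t) where end is the last frame's t plus its duration."""
    durs = _frame_durations(series.timestamps)
    runs: list[tuple[float, float]] = []
    start = None
    end = None
    for i, (t, s) in enumerate(zip(series.timestamps, series.scores)):
        critical = not isinstance(s, UnscorableFrame) and s >= threshold
        if critical:
            if start is None:
                start = t
            end = t + durs[i]
        elif start is not None:
            runs.append((start, end))
            start = None
    if start is not None:
        runs.append((start, end))
    return runs


def summarize_session(
    series: ScoreSeries,
    events: list[AlertEvent],
    cfg: AnalyticsConfig | None = None,
    alert_cfg: AlertConfig | None = None,
) -> SessionSummary:
    """Post-hoc risk metrics for one recorded session."""
    cfg = cfg or AnalyticsConfig()
    alert_cfg = alert_cfg or AlertConfig()
    if not series.timestamps:
        raise ValueError("empty series")
    scorable = series.scorable()
    durs = _frame_durations(series.timestamps)

    if scorable:
        vals = [s for _, _, s in scorable]
        max_score: int | None = max(vals)
        mean_score: float | None = float(np.mean(vals))
    else:
        max_score = mean_score = None

    thr = cfg.critical_threshold
    time_critical = float(
        sum(durs[i] for i, _, s in scorable if s >= thr)
    )

    fa, missed = error_rates(series, events, cfg, alert_cfg)
    r = risk_alert_correlation(series, events, cfg, alert_cfg)

    segment_flags = {seg: False for seg in cfg.segment_flag_min}
    if series.sub_scores is not None:
        for (i, _, s) in scorable:
            if s < thr:
                continue
            sub = series.sub_scores[i]
            if isinstance(sub, UnscorableFrame) or sub is None:
                continue
            for seg, floor_ in cfg.segment_flag_min.items():
                if getattr(sub, seg) >= floor_:
                    segment_flags[seg] = True

    t0 = series.timestamps[0]
    baseline = [s for _, t, s in scorable if t - t0 < cfg.baseline_s]
    static_score = max(baseline) if baseline else None

    return SessionSummary(
        max_score=max_score,
        mean_score=mean_score,
        time_critical=time_critical,
        alert_count=len(events),
        risk_alert_r=r,
        false_alarm_rate=fa,
        missed_rate=missed,
        segment_flags=segment_flags,
        static_score=static_score,
        duration=float(series.timestamps[-1] - t0 + durs[-1]) if len(series.timestamps) else 0.0,
        n_frames=len(series.timestamps),
        n_scorable=len(scorable),
    )


def risk_alert_correlation(
    series: ScoreSeries,
    events: list[AlertEvent],
    cfg: AnalyticsConfig | None = None,
    alert_cfg: AlertConfig | None = None,
) -> float | None:
    """Pearson r between per-frame risk and alert-coverage indicators.

    Risk indicator: score >= critical threshold.  Coverage indicator: frame
    timestamp falls within [event_t, event_t + refractory) of some alert.
    Returns None when either indicator is constant (undefined correlation).
    """
    cfg = cfg or AnalyticsConfig()
    alert_cfg = alert_cfg or AlertConfig()
    scorable = series.scorable()
    if len(scorable) < 2:
        return None
    risk = np.array([1.0 if s >= cfg.critical_threshold else 0.0 for _, _, s in scorable])
    starts = np.array([e.timestamp for e in events], dtype=float)
    cover = np.array(
        [
            1.0 if len(starts) and np.any((starts <= t) & (t < starts + alert_cfg.refractory)) else 0.0
            for _, t, _ in scorable
        ]
    )
    if risk.std() == 0.0 or cover.std() == 0.0:
        return None
    return float(np.corrcoef(risk, cover)[0, 1])


def error_rates(
    series: ScoreSeries,
    events: list[AlertEvent],
    cfg: AnalyticsConfig | None = None,
    alert_cfg: AlertConfig | None = None,
) -> tuple[float, float]:
    """(false_alarm_rate, missed_rate).

    False alarms: fraction of alert events whose trigger score was below the
    critical threshold (0 when there are no events).  Missed alerts: of the
    maximal critical runs lasting longer than the refractory period, the
    fraction containing no alert event (0 when there are no such runs).
    """
    cfg = cfg or AnalyticsConfig()
    alert_cfg = alert_cfg or AlertConfig()
    if events:
        fa = sum(1 for e in events if e.score_at_trigger < cfg.critical_threshold) / len(events)
    else:
        fa = 0.0
    runs = [
        (a, b) for a, b in _critical_runs(series, cfg.critical_threshold)
        if b - a > alert_cfg.refractory
    ]
    if runs:
        times = [e.timestamp for e in events]
        missed = sum(
            1 for a, b in runs if not any(a <= t <= b for t in times)
        ) / len(runs)
    else:
        missed = 0.0
    return float(fa), float(missed)


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedRiskTable:
    """2x2 paired-classification counts for static vs dynamic conditions.

    n11: critical in both; n10: critical in static only; n01: critical in
    dynamic only; n00: critical in neither.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def p_static(self) -> float:
        return (self.n11 + self.n10) / self.n

    @property
    def p_dynamic(self) -> float:
        return (self.n11 + self.n01) / self.n


def mcnemar_exact(table: PairedRiskTable, asymptotic: bool = False) -> float:
    """McNemar's test p-value on the discordant pairs.

    Exact (default): two-sided binomial, p = min(1, 2 * P(X <= min(n10, n01)))
    with X ~ Binomial(n10 + n01, 1/2).  With ``asymptotic=True`` the
    continuity-corrected chi-square variant is used instead.  No discordant
    pairs at all gives p = 1 (the conditions never disagree).
    """
    n_disc = table.n10 + table.n01
    if n_disc == 0:
        return 1.0
    if asymptotic:
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        tbl = [[table.n11, table.n10], [table.n01, table.n00]]
        return float(sm_mcnemar(tbl, exact=False, correction=True).pvalue)
    k = min(table.n10, table.n01)
    p = 2.0 * float(binom.cdf(k, n_disc, 0.5))
    return min(1.0, p)


def cohens_h(p1: float, p2: float) -> float:
    """Cohen's h effect size for two proportions: |2 asin sqrt(p1) - 2 asin sqrt(p2)|."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    return abs(2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2)))


SCORE_BANDS = ("1-2", "3", "4", "5-6", "7")


@dataclass
class CohortSummary:
    condition: str
    n: int
    count_by_band: dict[str, int]
    pct_critical: float
    action_by_band: dict[str, str] = field(
        default_factory=lambda: {
            "1-2": "acceptable",
            "3": "investigate",
            "4": "investigate",
            "5-6": "changes_soon",
            "7": "urgent",
        }
    )


def cohort_distribution(
    summaries: list[SessionSummary],
    condition: str = "dynamic",
    critical_threshold: int = 5,
) -> CohortSummary:
    """Bin per-participant maximum scores into action-level bands."""
    if not summaries:
        raise ValueError("no session summaries")
    counts = {b: 0 for b in SCORE_BANDS}
    n_crit = 0
    for s in summaries:
        m = s.max_score
        if m is None:
            raise ValueError("session with no scorable frames cannot enter the distribution")
        if m <= 2:
            counts["1-2"] += 1
        elif m == 3:
            counts["3"] += 1
        elif m == 4:
            counts["4"] += 1
        elif m <= 6:
            counts["5-6"] += 1
        else:
            counts["7"] += 1
        if m >= critical_threshold:
            n_crit += 1
    return CohortSummary(
        condition=condition,
        n=len(summaries),
        count_by_band=counts,
        pct_critical=100.0 * n_crit / len(summaries),
    )


def paired_risk_table(
    static_critical: list[bool], dynamic_critical: list[bool]
) -> PairedRiskTable:
    """Build the 2x2 paired table from per-participant critical flags."""
    if len(static_critical) != len(dynamic_critical):
        raise ValueError("paired conditions must have equal length")
    n11 = sum(1 for s, d in zip(static_critical, dynamic_critical) if s and d)
    n10 = sum(1 for s, d in zip(static_critical, dynamic_critical) if s and not d)
    n01 = sum(1 for s, d in zip(static_critical, dynamic_critical) if not s and d)
    n00 = sum(1 for s, d in zip(static_critical, dynamic_critical) if not s and not d)
    return PairedRiskTable(n11=n11, n10=n10, n01=n01, n00=n00)
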