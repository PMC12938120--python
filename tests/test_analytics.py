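"""Session metrics and cohort paired statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest

from rulakit.alerts import AlertConfig, AlertEvent, process_series
from rulakit.analytics import (
    AnalyticsConfig,
    PairedRiskTable,
    ScoreSeries,
    SessionSummary,
    cohens_h,
    cohort_distribution,
    error_rates,
    mcnemar_exact,
    paired_risk_table,
    risk_alert_correlation,
    summarize_session,
)
from rulakit.rula import UNSCORABLE


def uniform_series(scores, fps=30.0):
    ts = [i / fps for i in range(len(scores))]
    return ScoreSeries(timestamps=ts, scores=list(scores))


def make_event(t, score=7):
    return AlertEvent(timestamp=t, score_at_trigger=score, frequency=1000.0, duration_ms=200.0)


# ---------------------------------------------------------------------------
# Session summaries
# ---------------------------------------------------------------------------

def test_benign_session_summary():
    series = uniform_series([2] * 1800)  # 60 s of constant score 2
    s = summarize_session(series, [])
    assert s.max_score == 2
    assert s.mean_score == 2.0
    assert s.time_critical == 0.0
    assert s.alert_count == 0
    assert s.static_score == 2


def test_time_critical_duration_bookkeeping():
    """Score 7 for exactly half of a 60 s uniform session: ~30 s critical."""
    scores = [7] * 900 + [2] * 900
    series = uniform_series(scores)
    s = summarize_session(series, [])
    assert s.time_critical == pytest.approx(30.0, abs=1 / 30 + 1e-9)
    assert s.duration == pytest.approx(60.0, abs=1 / 30 + 1e-9)


def test_time_partition_accounts_for_whole_session():
    rng = np.random.default_rng(3)
    scores = [
        UNSCORABLE if rng.random() < 0.1 else int(rng.integers(1, 8)) for _ in range(600)
    ]
    series = uniform_series(scores)
    s = summarize_session(series, [])
    durs = np.full(600, 1 / 30.0)
    t_crit = sum(d for d, sc in zip(durs, scores) if sc is not UNSCORABLE and sc >= 5)
    t_non = sum(d for d, sc in zip(durs, scores) if sc is not UNSCORABLE and sc < 5)
    t_un = sum(d for d, sc in zip(durs, scores) if sc is UNSCORABLE)
    assert s.time_critical == pytest.approx(t_crit, abs=1 / 30)
    assert t_crit + t_non + t_un == pytest.approx(s.duration, abs=1 / 30)


def test_all_unscorable_session_reports_missing():
    series = uniform_series([UNSCORABLE] * 10)
    s = summarize_session(series, [])
    assert s.max_score is None and s.mean_score is None and s.static_score is None
    assert s.n_scorable == 0


def test_static_baseline_window():
    # first 3 s (90 frames) at 30 FPS are the baseline
    scores = [3] * 90 + [7] * 910
    s = summarize_session(uniform_series(scores), [])
    assert s.static_score == 3
    assert s.max_score == 7


# ---------------------------------------------------------------------------
# Risk-alert correlation
# ---------------------------------------------------------------------------

def _phi(x, y):
    """Closed-form Pearson correlation of two 0/1 vectors."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    n11 = float(np.sum((x == 1) & (y == 1)))
    num = n11 * n - x.sum() * y.sum()
    den = math.sqrt(x.sum() * (n - x.sum()) * y.sum() * (n - y.sum()))
    return num / den


def test_correlation_is_one_when_alerts_cover_runs():
    """Events generated from the same series, with critical runs spanning
    exactly one refractory window each, make the indicators coincide: r = 1."""
    scores = [2] * 30 + [7] * 60 + [2] * 30 + [6] * 60 + [2] * 30
    series = uniform_series(scores)
    cfg = AlertConfig(refractory=2.0)  # each run lasts exactly 60 frames = 2.0 s
    events = process_series(series.scores, series.timestamps, cfg)
    r = risk_alert_correlation(series, events, alert_cfg=cfg)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_correlation_undefined_for_constant_indicator():
    series = uniform_series([2] * 100)
    assert risk_alert_correlation(series, []) is None


def test_correlation_matches_direct_formula_for_shifted_coverage():
    n = 100
    scores = [7 if 10 <= i < 40 else 2 for i in range(n)]
    series = uniform_series(scores, fps=1.0)
    # coverage window of exactly the frames 15..44: event at t=15, refractory 30
    events = [make_event(15.0)]
    cfg = AlertConfig(refractory=30.0)
    r = risk_alert_correlation(series, events, alert_cfg=cfg)
    risk = [1 if s >= 5 else 0 for s in scores]
    cover = [1 if 15 <= t < 45 else 0 for t in range(n)]
    assert r == pytest.approx(_phi(risk, cover), abs=1e-12)
    # coincident coverage gives exactly 1
    events2 = [make_event(10.0)]
    r2 = risk_alert_correlation(series, events2, alert_cfg=cfg)
    assert r2 == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Error rates
# ---------------------------------------------------------------------------

def test_engine_generated_events_have_no_false_alarms():
    scores = [2] * 30 + [7] * 300 + [2] * 30
    series = uniform_series(scores)
    events = process_series(series.scores, series.timestamps)
    fa, missed = error_rates(series, events)
    assert fa == 0.0
    assert missed == 0.0


def test_stripped_events_give_full_missed_rate():
    scores = [2] * 30 + [7] * 150 + [2] * 30  # one 5 s critical run
    series = uniform_series(scores)
    fa, missed = error_rates(series, [])
    assert missed == 1.0
    assert fa == 0.0  # no events, rate defined as 0


def test_partial_coverage_missed_rate():
    # two long runs, alert inside the first only
    scores = [7] * 150 + [2] * 60 + [7] * 150
    series = uniform_series(scores)
    fa, missed = error_rates(series, [make_event(1.0)])
    assert missed == 0.5


def test_false_alarm_counts_subthreshold_triggers():
    series = uniform_series([2] * 100)
    events = [make_event(0.0, score=4), make_event(3.0, score=5)]
    fa, _ = error_rates(series, events)
    assert fa == 0.5


# ---------------------------------------------------------------------------
# McNemar exact and Cohen's h
# ---------------------------------------------------------------------------

def test_mcnemar_symmetric_discordance():
    assert mcnemar_exact(PairedRiskTable(0, 5, 5, 0)) == 1.0


def test_mcnemar_fully_asymmetric_small_p():
    p = mcnemar_exact(PairedRiskTable(3, 0, 22, 15))
    assert p == pytest.approx(2 * 0.5**22, rel=1e-12)
    assert p < 0.001


def test_mcnemar_single_discordant_capped():
    assert mcnemar_exact(PairedRiskTable(0, 0, 1, 10)) == 1.0


def test_mcnemar_no_discordant_pairs():
    assert mcnemar_exact(PairedRiskTable(5, 0, 0, 5)) == 1.0


def test_mcnemar_matches_exact_enumeration():
    """Agreement with a from-scratch rational enumeration of the binomial
    distribution for every discordant split with n10 + n01 <= 20."""
    for n in range(1, 21):
        for k10 in range(n + 1):
            k01 = n - k10
            k = min(k10, k01)
            tail = sum(Fraction(math.comb(n, j), 2**n) for j in range(k + 1))
            expected = min(Fraction(1), 2 * tail)
            got = mcnemar_exact(PairedRiskTable(0, k10, k01, 0))
            assert got == pytest.approx(float(expected), rel=1e-9)


def test_mcnemar_asymptotic_variant_close_for_large_counts():
    exact = mcnemar_exact(PairedRiskTable(10, 30, 60, 10))
    asym = mcnemar_exact(PairedRiskTable(10, 30, 60, 10), asymptotic=True)
    assert asym == pytest.approx(exact, rel=0.25)


def test_cohens_h_closed_forms():
    assert cohens_h(0.3, 0.3) == 0.0
    assert cohens_h(1.0, 0.0) == pytest.approx(math.pi)
    assert cohens_h(0.625, 0.075) == pytest.approx(1.2687, abs=1e-4)
    assert cohens_h(0.2, 0.7) == cohens_h(0.7, 0.2)  # symmetric


def test_cohens_h_monotone_in_separation():
    mid = 0.4
    hs = [cohens_h(mid - d, mid + d) for d in (0.05, 0.1, 0.2, 0.3)]
    assert all(b > a for a, b in zip(hs, hs[1:]))


# ---------------------------------------------------------------------------
# Cohort distribution
# ---------------------------------------------------------------------------

def _summary_with_max(m):
    return SessionSummary(
        max_score=m, mean_score=float(m), time_critical=0.0, alert_count=0,
        risk_alert_r=None, false_alarm_rate=0.0, missed_rate=0.0,
        segment_flags={}, static_score=1, duration=60.0, n_frames=1800, n_scorable=1800,
    )


def test_cohort_distribution_printed_counts():
    maxima = [3] * 6 + [4] * 12 + [5] * 10 + [6] * 10 + [7] * 2
    dist = cohort_distribution([_summary_with_max(m) for m in maxima])
    assert dist.n == 40
    assert dist.count_by_band == {"1-2": 0, "3": 6, "4": 12, "5-6": 20, "7": 2}
    assert dist.pct_critical == 55.0


def test_cohort_critical_proportion():
    maxima = [6] * 25 + [3] * 15
    dist = cohort_distribution([_summary_with_max(m) for m in maxima])
    assert dist.pct_critical == 62.5


def test_cohort_all_acceptable():
    dist = cohort_distribution([_summary_with_max(1) for _ in range(10)])
    assert dist.pct_critical == 0.0
    assert dist.count_by_band["1-2"] == 10


def test_paired_risk_table_from_flags():
    static = [True, True, False, False]
    dynamic = [True, False, True, False]
    t = paired_risk_table(static, dynamic)
    assert (t.n11, t.n10, t.n01, t.n00) == (1, 1, 1, 1)
    assert t.n == 4
    assert t.p_static == 0.5 and t.p_dynamic == 0.5
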