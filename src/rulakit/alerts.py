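"""Bio-inspired alert scheduling over the per-frame score stream.

Mimicking the proprioceptive reflex loop, a critical posture (final score at
or above the threshold, default 5) triggers an immediate auditory alert
event; a refractory period (default 2.0 s) between successive alerts
prevents alert fatigue while keeping risk communication continuous.  A
score of 7 escalates the tone from 1000 Hz to 2500 Hz.

Alerts are data: timestamped events suitable for an events file.  Audio
playback is a presentation concern left to callers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rula import UnscorableFrame


@dataclass
class AlertConfig:
    threshold: int = 5           # final score at/above which alerts fire
    refractory: float = 2.0      # seconds; strict gap required between alerts
    tone_low: float = 1000.0     # Hz
    tone_high: float = 2500.0    # Hz, used at high_score
    high_score: int = 7
    duration_ms: float = 200.0
    sustain_s: float = 0.0       # reserved for sustained-duration triggering

    def __post_init__(self) -> None:
        if not 1 <= self.threshold <= 7:
            raise ValueError("threshold must be in [1, 7]")
        if self.refractory <= 0:
            raise ValueError("refractory must be > 0")


@dataclass
class AlertState:
    last_alert_time: float | None = None
    last_time: float | None = None  # last processed timestamp, for the monotonicity contract


@dataclass(frozen=True)
class AlertEvent:
    timestamp: float
    score_at_trigger: int
    frequency: float
    duration_ms: float


def process_frame(
    score: int | UnscorableFrame,
    t: float,
    state: AlertState,
    cfg: AlertConfig | None = None,
) -> AlertEvent | None:
    """Alert decision for one frame.

    Emits an event iff the score is at/above the threshold and either no
    alert has fired yet or strictly more than the refractory period has
    elapsed since the last one.  Unscorable frames neither trigger nor reset
    the refractory clock.  Timestamps must be non-decreasing across calls.
    """
    cfg = cfg or AlertConfig()
    if state.last_time is not None and t < state.last_time:
        raise ValueError(f"timestamp {t} precedes already-processed {state.last_time}")
    state.last_time = t
    if isinstance(score, UnscorableFrame):
        return None
    if score < cfg.threshold:
        return None
    if state.last_alert_time is not None and not (t - state.last_alert_time > cfg.refractory):
        return None
    state.last_alert_time = t
    freq = cfg.tone_high if score >= cfg.high_score else cfg.tone_low
    return AlertEvent(timestamp=t, score_at_trigger=score, frequency=freq, duration_ms=cfg.duration_ms)


def process_series(
    scores: list,
    timestamps: list[float],
    cfg: AlertConfig | None = None,
) -> list[AlertEvent]:
    """Run the alert rule over an entire scored session."""
    cfg = cfg or AlertConfig()
    state = AlertState()
    events = []
    for score, t in zip(scores, timestamps):
        ev = process_frame(score, t, state, cfg)
        if ev is not None:
            events.append(ev)
    return events
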