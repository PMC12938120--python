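"""First-order exponential smoothing of per-segment angle channels.

Each angle channel (trunk, neck, per-side arm/forearm/abduction, lateral
tilt) is stabilised with

    L_t(smoothed) = alpha * L_t + (1 - alpha) * L_{t-1}

where alpha trades jitter suppression against step-response latency.  The
defaults follow a step-response tuning: alpha = 0.8 for the slow-moving trunk
and cervical channels (about 3 frames to 99% of a step at 30 FPS, ~100 ms)
and alpha = 0.7 for the faster arm channels, where responsiveness matters
more than smoothness.

Frames whose angle is invalidated by visibility gating do not update the
filter: the last smoothed value is held and flagged stale by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


DEFAULT_ALPHAS: dict[str, float] = {
    "trunk": 0.8,
    "neck": 0.8,
    "tilt": 0.8,
    "arm_left": 0.7,
    "arm_right": 0.7,
    "forearm_left": 0.7,
    "forearm_right": 0.7,
    "abduction_left": 0.7,
    "abduction_right": 0.7,
}


class UnknownChannelError(KeyError):
    """An angle channel not declared in the filter configuration."""


@dataclass
class FilterConfig:
    """Smoothing coefficients per channel and the smoothing mode.

    ``mode`` selects whether smoothing acts on derived angle channels
    (default, matching the per-segment stabiliser update of the scoring loop)
    or on raw landmark coordinates before any angle is computed.
    ``coordinate_alpha`` applies only in coordinate mode.
    """

    alpha_by_channel: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHAS))
    mode: str = "angles"
    coordinate_alpha: float = 0.8

    def __post_init__(self) -> None:
        for ch, a in self.alpha_by_channel.items():
            if not 0.0 < a <= 1.0:
                raise ValueError(f"alpha for channel {ch!r} must be in (0, 1], got {a}")
        if self.mode not in ("angles", "coordinates"):
            raise ValueError(f"mode must be 'angles' or 'coordinates', got {self.mode!r}")
        if not 0.0 < self.coordinate_alpha <= 1.0:
            raise ValueError("coordinate_alpha must be in (0, 1]")


@dataclass
class FilterState:
    """Last smoothed value per channel; a channel absent from the map has not
    yet seen a sample."""

    last_value_by_channel: dict[str, float] = field(default_factory=dict)


class Stabilizer:
    """Stateful exponential smoother over a fixed set of named channels."""

    def __init__(self, config: FilterConfig | None = None) -> None:
        self.config = config or FilterConfig()
        self.state = FilterState()

    def update(self, channel: str, value: float) -> float:
        return smooth_update(self.state, channel, value, self.config)

    def last(self, channel: str) -> float | None:
        return self.state.last_value_by_channel.get(channel)

    def reset(self) -> None:
        self.state = FilterState()


def smooth_update(
    state: FilterState, channel: str, value: float, config: FilterConfig
) -> float:
    """One filter step: returns alpha*value + (1-alpha)*previous.

    The first sample on a channel seeds the state and is returned unchanged
    (no zero-initialisation bias).  The state after the call always reflects
    the returned value.
    """
    if channel not in config.alpha_by_channel:
        raise UnknownChannelError(f"channel {channel!r} not in filter configuration")
    if not math.isfinite(value):
        raise ValueError(f"non-finite sample {value} on channel {channel!r}")
    prev = state.last_value_by_channel.get(channel)
    if prev is None:
        out = float(value)
    else:
        a = config.alpha_by_channel[channel]
        out = a * float(value) + (1.0 - a) * prev
    state.last_value_by_channel[channel] = out
    return out


def step_latency(alpha: float, settle_fraction: float = 0.99) -> int:
    """Frames for the filter to settle to a fraction of a unit step.

    Returns the smallest n >= 1 with 1 - (1-alpha)^n >= settle_fraction,
    i.e. the residual (1-alpha)^n has decayed below 1 - settle_fraction.
    With alpha = 0.8 and a 99% settle criterion this is 3 frames (100 ms at
    30 FPS); with alpha = 0.7 it is 4.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if not 0.0 < settle_fraction < 1.0:
        raise ValueError("settle_fraction must be in (0, 1)")
    if alpha == 1.0:
        return 1
    n = 1
    residual = 1.0 - alpha
    while 1.0 - residual ** n < settle_fraction:
        n += 1
    return n
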