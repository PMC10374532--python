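"""Optogenetic photostimulation pulse trains.

The experiments drive an implanted optical fiber with one of three sequences:
a continuous ("flat") light pulse, a 10-Hz train (12.5-ms on / 87.5-ms off,
duty cycle 12.5%, 40 pulses over 4 s), or a 4-Hz train (162.5-ms on /
87.5-ms off, duty cycle 65.0%, 16 pulses over 4 s).  This module models such
trains, derives duty cycle / repetition frequency / on-phase intervals, and
computes how much of a behavioral epoch (e.g. object exploration) is covered
by light-on time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .intervals import IntervalSet

__all__ = [
    "StimulusTrain",
    "FlatTrainError",
    "build_train",
    "duty_cycle",
    "repetition_frequency",
    "train_intervals",
    "coverage_ratio",
]


class FlatTrainError(ValueError):
    """Raised when a periodic-train quantity is requested of a flat train."""


@dataclass(frozen=True)
class StimulusTrain:
    """A photostimulation pulse schedule.

    mode
        ``"flat"`` (single continuous pulse) or ``"pulsed"`` (periodic train).
    pulse_on_ms, pulse_off_ms
        On/off phase durations of one period, milliseconds.  Flat trains have
        ``pulse_off_ms == 0`` and ``n_pulses == 1``.
    n_pulses
        Number of pulses in the train.
    start_s
        Train onset time in session coordinates, seconds.
    """

    mode: str
    pulse_on_ms: float
    pulse_off_ms: float
    n_pulses: int
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("flat", "pulsed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.pulse_on_ms <= 0:
            raise ValueError("pulse_on_ms must be > 0")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.mode == "flat" and (self.n_pulses != 1 or self.pulse_off_ms != 0):
            raise ValueError("flat mode requires n_pulses=1 and pulse_off_ms=0")
        if self.mode == "pulsed" and self.pulse_off_ms < 0:
            raise ValueError("pulse_off_ms must be >= 0")

    @property
    def period_ms(self) -> float:
        return self.pulse_on_ms + self.pulse_off_ms

    @property
    def duration_s(self) -> float:
        """Total train duration (n_pulses full periods for pulsed mode)."""
        return self.n_pulses * self.period_ms / 1000.0

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "StimulusTrain":
        return cls(**json.loads(text))


def build_train(
    mode: str,
    pulse_on_ms: float | None = None,
    pulse_off_ms: float | None = None,
    duration_s: float = 4.0,
    start_s: float = 0.0,
) -> StimulusTrain:
    """Construct a train of total length ``duration_s``.

    For pulsed mode the duration must hold an integer number of pulse
    periods; a non-integer count is rejected (the experimental trains are
    exact: 40 and 16 pulses) with the nearest valid durations suggested.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if mode == "flat":
        return StimulusTrain("flat", duration_s * 1000.0, 0.0, 1, start_s)
    if mode != "pulsed":
        raise ValueError(f"unknown mode {mode!r}")
    if pulse_on_ms is None or pulse_off_ms is None:
        raise ValueError("pulsed mode requires pulse_on_ms and pulse_off_ms")
    period_ms = pulse_on_ms + pulse_off_ms
    n_exact = duration_s * 1000.0 / period_ms
    n = round(n_exact)
    if n < 1 or abs(n_exact - n) > 1e-9 * max(1.0, abs(n_exact)):
        lo = max(1, int(n_exact)) * period_ms / 1000.0
        hi = (int(n_exact) + 1) * period_ms / 1000.0
        raise ValueError(
            f"duration {duration_s} s is not an integer number of "
            f"{period_ms}-ms periods; nearest valid durations: {lo} s or {hi} s"
        )
    return StimulusTrain("pulsed", pulse_on_ms, pulse_off_ms, n, start_s)


def duty_cycle(train: StimulusTrain) -> float:
    """Fraction of each period the light is on, in [0, 1]; 1 for flat."""
    if train.mode == "flat":
        return 1.0
    return train.pulse_on_ms / train.period_ms


def repetition_frequency(train: StimulusTrain) -> float:
    """Pulse repetition rate in Hz: 1000 / (on + off) ms."""
    if train.mode == "flat":
        raise FlatTrainError("repetition frequency is undefined for flat trains")
    return 1000.0 / train.period_ms


def train_intervals(train: StimulusTrain) -> IntervalSet:
    """Light-on intervals of the train: one [on-start, on-end) per pulse."""
    period_s = train.period_ms / 1000.0
    on_s = train.pulse_on_ms / 1000.0
    return IntervalSet(
        (train.start_s + k * period_s, train.start_s + k * period_s + on_s)
        for k in range(train.n_pulses)
    )


def coverage_ratio(stim: IntervalSet, behavior: IntervalSet) -> float:
    """Percent of behavioral time overlapped by stimulation time.

    100 * measure(stim ∩ behavior) / measure(behavior).  By default callers
    should pass the union of light-*on* phases (``train_intervals``); pass
    full train envelopes to compute envelope-based coverage instead.
    """
    denom = behavior.measure()
    if denom == 0:
        raise ValueError("behavior intervals have zero measure; coverage undefined")
    return 100.0 * stim.intersection(behavior).measure() / denom
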