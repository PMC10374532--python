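"""Synthetic whole-body plethysmography traces with known breath cycles.

The generator emulates the 1-kHz pressure signal of a mouse breathing in a
sealed chamber.  Each breath cycle is rendered as an asymmetric raised-cosine
pressure pulse (a shorter inspiratory limb followed by a longer expiratory
limb); cycle durations are lognormal with a configurable coefficient of
variation, optogenetically induced apnea flattens the trace to the noise
floor, and stimulation windows can rescale amplitude, retarget the mean
cycle length, or inflate the cycle-duration jitter.  Every generated cycle
is recorded in the returned ground truth, so detector and statistic code can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..intervals import IntervalSet
from ..respiration import CycleSeries, PlethTrace

__all__ = ["BreathSimConfig", "gen_pleth_trace"]

#: fraction of the cycle occupied by the inspiratory (rising) limb
_INSPIRATORY_FRACTION = 0.35


@dataclass
class BreathSimConfig:
    """Conditions for one simulated plethysmography recording.

    duration_s
        Recording length, seconds.
    mean_cycle_s
        Mean breath-cycle duration, seconds (mouse resting ~0.3 s, i.e.
        ~3.3 Hz).
    cycle_cv
        Target coefficient of variation (SD/mean) of cycle durations.
    amplitude
        Peak pressure excursion per cycle, arbitrary units (only relative
        changes are meaningful).
    amplitude_scale_during_stim
        Multiplicative amplitude factor applied to cycles whose onset falls
        inside a stimulation interval.
    apnea_intervals
        [start_s, end_s) windows with no breathing: the trace sits at the
        noise floor and no partial cycles are emitted.
    stim_intervals
        [start_s, end_s) photostimulation windows; cycles starting inside
        them use the ``*_during_stim`` overrides.
    cycle_cv_during_stim, mean_cycle_s_during_stim
        Optional CV / mean-cycle overrides inside stimulation windows
        (None = unchanged).
    noise_sd
        Additive white Gaussian noise SD, pressure a.u.
    sample_rate_hz
        Fixed at 1000 (hardware sampling rate).
    """

    duration_s: float = 30.0
    mean_cycle_s: float = 0.3
    cycle_cv: float = 0.1
    amplitude: float = 1.0
    amplitude_scale_during_stim: float = 1.0
    apnea_intervals: list[tuple[float, float]] = field(default_factory=list)
    stim_intervals: list[tuple[float, float]] = field(default_factory=list)
    cycle_cv_during_stim: float | None = None
    mean_cycle_s_during_stim: float | None = None
    noise_sd: float = 0.05
    sample_rate_hz: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.sample_rate_hz != 1000:
            raise ValueError("sample_rate_hz is fixed at 1000")
        if self.mean_cycle_s <= 2.0 / self.sample_rate_hz:
            raise ValueError("mean_cycle_s must exceed two sample periods")
        if self.cycle_cv < 0:
            raise ValueError("cycle_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for start, end in self.apnea_intervals:
            if not (0 <= start < end <= self.duration_s):
                raise ValueError(
                    f"apnea interval [{start}, {end}) outside [0, {self.duration_s})"
                )


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _cycle_waveform(n: int, amplitude: float) -> np.ndarray:
    """Asymmetric raised-cosine pressure pulse over n samples."""
    p = np.arange(n) / n  # phase in [0, 1)
    a = _INSPIRATORY_FRACTION
    wave = np.empty(n)
    rise = p < a
    wave[rise] = 0.5 * (1.0 - np.cos(np.pi * p[rise] / a))
    wave[~rise] = 0.5 * (1.0 + np.cos(np.pi * (p[~rise] - a) / (1.0 - a)))
    return amplitude * wave


def gen_pleth_trace(cfg: BreathSimConfig) -> tuple[PlethTrace, CycleSeries]:
    """Simulate a pressure trace; returns (trace, ground-truth cycles).

    Ground-truth onsets are the exact start times of the rendered cycles;
    a cycle is emitted only if it fits entirely outside every apnea
    interval (no partial cycles), so apnea windows contain no onsets.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz
    n_samples = int(round(cfg.duration_s * fs))
    samples = np.zeros(n_samples)

    apnea = IntervalSet(cfg.apnea_intervals)
    stim = IntervalSet(cfg.stim_intervals)

    onsets: list[float] = []
    durations: list[float] = []
    amplitudes: list[float] = []

    t = 0.0
    while t < cfg.duration_s:
        in_stim = stim.contains(t)
        mean = (
            cfg.mean_cycle_s_during_stim
            if (in_stim and cfg.mean_cycle_s_during_stim is not None)
            else cfg.mean_cycle_s
        )
        cv = (
            cfg.cycle_cv_during_stim
            if (in_stim and cfg.cycle_cv_during_stim is not None)
            else cfg.cycle_cv
        )
        if cv == 0:
            dur = mean
        else:
            mu, sigma = _lognormal_params(mean, cv)
            dur = float(rng.lognormal(mu, sigma))
        dur = max(dur, 2.0 / fs)

        # skip forward past any apnea interval this cycle would touch
        cycle = IntervalSet([(t, t + dur)])
        hit = cycle.intersection(apnea)
        if len(hit) > 0:
            # advance to the end of the first apnea interval intersected
            for a_start, a_end in apnea:
                if a_end > t and a_start < t + dur:
                    t = a_end
                    break
            continue
        if t + dur > cfg.duration_s:
            break  # no partial trailing cycle

        amp = cfg.amplitude * (
            cfg.amplitude_scale_during_stim if in_stim else 1.0
        )
        i0 = int(round(t * fs))
        i1 = int(round((t + dur) * fs))
        samples[i0:i1] = _cycle_waveform(i1 - i0, amp)

        onsets.append(t)
        durations.append(dur)
        amplitudes.append(amp)
        t += dur

    if cfg.noise_sd > 0:
        samples = samples + rng.normal(0.0, cfg.noise_sd, n_samples)

    trace = PlethTrace(samples=samples, sample_rate_hz=fs, t0=0.0)
    truth = CycleSeries(
        onset_times=np.asarray(onsets),
        peak_amplitudes=np.asarray(amplitudes),
        durations=np.asarray(durations),  # true per-cycle durations, one per onset
    )
    return trace, truth
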