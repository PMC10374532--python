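"""Breath-cycle detection and peri-stimulus respiratory statistics.

Works on whole-body plethysmography pressure traces sampled at 1 kHz.  The
detector finds inspiration onsets; downstream statistics are the ones used
to characterize optogenetic respiratory control: windowed breathing
frequency (events per second, well defined at 0 during apnea), the
coefficient of variation of cycle duration (SD/mean, sample SD), and the
percent change in pressure amplitude between pre-stimulation and
stimulation windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import ndimage

from .intervals import IntervalSet

__all__ = [
    "PlethTrace",
    "CycleSeries",
    "PeriStimulusSummary",
    "InsufficientCyclesError",
    "detect_cycles",
    "window_frequency",
    "cycle_cv",
    "amplitude_change_pct",
    "peristimulus_summary",
]


class InsufficientCyclesError(ValueError):
    """Raised when a statistic needs more complete cycles than are present."""


@dataclass
class PlethTrace:
    """A 1-kHz plethysmographic pressure signal.

    samples : pressure in arbitrary units; t0 : time of the first sample.
    """

    samples: np.ndarray
    sample_rate_hz: float = 1000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sample_rate_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "pressure": self.samples})

    @classmethod
    def from_csv(cls, path) -> "PlethTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        rate = 1.0 / np.median(np.diff(t))
        return cls(df["pressure"].to_numpy(), sample_rate_hz=rate, t0=float(t[0]))


@dataclass
class CycleSeries:
    """Detected (or ground-truth) breath cycles.

    onset_times are strictly increasing inspiration-onset times in seconds.
    ``durations``, when not provided, are the inter-onset differences
    (one fewer than onsets); generators may supply per-cycle durations
    explicitly (one per onset) when the final cycle's length is known.
    """

    onset_times: np.ndarray
    peak_amplitudes: np.ndarray | None = None
    durations: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if self.onset_times.size and np.any(np.diff(self.onset_times) <= 0):
            raise ValueError("onset_times must be strictly increasing")
        if self.peak_amplitudes is not None:
            self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.durations is None:
            self.durations = np.diff(self.onset_times)
        else:
            self.durations = np.asarray(self.durations, dtype=float)
            if np.any(self.durations <= 0):
                raise ValueError("durations must be > 0")

    def __len__(self) -> int:
        return len(self.onset_times)

    def onsets_in(self, interval: tuple[float, float]) -> np.ndarray:
        start, end = interval
        mask = (self.onset_times >= start) & (self.onset_times < end)
        return self.onset_times[mask]

    def to_frame(self) -> pd.DataFrame:
        n = len(self.onset_times)
        dur = self.durations
        if len(dur) == n - 1:
            dur = np.append(dur, np.nan)
        amp = (
            self.peak_amplitudes
            if self.peak_amplitudes is not None
            else np.full(n, np.nan)
        )
        return pd.DataFrame(
            {"onset_s": self.onset_times, "duration_s": dur, "amplitude": amp}
        )


@dataclass
class PeriStimulusSummary:
    """Pre/stim/post windowed respiratory statistics around one train."""

    pre: tuple[float, float]
    stim: tuple[float, float]
    post: tuple[float, float]
    frequency_hz: dict[str, float]
    cv: dict[str, float]
    amplitude_change_pct: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, bounds in (("pre", self.pre), ("stim", self.stim), ("post", self.post)):
            rows.append(
                {
                    "window": name,
                    "start_s": bounds[0],
                    "end_s": bounds[1],
                    "frequency_hz": self.frequency_hz[name],
                    "cv": self.cv[name],
                }
            )
        df = pd.DataFrame(rows)
        df["amplitude_change_pct"] = [np.nan, self.amplitude_change_pct, np.nan]
        return df


# ---------------------------------------------------------------------------
# detection

def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float = 10.0) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        return x.astype(float)
    b, a = sps.butter(4, cutoff_hz / nyq)
    return sps.filtfilt(b, a, x)


def _rolling_median(x: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    size = max(3, int(round(window_s * fs)) | 1)  # odd
    return ndimage.median_filter(x, size=size, mode="nearest")


def detect_cycles(
    trace: PlethTrace,
    min_cycle_s: float = 0.1,
    prominence_frac: float = 0.5,
    lowpass_hz: float = 10.0,
    min_prominence: float | None = None,
) -> CycleSeries:
    """Detect inspiration onsets in a pressure trace.

    The signal is low-pass filtered (default 10-Hz cutoff, zero phase) and a
    rolling median is subtracted to remove baseline drift.  Inspiratory
    peaks are found with a prominence threshold of ``prominence_frac`` times
    the interquartile range of the detrended signal, at least ``min_cycle_s``
    apart; each onset is then placed at the inter-peak trough — the minimum
    of the filtered signal between the previous accepted peak and the
    current one — which marks the foot of the inspiratory limb without
    assuming any particular waveform morphology.  A flat or all-noise trace
    yields an empty series; apnea segments (no peak above the prominence
    gate) yield no onsets.

    The prominence gate is scale-free (a fraction of the signal's own IQR),
    so a recording containing nothing but stationary noise can still yield
    pseudo-cycles; supply ``min_prominence`` (absolute pressure units, e.g.
    5x the known sensor noise SD) to suppress them when the noise floor is
    known.
    """
    fs = trace.sample_rate_hz
    if trace.duration_s < 2 * min_cycle_s:
        raise ValueError("trace shorter than two minimum cycles")
    x = _lowpass(trace.samples, fs, lowpass_hz)
    d = x - _rolling_median(x, fs)
    q75, q25 = np.percentile(d, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return CycleSeries(onset_times=np.empty(0), peak_amplitudes=np.empty(0))
    prominence = prominence_frac * iqr
    if min_prominence is not None:
        prominence = max(prominence, min_prominence)
    peaks, _ = sps.find_peaks(
        d,
        prominence=prominence,
        distance=max(1, int(round(min_cycle_s * fs))),
    )
    if len(peaks) == 0:
        return CycleSeries(onset_times=np.empty(0), peak_amplitudes=np.empty(0))

    onsets_idx = []
    kept_peaks = []
    prev_peak = 0
    for pk in peaks:
        seg = x[prev_peak:pk]
        if len(seg) > 0:
            onsets_idx.append(prev_peak + int(np.argmin(seg)))
            kept_peaks.append(pk)
        prev_peak = pk

    if not onsets_idx:
        return CycleSeries(onset_times=np.empty(0), peak_amplitudes=np.empty(0))

    onsets_idx = np.asarray(onsets_idx)
    kept_peaks = np.asarray(kept_peaks)
    # After a silent gap (apnea) the inter-peak minimum can land on a noise
    # dip far from the breathing resumption.  Re-anchor onsets whose
    # foot-to-peak rise is anomalously long to the last low-level crossing
    # (25% of rise height) before the peak.
    rises = kept_peaks - onsets_idx
    med_rise = np.median(rises)
    for k in np.nonzero(rises > 2.5 * med_rise)[0]:
        m, pk = onsets_idx[k], kept_peaks[k]
        thr = x[m] + 0.25 * (x[pk] - x[m])
        below = np.nonzero(x[m:pk] <= thr)[0]
        if len(below):
            onsets_idx[k] = m + below[-1]
    # enforce the minimum inter-onset separation (keep the earlier onset)
    keep = [0]
    min_gap = int(round(min_cycle_s * fs))
    for i in range(1, len(onsets_idx)):
        if onsets_idx[i] - onsets_idx[keep[-1]] >= min_gap:
            keep.append(i)
    onsets_idx = onsets_idx[keep]

    # per-cycle peak-to-trough excursion of the filtered signal
    bounds = np.append(onsets_idx, len(x) - 1)
    amps = np.array(
        [
            float(np.max(x[bounds[i]: bounds[i + 1] + 1]) - np.min(x[bounds[i]: bounds[i + 1] + 1]))
            for i in range(len(onsets_idx))
        ]
    )
    return CycleSeries(
        onset_times=trace.t0 + onsets_idx / fs, peak_amplitudes=amps
    )


# ---------------------------------------------------------------------------
# windowed statistics

def window_frequency(cycles: CycleSeries, interval: tuple[float, float]) -> float:
    """Breathing frequency in Hz: onset count / window length.

    Event counting keeps the statistic well defined at 0 events, matching
    the ~0-Hz frequencies observed under apnea-inducing stimulation.
    """
    start, end = interval
    if end <= start:
        raise ValueError("interval must have positive length")
    return len(cycles.onsets_in(interval)) / (end - start)


def cycle_cv(cycles: CycleSeries, interval: tuple[float, float] | None = None) -> float:
    """Coefficient of variation (sample SD / mean) of cycle durations.

    When an interval is given, only cycles lying completely inside it
    (both bounding onsets within the window) contribute.  Requires at
    least 3 complete durations.
    """
    if interval is None:
        durs = np.diff(cycles.onset_times)
    else:
        onsets = cycles.onsets_in(interval)
        durs = np.diff(onsets)
    if len(durs) < 3:
        raise InsufficientCyclesError(
            f"need >= 3 complete cycle durations, got {len(durs)}"
        )
    return float(np.std(durs, ddof=1) / np.mean(durs))


def _window_amplitude(
    trace: PlethTrace, cycles: CycleSeries, interval: tuple[float, float]
) -> float:
    """Mean peak-to-trough excursion over cycles in the window.

    In windows with no detected cycles (apnea) the pressure amplitude is
    summarized as the 95th percentile of the absolute deviation of the
    low-passed signal from its rolling median.
    """
    start, end = interval
    fs = trace.sample_rate_hz
    mask = (cycles.onset_times >= start) & (cycles.onset_times < end)
    if cycles.peak_amplitudes is not None and np.any(mask):
        return float(np.mean(cycles.peak_amplitudes[mask]))
    i0 = max(0, int(round((start - trace.t0) * fs)))
    i1 = min(len(trace.samples), int(round((end - trace.t0) * fs)))
    seg = _lowpass(trace.samples[i0:i1], fs)
    dev = np.abs(seg - np.median(seg))
    return float(np.percentile(dev, 95))


def amplitude_change_pct(
    trace: PlethTrace,
    pre_interval: tuple[float, float],
    stim_interval: tuple[float, float],
    cycles: CycleSeries | None = None,
) -> float:
    """Percent change of pressure amplitude from pre to stim windows.

    100 * (A_stim - A_pre) / A_pre; negative values indicate suppression.
    """
    if cycles is None:
        cycles = detect_cycles(trace)
    a_pre = _window_amplitude(trace, cycles, pre_interval)
    a_stim = _window_amplitude(trace, cycles, stim_interval)
    if a_pre == 0:
        raise ValueError("pre-window amplitude is zero; percent change undefined")
    return 100.0 * (a_stim - a_pre) / a_pre


def peristimulus_summary(
    trace: PlethTrace,
    train,
    window_s: float = 2.0,
    cycles: CycleSeries | None = None,
    **detect_kwargs,
) -> PeriStimulusSummary:
    """Pre/stim/post respiratory summary around a stimulation train.

    Windows of length ``window_s`` abut the train on both sides; the stim
    window is the train's own extent.  CV entries are NaN when a window
    holds fewer than 3 complete cycles (e.g. apnea).
    """
    pre = (train.start_s - window_s, train.start_s)
    stim = (train.start_s, train.end_s)
    post = (train.end_s, train.end_s + window_s)
    t_lo, t_hi = trace.t0, trace.t0 + trace.duration_s
    if pre[0] < t_lo or post[1] > t_hi:
        raise ValueError(
            f"train must be embedded with >= {window_s} s margin on both sides"
        )
    if cycles is None:
        cycles = detect_cycles(trace, **detect_kwargs)
    freq = {}
    cv = {}
    for name, bounds in (("pre", pre), ("stim", stim), ("post", post)):
        freq[name] = window_frequency(cycles, bounds)
        try:
            cv[name] = cycle_cv(cycles, bounds)
        except InsufficientCyclesError:
            cv[name] = float("nan")
    amp = amplitude_change_pct(trace, pre, stim, cycles=cycles)
    return PeriStimulusSummary(
        pre=pre, stim=stim, post=post,
        frequency_hz=freq, cv=cv, amplitude_change_pct=amp,
    )
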