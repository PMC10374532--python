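"""Video-derived behavioral statistics.

Implements the frame-differencing activity pipeline used in place of a
conventional freezing index: 60-Hz grayscale video is decimated to 20 Hz and
binarized, consecutive binary frames are XOR-compared to count nonmatching
pixels ("activity levels"), a background baseline separates active from
inactive 50-ms frame pairs, and active time is accumulated per onset/offset
time block.  Also implements object-zone exploration scoring (2-cm zones)
and the novel-object discrimination ratio d2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "FrameStack",
    "ActivityTrace",
    "BlockSchedule",
    "ExplorationResult",
    "preprocess_frames",
    "activity_levels",
    "estimate_baseline",
    "active_time_per_block",
    "zone_masks",
    "exploration_time",
    "discrimination_ratio",
]


@dataclass
class FrameStack:
    """Calibrated grayscale (or binary) video: (n_frames, H, W)."""

    frames: np.ndarray
    frame_rate_hz: float
    px_per_cm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, H, W)")
        if self.frame_rate_hz <= 0 or self.px_per_cm <= 0:
            raise ValueError("frame_rate_hz and px_per_cm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ActivityTrace:
    """Nonmatching-pixel counts for consecutive frame pairs.

    counts[t] compares frame t with frame t+1; the pair spans
    [t0 + t*dt, t0 + (t+1)*dt) and is assigned its start time, consistent
    with half-open block bounds.
    """

    counts: np.ndarray
    frame_period_s: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.counts)) * self.frame_period_s


@dataclass
class BlockSchedule:
    """Labeled onset/offset time blocks of a conditioning epoch.

    blocks: list of (label, start_s, end_s) with label in {"onset", "offset"};
    shocks and stimulation trains are carried along for alignment.
    """

    blocks: list[tuple[str, float, float]]
    shocks: list[tuple[float, float]] | None = None
    trains: list | None = None

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, start, end in self.blocks:
            if label not in ("onset", "offset"):
                raise ValueError(f"unknown block label {label!r}")
            if end <= start:
                raise ValueError("block end must exceed start")
            if start < prev_end:
                raise ValueError("blocks must be disjoint and ordered")
            prev_end = end

    def onset_blocks(self) -> list[tuple[float, float]]:
        return [(s, e) for lab, s, e in self.blocks if lab == "onset"]

    def offset_blocks(self) -> list[tuple[float, float]]:
        return [(s, e) for lab, s, e in self.blocks if lab == "offset"]

    def to_dict(self) -> dict:
        return {
            "blocks": [list(b) for b in self.blocks],
            "shocks": [list(s) for s in (self.shocks or [])],
            "trains": [
                {
                    "mode": t.mode,
                    "pulse_on_ms": t.pulse_on_ms,
                    "pulse_off_ms": t.pulse_off_ms,
                    "n_pulses": t.n_pulses,
                    "start_s": t.start_s,
                }
                for t in (self.trains or [])
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockSchedule":
        from .stimulation import StimulusTrain

        return cls(
            blocks=[tuple(b) for b in d["blocks"]],
            shocks=[tuple(s) for s in d.get("shocks", [])] or None,
            trains=[StimulusTrain(**t) for t in d.get("trains", [])] or None,
        )


@dataclass
class ExplorationResult:
    """Per-object exploration seconds plus the discrimination ratio d2."""

    seconds: dict[str, float]
    d2: float | None = None
    n_missing_frames: int = 0


# ---------------------------------------------------------------------------
# activity pipeline

def preprocess_frames(
    stack: FrameStack,
    target_rate_hz: float = 20.0,
    gray_threshold: float = 128.0,
) -> FrameStack:
    """Decimate to the target frame rate and binarize at a gray threshold.

    The 60->20 Hz conversion keeps every k-th frame (no averaging, which
    would blur motion and change the XOR counts); pixels strictly above
    ``gray_threshold`` become foreground.
    """
    ratio = stack.frame_rate_hz / target_rate_hz
    k = round(ratio)
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"frame rate {stack.frame_rate_hz} not divisible by target {target_rate_hz}"
        )
    frames = stack.frames[::k]
    binary = frames > gray_threshold
    return FrameStack(binary, frame_rate_hz=target_rate_hz, px_per_cm=stack.px_per_cm)


def activity_levels(binary_stack: FrameStack) -> ActivityTrace:
    """Nonmatching-pixel counts between each frame and its one-back frame."""
    frames = binary_stack.frames
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if frames.dtype != bool:
        frames = frames.astype(bool)
    counts = np.count_nonzero(frames[1:] ^ frames[:-1], axis=(1, 2))
    return ActivityTrace(counts, frame_period_s=1.0 / binary_stack.frame_rate_hz)


def estimate_baseline(background: ActivityTrace | FrameStack, q: float = 95.0) -> float:
    """Image-background activity baseline from an animal-free (or frozen)
    reference segment: the ``q``-th percentile of its nonmatching-pixel
    counts.  A high quantile of background noise is conservative: frame
    pairs are only called active when they exceed essentially all
    noise-driven counts.
    """
    if isinstance(background, FrameStack):
        background = activity_levels(background)
    if len(background.counts) == 0:
        raise ValueError("background trace is empty")
    return float(np.percentile(background.counts, q))


def active_time_per_block(
    trace: ActivityTrace,
    baseline: float,
    schedule: BlockSchedule,
) -> pd.DataFrame:
    """Active seconds (and percent of block) per scheduled time block.

    A 50-ms frame pair is active when its count strictly exceeds the
    baseline; active time is the number of active pairs times the frame
    period, bounded by the block duration.
    """
    times = trace.times
    rows = []
    for label, start, end in schedule.blocks:
        in_block = (times >= start) & (times < end)
        n_pairs = int(np.count_nonzero(in_block))
        if n_pairs == 0:
            raise ValueError(f"block [{start}, {end}) contains no frame pairs")
        active = np.count_nonzero(trace.counts[in_block] > baseline)
        active_s = min(active * trace.frame_period_s, end - start)
        rows.append(
            {
                "label": label,
                "start_s": start,
                "end_s": end,
                "active_s": active_s,
                "active_pct": 100.0 * active_s / (end - start),
                "mean_excess": float(
                    np.mean(np.maximum(trace.counts[in_block] - baseline, 0))
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# object exploration

def zone_masks(
    arena_shape_px: tuple[int, int],
    object_positions_cm: list[tuple[float, float]],
    px_per_cm: float,
    margin_cm: float = 2.0,
    object_radius_cm: float = 0.0,
) -> list[np.ndarray]:
    """Per-object exploration-zone masks.

    A zone is every pixel within ``object_radius_cm + margin_cm`` of the
    object's center (i.e. the object footprint dilated by the 2-cm
    proximity criterion).  Positions are (x, y) in cm with the origin at
    the top-left corner; masks are (H, W) boolean with row = y, col = x.
    """
    h, w = arena_shape_px
    rr, cc = np.mgrid[0:h, 0:w]
    masks = []
    radius_px = (object_radius_cm + margin_cm) * px_per_cm
    for x_cm, y_cm in object_positions_cm:
        col = x_cm * px_per_cm
        row = y_cm * px_per_cm
        if not (0 <= col < w and 0 <= row < h):
            raise ValueError(f"object at ({x_cm}, {y_cm}) cm lies outside the arena")
        masks.append((rr - row) ** 2 + (cc - col) ** 2 <= radius_px**2)
    return masks


def _blob_centroids(binary_stack: FrameStack) -> np.ndarray:
    """Centroid (row, col) of the largest foreground component per frame;
    NaN rows where no component exists."""
    out = np.full((binary_stack.n_frames, 2), np.nan)
    for i, frame in enumerate(binary_stack.frames):
        lab = measure.label(frame.astype(bool))
        if lab.max() == 0:
            continue
        props = measure.regionprops(lab)
        biggest = max(props, key=lambda p: p.area)
        out[i] = biggest.centroid
    return out


def exploration_time(
    positions_or_stack: np.ndarray | FrameStack,
    masks: list[np.ndarray],
    frame_rate_hz: float | None = None,
) -> ExplorationResult:
    """Per-object exploration seconds from per-frame animal positions.

    Accepts either an (n, 2) array of (row, col) pixel positions or a
    binary FrameStack, from which the reference point is the centroid of
    the largest foreground component (nose-directed orientation is not
    recoverable from a binary blob; the centroid is an approximation).
    Frames with no detectable blob are excluded and counted.
    """
    if isinstance(positions_or_stack, FrameStack):
        if frame_rate_hz is None:
            frame_rate_hz = positions_or_stack.frame_rate_hz
        positions = _blob_centroids(positions_or_stack)
    else:
        positions = np.asarray(positions_or_stack, dtype=float)
        if frame_rate_hz is None:
            raise ValueError("frame_rate_hz required with raw positions")
    valid = ~np.any(np.isnan(positions), axis=1)
    n_missing = int(np.count_nonzero(~valid))
    rows = np.clip(np.round(positions[valid, 0]).astype(int), 0, masks[0].shape[0] - 1)
    cols = np.clip(np.round(positions[valid, 1]).astype(int), 0, masks[0].shape[1] - 1)
    seconds = {}
    for i, mask in enumerate(masks):
        inside = mask[rows, cols]
        seconds[f"object_{i}"] = float(np.count_nonzero(inside) / frame_rate_hz)
    return ExplorationResult(seconds=seconds, n_missing_frames=n_missing)


def discrimination_ratio(novel_s: float, familiar_s: float) -> float:
    """Novel-object discrimination ratio d2 in [-1, 1].

    d2 = (novel - familiar) / (novel + familiar); values above zero
    indicate novelty preference.
    """
    if novel_s < 0 or familiar_s < 0:
        raise ValueError("exploration times must be >= 0")
    total = novel_s + familiar_s
    if total == 0:
        raise ValueError("both exploration times are zero; d2 undefined")
    return (novel_s - familiar_s) / total
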