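"""Conditioning-session block schedules.

One 5-min epoch alternates offset time blocks (randomized 30-50 s) with
four 20-s onset time blocks (tone/light cues).  A 2-s footshock follows
each onset block after a 2-3 s trace interval, and, when photostimulation
is enabled, two 4-s trains follow each onset block with the first train's
extent covering the shock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..behavior import BlockSchedule
from ..stimulation import StimulusTrain, build_train

__all__ = ["SessionSimConfig", "gen_session_schedule"]

_TRAIN_PARAMS = {
    "flat": dict(mode="flat"),
    "10hz": dict(mode="pulsed", pulse_on_ms=12.5, pulse_off_ms=87.5),
    "4hz": dict(mode="pulsed", pulse_on_ms=162.5, pulse_off_ms=87.5),
}


@dataclass
class SessionSimConfig:
    """Conditioning-epoch schedule parameters (defaults follow the
    standard paradigm: four 20-s onset blocks alternating with 30-50-s
    offset intervals within a 5-min epoch, 2-s shocks 2-3 s after each
    onset block)."""

    epoch_duration_s: float = 300.0
    n_onset_blocks: int = 4
    onset_block_s: float = 20.0
    offset_interval_range_s: tuple[float, float] = (30.0, 50.0)
    shock_duration_s: float = 2.0
    trace_interval_s: tuple[float, float] = (2.0, 3.0)
    stim_mode: str = "none"  # {"flat", "10hz", "4hz", "none"}
    stim_train_s: float = 4.0
    with_shocks: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stim_mode not in ("flat", "10hz", "4hz", "none"):
            raise ValueError(f"unknown stim_mode {self.stim_mode!r}")
        lo, hi = self.offset_interval_range_s
        if not (0 < lo <= hi):
            raise ValueError("offset interval range must satisfy 0 < lo <= hi")
        if self.n_onset_blocks < 1 or self.onset_block_s <= 0:
            raise ValueError("need >= 1 onset block of positive length")
        # worst case must fit inside the epoch
        worst = self.n_onset_blocks * (self.onset_block_s + hi)
        if worst > self.epoch_duration_s:
            raise ValueError(
                f"{self.n_onset_blocks} blocks of {self.onset_block_s} s with "
                f"offsets up to {hi} s cannot fit in {self.epoch_duration_s} s"
            )


def gen_session_schedule(cfg: SessionSimConfig) -> BlockSchedule:
    """Draw one epoch's schedule; deterministic under a fixed seed.

    Layout per repetition: offset block (uniform 30-50 s), then a 20-s
    onset block, then (optionally) a shock starting 2-3 s after the onset
    block ends.  With stimulation enabled, two trains follow each onset
    block; the first starts 1 s before the shock so its 4-s extent covers
    the 2-s shock interval, and the second follows immediately after.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.offset_interval_range_s
    blocks: list[tuple[str, float, float]] = []
    shocks: list[tuple[float, float]] = []
    trains: list[StimulusTrain] = []

    t = 0.0
    for _ in range(cfg.n_onset_blocks):
        off = float(rng.uniform(lo, hi))
        blocks.append(("offset", t, t + off))
        t += off
        blocks.append(("onset", t, t + cfg.onset_block_s))
        t += cfg.onset_block_s
        trace = float(rng.uniform(*cfg.trace_interval_s))
        shock = (t + trace, t + trace + cfg.shock_duration_s)
        if cfg.with_shocks:
            shocks.append(shock)
        if cfg.stim_mode != "none":
            params = _TRAIN_PARAMS[cfg.stim_mode]
            # first train covers the shock: center the 2-s shock in the 4-s train
            lead = (cfg.stim_train_s - cfg.shock_duration_s) / 2.0
            t1 = build_train(duration_s=cfg.stim_train_s, start_s=shock[0] - lead, **params)
            t2 = build_train(duration_s=cfg.stim_train_s, start_s=t1.end_s, **params)
            trains.extend([t1, t2])
    if t > cfg.epoch_duration_s:
        raise ValueError("drawn schedule exceeds the epoch duration")
    # trailing offset time up to the end of the epoch
    if t < cfg.epoch_duration_s:
        blocks.append(("offset", t, cfg.epoch_duration_s))
    return BlockSchedule(blocks=blocks, shocks=shocks or None, trains=trains or None)
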