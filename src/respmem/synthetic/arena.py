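"""Synthetic open-field / conditioning-box video with ground truth.

Renders a 60-Hz grayscale image stack of a single animal as a filled disk
with a soft (Gaussian-like) edge moving over a uniform background.  The
animal either holds still ("frozen") or takes a fixed-length step in a
random direction each frame, driven by a per-frame activity profile;
object positions define exploration zones.  Ground truth records the blob
centroid, the moved/frozen flag, and per-object in-zone membership for
every frame, so activity and exploration estimators can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..behavior import FrameStack

__all__ = ["ArenaSimConfig", "BehaviorGroundTruth", "gen_behavior_video"]


@dataclass
class ArenaSimConfig:
    """Conditions for one simulated arena recording.

    arena_size_cm : (width, height) of the floor seen by the camera.
    px_per_cm : camera calibration.
    frame_rate_hz : fixed 60 (camera hardware).
    blob_diameter_cm : apparent animal size.
    move_step_cm : displacement per active frame.
    activity_profile : scalar movement probability, or a per-frame array of
        booleans / probabilities (length = duration_s * 60).
    object_positions_cm : (x, y) object centers; zone membership uses
        ``zone_margin_cm`` (the 2-cm proximity criterion).
    trajectory_cm : optional scripted (n_frames, 2) path in cm overriding
        the random walk (activity then follows from actual displacement).
    background_gray / blob_gray : rendering contrast, gray levels 0-255.
    noise_sd : additive Gaussian pixel noise SD, gray levels.
    """

    arena_size_cm: tuple[float, float] = (27.5, 39.5)
    px_per_cm: float = 4.0
    frame_rate_hz: float = 60.0
    duration_s: float = 10.0
    blob_diameter_cm: float = 6.0
    move_step_cm: float = 0.5
    activity_profile: float | np.ndarray = 0.5
    object_positions_cm: list[tuple[float, float]] = field(default_factory=list)
    zone_margin_cm: float = 2.0
    trajectory_cm: np.ndarray | None = None
    background_gray: float = 60.0
    blob_gray: float = 200.0
    edge_softness_px: float = 1.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz != 60:
            raise ValueError("frame_rate_hz is fixed at 60")
        w, h = self.arena_size_cm
        if self.blob_diameter_cm >= min(w, h):
            raise ValueError("blob must fit inside the arena")
        for x, y in self.object_positions_cm:
            if not (0 <= x <= w and 0 <= y <= h):
                raise ValueError(f"object at ({x}, {y}) cm outside the arena")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def frame_shape(self) -> tuple[int, int]:
        w, h = self.arena_size_cm
        return (int(round(h * self.px_per_cm)), int(round(w * self.px_per_cm)))


@dataclass
class BehaviorGroundTruth:
    """Per-frame truth for one simulated video."""

    centroids_px: np.ndarray  # (n_frames, 2) as (row, col)
    centroids_cm: np.ndarray  # (n_frames, 2) as (x, y)
    moved: np.ndarray  # (n_frames,) bool; frame 0 is False
    in_zone: list[np.ndarray]  # per object, (n_frames,) bool
    frame_rate_hz: float

    @property
    def active_fraction(self) -> float:
        return float(np.mean(self.moved[1:])) if len(self.moved) > 1 else 0.0

    def exploration_s(self, obj: int) -> float:
        """Ground-truth exploration time: 1/rate x in-zone frame count."""
        return float(np.count_nonzero(self.in_zone[obj]) / self.frame_rate_hz)


def _resolve_profile(cfg: ArenaSimConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_frames
    prof = cfg.activity_profile
    if np.isscalar(prof):
        return rng.random(n) < float(prof)
    prof = np.asarray(prof)
    if len(prof) != n:
        raise ValueError(f"activity_profile length {len(prof)} != n_frames {n}")
    if prof.dtype == bool:
        return prof.copy()
    return rng.random(n) < prof


def _render_frame(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    radius_px: float,
    cfg: ArenaSimConfig,
) -> np.ndarray:
    h, w = shape
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    dist = np.sqrt((rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2)
    # soft-edged disk: 1 inside, 0 outside, linear ramp over the edge width
    alpha = np.clip((radius_px - dist) / max(cfg.edge_softness_px, 1e-6) + 0.5, 0.0, 1.0)
    return cfg.background_gray + (cfg.blob_gray - cfg.background_gray) * alpha


def gen_behavior_video(cfg: ArenaSimConfig) -> tuple[FrameStack, BehaviorGroundTruth]:
    """Simulate an arena video; returns (stack, ground truth).

    The animal performs a reflected random walk: on active frames it steps
    ``move_step_cm`` in a uniformly random direction, staying at least one
    blob radius away from the walls; on frozen frames it does not move.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    w_cm, h_cm = cfg.arena_size_cm
    r_cm = cfg.blob_diameter_cm / 2.0
    shape = cfg.frame_shape

    if cfg.trajectory_cm is not None:
        path = np.asarray(cfg.trajectory_cm, dtype=float)
        if path.shape != (n, 2):
            raise ValueError(f"trajectory_cm must be ({n}, 2)")
        moved = np.zeros(n, dtype=bool)
        moved[1:] = np.any(path[1:] != path[:-1], axis=1)
    else:
        active = _resolve_profile(cfg, rng)
        path = np.empty((n, 2))
        pos = np.array([w_cm / 2.0, h_cm / 2.0])
        moved = np.zeros(n, dtype=bool)
        for i in range(n):
            if i > 0 and active[i]:
                theta = rng.uniform(0, 2 * np.pi)
                step = cfg.move_step_cm * np.array([np.cos(theta), np.sin(theta)])
                cand = pos + step
                # reflect off walls keeping the blob inside the arena
                cand[0] = np.clip(cand[0], r_cm, w_cm - r_cm)
                cand[1] = np.clip(cand[1], r_cm, h_cm - r_cm)
                moved[i] = bool(np.any(cand != pos))
                pos = cand
            path[i] = pos

    radius_px = r_cm * cfg.px_per_cm
    frames = np.empty((n,) + shape, dtype=np.uint8)
    for i in range(n):
        x_cm, y_cm = path[i]
        img = _render_frame(shape, (y_cm * cfg.px_per_cm, x_cm * cfg.px_per_cm), radius_px, cfg)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    centroids_px = np.column_stack(
        [path[:, 1] * cfg.px_per_cm, path[:, 0] * cfg.px_per_cm]
    )
    in_zone = []
    for ox, oy in cfg.object_positions_cm:
        d = np.sqrt((path[:, 0] - ox) ** 2 + (path[:, 1] - oy) ** 2)
        in_zone.append(d <= cfg.zone_margin_cm)

    stack = FrameStack(frames, frame_rate_hz=cfg.frame_rate_hz, px_per_cm=cfg.px_per_cm)
    truth = BehaviorGroundTruth(
        centroids_px=centroids_px,
        centroids_cm=path,
        moved=moved,
        in_zone=in_zone,
        frame_rate_hz=cfg.frame_rate_hz,
    )
    return stack, truth
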