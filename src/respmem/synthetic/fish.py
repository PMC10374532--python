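"""Synthetic catFISH fluorescence fields with per-cell ground truth.

Emulates single-plane DAPI + Cy5 + Cy3 micrographs of a hippocampal region:
neuronal nuclei (~10 um, diffusely textured DAPI) and non-neuronal nuclei
(~5 um, intensely bright and uniform DAPI) are placed without overlap by
dart throwing; immediate-early-gene transcript signal is rendered inside the
nucleus for nuclear-positive cells and as a perinuclear ring for
cytoplasmic-positive cells.  The two positivity indicators per cell are
drawn from a Gaussian-copula threshold model whose correlation parameter
interpolates smoothly between independence (0) and identity (1), so true
marginal and joint positivity rates are controllable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["CatfishSimConfig", "ChannelStack", "PlacementError", "gen_catfish_image"]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap; reports the
    density achieved before giving up."""


@dataclass
class ChannelStack:
    """A registered multi-channel fluorescence field (DAPI, Cy5, Cy3)."""

    dapi: np.ndarray
    cy5: np.ndarray
    cy3: np.ndarray
    px_per_um: float

    def __post_init__(self) -> None:
        if not (self.dapi.shape == self.cy5.shape == self.cy3.shape):
            raise ValueError("channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape

    def as_array(self) -> np.ndarray:
        """(3, H, W) stack in channel order DAPI, Cy5, Cy3."""
        return np.stack([self.dapi, self.cy5, self.cy3])


@dataclass
class CatfishSimConfig:
    """Conditions for one simulated catFISH field.

    px_per_um defaults to 1/0.83 (0.83 x 0.83 um2 confocal pixels).
    p_cyt / p_nuc are the marginal positivity probabilities of the two
    compartments of the assayed pair; joint_dependence in [-1, 1] is the
    Gaussian-copula correlation between them (0 = independent, 1 = the
    positive sets coincide when the marginals are equal).

    pair_mode selects what the two indicators mean:
    ``"cyt_nuc"`` — cytoplasmic vs nuclear signal of one gene in Cy5
    (the Arc-style assay); ``"nuc_nuc"`` — nuclear signal of two genes,
    the first in Cy3 and the second in Cy5 (the H1a/Fos-style assay).
    """

    field_size_px: tuple[int, int] = (768, 768)
    px_per_um: float = 1.0 / 0.83
    n_neuronal: int = 150
    n_nonneuronal: int = 20
    neuronal_diameter_um: float = 10.0
    neuronal_diameter_jitter_um: float = 1.0
    nonneuronal_diameter_um: float = 5.0
    nonneuronal_brightness_factor: float = 2.5
    p_cyt: float = 0.3
    p_nuc: float = 0.3
    joint_dependence: float = 0.0
    pair_mode: str = "cyt_nuc"
    dapi_level: float = 100.0
    dapi_texture_cv: float = 0.30
    signal_level: float = 100.0
    ring_width_um: float = 2.5
    channel_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_cyt <= 1 and 0 <= self.p_nuc <= 1):
            raise ValueError("positivity probabilities must lie in [0, 1]")
        if not -1 <= self.joint_dependence <= 1:
            raise ValueError("joint_dependence must lie in [-1, 1]")
        if self.pair_mode not in ("cyt_nuc", "nuc_nuc"):
            raise ValueError(f"unknown pair_mode {self.pair_mode!r}")
        if self.n_neuronal < 0 or self.n_nonneuronal < 0:
            raise ValueError("cell counts must be >= 0")


def _place_nuclei(
    cfg: CatfishSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dart-throw non-overlapping centers; returns (rows, cols, radii_px)."""
    h, w = cfg.field_size_px
    n_total = cfg.n_neuronal + cfg.n_nonneuronal
    radii_um = np.concatenate(
        [
            np.maximum(
                cfg.neuronal_diameter_um
                + rng.normal(0, cfg.neuronal_diameter_jitter_um, cfg.n_neuronal),
                4.0,
            )
            / 2.0,
            np.full(cfg.n_nonneuronal, cfg.nonneuronal_diameter_um / 2.0),
        ]
    )
    radii_px = radii_um * cfg.px_per_um
    # largest first improves packing success
    order = np.argsort(-radii_px, kind="stable")
    rows = np.empty(n_total)
    cols = np.empty(n_total)
    placed_r: list[float] = []
    placed_c: list[float] = []
    placed_rad: list[float] = []
    max_attempts = 400 * max(n_total, 1)
    attempts = 0
    # shells must be attributable to single cells: keep centers separated by
    # the sum of radii plus a 2-px margin
    for k, idx in enumerate(order):
        rad = radii_px[idx]
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"placed only {k}/{n_total} nuclei in a {h}x{w} field "
                    f"(achieved density {k / (h * w):.2e} per px^2)"
                )
            r = rng.uniform(rad + 1, h - rad - 1)
            c = rng.uniform(rad + 1, w - rad - 1)
            ok = True
            for pr, pc, prad in zip(placed_r, placed_c, placed_rad):
                if (r - pr) ** 2 + (c - pc) ** 2 < (rad + prad + 2.0) ** 2:
                    ok = False
                    break
            if ok:
                break
        rows[idx], cols[idx] = r, c
        placed_r.append(r)
        placed_c.append(c)
        placed_rad.append(rad)
    return rows, cols, radii_px


def _copula_pair(
    n: int, p_a: float, p_b: float, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated Bernoulli pair via a Gaussian-copula threshold model."""
    z1 = rng.standard_normal(n)
    w = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * w
    a = z1 <= norm.ppf(p_a) if p_a > 0 else np.zeros(n, dtype=bool)
    b = z2 <= norm.ppf(p_b) if p_b > 0 else np.zeros(n, dtype=bool)
    return a, b


def _soft_disk(dist: np.ndarray, radius: float, softness: float = 0.7) -> np.ndarray:
    return np.clip((radius - dist) / softness + 0.5, 0.0, 1.0)


def gen_catfish_image(cfg: CatfishSimConfig) -> tuple[ChannelStack, pd.DataFrame]:
    """Simulate one catFISH field; returns (channels, per-cell ground truth).

    The ground-truth table has one row per cell: center (row, col),
    diameter_um, neuronal flag, and the two positivity indicators
    ``pos_a`` / ``pos_b`` (cytoplasmic / nuclear for ``cyt_nuc`` mode,
    Cy3-nuclear / Cy5-nuclear for ``nuc_nuc`` mode).  Non-neuronal cells
    never carry transcript signal.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.field_size_px
    rows, cols, radii_px = _place_nuclei(cfg, rng)
    n_total = cfg.n_neuronal + cfg.n_nonneuronal
    neuronal = np.zeros(n_total, dtype=bool)
    neuronal[: cfg.n_neuronal] = True

    pos_a = np.zeros(n_total, dtype=bool)
    pos_b = np.zeros(n_total, dtype=bool)
    a, b = _copula_pair(
        cfg.n_neuronal, cfg.p_cyt, cfg.p_nuc, cfg.joint_dependence, rng
    )
    pos_a[: cfg.n_neuronal] = a
    pos_b[: cfg.n_neuronal] = b

    dapi = np.zeros((h, w))
    cy5 = np.zeros((h, w))
    cy3 = np.zeros((h, w))
    ring_px = cfg.ring_width_um * cfg.px_per_um

    for i in range(n_total):
        rad = radii_px[i]
        r0 = int(max(0, np.floor(rows[i] - rad - ring_px - 3)))
        r1 = int(min(h, np.ceil(rows[i] + rad + ring_px + 4)))
        c0 = int(max(0, np.floor(cols[i] - rad - ring_px - 3)))
        c1 = int(min(w, np.ceil(cols[i] + rad + ring_px + 4)))
        rr = np.arange(r0, r1)[:, None]
        cc = np.arange(c0, c1)[None, :]
        dist = np.sqrt((rr - rows[i]) ** 2 + (cc - cols[i]) ** 2)
        disk = _soft_disk(dist, rad)

        if neuronal[i]:
            # large, diffusely stained: multiplicative speckle texture
            texture = np.clip(
                1.0 + cfg.dapi_texture_cv * rng.standard_normal(disk.shape), 0.05, None
            )
            dapi[r0:r1, c0:c1] += cfg.dapi_level * disk * texture
        else:
            # small, intensely bright, uniform
            dapi[r0:r1, c0:c1] += (
                cfg.dapi_level * cfg.nonneuronal_brightness_factor * disk
            )

        if not neuronal[i]:
            continue
        # transcript signal: nucleus interior for "nuclear", perinuclear
        # ring for "cytoplasmic"
        nuc_fill = _soft_disk(dist, rad - 1.0)
        ring = _soft_disk(dist, rad + ring_px) - _soft_disk(dist, rad + 0.5)
        ring = np.clip(ring, 0.0, 1.0)
        if cfg.pair_mode == "cyt_nuc":
            if pos_b[i]:
                cy5[r0:r1, c0:c1] += cfg.signal_level * nuc_fill
            if pos_a[i]:
                cy5[r0:r1, c0:c1] += cfg.signal_level * ring
        else:  # nuc_nuc: A in Cy3, B in Cy5, both nuclear
            if pos_a[i]:
                cy3[r0:r1, c0:c1] += cfg.signal_level * nuc_fill
            if pos_b[i]:
                cy5[r0:r1, c0:c1] += cfg.signal_level * nuc_fill

    if cfg.channel_noise_sd > 0:
        for img in (dapi, cy5, cy3):
            img += rng.normal(0.0, cfg.channel_noise_sd, (h, w))
    np.clip(dapi, 0, None, out=dapi)
    np.clip(cy5, 0, None, out=cy5)
    np.clip(cy3, 0, None, out=cy3)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(n_total),
            "row": rows,
            "col": cols,
            "diameter_um": 2 * radii_px / cfg.px_per_um,
            "neuronal": neuronal,
            "pos_a": pos_a,
            "pos_b": pos_b,
        }
    )
    stack = ChannelStack(dapi=dapi, cy5=cy5, cy3=cy3, px_per_um=cfg.px_per_um)
    return stack, truth
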