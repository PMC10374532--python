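"""catFISH image quantification.

The compartment analysis of temporal activity by FISH timestamps a neuron's
activation to one of two behavioral epochs ~20 min apart: a transcription
burst at the recent epoch leaves intranuclear transcript foci, while a burst
at the earlier epoch leaves transcript that has been exported to the
perinuclear cytoplasm.  This module segments DAPI nuclei, excludes
non-neuron-like nuclei (small, intensely bright, uniform DAPI), builds
perinuclear shell zones by morphological dilation, calls per-cell
nuclear/cytoplasmic positivity per channel, and summarizes region-level
ensemble percentages with real vs chance coexpression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure, morphology, segmentation

__all__ = [
    "NucleusSet",
    "EnsembleSummary",
    "segment_nuclei",
    "filter_nonneuronal",
    "shell_zones",
    "call_expression",
    "build_cell_table",
    "chance_coexpression",
    "summarize_ensembles",
    "ensemble_delta",
]


@dataclass
class NucleusSet:
    """Segmented nuclei: a label image plus a per-nucleus feature table.

    The table has one row per nucleus: label, centroid (row, col),
    equivalent diameter in um, mean DAPI intensity, intensity uniformity
    (within-mask SD/mean), and a ``neuronal`` flag (True until
    ``filter_nonneuronal`` marks exclusions).
    """

    labels: np.ndarray
    table: pd.DataFrame
    px_per_um: float

    def __len__(self) -> int:
        return len(self.table)

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["neuronal"]]

    def retained_labels(self) -> np.ndarray:
        """Label image keeping only neuron-like nuclei."""
        keep = set(self.retained["label"].tolist())
        out = self.labels.copy()
        mask = np.isin(out, list(keep))
        out[~mask] = 0
        return out


@dataclass
class EnsembleSummary:
    """Region-level ensemble percentages for one IEG pair.

    ``pct_a``/``pct_b`` are the marginal positive-cell percentages of the
    two compartments (cytoplasmic and nuclear for the Arc-style assay);
    real coexpression is the observed double-positive percentage, chance
    the independence product of the marginals.
    """

    n_cells: int
    n_sections: int
    pct_a: float
    pct_b: float
    pct_coexp_real: float
    pct_coexp_chance: float
    pair: tuple[str, str] = ("cyt", "nuc")

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_sections": self.n_sections,
            f"pct_{self.pair[0]}": self.pct_a,
            f"pct_{self.pair[1]}": self.pct_b,
            "pct_coexp_real": self.pct_coexp_real,
            "pct_coexp_chance": self.pct_coexp_chance,
        }


# ---------------------------------------------------------------------------
# segmentation

def segment_nuclei(
    dapi: np.ndarray,
    px_per_um: float,
    min_diameter_um: float = 3.0,
    smooth_sigma: float = 1.0,
) -> NucleusSet:
    """Segment DAPI-stained nuclei.

    Gaussian smoothing, Otsu threshold, hole filling, a minimum-size gate
    (equivalent diameter >= ``min_diameter_um``), then a distance-transform
    watershed to split touching nuclei.  Consistent criteria should be used
    across comparable images: pass the same parameters for every field of
    one experiment.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("dapi must be a single-channel 2-D image")
    smoothed = filters.gaussian(dapi, sigma=smooth_sigma, preserve_range=True)
    if smoothed.max() <= smoothed.min():
        return NucleusSet(
            labels=np.zeros(dapi.shape, dtype=int),
            table=_empty_table(),
            px_per_um=px_per_um,
        )
    thr = filters.threshold_otsu(smoothed)
    mask = smoothed > thr
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return NucleusSet(
            labels=np.zeros(dapi.shape, dtype=int),
            table=_empty_table(),
            px_per_um=px_per_um,
        )

    # split touching nuclei on the distance transform
    dist = ndimage.distance_transform_edt(mask)
    dist_sm = filters.gaussian(dist, sigma=1.0, preserve_range=True)
    # marker separation scaled to the typical nucleus radius in the field
    typical_radius = max(3, int(round(np.percentile(dist[mask], 90))))
    coords = feature.peak_local_max(
        dist_sm,
        min_distance=typical_radius,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = segmentation.watershed(-dist_sm, markers, mask=mask)

    # intensity features on an eroded core so the segmentation's soft-edge
    # skirt does not inflate the within-nucleus variation
    core = _core_labels(labels)
    rows = []
    for prop in measure.regionprops(labels, intensity_image=dapi):
        vals = dapi[core == prop.label]
        if vals.size == 0:
            vals = dapi[labels == prop.label]
        mean = float(vals.mean())
        rows.append(
            {
                "label": prop.label,
                "row": prop.centroid[0],
                "col": prop.centroid[1],
                "area_px": prop.area,
                "diameter_um": prop.equivalent_diameter_area / px_per_um,
                "mean_dapi": mean,
                "uniformity": float(vals.std() / mean) if mean > 0 else np.nan,
                "neuronal": True,
            }
        )
    table = pd.DataFrame(rows) if rows else _empty_table()
    # the size gate above works on raw areas; re-apply on equivalent diameter
    if len(table):
        table = table[table["diameter_um"] >= min_diameter_um].reset_index(drop=True)
        keep = set(table["label"].tolist())
        labels = np.where(np.isin(labels, list(keep)), labels, 0)
    return NucleusSet(labels=labels, table=table, px_per_um=px_per_um)


def _core_labels(labels: np.ndarray, erosion_px: int = 2) -> np.ndarray:
    """Label image eroded by ``erosion_px`` so measurements avoid the
    threshold-dependent boundary band of each nucleus."""
    if erosion_px <= 0:
        return labels
    eroded = ndimage.binary_erosion(
        labels > 0, structure=morphology.disk(erosion_px)
    )
    return np.where(eroded, labels, 0)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "label", "row", "col", "area_px", "diameter_um",
            "mean_dapi", "uniformity", "neuronal",
        ]
    )


def filter_nonneuronal(
    nuclei: NucleusSet,
    diameter_cut_um: float = 7.0,
    brightness_z: float = 2.0,
    uniformity_cut: float = 0.15,
) -> NucleusSet:
    """Flag non-neuron-like nuclei (small AND bright AND uniform).

    A nucleus is excluded only when all three hold: equivalent diameter
    below ``diameter_cut_um``, mean DAPI at least ``brightness_z`` robust
    z-scores above the field median, and within-mask SD/mean at most
    ``uniformity_cut``.  Large, diffusely stained (neuron-like) nuclei are
    retained.  Returns a new NucleusSet with updated ``neuronal`` flags.
    """
    table = nuclei.table.copy()
    if len(table) == 0:
        return NucleusSet(nuclei.labels.copy(), table, nuclei.px_per_um)
    med = table["mean_dapi"].median()
    mad = np.median(np.abs(table["mean_dapi"] - med))
    scale = 1.4826 * mad if mad > 0 else table["mean_dapi"].std() or 1.0
    z = (table["mean_dapi"] - med) / scale
    small = table["diameter_um"] < diameter_cut_um
    bright = z >= brightness_z
    uniform = table["uniformity"] <= uniformity_cut
    table["neuronal"] = ~(small & bright & uniform)
    return NucleusSet(nuclei.labels.copy(), table, nuclei.px_per_um)


def shell_zones(nuclei: NucleusSet, dilation_radius_px: int = 3) -> np.ndarray:
    """Perinuclear shell label image.

    Each retained nucleus is dilated by ``dilation_radius_px`` and its own
    mask subtracted; competing shell pixels go to the nearest nucleus
    boundary, so shells never overlap each other or any nucleus.  Returns
    an (H, W) int image whose value is the owning nucleus label (0 =
    no shell).  Radius 0 yields empty shells.
    """
    if dilation_radius_px < 0:
        raise ValueError("dilation_radius_px must be >= 0")
    base = nuclei.retained_labels()
    if dilation_radius_px == 0:
        return np.zeros_like(base)
    expanded = segmentation.expand_labels(base, distance=dilation_radius_px)
    shells = np.where(nuclei.labels == 0, expanded, 0)
    return shells


# ---------------------------------------------------------------------------
# expression calls

def _background_threshold(
    channel: np.ndarray, exclude: np.ndarray, z: float
) -> float:
    """Positivity threshold: mean + z * SD of background pixels (outside
    every nucleus and shell), after trimming the top 2% so stray signal
    bleed does not inflate the scale.  Plain MAD is avoided because
    detector offsets often clip background noise at zero, collapsing the
    median absolute deviation."""
    bg = channel[~exclude]
    if bg.size == 0:
        bg = channel.ravel()
    bg = bg[bg <= np.percentile(bg, 98)]
    return float(bg.mean() + z * bg.std())


def call_expression(
    nuclei: NucleusSet,
    channel: np.ndarray,
    compartment: str = "nucleus",
    shell_labels: np.ndarray | None = None,
    signal_threshold: float | None = None,
    min_positive_fraction: float = 0.10,
    background_z: float = 4.0,
) -> pd.DataFrame:
    """Per-cell positivity calls for one channel and compartment.

    A cell is positive when the fraction of its compartment pixels above
    ``signal_threshold`` reaches ``min_positive_fraction``.  When no
    threshold is given it is derived from channel background (median +
    ``background_z`` robust SDs of pixels outside all nuclei and shells).
    Returns a table with label, fraction, positive.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.shape != nuclei.labels.shape:
        raise ValueError("channel is not registered to the DAPI segmentation")
    if compartment not in ("nucleus", "shell"):
        raise ValueError(f"unknown compartment {compartment!r}")
    if compartment == "shell":
        if shell_labels is None:
            shell_labels = shell_zones(nuclei)
        comp = shell_labels
    else:
        # eroded core: keeps perinuclear ring signal from leaking into the
        # nuclear call through the segmentation's boundary band
        comp = _core_labels(nuclei.retained_labels())

    if signal_threshold is None:
        exclude = (nuclei.labels > 0)
        if shell_labels is not None:
            exclude = exclude | (shell_labels > 0)
        else:
            exclude = exclude | (shell_zones(nuclei) > 0)
        signal_threshold = _background_threshold(channel, exclude, background_z)

    above = channel > signal_threshold
    labels_present = nuclei.retained["label"].to_numpy()
    # per-label positive-pixel fraction via bincount
    n_above = np.bincount(comp.ravel(), weights=above.ravel().astype(float))
    n_tot = np.bincount(comp.ravel())
    rows = []
    for lab in labels_present:
        tot = n_tot[lab] if lab < len(n_tot) else 0
        frac = float(n_above[lab] / tot) if tot > 0 else 0.0
        rows.append(
            {"label": int(lab), "fraction": frac, "positive": frac >= min_positive_fraction}
        )
    return pd.DataFrame(rows)


def build_cell_table(
    nuclei: NucleusSet,
    channel_a: np.ndarray,
    channel_b: np.ndarray | None = None,
    pair_mode: str = "cyt_nuc",
    dilation_radius_px: int = 3,
    **call_kwargs,
) -> pd.DataFrame:
    """Two-compartment cell table for one field.

    ``cyt_nuc``: compartment A is the perinuclear shell and B the nucleus,
    both read from ``channel_a`` (Arc-style, Cy5).  ``nuc_nuc``: A is the
    nucleus in ``channel_b`` (Cy3) and B the nucleus in ``channel_a``
    (Cy5) (H1a/Fos-style).  Returns one row per retained cell with
    boolean ``pos_a`` / ``pos_b`` and the underlying pixel fractions.
    """
    shells = shell_zones(nuclei, dilation_radius_px)
    if pair_mode == "cyt_nuc":
        a = call_expression(
            nuclei, channel_a, "shell", shell_labels=shells, **call_kwargs
        )
        b = call_expression(
            nuclei, channel_a, "nucleus", shell_labels=shells, **call_kwargs
        )
    elif pair_mode == "nuc_nuc":
        if channel_b is None:
            raise ValueError("nuc_nuc mode needs both channels")
        a = call_expression(
            nuclei, channel_b, "nucleus", shell_labels=shells, **call_kwargs
        )
        b = call_expression(
            nuclei, channel_a, "nucleus", shell_labels=shells, **call_kwargs
        )
    else:
        raise ValueError(f"unknown pair_mode {pair_mode!r}")
    out = nuclei.retained[["label", "row", "col", "diameter_um"]].reset_index(drop=True)
    out["pos_a"] = a["positive"].to_numpy()
    out["frac_a"] = a["fraction"].to_numpy()
    out["pos_b"] = b["positive"].to_numpy()
    out["frac_b"] = b["fraction"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# ensemble summaries

def chance_coexpression(p_a_pct: float, p_b_pct: float) -> float:
    """Expected double-positive percentage under independence.

    The independence product on proportions: p_a * p_b / 100 (both inputs
    and the result on the 0-100 percent scale).
    """
    if not (0 <= p_a_pct <= 100 and 0 <= p_b_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    return p_a_pct * p_b_pct / 100.0


def summarize_ensembles(
    cell_tables: list[pd.DataFrame],
    pair: tuple[str, str] = ("cyt", "nuc"),
    mode: str = "pooled",
) -> EnsembleSummary:
    """Region-level summary over >= 1 sections' cell tables.

    ``pooled`` (default) counts over all retained cells across sections;
    ``per_section`` averages per-section percentages instead.  Region
    estimates should aggregate at least three nonadjacent sections when
    available.
    """
    tables = [t for t in cell_tables if len(t)]
    n_cells = sum(len(t) for t in tables)
    if n_cells == 0:
        raise ValueError("no retained cells; ensemble percentages undefined")
    if mode == "pooled":
        a = np.concatenate([t["pos_a"].to_numpy() for t in tables])
        b = np.concatenate([t["pos_b"].to_numpy() for t in tables])
        pct_a = 100.0 * a.mean()
        pct_b = 100.0 * b.mean()
        real = 100.0 * np.mean(a & b)
    elif mode == "per_section":
        pct_a = float(np.mean([100.0 * t["pos_a"].mean() for t in tables]))
        pct_b = float(np.mean([100.0 * t["pos_b"].mean() for t in tables]))
        real = float(
            np.mean([100.0 * (t["pos_a"] & t["pos_b"]).mean() for t in tables])
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EnsembleSummary(
        n_cells=n_cells,
        n_sections=len(tables),
        pct_a=float(pct_a),
        pct_b=float(pct_b),
        pct_coexp_real=float(real),
        pct_coexp_chance=chance_coexpression(float(pct_a), float(pct_b)),
        pair=pair,
    )


def ensemble_delta(summary: EnsembleSummary) -> float:
    """Nucleus-minus-cytoplasm percentage-point difference (pct_b - pct_a)."""
    return summary.pct_b - summary.pct_a
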