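"""catFISH segmentation, compartment calls, and ensemble summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from respmem.catfish import (
    NucleusSet,
    build_cell_table,
    call_expression,
    chance_coexpression,
    ensemble_delta,
    filter_nonneuronal,
    segment_nuclei,
    shell_zones,
    summarize_ensembles,
)
from respmem.synthetic import CatfishSimConfig, gen_catfish_image


def _disk_labels(shape, centers, radius):
    """Exact-disk NucleusSet for geometry tests (no segmentation noise)."""
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    labels = np.zeros(shape, dtype=int)
    rows = []
    for i, (r, c) in enumerate(centers, start=1):
        mask = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
        labels[mask] = i
        rows.append(
            {
                "label": i, "row": r, "col": c, "area_px": mask.sum(),
                "diameter_um": 2 * radius, "mean_dapi": 100.0,
                "uniformity": 0.3, "neuronal": True,
            }
        )
    return NucleusSet(labels=labels, table=pd.DataFrame(rows), px_per_um=1.0)


class TestSegmentation:
    def test_counts_and_centroids_match_ground_truth(self, catfish_field):
        cfg, channels, truth = catfish_field
        nuclei = segment_nuclei(channels.dapi, cfg.px_per_um)
        assert abs(len(nuclei) - len(truth)) <= 2
        tree = cKDTree(truth[["row", "col"]].to_numpy())
        d, _ = tree.query(nuclei.table[["row", "col"]].to_numpy())
        assert np.median(d) <= 1.0

    def test_blank_image_empty(self):
        nuclei = segment_nuclei(np.zeros((64, 64)), px_per_um=1.2)
        assert len(nuclei) == 0

    def test_tangent_nuclei_are_split(self):
        rr, cc = np.mgrid[0:64, 0:64]
        img = np.zeros((64, 64))
        for c in ((32, 20), (32, 44)):
            img[(rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= 12**2] = 100
        img += np.random.default_rng(0).normal(0, 5, img.shape)
        nuclei = segment_nuclei(img, px_per_um=1.2)
        assert len(nuclei) == 2


class TestNonneuronalFilter:
    def test_generator_mixture_recovered(self, catfish_field):
        cfg, channels, truth = catfish_field
        nuclei = filter_nonneuronal(segment_nuclei(channels.dapi, cfg.px_per_um))
        assert abs(len(nuclei.retained) - cfg.n_neuronal) <= 2

    def test_all_large_dim_nuclei_retained(self):
        table = pd.DataFrame(
            {
                "label": [1, 2, 3],
                "row": [10, 30, 50], "col": [10, 30, 50],
                "area_px": [100] * 3,
                "diameter_um": [10, 11, 12],
                "mean_dapi": [100, 105, 95],
                "uniformity": [0.3, 0.35, 0.4],
                "neuronal": [True] * 3,
            }
        )
        nuclei = NucleusSet(np.zeros((64, 64), int), table, px_per_um=1.0)
        assert filter_nonneuronal(nuclei).retained.shape[0] == 3

    def test_small_bright_uniform_excluded(self):
        # a field of neuron-like nuclei plus obvious non-neuron-like ones
        table = pd.DataFrame(
            {
                "label": np.arange(1, 11),
                "row": np.arange(10), "col": np.arange(10),
                "area_px": [100] * 10,
                "diameter_um": [10] * 8 + [5, 5],
                "mean_dapi": [100] * 8 + [250, 260],
                "uniformity": [0.3] * 8 + [0.05, 0.04],
                "neuronal": [True] * 10,
            }
        )
        nuclei = NucleusSet(np.zeros((64, 64), int), table, px_per_um=1.0)
        out = filter_nonneuronal(nuclei)
        assert out.retained["label"].tolist() == list(range(1, 9))


class TestShellZones:
    def test_isolated_disk_shell_matches_pixel_enumeration(self):
        nuclei = _disk_labels((64, 64), [(32, 32)], radius=12)
        shells = shell_zones(nuclei, dilation_radius_px=4)
        # oracle: pixels outside the mask whose distance to the nearest
        # mask pixel is <= 4
        mask_pts = np.argwhere(nuclei.labels > 0)
        out_pts = np.argwhere(nuclei.labels == 0)
        d = np.sqrt(
            ((out_pts[:, None, :] - mask_pts[None, :, :]) ** 2).sum(-1)
        ).min(1)
        expected = np.count_nonzero(d <= 4)
        assert np.count_nonzero(shells > 0) == expected

    def test_zero_radius_empty_shell(self):
        nuclei = _disk_labels((32, 32), [(16, 16)], radius=8)
        assert np.count_nonzero(shell_zones(nuclei, 0)) == 0

    def test_adjacent_shells_disjoint_and_nearest_assigned(self):
        nuclei = _disk_labels((64, 96), [(32, 30), (32, 60)], radius=10)
        shells = shell_zones(nuclei, dilation_radius_px=6)
        assert np.count_nonzero((shells > 0) & (nuclei.labels > 0)) == 0
        # every shell pixel is nearer to its own nucleus boundary
        for lab, other in ((1, 2), (2, 1)):
            pts = np.argwhere(shells == lab)
            own = np.argwhere(nuclei.labels == lab)
            oth = np.argwhere(nuclei.labels == other)
            d_own = np.sqrt(((pts[:, None] - own[None]) ** 2).sum(-1)).min(1)
            d_oth = np.sqrt(((pts[:, None] - oth[None]) ** 2).sum(-1)).min(1)
            assert np.all(d_own <= d_oth + 1e-9)


class TestExpressionCalls:
    def test_zero_signal_all_negative(self, catfish_field):
        cfg, channels, truth = catfish_field
        nuclei = filter_nonneuronal(segment_nuclei(channels.dapi, cfg.px_per_um))
        noise = np.random.default_rng(1).normal(0, 10, channels.dapi.shape).clip(0)
        calls = call_expression(nuclei, noise, "nucleus")
        assert calls["positive"].sum() == 0

    def test_call_accuracy_against_ground_truth(self, catfish_field):
        cfg, channels, truth = catfish_field
        nuclei = filter_nonneuronal(segment_nuclei(channels.dapi, cfg.px_per_um))
        cells = build_cell_table(nuclei, channels.cy5, channels.cy3)
        tr = truth[truth.neuronal]
        tree = cKDTree(tr[["row", "col"]].to_numpy())
        _, idx = tree.query(cells[["row", "col"]].to_numpy())
        matched = tr.iloc[idx]
        acc_a = (cells["pos_a"].to_numpy() == matched["pos_a"].to_numpy()).mean()
        acc_b = (cells["pos_b"].to_numpy() == matched["pos_b"].to_numpy()).mean()
        assert acc_a >= 0.98 and acc_b >= 0.98

    def test_ring_only_signal_separates_compartments(self):
        # signal rendered only perinuclearly: nuclear negative, shell positive
        cfg = CatfishSimConfig(
            n_neuronal=40, n_nonneuronal=0, p_cyt=1.0, p_nuc=0.0,
            field_size_px=(384, 384), seed=21,
        )
        channels, truth = gen_catfish_image(cfg)
        nuclei = filter_nonneuronal(segment_nuclei(channels.dapi, cfg.px_per_um))
        cells = build_cell_table(nuclei, channels.cy5, channels.cy3)
        assert cells["pos_a"].all()  # shell calls positive
        assert not cells["pos_b"].any()  # nuclear calls negative

    def test_unregistered_channel_rejected(self, catfish_field):
        cfg, channels, _ = catfish_field
        nuclei = segment_nuclei(channels.dapi, cfg.px_per_um)
        with pytest.raises(ValueError):
            call_expression(nuclei, np.zeros((10, 10)), "nucleus")


class TestEnsembleSummaries:
    def test_chance_examples(self):
        assert chance_coexpression(20, 30) == pytest.approx(6.0)
        assert chance_coexpression(0, 77) == 0.0
        with pytest.raises(ValueError):
            chance_coexpression(-1, 50)

    def test_chance_symmetry_and_homogeneity(self):
        assert chance_coexpression(15, 40) == chance_coexpression(40, 15)
        assert chance_coexpression(30, 40) == pytest.approx(
            2 * chance_coexpression(15, 40)
        )

    def test_counting_example(self):
        table = pd.DataFrame(
            {"pos_a": [True, False, True, False], "pos_b": [True, True, False, False]}
        )
        s = summarize_ensembles([table])
        assert (s.pct_a, s.pct_b) == (50.0, 50.0)
        assert s.pct_coexp_real == 25.0
        assert s.pct_coexp_chance == 25.0

    def test_all_negative(self):
        table = pd.DataFrame({"pos_a": [False] * 5, "pos_b": [False] * 5})
        s = summarize_ensembles([table])
        assert s.pct_a == s.pct_b == s.pct_coexp_real == s.pct_coexp_chance == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_ensembles([pd.DataFrame({"pos_a": [], "pos_b": []})])

    def test_real_coexpression_bounded_by_marginals(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = rng.integers(4, 100)
            table = pd.DataFrame(
                {"pos_a": rng.random(n) < rng.random(), "pos_b": rng.random(n) < rng.random()}
            )
            s = summarize_ensembles([table])
            assert s.pct_coexp_real <= min(s.pct_a, s.pct_b) + 1e-9

    def test_dependent_generator_exceeds_chance(self):
        reals, chances = [], []
        for seed in range(10):
            cfg = CatfishSimConfig(
                n_neuronal=200, n_nonneuronal=0, p_cyt=0.3, p_nuc=0.3,
                joint_dependence=1.0, field_size_px=(900, 900), seed=seed,
            )
            _, truth = gen_catfish_image(cfg)
            t = truth.rename(columns={"pos_a": "pos_a", "pos_b": "pos_b"})
            s = summarize_ensembles([t])
            reals.append(s.pct_coexp_real)
            chances.append(s.pct_coexp_chance)
        assert np.mean(reals) == pytest.approx(30.0, abs=5.0)
        assert np.mean(reals) > 2 * np.mean(chances)

    def test_pooled_vs_per_section_modes(self):
        t1 = pd.DataFrame({"pos_a": [True] * 4, "pos_b": [True] * 4})
        t2 = pd.DataFrame({"pos_a": [False] * 12, "pos_b": [False] * 12})
        pooled = summarize_ensembles([t1, t2], mode="pooled")
        per = summarize_ensembles([t1, t2], mode="per_section")
        assert pooled.pct_a == pytest.approx(25.0)
        assert per.pct_a == pytest.approx(50.0)
        assert pooled.n_sections == 2

    def test_delta_antisymmetry(self):
        table = pd.DataFrame({"pos_a": [True, True, False], "pos_b": [True, False, False]})
        s = summarize_ensembles([table])
        swapped = summarize_ensembles(
            [table.rename(columns={"pos_a": "pos_b", "pos_b": "pos_a"})]
        )
        assert ensemble_delta(s) == pytest.approx(-ensemble_delta(swapped))
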