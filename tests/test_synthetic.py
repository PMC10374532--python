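"""Ground-truth contracts of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

from respmem.synthetic import (
    ArenaSimConfig,
    BreathSimConfig,
    CatfishSimConfig,
    CohortSimConfig,
    PlacementError,
    SessionSimConfig,
    gen_behavior_video,
    gen_catfish_image,
    gen_cohort_contrasts,
    gen_pleth_trace,
    gen_session_schedule,
)


class TestBreathGenerator:
    def test_zero_jitter_gives_exact_cycles(self):
        cfg = BreathSimConfig(
            duration_s=10, mean_cycle_s=0.25, cycle_cv=0, noise_sd=0, seed=1
        )
        trace, truth = gen_pleth_trace(cfg)
        assert len(trace.samples) == 10_000
        assert len(truth) == 40
        assert np.allclose(truth.durations, 0.25)

    def test_apnea_interval_has_no_onsets(self):
        cfg = BreathSimConfig(
            duration_s=10, mean_cycle_s=0.3, apnea_intervals=[(2, 4)], seed=2
        )
        _, truth = gen_pleth_trace(cfg)
        assert not np.any((truth.onset_times >= 2) & (truth.onset_times < 4))

    def test_cycle_cv_matches_target(self):
        cfg = BreathSimConfig(duration_s=150, mean_cycle_s=0.3, cycle_cv=0.15, seed=3)
        _, truth = gen_pleth_trace(cfg)
        d = truth.durations
        assert np.std(d, ddof=1) / np.mean(d) == pytest.approx(0.15, abs=0.02)

    def test_frequency_matches_inverse_mean_duration(self):
        cfg = BreathSimConfig(duration_s=60, mean_cycle_s=0.3, cycle_cv=0.1, seed=4)
        _, truth = gen_pleth_trace(cfg)
        span = truth.onset_times[-1] - truth.onset_times[0]
        freq = (len(truth) - 1) / span
        assert freq == pytest.approx(1 / np.mean(truth.durations), abs=1 / span)

    def test_deterministic_under_seed(self):
        cfg = dict(duration_s=20, mean_cycle_s=0.3, cycle_cv=0.1, seed=9)
        t1, g1 = gen_pleth_trace(BreathSimConfig(**cfg))
        t2, g2 = gen_pleth_trace(BreathSimConfig(**cfg))
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(g1.onset_times, g2.onset_times)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BreathSimConfig(duration_s=10, apnea_intervals=[(8, 12)])
        with pytest.raises(ValueError):
            BreathSimConfig(duration_s=10, mean_cycle_s=0.001)
        with pytest.raises(ValueError):
            BreathSimConfig(duration_s=10, sample_rate_hz=500)


class TestArenaGenerator:
    def test_frozen_animal_changes_only_by_noise(self):
        cfg = ArenaSimConfig(duration_s=2, activity_profile=0.0, noise_sd=0, seed=0)
        stack, truth = gen_behavior_video(cfg)
        assert truth.active_fraction == 0.0
        assert np.array_equal(stack.frames[0], stack.frames[-1])

    def test_scripted_exploration_is_exact(self):
        n = 600
        traj = np.tile([20.0, 30.0], (n, 1))
        traj[:360] = [5.0, 5.0]  # 6 s at object A
        cfg = ArenaSimConfig(
            duration_s=10,
            trajectory_cm=traj,
            object_positions_cm=[(5, 5), (20, 30)],
            seed=1,
        )
        _, truth = gen_behavior_video(cfg)
        assert truth.exploration_s(0) == pytest.approx(6.0)
        # exploration time is exactly (in-zone frame count) / 60
        assert truth.exploration_s(1) == np.count_nonzero(truth.in_zone[1]) / 60.0

    def test_bernoulli_profile_within_binomial_bound(self):
        n_frames = 3600
        cfg = ArenaSimConfig(duration_s=60, activity_profile=0.5, seed=2)
        _, truth = gen_behavior_video(cfg)
        # 99% binomial interval for p=0.5
        lo, hi = stats.binom.interval(0.99, n_frames - 1, 0.5)
        assert lo <= np.count_nonzero(truth.moved[1:]) <= hi

    def test_deterministic_under_seed(self):
        cfg = dict(duration_s=2, seed=5)
        s1, _ = gen_behavior_video(ArenaSimConfig(**cfg))
        s2, _ = gen_behavior_video(ArenaSimConfig(**cfg))
        assert np.array_equal(s1.frames, s2.frames)

    def test_oversized_blob_rejected(self):
        with pytest.raises(ValueError):
            ArenaSimConfig(arena_size_cm=(10, 10), blob_diameter_cm=12)


class TestCatfishGenerator:
    def test_zero_probability_channels_are_noise_only(self):
        cfg = CatfishSimConfig(
            n_neuronal=40, n_nonneuronal=5, p_cyt=0, p_nuc=0,
            channel_noise_sd=5.0, field_size_px=(384, 384), seed=3,
        )
        channels, truth = gen_catfish_image(cfg)
        # no pixel above noise mean + 5 SD inside any cell footprint
        cut = 5 * 5.0
        for _, cell in truth.iterrows():
            r, c, rad = int(cell.row), int(cell.col), int(cell.diameter_um * cfg.px_per_um / 2)
            patch = channels.cy5[max(0, r - rad): r + rad, max(0, c - rad): c + rad]
            assert patch.max() < cut + 5 * 5.0  # clip-at-zero raises the mean slightly

    def test_marginal_positive_count_within_binomial_bound(self):
        cfg = CatfishSimConfig(
            n_neuronal=200, n_nonneuronal=0, p_nuc=0.3, p_cyt=0.2,
            joint_dependence=0, field_size_px=(900, 900), seed=4,
        )
        _, truth = gen_catfish_image(cfg)
        lo, hi = stats.binom.interval(0.99, 200, 0.3)
        assert lo <= truth.pos_b.sum() <= hi

    def test_perfect_dependence_forces_identity(self):
        cfg = CatfishSimConfig(
            n_neuronal=100, n_nonneuronal=0, p_cyt=0.3, p_nuc=0.3,
            joint_dependence=1.0, field_size_px=(640, 640), seed=5,
        )
        _, truth = gen_catfish_image(cfg)
        assert (truth.pos_a & truth.pos_b).sum() == truth.pos_b.sum()
        assert truth.pos_a.sum() == truth.pos_b.sum()

    def test_independence_coexpression_unbiased_over_seeds(self):
        # under joint_dependence=0 the mean of (coexpression - p_a*p_b*n)
        # over seeds should cover 0
        excess = []
        for seed in range(50):
            cfg = CatfishSimConfig(
                n_neuronal=150, n_nonneuronal=0, p_cyt=0.3, p_nuc=0.3,
                joint_dependence=0, field_size_px=(768, 768), seed=seed,
            )
            _, truth = gen_catfish_image(cfg)
            excess.append((truth.pos_a & truth.pos_b).sum() - 0.3 * 0.3 * 150)
        m = np.mean(excess)
        ci = 1.96 * np.std(excess, ddof=1) / np.sqrt(len(excess))
        assert abs(m) <= ci + 1e-9

    def test_nuclei_do_not_overlap(self, catfish_field):
        _, _, truth = catfish_field
        pos = truth[["row", "col"]].to_numpy()
        rad = truth["diameter_um"].to_numpy() / 2 * catfish_field[0].px_per_um
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        min_allowed = (rad[:, None] + rad[None, :]) ** 2
        assert np.all(d2 >= min_allowed)

    def test_placement_failure_reports_density(self):
        with pytest.raises(PlacementError, match="density"):
            gen_catfish_image(
                CatfishSimConfig(n_neuronal=500, field_size_px=(128, 128), seed=6)
            )

    def test_deterministic_under_seed(self):
        cfg = dict(n_neuronal=30, field_size_px=(256, 256), seed=7)
        c1, t1 = gen_catfish_image(CatfishSimConfig(**cfg))
        c2, t2 = gen_catfish_image(CatfishSimConfig(**cfg))
        assert np.array_equal(c1.dapi, c2.dapi)
        assert t1.equals(t2)


class TestSessionGenerator:
    def test_default_schedule_geometry(self):
        sch = gen_session_schedule(SessionSimConfig(seed=0))
        onsets = sch.onset_blocks()
        assert len(onsets) == 4
        assert all(e - s == pytest.approx(20.0) for s, e in onsets)

    def test_offsets_within_range_and_alternation(self):
        sch = gen_session_schedule(SessionSimConfig(seed=1))
        labels = [lab for lab, _, _ in sch.blocks]
        # strict alternation offset/onset (trailing offset filler allowed)
        for a, b in zip(labels, labels[1:]):
            assert a != b
        interleaved = sch.offset_blocks()[:4]
        assert all(30 <= e - s <= 50 for s, e in interleaved)

    @pytest.mark.parametrize("mode", ["flat", "10hz", "4hz"])
    def test_eight_trains_first_covers_shock(self, mode):
        sch = gen_session_schedule(SessionSimConfig(stim_mode=mode, seed=2))
        assert len(sch.trains) == 8
        assert all(t.duration_s == pytest.approx(4.0) for t in sch.trains)
        for (s0, s1), train in zip(sch.shocks, sch.trains[::2]):
            assert train.start_s <= s0 and train.end_s >= s1

    def test_shock_trace_interval(self):
        sch = gen_session_schedule(SessionSimConfig(seed=3))
        for (_, _, end), (s0, _) in zip(
            [b for b in sch.blocks if b[0] == "onset"], sch.shocks
        ):
            assert 2.0 <= s0 - end <= 3.0

    def test_unfittable_schedule_rejected(self):
        with pytest.raises(ValueError):
            SessionSimConfig(epoch_duration_s=100, seed=0)


class TestCohortGenerator:
    def test_columns_and_identity(self):
        df = gen_cohort_contrasts(CohortSimConfig(n_animals=8, seed=0))
        assert len(df) == 8
        assert np.allclose(
            df.delta_active_s, df.cs_plus_active_s - df.cs_minus_active_s
        )

    def test_latent_correlation_recovered_in_expectation(self):
        rs = []
        for seed in range(100):
            df = gen_cohort_contrasts(CohortSimConfig(n_animals=40, seed=seed))
            rs.append(np.corrcoef(df.delta_active_s, df.ensemble_delta_pct)[0, 1])
        assert np.mean(rs) == pytest.approx(-0.75, abs=0.03)
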