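"""Derived endpoints and end-to-end orchestration.

Composes the stage outputs into the study's headline quantities: per-animal
CS+/CS- active-time contrasts, the correlation between behavioral change and
IEG ensemble change, and a deterministic simulate->analyze->summarize
pipeline driven by one YAML config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import catfish as cf
from . import behavior as bh
from . import respiration as rp
from .stimulation import build_train, coverage_ratio, duty_cycle, train_intervals
from .synthetic import (
    ArenaSimConfig,
    BreathSimConfig,
    CatfishSimConfig,
    CohortSimConfig,
    SessionSimConfig,
    gen_behavior_video,
    gen_catfish_image,
    gen_cohort_contrasts,
    gen_pleth_trace,
    gen_session_schedule,
)

__all__ = ["condition_contrast", "behavior_ensemble_correlation", "run_pipeline"]


def condition_contrast(block_results: pd.DataFrame, how: str = "sum") -> tuple[pd.DataFrame, list[str]]:
    """Per-animal CS+ minus CS- onset-block active-time contrast.

    ``block_results`` is a tidy table with columns animal, condition
    ("cs_minus"/"cs_plus"), label ("onset"/"offset"), active_s.  Onset-block
    active times are aggregated (summed by default; ``how="mean"`` for the
    per-block mean) per animal and condition; animals missing either
    condition are rejected and reported.  Returns (contrasts, rejected).
    """
    required = {"animal", "condition", "label", "active_s"}
    missing = required - set(block_results.columns)
    if missing:
        raise ValueError(f"block_results missing columns: {sorted(missing)}")
    onset = block_results[block_results["label"] == "onset"]
    agg = getattr(onset.groupby(["animal", "condition"])["active_s"], how)()
    wide = agg.unstack("condition")
    rejected = [
        str(a)
        for a, row in wide.iterrows()
        if row.isna().any() or {"cs_minus", "cs_plus"} - set(wide.columns)
    ]
    if {"cs_minus", "cs_plus"} - set(wide.columns):
        rejected = [str(a) for a in wide.index]
        return pd.DataFrame(
            columns=["animal", "cs_minus_active_s", "cs_plus_active_s", "delta_active_s"]
        ), rejected
    wide = wide.dropna()
    out = pd.DataFrame(
        {
            "animal": wide.index,
            "cs_minus_active_s": wide["cs_minus"].to_numpy(),
            "cs_plus_active_s": wide["cs_plus"].to_numpy(),
        }
    ).reset_index(drop=True)
    out["delta_active_s"] = out["cs_plus_active_s"] - out["cs_minus_active_s"]
    return out, rejected


def behavior_ensemble_correlation(
    contrasts: pd.DataFrame,
    x: str = "delta_active_s",
    y: str = "ensemble_delta_pct",
) -> tuple[float, int]:
    """Pearson r between active-time change and ensemble change.

    Returns (r, n).  Significance testing is left to the caller's
    statistics environment.
    """
    xs = contrasts[x].to_numpy(dtype=float)
    ys = contrasts[y].to_numpy(dtype=float)
    if len(xs) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(stats.pearsonr(xs, ys).statistic)
    return r, len(xs)


# ---------------------------------------------------------------------------
# pipeline

def _pleth_stage(params: dict, seed: int, out: Path) -> dict:
    train_params = params.pop("train", {"mode": "flat", "duration_s": 2.0, "start_s": None})
    cfg = BreathSimConfig(seed=seed, **params)
    duration = train_params.get("duration_s", 2.0)
    start = train_params.get("start_s") or (cfg.duration_s - duration) / 2.0
    train = build_train(
        mode=train_params.get("mode", "flat"),
        pulse_on_ms=train_params.get("pulse_on_ms"),
        pulse_off_ms=train_params.get("pulse_off_ms"),
        duration_s=duration,
        start_s=start,
    )
    # stimulation drives apnea in the simulated animal
    cfg.apnea_intervals = [(train.start_s, train.end_s)]
    trace, truth = gen_pleth_trace(cfg)
    cycles = rp.detect_cycles(trace)
    summary = rp.peristimulus_summary(trace, train, cycles=cycles)
    trace.to_frame().to_csv(out / "pleth_trace.csv", index=False)
    cycles.to_frame().to_csv(out / "pleth_cycles.csv", index=False)
    summary.to_frame().to_csv(out / "pleth_peristimulus.csv", index=False)
    return {
        "n_cycles": len(cycles),
        "frequency_hz": summary.frequency_hz,
        "duty_cycle": duty_cycle(train),
    }


def _video_stage(params: dict, seed: int, out: Path) -> dict:
    cfg = ArenaSimConfig(seed=seed, **params)
    stack, truth = gen_behavior_video(cfg)
    binary = bh.preprocess_frames(
        stack, gray_threshold=(cfg.background_gray + cfg.blob_gray) / 2.0
    )
    trace = bh.activity_levels(binary)
    df = pd.DataFrame({"time_s": trace.times, "nonmatching_px": trace.counts})
    df.to_csv(out / "activity_levels.csv", index=False)
    result = {"n_frames": stack.n_frames, "true_active_fraction": truth.active_fraction}
    if cfg.object_positions_cm:
        masks = bh.zone_masks(
            binary.shape, cfg.object_positions_cm, px_per_cm=cfg.px_per_cm
        )
        explo = bh.exploration_time(binary, masks)
        result["exploration_s"] = explo.seconds
        if len(cfg.object_positions_cm) == 2:
            secs = list(explo.seconds.values())
            if sum(secs) > 0:
                result["d2"] = bh.discrimination_ratio(secs[0], secs[1])
    return result


def _catfish_stage(params: dict, seed: int, out: Path) -> dict:
    cfg = CatfishSimConfig(seed=seed, **params)
    channels, truth = gen_catfish_image(cfg)
    nuclei = cf.segment_nuclei(channels.dapi, channels.px_per_um)
    nuclei = cf.filter_nonneuronal(nuclei)
    cells = cf.build_cell_table(
        nuclei, channels.cy5, channels.cy3, pair_mode=cfg.pair_mode
    )
    summary = cf.summarize_ensembles([cells])
    cells.to_csv(out / "catfish_cells.csv", index=False)
    with open(out / "catfish_summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    return summary.to_dict()


def _session_stage(params: dict, seed: int, out: Path) -> dict:
    cfg = SessionSimConfig(seed=seed, **params)
    schedule = gen_session_schedule(cfg)
    with open(out / "session_schedule.json", "w") as fh:
        json.dump(schedule.to_dict(), fh, indent=2)
    result = {
        "n_onset_blocks": len(schedule.onset_blocks()),
        "n_trains": len(schedule.trains or []),
    }
    if schedule.trains:
        from .intervals import IntervalSet

        stim = IntervalSet()
        for t in schedule.trains:
            stim = stim.union(train_intervals(t))
        onset = IntervalSet(schedule.onset_blocks())
        result["stim_coverage_of_onset_pct"] = coverage_ratio(stim, onset)
    return result


def _cohort_stage(params: dict, seed: int, out: Path) -> dict:
    cfg = CohortSimConfig(seed=seed, **params)
    cohort = gen_cohort_contrasts(cfg)
    cohort.to_csv(out / "cohort_contrasts.csv", index=False)
    r, n = behavior_ensemble_correlation(cohort)
    with open(out / "cohort_correlation.json", "w") as fh:
        json.dump({"r": r, "n": n}, fh, indent=2)
    return {"r": r, "n": n}


_STAGES = {
    "pleth": _pleth_stage,
    "video": _video_stage,
    "catfish": _catfish_stage,
    "session": _session_stage,
    "cohort": _cohort_stage,
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the configured simulate->analyze->summarize stages.

    ``config`` is a dict or a YAML file path with an optional ``seed``,
    an ``out_dir``, and one section per stage (``pleth``, ``video``,
    ``catfish``, ``session``, ``cohort``) holding that stage's simulation
    parameters.  All outputs (tidy CSV tables, JSON summaries, and a run
    manifest recording every parameter) are written under ``out_dir``;
    reruns with the same config are byte-identical.  A stage failure
    aborts with the stage name attached.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    seed = int(config.pop("seed", 0))
    out = Path(out_dir or config.pop("out_dir", "results"))
    config.pop("out_dir", None)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"seed": seed, "stages": {}}
    results: dict = {}
    for i, (name, params) in enumerate(config.items()):
        if name not in _STAGES:
            raise ValueError(f"unknown pipeline stage {name!r}")
        params = dict(params or {})
        manifest["stages"][name] = dict(params)
        stage_seed = seed + 1000 * (i + 1)
        try:
            results[name] = _STAGES[name](params, stage_seed, out)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage attribution
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest["results"] = results
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float, sort_keys=True)
    return results
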