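"""Synthetic animal cohorts for behavior-ensemble correlation studies.

Generates per-animal paired endpoints — onset-block active time under CS-
and CS+ presentations, and the nucleus-minus-cytoplasm change in IEG-positive
cell percentage — with a controllable latent Pearson correlation between the
active-time change and the ensemble change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CohortSimConfig", "gen_cohort_contrasts"]


@dataclass
class CohortSimConfig:
    """Latent-variable model for a conditioning cohort.

    delta_active: CS+ minus CS- summed onset-block active time, seconds
    (negative = freezing to the CS+).  ensemble_delta: nuclear minus
    cytoplasmic positive-cell percentage, points.  latent_r is the
    population correlation between the two.
    """

    n_animals: int = 12
    latent_r: float = -0.75
    mean_delta_active_s: float = -10.0
    sd_delta_active_s: float = 8.0
    mean_ensemble_delta_pct: float = 10.0
    sd_ensemble_delta_pct: float = 6.0
    mean_cs_minus_active_s: float = 40.0
    sd_cs_minus_active_s: float = 6.0
    region: str = "distal_CA3"
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 <= self.latent_r <= 1:
            raise ValueError("latent_r must lie in [-1, 1]")
        if self.n_animals < 3:
            raise ValueError("need >= 3 animals for a correlation")


def gen_cohort_contrasts(cfg: CohortSimConfig) -> pd.DataFrame:
    """Draw one cohort; returns a tidy per-animal table.

    Columns: animal, region, cs_minus_active_s, cs_plus_active_s,
    delta_active_s, ensemble_delta_pct.
    """
    rng = np.random.default_rng(cfg.seed)
    r = cfg.latent_r
    z1 = rng.standard_normal(cfg.n_animals)
    z2 = r * z1 + np.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal(cfg.n_animals)
    delta_active = cfg.mean_delta_active_s + cfg.sd_delta_active_s * z1
    ensemble_delta = cfg.mean_ensemble_delta_pct + cfg.sd_ensemble_delta_pct * z2
    cs_minus = np.maximum(
        cfg.mean_cs_minus_active_s
        + cfg.sd_cs_minus_active_s * rng.standard_normal(cfg.n_animals),
        0.0,
    )
    return pd.DataFrame(
        {
            "animal": [f"m{i:02d}" for i in range(cfg.n_animals)],
            "region": cfg.region,
            "cs_minus_active_s": cs_minus,
            "cs_plus_active_s": cs_minus + delta_active,
            "delta_active_s": delta_active,
            "ensemble_delta_pct": ensemble_delta,
        }
    )
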