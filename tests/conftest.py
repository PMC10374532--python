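import numpy as np
import pytest


def onset_f1(detected, true, tol_s=0.030):
    """F1 of nearest-neighbor onset matching within a time tolerance."""
    detected = np.asarray(detected)
    true = np.asarray(true)
    if len(detected) == 0 and len(true) == 0:
        return 1.0
    used = np.zeros(len(true), dtype=bool)
    tp = 0
    for t in detected:
        d = np.abs(true - t)
        d[used] = np.inf
        i = int(np.argmin(d)) if len(d) else 0
        if len(d) and d[i] <= tol_s:
            used[i] = True
            tp += 1
    prec = tp / len(detected) if len(detected) else 0.0
    rec = tp / len(true) if len(true) else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


@pytest.fixture(scope="session")
def catfish_field():
    """One medium synthetic catFISH field shared across image tests."""
    from respmem.synthetic import CatfishSimConfig, gen_catfish_image

    cfg = CatfishSimConfig(
        n_neuronal=120, n_nonneuronal=15, p_cyt=0.3, p_nuc=0.3,
        field_size_px=(640, 640), seed=11,
    )
    channels, truth = gen_catfish_image(cfg)
    return cfg, channels, truth
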