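import numpy as np
import pytest

import panelfa as pf


@pytest.fixture(scope="session")
def rat_truth():
    """Small rat-style dataset with a planted latent effect."""
    cfg = pf.rat_config(seed=11, grid_shape=(12, 12, 6),
                        effect_amplitude=0.1, noise_sd_fa=0.01,
                        outlier_rate=0.0)
    return cfg, pf.generate_dataset(cfg)


@pytest.fixture(scope="session")
def human_recovery():
    """Human-style dataset in the strong-signal regime (for recovery tests)."""
    cfg = pf.human_config(seed=5, grid_shape=(16, 16, 8),
                          effect_amplitude=0.12, noise_sd_fa=0.004,
                          noise_sd_panel=0.15, marker_loadings=0.3,
                          outlier_rate=0.0)
    return cfg, pf.generate_dataset(cfg)


@pytest.fixture(scope="session")
def patient_stack(human_recovery):
    """Patient-group volumes + fitted PCA + design for the recovery dataset."""
    cfg, truth = human_recovery
    tbl = truth.panel.select(group="B")
    model = pf.fit(tbl, max_components=3)
    idx = np.arange(cfg.n_group_a, cfg.n_subjects)
    vols = pf.VolumeStack(truth.volumes[idx], truth.brain_mask, cfg.affine,
                          subject_ids=np.array(
                              [f"sub-{i + 1:03d}" for i in idx]))
    scores = pf.transform(model, tbl)
    return vols, model, pf.Design.from_scores(scores)
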