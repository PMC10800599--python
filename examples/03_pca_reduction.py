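"""Standardise a panel and reduce it to three principal components.

Each marker is scaled to mean 0 / SD 1 so the PCA acts on the correlation
matrix; eigenvalues then sum to the marker count and the proportion of
variance of PC k is eigenvalue_k / m.
"""

import panelfa as pf

cfg = pf.rat_config(seed=3, outlier_rate=0.0)
panel, _ = pf.generate_panel(cfg)
tbi_day60 = panel.select(group="B", timepoint="t4")

model = pf.fit(tbi_day60, max_components=3)
print(model.summary().round(1).to_string())
print(f"\neigenvalue sum = {model.eigenvalues.sum():.2f} "
      f"(= {model.m} markers)")
print(f"PC scores: {model.scores.shape[0]} subjects x "
      f"{model.n_components} components")
# With a strong shared latent factor most panel variance loads on PC1;
# the scores are the low-dimensional predictors for the voxel-wise stage.
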