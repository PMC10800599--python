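"""Voxel-wise permutation GLM with TFCE and max-statistic FWE correction.

FA is regressed on the PC scores voxel by voxel; the omnibus F map is
enhanced with TFCE and compared against the permutation distribution of
its image-wide maximum, giving FWE-corrected p-values.
"""

import numpy as np

import panelfa as pf

cfg = pf.human_config(seed=5, grid_shape=(16, 16, 8), effect_amplitude=0.12,
                      noise_sd_fa=0.004, noise_sd_panel=0.15,
                      marker_loadings=0.3, outlier_rate=0.0)
truth = pf.generate_dataset(cfg)
patients = truth.panel.select(group="B")
model = pf.fit(patients, max_components=3)
idx = np.arange(cfg.n_group_a, cfg.n_subjects)
vols = pf.VolumeStack(truth.volumes[idx], truth.brain_mask, cfg.affine)

res = pf.permutation_fwe(vols, pf.Design.from_scores(model.scores),
                         n_perm_requested=1000, alpha=0.05, seed=1)
planted = truth.effect_voxels()
sens = (res.sig_mask & planted).sum() / planted.sum()
print(f"permutations: {res.n_perm} "
      f"({'exhaustive' if res.exhaustive else 'random'})")
print(f"minimum corrected p: {res.corrp_maps['f'].min():.4f}")
print(f"significant voxels: {res.sig_mask.sum()} "
      f"(sensitivity over planted effect: {100 * sens:.0f}%)")
labels = pf.extract_rois(res.sig_mask)
print(f"connected ROIs: {labels.max()}")
# Corrected p < 0.05 controls the probability of ANY false-positive voxel
# across the whole mask; the surviving cluster is the ROI analysed next.
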