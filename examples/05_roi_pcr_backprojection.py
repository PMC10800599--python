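"""ROI principal-component regression with back-projection to biomarkers.

Mean FA over the recovered ROI is regressed on the three PC scores; the
score coefficients are then mapped back through the loading matrix to one
interpretable coefficient per biomarker (FA change per pg/mL).
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

y = pf.extract_roi_fa(vols, truth.effect_voxels())
res = pf.pcr_fit(y, model)
print(res.summary())
signs = np.sign(res.coefficients["beta"].to_numpy())
agree = (signs == np.sign(truth.marker_loadings)).mean()
print(f"\nback-projected coefficient signs matching the generating "
      f"loadings: {100 * agree:.0f}%")
# The ANOVA block tests whether the panel explains ROI FA at all; the
# per-marker rows say which direction each biomarker moves with FA.
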