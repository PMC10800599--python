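"""Generate a synthetic study: biomarker panel + FA volumes with known truth.

A single latent severity factor per subject drives both the log-normal
marker concentrations and the FA change in a planted voxel block, so the
whole downstream pipeline can be checked against ground truth.
"""

import panelfa as pf

cfg = pf.rat_config(seed=42, grid_shape=(16, 16, 8))
truth = pf.generate_dataset(cfg)
out = pf.write_dataset(truth, cfg, "scratch/example_rat")

panel = truth.panel
print(f"panel: {panel.n_rows} rows ({cfg.n_subjects} subjects x "
      f"{cfg.n_timepoints} timepoints), {panel.n_markers} markers")
print(f"below-LOD zeros: {(panel.values == 0).sum()}")
print(f"FA volumes: {truth.volumes.shape}, range "
      f"[{truth.volumes.min():.3f}, {truth.volumes.max():.3f}]")
print(f"planted effect voxels: {truth.effect_voxels().sum()}")
print(f"files written to {out}")
# The effect voxels are where FA responds to the latent factor; they are
# what the voxel-wise inference stage should rediscover.
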