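# panelfa

Links plasma immunological biomarker panels to white-matter microstructure.
`panelfa` implements, as a reusable and tested Python pipeline, the
statistical workflow used to relate multiplex plasma panels (cytokines,
chemokines, growth factors; pg/mL, heavy right-skew, exact zeros below the
limit of detection) to voxel-wise fractional anisotropy (FA) maps from
diffusion MRI — the setting being traumatic brain injury studies in which
a small cohort (e.g. 8 injured + 6 sham animals, or 15 patients + 19
controls) has both a blood panel and a registered FA volume per subject.

It is a library first (see `examples/`), with a thin `panelfa` CLI for the
file-based stages.

## The method

1. **Group comparison** — per marker, a two-sided Mann–Whitney test
   (exact enumeration when C(n_a+n_b, n_a) ≤ 2·10⁵ and no ties, else the
   tie- and continuity-corrected normal approximation), with the adaptive
   two-stage linear step-up FDR procedure of Benjamini, Krieger &
   Yekutieli at Q < 0.1 within each timepoint family (or raw p < 0.05 in
   the single-timepoint clinical variant).
2. **Data reduction** — each marker standardised to mean 0 / SD 1
   (n−1 divisor), PCA of the resulting correlation matrix; at most K = 3
   components retained (λ₁ ≥ λ₂ ≥ …, proportion of variance λ_k/m).
3. **Voxel-wise inference** — per voxel, OLS of FA on the K PC scores
   (t per score, omnibus F); permutation inference (10,000 permutations
   or exhaustive, whichever is smaller) with threshold-free cluster
   enhancement, TFCE(v) = Σ_h e(h,v)^E h^H dh with E = 0.5, H = 2
   (cluster-mass support optional), and FWE correction by the null
   distribution of the image-wide maximum, two-tailed at p < 0.05.
4. **ROI analysis** — connected components of the significant mask become
   ROIs; mean ROI FA is regressed on the PC scores (principal-component
   regression) with a full ANOVA table, R²/adjusted R², and the score
   coefficients γ **back-projected** to per-biomarker coefficients
   β_j = (Wγ)_j / sd_j with linearly propagated uncertainty; residual
   normality is checked by a Shapiro–Wilk test.

A synthetic-data module generates both study designs from a shared latent
severity factor with known marker loadings and a known voxel effect map,
so every stage is testable against ground truth.

## Worked example

```python
import numpy as np, panelfa as pf

cfg = pf.human_config(seed=5, grid_shape=(16, 16, 8), effect_amplitude=0.12,
                      noise_sd_fa=0.004, noise_sd_panel=0.15,
                      marker_loadings=0.3, outlier_rate=0.0)
truth = pf.generate_dataset(cfg)
patients = truth.panel.select(group="B")
model = pf.fit(patients, max_components=3)
vols = pf.VolumeStack(truth.volumes[cfg.n_group_a:], truth.brain_mask,
                      cfg.affine)
res = pf.permutation_fwe(vols, pf.Design.from_scores(model.scores),
                         n_perm_requested=1000, alpha=0.05, seed=1)
roi = pf.extract_rois(res.sig_mask) == 1
pcr = pf.pcr_fit(pf.extract_roi_fa(vols, roi), model)
```

This prints (via `examples/04_voxelwise_tfce.py` and
`examples/05_roi_pcr_backprojection.py`):

```
permutations: 1000 (random)
minimum corrected p: 0.0010
significant voxels: 32 (sensitivity over planted effect: 100%)
connected ROIs: 1
...
back-projected coefficient signs matching the generating loadings: 100%
```

i.e. the 32-voxel planted effect is recovered in full at FWE-corrected
p < 0.05, and the per-biomarker coefficients obtained by back-projection
point in the direction the generator used. The remaining examples cover
simulation, the group comparison, the PC summary table (eigenvalue,
% variance, cumulative %), and the file-based end-to-end run.

## CLI

```sh
panelfa simulate --design rat --out data/ --seed 42
panelfa panel-stats --panel data/panel.csv --out mw.csv
panelfa pca --panel data/panel.csv --group B --out pca/
panelfa voxelwise --volumes ... --mask ... --scores pca/scores.csv --out vox/
panelfa roi-pcr --volumes ... --mask ... --roi-labels vox/roi_labels.nii.gz \
                --pca-model pca/pca_model.json --out pcr/
panelfa run --config config.yaml
```

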