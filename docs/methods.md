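# Methods

## Problem and model

The pipeline asks whether the between-subject variation of a plasma
immunological panel (m markers, pg/mL scale) explains the between-subject
variation of white-matter FA, voxel by voxel, in small two-group imaging
cohorts. Concentrations are non-negative, strongly right-skewed with
occasional extreme values, and censored below the assay's limit of
detection (LOD); per this pipeline's input convention a below-LOD value
is recorded as exactly 0 and is treated as a tie at the common lower
bound by the rank tests and as 0 pg/mL by the standardisation.

Stages and their contracts:

1. **Mann–Whitney per marker.** U = #{(i,j): a_i > b_j} + ½·#ties.
   `mode="auto"` switches to exact enumeration whenever
   C(n_a+n_b, n_a) ≤ 200,000 and the pooled sample is tie-free (this
   covers the 6-vs-8 animal design, C(14,6) = 3003; the 19-vs-15 human
   design, C(34,15) ≈ 1.9·10⁹, uses the normal approximation with tie and
   continuity correction). Two-sided p doubles the smaller tail and is
   capped at 1; two completely identical samples report p = 1 rather than
   erroring. The exact path is validated against brute-force enumeration
   of every labeling.
2. **Two-stage FDR (BKY).** Stage 1 is a linear step-up at
   q′ = q/(1+q); its discovery count r₁ gives the null estimate
   m̂₀ = m − r₁; stage 2 re-runs the step-up at q′·m/m̂₀ (no discoveries
   if r₁ = 0, all if r₁ = m). This is the standard adaptive two-stage
   definition (it matches statsmodels' `fdr_tsbky`, which the tests
   check). The family is all markers within one timepoint, matching how
   per-timepoint results are reported; the clinical variant skips FDR and
   flags raw p < 0.05.
3. **Standardised PCA.** Sample SD uses the n−1 divisor so the
   decomposition is of the sample correlation matrix and Σλ equals the
   number of non-degenerate markers exactly; the variance proportion of
   PC k is λ_k/m. Zero-variance markers are dropped with a warning and
   reported as absent downstream. K = min(3, rank): three components cap
   over-fitting at n = 8–15, and rank ≤ n−1 guards the degenerate case.
   Eigenvector signs are fixed by making the largest-|loading| entry of
   each column positive, so fits are bit-reproducible.
4. **Voxel-wise GLM + permutation TFCE.** OLS per voxel of FA on
   [1 | scores]; statistics are t per score column and the omnibus F over
   all K score columns. Permutation scheme: with an intercept-only
   nuisance, Freedman–Lane reduces to permuting subject rows of the
   outcome; all n! orderings are enumerated when n! ≤ the requested
   count (n ≤ 7 at the default 10,000), else identity + random draws
   without deduplication (collision probability is negligible for
   n ≥ 8). TFCE(v) = Σ_{h=dh..h_v} e(h,v)^E h^H dh with E = 0.5, H = 2,
   100 steps, 26-connectivity, e = component voxel count × voxel volume;
   a cluster-mass variant (e = Σ(stat−h) × voxel volume) is available
   because "mass-based" enhancement can denote either convention — TFCE
   is the default and no claim is made about which the original analysis
   used. dh = max/n_steps is recomputed per map, including per
   permutation, keeping the integration grid scale-free. Two-tailed t
   inference enhances +t and −t separately and pools both tails into one
   max-statistic null; F uses a single tail. Corrected
   p(v) = #{null max ≥ observed enhanced(v)}/P with the identity among
   the P permutations, so min p = 1/P and validity is exact. The
   significant mask defaults to the omnibus F (the per-score t maps are
   also produced, since the contrast behind the published maps is not
   derivable); ROIs are its connected components, labelled largest
   first.
5. **ROI PCR with back-projection.** y = mean ROI FA (median behind a
   flag; mean is the field convention). OLS on [1 | T] yields the ANOVA
   table (SS_total = SS_reg + SS_res, F = MS_reg/MS_res,
   adj R² = 1 − (1−R²)(n−1)/(n−K−1)). Because T = ZW with fixed W, the
   standardised coefficient vector is b = Wγ and the concentration-scale
   coefficient for marker j is β_j = b_j/sd_j with
   Var(β_j) = w_jᵀ Σ_γ w_j / sd_j², Σ_γ = MS_res (T_cᵀT_c)⁻¹. The PCA is
   deliberately treated as fixed rather than resampled: that is the only
   convention under which per-biomarker t statistics and CIs carry the
   residual df n−K−1 of the score regression, matching how such tables
   are reported; the alternative (resampling the PCA) is out of scope.
   |t| and 95% CIs use Student t with n−K−1 df. Residual normality is
   Royston's Shapiro–Wilk (scipy), with constant residuals an explicit
   error and perfect fits flagged degenerate instead.
6. **`f_to_r2`.** R² = F·df_n/(F·df_n+df_d),
   adj R² = 1 − (1−R²)(df_n+df_d)/df_d, p = upper-tail F. It inverts the
   ANOVA of stage 5 exactly and lets a reported (F, df) pair be checked
   for internal consistency with its reported adjusted R² and P.

## Synthetic data: what it emulates and what it does not

One latent severity factor z_i ~ N(0,1) per subject drives both sides:
log-normal concentrations c_ij = exp(μ_j + λ_j z_i + δ_j g_i + ε_ij)
(right-skew and non-negativity for free), multiplicative outliers
(default confined to the case group, emulating the extreme elevations
seen in some injured subjects), LOD censoring to exact zeros, and FA
volumes baseline(v) + β(v) z_i + smoothed noise clipped to [0,1], with a
high-FA slab (0.6 vs 0.25) standing in for a white-matter tract. Defaults
follow the two study designs: 23 markers, 6+8 subjects, 4 timepoints
(rodent) and 20 markers, 19+15, one timepoint (human); grids default to
16×16×8 at 0.5 mm — statistics per voxel are grid-size independent, so a
desk-scale grid tests the same machinery as a full map. Panel noise SD
0.6 (log scale), marker loadings 0.8, FA noise SD 0.02 smoothed to
1.5 mm FWHM are chosen to resemble multiplex-panel dispersion and
template-space FA residuals; no effect sizes for the marker–FA coupling
are derivable from published summaries, so the planted-effect amplitude
(0.08 FA per latent SD) is chosen for test power, not realism.

Not emulated: diffusion-weighted acquisition and tensor fitting,
registration error, lesion morphology, assay standard curves, spatial
heterogeneity of the panel–FA coupling beyond a block effect map.
Passing tests therefore certify the statistics, not robustness to
registration or segmentation artefacts.

A note on power at the animal design: with n = 8 and K = 3 the residual
df is 4, whose F null has a polynomially heavy tail; isolated noise
voxels can then out-enhance a moderate planted block (TFCE weights
height as h²), so ground-truth recovery tests run on the human-shaped
design (n = 15, df 11) in a strong-coupling regime (small loadings so
exp(·) is near-linear, low noise), where recovery is complete. The same
heavy tail is also why a real day-60 animal analysis hinges on the
spatial coherence of genuine tract effects.

## Numerical choices

- TFCE is computed by an incremental union-find over descending
  thresholds (numba), exactly equivalent to relabelling the
  suprathreshold set at every height — the test suite checks bitwise
  agreement with a literal scipy.ndimage re-implementation — and ~15×
  faster, which is what makes 500-replicate FWE calibration runs
  affordable. Thresholds are h_k = h_max·k/n_steps so the map maximum is
  included exactly.
- Discrete TFCE with a per-map dh is pointwise monotone under map
  dominance only when both maps share the threshold grid (equal maxima);
  the monotonicity test is constructed accordingly.
- Voxels with zero FA variance carry statistic 0; numerically perfect
  fits are capped at ±10⁶ rather than ±∞ (rank order under TFCE is
  unaffected).
- Exact Mann–Whitney, Shapiro–Wilk and the F/t distributions come from
  scipy; PCA uses SVD of Z/√(n−1) with a rank tolerance of 1e−10
  relative to λ₁.
- Panel CSVs are parsed with round-trip float precision so
  write → read → write is bitwise stable; NIfTI outputs are float32
  (masks int8, labels int32) with fixed gzip timestamps, so identical
  configs reproduce identical bytes.

## Problem sizes used by the shipped checks

FWE calibration: 500 replicates × 500 permutations on a 16×16×8 grid
with n = 12 null subjects (the acceptance script uses 150 × 400);
recovery: n = 15 patients, 1000 permutations; FDR calibration: 500 null
panels of 23 markers at 6 vs 8; Shapiro–Wilk calibration: 1000 samples
of n = 50. These sizes give binomial error bands comfortably inside the
asserted ranges while keeping a full run to a few minutes.

## Known limitations

- No exchangeability blocks, variance smoothing, or cluster-extent
  thresholding; no 2D slice mode.
- Below-LOD zeros are not imputed; with many censored values the
  standardised marker becomes a near-indicator variable and its
  back-projected coefficient should be interpreted accordingly.
- The human marker-set ambiguity (20 listed vs 21 implied by one
  published PC summary) is left to the caller: m is taken from the input
  panel and reported, never silently adjusted.
- Back-projected per-marker inferences are conditional on the fitted
  loadings; they do not propagate PCA sampling variability.
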