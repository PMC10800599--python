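"""Synthetic biomarker panels and FA volumes with known latent structure.

The generator emulates the two study designs the pipeline targets —
a rodent controlled-cortical-impact experiment (23 plasma markers,
6 sham + 8 injured animals, 4 timepoints, day-60 FA maps) and a human
cohort (20 markers, 15 patients + 19 controls, one FA map each) — while
retaining the generating parameters so every downstream stage can be
tested against ground truth.

A single per-subject latent severity factor z_i ~ N(0,1) drives both
sides of the data.  Marker concentrations follow a log-normal model

    c_ij = exp(mu_j + lambda_j * z_i + delta_j * g_i + eps_ij),

with g_i the group indicator, giving the non-negative, right-skewed
distributions with occasional extreme values seen in real multiplex
panels; multiplicative outliers (by default confined to the injured
group) and recording of below-LOD values as exact zeros complete the
emulation.  FA volumes are a smooth tract-bearing baseline plus
beta(v) * z_i in the voxels named by the latent effect map, plus
spatially smoothed Gaussian noise, clipped to the defining FA range [0,1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .panel import PanelTable

MAX_GRID_VOXELS = 1_000_000


def _per_marker(value, n_markers: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_markers, float(arr))
    if arr.shape != (n_markers,):
        raise ValueError(f"{name} must be scalar or length {n_markers}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study.

    Scalars given for per-marker fields are broadcast to all markers.
    ``group_shift`` acts on the log scale, so a shift of 1 multiplies the
    typical concentration of group B by e.  ``latent_effect_map`` (voxel
    weights beta(v), FA units per latent SD) defaults to a block planted
    inside the synthetic tract; pass an array to control it.
    """

    n_group_a: int = 6            # e.g. sham animals / healthy controls
    n_group_b: int = 8            # e.g. injured animals / patients
    n_markers: int = 23
    n_timepoints: int = 4
    grid_shape: tuple = (16, 16, 8)
    voxel_size_mm: tuple = (0.5, 0.5, 0.5)
    latent_effect_map: np.ndarray | None = None
    effect_amplitude: float = 0.08    # FA per latent SD in the default block
    marker_loadings: float | np.ndarray = 0.8
    group_shift: float | np.ndarray = 0.0
    marker_log_mean: float | np.ndarray = 3.0   # exp(3) ≈ 20 pg/mL
    lod: float | np.ndarray = 0.0
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0
    outliers_group_b_only: bool = True
    noise_sd_panel: float = 0.6
    noise_sd_fa: float = 0.02
    fwhm_mm: float = 1.5
    baseline_fa_tract: float = 0.6
    baseline_fa_outside: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_group_a", "n_group_b", "n_markers", "n_timepoints"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be a positive 3-tuple")
        if int(np.prod(self.grid_shape)) > MAX_GRID_VOXELS:
            raise ValueError(f"grid exceeds {MAX_GRID_VOXELS} voxels")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if min(self.voxel_size_mm) <= 0:
            raise ValueError("voxel sizes must be positive")
        if not (0.0 <= float(self.outlier_rate) <= 1.0):
            raise ValueError("outlier_rate must lie in [0, 1]")
        if float(self.outlier_scale) <= 1.0:
            raise ValueError("outlier_scale must exceed 1")
        for name in ("noise_sd_panel", "noise_sd_fa", "fwhm_mm",
                     "effect_amplitude", "baseline_fa_tract",
                     "baseline_fa_outside"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        self.marker_loadings = _per_marker(self.marker_loadings,
                                           self.n_markers, "marker_loadings")
        self.group_shift = _per_marker(self.group_shift, self.n_markers,
                                       "group_shift")
        self.marker_log_mean = _per_marker(self.marker_log_mean,
                                           self.n_markers, "marker_log_mean")
        self.lod = _per_marker(self.lod, self.n_markers, "lod")
        if (self.lod < 0).any():
            raise ValueError("lod must be non-negative")
        if self.latent_effect_map is not None:
            self.latent_effect_map = np.asarray(self.latent_effect_map,
                                                dtype=float)
            if self.latent_effect_map.shape != self.grid_shape:
                raise ValueError("latent_effect_map shape must match grid")
            if not np.all(np.isfinite(self.latent_effect_map)):
                raise ValueError("latent_effect_map must be finite")

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff


def rat_config(**overrides) -> GeneratorConfig:
    """Rodent-style design: 23 markers, 6 sham + 8 injured, 4 timepoints."""
    defaults = dict(n_group_a=6, n_group_b=8, n_markers=23, n_timepoints=4,
                    outlier_rate=0.03)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def human_config(**overrides) -> GeneratorConfig:
    """Human-style design: 20 markers, 19 controls + 15 patients, 1 timepoint."""
    defaults = dict(n_group_a=19, n_group_b=15, n_markers=20, n_timepoints=1,
                    outlier_rate=0.01)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@dataclass
class SyntheticTruth:
    """Generating parameters kept for recovery tests."""

    latent: np.ndarray                     # z_i per subject
    marker_loadings: np.ndarray
    group_shift: np.ndarray
    latent_effect_map: np.ndarray | None = None
    baseline: np.ndarray | None = None
    tract_mask: np.ndarray | None = None
    panel: PanelTable | None = None
    volumes: np.ndarray | None = None      # (n_subjects, X, Y, Z)
    brain_mask: np.ndarray | None = None

    def effect_voxels(self) -> np.ndarray:
        return self.latent_effect_map != 0


def generate_panel(config: GeneratorConfig) -> tuple[PanelTable, SyntheticTruth]:
    """Draw a concentration panel from the log-normal latent-factor model.

    The latent factor is constant across timepoints for each subject;
    measurement noise, outliers and LOD censoring are drawn independently
    per row.  The group labels are ``"A"`` and ``"B"``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    z = rng.standard_normal(n)
    g = np.concatenate([np.zeros(config.n_group_a),
                        np.ones(config.n_group_b)])
    subj = np.array([f"sub-{i + 1:03d}" for i in range(n)])
    groups = np.where(g == 0, "A", "B")

    rows_v, rows_s, rows_g, rows_t = [], [], [], []
    for t in range(config.n_timepoints):
        log_c = (config.marker_log_mean[None, :]
                 + np.outer(z, config.marker_loadings)
                 + np.outer(g, config.group_shift)
                 + config.noise_sd_panel * rng.standard_normal(
                     (n, config.n_markers)))
        c = np.exp(log_c)
        if config.outlier_rate > 0:
            hit = rng.random((n, config.n_markers)) < config.outlier_rate
            if config.outliers_group_b_only:
                hit &= (g == 1)[:, None]
            c = np.where(hit, c * config.outlier_scale, c)
        c = np.where(c < config.lod[None, :], 0.0, c)
        rows_v.append(c)
        rows_s.append(subj)
        rows_g.append(groups)
        rows_t.append(np.full(n, f"t{t + 1}"))

    markers = [f"marker_{j + 1:02d}" for j in range(config.n_markers)]
    panel = PanelTable(values=np.vstack(rows_v),
                       subject_id=np.concatenate(rows_s),
                       group=np.concatenate(rows_g),
                       timepoint=np.concatenate(rows_t),
                       markers=markers)
    truth = SyntheticTruth(latent=z, marker_loadings=config.marker_loadings,
                           group_shift=config.group_shift, panel=panel)
    return panel, truth


def default_effect_map(config: GeneratorConfig) -> np.ndarray:
    """Effect block planted inside the synthetic tract."""
    beta = np.zeros(config.grid_shape)
    tract = _tract_mask(config.grid_shape)
    sx, sy, sz = config.grid_shape
    block = (slice(sx // 4, sx // 4 + max(2, sx // 4)),
             slice(sy // 2 - 2, sy // 2 + 2),
             slice(max(0, sz // 2 - 2), sz // 2 + 2))
    beta[block] = config.effect_amplitude
    beta *= tract  # keep the responsive voxels on the tract
    return beta


def _tract_mask(shape) -> np.ndarray:
    """A horizontal slab posing as a high-FA white-matter tract."""
    sx, sy, sz = shape
    tract = np.zeros(shape, dtype=bool)
    z0 = max(0, sz // 2 - max(1, sz // 6))
    z1 = min(sz, sz // 2 + max(1, sz // 6))
    tract[:, sy // 4: 3 * sy // 4, z0:z1] = True
    return tract


def _smooth_noise(rng, shape, sigma_vox, sd):
    """Spatially smoothed Gaussian field rescaled to marginal SD ``sd``."""
    eta = rng.standard_normal(shape)
    if max(sigma_vox) > 0:
        eta = ndimage.gaussian_filter(eta, sigma=sigma_vox)
        s = eta.std()
        if s > 0:
            eta /= s
    return sd * eta


def generate_fa_volumes(config: GeneratorConfig,
                        truth: SyntheticTruth) -> SyntheticTruth:
    """Add per-subject FA volumes FA_i(v) = baseline(v) + beta(v)·z_i + noise.

    The baseline holds one synthetic high-FA tract; noise is Gaussian,
    smoothed to the configured FWHM and rescaled to the requested marginal
    SD; volumes are clipped to [0, 1].  Results (volumes, brain mask,
    tract mask, baseline, effect map) are stored on the returned truth.
    """
    if truth.latent is None:
        raise ValueError("truth.latent must be defined (run generate_panel)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    beta = (config.latent_effect_map if config.latent_effect_map is not None
            else default_effect_map(config))
    tract = _tract_mask(config.grid_shape)
    baseline = np.where(tract, config.baseline_fa_tract,
                        config.baseline_fa_outside).astype(float)
    sigma_vox = tuple(config.fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
                      for v in config.voxel_size_mm)
    vols = np.empty((truth.latent.size,) + config.grid_shape)
    for i, z_i in enumerate(truth.latent):
        eta = _smooth_noise(rng, config.grid_shape, sigma_vox,
                            config.noise_sd_fa)
        vols[i] = np.clip(baseline + beta * z_i + eta, 0.0, 1.0)
    truth.latent_effect_map = beta
    truth.baseline = baseline
    truth.tract_mask = tract
    truth.volumes = vols
    truth.brain_mask = np.ones(config.grid_shape, dtype=bool)
    return truth


def generate_dataset(config: GeneratorConfig) -> SyntheticTruth:
    """Panel plus FA volumes in one call."""
    _, truth = generate_panel(config)
    return generate_fa_volumes(config, truth)


def write_dataset(truth: SyntheticTruth, config: GeneratorConfig,
                  out_dir) -> Path:
    """Write panel CSV, per-subject NIfTI volumes, masks and a truth sidecar.

    Outputs are deterministic for a fixed config (gzip timestamps are
    fixed to zero by the NIfTI writer).
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.panel.to_csv(out / "panel.csv")
    aff = config.affine
    subjects = [f"sub-{i + 1:03d}" for i in range(truth.latent.size)]
    for i, sid in enumerate(subjects):
        img = nib.Nifti1Image(truth.volumes[i].astype(np.float32), aff)
        img.to_filename(out / f"{sid}_fa.nii.gz")
    nib.Nifti1Image(truth.brain_mask.astype(np.int8), aff).to_filename(
        out / "brain_mask.nii.gz")
    nib.Nifti1Image(truth.tract_mask.astype(np.int8), aff).to_filename(
        out / "tract_mask.nii.gz")
    sidecar = {"seed": config.seed,
               "n_group_a": config.n_group_a,
               "n_group_b": config.n_group_b,
               "n_markers": config.n_markers,
               "n_timepoints": config.n_timepoints,
               "grid_shape": list(config.grid_shape),
               "voxel_size_mm": list(config.voxel_size_mm),
               "latent": truth.latent.tolist(),
               "marker_loadings": truth.marker_loadings.tolist(),
               "group_shift": truth.group_shift.tolist(),
               "effect_voxels": int(truth.effect_voxels().sum()),
               "noise_sd_panel": config.noise_sd_panel,
               "noise_sd_fa": config.noise_sd_fa,
               "fwhm_mm": config.fwhm_mm}
    with open(out / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out
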