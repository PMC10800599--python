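"""Voxel-wise GLM of FA on PC scores with permutation/TFCE inference.

Per voxel, FA is regressed on an intercept plus the retained PC scores by
ordinary least squares; per-score t maps and the omnibus F map over the
score columns are the raw statistics.  Family-wise error over voxels is
controlled by sign/row permutation of the outcome (Freedman–Lane with an
intercept-only nuisance, i.e. permuting subject rows of FA against the
scores), enhancing each permuted statistic map with threshold-free
cluster enhancement (or cluster-mass enhancement) and recording the
image-wide maximum; two-tailed t inference enhances the positive and
negated-negative parts separately against a common two-tail null.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._tfce import _CONNECTIVITY_RANK, build_adjacency, tfce_flat

logger = logging.getLogger(__name__)

#: finite stand-in for an infinite statistic at numerically perfect fits
STAT_CAP = 1e6


@dataclass
class VolumeStack:
    """Subject-aligned 3D volumes plus analysis mask."""

    data: np.ndarray                     # (n_subjects, X, Y, Z)
    mask: np.ndarray                     # (X, Y, Z) bool
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be (subjects, X, Y, Z)")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must match volume shape")
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)
            if self.subject_ids.shape != (self.data.shape[0],):
                raise ValueError("one subject id per volume required")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def flat(self) -> np.ndarray:
        """(n_subjects, n_masked_voxels) view of the masked data."""
        return self.data[:, self.mask]

    def unflatten(self, values: np.ndarray) -> np.ndarray:
        out = np.zeros(self.mask.shape, dtype=float)
        out[self.mask] = values
        return out


@dataclass
class Design:
    """Design matrix: intercept column followed by K PC-score columns."""

    X: np.ndarray
    score_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the intercept")
        if n <= p:
            raise ValueError(f"need n > K+1 subjects (n={n}, columns={p})")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("design matrix is rank deficient")
        if not self.score_names:
            self.score_names = [f"PC{k + 1}" for k in range(p - 1)]

    @classmethod
    def from_scores(cls, scores: np.ndarray,
                    score_names: list[str] | None = None) -> "Design":
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[0] == 1 and scores.shape[1] > 1:
            scores = scores.T
        X = np.column_stack([np.ones(scores.shape[0]), scores])
        return cls(X, score_names or [f"PC{k + 1}"
                                      for k in range(scores.shape[1])])

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        """Number of score regressors (excluding intercept)."""
        return self.X.shape[1] - 1

    @property
    def df_resid(self) -> int:
        return self.n - self.k - 1


@dataclass
class TFCEParams:
    """Enhancement parameters (defaults follow the common 3D convention)."""

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 26
    mode: str = "tfce"          # "tfce" (support = extent) or "cluster_mass"

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.mode not in ("tfce", "cluster_mass"):
            raise ValueError("mode must be 'tfce' or 'cluster_mass'")


class _GlmEngine:
    """Vectorised per-voxel OLS for a fixed design, reused across permutations."""

    def __init__(self, X: np.ndarray):
        self.X = X
        self.n, self.p = X.shape
        self.k = self.p - 1
        self.df_resid = self.n - self.p
        xtx_inv = np.linalg.inv(X.T @ X)
        self.pinv = xtx_inv @ X.T
        self.score_var = np.diag(xtx_inv)[1:]

    def stats(self, Y: np.ndarray, want_t: bool, want_f: bool):
        """t maps (k, V) and/or F map (V,) for outcome matrix Y (n, V)."""
        beta = self.pinv @ Y
        resid = Y - self.X @ beta
        rss = np.einsum("ij,ij->j", resid, resid)
        tss = np.einsum("ij,ij->j", Y - Y.mean(axis=0), Y - Y.mean(axis=0))
        sigma2 = rss / self.df_resid
        dead = tss <= 0.0                      # zero FA variance -> stat 0
        perfect = (~dead) & (sigma2 <= 1e-14 * (tss / self.n + 1e-30))
        t_maps = f_map = None
        with np.errstate(divide="ignore", invalid="ignore"):
            if want_t:
                se = np.sqrt(sigma2[None, :] * self.score_var[:, None])
                t_maps = np.where(se > 0, beta[1:] / se, 0.0)
                t_maps = np.clip(t_maps, -STAT_CAP, STAT_CAP)
                t_maps[:, perfect] = np.sign(beta[1:, perfect]) * STAT_CAP
                t_maps[:, dead] = 0.0
            if want_f:
                f_map = np.where(sigma2 > 0,
                                 ((tss - rss) / self.k) / sigma2, 0.0)
                f_map = np.clip(f_map, 0.0, STAT_CAP)
                f_map[perfect] = STAT_CAP
                f_map[dead] = 0.0
        return t_maps, f_map


def fit_glm(volumes: VolumeStack, design: Design):
    """Observed per-score t maps and omnibus F map as 3D arrays.

    Returns ``(t_maps, f_map)`` where ``t_maps`` is a dict keyed by score
    name.  Voxels with no FA variance carry statistic 0; numerically
    perfect fits are capped at ±``STAT_CAP`` rather than reported infinite.
    """
    if volumes.n_subjects != design.n:
        raise ValueError("subject count mismatch between volumes and design")
    if volumes.n_subjects < design.k + 2:
        raise ValueError("need at least K+2 subjects")
    engine = _GlmEngine(design.X)
    t_flat, f_flat = engine.stats(volumes.flat(), want_t=True, want_f=True)
    t_maps = {name: volumes.unflatten(t_flat[i])
              for i, name in enumerate(design.score_names)}
    return t_maps, volumes.unflatten(f_flat)


class _TfceEngine:
    """TFCE over a fixed mask; adjacency built once."""

    def __init__(self, mask: np.ndarray, params: TFCEParams,
                 voxel_volume: float = 1.0):
        self.mask = np.asarray(mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("mask is empty")
        self.params = params
        self.voxel_volume = float(voxel_volume)
        self.indptr, self.indices = build_adjacency(self.mask,
                                                    params.connectivity)

    def enhance_flat(self, stat_flat: np.ndarray) -> np.ndarray:
        return tfce_flat(np.ascontiguousarray(stat_flat, dtype=np.float64),
                         self.indptr, self.indices, self.params.n_steps,
                         self.params.E, self.params.H, self.voxel_volume,
                         self.params.mode == "cluster_mass")


def tfce_enhance(stat_map: np.ndarray, params: TFCEParams | None = None,
                 mask: np.ndarray | None = None,
                 voxel_volume: float = 1.0) -> np.ndarray:
    """Enhance a non-negative 3D statistic map (signs are the caller's job)."""
    params = params or TFCEParams()
    stat_map = np.asarray(stat_map, dtype=float)
    if mask is None:
        mask = np.ones(stat_map.shape, dtype=bool)
    if (stat_map[mask] < 0).any():
        raise ValueError("stat map must be non-negative; enhance each sign "
                         "separately")
    engine = _TfceEngine(mask, params, voxel_volume)
    out = np.zeros(stat_map.shape)
    out[mask] = engine.enhance_flat(stat_map[mask])
    return out


@dataclass
class InferenceResult:
    """Permutation-inference output for one volume stack + design."""

    stat_maps: dict                 # raw 3D maps ("f", "PC1", ...)
    enhanced_maps: dict             # observed enhanced 3D maps (same keys)
    corrp_maps: dict                # FWE-corrected p, 3D (1.0 outside mask)
    null_max: dict                  # per-contrast null max distributions
    sig_mask: np.ndarray            # corrected p < alpha, chosen contrast
    sig_contrast: str
    mask: np.ndarray
    alpha: float
    n_perm: int
    exhaustive: bool
    params: TFCEParams


def _permutations(n: int, n_perm_requested: int, seed):
    """All n! orderings if affordable, else identity + random draws."""
    if math.factorial(n) <= n_perm_requested:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        return perms, True
    rng = np.random.default_rng(seed)
    perms = [np.arange(n)]
    perms.extend(rng.permutation(n) for _ in range(n_perm_requested - 1))
    return perms, False


def permutation_fwe(volumes: VolumeStack, design: Design,
                    params: TFCEParams | None = None,
                    n_perm_requested: int = 10_000, alpha: float = 0.05,
                    seed: int | None = 0,
                    contrast: str = "f") -> InferenceResult:
    """Permutation FWE inference with TFCE and max-statistic correction.

    ``contrast`` selects which null distributions are built: ``"f"`` for
    the omnibus F over the score columns, ``"t"`` for per-score two-tailed
    t, or ``"both"``.  The significant mask is thresholded at
    ``corrected p < alpha`` on the omnibus F when available, else on the
    first t contrast.  Corrected p(v) is the fraction of the P null
    image-wide maxima (identity permutation included) at or above the
    observed enhanced statistic, so the smallest attainable value is 1/P.
    """
    params = params or TFCEParams()
    if contrast not in ("f", "t", "both"):
        raise ValueError("contrast must be 'f', 't' or 'both'")
    if n_perm_requested < 100:
        warnings.warn("fewer than 100 permutations gives very coarse "
                      "p-value granularity", stacklevel=2)
    if not volumes.mask.any():
        raise ValueError("mask is empty")
    if volumes.n_subjects != design.n:
        raise ValueError("subject count mismatch between volumes and design")

    want_f = contrast in ("f", "both")
    want_t = contrast in ("t", "both")
    glm = _GlmEngine(design.X)
    tfce = _TfceEngine(volumes.mask, params, volumes.voxel_volume)
    Y = volumes.flat()
    perms, exhaustive = _permutations(design.n, n_perm_requested, seed)
    P = len(perms)
    logger.info("permutation inference: %d permutations (%s)", P,
                "exhaustive" if exhaustive else "random")

    t_obs, f_obs = glm.stats(Y, want_t=want_t, want_f=want_f)
    obs_enh: dict[str, np.ndarray] = {}
    stat_flat: dict[str, np.ndarray] = {}
    if want_f:
        stat_flat["f"] = f_obs
        obs_enh["f"] = tfce.enhance_flat(f_obs)
    if want_t:
        for i, name in enumerate(design.score_names):
            stat_flat[name] = t_obs[i]
            pos = tfce.enhance_flat(np.maximum(t_obs[i], 0.0))
            neg = tfce.enhance_flat(np.maximum(-t_obs[i], 0.0))
            obs_enh[name] = np.maximum(pos, neg)

    null_max = {key: np.empty(P) for key in obs_enh}
    for pi, perm in enumerate(perms):
        t_p, f_p = glm.stats(Y[perm], want_t=want_t, want_f=want_f)
        if want_f:
            null_max["f"][pi] = tfce.enhance_flat(f_p).max()
        if want_t:
            for i, name in enumerate(design.score_names):
                mx_pos = tfce.enhance_flat(np.maximum(t_p[i], 0.0)).max()
                mx_neg = tfce.enhance_flat(np.maximum(-t_p[i], 0.0)).max()
                null_max[name][pi] = max(mx_pos, mx_neg)

    corrp_flat = {}
    for key, enh in obs_enh.items():
        nm = np.sort(null_max[key])
        # fraction of null maxima >= observed, via searchsorted
        counts = P - np.searchsorted(nm, enh, side="left")
        corrp_flat[key] = counts / P

    sig_key = "f" if want_f else design.score_names[0]
    sig = np.zeros(volumes.mask.shape, dtype=bool)
    sig[volumes.mask] = corrp_flat[sig_key] < alpha

    def _vol(v, fill=0.0):
        out = np.full(volumes.mask.shape, fill)
        out[volumes.mask] = v
        return out

    return InferenceResult(
        stat_maps={k: _vol(v) for k, v in stat_flat.items()},
        enhanced_maps={k: _vol(v) for k, v in obs_enh.items()},
        corrp_maps={k: _vol(v, fill=1.0) for k, v in corrp_flat.items()},
        null_max=null_max, sig_mask=sig, sig_contrast=sig_key,
        mask=volumes.mask, alpha=alpha, n_perm=P, exhaustive=exhaustive,
        params=params)


def extract_rois(sig_mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components of the significant mask, largest first.

    Returns an integer volume with labels 1..n ordered by descending voxel
    count (an empty mask yields an all-zero volume).
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    st = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    lab, n = ndimage.label(sig_mask, structure=st)
    if n == 0:
        return np.zeros(sig_mask.shape, dtype=np.int32)
    sizes = np.bincount(lab.ravel())[1:]
    order = np.argsort(-sizes, kind="stable")
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return relabel[lab]
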