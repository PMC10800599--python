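"""ROI-level principal-component regression with coefficient back-projection.

Mean FA over a significant ROI is regressed on the retained PC scores.
Because each score is a fixed linear combination of the standardised
markers (T = Z W), the fitted score coefficients γ map back to the
original concentration scale as

    β_j = (W γ)_j / sd_j        (per pg/mL of marker j),

with uncertainty propagated linearly through the fixed loading matrix:
Var(β_j) = w_jᵀ Σ_γ w_j / sd_j², Σ_γ = MS_res (T_cᵀ T_c)⁻¹.  The PCA is
treated as fixed (not resampled), so each back-projected coefficient
carries the residual degrees of freedom n − K − 1 of the score
regression.  Model validity is checked by a Shapiro–Wilk normality test
of the residuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pca import PCAModel
from .voxelwise import VolumeStack


def extract_roi_fa(volumes: VolumeStack, roi_mask: np.ndarray,
                   summary: str = "mean") -> np.ndarray:
    """Per-subject summary FA (mean by default, median behind a flag)."""
    roi = np.asarray(roi_mask).astype(bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    if roi.shape != volumes.mask.shape:
        raise ValueError("ROI shape must match the volume grid")
    vals = volumes.data[:, roi]
    if summary == "mean":
        return vals.mean(axis=1)
    if summary == "median":
        return np.median(vals, axis=1)
    raise ValueError("summary must be 'mean' or 'median'")


def shapiro_wilk(residuals) -> dict:
    """Shapiro–Wilk W and p (Royston AS R94, via scipy)."""
    r = np.asarray(residuals, dtype=float)
    if not 3 <= r.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(r) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant residuals")
    w, p = stats.shapiro(r)
    return {"W": float(w), "p": float(p), "passed": bool(p > 0.05)}


def f_to_r2(F: float, df_n: int, df_d: int) -> dict:
    """R², adjusted R² and upper-tail p implied by an ANOVA F statistic.

    R² = F·df_n/(F·df_n + df_d); adjusted R² = 1 − (1−R²)(df_n+df_d)/df_d.
    Useful for validating a reported ANOVA table from its printed F and
    degrees of freedom alone.
    """
    if F < 0 or df_n < 1 or df_d < 1:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    r2 = F * df_n / (F * df_n + df_d)
    adj = 1.0 - (1.0 - r2) * (df_n + df_d) / df_d
    p = float(stats.f.sf(F, df_n, df_d))
    return {"r_squared": r2, "adjusted_r_squared": adj, "p": p}


@dataclass
class PCRResult:
    """ANOVA table, fit statistics and back-projected marker coefficients."""

    anova: dict               # SS/DF/MS/F/p blocks
    r_squared: float
    adjusted_r_squared: float
    intercept: float          # concentration-scale intercept
    intercept_se: float
    gamma: np.ndarray         # PC-score coefficients
    gamma_cov: np.ndarray
    coefficients: pd.DataFrame   # per-marker beta/se/|t|/p/CI
    shapiro: dict
    df_num: int
    df_den: int
    degenerate: bool = False  # perfect fit (zero residual SS)

    def predict_from_scores(self, scores: np.ndarray) -> np.ndarray:
        a = self.anova["intercept_scores"]
        return a + np.asarray(scores) @ self.gamma

    def predict_from_concentrations(self, X: np.ndarray) -> np.ndarray:
        beta = self.coefficients["beta"].to_numpy()
        return self.intercept + np.asarray(X) @ beta

    def to_json(self, path) -> None:
        obj = {"anova": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in self.anova.items()},
               "r_squared": self.r_squared,
               "adjusted_r_squared": self.adjusted_r_squared,
               "intercept": self.intercept,
               "intercept_se": self.intercept_se,
               "gamma": self.gamma.tolist(),
               "gamma_cov": self.gamma_cov.tolist(),
               "coefficients": self.coefficients.to_dict(orient="list"),
               "shapiro": self.shapiro,
               "df": [self.df_num, self.df_den],
               "degenerate": self.degenerate}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    def summary(self) -> str:
        a = self.anova
        lines = [
            "Analysis of Variance",
            f"  Regression  SS={a['ss_regression']:.6g}  DF={self.df_num}  "
            f"MS={a['ms_regression']:.6g}  F({self.df_num},{self.df_den})="
            f"{a['F']:.4g}  P={a['p']:.4g}",
            f"  Residual    SS={a['ss_residual']:.6g}  DF={self.df_den}  "
            f"MS={a['ms_residual']:.6g}",
            f"  Total       SS={a['ss_total']:.6g}  DF={self.df_num + self.df_den}",
            f"R squared = {self.r_squared:.4f}   "
            f"Adjusted R squared = {self.adjusted_r_squared:.4f}",
            f"Normality of residuals: Shapiro-Wilk W={self.shapiro['W']:.4f} "
            f"P={self.shapiro['p']:.4g}  "
            f"passed (alpha=0.05)? {'Yes' if self.shapiro['passed'] else 'No'}",
            "Parameter estimates (back-projected to biomarkers):",
        ]
        lines.append(self.coefficients.to_string(index=False,
                                                 float_format="%.5g"))
        return "\n".join(lines)


def pcr_fit(y, model: PCAModel, alpha_ci: float = 0.05) -> PCRResult:
    """OLS of an ROI FA summary on the model's PC scores, with back-projection.

    ``y`` must be aligned to the subjects whose scores are stored on the
    fitted PCA model.  Raises on constant y (zero total sum of squares).
    """
    y = np.asarray(y, dtype=float)
    T = model.scores
    n, K = T.shape
    if y.shape != (n,):
        raise ValueError(f"y must have {n} entries matching the PCA scores")
    if n <= K + 1:
        raise ValueError("need n > K+1 subjects for the score regression")
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total <= 0:
        raise ValueError("ROI FA is constant: zero total sum of squares")

    X = np.column_stack([np.ones(n), T])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_reg = ss_total - ss_res
    df_num, df_den = K, n - K - 1
    ms_reg = ss_reg / df_num
    ms_res = ss_res / df_den
    degenerate = ms_res <= 1e-12 * ss_total
    F = ms_reg / ms_res if not degenerate else np.inf
    p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    r2 = ss_reg / ss_total
    adj = 1.0 - (1.0 - r2) * (n - 1) / df_den

    gamma = coef[1:]
    Tc = T - T.mean(axis=0)
    gamma_cov = ms_res * np.linalg.inv(Tc.T @ Tc)

    W = model.loadings
    b_std = W @ gamma
    beta = b_std / model.sds
    var_beta = np.einsum("jk,kl,jl->j", W, gamma_cov, W) / model.sds ** 2
    se = np.sqrt(np.maximum(var_beta, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, np.abs(beta) / se, np.inf)
    pvals = 2.0 * stats.t.sf(tvals, df_den)
    tcrit = stats.t.ppf(1.0 - alpha_ci / 2.0, df_den)
    coef_table = pd.DataFrame({
        "marker": model.markers,
        "beta": beta,
        "se": se,
        "abs_t": tvals,
        "p": pvals,
        "ci_low": beta - tcrit * se,
        "ci_high": beta + tcrit * se,
    })

    # concentration-scale intercept: a - sum_j beta_j * mean_j
    a = coef[0]
    intercept = float(a - beta @ model.means)
    v = W.T @ (model.means / model.sds)
    var_intercept = ms_res / n + float(v @ gamma_cov @ v)
    intercept_se = float(np.sqrt(max(var_intercept, 0.0)))

    shapiro = shapiro_wilk(resid) if not degenerate else \
        {"W": np.nan, "p": np.nan, "passed": False}

    anova = {"ss_regression": ss_reg, "ss_residual": ss_res,
             "ss_total": ss_total, "ms_regression": ms_reg,
             "ms_residual": ms_res, "F": F, "p": p,
             "intercept_scores": float(a)}
    return PCRResult(anova=anova, r_squared=r2, adjusted_r_squared=adj,
                     intercept=intercept, intercept_se=intercept_se,
                     gamma=gamma, gamma_cov=gamma_cov,
                     coefficients=coef_table, shapiro=shapiro,
                     df_num=df_num, df_den=df_den, degenerate=degenerate)
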