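"""Standardised PCA of a biomarker panel, as the low-dimensional predictor set.

Each marker is centred to mean zero and scaled to unit sample standard
deviation (n−1 divisor) so that the decomposition acts on the sample
correlation matrix and its eigenvalues sum to the number of retained
markers; the proportion of variance carried by component k is then
λ_k / m.  At most ``max_components`` (default 3) components are kept to
limit over-fitting at the small per-group sample sizes these panels have.
Below-LOD zeros participate in the standardisation as 0 pg/mL.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelTable

_RANK_TOL = 1e-10


@dataclass
class PCAModel:
    """Fitted standardise-then-PCA model.

    ``loadings`` has orthonormal columns (markers × K); ``eigenvalues``
    holds the full descending spectrum of the correlation matrix while
    ``scores`` and ``loadings`` are truncated to the K retained
    components.  ``dropped`` lists zero-variance markers excluded from the
    decomposition.
    """

    markers: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # (m, K), orthonormal columns
    eigenvalues: np.ndarray       # full spectrum, descending
    scores: np.ndarray            # (n, K)
    dropped: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def m(self) -> int:
        """Number of markers entering the decomposition."""
        return len(self.markers)

    @property
    def proportions(self) -> np.ndarray:
        """Proportion of total variance per component, λ_k / m."""
        return self.eigenvalues / self.m

    def summary(self) -> pd.DataFrame:
        """Eigenvalue / % variance / cumulative % table for the retained PCs."""
        k = self.n_components
        lam = self.eigenvalues[:k]
        pct = 100.0 * lam / self.m
        return pd.DataFrame(
            {f"PC{i + 1}": [lam[i], pct[i], pct[: i + 1].sum()]
             for i in range(k)},
            index=["Eigenvalue", "Proportion of variance (%)",
                   "Cumulative proportion of variance (%)"])

    def to_json(self, path) -> None:
        obj = {"markers": self.markers,
               "means": self.means.tolist(),
               "sds": self.sds.tolist(),
               "loadings": self.loadings.tolist(),
               "eigenvalues": self.eigenvalues.tolist(),
               "scores": self.scores.tolist(),
               "dropped": self.dropped}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(markers=obj["markers"],
                   means=np.asarray(obj["means"]),
                   sds=np.asarray(obj["sds"]),
                   loadings=np.asarray(obj["loadings"]),
                   eigenvalues=np.asarray(obj["eigenvalues"]),
                   scores=np.asarray(obj["scores"]),
                   dropped=list(obj["dropped"]))


def standardize(panel: PanelTable | np.ndarray, markers: list[str] | None = None):
    """Centre/scale each marker to mean 0, sample SD 1 (n−1 divisor).

    Zero-variance markers are dropped with a warning.  Returns
    ``(Z, means, sds, kept_markers, dropped_markers)``.
    """
    if isinstance(panel, PanelTable):
        X = panel.values
        markers = list(panel.markers)
    else:
        X = np.asarray(panel, dtype=float)
        markers = list(markers) if markers is not None \
            else [f"m{j}" for j in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("standardisation needs at least 2 subjects")

    sds_all = X.std(axis=0, ddof=1)
    keep = sds_all > 0
    dropped = [m for m, k in zip(markers, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance markers: {dropped}",
                      stacklevel=2)
    if not keep.any():
        raise ValueError("all markers have zero variance")
    kept = [m for m, k in zip(markers, keep) if k]
    Xk = X[:, keep]
    means = Xk.mean(axis=0)
    sds = sds_all[keep]
    Z = (Xk - means) / sds
    return Z, means, sds, kept, dropped


def fit_pca(Z: np.ndarray, max_components: int = 3, *,
            markers: list[str] | None = None,
            means: np.ndarray | None = None,
            sds: np.ndarray | None = None,
            dropped: list[str] | None = None) -> PCAModel:
    """PCA of an already standardised matrix via SVD of Z/√(n−1).

    Keeps K = min(max_components, rank) components.  The sign of each
    loading column is fixed so its largest-magnitude entry is positive,
    making the decomposition deterministic.
    """
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 subjects")
    U, s, Vt = np.linalg.svd(Z / np.sqrt(n - 1), full_matrices=False)
    lam = s ** 2
    rank = int(np.sum(lam > _RANK_TOL * max(lam[0], 1.0)))
    K = min(max_components, rank)
    W = Vt[:K].T
    # deterministic sign: largest-|loading| entry of each column positive
    for k in range(K):
        j = np.argmax(np.abs(W[:, k]))
        if W[j, k] < 0:
            W[:, k] = -W[:, k]
    eig = np.zeros(m)
    eig[: lam.size] = lam
    return PCAModel(markers=markers if markers is not None
                    else [f"m{j}" for j in range(m)],
                    means=means if means is not None else np.zeros(m),
                    sds=sds if sds is not None else np.ones(m),
                    loadings=W, eigenvalues=eig, scores=Z @ W,
                    dropped=list(dropped or []))


def fit(panel: PanelTable, max_components: int = 3) -> PCAModel:
    """Standardise a panel and fit the PCA in one step."""
    Z, means, sds, kept, dropped = standardize(panel)
    return fit_pca(Z, max_components, markers=kept, means=means, sds=sds,
                   dropped=dropped)


def transform(model: PCAModel, panel: PanelTable | np.ndarray) -> np.ndarray:
    """Score new subjects with a fitted model."""
    if isinstance(panel, PanelTable):
        missing = [m for m in model.markers if m not in panel.markers]
        if missing:
            raise ValueError(f"panel lacks fitted markers: {missing}")
        cols = [panel.markers.index(m) for m in model.markers]
        X = panel.values[:, cols]
    else:
        X = np.asarray(panel, dtype=float)
        if X.shape[1] != model.m:
            raise ValueError(f"expected {model.m} marker columns, "
                             f"got {X.shape[1]}")
    Z = (X - model.means) / model.sds
    return Z @ model.loadings
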