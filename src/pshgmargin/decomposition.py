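"""Standardization, PCA and data-subset selection for the feature table.

The 36 features live on incommensurable scales (counts, dimensionless
ratios, bits), so each column is standardized to zero mean and unit SD
before PCA.  PCA is an eigendecomposition of the covariance matrix of the
standardized data; with unit-variance columns the eigenvalues sum to the
number of features, and the Kaiser criterion retains components whose
eigenvalue is at least 1 (they carry more variance than any single original
feature).

The clustering stage consumes eight data subsets: feature groups

    INT      SHG-intensity mean/MAD + pixel density
    INT+TXT  INT plus the SHG-intensity texture features
    POL      mean/MAD of all five polarimetric parameters + pixel density
    ALL      all 36 features

and the single-column score of each retained principal component (PC1–PC4
in the default configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .texture import STATS, feature_columns

PARAMS = ("shg", "rratio", "dcp", "shgcd", "shgld")

SUBSET_NAMES = ("INT", "INT+TXT", "POL", "ALL", "PC1", "PC2", "PC3", "PC4")


@dataclass
class StandardizationModel:
    """Fitted per-feature location/scale (SD with ddof=1)."""

    columns: list[str]
    mean: np.ndarray
    std: np.ndarray

    def apply(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.columns].to_numpy(dtype=float)
        return (x - self.mean) / self.std


@dataclass
class PCAModel:
    """Eigendecomposition of the covariance matrix of standardized data.

    ``loadings[:, k]`` is the (orthonormal) loading vector of PC k+1, signed
    so its largest-magnitude entry is positive; ``scores[:, k]`` the per-row
    scores.  Eigenvalues are sorted descending.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained: np.ndarray
    columns: list[str]

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)

    def to_json_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained.tolist(),
        }


def standardize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[np.ndarray, StandardizationModel, pd.Index]:
    """Zero-mean/unit-SD matrix from the feature table.

    Rows containing non-finite feature values (tiles with undefined
    textures) are dropped; the surviving row index is returned so grid
    placement can be recovered.  A zero-variance column raises.
    """
    columns = list(columns) if columns is not None else feature_columns()
    x = table[columns].to_numpy(dtype=float)
    keep = np.all(np.isfinite(x), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} rows with undefined features")
    x = x[keep]
    if x.shape[0] < 2:
        raise ValueError("standardization needs at least 2 complete rows")
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    zero = std == 0
    if np.any(zero):
        raise ValueError(
            f"zero-variance feature column(s): {[c for c, z in zip(columns, zero) if z]}"
        )
    model = StandardizationModel(columns=columns, mean=mean, std=std)
    return (x - mean) / std, model, table.index[keep]


def run_pca(z: np.ndarray, columns: list[str] | None = None) -> PCAModel:
    """PCA by eigendecomposition of the sample covariance (ddof=1).

    Deterministic sign convention: each loading vector is flipped, if
    needed, so that its largest-|.| entry is positive.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("PCA input contains non-finite values")
    n, p = z.shape
    if n <= p:
        warnings.warn(f"PCA with n={n} rows <= p={p} features: eigenvalues rank-deficient")
    cov = np.cov(z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    for k in range(p):
        if eigvecs[np.argmax(np.abs(eigvecs[:, k])), k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    scores = z @ eigvecs
    total = eigvals.sum()
    explained = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAModel(
        eigenvalues=eigvals,
        loadings=eigvecs,
        scores=scores,
        explained=explained,
        columns=list(columns) if columns is not None else feature_columns(),
    )


def kaiser_retain(model: PCAModel) -> list[int]:
    """0-based indices of PCs with eigenvalue >= 1 (inclusive boundary)."""
    retained = [int(k) for k, lam in enumerate(model.eigenvalues) if lam >= 1.0]
    if not retained:
        warnings.warn("Kaiser criterion retains no components (all eigenvalues < 1)")
    return retained


def subset_columns(name: str) -> list[str]:
    """Feature-column membership of the non-PC subsets."""
    if name == "INT":
        return ["shg_mean", "shg_mad", "pixel_density"]
    if name == "INT+TXT":
        return ["shg_mean", "shg_mad", "pixel_density"] + [
            f"shg_{s}" for s in STATS if s not in ("mean", "mad")
        ]
    if name == "POL":
        return [f"{p}_{s}" for p in PARAMS for s in ("mean", "mad")] + ["pixel_density"]
    if name == "ALL":
        return feature_columns()
    raise ValueError(f"unknown subset identifier {name!r}")


def select_subset(
    table: pd.DataFrame,
    model: PCAModel | None,
    name: str,
    rows: pd.Index | None = None,
) -> np.ndarray:
    """Matrix for clustering: feature columns (raw) or a single PC score column.

    ``rows`` restricts the table to the rows that survived standardization
    (PC scores are aligned to those rows already).
    """
    if name.startswith("PC"):
        if model is None:
            raise ValueError("a PCAModel is required for PC subsets")
        k = int(name[2:]) - 1
        if not 0 <= k < model.scores.shape[1]:
            raise ValueError(f"{name} out of range for {model.scores.shape[1]} components")
        return model.scores[:, [k]]
    cols = subset_columns(name)
    sub = table if rows is None else table.loc[rows]
    return sub[cols].to_numpy(dtype=float)
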