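"""Binary K-Means with silhouette-weighted continuous cluster maps.

K-Means with k = 2 partitions the sub-images; per-point silhouette scores
S in [-1, 1] grade the assignment.  Label indices from K-Means are
arbitrary, so labels are canonicalized: cluster 1 is the cluster with the
higher mean pixel density (normal-like collagen), making the tumor/normal
reading of downstream maps reproducible.

The binary label B and silhouette S are fused into a continuous cluster
association

    C = B + (1 - S)/2   if B = 1
    C = B - (1 - S)/2   if B = 2

ranging over [1, 2]: 1 and 2 mean perfect association with clusters 1 and
2, the inter-cluster boundary sits at 1.5, and a negative silhouette pushes
a point past 1.5 toward the opposite cluster.  Rendered on the sub-image
grid, C maps are median-filtered (3x3, NaN-preserving) and summarized by
per-column vertical profiles.

Subsets are compared by the harmonic mean H = N / sum(1/x_i) of the two
per-cluster mean silhouettes: unlike the arithmetic mean it punishes a
degenerate solution in which one cluster scores well only because the other
absorbed nearly everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from . import decomposition
from .decomposition import PCAModel, select_subset

KMEANS_RESTARTS = 50


@dataclass
class ClusterResult:
    """Binary labels, silhouettes and continuous association of one subset."""

    labels: np.ndarray  # B in {1, 2}
    silhouette: np.ndarray  # S in [-1, 1]
    association: np.ndarray  # C in [1, 2]
    grid_row: np.ndarray
    grid_col: np.ndarray

    def to_grid(self, n_rows: int, n_cols: int, filtered: bool = False) -> np.ndarray:
        """Render C on the sub-image grid; absent tiles are NaN."""
        g = np.full((n_rows, n_cols), np.nan)
        g[self.grid_row, self.grid_col] = self.association
        return median_filter_map(g) if filtered else g


def kmeans_binary(
    matrix: np.ndarray, seed: int, pixel_density: np.ndarray | None = None
) -> np.ndarray:
    """k=2 K-Means labels in {1, 2}, canonicalized by mean pixel density.

    With ``pixel_density`` given, the cluster whose members have the higher
    mean density becomes cluster 1; ties (or no densities) fall back to the
    cluster containing row 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("K-Means needs a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("K-Means input contains non-finite values")
    km = KMeans(n_clusters=2, n_init=KMEANS_RESTARTS, random_state=seed)
    raw = km.fit_predict(matrix)
    if pixel_density is not None:
        d0 = pixel_density[raw == 0].mean()
        d1 = pixel_density[raw == 1].mean()
        cluster_one = 0 if d0 > d1 else 1 if d1 > d0 else raw[0]
    else:
        cluster_one = raw[0]
    return np.where(raw == cluster_one, 1, 2)


def silhouette_map(matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Euclidean per-point silhouette scores (singleton cluster -> 0)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires two non-empty clusters")
    return silhouette_samples(np.asarray(matrix, dtype=float), labels)


def continuous_association(labels: np.ndarray, silhouette: np.ndarray) -> np.ndarray:
    """Fuse binary labels and silhouettes into C in [1, 2]."""
    b = np.asarray(labels)
    s = np.asarray(silhouette, dtype=float)
    if not np.all(np.isin(b, (1, 2))):
        raise ValueError("binary labels must be 1 or 2")
    if np.any(s < -1) or np.any(s > 1):
        raise ValueError("silhouette scores must lie in [-1, 1]")
    return np.where(b == 1, b + 0.5 * (1 - s), b - 0.5 * (1 - s))


def median_filter_map(grid: np.ndarray) -> np.ndarray:
    """3x3 neighborhood median over present values; NaN cells stay NaN.

    Border cells use their available neighbors only (no padding values are
    invented).
    """
    grid = np.asarray(grid, dtype=float)
    out = np.full_like(grid, np.nan)
    n_rows, n_cols = grid.shape
    for r in range(n_rows):
        for c in range(n_cols):
            if np.isnan(grid[r, c]):
                continue
            window = grid[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
            out[r, c] = np.nanmedian(window)
    return out


def vertical_profile(grid: np.ndarray) -> np.ndarray:
    """Per-column mean of present values; all-missing columns stay NaN."""
    grid = np.asarray(grid, dtype=float)
    out = np.full(grid.shape[1], np.nan)
    for c in range(grid.shape[1]):
        col = grid[:, c]
        if np.any(np.isfinite(col)):
            out[c] = np.nanmean(col)
    return out


def harmonic_mean(values) -> float:
    """H = N / sum(1/x_i); requires strictly positive inputs."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("harmonic mean of an empty set")
    if np.any(x <= 0):
        raise ValueError("harmonic mean requires strictly positive values")
    return float(x.size / np.sum(1.0 / x))


def cluster_subset(
    table: pd.DataFrame,
    model: PCAModel | None,
    subset: str,
    seed: int,
    rows: pd.Index | None = None,
    standardize_features: bool = True,
) -> ClusterResult:
    """Run the full clustering stage on one data subset.

    Non-PC subsets are standardized column-wise before K-Means (PC scores
    are used as-is), consistent with the standardization applied ahead of
    PCA.
    """
    matrix = select_subset(table, model, subset, rows=rows)
    if standardize_features and not subset.startswith("PC"):
        mean = matrix.mean(axis=0)
        std = matrix.std(axis=0, ddof=1)
        std[std == 0] = 1.0
        matrix = (matrix - mean) / std
    sub = table if rows is None else table.loc[rows]
    density = sub["pixel_density"].to_numpy(dtype=float)
    labels = kmeans_binary(matrix, seed=seed, pixel_density=density)
    sil = silhouette_map(matrix, labels)
    return ClusterResult(
        labels=labels,
        silhouette=sil,
        association=continuous_association(labels, sil),
        grid_row=sub["grid_row"].to_numpy(dtype=int),
        grid_col=sub["grid_col"].to_numpy(dtype=int),
    )


def compare_subsets(
    table: pd.DataFrame,
    model: PCAModel | None,
    subsets: tuple[str, ...] = decomposition.SUBSET_NAMES,
    seed: int = 0,
    rows: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-subset cluster silhouettes with arithmetic and harmonic means.

    The harmonic mean is taken over the two per-cluster mean silhouettes;
    subsets where a cluster mean is non-positive get H = NaN (undefined) and
    cannot be flagged best.  The subset(s) with maximal H are marked in the
    ``best`` column.
    """
    records = []
    for name in subsets:
        res = cluster_subset(table, model, name, seed=seed, rows=rows)
        m1 = float(res.silhouette[res.labels == 1].mean())
        m2 = float(res.silhouette[res.labels == 2].mean())
        arith = 0.5 * (m1 + m2)
        try:
            harm = harmonic_mean([m1, m2])
        except ValueError:
            harm = float("nan")
        records.append(
            {
                "subset": name,
                "cluster1_mean_silhouette": m1,
                "cluster2_mean_silhouette": m2,
                "arithmetic_mean": arith,
                "harmonic_mean": harm,
            }
        )
    df = pd.DataFrame(records)
    hmax = df["harmonic_mean"].max()
    df["best"] = np.isfinite(df["harmonic_mean"]) & (df["harmonic_mean"] == hmax)
    return df
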