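"""Tumor-margin scoring against a ground-truth tumor/normal partition.

Given a continuous cluster-association map C (1 = cluster 1, 2 = cluster 2,
1.5 = no association) and a per-tile ground truth (tumor left of a
boundary, normal right), the silhouette-weighted occupancy of cluster a in
region r is

    Q_{a,r} = sum_{i in cluster a, region r} |C_i - 1.5|
              / sum_{j in region r} |C_j - 1.5|

where effective cluster membership is decided by C itself (C < 1.5 ->
cluster 1, C > 1.5 -> cluster 2), so points whose negative silhouette moved
them past the boundary count toward the opposite cluster.  Per region,
Q_{1,r} + Q_{2,r} = 1.

A good margin detector has one cluster dominating each side and swapping
across the boundary.  Both requirements are condensed into the inter/
intra-cluster occupancy difference

    IIOD = |Q_{1,L}-Q_{2,L}| |Q_{1,R}-Q_{2,R}| |Q_{1,L}-Q_{1,R}| |Q_{2,L}-Q_{2,R}|

which is 1 when each cluster is confined to one side and 0 when occupancies
are even or a single cluster covers everything.  Data subsets are ranked by
IIOD; the winner's vertical profile localizes the boundary.

The module also implements the loading-transfer validation: the loading
vector of a reference region's principal component is applied to a new
region's (standardized) feature table to produce a single projected score
column for clustering there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterResult, median_filter_map, vertical_profile
from .decomposition import PCAModel, StandardizationModel
from .phantom import EXCLUDED, NORMAL, TUMOR
from .texture import SubImageGrid


@dataclass
class GroundTruth:
    """Per-tile region labels on the sub-image grid ({EXCLUDED, TUMOR, NORMAL})."""

    tile_labels: np.ndarray
    boundary_column: float | None = None  # in sub-image columns, if known

    @property
    def n_rows(self) -> int:
        return self.tile_labels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.tile_labels.shape[1]


@dataclass
class MarginReport:
    """Per-subset occupancies, IIOD and boundary estimates; best = argmax IIOD."""

    table: pd.DataFrame
    best_subset: str


def rasterize_ground_truth(
    source: np.ndarray | int, grid: SubImageGrid, image_shape: tuple[int, int] | None = None
) -> GroundTruth:
    """Per-tile labels from a pixel label raster or a boundary column.

    With a pixel raster, each tile takes its majority pixel label; ties are
    excluded (no class is fabricated on the boundary).  With an integer
    boundary column (pixels), tiles are labelled analytically.
    """
    if np.isscalar(source):
        bc = int(source)
        if image_shape is None:
            image_shape = (grid.n_rows * grid.tile_size, grid.n_cols * grid.tile_size)
        raster = np.full(image_shape, NORMAL, dtype=np.uint8)
        raster[:, :bc] = TUMOR
    else:
        raster = np.asarray(source)
        bc = None
    h, w = raster.shape
    if (grid.n_rows * grid.tile_size, grid.n_cols * grid.tile_size) != (h, w):
        raise ValueError("label raster geometry does not match the grid")
    tiles = np.empty((grid.n_rows, grid.n_cols), dtype=np.uint8)
    for r, c in grid.tiles():
        counts = np.bincount(raster[grid.bounds(r, c)].ravel(), minlength=3)
        best = int(np.argmax(counts))
        tiles[r, c] = EXCLUDED if np.sum(counts == counts[best]) > 1 else best
    return GroundTruth(
        tile_labels=tiles,
        boundary_column=None if bc is None else bc / grid.tile_size,
    )


def occupancies(c_values: np.ndarray, region_mask: np.ndarray) -> tuple[float, float]:
    """(Q_1, Q_2) of one region; NaN if the region carries no weight."""
    c = np.asarray(c_values, dtype=float)[np.asarray(region_mask, dtype=bool)]
    c = c[np.isfinite(c)]
    w = np.abs(c - 1.5)
    total = w.sum()
    if c.size == 0 or total == 0:
        return float("nan"), float("nan")
    q1 = float(w[c < 1.5].sum() / total)
    return q1, 1.0 - q1


def cluster_occupancy(
    c_values: np.ndarray, region_mask: np.ndarray, cluster: int
) -> float:
    """Q_{a,r} for one cluster (1 or 2) in one region."""
    if cluster not in (1, 2):
        raise ValueError("cluster must be 1 or 2")
    q1, q2 = occupancies(c_values, region_mask)
    return q1 if cluster == 1 else q2


def iiod(q1l: float, q2l: float, q1r: float, q2r: float) -> float:
    """Product of the four absolute occupancy differences; in [0, 1]."""
    qs = (q1l, q2l, q1r, q2r)
    if any(not np.isfinite(q) for q in qs):
        return float("nan")
    return float(
        abs(q1l - q2l) * abs(q1r - q2r) * abs(q1l - q1r) * abs(q2l - q2r)
    )


def estimate_boundary_column(c_grid: np.ndarray) -> float:
    """Boundary position (in sub-image columns) from a continuous map.

    The median-filtered map is averaged into a vertical profile and the
    boundary is taken as the column split maximising the absolute
    left/right mean difference; if the profile straddles 1.5 at the split,
    the crossing is refined by linear interpolation.  Returns the number of
    columns left of the boundary (a float), or NaN when no split exists.
    """
    profile = vertical_profile(median_filter_map(np.asarray(c_grid, dtype=float)))
    cols = np.where(np.isfinite(profile))[0]
    if cols.size < 2:
        return float("nan")
    p = profile[cols]
    best_t, best_gap = None, -np.inf
    for t in range(1, p.size):
        gap = abs(p[:t].mean() - p[t:].mean())
        if gap > best_gap:
            best_t, best_gap = t, gap
    left, right = p[best_t - 1], p[best_t]
    split = cols[best_t]  # first column right of the split
    if (left - 1.5) * (right - 1.5) < 0:
        frac = (1.5 - left) / (right - left)  # in (0, 1)
        return float(cols[best_t - 1] + 0.5 + frac * (split - cols[best_t - 1]))
    return float(split)


def transfer_pc_projection(
    model: PCAModel,
    std_model: StandardizationModel,
    pc_index: int,
    new_table: pd.DataFrame,
    use_reference_stats: bool = False,
) -> np.ndarray:
    """Project a new region's features onto a stored PC loading vector.

    ``pc_index`` is 0-based.  The new table is standardized with its own
    column statistics by default; ``use_reference_stats=True`` uses the
    stored reference means/SDs instead.  Returns a (n, 1) score column.
    """
    missing = [c for c in std_model.columns if c not in new_table.columns]
    if missing:
        raise ValueError(f"new table lacks feature columns: {missing}")
    x = new_table[std_model.columns].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("new table contains non-finite features; drop those rows first")
    if use_reference_stats:
        z = (x - std_model.mean) / std_model.std
    else:
        mean = x.mean(axis=0)
        std = x.std(axis=0, ddof=1)
        std[std == 0] = 1.0
        z = (x - mean) / std
    return (z @ model.loadings[:, pc_index])[:, None]


def build_margin_report(
    results: dict[str, ClusterResult], truth: GroundTruth
) -> MarginReport:
    """Occupancy table, IIOD and boundary estimate per subset.

    All subset results must live on the same sub-image grid as ``truth``.
    The best subset is the IIOD argmax; ties resolve to the earliest subset
    in insertion order.
    """
    records = []
    for name, res in results.items():
        c_grid = res.to_grid(truth.n_rows, truth.n_cols)
        tumor = truth.tile_labels == TUMOR
        normal = truth.tile_labels == NORMAL
        q1l, q2l = occupancies(c_grid[tumor], np.ones(int(tumor.sum()), dtype=bool))
        q1r, q2r = occupancies(c_grid[normal], np.ones(int(normal.sum()), dtype=bool))
        records.append(
            {
                "subset": name,
                "Q1_left": q1l,
                "Q2_left": q2l,
                "Q1_right": q1r,
                "Q2_right": q2r,
                "iiod": iiod(q1l, q2l, q1r, q2r),
                "boundary_estimate": estimate_boundary_column(c_grid),
            }
        )
    df = pd.DataFrame(records)
    finite = df["iiod"].to_numpy(dtype=float)
    if np.all(~np.isfinite(finite)):
        raise ValueError("IIOD undefined for every subset (no region weight)")
    best_idx = int(np.nanargmax(finite))
    df["best"] = False
    df.loc[best_idx, "best"] = True
    return MarginReport(table=df, best_subset=str(df.loc[best_idx, "subset"]))
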