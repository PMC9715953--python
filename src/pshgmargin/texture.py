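"""Sub-image texture analysis of polarimetric parameter maps.

Each parameter map is tiled into square sub-images (128 x 128 px by default),
and per tile five Haralick features are computed from an angle-averaged,
symmetric grey-level co-occurrence matrix (GLCM) at distance d = 1 over the
four directions {0, 45, 90, 135} degrees:

    contrast     nu  = sum (i-j)^2 P(i,j)
    correlation  rho = sum P(i,j) (i-mu)(j-mu) / sigma^2
    entropy      S   = -sum P log2 P              (over nonzero entries)
    ASM              = sum P(i,j)^2
    IDM              = sum P(i,j) / (1 + (i-j)^2)

with mu, sigma the marginal grey-level mean/SD of the symmetric GLCM.  The
correlation is signed so that a perfectly positively correlated image gives
+1 and a perfectly anti-correlated one -1.

Background pixels (below the SNR threshold, or where a parameter is
undefined) are removed from the analysis: any pixel pair with at least one
background member is excluded from the co-occurrence counts.  The per-angle
count matrices are averaged first and then normalized to a probability
matrix.

Alongside the five textures, the per-tile mean, mean absolute deviation
(MAD, about the mean) and pixel density (fraction of valid pixels) are
computed.  For five parameter maps this yields the 36-column feature table
(pixel density + 5 parameters x {mean, MAD, contrast, correlation, entropy,
ASM, IDM}) consumed by the decomposition and clustering stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

from .polarimetry import PolarimetricMaps

#: feature-statistic order within the table
STATS = ("mean", "mad", "contrast", "correlation", "entropy", "asm", "idm")

#: GLCM directions in degrees (d = 1)
ANGLES = (0.0, 45.0, 90.0, 135.0)

DEFAULT_N_LEVELS = 64


@dataclass
class SubImageGrid:
    """Disjoint tiling of a mosaic into tile_size x tile_size sub-images."""

    tile_size: int
    n_rows: int
    n_cols: int

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def bounds(self, row: int, col: int) -> tuple[slice, slice]:
        t = self.tile_size
        return slice(row * t, (row + 1) * t), slice(col * t, (col + 1) * t)

    def tiles(self):
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield r, c


@dataclass
class GLCM:
    """Angle-averaged normalized co-occurrence matrix.

    ``matrix`` sums to 1 when any valid pair exists; ``empty`` flags tiles
    with no valid pixel pair in any direction.
    """

    matrix: np.ndarray
    n_levels: int
    n_pairs: float
    empty: bool


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float
    entropy: float
    asm: float
    idm: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.contrast, self.correlation, self.entropy, self.asm, self.idm)


def tile_grid(height: int, width: int, tile_size: int) -> SubImageGrid:
    """Tile an image into a full cover of square sub-images (no partial tiles)."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if height % tile_size or width % tile_size:
        raise ValueError(
            f"tile_size {tile_size} does not divide image dimensions "
            f"{height} x {width}"
        )
    return SubImageGrid(tile_size, height // tile_size, width // tile_size)


def quantize(
    values: np.ndarray,
    valid: np.ndarray,
    n_levels: int,
    vrange: tuple[float, float],
) -> np.ndarray:
    """Equal-width binning of valid pixels into n_levels grey levels.

    Values are clipped to ``vrange``; invalid pixels carry the background
    code ``n_levels``.  A degenerate range (max == min) puts every valid
    pixel in level 0.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    lo, hi = vrange
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
        raise ValueError(f"invalid quantization range {vrange}")
    out = np.full(values.shape, n_levels, dtype=np.int32)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(values)
    if hi == lo:
        out[valid] = 0
        return out
    v = np.clip(values[valid], lo, hi)
    levels = np.floor((v - lo) / (hi - lo) * n_levels).astype(np.int32)
    out[valid] = np.minimum(levels, n_levels - 1)
    return out


def compute_glcm(
    grey: np.ndarray,
    n_levels: int,
    angles: tuple[float, ...] = ANGLES,
    distance: int = 1,
) -> GLCM:
    """Symmetric co-occurrence counts, averaged over angles, then normalized.

    ``grey`` is an integer tile from :func:`quantize`, with the background
    code ``n_levels``; pairs touching a background pixel are skipped by
    dropping the background row/column of the count matrix before averaging.
    """
    grey = np.ascontiguousarray(grey, dtype=np.uint16)
    rad = [np.deg2rad(a) for a in angles]
    counts = graycomatrix(
        grey, distances=[distance], angles=rad, levels=n_levels + 1, symmetric=True
    ).astype(float)
    counts = counts[:n_levels, :n_levels, 0, :]  # drop background row/col
    avg = counts.mean(axis=-1)
    total = avg.sum()
    if total == 0:
        return GLCM(matrix=avg, n_levels=n_levels, n_pairs=0.0, empty=True)
    return GLCM(matrix=avg / total, n_levels=n_levels, n_pairs=float(total), empty=False)


def haralick_features(glcm: GLCM) -> TextureFeatures:
    """The five texture features of a normalized GLCM.

    An empty GLCM yields all-NaN features; a constant tile (sigma = 0) yields
    NaN correlation (undefined) with the remaining features well-defined.
    """
    if glcm.empty:
        nan = float("nan")
        return TextureFeatures(nan, nan, nan, nan, nan)
    p = glcm.matrix
    n = glcm.n_levels
    i = np.arange(n, dtype=float)[:, None]
    j = np.arange(n, dtype=float)[None, :]
    contrast = float(np.sum((i - j) ** 2 * p))
    marginal = p.sum(axis=1)  # symmetric: row and column marginals agree
    mu = float(np.sum(np.arange(n) * marginal))
    var = float(np.sum((np.arange(n) - mu) ** 2 * marginal))
    if var > 0:
        correlation = float(np.sum(p * (i - mu) * (j - mu)) / var)
    else:
        correlation = float("nan")
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    asm = float(np.sum(p**2))
    idm = float(np.sum(p / (1.0 + (i - j) ** 2)))
    return TextureFeatures(contrast, correlation, entropy, asm, idm)


def tile_summary(
    values: np.ndarray, valid: np.ndarray
) -> tuple[float, float, float]:
    """(mean, MAD about the mean, pixel density) over valid pixels."""
    valid = np.asarray(valid, dtype=bool) & np.isfinite(values)
    density = float(valid.sum() / valid.size)
    if not np.any(valid):
        return float("nan"), float("nan"), 0.0
    v = values[valid]
    mean = float(v.mean())
    mad = float(np.abs(v - mean).mean())
    return mean, mad, density


def feature_columns(param_names=("shg", "rratio", "dcp", "shgcd", "shgld")) -> list[str]:
    """The stable 36-column feature order."""
    cols = ["pixel_density"]
    for p in param_names:
        cols += [f"{p}_{s}" for s in STATS]
    return cols


def build_feature_table(
    maps: PolarimetricMaps,
    grid: SubImageGrid,
    exclusion_mask: np.ndarray | None = None,
    min_density: float = 0.1,
    n_levels: int = DEFAULT_N_LEVELS,
    range_percentiles: tuple[float, float] = (1.0, 99.0),
) -> pd.DataFrame:
    """Per-sub-image 36-column feature table.

    Tiles whose majority of pixels fall in ``exclusion_mask`` (adipose /
    vessel stand-ins), and tiles with pixel density below ``min_density``,
    are omitted.  Quantization uses a per-parameter global range (robust
    1st–99th percentile over all valid pixels of the mosaic) so that texture
    is comparable across tiles.

    Returns a DataFrame indexed by tile with columns ``grid_row``,
    ``grid_col`` and the 36 features.  Tiles where a feature is undefined
    (e.g. constant quantized tile -> correlation) carry NaN in that cell.
    """
    param_maps = maps.as_dict()
    h, w = maps.valid.shape
    if (grid.n_rows * grid.tile_size, grid.n_cols * grid.tile_size) != (h, w):
        raise ValueError("grid geometry does not match the parameter maps")
    if exclusion_mask is not None and exclusion_mask.shape != (h, w):
        raise ValueError("exclusion mask geometry does not match the maps")

    ranges = {}
    for name, arr in param_maps.items():
        vals = arr[np.isfinite(arr)]
        if vals.size:
            ranges[name] = tuple(np.percentile(vals, range_percentiles))
        else:
            ranges[name] = (0.0, 0.0)

    rows = []
    for r, c in grid.tiles():
        sl = grid.bounds(r, c)
        if exclusion_mask is not None and exclusion_mask[sl].mean() >= 0.5:
            continue
        tile_valid = maps.valid[sl]
        density = float(tile_valid.sum() / tile_valid.size)
        if density < min_density:
            continue
        row: dict[str, float] = {
            "grid_row": r,
            "grid_col": c,
            "pixel_density": density,
        }
        for name, arr in param_maps.items():
            tile = arr[sl]
            mean, mad, _ = tile_summary(tile, tile_valid)
            grey = quantize(tile, tile_valid, n_levels, ranges[name])
            feats = haralick_features(compute_glcm(grey, n_levels))
            row[f"{name}_mean"] = mean
            row[f"{name}_mad"] = mad
            row[f"{name}_contrast"] = feats.contrast
            row[f"{name}_correlation"] = feats.correlation
            row[f"{name}_entropy"] = feats.entropy
            row[f"{name}_asm"] = feats.asm
            row[f"{name}_idm"] = feats.idm
        rows.append(row)

    table = pd.DataFrame(rows, columns=["grid_row", "grid_col"] + feature_columns())
    return table.reset_index(drop=True)
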