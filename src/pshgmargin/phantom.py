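"""Synthetic widefield P-SHG phantoms with a known tumor/normal boundary.

The phantom emulates the contrasts that distinguish tumor-involved from
normal collagenous tissue in polarization-resolved SHG imaging:

* lower SHG intensity and a smaller fraction of signal-bearing pixels
  ("pixel density") on the tumor side,
* a shifted R-ratio distribution (collagen ultrastructure); note that the
  R definition from Stokes elements, R = 1 + 2A + 2 sqrt(A^2 - 1), returns
  the principal branch R >= 3 for any feasible A >= 1 (R-1 and 4/(R-1)
  share the same A), so target R values are drawn on that branch to keep
  the forward/inverse roundtrip exact,
* shorter spatial correlation of the SHG-CD / SHG-LD fields on the tumor
  side (fiber-orientation disorder), which is what drives the texture
  differences (contrast, entropy, IDM) the downstream clustering keys on.

Every signal pixel carries known target values of the five polarimetric
parameters (I_CP, R, DCP, SHG-CD, SHG-LD).  :func:`synthesize_stack` inverts
the parameter definitions to Stokes elements and maps those to the 16 raw
polarization-state images, so the whole analysis chain can be validated
round-trip against the truth maps.

Stokes feasibility constrains the parameters jointly: with
A(R) = ((R-1)^2 + 4) / (4 (R-1)) and c = SHG_CD/2, the degree of circular
polarization at a pixel must lie in the band traced out by
DCP = (alpha + beta)/2 subject to alpha (1+c) + beta (1-c) = 2/A with
alpha, beta in [0, 1] (alpha = s3_RCP/s0_RCP, beta = -s3_LCP/s0_LCP).  When
SHG_CD = 0 the band degenerates to the single point DCP = 1/A, i.e. DCP is
slaved to the R-ratio — consistent with DCP being proportional to R in
collagen.  The generator therefore treats the configured DCP distribution as
a proposal and clips each sample into its pixel's feasible band, recording
how many pixels were clipped.

Noise is shot-like: counts are drawn as Poisson(gain * mu) / gain, giving
variance mu / gain and SNR = mu / sigma = sqrt(gain * mu), matching the
power-law SNR calibration the polarimetry module fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .polarimetry import STATES, PolarizationStack

#: pixel label codes in the region map
EXCLUDED, TUMOR, NORMAL = 0, 1, 2

#: length scale (px) of the fiber-mask blobs, shared by both regions
_FIBER_SCALE = 3.0

#: |SHG_CD/2| below which the DCP band collapses numerically; there DCP is
#: pinned to 1/A, where alpha = beta = DCP solves the Stokes system exactly
#: for any c (the c-terms cancel), keeping the inversion well-conditioned.
_C_MIN = 1e-4


@dataclass
class RegionParams:
    """Target parameter distributions for one tissue region.

    Means/spreads are per-pixel Gaussian parameters except where clipped to a
    physical range.  ``correlation_length`` (px) sets the smoothing scale of
    the SHG-CD/LD random fields: small values give spatially disordered
    dichroism (tumor-like texture), large values smooth, organized fields.
    """

    fiber_density: float = 0.5
    icp_mean: float = 400.0
    icp_spread: float = 120.0
    r_mean: float = 3.5
    r_spread: float = 0.25
    dcp_mean: float = 0.97
    dcp_spread: float = 0.02
    cd_mean: float = 0.0
    cd_spread: float = 0.45
    ld_mean: float = 0.0
    ld_spread: float = 0.45
    correlation_length: float = 8.0


def tumor_defaults() -> RegionParams:
    """Tumor-side defaults: dimmer, sparser, higher R, disordered dichroism."""
    return RegionParams(
        fiber_density=0.25,
        icp_mean=150.0,
        icp_spread=60.0,
        r_mean=4.0,
        r_spread=0.3,
        dcp_mean=0.92,
        dcp_spread=0.03,
        cd_spread=0.6,
        ld_spread=0.6,
        correlation_length=2.0,
    )


@dataclass
class PhantomConfig:
    """Geometry, per-region targets, noise model and seed for one phantom.

    The raster is a single mosaic of ``image_height x image_width`` pixels;
    ``mosaic_rows x mosaic_cols`` records how many camera fields of view it
    represents.  Columns left of ``boundary_column`` are tumor-like, columns
    right of it normal-like.  ``exclusions`` are (row, col, r_row, r_col)
    ellipses standing in for adipose/vessel areas marked by a pathologist.
    """

    image_height: int = 1024
    image_width: int = 1024
    tile_size: int = 128
    mosaic_rows: int = 1
    mosaic_cols: int = 1
    boundary_column: int = 512
    tumor: RegionParams = field(default_factory=tumor_defaults)
    normal: RegionParams = field(default_factory=RegionParams)
    exclusions: tuple[tuple[float, float, float, float], ...] = ()
    noise: str = "shot"  # "shot" | "none"
    gain: float = 1.0
    background_level: float = 0.05
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height % self.tile_size or self.image_width % self.tile_size:
            raise ValueError("tile_size must divide image_height and image_width")
        if not 0 < self.boundary_column < self.image_width:
            raise ValueError("boundary_column must lie inside the image")
        if self.noise not in ("shot", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        for name, reg in (("tumor", self.tumor), ("normal", self.normal)):
            if not 0 < reg.fiber_density <= 1:
                raise ValueError(f"{name}: fiber_density must be in (0, 1]")
            if reg.r_mean < 3:
                raise ValueError(
                    f"{name}: r_mean must be at least 3 (the principal branch of "
                    "the R definition from Stokes elements)"
                )
            if not 0 <= reg.dcp_mean <= 1:
                raise ValueError(f"{name}: dcp_mean must be in [0, 1]")
            if reg.dcp_mean + 2 * reg.dcp_spread > 1.5:
                raise ValueError(f"{name}: DCP spread forces values far outside [0, 1]")
            if abs(reg.cd_mean) > 2 or abs(reg.ld_mean) > 2:
                raise ValueError(f"{name}: dichroism means must be within [-2, 2]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("tumor", "normal"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = RegionParams(**raw[key])
        if "exclusions" in raw and raw["exclusions"] is not None:
            raw["exclusions"] = tuple(tuple(e) for e in raw["exclusions"])
        return cls(**raw)


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom.

    ``region_label`` is a per-pixel raster of {EXCLUDED, TUMOR, NORMAL};
    ``fiber_mask`` marks signal-bearing pixels; ``maps`` carries the five
    target parameter maps (NaN off-fiber); ``clip_counts`` records how many
    sampled values had to be clipped into their physical/feasible range.
    """

    region_label: np.ndarray
    fiber_mask: np.ndarray
    maps: dict[str, np.ndarray]
    boundary_column: int
    clip_counts: dict[str, int]

    def tile_region_labels(self, tile_size: int) -> np.ndarray:
        """Majority region label per tile (ties and excluded-majority -> EXCLUDED)."""
        h, w = self.region_label.shape
        rows, cols = h // tile_size, w // tile_size
        out = np.empty((rows, cols), dtype=np.uint8)
        for r in range(rows):
            for c in range(cols):
                tile = self.region_label[
                    r * tile_size : (r + 1) * tile_size,
                    c * tile_size : (c + 1) * tile_size,
                ]
                counts = np.bincount(tile.ravel(), minlength=3)
                best = int(np.argmax(counts))
                ties = np.sum(counts == counts[best])
                out[r, c] = EXCLUDED if ties > 1 else best
        return out


def feasibility_constant(r: np.ndarray) -> np.ndarray:
    """A(R) = ((R-1)^2 + 4) / (4 (R-1)); inverse of R = 1 + 2A + 2 sqrt(A^2-1)."""
    u = np.asarray(r, dtype=float) - 1.0
    return (u**2 + 4.0) / (4.0 * u)


def dcp_feasible_band(r: np.ndarray, cd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (lo, hi) bounds of DCP compatible with the given R and SHG-CD."""
    a = feasibility_constant(r)
    c = np.asarray(cd, dtype=float) / 2.0
    target = 2.0 / a  # required alpha (1+c) + beta (1-c)
    alpha_hi = np.minimum(1.0, target / (1.0 + c))
    alpha_lo = np.maximum(0.0, (target - (1.0 - c)) / (1.0 + c))

    def dcp_of(alpha):
        beta = (target - alpha * (1.0 + c)) / (1.0 - c)
        return 0.5 * (alpha + beta)

    d1, d2 = dcp_of(alpha_lo), dcp_of(alpha_hi)
    return np.minimum(d1, d2), np.maximum(d1, d2)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance, zero-mean smoothed Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=max(sigma, 1e-6))
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipse_mask(shape, cy, cx, ry, rx) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Generate truth maps for a two-region phantom; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    shape = (config.image_height, config.image_width)

    region = np.full(shape, NORMAL, dtype=np.uint8)
    region[:, : config.boundary_column] = TUMOR
    exclusion = np.zeros(shape, dtype=bool)
    for cy, cx, ry, rx in config.exclusions:
        exclusion |= _ellipse_mask(shape, cy, cx, ry, rx)
    region[exclusion] = EXCLUDED

    clip_counts = {"dcp": 0, "r": 0, "cd": 0, "ld": 0, "icp": 0}

    # fiber mask: thresholded smooth field, per-region quantile -> exact density
    blob = gaussian_filter(rng.standard_normal(shape), sigma=_FIBER_SCALE)
    fiber = np.zeros(shape, dtype=bool)
    for code, params in ((TUMOR, config.tumor), (NORMAL, config.normal)):
        sel = region == code
        thr = np.quantile(blob[sel], 1.0 - params.fiber_density)
        fiber[sel] = blob[sel] >= thr
    fiber[exclusion] = False

    maps = {k: np.full(shape, np.nan) for k in ("shg", "rratio", "dcp", "shgcd", "shgld")}
    for code, params in ((TUMOR, config.tumor), (NORMAL, config.normal)):
        sel = (region == code) & fiber
        n = int(sel.sum())
        if n == 0:
            continue
        icp = rng.normal(params.icp_mean, params.icp_spread, n)
        low = np.maximum(1.0, 0.01 * params.icp_mean)
        clip_counts["icp"] += int(np.sum(icp < low))
        icp = np.maximum(icp, low)

        r = rng.normal(params.r_mean, params.r_spread, n)
        clip_counts["r"] += int(np.sum(r < 3.02))
        r = np.maximum(r, 3.02)  # stay on the R >= 3 principal branch

        # spatially correlated dichroism fields; clipped into [-2, 2]
        cd_f = _smooth_field(rng, shape, params.correlation_length)[sel]
        ld_f = _smooth_field(rng, shape, params.correlation_length)[sel]
        cd = params.cd_mean + params.cd_spread * cd_f
        ld = params.ld_mean + params.ld_spread * ld_f
        clip_counts["cd"] += int(np.sum(np.abs(cd) > 2))
        clip_counts["ld"] += int(np.sum(np.abs(ld) > 2))
        cd = np.clip(cd, -1.99, 1.99)  # strict: keeps s0 of both helicities > 0
        ld = np.clip(ld, -1.99, 1.99)

        dcp = rng.normal(params.dcp_mean, params.dcp_spread, n)
        lo, hi = dcp_feasible_band(r, cd)
        clip_counts["dcp"] += int(np.sum((dcp < lo) | (dcp > hi)))
        dcp = np.clip(dcp, lo, hi)
        degenerate = np.abs(cd / 2.0) < _C_MIN  # band ~ a point: pin to 1/A
        clip_counts["dcp"] += int(np.sum(degenerate))
        dcp = np.where(degenerate, 1.0 / feasibility_constant(r), dcp)

        maps["shg"][sel] = icp
        maps["rratio"][sel] = r
        maps["dcp"][sel] = dcp
        maps["shgcd"][sel] = cd
        maps["shgld"][sel] = ld

    return PhantomTruth(
        region_label=region,
        fiber_mask=fiber,
        maps=maps,
        boundary_column=config.boundary_column,
        clip_counts=clip_counts,
    )


def _stokes_targets(truth: PhantomTruth) -> dict[str, np.ndarray]:
    """Invert the five parameter maps to Stokes elements on fiber pixels.

    Convention: s3_RCP >= 0 >= s3_LCP, s1 = 0 for every incoming state.
    Returns full-size maps that are 0 off-fiber.
    """
    m = truth.maps
    fiber = truth.fiber_mask
    icp = np.where(fiber, m["shg"], 0.0)
    cd = np.where(fiber, m["shgcd"], 0.0)
    ld = np.where(fiber, m["shgld"], 0.0)
    r = np.where(fiber, m["rratio"], 3.0)  # dummy off-fiber (A=1)
    dcp = np.where(fiber, m["dcp"], 0.0)

    c = cd / 2.0
    s0_rcp = icp * (1.0 + c)
    s0_lcp = icp * (1.0 - c)
    a = feasibility_constant(r)
    target = 2.0 / a  # alpha (1+c) + beta (1-c)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            np.abs(c) >= _C_MIN, (1.0 / a - dcp * (1.0 - c)) / c, dcp
        )
    beta = 2.0 * dcp - alpha
    # numerical safety: alpha/beta must be fractions of s0
    eps = 1e-9
    bad = fiber & (
        (alpha < -eps) | (alpha > 1 + eps) | (beta < -eps) | (beta > 1 + eps)
    )
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "Stokes inversion infeasible (|s3| > s0) at pixel "
            f"({i}, {j}): R={m['rratio'][i, j]:.4f}, DCP={m['dcp'][i, j]:.4f}, "
            f"SHG_CD={m['shgcd'][i, j]:.4f}"
        )
    alpha = np.clip(alpha, 0.0, 1.0)
    beta = np.clip(beta, 0.0, 1.0)
    s3_rcp = alpha * s0_rcp
    s3_lcp = -beta * s0_lcp
    del target
    return {
        "s0_RCP": s0_rcp,
        "s0_LCP": s0_lcp,
        "s3_RCP": s3_rcp,
        "s3_LCP": s3_lcp,
        "s0_VLP": icp * (1.0 + ld / 2.0),
        "s0_HLP": icp * (1.0 - ld / 2.0),
    }


def synthesize_stack(truth: PhantomTruth, config: PhantomConfig) -> PolarizationStack:
    """Forward-model the 16 raw polarization-state images from truth maps.

    Per incoming state the analyzed intensities are I = (s0 +/- s1)/2 and
    (s0 +/- s3)/2; incoming VLP/HLP states carry s1 = s3 = 0 (the five
    parameters do not constrain them).  Background pixels receive
    ``background_level`` mean counts (noise only after the noise model).
    """
    st = _stokes_targets(truth)
    fiber = truth.fiber_mask
    shape = truth.region_label.shape
    zeros = np.zeros(shape)

    # per incoming state: (s0, s1, s3)
    stokes_in = {
        "LCP": (st["s0_LCP"], zeros, st["s3_LCP"]),
        "RCP": (st["s0_RCP"], zeros, st["s3_RCP"]),
        "VLP": (st["s0_VLP"], zeros, zeros),
        "HLP": (st["s0_HLP"], zeros, zeros),
    }

    mean = np.empty((4, 4, *shape))
    for i, inc in enumerate(STATES):
        s0, s1, s3 = stokes_in[inc]
        analyzed = {
            "LCP": (s0 - s3) / 2.0,
            "RCP": (s0 + s3) / 2.0,
            "VLP": (s0 - s1) / 2.0,
            "HLP": (s0 + s1) / 2.0,
        }
        for j, ana in enumerate(STATES):
            img = np.where(fiber, analyzed[ana], config.background_level)
            if np.any(img < 0):
                raise ValueError(f"negative mean intensity for {inc}->{ana}")
            mean[i, j] = img

    rng = np.random.default_rng(config.seed + 1)
    frames = np.empty((4, 4, config.n_frames, *shape))
    for f in range(config.n_frames):
        if config.noise == "none":
            frames[:, :, f] = mean
        else:
            frames[:, :, f] = rng.poisson(config.gain * mean) / config.gain
    return PolarizationStack(intensities=frames)


# ---------------------------------------------------------------------------
# TIFF / YAML I/O


def write_stack(path, stack: PolarizationStack) -> None:
    """16-bit unsigned multi-page TIFF; page order incoming-major
    (LCP,RCP,VLP,HLP incoming x LCP,RCP,VLP,HLP analyzed), frames innermost."""
    import tifffile

    a = stack.intensities
    pages = a.reshape(-1, *a.shape[3:])
    tifffile.imwrite(path, np.clip(np.round(pages), 0, 65535).astype(np.uint16))


def read_stack(path, n_frames: int = 1) -> PolarizationStack:
    import tifffile

    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    h, w = pages.shape[-2:]
    return PolarizationStack(
        intensities=pages.reshape(4, 4, n_frames, h, w).astype(float)
    )


def write_truth(directory, truth: PhantomTruth) -> list:
    """Truth maps as 32-bit float TIFF, masks as 8-bit label TIFF."""
    import tifffile
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in truth.maps.items():
        p = directory / f"truth_{name}.tif"
        tifffile.imwrite(p, arr.astype(np.float32))
        written.append(p)
    for name, arr in (
        ("region_label", truth.region_label),
        ("fiber_mask", truth.fiber_mask.astype(np.uint8)),
    ):
        p = directory / f"{name}.tif"
        tifffile.imwrite(p, arr.astype(np.uint8))
        written.append(p)
    return written
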