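# Methods

This note documents the models, conventions and numerical choices behind
`pshgmargin`, and what the synthetic phantoms do and do not establish about
real tissue data.

## Polarimetric model and conventions

The analysis consumes a 16-image stack: 4 incoming polarization states
(LCP, RCP, VLP, HLP) × 4 analyzed states, in exposure-consistent camera
counts.  Per incoming state the Stokes elements of the emitted SHG are
formed from the analyzed intensities as s0 = I_HLP + I_VLP,
s1 = I_HLP − I_VLP, s3 = I_RCP − I_LCP.  No further normalization is
applied: the five derived parameters are either intensity ratios or enter
the feature table only after standardization, so a global intensity scale
cancels.  s1 is computed for completeness but none of the five parameters
consumes it.

**R-ratio branch.**  R = 1 + 2A + 2√(A²−1) with
A = (s0ᴿ+s0ᴸ)/(s3ᴿ−s3ᴸ) maps every feasible A ≥ 1 to R ≥ 3; R−1 and
4/(R−1) share the same A, and the principal (+) root selects the larger.
Pixels with |A| < 1 (radicand negative, only reachable through noise) are
marked invalid, as are |A| > 10⁶ (near-zero s3 difference; numerically
meaningless).  The phantom generator samples target R on the R ≥ 3 branch
so the forward/inverse roundtrip is exact.

**DCP coupling.**  Stokes feasibility (|s3| ≤ s0) ties DCP to R and
SHG-CD.  Writing α = s3ᴿ/s0ᴿ, β = −s3ᴸ/s0ᴸ (convention s3ᴿ ≥ 0 ≥ s3ᴸ) and
c = SHG-CD/2, the constraints are α + β = 2·DCP and
α(1+c) + β(1−c) = 2/A with α, β ∈ [0, 1].  At c = 0 the feasible DCP
collapses to the single value 1/A — DCP is slaved to the R-ratio, which is
physically sensible (DCP is proportional to R in collagen).  The phantom
treats its configured DCP distribution as a proposal and clips each sample
into the per-pixel feasible band, recording the number of clipped samples
in `PhantomTruth.clip_counts`.  For |c| < 10⁻⁴ the inversion for α is
ill-conditioned (catastrophic cancellation amplified by 1/c), so DCP is
pinned to exactly 1/A there; α = β = DCP then satisfies both constraints
exactly for any c, keeping the synthesis well-conditioned and the
zero-noise roundtrip exact to ~10⁻¹⁰ relative.

**SNR calibration.**  From ≥ 3 repeated frames, per-pixel μ (mean) and σ
(SD, ddof = 1) give SNR = μ/σ; a power law SNR = a·μᵇ is fitted by least
squares on log–log axes over pixels with μ, σ > 0.  Validity thresholding
applies the fitted curve to the I_CP intensity with an inclusive boundary
(predicted SNR ≥ min_snr, default 1).  Frames are averaged before Stokes
computation; the calibration uses the unaveraged repeats.

## Texture features

Tiles are 128 × 128 px by default (a 1024 × 1024 mosaic → 8 × 8 grid).
Per parameter map the quantization range is the global robust 1st–99th
percentile over all valid pixels of the mosaic, shared by all tiles, so
that texture values are comparable across tiles — a requirement for
inter-tile clustering.  N_g = 64 grey levels by default: fine enough to
resolve the continuous parameters, coarse enough that a 128² tile
populates the GLCM densely.

Co-occurrence counting is symmetric, d = 1, four directions, with any pair
touching a background pixel (below SNR, or NaN in that parameter) dropped;
per-direction count matrices are averaged first and the average is then
normalized.  Implementation detail: counts come from
`skimage.feature.graycomatrix` with one extra grey level reserved as the
background code, whose row/column is removed before averaging; the five
features are evaluated directly from the normalized matrix and are checked
against a brute-force double-loop oracle in the tests.

**Correlation sign.**  The correlation feature is implemented so that a
perfectly positively correlated image scores +1 and a perfectly
anti-correlated one −1 (ρ = Σ P(i,j)(i−μ)(j−μ)/σ², no leading minus).
A constant tile has σ = 0 and carries NaN correlation; rows with NaN
features are dropped (with a warning) before standardization.

**MAD** is the mean absolute deviation about the tile mean (the mean
center is chosen for consistency with the name; the median variant is not
used).  **Pixel density** is the fraction of SNR-valid pixels in the tile.
Tiles with density < 0.1 (configurable) or with a majority of pixels in
the exclusion mask are omitted.

## PCA and subsets

Standardization uses ddof = 1 SDs so that the covariance of the
standardized data has unit diagonal and its eigenvalues sum to the number
of features; the Kaiser rule retains eigenvalues ≥ 1 (inclusive).  PCA is
a deterministic eigendecomposition (`numpy.linalg.eigh`), with each
loading vector signed so its largest-magnitude entry is positive — PC
transfer and cluster canonicalization need a reproducible orientation.

Subset membership: INT = {SHG mean, SHG MAD, pixel density};
INT+TXT = INT ∪ {SHG contrast, correlation, entropy, ASM, IDM};
POL = {mean, MAD of all five parameters} ∪ {pixel density}; ALL = all 36;
PC1–PC4 = single score columns.  The INT/POL membership is an
interpretation (mean+MAD rather than mean-only) and is centralized in
`decomposition.subset_columns`.

## Clustering and margin statistics

K-Means uses k = 2, 50 seeded restarts, squared-Euclidean objective.
Non-PC subsets are standardized column-wise before clustering (PC scores
are used as-is), consistent with the standardization ahead of PCA.  Labels
are canonicalized so that cluster 1 is the cluster with the higher mean
pixel density (normal-like); the raw K-Means indices are arbitrary but the
occupancy statistics and the tumor/normal reading depend on which cluster
is "1".  Silhouettes are Euclidean; a singleton cluster's point scores 0
(the usual convention, avoiding an undefined division).

The continuous association C = B ± (1−S)/2 is a bijection of S on each
branch; C = 1.5 means no association, and a negative silhouette moves a
point past 1.5 toward the opposite cluster.  Effective membership in the
occupancy statistic is therefore decided by C (< 1.5 vs > 1.5), not by the
raw label B; C = 1.5 carries zero weight.  Median filtering uses a 3 × 3
window of present values, keeps missing cells missing, and shrinks the
window at borders rather than inventing padding values.

**Boundary estimator.**  The vertical profile of the median-filtered C map
is split at the column maximizing the absolute left/right mean difference
(a raw "first crossing of 1.5" is ill-defined on oscillating profiles);
when the profile straddles 1.5 at the split, the crossing is refined by
linear interpolation between the two column centers.  The estimate is
reported in sub-image columns.

**Ground truth rasterization.**  Tiles take their majority pixel label;
exact ties are excluded rather than assigned, so no class is fabricated on
the boundary.  PC-loading transfer standardizes a new region with its own
column statistics by default (`use_reference_stats=True` switches to the
stored reference statistics); both are supported because either choice is
defensible and the difference matters only when acquisition conditions
drift between regions.

## Phantom: what it emulates, what it does not

The generator produces a two-region raster (tumor left of a configurable
boundary column, normal right) with, by default: fiber density 0.25 vs
0.50; I_CP ~ N(150, 60) vs N(400, 120) counts; R ~ N(4.0, 0.3) vs
N(3.5, 0.25) (clipped to ≥ 3.02); SHG-CD/LD zero-mean smoothed Gaussian
random fields with spread 0.6 vs 0.45 and spatial correlation length 2 px
vs 8 px.  The short tumor-side correlation length is what drives the
dichroism texture contrast (higher GLCM contrast/entropy, lower IDM) that
texture-bearing subsets key on.  The fiber mask is a thresholded smoothed
random field (blob scale 3 px), thresholded at the per-region density
quantile.  Optional ellipses stand in for pathologist-excluded
adipose/vessel areas and exercise the tile-rejection path.  Noise is
Poisson(gain·μ)/gain per frame (variance μ/gain, SNR = √(gain·μ)),
matching the power-law calibration; `noise="none"` gives exact means for
roundtrip tests.  Intensity-bearing effect sizes are package choices in
the range a dim, sparse tumor matrix plausibly produces; the
dichroism/R/DCP effect sizes are free parameters, not calibrated to
tissue.

Not emulated: the C6v susceptibility tensor physics (dichroism fields are
statistical, not derived from fiber orientations), instrument polarization
imperfections, detector read noise and fixed-pattern noise, H&E
appearance, and the spatial irregularity of real tumor margins (the truth
boundary is a straight column).  Passing tests therefore demonstrate the
correctness and statistical behavior of the analysis chain, not clinical
performance on tissue.

At the default problem sizes (1024 × 1024 phantom, 64 tiles, 36 features)
a full run takes a few tens of seconds on one core; the recovery-error and
SNR-scaling checks use 256 × 256 phantoms.  At SNR ≈ 10 the mean absolute
recovery errors are about 18 counts (I_CP), 0.7 (R), 0.07 (DCP) and 0.13
(dichroisms), scaling as 1/SNR across levels.

## Design notes and limitations

* The pipeline recomputes all stages per run instead of caching
  intermediates: every stage is deterministic given the config seed and
  cheap at these problem sizes, so a cache would add state without value.
  Per-stage seeds are derived from the config seed by fixed offsets so
  stages rerun in isolation reproduce the full-run results.
* With 64 tiles and 36 features the feature matrix is close to square;
  PCA warns when rows ≤ columns.  Larger mosaics remove the warning.
* IIOD compares exactly two regions split by one boundary; multi-region or
  curved-margin geometries would need a generalized occupancy statistic.
* The harmonic mean of per-cluster silhouettes is undefined when a cluster
  mean is ≤ 0; such subsets are reported with H = NaN and cannot be
  flagged best.
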