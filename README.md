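# pshgmargin

Unsupervised mapping of collagen ultrastructure and tumor-margin
localization from widefield **polarimetric second-harmonic generation
(P-SHG)** image stacks.

SHG microscopy visualizes fibrillar collagen in the extracellular matrix;
tumors disorganize that collagen well beyond the cellular tumor mass.  This
package implements an analysis chain that turns a 16-state polarization
stack (4 incoming × 4 analyzed states: LCP, RCP, VLP, HLP) into a spatial
map of "tumor-like" vs "normal-like" tissue and a quantitative estimate of
the margin between them — without any supervision or cellular information.
It is intended for researchers in nonlinear optical microscopy and
computational pathology who want a reproducible, testable reference
implementation of the method, complete with a synthetic phantom generator
that makes every stage verifiable without tissue data.

## The method

1. **Polarimetry.** Per incoming state, Stokes elements are formed from the
   analyzed intensities (s0 = I_HLP + I_VLP, s1 = I_HLP − I_VLP,
   s3 = I_RCP − I_LCP) and combined into five per-pixel parameters: the
   circularly-polarized SHG intensity I_CP = (s0ᴿ + s0ᴸ)/2; the
   susceptibility ratio R = χ⁽²⁾zzz/χ⁽²⁾zxx = 1 + 2A + 2√(A²−1) with
   A = (s0ᴿ + s0ᴸ)/(s3ᴿ − s3ᴸ); the degree of circular polarization
   DCP = (|s3ᴿ|/s0ᴿ + |s3ᴸ|/s0ᴸ)/2; and the circular and linear dichroisms
   SHG-CD = 2(s0ᴿ − s0ᴸ)/(s0ᴿ + s0ᴸ), SHG-LD = 2(s0ⱽ − s0ᴴ)/(s0ⱽ + s0ᴴ).
   Pixels below a power-law SNR calibration (SNR(μ) = a·μᵇ, fitted from
   repeated frames; threshold SNR ≥ 1) are discarded.
2. **Texture.** Each map is tiled into 128 × 128-px sub-images.  Per tile
   and parameter, five Haralick features (contrast, correlation, entropy,
   ASM, IDM) are computed from a symmetric, angle-averaged GLCM (d = 1;
   0°, 45°, 90°, 135°) with background pixels removed, plus the mean, MAD
   and the fraction of signal pixels ("pixel density") — a 36-column
   feature table.
3. **PCA.** Features are standardized; principal components with
   covariance eigenvalue ≥ 1 are retained (Kaiser criterion).
4. **Clustering.** Binary K-Means over eight data subsets (intensity-only,
   intensity+texture, polarimetric means, all features, PC1–PC4).  Labels B
   and silhouette scores S fuse into a continuous association
   C = B ± (1 − S)/2 ∈ [1, 2] (boundary at 1.5); maps are median-filtered
   and summarized by vertical profiles.  Subsets are ranked by the harmonic
   mean of per-cluster silhouettes.
5. **Margin.** Against a ground-truth left/right partition, silhouette-
   weighted cluster occupancies Q_{a,r} = Σ|C−1.5| (cluster a, region r) /
   Σ|C−1.5| (region r) feed the inter/intra-cluster occupancy difference
   IIOD = |Q₁ₗ−Q₂ₗ|·|Q₁ᵣ−Q₂ᵣ|·|Q₁ₗ−Q₁ᵣ|·|Q₂ₗ−Q₂ᵣ| ∈ [0, 1].  The best
   subset's profile crossing of C = 1.5 localizes the margin.  A stored PC
   loading vector can be transferred to cluster new regions.

A phantom module generates synthetic 16-state stacks with known per-pixel
parameters, a known boundary, region-dependent fiber density and
orientation disorder, and shot-like noise — the test bed for the whole
chain.

## Worked example

```bash
python examples/04_margin_pipeline.py
```

runs the full chain on the default 1024 × 1024 phantom (8 × 8 grid of
128-px sub-images, true boundary at tile column 4) and prints, among other
rows:

```
 subset  Q1_left  Q2_left  Q1_right  Q2_right  iiod  boundary_estimate  best
    INT    0.000    1.000     1.000     0.000 1.000              4.010  True
    ALL    0.000    1.000     1.000     0.000 1.000              4.019 False
    PC2    0.352    0.648     0.482     0.518 0.000              5.000 False
...
best subset: INT (IIOD = 1.000)
estimated boundary: column 4.01 (truth: 4.0)
```

Reading: on this phantom the tumor side is confined to cluster 2 and the
normal side to cluster 1 for the intensity-bearing subsets (occupancies
0/1 swap across the boundary → IIOD = 1), and the estimated margin lands
within a hundredth of a sub-image column of the truth.  A subset whose
occupancies hover near 0.5 (here PC2) carries no margin information and
scores IIOD ≈ 0.

Other examples: `01_phantom_roundtrip.py` (exact zero-noise recovery of all
five parameter maps), `02_snr_calibration.py` (fitted SNR exponent ≈ 0.5
for shot-like noise), `03_texture_features.py` (dichroism texture contrast
between regions).

The same pipeline is scriptable from the shell:

```bash
pshgmargin run-all --seed 1 --out runs/demo
pshgmargin simulate --seed 3 --out runs/sim
pshgmargin polarimetry --stack runs/sim/stack.tif --out runs/pol
```

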