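"""Tiling, quantization, GLCM construction and Haralick features.

The reference oracle below recomputes the co-occurrence counts and all five
features with plain double loops, independently of the array-based
implementation and of skimage.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pshgmargin as pm
from pshgmargin.polarimetry import PolarimetricMaps
from pshgmargin.texture import (
    GLCM,
    build_feature_table,
    compute_glcm,
    feature_columns,
    quantize,
    tile_grid,
    tile_summary,
)

# offsets (drow, dcol) per GLCM direction in degrees
OFFSETS = {0.0: (0, 1), 45.0: (-1, 1), 90.0: (-1, 0), 135.0: (-1, -1)}


def oracle_glcm(grey, n_levels, angles):
    """Symmetric pair counts by explicit enumeration; background = n_levels."""
    h, w = grey.shape
    per_angle = []
    for ang in angles:
        dr, dc = OFFSETS[ang]
        m = np.zeros((n_levels, n_levels))
        for i in range(h):
            for j in range(w):
                i2, j2 = i + dr, j + dc
                if not (0 <= i2 < h and 0 <= j2 < w):
                    continue
                a, b = grey[i, j], grey[i2, j2]
                if a >= n_levels or b >= n_levels:
                    continue
                m[a, b] += 1
                m[b, a] += 1
        per_angle.append(m)
    avg = np.mean(per_angle, axis=0)
    total = avg.sum()
    return avg / total if total else avg


def oracle_features(p, n_levels):
    """Double-loop evaluation of contrast, correlation, entropy, ASM, IDM."""
    marg = p.sum(axis=1)
    mu = sum(i * marg[i] for i in range(n_levels))
    var = sum((i - mu) ** 2 * marg[i] for i in range(n_levels))
    contrast = corr_num = entropy = asm = idm = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            pij = p[i, j]
            contrast += (i - j) ** 2 * pij
            corr_num += pij * (i - mu) * (j - mu)
            if pij > 0:
                entropy -= pij * np.log2(pij)
            asm += pij**2
            idm += pij / (1 + (i - j) ** 2)
    corr = corr_num / var if var > 0 else np.nan
    return contrast, corr, entropy, asm, idm


def test_tile_grid_counts():
    assert tile_grid(2048, 2048, 128).n_tiles == 256
    assert tile_grid(256, 256, 128).n_tiles == 4
    with pytest.raises(ValueError, match="does not divide"):
        tile_grid(2048, 2000, 128)


def test_quantize_constant_ramp_and_background():
    const = np.full((4, 4), 2.5)
    grey = quantize(const, np.ones((4, 4), bool), 8, (0.0, 5.0))
    assert len(np.unique(grey)) == 1
    ramp = np.linspace(0, 1, 16, endpoint=False).reshape(4, 4)
    grey = quantize(ramp, np.ones((4, 4), bool), 4, (0.0, 1.0))
    assert np.array_equal(np.bincount(grey.ravel()), [4, 4, 4, 4])
    valid = np.ones((4, 4), bool)
    valid[0] = False
    grey = quantize(ramp, valid, 4, (0.0, 1.0))
    assert np.all(grey[0] == 4)  # background code, never a grey level
    # degenerate range: single occupied level
    grey = quantize(const, np.ones((4, 4), bool), 8, (2.5, 2.5))
    assert np.all(grey == 0)


def test_glcm_hand_enumerated_horizontal_pairs():
    tile = np.array([[0, 0], [1, 1]])
    g = compute_glcm(tile, n_levels=2, angles=(0.0,))
    assert g.matrix[0, 0] == pytest.approx(0.5)
    assert g.matrix[1, 1] == pytest.approx(0.5)
    assert g.matrix[0, 1] == 0


def test_glcm_uniform_tile_single_entry():
    g = compute_glcm(np.zeros((8, 8), int), n_levels=4)
    assert g.matrix[0, 0] == pytest.approx(1.0)
    assert g.matrix.sum() == pytest.approx(1.0)


def test_glcm_symmetric_normalized_and_background_pairs_skipped(rng):
    grey = rng.integers(0, 5, (16, 16))
    grey[rng.random((16, 16)) < 0.3] = 5  # background code for n_levels=5
    g = compute_glcm(grey, n_levels=5)
    assert g.matrix.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(g.matrix, g.matrix.T)
    np.testing.assert_allclose(g.matrix, oracle_glcm(grey, 5, (0.0, 45.0, 90.0, 135.0)))


def test_glcm_all_background_marked_empty():
    g = compute_glcm(np.full((4, 4), 3), n_levels=3)
    assert g.empty
    feats = pm.haralick_features(g)
    assert all(np.isnan(v) for v in feats.as_tuple())


def test_haralick_uniform_tile_limits():
    g = compute_glcm(np.zeros((128, 128), int), n_levels=64)
    f = pm.haralick_features(g)
    assert f.asm == pytest.approx(1.0)
    assert f.idm == pytest.approx(1.0)
    assert f.contrast == pytest.approx(0.0)
    assert f.entropy == pytest.approx(0.0)
    assert np.isnan(f.correlation)  # sigma = 0: undefined


def test_haralick_correlation_sign_limits():
    stripes = np.tile([0, 1], (8, 4))  # alternating along the scan direction
    f = pm.haralick_features(compute_glcm(stripes, n_levels=2, angles=(0.0,)))
    assert f.correlation == pytest.approx(-1.0)
    columns = np.tile(np.arange(8), (8, 1))  # each column constant
    f = pm.haralick_features(compute_glcm(columns, n_levels=8, angles=(90.0,)))
    assert f.correlation == pytest.approx(1.0)


def test_features_match_double_loop_oracle(rng):
    """All five features agree with the brute-force oracle to 1e-12."""
    for _ in range(100):
        n_levels = int(rng.integers(2, 6))
        size = int(rng.integers(3, 7))
        grey = rng.integers(0, n_levels + 1, (size, size))  # incl. background
        g = compute_glcm(grey, n_levels=n_levels)
        if g.empty:
            continue
        ours = pm.haralick_features(g).as_tuple()
        p = oracle_glcm(grey, n_levels, (0.0, 45.0, 90.0, 135.0))
        np.testing.assert_allclose(p, g.matrix, atol=1e-12)
        expected = oracle_features(p, n_levels)
        for a, b in zip(ours, expected):
            if np.isnan(b):
                assert np.isnan(a)
            else:
                assert a == pytest.approx(b, abs=1e-12)


def test_tile_summary_basics():
    const = np.full((4, 4), 3.0)
    mean, mad, density = tile_summary(const, np.ones((4, 4), bool))
    assert (mean, mad, density) == (3.0, 0.0, 1.0)
    valid = np.zeros((4, 4), bool)
    valid[:2] = True
    _, _, density = tile_summary(const, valid)
    assert density == 0.5
    vals = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
    mean, mad, _ = tile_summary(vals, np.ones((3, 3), bool))
    assert mean == pytest.approx(5.0)
    assert mad == pytest.approx(np.abs(vals - 5.0).mean())
    mean, mad, density = tile_summary(const, np.zeros((4, 4), bool))
    assert np.isnan(mean) and np.isnan(mad) and density == 0.0


@given(st.floats(-5, 5), st.integers(0, 2**31 - 1))
def test_features_invariant_to_common_shift(shift, seed):
    """Adding a constant while shifting the quantization range is a no-op."""
    rng = np.random.default_rng(seed)
    tile = rng.uniform(0, 1, (8, 8))
    valid = rng.random((8, 8)) < 0.8
    g1 = compute_glcm(quantize(tile, valid, 8, (0.0, 1.0)), 8)
    g2 = compute_glcm(quantize(tile + shift, valid, 8, (shift, 1.0 + shift)), 8)
    np.testing.assert_allclose(g1.matrix, g2.matrix, atol=1e-12)


def maps_from_array(arr, valid):
    return PolarimetricMaps(
        icp=arr, rratio=arr, dcp=arr, shgcd=arr, shgld=arr, valid=valid
    )


def test_feature_table_shape_exclusion_and_density_filter(rng):
    arr = rng.uniform(0, 1, (128, 128))
    valid = np.ones((128, 128), bool)
    valid[:32, :32] = False  # first tile loses all signal
    arr = np.where(valid, arr, np.nan)
    grid = tile_grid(128, 128, 32)
    excl = np.zeros((128, 128), bool)
    excl[96:, 96:] = True  # last tile excluded
    table = build_feature_table(
        maps_from_array(arr, valid), grid, exclusion_mask=excl, min_density=0.1,
        n_levels=8,
    )
    assert list(table.columns[2:]) == feature_columns()
    assert len(feature_columns()) == 36
    assert len(table) == 14  # 16 tiles - 1 empty - 1 excluded
    assert not ((table.grid_row == 0) & (table.grid_col == 0)).any()
    assert not ((table.grid_row == 3) & (table.grid_col == 3)).any()
    assert table.pixel_density.between(0, 1).all()


def test_feature_table_geometry_mismatch(rng):
    arr = rng.uniform(0, 1, (64, 64))
    with pytest.raises(ValueError, match="geometry"):
        build_feature_table(
            maps_from_array(arr, np.ones((64, 64), bool)), tile_grid(128, 128, 32)
        )
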