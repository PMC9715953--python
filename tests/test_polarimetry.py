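"""Stokes combination, SNR calibration/masking, and the five parameter maps."""

import numpy as np
import pytest

import pshgmargin as pm
from pshgmargin.polarimetry import (
    STATES,
    StokesMaps,
    compute_dcp,
    compute_dichroisms,
    compute_icp,
    compute_rratio,
    compute_stokes,
)


def stack_from_analyzed(**analyzed):
    """Uniform 2x2 stack with the given analyzed intensities for every incoming."""
    a = np.zeros((4, 4, 2, 2))
    for name, value in analyzed.items():
        a[:, STATES.index(name)] = value
    return pm.PolarizationStack(intensities=a)


def stokes_from_scalars(**kw):
    """StokesMaps with 1x1 maps; keys like s0_RCP, s3_LCP."""
    s0 = np.zeros((4, 1, 1))
    s1 = np.zeros((4, 1, 1))
    s3 = np.zeros((4, 1, 1))
    arrays = {"s0": s0, "s1": s1, "s3": s3}
    for key, value in kw.items():
        el, state = key.split("_")
        arrays[el][STATES.index(state)] = value
    return StokesMaps(s0=s0, s1=s1, s3=s3)


@pytest.mark.parametrize(
    "analyzed, exp_s0, exp_s1, exp_s3",
    [
        (dict(LCP=1, RCP=1, VLP=1, HLP=1), 2.0, 0.0, 0.0),
        (dict(RCP=2, LCP=0, HLP=1, VLP=1), 2.0, 0.0, 2.0),
    ],
)
def test_stokes_combination_rule(analyzed, exp_s0, exp_s1, exp_s3):
    stokes = compute_stokes(stack_from_analyzed(**analyzed))
    for inc in STATES:
        assert stokes.get("s0", inc)[0, 0] == exp_s0
        assert stokes.get("s1", inc)[0, 0] == exp_s1
        assert stokes.get("s3", inc)[0, 0] == exp_s3


def test_malformed_stack_rejected():
    with pytest.raises(ValueError, match="shape"):
        pm.PolarizationStack(intensities=np.zeros((3, 4, 8, 8)))
    with pytest.raises(ValueError, match="non-negative"):
        pm.PolarizationStack(intensities=-np.ones((4, 4, 8, 8)))


def test_icp_is_mean_of_circular_s0():
    st = stokes_from_scalars(s0_RCP=3.0, s0_LCP=1.0)
    assert compute_icp(st)[0, 0] == 2.0
    st = stokes_from_scalars(s0_RCP=1.0, s0_LCP=1.0)
    assert compute_icp(st)[0, 0] == 1.0


@pytest.mark.parametrize(
    "s0_sum, s3_diff, expected",
    [
        (2.0, 2.0, 3.0),  # A = 1 -> 1 + 2 + 2*sqrt(0)
        (2.0, -2.0, -1.0),  # A = -1 -> 1 - 2 + 0
    ],
)
def test_rratio_closed_form_cases(s0_sum, s3_diff, expected):
    st = stokes_from_scalars(s0_RCP=s0_sum / 2, s0_LCP=s0_sum / 2, s3_RCP=s3_diff)
    assert compute_rratio(st)[0, 0] == pytest.approx(expected)


def test_rratio_invalid_for_small_or_huge_A():
    st = stokes_from_scalars(s0_RCP=0.5, s0_LCP=0.5, s3_RCP=2.0)  # |A| = 0.5
    assert np.isnan(compute_rratio(st)[0, 0])
    st = stokes_from_scalars(s0_RCP=1e7, s0_LCP=1e7, s3_RCP=1.0)  # A > cap
    assert np.isnan(compute_rratio(st)[0, 0])


@pytest.mark.parametrize(
    "kw, expected",
    [
        (dict(s0_RCP=1, s0_LCP=1, s3_RCP=1, s3_LCP=-1), 1.0),
        (dict(s0_RCP=1, s0_LCP=1, s3_RCP=0, s3_LCP=0), 0.0),
        (dict(s0_RCP=1, s0_LCP=0.5, s3_RCP=0.5, s3_LCP=-0.25), 0.5),
    ],
)
def test_dcp_closed_form_cases(kw, expected):
    assert compute_dcp(stokes_from_scalars(**kw))[0, 0] == pytest.approx(expected)


def test_dichroism_closed_form_and_antisymmetry():
    st = stokes_from_scalars(s0_RCP=3.0, s0_LCP=1.0, s0_VLP=2.0, s0_HLP=2.0)
    cd, ld = compute_dichroisms(st)
    assert cd[0, 0] == pytest.approx(1.0)
    assert ld[0, 0] == pytest.approx(0.0)
    swapped = stokes_from_scalars(s0_RCP=1.0, s0_LCP=3.0, s0_VLP=2.0, s0_HLP=2.0)
    cd2, _ = compute_dichroisms(swapped)
    assert cd2[0, 0] == pytest.approx(-cd[0, 0])


def test_maps_match_per_pixel_scalar_recomputation(rng):
    """Vectorized maps equal a plain per-pixel Python evaluation."""
    s0 = rng.uniform(1, 10, (4, 5, 5))
    s3 = rng.uniform(-0.9, 0.9, (4, 5, 5)) * s0
    st = StokesMaps(s0=s0, s1=np.zeros_like(s0), s3=s3)
    icp, rr = compute_icp(st), compute_rratio(st)
    dcp = compute_dcp(st)
    cd, ld = compute_dichroisms(st)
    iR, iL, iV, iH = (STATES.index(s) for s in ("RCP", "LCP", "VLP", "HLP"))
    for i in range(5):
        for j in range(5):
            s0r, s0l = s0[iR, i, j], s0[iL, i, j]
            s3r, s3l = s3[iR, i, j], s3[iL, i, j]
            assert icp[i, j] == pytest.approx((s0r + s0l) / 2, abs=1e-12)
            a = (s0r + s0l) / (s3r - s3l)
            if 1 <= abs(a) <= 1e6:
                assert rr[i, j] == pytest.approx(
                    1 + 2 * a + 2 * np.sqrt(a**2 - 1), abs=1e-9
                )
            else:
                assert np.isnan(rr[i, j])
            assert dcp[i, j] == pytest.approx(
                0.5 * (abs(s3r) / s0r + abs(s3l) / s0l), abs=1e-12
            )
            assert cd[i, j] == pytest.approx(2 * (s0r - s0l) / (s0r + s0l), abs=1e-12)
            assert ld[i, j] == pytest.approx(
                2 * (s0[iV, i, j] - s0[iH, i, j]) / (s0[iV, i, j] + s0[iH, i, j]),
                abs=1e-12,
            )


def shot_noise_stack(rng, mu, n_frames=10, shape=(64, 64)):
    means = rng.uniform(mu / 10, mu, (4, 4, 1, *shape))
    frames = rng.poisson(np.broadcast_to(means, (4, 4, n_frames, *shape))).astype(float)
    return pm.PolarizationStack(intensities=frames)


def test_snr_calibration_recovers_square_root_law(rng):
    cal = pm.fit_snr_calibration(shot_noise_stack(rng, mu=2000.0))
    assert cal.b == pytest.approx(0.5, abs=0.05)
    assert cal.a > 0 and cal.n_pixels > 0


def test_snr_calibration_predicts_doubling_under_4x_intensity(rng):
    cal_lo = pm.fit_snr_calibration(shot_noise_stack(rng, mu=500.0))
    mu_q = 300.0
    ratio = cal_lo.predict(np.array(4 * mu_q)) / cal_lo.predict(np.array(mu_q))
    assert ratio == pytest.approx(2.0, rel=0.1)


def test_snr_calibration_requires_variation():
    const = pm.PolarizationStack(intensities=np.ones((4, 4, 5, 4, 4)))
    with pytest.raises(ValueError, match="constant"):
        pm.fit_snr_calibration(const)
    few = pm.PolarizationStack(intensities=np.ones((4, 4, 2, 4, 4)))
    with pytest.raises(ValueError, match="3 repeated frames"):
        pm.fit_snr_calibration(few)


def test_snr_calibration_skips_constant_pixels(rng):
    stack = shot_noise_stack(rng, mu=1000.0, shape=(16, 16))
    stack.intensities[:, :, :, 0, 0] = 5.0  # sigma = 0 at one pixel
    cal = pm.fit_snr_calibration(stack)
    assert cal.n_pixels < 4 * 4 * 16 * 16
    assert cal.b == pytest.approx(0.5, abs=0.06)


def test_snr_mask_zero_image_and_inclusive_boundary():
    cal = pm.SNRCalibration(a=1.0, b=0.5, n_pixels=10, residual_scale=0.0, mu_range=(1, 100))
    assert not pm.snr_mask(np.zeros((3, 3)), cal).any()
    # predicted SNR exactly 1.0 at mu=1 -> valid (inclusive >=)
    assert pm.snr_mask(np.ones((2, 2)), cal).all()
    assert not pm.snr_mask(np.full((2, 2), 0.99), cal).any()


def test_snr_mask_matches_per_pixel_mu_sigma_thresholding(rng):
    """Calibration-based masking agrees with direct mu/sigma thresholding."""
    stack = shot_noise_stack(rng, mu=50.0, n_frames=40)
    cal = pm.fit_snr_calibration(stack)
    mu = stack.intensities.mean(axis=2)
    sigma = stack.intensities.std(axis=2, ddof=1)
    direct = np.divide(mu, sigma, out=np.zeros_like(mu), where=sigma > 0) >= 3.0
    predicted = pm.snr_mask(mu, cal, min_snr=3.0)
    agreement = (direct == predicted).mean()
    assert agreement > 0.95


def test_mask_monotone_in_threshold(rng):
    cal = pm.SNRCalibration(a=1.2, b=0.48, n_pixels=10, residual_scale=0.0, mu_range=(1, 100))
    img = rng.uniform(0, 50, (32, 32))
    lo = pm.snr_mask(img, cal, min_snr=1.0)
    hi = pm.snr_mask(img, cal, min_snr=3.0)
    assert np.all(lo | ~hi)  # raising the threshold never adds valid pixels


def test_zero_noise_phantom_roundtrip_exact(zero_noise_phantom):
    cfg, truth, stack = zero_noise_phantom
    maps = pm.compute_parameter_maps(stack, valid=truth.fiber_mask)
    for name, arr in maps.as_dict().items():
        np.testing.assert_allclose(
            arr[truth.fiber_mask], truth.maps[name][truth.fiber_mask],
            rtol=1e-8, atol=1e-8, err_msg=name,
        )
    # invalid pixels carry NaN in every map
    assert np.all(np.isnan(maps.icp[~truth.fiber_mask]))


def test_mask_propagates_to_all_maps(zero_noise_phantom):
    cfg, truth, stack = zero_noise_phantom
    maps = pm.compute_parameter_maps(stack, valid=truth.fiber_mask)
    for arr in maps.as_dict().values():
        assert np.all(np.isnan(arr[~maps.valid]))
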