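"""Stokes–Mueller polarimetry of widefield P-SHG image stacks.

A polarization-resolved SHG acquisition records the SHG intensity for all
16 combinations of 4 incoming and 4 analyzed polarization states
(LCP, RCP, VLP, HLP).  For each incoming state three Stokes elements of the
emitted SHG are formed from the analyzed intensities:

    s0 = I_HLP + I_VLP        (total intensity)
    s1 = I_HLP - I_VLP        (linear-polarization difference)
    s3 = I_RCP - I_LCP        (circular-polarization difference)

and combined into five per-pixel polarimetric parameters:

    I_CP    = (s0_RCP + s0_LCP) / 2
    R       = 1 + 2A + 2*sqrt(A^2 - 1),  A = (s0_RCP + s0_LCP)/(s3_RCP - s3_LCP)
    DCP     = (|s3_RCP|/s0_RCP + |s3_LCP|/s0_LCP) / 2
    SHG-CD  = 2 (s0_RCP - s0_LCP) / (s0_RCP + s0_LCP)
    SHG-LD  = 2 (s0_VLP - s0_HLP) / (s0_VLP + s0_HLP)

where superscripts denote the *incoming* state.  R is the ratio of the two
achiral second-order susceptibility tensor elements chi2_zzz/chi2_zxx for a
fiber axis z; SHG-CD and SHG-LD report out-of-plane and in-plane fiber
orientation; DCP the degree of circular polarization of the emitted SHG.

Stokes elements are kept in exposure-consistent camera counts; no additional
normalization is applied.  The five parameters are ratios (or are later
standardized), so any global intensity scale cancels.  s1 elements are
computed for completeness but are not consumed by the five parameters.

Invalid pixels carry NaN and are excluded from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical polarization-state order used for both stack axes.
STATES = ("LCP", "RCP", "VLP", "HLP")

#: Cap on |A| in the R-ratio: larger values come from near-zero s3
#: differences and are numerically meaningless.
A_CAP = 1e6


@dataclass
class PolarizationStack:
    """Raw 16-state P-SHG stack.

    ``intensities`` has shape (4 incoming, 4 analyzed, n_frames, H, W) in the
    state order :data:`STATES` on both polarization axes.  Repeated frames
    (``n_frames`` > 1) are used for SNR calibration and averaged before the
    Stokes computation.
    """

    intensities: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities, dtype=float)
        if a.ndim == 4:  # no frame axis: insert singleton
            a = a[:, :, None, :, :]
        if a.ndim != 5 or a.shape[0] != 4 or a.shape[1] != 4:
            raise ValueError(
                "intensities must have shape (4, 4, [frames,] H, W); "
                f"got {np.asarray(self.intensities).shape}"
            )
        if np.any(a < 0):
            raise ValueError("raw intensities must be non-negative")
        self.intensities = a

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[3:]

    def frame_mean(self) -> np.ndarray:
        """Average over repeated frames -> (4, 4, H, W)."""
        return self.intensities.mean(axis=2)

    def image(self, incoming: str, analyzed: str, frame: int | None = None) -> np.ndarray:
        i, j = STATES.index(incoming), STATES.index(analyzed)
        if frame is None:
            return self.intensities[i, j].mean(axis=0)
        return self.intensities[i, j, frame]


@dataclass
class StokesMaps:
    """Per-incoming-state Stokes elements s0, s1, s3, each (4, H, W)."""

    s0: np.ndarray
    s1: np.ndarray
    s3: np.ndarray

    def get(self, element: str, incoming: str) -> np.ndarray:
        return getattr(self, element)[STATES.index(incoming)]


@dataclass
class SNRCalibration:
    """Power-law SNR model SNR(mu) = a * mu**b.

    Fitted on log–log axes from per-pixel mean/SD over repeated frames.
    ``mu_range`` records the intensity domain of the fit; predictions outside
    it are extrapolations.
    """

    a: float
    b: float
    n_pixels: int
    residual_scale: float
    mu_range: tuple[float, float]

    def predict(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        out = np.zeros_like(mu)
        pos = mu > 0
        out[pos] = self.a * mu[pos] ** self.b
        return out


@dataclass
class PolarimetricMaps:
    """The five per-pixel polarimetric parameter maps plus a validity mask.

    ``valid`` is the intensity-level mask (SNR thresholding); individual maps
    may carry additional NaNs where their own formula is undefined (e.g. the
    R-ratio radicand going negative under noise).
    """

    icp: np.ndarray
    rratio: np.ndarray
    dcp: np.ndarray
    shgcd: np.ndarray
    shgld: np.ndarray
    valid: np.ndarray

    #: stable parameter-name -> map ordering used across the package
    names: tuple[str, ...] = field(
        default=("shg", "rratio", "dcp", "shgcd", "shgld"), init=False, repr=False
    )

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "shg": self.icp,
            "rratio": self.rratio,
            "dcp": self.dcp,
            "shgcd": self.shgcd,
            "shgld": self.shgld,
        }


def compute_stokes(stack: PolarizationStack) -> StokesMaps:
    """Stokes elements per incoming state from frame-averaged intensities."""
    mean = stack.frame_mean()  # (4 incoming, 4 analyzed, H, W)
    i_lcp = mean[:, STATES.index("LCP")]
    i_rcp = mean[:, STATES.index("RCP")]
    i_vlp = mean[:, STATES.index("VLP")]
    i_hlp = mean[:, STATES.index("HLP")]
    return StokesMaps(s0=i_hlp + i_vlp, s1=i_hlp - i_vlp, s3=i_rcp - i_lcp)


def fit_snr_calibration(stack: PolarizationStack) -> SNRCalibration:
    """Fit SNR(mu) = a*mu**b from repeated frames.

    Per pixel and per state combination, mu is the mean and sigma the standard
    deviation over frames; SNR = mu/sigma.  The power law is fitted by least
    squares on log–log axes over pixels with sigma > 0 and mu > 0.
    """
    if stack.n_frames < 3:
        raise ValueError("SNR calibration requires at least 3 repeated frames")
    mu = stack.intensities.mean(axis=2).ravel()
    sigma = stack.intensities.std(axis=2, ddof=1).ravel()
    ok = (sigma > 0) & (mu > 0)
    if not np.any(ok):
        raise ValueError("all pixels constant across frames: no SNR fit possible")
    snr = mu[ok] / sigma[ok]
    x, y = np.log(mu[ok]), np.log(snr)
    b, log_a = np.polyfit(x, y, 1)
    resid = y - (log_a + b * x)
    return SNRCalibration(
        a=float(np.exp(log_a)),
        b=float(b),
        n_pixels=int(ok.sum()),
        residual_scale=float(np.std(resid)),
        mu_range=(float(mu[ok].min()), float(mu[ok].max())),
    )


def snr_mask(
    intensity: np.ndarray, calibration: SNRCalibration, min_snr: float = 1.0
) -> np.ndarray:
    """Boolean validity mask: predicted SNR(mu) >= min_snr (inclusive)."""
    return calibration.predict(intensity) >= min_snr


def compute_icp(stokes: StokesMaps) -> np.ndarray:
    return 0.5 * (stokes.get("s0", "RCP") + stokes.get("s0", "LCP"))


def compute_rratio(stokes: StokesMaps, a_cap: float = A_CAP) -> np.ndarray:
    """R-ratio map; NaN where |A| < 1 (negative radicand) or |A| > a_cap."""
    num = stokes.get("s0", "RCP") + stokes.get("s0", "LCP")
    den = stokes.get("s3", "RCP") - stokes.get("s3", "LCP")
    with np.errstate(divide="ignore", invalid="ignore"):
        a = num / den
        bad = ~np.isfinite(a) | (np.abs(a) < 1.0) | (np.abs(a) > a_cap)
        a = np.where(bad, np.nan, a)
        r = 1.0 + 2.0 * a + 2.0 * np.sqrt(a**2 - 1.0)
    return r


def compute_dcp(stokes: StokesMaps, tolerance: float = 1e-9) -> np.ndarray:
    """DCP map; NaN where s0 <= 0 or DCP exceeds 1 beyond ``tolerance``."""
    s0r, s0l = stokes.get("s0", "RCP"), stokes.get("s0", "LCP")
    s3r, s3l = stokes.get("s3", "RCP"), stokes.get("s3", "LCP")
    with np.errstate(divide="ignore", invalid="ignore"):
        dcp = 0.5 * (np.abs(s3r) / s0r + np.abs(s3l) / s0l)
    dcp = np.where((s0r > 0) & (s0l > 0), dcp, np.nan)
    dcp = np.where(dcp > 1.0 + tolerance, np.nan, dcp)
    return np.minimum(dcp, 1.0)


def compute_dichroisms(stokes: StokesMaps) -> tuple[np.ndarray, np.ndarray]:
    """(SHG-CD, SHG-LD) maps, each in [-2, 2]; NaN where the denominator <= 0."""
    s0r, s0l = stokes.get("s0", "RCP"), stokes.get("s0", "LCP")
    s0v, s0h = stokes.get("s0", "VLP"), stokes.get("s0", "HLP")
    with np.errstate(divide="ignore", invalid="ignore"):
        cd = 2.0 * (s0r - s0l) / (s0r + s0l)
        ld = 2.0 * (s0v - s0h) / (s0v + s0h)
    cd = np.where(s0r + s0l > 0, cd, np.nan)
    ld = np.where(s0v + s0h > 0, ld, np.nan)
    return cd, ld


def compute_parameter_maps(
    stack: PolarizationStack,
    calibration: SNRCalibration | None = None,
    min_snr: float = 1.0,
    valid: np.ndarray | None = None,
) -> PolarimetricMaps:
    """Full polarimetric analysis of a stack.

    The validity mask is taken from ``valid`` if given, otherwise from SNR
    thresholding of the I_CP intensity with ``calibration``; with neither, all
    pixels with positive I_CP are considered valid (useful for noise-free
    synthetic stacks where no calibration can be fitted).
    """
    stokes = compute_stokes(stack)
    icp = compute_icp(stokes)
    if valid is None:
        if calibration is not None:
            valid = snr_mask(icp, calibration, min_snr)
        else:
            valid = icp > 0
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != icp.shape:
        raise ValueError("validity mask geometry does not match the stack")

    rr = compute_rratio(stokes)
    dcp = compute_dcp(stokes)
    cd, ld = compute_dichroisms(stokes)
    nan = np.where(valid, 0.0, np.nan)
    return PolarimetricMaps(
        icp=icp + nan,
        rratio=rr + nan,
        dcp=dcp + nan,
        shgcd=cd + nan,
        shgld=ld + nan,
        valid=valid,
    )
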