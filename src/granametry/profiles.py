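"""Stack-axis estimation, calibrated intensity profiles, and curve fits.

This is the shared geometric core of both measurement methods: find the
stacking axis of a lamellar system, average the image into a calibrated 1D
intensity profile along that axis, fit a sinusoid to recover the repeat
distance, and fit Gaussians to individual troughs to measure the stromal
gap as a full width at half maximum (FWHM = 2*sqrt(2 ln 2) * sigma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.ndimage import map_coordinates

from .errors import (
    DetectionError,
    FitQualityError,
    InsufficientDataError,
    ValidationError,
)
from .image import CalibratedImage, RoiSpec, crop_roi

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.35482


@dataclass(frozen=True)
class IntensityProfile:
    """Mean intensity versus position (nm) along the stacking axis."""

    positions_nm: np.ndarray
    values: np.ndarray
    spacing_nm: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_nm, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 1 or pos.shape != val.shape or pos.size < 8:
            raise ValidationError("profile needs >= 8 matching positions/values")
        d = np.diff(pos)
        if not (np.all(d > 0) and np.allclose(d, d[0], rtol=1e-6, atol=1e-9)):
            raise ValidationError("positions must be strictly increasing, uniform")
        if self.spacing_nm <= 0 or not math.isclose(d[0], self.spacing_nm, rel_tol=1e-6):
            raise ValidationError("spacing_nm inconsistent with positions")
        object.__setattr__(self, "positions_nm", pos)
        object.__setattr__(self, "values", val)

    @property
    def span_nm(self) -> float:
        return float(self.positions_nm[-1] - self.positions_nm[0])


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares fit of offset + amplitude*sin(2*pi*x/period + phase)."""

    period_nm: float
    amplitude: float
    phase: float
    offset: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.period_nm <= 0:
            raise ValidationError("period must be positive")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError("r_squared must lie in [0, 1]")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.offset + self.amplitude * np.sin(
            2.0 * np.pi * np.asarray(x) / self.period_nm + self.phase
        )


@dataclass(frozen=True)
class PeakFit:
    """Gaussian peak/trough fit; FWHM is derived from sigma."""

    center_nm: float
    sigma_nm: float
    r_squared: float
    amplitude: float = 0.0
    baseline: float = 0.0
    fwhm_nm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValidationError("sigma must be positive")
        object.__setattr__(self, "fwhm_nm", FWHM_PER_SIGMA * self.sigma_nm)


# ----------------------------------------------------------------------
# axis estimation


def _rotated_rect(
    image: CalibratedImage,
    roi: RoiSpec,
    angle_deg: float,
    half_axis: float | None = None,
    half_lat: float | None = None,
    spacing_px: float = 1.0,
) -> np.ndarray:
    """Bilinear resample of the ROI into an axis-aligned frame.

    Rows run along the stacking axis, columns along the lateral direction.
    """
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    ha = roi.half_axis_px if half_axis is None else half_axis
    hl = roi.half_lat_px if half_lat is None else half_lat
    # grids symmetric about the ROI center so that, for an axis-aligned ROI
    # at an integer center, samples land exactly on pixel centers
    na = 2 * int(ha / spacing_px) + 1
    nl = 2 * int(hl / spacing_px) + 1
    sa = (np.arange(na) - (na - 1) / 2.0) * spacing_px
    sl = (np.arange(nl) - (nl - 1) / 2.0) * spacing_px
    r0, c0 = roi.center
    rows = r0 + sa[:, None] * c - sl[None, :] * s
    cols = c0 + sa[:, None] * s + sl[None, :] * c
    nr, nc = image.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() > nr - 1 or cols.max() > nc - 1:
        raise ValidationError("sampling band extends outside the image")
    return map_coordinates(image.pixels, [rows, cols], order=1, mode="nearest")


def estimate_axis(
    image: CalibratedImage,
    roi: RoiSpec | None = None,
    min_radial_bins: int = 3,
    peak_energy_frac: float = 5e-3,
) -> float:
    """Stacking-axis angle (deg, in [-90, 90)) of a periodic stripe stack.

    The axis is the direction of maximal periodic intensity variation,
    found as the dominant off-center peak of the windowed 2D power
    spectrum, refined by a local center-of-mass in frequency space.
    Raises :class:`DetectionError` when no spectral peak stands out
    (aperiodic or uniform ROI).
    """
    roi = roi or RoiSpec.full(image)
    patch, _ = crop_roi(image, roi)
    patch = patch.astype(float)
    if patch.std() < 1e-9 * max(1.0, abs(float(patch.mean()))):
        raise DetectionError("ROI is uniform; no periodic orientation")
    wr = np.hanning(patch.shape[0])[:, None]
    wc = np.hanning(patch.shape[1])[None, :]
    spec = np.fft.fftshift(np.abs(np.fft.fft2((patch - patch.mean()) * wr * wc)) ** 2)
    nr, nc = spec.shape
    fr = np.fft.fftshift(np.fft.fftfreq(nr))[:, None]
    fc = np.fft.fftshift(np.fft.fftfreq(nc))[None, :]
    # suppress DC and the low-frequency envelope of the stack outline
    radial_bins = np.hypot(fr * nr, fc * nc)
    search = spec.copy()
    search[radial_bins < min_radial_bins] = 0.0
    total = search.sum()
    if total <= 0:
        raise DetectionError("no off-center spectral energy")
    ir, ic = np.unravel_index(int(np.argmax(search)), search.shape)
    if search[ir, ic] < peak_energy_frac * total:
        raise DetectionError("no dominant periodic orientation in ROI")
    # sub-bin refinement: power-weighted centroid in a small neighborhood
    r0, r1 = max(ir - 2, 0), min(ir + 3, nr)
    c0, c1 = max(ic - 2, 0), min(ic + 3, nc)
    w = search[r0:r1, c0:c1]
    fr_hat = float((fr[r0:r1, :] * w.sum(axis=1, keepdims=True)).sum() / w.sum())
    fc_hat = float((fc[:, c0:c1] * w.sum(axis=0, keepdims=True)).sum() / w.sum())
    if fr_hat < 0 or (fr_hat == 0 and fc_hat < 0):
        fr_hat, fc_hat = -fr_hat, -fc_hat
    ang = math.degrees(math.atan2(fc_hat, fr_hat))
    if ang >= 90.0:
        ang -= 180.0
    return ang


def estimate_axis_gradient(image: CalibratedImage, roi: RoiSpec | None = None) -> float:
    """Axis angle from the structure tensor (dominant gradient direction).

    Works for a single band (stroma lamella), where the spectral method has
    no repeat to lock onto.
    """
    roi = roi or RoiSpec.full(image)
    patch, _ = crop_roi(image, roi)
    gr, gc = np.gradient(patch.astype(float))
    arr, acc, arc = (gr * gr).sum(), (gc * gc).sum(), (gr * gc).sum()
    trace = arr + acc
    if trace < 1e-12 * patch.size:
        raise DetectionError("ROI is uniform; no gradient orientation")
    # principal eigenvector of [[arr, arc], [arc, acc]]
    theta = 0.5 * math.atan2(2.0 * arc, arr - acc)
    # eigen-direction with the larger eigenvalue
    lam1 = 0.5 * (trace + math.hypot(arr - acc, 2 * arc))
    if lam1 < 0.55 * trace:
        raise DetectionError("no dominant gradient orientation")
    ang = math.degrees(theta)
    if ang >= 90.0:
        ang -= 180.0
    elif ang < -90.0:
        ang += 180.0
    return ang


# ----------------------------------------------------------------------
# profile extraction


def extract_profile(
    image: CalibratedImage,
    roi: RoiSpec,
    angle_deg: float,
    band_px: int = 10,
    spacing_px: float = 1.0,
) -> IntensityProfile:
    """Average the ROI into a 1D intensity profile along the given axis.

    Each profile value is the mean over ``band_px`` bilinear samples taken
    perpendicular to the axis; positions are converted to nm.
    """
    if band_px < 1:
        raise ValidationError("band_px must be >= 1")
    if spacing_px <= 0 or spacing_px > 1.0:
        raise ValidationError("spacing_px must be in (0, 1] px")
    rect = _rotated_rect(
        image, roi, angle_deg,
        half_axis=roi.half_axis_px,
        half_lat=(band_px - 1) / 2.0 if band_px > 1 else 0.0,
        spacing_px=spacing_px,
    )
    if band_px == 1:
        rect = rect[:, :1]
    values = rect.mean(axis=1)
    n = values.size
    positions = (np.arange(n) - (n - 1) / 2.0) * spacing_px * image.nm_per_px
    return IntensityProfile(positions, values, spacing_px * image.nm_per_px)


# ----------------------------------------------------------------------
# fits


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def dominant_period(profile: IntensityProfile) -> float:
    """Initial repeat estimate from the dominant discrete-spectrum frequency."""
    y = profile.values - profile.values.mean()
    if np.allclose(y, 0):
        raise FitQualityError("constant profile has no dominant frequency")
    mag = np.abs(np.fft.rfft(y * np.hanning(y.size)))
    mag[0] = 0.0
    k = int(np.argmax(mag))
    if k == 0 or mag[k] == 0:
        raise FitQualityError("no dominant frequency in profile")
    # parabolic interpolation of log-magnitude around the peak bin
    if 1 <= k < mag.size - 1 and mag[k - 1] > 0 and mag[k + 1] > 0:
        a, b, c = np.log(mag[k - 1 : k + 2])
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        k = k + float(np.clip(delta, -0.5, 0.5))
    n = y.size
    return n * profile.spacing_nm / k


def fit_sinusoid(
    profile: IntensityProfile,
    r2_floor: float = 0.5,
    min_periods: float = 3.0,
) -> SinusoidFit:
    """Fit offset + amplitude*sin(2*pi*x/period + phase) by least squares.

    The period is initialized from the discrete spectrum and refined by
    nonlinear least squares.  Raises :class:`FitQualityError` when the fit
    does not converge or explains less than ``r2_floor`` of the variance,
    and :class:`InsufficientDataError` when fewer than ``min_periods``
    periods fit in the profile.
    """
    x, y = profile.positions_nm, profile.values
    p0_period = dominant_period(profile)
    if profile.span_nm / p0_period < min_periods:
        raise InsufficientDataError(
            f"profile spans {profile.span_nm / p0_period:.2f} periods; "
            f"need >= {min_periods}"
        )

    def model(x, offset, amp, period, phase):
        return offset + amp * np.sin(2.0 * np.pi * x / period + phase)

    # phase/amplitude start from the linear solution at the initial period
    w = 2.0 * np.pi / p0_period
    basis = np.column_stack([np.ones_like(x), np.sin(w * x), np.cos(w * x)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    amp0 = math.hypot(coef[1], coef[2])
    phase0 = math.atan2(coef[2], coef[1])
    try:
        popt, _ = optimize.curve_fit(
            model, x, y,
            p0=[coef[0], amp0, p0_period, phase0],
            bounds=(
                [-np.inf, 0.0, 2.0 * profile.spacing_nm, -2 * np.pi],
                [np.inf, np.inf, profile.span_nm, 2 * np.pi],
            ),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitQualityError(f"sinusoid fit did not converge: {exc}") from exc
    offset, amp, period, phase = popt
    r2 = _r_squared(y, model(x, *popt))
    if r2 < r2_floor:
        raise FitQualityError(f"sinusoid fit r^2 = {r2:.3f} below floor {r2_floor}")
    return SinusoidFit(
        period_nm=float(period), amplitude=float(amp),
        phase=float(phase), offset=float(offset), r_squared=r2,
    )


def fit_trough_fwhm(
    profile: IntensityProfile,
    center_guess_nm: float,
    window_nm: float,
    mode: str = "gauss",
) -> PeakFit:
    """Measure one intensity trough (the stromal gap) as a FWHM.

    The windowed profile is inverted so the trough becomes a peak and a
    Gaussian with baseline is fitted; FWHM = 2*sqrt(2 ln 2)*sigma.  With
    ``mode='crossing'`` the FWHM is read directly from the half-depth
    crossings of the inverted window (linear interpolation), a
    sensitivity-check alternative to the fit.  The window must contain
    exactly one prominent trough.
    """
    x, y = profile.positions_nm, profile.values
    sel = np.abs(x - center_guess_nm) <= window_nm / 2.0
    if sel.sum() < 5:
        raise ValidationError("window contains fewer than 5 samples")
    xw, yw = x[sel], -y[sel]  # invert: trough -> peak
    rng_w = float(yw.max() - yw.min())
    if rng_w == 0:
        raise FitQualityError("window is constant; no trough")
    peaks, _ = signal.find_peaks(yw, prominence=0.25 * rng_w)
    interior_max = 1 <= int(np.argmax(yw)) < yw.size - 1
    if len(peaks) != 1 and not (len(peaks) == 0 and interior_max):
        raise FitQualityError(
            f"window must contain exactly one trough; found {max(len(peaks), 2)}"
        )
    ipk = int(peaks[0]) if len(peaks) == 1 else int(np.argmax(yw))

    if mode == "crossing":
        level = yw.min() + 0.5 * (yw[ipk] - yw.min())
        left = right = None
        for i in range(ipk, 0, -1):
            if yw[i - 1] <= level <= yw[i]:
                f = (level - yw[i - 1]) / (yw[i] - yw[i - 1])
                left = xw[i - 1] + f * (xw[i] - xw[i - 1])
                break
        for i in range(ipk, yw.size - 1):
            if yw[i + 1] <= level <= yw[i]:
                f = (yw[i] - level) / (yw[i] - yw[i + 1])
                right = xw[i] + f * (xw[i + 1] - xw[i])
                break
        if left is None or right is None:
            raise FitQualityError("half-depth crossings not bracketed in window")
        fwhm = right - left
        sigma = fwhm / FWHM_PER_SIGMA
        return PeakFit(center_nm=0.5 * (left + right), sigma_nm=float(sigma),
                       r_squared=1.0, amplitude=rng_w, baseline=float(-yw.min()))

    def model(x, base, amp, c, sig):
        return base + amp * np.exp(-0.5 * ((x - c) / sig) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            model, xw, yw,
            p0=[float(yw.min()), rng_w, float(xw[ipk]), window_nm / 6.0],
            bounds=(
                [-np.inf, 0.0, xw[0], profile.spacing_nm / 4.0],
                [np.inf, np.inf, xw[-1], window_nm],
            ),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitQualityError(f"trough fit did not converge: {exc}") from exc
    base, amp, center, sigma = popt
    return PeakFit(
        center_nm=float(center), sigma_nm=float(sigma),
        r_squared=_r_squared(yw, model(xw, *popt)),
        amplitude=float(amp), baseline=float(base),
    )
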