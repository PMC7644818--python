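"""Stroma-lamella measurements: total thickness, lumen, and membranes.

A stroma lamella is a single membrane-lumen-membrane band.  In HPF contrast
the band is one bright stripe whose total width is measurable; in microwave
contrast the two osmium-dark membranes flank a bright lumen against
intermediate-gray stroma, so lumen width and single-membrane thickness can
be measured separately by three-class segmentation of the perpendicular
intensity profile.

Microwave measurements run on the column-averaged profile rather than per
column: membranes are only ~5 nm (a few pixels) thick, and per-column noise
at realistic SNR would dominate the sub-band widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.filters import threshold_multiotsu
from skimage.measure import label

from .errors import DetectionError, SegmentationError
from .image import CalibratedImage, RoiSpec
from .method2 import Method2Config, _subpixel_crossing, binarize
from .profiles import _rotated_rect, estimate_axis_gradient

HPF = "HPF"
MICROWAVE = "MICROWAVE"


@dataclass(frozen=True)
class LamellaResult:
    """Widths (nm) measured on one stroma lamella."""

    total_nm: float
    contrast_mode: str
    lumen_nm: float | None = None
    membrane_nm_values: tuple[float, float] | None = None

    @property
    def membrane_nm(self) -> float | None:
        if self.membrane_nm_values is None:
            return None
        return float(np.mean(self.membrane_nm_values))


@dataclass(frozen=True)
class LamellaConfig:
    min_component_px: int = 32
    min_band_frac: float = 0.5
    smooth_sigma_px: float = 1.0
    min_membrane_px: int = 2


def _lamella_frame(
    image: CalibratedImage, roi: RoiSpec | None, angle_deg: float | None
) -> tuple[np.ndarray, RoiSpec, float]:
    roi = roi or RoiSpec.full(image, margin_px=1.0)
    if angle_deg is None:
        angle_deg = roi.angle_hint_deg
    if angle_deg is None:
        angle_deg = estimate_axis_gradient(image, roi)
    rect = _rotated_rect(image, roi, angle_deg, spacing_px=1.0)
    return rect, roi, angle_deg


def measure_lamella_hpf(
    image: CalibratedImage,
    roi: RoiSpec | None = None,
    config: LamellaConfig | None = None,
    angle_deg: float | None = None,
) -> LamellaResult:
    """Total membrane-lumen-membrane thickness of one HPF-contrast lamella.

    The single bright band is thresholded and its two borders localized per
    column at the sub-pixel half-level crossing (shared with Method 2); the
    total is the mean per-column width.  Zero or multiple bands raise
    :class:`DetectionError`.
    """
    cfg = config or LamellaConfig()
    rect, roi, angle_deg = _lamella_frame(image, roi, angle_deg)
    m2cfg = Method2Config(
        min_component_px=cfg.min_component_px,
        min_stripe_frac=cfg.min_band_frac,
        smooth_sigma_px=cfg.smooth_sigma_px,
    )
    try:
        mask, half_level = binarize(rect, m2cfg)
    except SegmentationError as exc:
        raise DetectionError(f"no band detected: {exc}") from exc
    nc = mask.shape[1]
    lab, n = label(mask, return_num=True, connectivity=2)
    sizes = np.bincount(lab.ravel())
    bands = [
        l for l in range(1, n + 1)
        if np.flatnonzero((lab == l).any(axis=0)).size >= cfg.min_band_frac * nc
    ]
    if len(bands) != 1:
        raise DetectionError(f"expected exactly one band crossing the ROI, found {len(bands)}")
    only = lab == bands[0]
    rect_s = gaussian_filter1d(rect, cfg.smooth_sigma_px, axis=0) if cfg.smooth_sigma_px > 0 else rect
    widths = []
    nr = rect.shape[0]
    for c in np.flatnonzero(only.any(axis=0)):
        rows = np.flatnonzero(only[:, c])
        r0, r1 = rows[0], rows[-1]
        lo = _subpixel_crossing(rect_s[:, c], max(r0 - 1, 0), half_level, rising=True)
        hi = _subpixel_crossing(rect_s[:, c], min(r1, nr - 2), half_level, rising=False)
        if lo is None:
            lo = r0 - 0.5
        if hi is None:
            hi = r1 + 0.5
        if hi > lo:
            widths.append(hi - lo)
    if len(widths) < cfg.min_band_frac * nc:
        raise DetectionError("band borders measurable on too few columns")
    return LamellaResult(
        total_nm=float(np.mean(widths)) * image.nm_per_px, contrast_mode=HPF
    )


def _core_level(y: np.ndarray, sel: np.ndarray, k: int = 3) -> float:
    """Median of class samples at least ``k`` samples from a class edge."""
    from scipy.ndimage import binary_erosion

    for kk in range(k, 0, -1):
        core = binary_erosion(sel, structure=np.ones(2 * kk + 1, dtype=bool))
        if core.any():
            return float(np.median(y[core]))
    return float(np.median(y[sel]))


def _crossing_on_profile(y: np.ndarray, i: int, level: float, rising: bool) -> float:
    """Linear-interpolated crossing of ``level`` between samples i and i+1."""
    a, b = y[i], y[i + 1]
    if b == a:
        return float(i) + 0.5
    f = (level - a) / (b - a)
    return float(i) + float(np.clip(f, 0.0, 1.0))


def measure_lamella_microwave(
    image: CalibratedImage,
    roi: RoiSpec | None = None,
    config: LamellaConfig | None = None,
    angle_deg: float | None = None,
) -> LamellaResult:
    """Three-band analysis of one microwave-contrast lamella.

    The column-averaged perpendicular profile is segmented into three
    intensity classes (membrane < stroma < lumen) by two thresholds that
    maximize between-class variance.  The two dark (membrane) runs and the
    bright (lumen) core between them fix four boundaries, each refined to
    the half-level crossing between the adjacent class mean levels:
    membrane thickness = width of each dark sub-band, lumen = bright core,
    total = outer edge to outer edge.
    """
    cfg = config or LamellaConfig()
    rect, roi, angle_deg = _lamella_frame(image, roi, angle_deg)
    y = rect.mean(axis=1)
    rng = float(y.max() - y.min())
    if rng <= 1e-12 * max(1.0, abs(float(y.mean()))):
        raise SegmentationError("profile intensity range is degenerate")
    try:
        t_lo, t_hi = threshold_multiotsu(y, classes=3, nbins=256)
    except ValueError as exc:
        raise SegmentationError(f"three classes not separable: {exc}") from exc
    cls = np.digitize(y, [t_lo, t_hi])  # 0 = membrane, 1 = stroma, 2 = lumen
    if not (np.any(cls == 0) and np.any(cls == 1) and np.any(cls == 2)):
        raise SegmentationError("three classes not separable in profile")
    # plateau levels from run cores (transition samples would bias the
    # half-levels and so every sub-band boundary)
    level = [_core_level(y, cls == k) for k in range(3)]
    if not level[0] < level[1] < level[2]:
        raise SegmentationError("class levels not ordered membrane < stroma < lumen")

    # a lamella floats in stroma: both profile ends must be stroma-class,
    # otherwise the "dark bands" are background, not membranes
    if cls[0] != 1 or cls[-1] != 1:
        raise SegmentationError("profile does not start/end in stroma")

    # runs of the dark (membrane) class
    dark = cls == 0
    edges = np.diff(dark.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if dark[0]:
        starts.insert(0, 0)
    if dark[-1]:
        ends.append(dark.size)
    runs = [(a, b) for a, b in zip(starts, ends) if b - a >= cfg.min_membrane_px]
    if len(runs) != 2:
        raise SegmentationError(
            f"expected a dark-bright-dark membrane triplet, found {len(runs)} dark bands"
        )
    (a0, b0), (a1, b1) = runs
    core = cls[b0:a1]
    if core.size == 0 or not np.any(core == 2):
        raise SegmentationError("no bright lumen core between the membranes")

    sm_level = 0.5 * (level[0] + level[1])  # stroma <-> membrane half level
    ml_level = 0.5 * (level[0] + level[2])  # membrane <-> lumen half level

    def fall_before(idx: int, level_: float) -> float:
        i = idx
        while i > 0 and not (y[i - 1] >= level_ >= y[i]):
            i -= 1
        return _crossing_on_profile(y, max(i - 1, 0), level_, rising=False)

    def rise_after(idx: int, level_: float) -> float:
        i = idx
        while i < y.size - 1 and not (y[i] <= level_ <= y[i + 1]):
            i += 1
        return _crossing_on_profile(y, min(i, y.size - 2), level_, rising=True)

    b_outer_lo = fall_before(a0, sm_level)      # stroma -> membrane 1
    b_inner_lo = rise_after(b0 - 1, ml_level)   # membrane 1 -> lumen
    b_inner_hi = fall_before(a1, ml_level)      # lumen -> membrane 2
    b_outer_hi = rise_after(b1 - 1, sm_level)   # membrane 2 -> stroma

    if not (b_outer_lo < b_inner_lo < b_inner_hi < b_outer_hi):
        raise SegmentationError("band boundaries are not ordered")
    nm = image.nm_per_px
    m1 = (b_inner_lo - b_outer_lo) * nm
    m2 = (b_outer_hi - b_inner_hi) * nm
    lum = (b_inner_hi - b_inner_lo) * nm
    return LamellaResult(
        total_nm=(b_outer_hi - b_outer_lo) * nm,
        contrast_mode=MICROWAVE,
        lumen_nm=float(lum),
        membrane_nm_values=(float(m1), float(m2)),
    )
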