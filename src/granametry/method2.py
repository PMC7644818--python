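"""Method 2: binarize, extract stripe borders, measure rectangular widths.

The granum ROI is resampled into an axis-aligned frame (stripes running
across the columns), thresholded into a black-and-white image, and each
bright stripe's two borders are extracted as sub-pixel polylines: per
column, the border is the half-level crossing of the pre-threshold
intensity, localized by linear interpolation.  Each stripe is then reduced
to its *rectangular representation* — the arithmetic mean of per-column
widths — giving per-layer lumen+membranes (lm), stromal gap, and
repeat = lm + gap.

Counting convention: every adjacent stripe pair yields a gap; only interior
stripes (both neighbours present) yield an lm and hence a full layer row,
so N(gap) >= N(repeat) >= N(lm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import remove_small_holes

from .errors import (
    ExtractionError,
    InsufficientDataError,
    SegmentationError,
    ValidationError,
)
from .image import CalibratedImage, RoiSpec
from .profiles import _rotated_rect, estimate_axis


@dataclass(frozen=True)
class Method2Config:
    threshold: float | None = None  # fixed-threshold override for binarize
    min_component_px: int = 32
    min_stripe_frac: float = 0.5  # of the ROI lateral length
    max_discard_frac: float = 0.6  # of foreground area lost to unlinkable fragments
    smooth_sigma_px: float = 1.0  # light pre-smoothing for crossing localization


@dataclass(frozen=True)
class StripeBorders:
    """Sub-pixel borders of one bright stripe in the rotated frame (nm).

    ``cols_nm`` are lateral positions; ``lower_nm``/``upper_nm`` are the
    axis positions of the stripe's two borders per column (lower < upper).
    """

    index: int
    cols_nm: np.ndarray
    lower_nm: np.ndarray
    upper_nm: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(self.upper_nm > self.lower_nm):
            raise ValidationError("upper border must exceed lower border everywhere")

    @property
    def width_nm(self) -> float:
        return float(np.mean(self.upper_nm - self.lower_nm))


@dataclass(frozen=True)
class BorderSet:
    """Ordered, non-overlapping stripe borders plus the frame transform."""

    stripes: tuple[StripeBorders, ...]
    angle_deg: float
    center_rc: tuple[float, float]
    nm_per_px: float

    def __post_init__(self) -> None:
        mids = [0.5 * (s.lower_nm.mean() + s.upper_nm.mean()) for s in self.stripes]
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValidationError("stripes must be ordered along the stacking axis")

    def to_image_coords(self, stripe: StripeBorders, which: str = "lower") -> np.ndarray:
        """Map one border polyline back to (row, col) image coordinates."""
        t = math.radians(self.angle_deg)
        c, s = math.cos(t), math.sin(t)
        axis = (stripe.lower_nm if which == "lower" else stripe.upper_nm) / self.nm_per_px
        lat = stripe.cols_nm / self.nm_per_px
        r = self.center_rc[0] + axis * c - lat * s
        col = self.center_rc[1] + axis * s + lat * c
        return np.column_stack([r, col])


@dataclass(frozen=True)
class LayerMeasurement:
    """One thylakoid layer: bright-stripe width plus the gap above it."""

    index: int
    lm_nm: float
    gap_nm: float
    repeat_nm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.lm_nm <= 0 or self.gap_nm <= 0:
            raise ValidationError("layer widths must be positive")
        object.__setattr__(self, "repeat_nm", self.lm_nm + self.gap_nm)


@dataclass(frozen=True)
class Method2Result:
    """Per-granum output of Method 2."""

    layers: tuple[LayerMeasurement, ...]
    gap_values_nm: tuple[float, ...]  # all adjacent-pair gaps
    n_stripes: int

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def lm_nm(self) -> float:
        return float(np.mean([l.lm_nm for l in self.layers]))

    @property
    def gap_nm(self) -> float:
        return float(np.mean(self.gap_values_nm))

    @property
    def repeat_nm(self) -> float:
        return float(np.mean([l.repeat_nm for l in self.layers]))


def _plateau_level(rect: np.ndarray, sel: np.ndarray, k: int = 3) -> float:
    """Median intensity of the class core: ``sel`` eroded along the axis.

    Falls back to smaller erosions (then to the raw class) when the class
    runs are too thin to have a core.
    """
    for kk in range(k, 0, -1):
        structure = np.ones((2 * kk + 1, 1), dtype=bool)
        core = ndimage.binary_erosion(sel, structure=structure)
        if core.any():
            return float(np.median(rect[core]))
    return float(np.median(rect[sel]))


def _rect_frame(
    image: CalibratedImage, roi: RoiSpec, angle_deg: float
) -> np.ndarray:
    return _rotated_rect(image, roi, angle_deg, spacing_px=1.0)


def binarize(
    rect: np.ndarray, config: Method2Config | None = None
) -> tuple[np.ndarray, float]:
    """Threshold the axis-aligned ROI into a bright-stripe mask.

    The threshold maximizes between-class variance (Otsu) unless a fixed
    override is configured; connected components below the area floor are
    removed.  Returns the mask and the half-level used for sub-pixel border
    localization (midpoint of the two class means).
    """
    cfg = config or Method2Config()
    rect = np.asarray(rect, dtype=float)
    rng = float(rect.max() - rect.min())
    if rng <= 1e-12 * max(1.0, abs(float(rect.mean()))):
        raise SegmentationError("ROI intensity range is degenerate")
    # light smoothing before thresholding: suppresses per-pixel speckle in
    # the blur transition zones without moving (symmetric) edges
    rect_t = (ndimage.gaussian_filter(rect, cfg.smooth_sigma_px)
              if cfg.smooth_sigma_px > 0 else rect)
    thr = cfg.threshold if cfg.threshold is not None else float(threshold_otsu(rect_t))
    mask = rect_t > thr
    if mask.all() or not mask.any():
        raise SegmentationError("threshold separates no classes in ROI")
    # Plateau gray levels, not class means: class means are contaminated by
    # PSF-blurred transition pixels, which would bias the half-level and
    # hence every sub-pixel border.  Erode each class along the stacking
    # axis and take the median of the surviving core pixels.
    bright = _plateau_level(rect, mask)
    dark = _plateau_level(rect, ~mask)
    half_level = 0.5 * (bright + dark)
    if cfg.threshold is None:
        # re-threshold at the half-level so the mask is the pixel-resolution
        # version of the sub-pixel border definition
        mask = rect_t > half_level
        if mask.all() or not mask.any():
            raise SegmentationError("half-level separates no classes in ROI")
    lab, n = label(mask, return_num=True, connectivity=2)
    if n > 0:
        sizes = np.bincount(lab.ravel())
        keep = sizes >= cfg.min_component_px
        keep[0] = False
        mask = keep[lab]
    if not mask.any():
        raise SegmentationError("no component survives the area floor")
    mask = remove_small_holes(mask, max_size=cfg.min_component_px)
    return mask, half_level


def _subpixel_crossing(col: np.ndarray, idx: int, level: float, rising: bool) -> float | None:
    """Half-level crossing position near sample ``idx`` along one column."""
    lo = max(idx - 2, 0)
    hi = min(idx + 2, col.size - 1)
    for i in range(lo, hi):
        a, b = col[i], col[i + 1]
        if rising and a <= level <= b and b > a:
            return i + (level - a) / (b - a)
        if not rising and a >= level >= b and a > b:
            return i + (a - level) / (a - b)
    return None


def extract_borders(
    mask: np.ndarray,
    rect: np.ndarray,
    half_level: float,
    nm_per_px: float,
    config: Method2Config | None = None,
    angle_deg: float = 0.0,
    center_rc: tuple[float, float] = (0.0, 0.0),
) -> BorderSet:
    """Extract per-stripe sub-pixel border polylines from a binary mask.

    ``mask`` and ``rect`` (the pre-threshold intensities) live in the
    axis-aligned frame with the stacking axis along rows.  Per column, each
    stripe border is refined to the half-level crossing of a lightly
    smoothed intensity; columns are linked through the mask's connected
    components.  Stripes shorter than ``min_stripe_frac`` of the ROI width
    are discarded; if too much foreground is lost, extraction fails.
    """
    cfg = config or Method2Config()
    if cfg.smooth_sigma_px > 0:
        rect_s = ndimage.gaussian_filter1d(np.asarray(rect, float), cfg.smooth_sigma_px, axis=0)
    else:
        rect_s = np.asarray(rect, float)
    nr, nc = mask.shape
    lab, n = label(mask, return_num=True, connectivity=2)
    total_fg = int(mask.sum())
    if total_fg == 0:
        raise ExtractionError("empty mask")
    stripes: list[StripeBorders] = []
    discarded = 0
    order = []
    for lbl in range(1, n + 1):
        comp = lab == lbl
        cols_present = np.flatnonzero(comp.any(axis=0))
        if cols_present.size < cfg.min_stripe_frac * nc:
            discarded += int(comp.sum())
            continue
        cols, lowers, uppers = [], [], []
        for c in cols_present:
            rows = np.flatnonzero(comp[:, c])
            r0, r1 = rows[0], rows[-1]
            colint = rect_s[:, c]
            lo = _subpixel_crossing(colint, max(r0 - 1, 0), half_level, rising=True)
            hi = _subpixel_crossing(colint, min(r1, nr - 2), half_level, rising=False)
            if lo is None:
                lo = r0 - 0.5
            if hi is None:
                hi = r1 + 0.5
            if hi <= lo:
                continue
            cols.append(c)
            lowers.append(lo)
            uppers.append(hi)
        if len(cols) < cfg.min_stripe_frac * nc:
            discarded += int(comp.sum())
            continue
        off_axis = (nr - 1) / 2.0
        off_lat = (nc - 1) / 2.0
        sb_cols = (np.asarray(cols, float) - off_lat) * nm_per_px
        stripes.append(
            StripeBorders(
                index=0,
                cols_nm=sb_cols,
                lower_nm=(np.asarray(lowers) - off_axis) * nm_per_px,
                upper_nm=(np.asarray(uppers) - off_axis) * nm_per_px,
            )
        )
        order.append(float(np.mean(lowers) + np.mean(uppers)))
    if discarded > cfg.max_discard_frac * total_fg:
        raise ExtractionError(
            f"{discarded}/{total_fg} foreground px in unlinkable fragments"
        )
    if len(stripes) < 2:
        raise ExtractionError(f"only {len(stripes)} stripe(s) found; need >= 2")
    ranked = sorted(range(len(stripes)), key=lambda i: order[i])
    stripes = [
        StripeBorders(index=k, cols_nm=stripes[i].cols_nm,
                      lower_nm=stripes[i].lower_nm, upper_nm=stripes[i].upper_nm)
        for k, i in enumerate(ranked)
    ]
    return BorderSet(tuple(stripes), angle_deg, center_rc, nm_per_px)


def measure_borders(borders: BorderSet) -> Method2Result:
    """Reduce a border set to per-layer rectangular-representation widths."""
    stripes = borders.stripes
    n = len(stripes)
    if n < 2:
        raise InsufficientDataError("need at least 2 stripes")
    gaps: list[float] = []
    for a, b in zip(stripes, stripes[1:]):
        common, ia, ib = np.intersect1d(a.cols_nm, b.cols_nm, return_indices=True)
        if common.size == 0:
            raise ExtractionError("adjacent stripes share no columns")
        gaps.append(float(np.mean(b.lower_nm[ib] - a.upper_nm[ia])))
        if gaps[-1] <= 0:
            raise ExtractionError("negative gap: stripes overlap")
    layers = []
    for i in range(1, n - 1):
        layers.append(LayerMeasurement(index=i, lm_nm=stripes[i].width_nm, gap_nm=gaps[i]))
    return Method2Result(layers=tuple(layers), gap_values_nm=tuple(gaps), n_stripes=n)


def measure_method2(
    image: CalibratedImage,
    roi: RoiSpec | None = None,
    config: Method2Config | None = None,
    angle_deg: float | None = None,
    return_borders: bool = False,
):
    """Run Method 2 on one granum ROI; see module docstring.

    With ``return_borders=True`` also returns the :class:`BorderSet` for
    overlay rendering.
    """
    cfg = config or Method2Config()
    roi = roi or RoiSpec.full(image, margin_px=1.0)
    if angle_deg is None:
        angle_deg = estimate_axis(image, roi)
    rect = _rect_frame(image, roi, angle_deg)
    mask, half_level = binarize(rect, cfg)
    borders = extract_borders(
        mask, rect, half_level, image.nm_per_px, cfg,
        angle_deg=angle_deg, center_rc=roi.center,
    )
    result = measure_borders(borders)
    if not result.layers:
        raise InsufficientDataError("no interior stripe yields a full layer")
    if return_borders:
        return result, borders
    return result
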