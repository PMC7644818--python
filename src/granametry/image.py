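"""Calibrated micrographs and regions of interest.

A :class:`CalibratedImage` is the raw input to every measurement: a 2D
grayscale pixel grid plus the nm-per-pixel scale of the micrograph.  Pixel
centers sit at integer 0-based coordinates, so a pixel ``(r, c)`` covers the
square ``[r-0.5, r+0.5] x [c-0.5, c+0.5]``; stripe edges may fall at
sub-pixel positions.

ROIs are rotated rectangles in pixel units, matching how an operator draws
a box over a granum or a lamella in an external viewer.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError, ValidationError

logger = logging.getLogger("granametry")

MIN_IMAGE_SIDE = 16


@dataclass(frozen=True)
class CalibratedImage:
    """Grayscale pixel grid with a physical scale.

    Parameters
    ----------
    pixels:
        2D float array of intensities; must be finite everywhere and at
        least 16 x 16.
    nm_per_px:
        Physical size of one pixel in nanometres (> 0).
    identifier:
        Free-text label (file stem, simulation id, ...).
    """

    pixels: np.ndarray
    nm_per_px: float
    identifier: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image must be 2D and at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}, "
                f"got shape {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite intensities")
        object.__setattr__(self, "pixels", px)
        if not (self.nm_per_px > 0):
            raise ValidationError(f"nm_per_px must be positive, got {self.nm_per_px}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_scale(self, nm_per_px: float) -> "CalibratedImage":
        return CalibratedImage(self.pixels, nm_per_px, self.identifier)


@dataclass(frozen=True)
class RoiSpec:
    """Rotated rectangle over an image, in 0-based pixel coordinates.

    ``center`` is (row, col); ``half_axis_px`` is the half-length along the
    (possibly hinted) stacking axis and ``half_lat_px`` the half-length
    across it.  ``angle_hint_deg`` is an optional operator estimate of the
    stacking-axis angle; measurement code refines it.
    """

    center: tuple[float, float]
    half_axis_px: float
    half_lat_px: float
    angle_hint_deg: float | None = None

    def __post_init__(self) -> None:
        if self.half_axis_px <= 0 or self.half_lat_px <= 0:
            raise ValidationError("ROI half-lengths must be positive")

    def validate_inside(self, image: CalibratedImage) -> None:
        """Require the rotated rectangle to lie fully inside the image."""
        ang = math.radians(self.angle_hint_deg or 0.0)
        c, s = abs(math.cos(ang)), abs(math.sin(ang))
        half_r = self.half_axis_px * c + self.half_lat_px * s
        half_c = self.half_axis_px * s + self.half_lat_px * c
        r0, c0 = self.center
        nr, nc = image.shape
        if (
            r0 - half_r < -0.5
            or c0 - half_c < -0.5
            or r0 + half_r > nr - 0.5
            or c0 + half_c > nc - 0.5
        ):
            raise ValidationError("ROI extends outside the image")

    @classmethod
    def full(cls, image: CalibratedImage, margin_px: float = 0.0) -> "RoiSpec":
        """Axis-aligned ROI covering the whole image (minus a margin)."""
        nr, nc = image.shape
        return cls(
            center=((nr - 1) / 2.0, (nc - 1) / 2.0),
            half_axis_px=(nr - 1) / 2.0 - margin_px,
            half_lat_px=(nc - 1) / 2.0 - margin_px,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            center=(float(d["center_row"]), float(d["center_col"])),
            half_axis_px=float(d["half_axis_px"]),
            half_lat_px=float(d["half_lat_px"]),
            angle_hint_deg=(None if d.get("angle_hint_deg") is None else float(d["angle_hint_deg"])),
        )

    def to_json(self, path: str | Path) -> None:
        d = {
            "center_row": self.center[0],
            "center_col": self.center[1],
            "half_axis_px": self.half_axis_px,
            "half_lat_px": self.half_lat_px,
            "angle_hint_deg": self.angle_hint_deg,
        }
        Path(path).write_text(json.dumps(d, indent=2))


def crop_roi(image: CalibratedImage, roi: RoiSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Axis-aligned bounding-box crop of the ROI.

    Returns the cropped array and the (row, col) offset of its origin in the
    parent image.
    """
    roi.validate_inside(image)
    ang = math.radians(roi.angle_hint_deg or 0.0)
    c, s = abs(math.cos(ang)), abs(math.sin(ang))
    half_r = roi.half_axis_px * c + roi.half_lat_px * s
    half_c = roi.half_axis_px * s + roi.half_lat_px * c
    r0 = max(0, int(math.floor(roi.center[0] - half_r)))
    r1 = min(image.shape[0], int(math.ceil(roi.center[0] + half_r)) + 1)
    c0 = max(0, int(math.floor(roi.center[1] - half_c)))
    c1 = min(image.shape[1], int(math.ceil(roi.center[1] + half_c)) + 1)
    return image.pixels[r0:r1, c0:c1], (r0, c0)


def _nm_per_px_from_tiff_tags(path: Path) -> float | None:
    """Read calibration from TIFF resolution tags (pixels per unit)."""
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is None:
                return None
            num, den = res.value if isinstance(res.value, tuple) else (res.value, 1)
            if den == 0 or num == 0:
                return None
            px_per_unit = num / den
            unit_val = unit.value if unit is not None else 2
            unit_val = int(unit_val)
            if unit_val == 3:  # centimetre
                unit_nm = 1e7
            elif unit_val == 2:  # inch
                unit_nm = 2.54e7
            else:
                return None
            return unit_nm / px_per_unit
    except Exception:
        return None


def read_image(path: str | Path, nm_per_px: float | None = None) -> CalibratedImage:
    """Load a TIFF or PNG micrograph as a :class:`CalibratedImage`.

    Calibration precedence: the explicit ``nm_per_px`` argument, then a JSON
    sidecar ``<path>.json`` with key ``nm_per_px``, then TIFF resolution
    tags.  RGB images are converted to luminance with a logged warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        data = iio.imread(path)
    else:
        raise ValidationError(f"unsupported image format: {path.suffix}")
    data = np.asarray(data)
    if data.ndim == 3:
        logger.warning("%s: RGB input converted to luminance", path.name)
        data = data[..., :3] @ np.array([0.2126, 0.7152, 0.0722])

    scale = nm_per_px
    if scale is None:
        sidecar = path.with_name(path.name + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "nm_per_px" in meta:
                scale = float(meta["nm_per_px"])
    if scale is None and suffix in (".tif", ".tiff"):
        scale = _nm_per_px_from_tiff_tags(path)
    if scale is None:
        raise CalibrationError(
            f"{path.name}: no nm-per-pixel calibration (flag, sidecar, or TIFF tag)"
        )
    return CalibratedImage(data.astype(float), scale, identifier=path.stem)


def write_image(image: CalibratedImage, path: str | Path) -> None:
    """Write as 16-bit grayscale TIFF with a calibration sidecar."""
    path = Path(path)
    px = np.clip(image.pixels, 0, 65535)
    tifffile.imwrite(path, np.round(px).astype(np.uint16))
    path.with_name(path.name + ".json").write_text(
        json.dumps({"nm_per_px": image.nm_per_px, "identifier": image.identifier})
    )
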