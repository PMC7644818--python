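"""Synthetic TEM micrographs of grana stacks and stroma lamellae.

The renderer draws an ideal scene with exact ground truth, then degrades it
the way a real micrograph is degraded: Gaussian point-spread blur followed
by noise.  Two contrast regimes are emulated:

``HPF``
    High-pressure-frozen / freeze-substituted contrast.  Each thylakoid
    disc appears as one bright stripe (two membranes plus lumen,
    indistinguishable from each other), separated by darker stromal
    material; exactly two intensity classes exist.

``MICROWAVE``
    Microwave chemical fixation stains membranes strongly: dark membranes,
    bright lumen, and stroma at an intermediate gray, so membrane thickness
    and lumen width are individually resolvable (three or more classes).

Geometry is rendered with area-weighted (anti-aliased) pixel coverage so
edges can sit at sub-pixel positions; tilt is applied analytically in the
scene coordinates, which keeps the nm ground truth exact.  Identical seed
and inputs give bit-identical images.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .errors import ResolutionError, ValidationError
from .geometry import GranaGeometry, LamellaGeometry, make_grana_truth, make_lamella_truth
from .image import CalibratedImage, write_image

HPF = "HPF"
MICROWAVE = "MICROWAVE"

#: Default mean gray values per material class, in a 16-bit-friendly range.
DEFAULT_LEVELS = {
    HPF: {"stripe": 28000.0, "background": 8000.0},
    MICROWAVE: {"membrane": 6000.0, "lumen": 30000.0, "stroma": 18000.0},
}


@dataclass(frozen=True)
class RenderOptions:
    """Imaging parameters for the synthetic microscope.

    ``snr`` is defined as (bright-class mean - dark-class mean) divided by
    the noise standard deviation; ``phase_px`` shifts the scene along the
    stacking axis for sub-pixel edge-placement studies.
    """

    nm_per_px: float = 0.5
    psf_sigma_px: float = 2.0
    noise_model: str = "poisson_gaussian"  # none | gaussian | poisson_gaussian
    snr: float = 5.0
    contrast_mode: str = HPF
    intensity_levels: Mapping[str, float] | None = None
    seed: int = 0
    margin_nm: float = 20.0
    phase_px: float = 0.0

    def __post_init__(self) -> None:
        if self.nm_per_px <= 0:
            raise ValidationError("nm_per_px must be positive")
        if self.psf_sigma_px < 0:
            raise ValidationError("psf_sigma_px must be non-negative")
        if self.contrast_mode not in (HPF, MICROWAVE):
            raise ValidationError(f"unknown contrast mode {self.contrast_mode!r}")
        if self.noise_model not in ("none", "gaussian", "poisson_gaussian"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.snr <= 0:
            raise ValidationError("snr must be positive")
        levels = self.levels()
        if self.contrast_mode == HPF and set(levels) != {"stripe", "background"}:
            raise ValidationError("HPF mode needs exactly the classes {stripe, background}")
        if self.contrast_mode == MICROWAVE and not {"membrane", "lumen", "stroma"} <= set(levels):
            raise ValidationError("MICROWAVE mode needs classes membrane, lumen, stroma")
        if len(set(levels.values())) != len(levels):
            raise ValidationError("intensity levels must be distinct per class")

    def levels(self) -> dict[str, float]:
        if self.intensity_levels is not None:
            return dict(self.intensity_levels)
        return dict(DEFAULT_LEVELS[self.contrast_mode])

    def bright_dark(self) -> tuple[float, float]:
        lv = self.levels()
        if self.contrast_mode == HPF:
            return lv["stripe"], lv["background"]
        return lv["lumen"], lv["membrane"]


@dataclass(frozen=True)
class GroundTruthRecord:
    """Exact geometry and render settings behind one synthetic image."""

    image_id: str
    kind: str  # "grana" | "lamella"
    condition: str
    geometry: GranaGeometry | LamellaGeometry
    options: RenderOptions

    def to_row(self) -> dict:
        g, o = self.geometry, self.options
        row = {
            "image": self.image_id,
            "condition": self.condition,
            "kind": self.kind,
            "repeat_nm": getattr(g, "repeat_nm", ""),
            "gap_nm": getattr(g, "gap_nm", ""),
            "lm_nm": getattr(g, "lm_nm", ""),
            "total_nm": getattr(g, "total_nm", ""),
            "membrane_nm": "" if g.membrane_nm is None else g.membrane_nm,
            "lumen_nm": "" if g.lumen_nm is None else g.lumen_nm,
            "nm_per_px": o.nm_per_px,
            "seed": o.seed,
            "tilt_deg": g.tilt_deg,
            "n_layers": getattr(g, "n_layers", ""),
            "diameter_nm": getattr(g, "diameter_nm", ""),
            "length_nm": getattr(g, "length_nm", ""),
            "psf_sigma_px": o.psf_sigma_px,
            "snr": o.snr,
            "noise_model": o.noise_model,
            "contrast_mode": o.contrast_mode,
            "phase_px": o.phase_px,
            "margin_nm": o.margin_nm,
        }
        return row

    @classmethod
    def from_row(cls, row: Mapping) -> "GroundTruthRecord":
        def _opt(key):
            v = row.get(key, "")
            if v == "" or v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        opts = RenderOptions(
            nm_per_px=float(row["nm_per_px"]),
            psf_sigma_px=float(row["psf_sigma_px"]),
            noise_model=str(row["noise_model"]),
            snr=float(row["snr"]),
            contrast_mode=str(row["contrast_mode"]),
            seed=int(row["seed"]),
            phase_px=float(row.get("phase_px", 0.0)),
            margin_nm=float(row.get("margin_nm", 20.0)),
        )
        if row["kind"] == "grana":
            geom = make_grana_truth(
                gap_nm=float(row["gap_nm"]),
                lm_nm=float(row["lm_nm"]),
                n_layers=int(float(row["n_layers"])),
                diameter_nm=float(row["diameter_nm"]),
                tilt_deg=float(row["tilt_deg"]),
                membrane_nm=_opt("membrane_nm"),
                lumen_nm=_opt("lumen_nm"),
            )
        else:
            geom = make_lamella_truth(
                total_nm=float(row["total_nm"]),
                length_nm=float(row["length_nm"]),
                tilt_deg=float(row["tilt_deg"]),
                membrane_nm=_opt("membrane_nm"),
                lumen_nm=_opt("lumen_nm"),
            )
        return cls(
            image_id=str(row["image"]),
            kind=str(row["kind"]),
            condition=str(row["condition"]),
            geometry=geom,
            options=opts,
        )


# ----------------------------------------------------------------------
# rendering core


def _interval_coverage(u: np.ndarray, intervals: list[tuple[float, float]], w: float) -> np.ndarray:
    """Fraction of the window [u - w/2, u + w/2] covered by the intervals.

    Intervals must be disjoint; this is exact area-weighted anti-aliasing
    in one dimension.
    """
    lo, hi = u - w / 2.0, u + w / 2.0
    cov = np.zeros(u.shape, dtype=float)
    for a, b in intervals:
        cov += np.clip(np.minimum(hi, b) - np.maximum(lo, a), 0.0, None)
    return cov / w


def _axis_coords(shape: tuple[int, int], tilt_deg: float) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-pixel (u, v) scene coordinates in px and the projected pixel
    footprint widths along each axis."""
    nr, nc = shape
    t = math.radians(tilt_deg)
    c, s = math.cos(t), math.sin(t)
    r = np.arange(nr, dtype=float)[:, None] - (nr - 1) / 2.0
    col = np.arange(nc, dtype=float)[None, :] - (nc - 1) / 2.0
    u = r * c + col * s
    v = -r * s + col * c
    w_u = abs(c) + abs(s)
    return u, v, w_u, w_u  # square pixel: same projection both axes


def _canvas_shape(span_px: float, lat_px: float, tilt_deg: float, margin_px: float) -> tuple[int, int]:
    t = math.radians(tilt_deg)
    c, s = abs(math.cos(t)), abs(math.sin(t))
    hu = span_px / 2.0 + margin_px
    hv = lat_px / 2.0 + margin_px
    hr = hu * c + hv * s
    hc = hu * s + hv * c
    return 2 * math.ceil(hr) + 1, 2 * math.ceil(hc) + 1


def _snap_start(span_px: float, phase_px: float) -> float:
    """Scene start along the axis: snapped so that integer-px widths put
    every edge on a pixel boundary (half-integer coordinate)."""
    u0 = -span_px / 2.0
    return u0 + ((0.5 - u0) % 1.0) + phase_px


def _grana_intervals(
    geometry: GranaGeometry, nm_per_px: float, phase_px: float
) -> dict[str, list[tuple[float, float]]]:
    """Disjoint class intervals along the stacking axis, in px."""
    lm = geometry.lm_nm / nm_per_px
    gap = geometry.gap_nm / nm_per_px
    n = geometry.n_layers
    span = n * lm + (n - 1) * gap
    start = _snap_start(span, phase_px)
    stripes = []
    for k in range(n):
        a = start + k * (lm + gap)
        stripes.append((a, a + lm))
    out: dict[str, list[tuple[float, float]]] = {"stripe": stripes}
    if geometry.membrane_nm is not None:
        m = geometry.membrane_nm / nm_per_px
        membranes, lumens = [], []
        for a, b in stripes:
            membranes.extend([(a, a + m), (b - m, b)])
            lumens.append((a + m, b - m))
        out["membrane"] = membranes
        out["lumen"] = lumens
    return out


def _lamella_intervals(
    geometry: LamellaGeometry, nm_per_px: float, phase_px: float
) -> dict[str, list[tuple[float, float]]]:
    total = geometry.total_nm / nm_per_px
    start = _snap_start(total, phase_px)
    band = (start, start + total)
    out: dict[str, list[tuple[float, float]]] = {"stripe": [band]}
    if geometry.membrane_nm is not None:
        m = geometry.membrane_nm / nm_per_px
        out["membrane"] = [(band[0], band[0] + m), (band[1] - m, band[1])]
        out["lumen"] = [(band[0] + m, band[1] - m)]
    return out


def _compose_scene(
    intervals: dict[str, list[tuple[float, float]]],
    u: np.ndarray,
    v: np.ndarray,
    w_u: float,
    w_v: float,
    lat_px: float,
    options: RenderOptions,
) -> np.ndarray:
    levels = options.levels()
    lat = _interval_coverage(v, [(-lat_px / 2.0, lat_px / 2.0)], w_v)
    if options.contrast_mode == HPF:
        bg = levels["background"]
        cov = _interval_coverage(u, intervals["stripe"], w_u)
        return bg + (levels["stripe"] - bg) * cov * lat
    if "membrane" not in intervals:
        raise ValidationError(
            "MICROWAVE rendering requires membrane_nm and lumen_nm in the geometry"
        )
    bg = levels["stroma"]
    cov_m = _interval_coverage(u, intervals["membrane"], w_u)
    cov_l = _interval_coverage(u, intervals["lumen"], w_u)
    return bg + ((levels["membrane"] - bg) * cov_m + (levels["lumen"] - bg) * cov_l) * lat


def _apply_noise(scene: np.ndarray, options: RenderOptions) -> np.ndarray:
    if options.noise_model == "none":
        return scene
    bright, dark = options.bright_dark()
    sd = abs(bright - dark) / options.snr
    rng = np.random.default_rng(options.seed)
    if options.noise_model == "gaussian":
        return scene + rng.normal(0.0, sd, scene.shape)
    # poisson_gaussian: half the target variance as shot noise at the mean
    # scene level, half as Gaussian read noise
    mean_level = 0.5 * (bright + dark)
    gain = 0.5 * sd**2 / mean_level
    shot = rng.poisson(np.clip(scene, 0, None) / gain) * gain
    return shot + rng.normal(0.0, math.sqrt(0.5) * sd, scene.shape)


def _render(
    kind: str,
    geometry: GranaGeometry | LamellaGeometry,
    options: RenderOptions,
    condition: str = "",
    image_id: str | None = None,
) -> tuple[CalibratedImage, GroundTruthRecord]:
    nm = options.nm_per_px
    if kind == "grana":
        if geometry.repeat_nm / nm < 2.0:
            raise ResolutionError(
                f"repeat {geometry.repeat_nm} nm < 2 px at {nm} nm/px"
            )
        span_px = (geometry.n_layers * geometry.lm_nm + (geometry.n_layers - 1) * geometry.gap_nm) / nm
        lat_px = geometry.diameter_nm / nm
        intervals = _grana_intervals(geometry, nm, options.phase_px)
    else:
        if geometry.total_nm / nm < 2.0:
            raise ResolutionError(f"band {geometry.total_nm} nm < 2 px at {nm} nm/px")
        span_px = geometry.total_nm / nm
        lat_px = geometry.length_nm / nm
        intervals = _lamella_intervals(geometry, nm, options.phase_px)
    shape = _canvas_shape(span_px, lat_px, geometry.tilt_deg, options.margin_nm / nm)
    u, v, w_u, w_v = _axis_coords(shape, geometry.tilt_deg)
    scene = _compose_scene(intervals, u, v, w_u, w_v, lat_px, options)
    if options.psf_sigma_px > 0:
        scene = gaussian_filter(scene, options.psf_sigma_px, mode="nearest")
    scene = _apply_noise(scene, options)
    ident = image_id or f"{kind}-{condition or 'sim'}-{options.seed}"
    img = CalibratedImage(scene, nm, identifier=ident)
    rec = GroundTruthRecord(
        image_id=ident, kind=kind, condition=condition, geometry=geometry, options=options
    )
    return img, rec


def render_grana(
    geometry: GranaGeometry,
    options: RenderOptions,
    condition: str = "",
    image_id: str | None = None,
) -> tuple[CalibratedImage, GroundTruthRecord]:
    """Render one granum stack; see module docstring for the scene model."""
    return _render("grana", geometry, options, condition, image_id)


def render_lamella(
    geometry: LamellaGeometry,
    options: RenderOptions,
    condition: str = "",
    image_id: str | None = None,
) -> tuple[CalibratedImage, GroundTruthRecord]:
    """Render one stroma lamella (single membrane-lumen-membrane band)."""
    return _render("lamella", geometry, options, condition, image_id)


def render_truth_mask(record: GroundTruthRecord) -> np.ndarray:
    """Boolean bright-class map of the ideal (unblurred, noiseless) scene.

    Pixels are True where more than half the pixel area is covered by the
    bright stripe class — the reference for segmentation accuracy checks.
    """
    opts = dataclasses.replace(
        record.options, psf_sigma_px=0.0, noise_model="none", contrast_mode=HPF,
        intensity_levels={"stripe": 1.0, "background": 0.0},
    )
    geom = record.geometry
    if record.kind == "lamella" and geom.membrane_nm is not None:
        geom = make_lamella_truth(geom.total_nm, geom.length_nm, geom.tilt_deg)
    img, _ = _render(record.kind, geom, opts, record.condition, record.image_id)
    return img.pixels > 0.5


# ----------------------------------------------------------------------
# cohorts


_DIST_KEYS = {"mean", "sd", "min", "max"}


def _sample_value(spec, rng: np.random.Generator) -> float:
    """Sample one value from a config entry: scalar, {mean, sd}, or {min, max}."""
    if isinstance(spec, (int, float)):
        return float(spec)
    if not isinstance(spec, Mapping) or not set(spec) <= _DIST_KEYS:
        raise ValidationError(f"invalid distribution spec {spec!r}")
    if "mean" in spec:
        return float(rng.normal(spec["mean"], spec.get("sd", 0.0)))
    return float(rng.uniform(spec["min"], spec["max"]))


#: Generator defaults reflecting the study conditions: dark- and
#: light-adapted grana geometries (rectangular-representation means) and
#: the corresponding lamella geometries.
DEFAULT_COHORT_CONFIG: dict = {
    "render": {
        "nm_per_px": 0.5,
        "psf_sigma_px": 2.0,
        "snr": 5.0,
        "noise_model": "poisson_gaussian",
        "contrast_mode": HPF,
    },
    "conditions": {
        "dark": {
            "kind": "grana",
            "count": 25,
            "gap_nm": {"mean": 4.68, "sd": 0.3},
            "lm_nm": {"mean": 12.22, "sd": 0.8},
            "n_layers": {"min": 8, "max": 12},
            "diameter_nm": 200.0,
            "tilt_deg": {"min": -15.0, "max": 15.0},
        },
        "light": {
            "kind": "grana",
            "count": 25,
            "gap_nm": {"mean": 4.20, "sd": 0.3},
            "lm_nm": {"mean": 15.68, "sd": 0.8},
            "n_layers": {"min": 8, "max": 12},
            "diameter_nm": 200.0,
            "tilt_deg": {"min": -15.0, "max": 15.0},
        },
    },
}


#: Rectangular-representation grana geometries (nm) for the two adaptation
#: states, and the corresponding stroma-lamella widths.
GRANA_CONDITIONS = {
    "dark": {"gap_nm": 4.68, "lm_nm": 12.22},
    "light": {"gap_nm": 4.20, "lm_nm": 15.68},
}
LAMELLA_HPF_TOTALS_NM = {"dark": 15.7, "light": 20.9}
LAMELLA_MICROWAVE_NM = {
    "dark": {"membrane_nm": 5.1, "lumen_nm": 5.0},
    "light": {"membrane_nm": 4.8, "lumen_nm": 9.4},
}

#: Between-image variability of the cohort generator (SD, nm): grana widths
#: spread to match ~1 nm-wide width histograms; lamella widths similarly.
COHORT_SDS = {"gap_nm": 0.3, "lm_nm": 0.8, "total_nm": 0.8,
              "membrane_nm": 0.3, "lumen_nm": 0.5}


def grana_cohort_config(
    condition: str,
    count: int = 25,
    nm_per_px: float = 0.5,
    psf_sigma_px: float = 2.0,
    snr: float = 5.0,
) -> dict:
    """Cohort config for dark- or light-adapted granum stacks."""
    geo = GRANA_CONDITIONS[condition]
    return {
        "render": {"nm_per_px": nm_per_px, "psf_sigma_px": psf_sigma_px,
                   "snr": snr, "noise_model": "poisson_gaussian",
                   "contrast_mode": HPF},
        "conditions": {condition: {
            "kind": "grana", "count": count,
            "gap_nm": {"mean": geo["gap_nm"], "sd": COHORT_SDS["gap_nm"]},
            "lm_nm": {"mean": geo["lm_nm"], "sd": COHORT_SDS["lm_nm"]},
            "n_layers": {"min": 8, "max": 12},
            "diameter_nm": 200.0,
            "tilt_deg": {"min": -15.0, "max": 15.0},
        }},
    }


def lamella_cohort_config(
    condition: str,
    contrast_mode: str = HPF,
    count: int = 25,
    nm_per_px: float | None = None,
    psf_sigma_px: float = 2.0,
    snr: float = 5.0,
) -> dict:
    """Cohort config for dark- or light-adapted stroma lamellae."""
    if nm_per_px is None:
        nm_per_px = 0.5 if contrast_mode == HPF else 0.3
    cond: dict = {"kind": "lamella", "count": count, "length_nm": 200.0,
                  "tilt_deg": {"min": -15.0, "max": 15.0}}
    if contrast_mode == HPF:
        cond["total_nm"] = {"mean": LAMELLA_HPF_TOTALS_NM[condition],
                            "sd": COHORT_SDS["total_nm"]}
    else:
        geo = LAMELLA_MICROWAVE_NM[condition]
        cond["membrane_nm"] = {"mean": geo["membrane_nm"],
                               "sd": COHORT_SDS["membrane_nm"]}
        cond["lumen_nm"] = {"mean": geo["lumen_nm"], "sd": COHORT_SDS["lumen_nm"]}
    return {
        "render": {"nm_per_px": nm_per_px, "psf_sigma_px": psf_sigma_px,
                   "snr": snr, "noise_model": "poisson_gaussian",
                   "contrast_mode": contrast_mode},
        "conditions": {condition: cond},
    }


def _sample_geometry(cond: Mapping, rng: np.random.Generator):
    kind = cond.get("kind", "grana")
    tilt = _sample_value(cond.get("tilt_deg", 0.0), rng)
    tilt = ((tilt + 90.0) % 180.0) - 90.0
    if kind == "grana":
        gap = _sample_value(cond["gap_nm"], rng)
        membrane = lumen = None
        if "membrane_nm" in cond and "lumen_nm" in cond:
            membrane = _sample_value(cond["membrane_nm"], rng)
            lumen = _sample_value(cond["lumen_nm"], rng)
            lm = 2.0 * membrane + lumen
        else:
            lm = _sample_value(cond["lm_nm"], rng)
        n_layers = int(round(_sample_value(cond.get("n_layers", 10), rng)))
        return make_grana_truth(
            gap_nm=gap, lm_nm=lm, n_layers=n_layers,
            diameter_nm=_sample_value(cond.get("diameter_nm", 200.0), rng),
            tilt_deg=tilt, membrane_nm=membrane, lumen_nm=lumen,
        )
    if kind == "lamella":
        membrane = lumen = None
        if "membrane_nm" in cond and "lumen_nm" in cond:
            membrane = _sample_value(cond["membrane_nm"], rng)
            lumen = _sample_value(cond["lumen_nm"], rng)
            total = 2.0 * membrane + lumen
        else:
            total = _sample_value(cond["total_nm"], rng)
        return make_lamella_truth(
            total_nm=total,
            length_nm=_sample_value(cond.get("length_nm", 200.0), rng),
            tilt_deg=tilt, membrane_nm=membrane, lumen_nm=lumen,
        )
    raise ValidationError(f"unknown cohort kind {kind!r}")


_ALLOWED_COND_KEYS = {
    "kind", "count", "gap_nm", "lm_nm", "membrane_nm", "lumen_nm", "total_nm",
    "n_layers", "diameter_nm", "length_nm", "tilt_deg",
}


def sample_cohort(
    config: Mapping | None = None, seed: int = 0
) -> Iterator[tuple[CalibratedImage, GroundTruthRecord]]:
    """Yield (image, truth) pairs for every entry in the cohort config.

    Per-image render seeds are derived deterministically from ``seed``, so
    two runs with the same config and seed produce identical cohorts.
    """
    config = dict(DEFAULT_COHORT_CONFIG if config is None else config)
    render_cfg = dict(config.get("render", {}))
    rng = np.random.default_rng(seed)
    for cond_name, cond in config["conditions"].items():
        bad = set(cond) - _ALLOWED_COND_KEYS
        if bad:
            raise ValidationError(f"unknown config keys in condition {cond_name!r}: {sorted(bad)}")
        count = int(cond.get("count", 0))
        for i in range(count):
            geom = _sample_geometry(cond, rng)
            img_seed = int(rng.integers(0, 2**31 - 1))
            opts = RenderOptions(seed=img_seed, **render_cfg)
            image_id = f"{cond_name}-{i:04d}"
            kind = cond.get("kind", "grana")
            if kind == "grana":
                yield render_grana(geom, opts, condition=cond_name, image_id=image_id)
            else:
                yield render_lamella(geom, opts, condition=cond_name, image_id=image_id)


def generate_cohort(
    config: Mapping | str | Path | None,
    out_dir: str | Path,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a cohort of TIFF images plus a ground-truth manifest CSV.

    ``config`` may be a mapping or a path to a YAML file; ``None`` uses the
    default dark/light grana cohort.  Returns the manifest as a DataFrame
    (also written to ``out_dir/manifest.csv``).
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, rec in sample_cohort(config, seed):
        write_image(img, out_dir / f"{rec.image_id}.tif")
        row = rec.to_row()
        row["image"] = f"{rec.image_id}.tif"
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if manifest.empty:
        manifest = pd.DataFrame(
            columns=["image", "condition", "kind", "repeat_nm", "gap_nm", "lm_nm",
                     "total_nm", "membrane_nm", "lumen_nm", "nm_per_px", "seed"]
        )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path: str | Path) -> list[GroundTruthRecord]:
    """Read a manifest CSV back into ground-truth records."""
    df = pd.read_csv(Path(path), keep_default_na=False)
    return [GroundTruthRecord.from_row(row) for _, row in df.iterrows()]
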