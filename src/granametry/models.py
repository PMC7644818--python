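"""Model/Results interface over the measurement pipeline.

The presented API follows the fit-and-summarize idiom of statistical
modelling packages: a model object is built from data (a calibrated
micrograph plus a region of interest), ``fit()`` runs the estimation and
returns an immutable results object carrying the estimates, their
dispersion, diagnostics, and a ``summary()`` table.

``GranaStackModel``
    Fits both repeat-distance estimators to one granum stack: Method 1
    (sinusoid period + trough FWHMs) and Method 2 (binarize + sub-pixel
    stripe borders), then applies the cross-method acceptance gate and the
    compressed-stack artifact flag.

``LamellaModel``
    Fits a single stroma lamella: total thickness in HPF contrast, or
    membrane/lumen/total via three-band analysis in microwave contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import GranametryError
from .image import CalibratedImage, RoiSpec, read_image
from .lamella import (
    HPF,
    MICROWAVE,
    LamellaConfig,
    LamellaResult,
    measure_lamella_hpf,
    measure_lamella_microwave,
)
from .method1 import Method1Config, Method1Result, measure_method1
from .method2 import BorderSet, Method2Config, Method2Result, measure_method2
from .profiles import estimate_axis
from .qc import DEFAULT_GATE_THRESHOLD, CrossValVerdict, QcFlags, cross_validate, make_flags


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable parameters of a grana-stack analysis."""

    method1: Method1Config = field(default_factory=Method1Config)
    method2: Method2Config = field(default_factory=Method2Config)
    gate_threshold: float = DEFAULT_GATE_THRESHOLD
    r2_floor: float = 0.5


@dataclass(frozen=True)
class GranaStackResults:
    """Joint results of both methods on one granum, with QC verdicts."""

    image_id: str
    angle_deg: float
    method1: Method1Result
    method2: Method2Result
    verdict: CrossValVerdict
    flags: QcFlags
    borders: BorderSet

    @property
    def accepted(self) -> bool:
        return self.verdict.accepted and not self.flags.compressed

    def summary(self) -> str:
        m1, m2, v = self.method1, self.method2, self.verdict
        lines = [
            f"Grana stack analysis: {self.image_id or '<in-memory>'}",
            f"  stacking axis           {self.angle_deg:8.2f} deg",
            "                         Method 1    Method 2",
            f"  repeat distance (nm)   {m1.repeat_nm:8.2f}    {m2.repeat_nm:8.2f}",
            f"  stromal gap (nm)       {m1.gap_nm:8.2f}    {m2.gap_nm:8.2f}",
            f"  lumen+membranes (nm)   {m1.lm_nm:8.2f}    {m2.lm_nm:8.2f}",
            f"  n (troughs / layers)   {m1.n_repeats:8d}    {m2.n_layers:8d}",
            f"  sinusoid r^2           {m1.fit_r_squared:8.3f}",
            f"  cross-method deviation {100 * v.deviation_fraction:7.2f} %"
            f"  (threshold {100 * v.threshold_fraction:.0f} %)",
            f"  gate                   {'ACCEPTED' if v.accepted else 'REJECTED'}",
        ]
        if self.flags.compressed:
            lines.append("  flag: compressed stack (repeat < 13 nm)")
        if self.flags.sinusoid_quality_low:
            lines.append("  flag: low sinusoid fit quality")
        return "\n".join(lines)

    def plot_overlay(self, image: CalibratedImage, ax=None):
        """Draw the extracted stripe borders over the micrograph."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(image.pixels, cmap="gray")
        for stripe in self.borders.stripes:
            for which, color in (("lower", "tab:orange"), ("upper", "tab:cyan")):
                rc = self.borders.to_image_coords(stripe, which)
                ax.plot(rc[:, 1], rc[:, 0], color=color, lw=0.8)
        ax.set_title(f"{self.image_id}: border overlay")
        ax.set_axis_off()
        return ax


class GranaStackModel:
    """Two-method morphometry model for one granum stack.

    Parameters
    ----------
    image:
        The calibrated micrograph.
    roi:
        Rotated-rectangle region over the granum; defaults to (almost) the
        whole image.
    config:
        :class:`AnalysisConfig` with method parameters and gate threshold.
    """

    def __init__(
        self,
        image: CalibratedImage,
        roi: RoiSpec | None = None,
        config: AnalysisConfig | None = None,
    ) -> None:
        self.image = image
        self.roi = roi or RoiSpec.full(image, margin_px=1.0)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        nm_per_px: float | None = None,
        roi: RoiSpec | None = None,
        config: AnalysisConfig | None = None,
    ) -> "GranaStackModel":
        return cls(read_image(path, nm_per_px), roi=roi, config=config)

    def fit(self, angle_deg: float | None = None) -> GranaStackResults:
        cfg = self.config
        if angle_deg is None:
            angle_deg = estimate_axis(self.image, self.roi)
        m1 = measure_method1(self.image, self.roi, cfg.method1, angle_deg=angle_deg)
        m2, borders = measure_method2(
            self.image, self.roi, cfg.method2, angle_deg=angle_deg, return_borders=True
        )
        verdict = cross_validate(m1, m2, threshold=cfg.gate_threshold)
        flags = make_flags(m2.repeat_nm, m1.fit_r_squared, r2_floor=cfg.r2_floor)
        return GranaStackResults(
            image_id=self.image.identifier,
            angle_deg=angle_deg,
            method1=m1,
            method2=m2,
            verdict=verdict,
            flags=flags,
            borders=borders,
        )


@dataclass(frozen=True)
class LamellaResults:
    """Results of a single-lamella fit."""

    image_id: str
    angle_deg: float
    result: LamellaResult

    def summary(self) -> str:
        r = self.result
        lines = [
            f"Stroma lamella analysis: {self.image_id or '<in-memory>'} "
            f"({r.contrast_mode} contrast)",
            f"  stacking axis          {self.angle_deg:8.2f} deg",
            f"  total thickness (nm)   {r.total_nm:8.2f}",
        ]
        if r.lumen_nm is not None:
            lines.append(f"  lumen width (nm)       {r.lumen_nm:8.2f}")
            m1, m2 = r.membrane_nm_values
            lines.append(
                f"  membrane (nm)          {r.membrane_nm:8.2f}   (individually {m1:.2f} / {m2:.2f})"
            )
        return "\n".join(lines)


class LamellaModel:
    """Single stroma-lamella morphometry model.

    ``contrast_mode`` selects the estimator: ``"HPF"`` measures the total
    membrane-lumen-membrane width of the one bright band; ``"MICROWAVE"``
    additionally resolves lumen width and single-membrane thickness.
    """

    def __init__(
        self,
        image: CalibratedImage,
        roi: RoiSpec | None = None,
        contrast_mode: str = HPF,
        config: LamellaConfig | None = None,
    ) -> None:
        if contrast_mode not in (HPF, MICROWAVE):
            raise GranametryError(f"unknown contrast mode {contrast_mode!r}")
        self.image = image
        self.roi = roi or RoiSpec.full(image, margin_px=1.0)
        self.contrast_mode = contrast_mode
        self.config = config or LamellaConfig()

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        nm_per_px: float | None = None,
        roi: RoiSpec | None = None,
        contrast_mode: str = HPF,
        config: LamellaConfig | None = None,
    ) -> "LamellaModel":
        return cls(read_image(path, nm_per_px), roi=roi,
                   contrast_mode=contrast_mode, config=config)

    def fit(self, angle_deg: float | None = None) -> LamellaResults:
        from .profiles import estimate_axis_gradient

        if angle_deg is None:
            angle_deg = (
                self.roi.angle_hint_deg
                if self.roi.angle_hint_deg is not None
                else estimate_axis_gradient(self.image, self.roi)
            )
        if self.contrast_mode == HPF:
            res = measure_lamella_hpf(self.image, self.roi, self.config, angle_deg=angle_deg)
        else:
            res = measure_lamella_microwave(self.image, self.roi, self.config, angle_deg=angle_deg)
        return LamellaResults(
            image_id=self.image.identifier, angle_deg=angle_deg, result=res
        )
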