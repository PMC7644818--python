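"""End-to-end cohort pipeline: measure, tabulate, compare, report.

``run_measure`` walks a directory of calibrated micrographs (TIFF/PNG plus
a manifest or sidecar calibrations), fits the appropriate model per image,
and writes a per-layer results table, per-group summaries, and border
overlays for visual inspection.  Per-image failures are logged and
skipped; the run fails only if every image fails.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import GranametryError
from .image import CalibratedImage, RoiSpec, read_image
from .lamella import MICROWAVE
from .models import AnalysisConfig, GranaStackModel, LamellaModel
from .simulate import GroundTruthRecord, load_manifest
from .stats import compare_groups, correlate_methods, fit_gaussian_hist, summarize

logger = logging.getLogger("granametry")

RESULT_COLUMNS = [
    "image", "condition", "method", "layer_index",
    "lm_nm", "gap_nm", "repeat_nm",
    "gate_accepted", "deviation_fraction", "compressed",
    "sinusoid_quality_low", "status",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one measurement run."""

    input_dir: str | Path
    output_dir: str | Path
    nm_per_px: float | None = None
    roi_dir: str | Path | None = None
    mode: str = "auto"  # auto | grana | lamella_hpf | lamella_microwave
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    write_overlays: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "grana", "lamella_hpf", "lamella_microwave"):
            raise GranametryError(f"unknown run mode {self.mode!r}")
        if not Path(self.input_dir).exists():
            raise GranametryError(f"input path {self.input_dir} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        analysis = AnalysisConfig(
            gate_threshold=float(d.get("gate_threshold", 0.09)),
            r2_floor=float(d.get("r2_floor", 0.5)),
        )
        return cls(
            input_dir=d["input_dir"],
            output_dir=d["output_dir"],
            nm_per_px=d.get("nm_per_px"),
            roi_dir=d.get("roi_dir"),
            mode=d.get("mode", "auto"),
            analysis=analysis,
            write_overlays=bool(d.get("write_overlays", True)),
            log_level=d.get("log_level", "INFO"),
        )


def roi_for_record(record: GroundTruthRecord, image: CalibratedImage) -> RoiSpec:
    """Derive the analysis ROI from a simulation ground-truth record.

    Real micrographs come with operator-drawn ROIs; for synthetic cohorts
    the ROI is placed from the known scene layout: centred on the stack,
    padded along the axis to include the outer stripe borders, and
    trimmed laterally to avoid the blur-softened stripe ends.
    """
    g, o = record.geometry, record.options
    nm = o.nm_per_px
    lat_trim = max(4.0, 3.0 * o.psf_sigma_px + 2.0)
    nr, nc = image.shape
    center = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    if record.kind == "grana":
        span_px = (g.n_layers * g.lm_nm + (g.n_layers - 1) * g.gap_nm) / nm
        half_axis = span_px / 2.0 + min(6.0, o.margin_nm / nm - 2.0)
        half_lat = g.diameter_nm / (2.0 * nm) - lat_trim
    else:
        pad = max(12.0, 3.0 * o.psf_sigma_px + 8.0)
        pad = min(pad, o.margin_nm / nm - 2.0)
        half_axis = g.total_nm / (2.0 * nm) + pad
        half_lat = g.length_nm / (2.0 * nm) - lat_trim
    return RoiSpec(center=center, half_axis_px=half_axis, half_lat_px=half_lat,
                   angle_hint_deg=g.tilt_deg)


def _rows_for_grana(res, image_id: str, condition: str) -> list[dict]:
    rows = []
    base = {
        "image": image_id, "condition": condition,
        "gate_accepted": res.verdict.accepted,
        "deviation_fraction": res.verdict.deviation_fraction,
        "compressed": res.flags.compressed,
        "sinusoid_quality_low": res.flags.sinusoid_quality_low,
        "status": "ok" if res.accepted else "rejected_gate",
    }
    if res.flags.compressed:
        base["status"] = "rejected_compressed"
    rows.append({
        **base, "method": "method1", "layer_index": -1,
        "lm_nm": res.method1.lm_nm, "gap_nm": res.method1.gap_nm,
        "repeat_nm": res.method1.repeat_nm,
    })
    for layer in res.method2.layers:
        rows.append({
            **base, "method": "method2", "layer_index": layer.index,
            "lm_nm": layer.lm_nm, "gap_nm": layer.gap_nm,
            "repeat_nm": layer.repeat_nm,
        })
    return rows


def _measure_one(config: RunConfig, image: CalibratedImage,
                 record: GroundTruthRecord | None, roi: RoiSpec | None) -> list[dict]:
    mode = config.mode
    if mode == "auto":
        if record is not None:
            if record.kind == "grana":
                mode = "grana"
            else:
                mode = ("lamella_microwave" if record.options.contrast_mode == MICROWAVE
                        else "lamella_hpf")
        else:
            mode = "grana"
    if roi is None and record is not None:
        roi = roi_for_record(record, image)
    condition = record.condition if record is not None else ""
    if mode == "grana":
        res = GranaStackModel(image, roi, config.analysis).fit()
        return _rows_for_grana(res, image.identifier, condition), res
    model = LamellaModel(
        image, roi, contrast_mode=MICROWAVE if mode == "lamella_microwave" else "HPF"
    )
    lres = model.fit()
    row = {
        "image": image.identifier, "condition": condition, "method": mode,
        "layer_index": -1, "lm_nm": lres.result.total_nm, "gap_nm": np.nan,
        "repeat_nm": np.nan, "gate_accepted": True, "deviation_fraction": np.nan,
        "compressed": False, "sinusoid_quality_low": False, "status": "ok",
    }
    rows = [row]
    if lres.result.lumen_nm is not None:
        rows.append({**row, "method": mode + ":lumen", "lm_nm": lres.result.lumen_nm})
        rows.append({**row, "method": mode + ":membrane", "lm_nm": lres.result.membrane_nm})
    return rows, lres


def run_measure(config: RunConfig) -> pd.DataFrame:
    """Measure every image of a cohort; write results.csv + summary.json."""
    logging.basicConfig(level=config.log_level)
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = in_dir / "manifest.csv"
    records: dict[str, GroundTruthRecord] = {}
    if manifest_path.exists():
        for rec in load_manifest(manifest_path):
            records[Path(rec.image_id).stem] = rec
        paths = sorted(in_dir / Path(r.image_id).name for r in records.values())
    else:
        paths = sorted(p for p in in_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png"))
    if not paths:
        raise GranametryError(f"no input images found in {in_dir}")

    all_rows: list[dict] = []
    n_failed = 0
    overlay_dir = out_dir / "overlays"
    if config.write_overlays:
        overlay_dir.mkdir(exist_ok=True)
    for path in paths:
        t0 = time.perf_counter()
        try:
            image = read_image(path, config.nm_per_px)
            record = records.get(path.stem)
            roi = None
            if config.roi_dir is not None:
                roi_path = Path(config.roi_dir) / f"{path.stem}.json"
                if roi_path.exists():
                    roi = RoiSpec.from_json(roi_path)
            rows, res = _measure_one(config, image, record, roi)
            all_rows.extend(rows)
            if config.write_overlays and hasattr(res, "plot_overlay"):
                import matplotlib

                matplotlib.use("Agg", force=False)
                import matplotlib.pyplot as plt

                ax = res.plot_overlay(image)
                ax.figure.savefig(overlay_dir / f"{path.stem}.png", dpi=120)
                plt.close(ax.figure)
            logger.info("%s: ok (%.2f s)", path.name, time.perf_counter() - t0)
        except (GranametryError, OSError, ValueError) as exc:
            n_failed += 1
            logger.warning("%s: skipped (%s)", path.name, exc)
            all_rows.append({
                "image": path.stem, "condition": "", "method": "",
                "layer_index": -1, "lm_nm": np.nan, "gap_nm": np.nan,
                "repeat_nm": np.nan, "gate_accepted": False,
                "deviation_fraction": np.nan, "compressed": False,
                "sinusoid_quality_low": False,
                "status": f"error:{type(exc).__name__}",
            })
    if n_failed == len(paths):
        raise GranametryError("every image in the run failed")
    table = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)
    table.to_csv(out_dir / "results.csv", index=False)
    summary = summarize_table(table)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return table


def _group_summary_dict(values) -> dict:
    s = summarize(values)
    return {"n": s.n, "mean": s.mean, "sem": s.sem}


def summarize_table(table: pd.DataFrame, bin_width: float = 0.5) -> dict:
    """Per-condition/method summaries, Gaussian fits, and the cross-method
    repeat correlation, from a per-layer results table."""
    out: dict = {"groups": {}, "method_correlation": None}
    ok = table[table["status"].isin(["ok", "rejected_gate", "rejected_compressed"])]
    accepted = ok[ok["status"] == "ok"]
    for (condition, method), grp in accepted.groupby(["condition", "method"]):
        entry: dict = {}
        for col in ("lm_nm", "gap_nm", "repeat_nm"):
            vals = grp[col].dropna().to_numpy()
            if vals.size:
                entry[col] = _group_summary_dict(vals)
                if vals.size >= 30:
                    try:
                        gf = fit_gaussian_hist(vals, bin_width)
                        entry[f"{col}_gaussian"] = {
                            "mu": gf.mu, "sigma": gf.sigma, "r_squared": gf.r_squared,
                        }
                    except GranametryError:
                        pass
        out["groups"][f"{condition}/{method}"] = entry
    m1 = ok[ok["method"] == "method1"].groupby("image")["repeat_nm"].mean()
    m2 = ok[ok["method"] == "method2"].groupby("image")["repeat_nm"].mean()
    joined = pd.concat([m1, m2], axis=1, keys=["m1", "m2"]).dropna()
    if len(joined) >= 3 and joined["m1"].std() > 0 and joined["m2"].std() > 0:
        out["method_correlation"] = correlate_methods(joined.to_numpy())
    n_gate = ok[ok["method"] == "method1"]
    if len(n_gate):
        out["gate_acceptance_rate"] = float(n_gate["gate_accepted"].mean())
    return out


def compare_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    value: str = "repeat_nm",
    method: str = "method2",
    accepted_only: bool = True,
) -> dict:
    """Dark-vs-light style comparison of one width between two cohorts."""
    def _vals(t):
        sel = t[t["method"] == method]
        if accepted_only:
            sel = sel[sel["status"] == "ok"]
        return sel[value].dropna().to_numpy()

    va, vb = _vals(table_a), _vals(table_b)
    delta = compare_groups(va, vb)
    return {
        "value": value,
        "method": method,
        "group_a": _group_summary_dict(va),
        "group_b": _group_summary_dict(vb),
        "delta_nm": delta.delta,
        "percent_change": delta.percent_change,
        "mwu_u": delta.mwu.u_statistic,
        "mwu_p_two_sided": delta.mwu.p_two_sided,
        "mwu_method": delta.mwu.method,
    }
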