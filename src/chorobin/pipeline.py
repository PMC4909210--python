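"""End-to-end orchestration: phantom cohort (or image files) through
binarization, segmentation, measurement and statistics.

Every stage that involves random selection (vessel sampling, lumen
sampling for the layer border, phantom synthesis) draws its seed
deterministically from one master seed, so a rerun with the same
configuration is bit-identical.  Per-eye failures (too few lumens, a
degenerate segmentation, an unreadable file) exclude that eye and are
recorded in the manifest — the analogue of an image-quality gate — but
never abort the run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binarization as bz
from . import layers as ly
from .bscan_io import BScanImage, ChoroidTraces, load_bscan, load_traces, save_cohort_table
from .cohort_stats import ICCResult, TestResult, run_study_comparisons
from .errors import ChorobinError
from .phantom import generate_cohort
from .quantification import ChoroidMeasurement, measure_eye, measurement_to_row, ratio_report

__all__ = ["PipelineConfig", "EyeResult", "PipelineResult",
           "process_eye", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``inputs`` lists image/trace file pairs, or (default) a
    synthetic phantom cohort of ``n_per_group`` eyes per arm is
    generated.  All randomness flows from ``seed``.
    """

    seed: int = 0
    n_per_group: int = 20
    group_spec: dict | None = None           # phantom group overrides
    inputs: tuple = ()                       # of dicts: path, traces, case_id, group
    lateral_scale: float = 11.3              # um/px, for file inputs
    axial_scale: float = 3.87
    niblack: bz.NiblackParams = field(default_factory=bz.NiblackParams)
    half_width_um: float = 750.0
    n_lumens: int = 5
    min_extent_um: float = 100.0
    vessel_n: int = 3
    vessel_min_diameter_um: float = 100.0
    paired_controls: bool = False
    border_mode: str = "normal"


@dataclass
class EyeResult:
    """Measurement plus the per-eye audit log of every intermediate scalar."""

    case_id: str
    group: str
    measurement: ChoroidMeasurement
    log: dict


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    stats_report: dict
    ratios: dict
    eyes: list[EyeResult]
    skipped: list[dict]
    manifest: dict


def _eye_seed(master_seed: int, index: int, purpose: int) -> int:
    """Deterministic per-eye, per-stage seed below 2**31."""
    ss = np.random.SeedSequence([master_seed, purpose, index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def process_eye(image: BScanImage, traces: ChoroidTraces,
                config: PipelineConfig, case_id: str = "eye",
                group: str = "control", index: int = 0) -> EyeResult:
    """Run the per-eye chain: grayscale -> vessel floor -> clamp ->
    binarize -> subfoveal ROI -> layer border -> split -> measure."""
    gray = bz.to_grayscale(image.pixels)
    roi = ly.extract_roi(traces, image, config.half_width_um)
    candidates = bz.detect_dark_components(
        gray, roi.roi_mask, image.lateral_scale, config.vessel_min_diameter_um)
    vessels = bz.sample_vessel_floor(
        gray, candidates, image.lateral_scale, image.axial_scale,
        n=config.vessel_n, min_diameter_um=config.vessel_min_diameter_um,
        seed=_eye_seed(config.seed, index, 1))
    clamped = bz.clamp_floor(gray, vessels.mean_reflectivity)
    bmap = bz.niblack_binarize(clamped, roi.roi_mask, config.niblack)
    boundary = ly.inner_outer_border(
        bmap, traces, roi, n_lumens=config.n_lumens,
        seed=_eye_seed(config.seed, index, 2),
        min_extent_um=config.min_extent_um, mode=config.border_mode)
    inner, outer = ly.split_layers(roi, boundary)
    measurement = measure_eye(bmap, roi.roi_mask, inner, outer, image)
    log = {
        "case_id": case_id,
        "group": group,
        "vessel_floor": vessels.mean_reflectivity,
        "vessel_centers": [list(c) for c in vessels.centers],
        "border_offset_um": boundary.offset_um,
        "per_lumen_depths_um": boundary.per_lumen_depths_um,
        "sampled_lumen_labels": [c.label for c in boundary.sampled_lumens],
        "roi_columns": list(roi.x_range),
        "roi_pixels": int(roi.roi_mask.sum()),
    }
    return EyeResult(case_id=case_id, group=group,
                     measurement=measurement, log=log)


def _collect_cases(config: PipelineConfig):
    """Yield (case_id, group, loader, extra_truth_columns).

    ``loader`` defers file reading into the caller's per-eye error
    handling, so a corrupt input fails that eye only.
    """
    if config.inputs:
        for item in config.inputs:
            def loader(item=item):
                image = load_bscan(item["path"], config.lateral_scale,
                                   config.axial_scale)
                return image, load_traces(item["traces"])
            yield item["case_id"], item["group"], loader, {}
    else:
        for case in generate_cohort(config.group_spec, config.n_per_group,
                                    seed=config.seed):
            truth_cols = {
                "true_luminal_fraction_inner": case.truth.true_luminal_fraction_inner,
                "true_luminal_fraction_outer": case.truth.true_luminal_fraction_outer,
            }
            yield (case.case_id, case.group,
                   lambda case=case: (case.image, case.truth.traces), truth_cols)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Process every input eye, assemble the cohort table and run the
    statistics; optionally write cohort CSV, stats report and manifest.

    Per-eye failures are logged under ``skipped`` and the eye is
    excluded; the run only fails on configuration errors.
    """
    eyes: list[EyeResult] = []
    skipped: list[dict] = []
    rows: list[dict] = []
    for index, (case_id, group, loader, extra) in enumerate(_collect_cases(config)):
        try:
            image, traces = loader()
            eye = process_eye(image, traces, config, case_id, group, index)
        except (ChorobinError, ValueError) as exc:
            skipped.append({"case_id": case_id, "group": group,
                            "reason": f"{type(exc).__name__}: {exc}"})
            continue
        eyes.append(eye)
        row = {"case_id": case_id, "group": group,
               "patient_id": case_id.split("-")[-1]}
        row.update(measurement_to_row(eye.measurement))
        row.update(extra)
        rows.append(row)
    cohort = pd.DataFrame(rows)
    if cohort.empty:
        raise ChorobinError("no eye survived processing; nothing to report")

    measurement_cols = [c for c in cohort.columns
                        if c.endswith("_um2") or c.endswith("_ratio")
                        or c == "csc_index"]
    stats_report = run_study_comparisons(cohort, measurements=measurement_cols,
                                         paired_controls=config.paired_controls)
    ratios = ratio_report(cohort, measurements=measurement_cols)

    manifest = {
        "config": _config_dict(config),
        "eyes": [e.log for e in eyes],
        "skipped": skipped,
        "n_processed": len(eyes),
    }
    result = PipelineResult(cohort=cohort, stats_report=stats_report,
                            ratios=ratios, eyes=eyes, skipped=skipped,
                            manifest=manifest)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["inputs"] = [dict(i) for i in config.inputs]
    return d


def _jsonable(obj):
    if isinstance(obj, (TestResult, ICCResult)):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, str]:
    """Write cohort.csv, stats report, ratio tables and the run manifest.

    Outputs contain no timestamps, so a rerun from the same
    configuration reproduces them byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "cohort": out / "cohort.csv",
        "report": out / "report.json",
        "manifest": out / "manifest.json",
    }
    save_cohort_table(result.cohort, files["cohort"])
    report = {
        "group_comparisons": _jsonable(result.stats_report["group_comparisons"]),
        "ia_comparisons": _jsonable(result.stats_report["ia_comparisons"]),
        "group_summary": json.loads(
            result.ratios["summary"].to_json(orient="index")),
        "percent_ratios": result.ratios["percent_ratios"].to_dict(orient="records"),
    }
    files["report"].write_text(json.dumps(report, indent=2, sort_keys=True))
    files["manifest"].write_text(json.dumps(_jsonable(result.manifest),
                                            indent=2, sort_keys=True))
    return {k: str(v) for k, v in files.items()}
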