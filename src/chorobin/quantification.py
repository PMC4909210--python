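"""Per-eye area measurements, ratios and the CSC index.

Areas are pixel counts converted to um^2 by the pixel-scale calibration;
pixel counts are retained alongside so conservation (hypo + hyper =
total, inner + outer = whole) can be checked exactly at integer level.

The CSC index contrasts the luminal-to-stromal balance of the outer
choroid against the inner choroid:

    CSC index = (outer hypo / outer hyper) / (inner hypo / inner hyper)

An index above 1 means the outer choroid holds relatively more
hyporeflective (luminal) area than the inner choroid — the signature of
dilated Haller-layer vessels.  The index is unit-free: rescaling every
area by a common factor leaves it unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binarization import BinaryChoroidMap
from .bscan_io import BScanImage, pixels_to_um2

__all__ = [
    "RegionMeasurement",
    "ChoroidMeasurement",
    "measure_region",
    "measure_eye",
    "csc_index",
    "csc_index_from_areas",
    "ratio_report",
]


@dataclass(frozen=True)
class RegionMeasurement:
    """Total / hyporeflective / hyperreflective areas of one region."""

    total_px: int
    hypo_px: int
    total_area_um2: float
    hypo_area_um2: float
    hyper_area_um2: float

    @property
    def hyper_px(self) -> int:
        return self.total_px - self.hypo_px

    @property
    def hypo_ratio(self) -> float:
        """Hyporeflective share of the region; NaN for an empty region."""
        if self.total_px == 0:
            return math.nan
        return self.hypo_px / self.total_px


@dataclass(frozen=True)
class ChoroidMeasurement:
    """Whole / inner / outer measurements plus the CSC index for one eye."""

    whole: RegionMeasurement
    inner: RegionMeasurement
    outer: RegionMeasurement
    csc_index: float    # NaN when a hyperreflective component is empty


def measure_region(bmap: BinaryChoroidMap, region_mask: np.ndarray,
                   image: BScanImage) -> RegionMeasurement:
    """Measure one region: areas from pixel counts times pixel area.

    ``region_mask`` must lie within the classified ROI.  Hyporeflective
    pixels are counted from ``hypo_mask & region``; the hyperreflective
    area is the remainder of the region.
    """
    region = np.asarray(region_mask, dtype=bool)
    if (region & ~bmap.roi_mask).any():
        raise ValueError("region_mask extends outside the classified ROI")
    total_px = int(region.sum())
    hypo_px = int((bmap.hypo_mask & region).sum())
    return RegionMeasurement(
        total_px=total_px,
        hypo_px=hypo_px,
        total_area_um2=pixels_to_um2(total_px, image),
        hypo_area_um2=pixels_to_um2(hypo_px, image),
        hyper_area_um2=pixels_to_um2(total_px - hypo_px, image),
    )


def csc_index_from_areas(inner_hypo: float, inner_hyper: float,
                         outer_hypo: float, outer_hyper: float) -> float:
    """(outer hypo/hyper) divided by (inner hypo/hyper); NaN if a
    denominator vanishes (undefined index, reported as missing)."""
    if outer_hyper <= 0 or inner_hyper <= 0 or inner_hypo <= 0:
        return math.nan
    return (outer_hypo / outer_hyper) / (inner_hypo / inner_hyper)


def csc_index(m: ChoroidMeasurement) -> float:
    return csc_index_from_areas(m.inner.hypo_area_um2, m.inner.hyper_area_um2,
                                m.outer.hypo_area_um2, m.outer.hyper_area_um2)


def measure_eye(bmap: BinaryChoroidMap, roi_mask: np.ndarray,
                inner_mask: np.ndarray, outer_mask: np.ndarray,
                image: BScanImage) -> ChoroidMeasurement:
    """Measure whole/inner/outer compartments and the CSC index.

    Because the layer masks partition the ROI, additivity (inner +
    outer = whole for total, hypo and hyper) holds exactly at the
    pixel-count level.
    """
    whole = measure_region(bmap, roi_mask, image)
    inner = measure_region(bmap, inner_mask, image)
    outer = measure_region(bmap, outer_mask, image)
    if inner.total_px + outer.total_px != whole.total_px:
        raise ValueError("inner and outer masks do not partition the ROI")
    idx = csc_index_from_areas(inner.hypo_area_um2, inner.hyper_area_um2,
                               outer.hypo_area_um2, outer.hyper_area_um2)
    return ChoroidMeasurement(whole=whole, inner=inner, outer=outer, csc_index=idx)


def measurement_to_row(m: ChoroidMeasurement) -> dict[str, float]:
    """Flatten a ChoroidMeasurement into cohort-table columns."""
    row: dict[str, float] = {}
    for name, reg in (("whole", m.whole), ("inner", m.inner), ("outer", m.outer)):
        row[f"{name}_total_um2"] = reg.total_area_um2
        row[f"{name}_hypo_um2"] = reg.hypo_area_um2
        row[f"{name}_hyper_um2"] = reg.hyper_area_um2
        row[f"{name}_hypo_ratio"] = reg.hypo_ratio
    row["csc_index"] = m.csc_index
    return row


def ratio_report(cohort: pd.DataFrame,
                 measurements: list[str] | None = None,
                 groups: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Group-level summary: per-group mean/SD and pairwise percent ratios.

    Percent ratios are ratios of group *means* rounded to the nearest
    integer percent (the convention used for cohort-level summaries);
    per-eye ratios, which feed the statistics, live in the cohort table
    itself.  Returns ``{"summary": ..., "percent_ratios": ...}``.
    Raises ValueError if a requested group has no rows.
    """
    if measurements is None:
        skip = {"case_id", "group", "patient_id", "match_id", "ia_grade"}
        measurements = [c for c in cohort.columns
                        if c not in skip and pd.api.types.is_numeric_dtype(cohort[c])]
    if groups is None:
        groups = list(cohort["group"].unique())
    for g in groups:
        if cohort[cohort["group"] == g].empty:
            raise ValueError(f"group {g!r} is empty")
    summary = cohort.groupby("group")[measurements].agg(["mean", "std"])
    rows = []
    for num in groups:
        for den in groups:
            if num == den:
                continue
            for mcol in measurements:
                a = cohort.loc[cohort["group"] == num, mcol].mean()
                b = cohort.loc[cohort["group"] == den, mcol].mean()
                pct = int(round(100.0 * a / b)) if b else math.nan
                rows.append({"measurement": mcol, "numerator": num,
                             "denominator": den, "percent": pct})
    return {"summary": summary, "percent_ratios": pd.DataFrame(rows)}
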