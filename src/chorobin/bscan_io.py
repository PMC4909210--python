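"""Image, trace and cohort-table I/O plus pixel/physical unit conversion.

EDI-OCT B-scans are exchanged as single-frame TIFF files (8-bit grayscale
or 24-bit RGB).  Exported TIFFs carry no reliable scale metadata, so the
pixel calibration (micrometres per pixel, laterally and axially) is always
supplied by the caller.  Boundary traces — the retinal pigment epithelium
(RPE) polyline, the chorioscleral border (CSB) polyline and the foveal
centre column — travel as a CSV (columns ``x, y_rpe, y_csb``) with a JSON
sidecar holding ``fovea_x`` and the scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import TraceError

#: The three study arms a cohort row may belong to.
GROUPS = ("CSC", "fellow", "control")

#: Recognised indocyanine-green angiography hyperpermeability grades.
IA_GRADES = ("very severe", "severe", "moderate", "mild")


@dataclass(frozen=True)
class BScanImage:
    """A 2-D OCT intensity raster with its pixel-scale calibration.

    Parameters
    ----------
    pixels
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array.  Row index
        increases with depth (y down), column index laterally.
    lateral_scale, axial_scale
        Micrometres per pixel along x and y respectively; must be > 0.
    """

    pixels: np.ndarray
    lateral_scale: float
    axial_scale: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D or 3-D raster")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ValueError(f"3-D raster must have 3 channels, got {px.shape[2]}")
        if not (self.lateral_scale > 0 and self.axial_scale > 0):
            raise ValueError("pixel scales must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_area_um2(self) -> float:
        """Physical area of one pixel in square micrometres."""
        return self.lateral_scale * self.axial_scale


def pixels_to_um2(n_pixels: float, image: BScanImage) -> float:
    """Convert a pixel count to an area in square micrometres."""
    if n_pixels < 0:
        raise ValueError("pixel count must be non-negative")
    return float(n_pixels) * image.pixel_area_um2


def um2_to_pixels(area_um2: float, image: BScanImage) -> float:
    """Inverse of :func:`pixels_to_um2` (fractional pixel count)."""
    return float(area_um2) / image.pixel_area_um2


def load_bscan(path: str | Path, lateral_scale: float, axial_scale: float) -> BScanImage:
    """Read a single-frame grayscale or RGB TIFF as a :class:`BScanImage`.

    RGB content is retained (vessel reflectivity is sampled on the
    original image; conversion to 8-bit happens later in the pipeline).

    Raises
    ------
    ValueError
        Unreadable file, multi-frame stack, or non-positive scales.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise ValueError(f"{path}: expected a single frame, got {len(tif.pages)}")
            arr = tif.asarray()
    except ValueError:
        raise
    except Exception as exc:  # tifffile raises various types on corrupt input
        raise ValueError(f"{path}: cannot decode TIFF ({exc})") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return BScanImage(arr, lateral_scale, axial_scale)


def save_bscan(image: BScanImage, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(image.pixels, dtype=np.uint8))


@dataclass
class ChoroidTraces:
    """Manual boundary traces delimiting the choroid band.

    ``x`` must be strictly increasing (polylines are single-valued
    functions of x) and ``y_rpe < y_csb`` everywhere — the RPE lies above
    the chorioscleral border.  Values between listed vertices are linearly
    interpolated.
    """

    x: np.ndarray
    y_rpe: np.ndarray
    y_csb: np.ndarray
    fovea_x: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y_rpe = np.asarray(self.y_rpe, dtype=float)
        self.y_csb = np.asarray(self.y_csb, dtype=float)
        if not (self.x.shape == self.y_rpe.shape == self.y_csb.shape) or self.x.ndim != 1:
            raise TraceError("x, y_rpe, y_csb must be 1-D arrays of equal length")
        if self.x.size < 2:
            raise TraceError("traces need at least two vertices")
        if not np.all(np.diff(self.x) > 0):
            raise TraceError("trace x coordinates must be strictly increasing (no folds)")
        crossing = self.y_rpe >= self.y_csb
        if crossing.any():
            xbad = self.x[int(np.argmax(crossing))]
            raise TraceError(f"RPE/CSB traces cross at x = {xbad:g}")

    def rpe_at(self, xq) -> np.ndarray:
        return np.interp(xq, self.x, self.y_rpe)

    def csb_at(self, xq) -> np.ndarray:
        return np.interp(xq, self.x, self.y_csb)


def save_traces(traces: ChoroidTraces, csv_path: str | Path,
                lateral_scale: float | None = None,
                axial_scale: float | None = None) -> None:
    """Write traces as CSV plus a JSON header sidecar (``<stem>.json``)."""
    csv_path = Path(csv_path)
    pd.DataFrame({"x": traces.x, "y_rpe": traces.y_rpe, "y_csb": traces.y_csb}
                 ).to_csv(csv_path, index=False)
    header = {"fovea_x": float(traces.fovea_x)}
    if lateral_scale is not None:
        header["lateral_scale"] = float(lateral_scale)
    if axial_scale is not None:
        header["axial_scale"] = float(axial_scale)
    csv_path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def load_traces(csv_path: str | Path) -> ChoroidTraces:
    """Read traces written by :func:`save_traces`; save∘load is identity.

    Raises :class:`~chorobin.errors.TraceError` on missing columns or
    crossing polylines (the error names the first offending column).
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = {"x", "y_rpe", "y_csb"} - set(df.columns)
    if missing:
        raise TraceError(f"{csv_path}: missing columns {sorted(missing)}")
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise TraceError(f"{csv_path}: missing JSON header {sidecar.name}")
    header = json.loads(sidecar.read_text())
    if "fovea_x" not in header:
        raise TraceError(f"{sidecar}: missing fovea_x")
    return ChoroidTraces(df["x"].to_numpy(), df["y_rpe"].to_numpy(),
                         df["y_csb"].to_numpy(), float(header["fovea_x"]))


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check group labels, IA grades and area signs of a cohort table."""
    if "case_id" not in df.columns or "group" not in df.columns:
        raise ValueError("cohort table needs 'case_id' and 'group' columns")
    bad = set(df["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; allowed: {GROUPS}")
    if "ia_grade" in df.columns:
        grades = set(df["ia_grade"].dropna().unique()) - set(IA_GRADES)
        if grades:
            raise ValueError(f"unknown IA grades {sorted(grades)}")
    for col in df.columns:
        if col.endswith("_um2") and (df[col].dropna() < 0).any():
            raise ValueError(f"negative area in column {col}")
    return df


def load_cohort_table(path: str | Path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path))


def save_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort_table(df).to_csv(path, index=False)
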