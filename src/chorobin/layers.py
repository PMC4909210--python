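"""Subfoveal ROI extraction and inner/outer choroid layer segmentation.

The region of interest spans 750 um nasally and temporally from the
foveal centre and extends from the RPE down to the chorioscleral border.
The inner/outer split follows a depth rule applied to the *binarized*
image: perpendiculars are dropped from the RPE to the innermost point of
5 randomly chosen large (lateral extent >= 100 um) hyporeflective lumen
components, and the mean of those 5 perpendicular depths defines the
border between the inner choroidal vascular layer (choriocapillaris +
Sattler) and the outer layer (Haller).  The border polyline is the RPE
polyline displaced by that mean depth along the local inward normal of
the smoothed RPE; a horizontal-line variant is available via
``mode="horizontal"``.

Conventions: a pixel belongs to the ROI iff ``rpe(x) < y <= csb(x)``
within the x-range; pixels exactly on the inner/outer border belong to
the outer layer.  Because raw manual traces are jagged, normals are
taken on an RPE polyline smoothed with a 7-vertex moving average, with
tangents from central differences in physical (um) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .binarization import BinaryChoroidMap
from .bscan_io import BScanImage, ChoroidTraces
from .errors import RoiError, SegmentationError

__all__ = [
    "SubfovealROI",
    "LumenComponent",
    "LayerBoundary",
    "extract_roi",
    "find_lumen_components",
    "inner_outer_border",
    "split_layers",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SubfovealROI:
    """The subfoveal choroid band: x-range plus per-pixel mask."""

    x_range: tuple[int, int]     # [x0, x1) pixel columns
    roi_mask: np.ndarray         # bool raster
    traces: ChoroidTraces
    lateral_scale: float
    axial_scale: float

    @property
    def width_px(self) -> int:
        return self.x_range[1] - self.x_range[0]

    @property
    def columns(self) -> np.ndarray:
        return np.arange(self.x_range[0], self.x_range[1])


@dataclass
class LumenComponent:
    """One 8-connected hyporeflective component within the ROI."""

    label: int
    n_pixels: int
    lateral_extent_um: float
    innermost_point: tuple[int, int]   # (x_px, y_px) closest to the RPE
    depth_um: float                    # perpendicular distance to the RPE


@dataclass
class LayerBoundary:
    """Inner/outer choroid border derived from sampled lumen depths."""

    offset_um: float                       # mean of per_lumen_depths_um
    boundary_x: np.ndarray                 # ROI columns
    boundary_y: np.ndarray                 # border row (float) per column
    sampled_lumens: list[LumenComponent]
    per_lumen_depths_um: list[float]


def extract_roi(traces: ChoroidTraces, image: BScanImage,
                half_width_um: float = 750.0) -> SubfovealROI:
    """Build the subfoveal ROI mask.

    The x-range is ``[fovea_x - hw, fovea_x + hw)`` with
    ``hw = round(half_width_um / lateral_scale)`` pixels, giving a
    physical width of ``2 * half_width_um`` to within one pixel.  A
    pixel column contributes the rows with ``rpe(x) < y <= csb(x)``.

    Raises
    ------
    RoiError
        If the requested span is clipped by the image edge.
    """
    hw = int(round(half_width_um / image.lateral_scale))
    fx = int(round(traces.fovea_x))
    x0, x1 = fx - hw, fx + hw
    if x0 < 0 or x1 > image.width:
        raise RoiError(
            f"ROI columns [{x0}, {x1}) exceed image width {image.width}; "
            "fovea too close to the scan edge")
    cols = np.arange(x0, x1)
    rpe = traces.rpe_at(cols)
    csb = traces.csb_at(cols)
    if csb.max() > image.height - 1:
        raise RoiError("chorioscleral border extends below the image")
    rows = np.arange(image.height)[:, None].astype(float)
    mask = np.zeros((image.height, image.width), dtype=bool)
    mask[:, x0:x1] = (rows > rpe) & (rows <= csb)
    return SubfovealROI((x0, x1), mask, traces,
                        image.lateral_scale, image.axial_scale)


def _smoothed_rpe(traces: ChoroidTraces, cols: np.ndarray) -> np.ndarray:
    """RPE rows at integer columns, smoothed with a 7-vertex window."""
    y = traces.rpe_at(cols)
    return ndimage.uniform_filter1d(y, size=7, mode="nearest")


def find_lumen_components(bmap: BinaryChoroidMap, roi: SubfovealROI,
                          min_extent_um: float = 100.0) -> list[LumenComponent]:
    """8-connected hyporeflective components with lateral extent
    >= ``min_extent_um`` inside the ROI, each with its innermost point.

    The innermost point is the component pixel at minimum perpendicular
    (Euclidean, in physical units) distance to the smoothed RPE
    polyline; since distance to the RPE grows with depth, only each
    component's top-of-column pixels need to be examined.
    """
    hypo = bmap.hypo_mask & roi.roi_mask
    labels, n = ndimage.label(hypo, structure=_EIGHT)
    if n == 0:
        return []
    # dense RPE curve in physical coordinates, slightly beyond the ROI
    pad = 10
    x0 = max(roi.x_range[0] - pad, int(roi.traces.x[0]))
    x1 = min(roi.x_range[1] + pad, int(roi.traces.x[-1]) + 1)
    curve_cols = np.arange(x0, x1)
    curve_y = _smoothed_rpe(roi.traces, curve_cols)
    cx = curve_cols * roi.lateral_scale
    cy = curve_y * roi.axial_scale

    out: list[LumenComponent] = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        rows, cols = np.nonzero(comp)
        cols_abs = cols + sl[1].start
        rows_abs = rows + sl[0].start
        extent_um = (cols_abs.max() - cols_abs.min() + 1) * roi.lateral_scale
        if extent_um < min_extent_um:
            continue
        # top pixel of each occupied column
        order = np.lexsort((rows_abs, cols_abs))
        ca, ra = cols_abs[order], rows_abs[order]
        first = np.concatenate(([True], np.diff(ca) > 0))
        tx, ty = ca[first], ra[first]
        px = tx * roi.lateral_scale
        py = ty * roi.axial_scale
        d2 = (px[:, None] - cx[None, :]) ** 2 + (py[:, None] - cy[None, :]) ** 2
        dmin = np.sqrt(d2.min(axis=1))
        k = int(np.argmin(dmin))
        out.append(LumenComponent(
            label=lab,
            n_pixels=int(comp.sum()),
            lateral_extent_um=float(extent_um),
            innermost_point=(int(tx[k]), int(ty[k])),
            depth_um=float(dmin[k]),
        ))
    return out


def inner_outer_border(bmap: BinaryChoroidMap, traces: ChoroidTraces,
                       roi: SubfovealROI, n_lumens: int = 5,
                       seed: int | np.random.Generator = 0,
                       min_extent_um: float = 100.0,
                       mode: str = "normal") -> LayerBoundary:
    """Derive the inner/outer choroid border from sampled lumen depths.

    ``n_lumens`` qualifying components are chosen uniformly without
    replacement (seeded); the border offset is the arithmetic mean of
    their perpendicular depths below the RPE.  With ``mode="normal"``
    (default) the border polyline is the smoothed RPE displaced by the
    offset along its local inward normal; ``mode="horizontal"`` places a
    flat line at the mean RPE row plus the offset.

    Raises
    ------
    SegmentationError
        Fewer than ``n_lumens`` qualifying components — an unsegmentable
        scan (the image-quality gate).
    """
    comps = find_lumen_components(bmap, roi, min_extent_um=min_extent_um)
    if len(comps) < n_lumens:
        raise SegmentationError(
            f"only {len(comps)} lumen components with lateral extent >= "
            f"{min_extent_um} um in the ROI; need {n_lumens}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = sorted(int(i) for i in rng.choice(len(comps), size=n_lumens, replace=False))
    sampled = [comps[i] for i in idx]
    depths = [c.depth_um for c in sampled]
    offset_um = float(np.mean(depths))

    cols = roi.columns.astype(float)
    y_s = _smoothed_rpe(traces, cols)
    if mode == "horizontal":
        by = np.full_like(cols, float(y_s.mean()) + offset_um / roi.axial_scale)
        return LayerBoundary(offset_um, cols.astype(int), by, sampled, depths)
    if mode != "normal":
        raise ValueError(f"unknown border mode {mode!r}")
    # displace along the local inward normal, in physical coordinates
    X = cols * roi.lateral_scale
    Y = y_s * roi.axial_scale
    tx = np.gradient(X)
    ty = np.gradient(Y)
    norm = np.hypot(tx, ty)
    nx, ny = -ty / norm, tx / norm
    flip = ny < 0          # inward normal points to larger y (deeper)
    nx[flip] *= -1.0
    ny[flip] *= -1.0
    bx = (X + offset_um * nx) / roi.lateral_scale
    by = (Y + offset_um * ny) / roi.axial_scale
    # resample to one row value per integer ROI column
    by_cols = np.interp(cols, bx, by)
    return LayerBoundary(offset_um, cols.astype(int), by_cols, sampled, depths)


def split_layers(roi: SubfovealROI,
                 boundary: LayerBoundary) -> tuple[np.ndarray, np.ndarray]:
    """Partition the ROI into inner and outer layer masks.

    Inner = ROI pixels strictly above the border polyline; outer = ROI
    pixels on or below it.  The two masks are disjoint and their union
    is exactly the ROI.

    Raises
    ------
    SegmentationError
        Border at or below the chorioscleral border for more than half
        of the ROI columns (degenerate segmentation).
    """
    x0, x1 = roi.x_range
    csb = roi.traces.csb_at(roi.columns)
    degenerate = boundary.boundary_y >= csb
    if degenerate.mean() > 0.5:
        raise SegmentationError(
            f"border lies below the chorioscleral border for "
            f"{int(degenerate.sum())}/{degenerate.size} columns")
    h = roi.roi_mask.shape[0]
    rows = np.arange(h)[:, None].astype(float)
    above = np.zeros_like(roi.roi_mask)
    above[:, x0:x1] = rows < boundary.boundary_y
    inner = roi.roi_mask & above
    outer = roi.roi_mask & ~above
    return inner, outer
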