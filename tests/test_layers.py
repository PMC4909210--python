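"""Subfoveal ROI geometry, lumen component detection and the
inner/outer layer split."""

import numpy as np
import pytest

from chorobin import binarization as bz
from chorobin import layers as ly
from chorobin.bscan_io import BScanImage, ChoroidTraces
from chorobin.errors import RoiError, SegmentationError


def _flat_setup(width=400, height=300, rpe=100.0, csb=200.0, scale=5.0):
    img = BScanImage(np.zeros((height, width), dtype=np.uint8), scale, scale)
    x = np.arange(width)
    traces = ChoroidTraces(x, np.full(width, rpe), np.full(width, csb),
                           fovea_x=(width - 1) / 2.0)
    return img, traces


def _bmap_from_hypo(hypo, roi_mask):
    return bz.BinaryChoroidMap(hypo_mask=hypo & roi_mask, roi_mask=roi_mask,
                               threshold_map=np.zeros_like(hypo, dtype=float))


def _ellipse(mask, x0, y0, a, b):
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    mask |= ((xx - x0) / a) ** 2 + ((yy - y0) / b) ** 2 <= 1.0
    return mask


# --- extract_roi ------------------------------------------------------------

def test_flat_roi_is_a_rectangle():
    img, traces = _flat_setup()
    roi = ly.extract_roi(traces, img, half_width_um=750.0)
    # 1500 um / 5 um/px = 300 columns; rows 101..200 inclusive = 100 rows
    assert roi.width_px == 300
    assert roi.roi_mask.sum() == 300 * 100
    rows = np.nonzero(roi.roi_mask.any(axis=1))[0]
    assert rows.min() == 101 and rows.max() == 200


def test_fovea_near_edge_is_an_error():
    img, traces = _flat_setup()
    traces = ChoroidTraces(traces.x, traces.y_rpe, traces.y_csb, fovea_x=20.0)
    with pytest.raises(RoiError):
        ly.extract_roi(traces, img, half_width_um=750.0)


def test_curved_roi_pixel_count_matches_columnwise_oracle(phantom_speckle):
    _, image, gt = phantom_speckle
    roi = ly.extract_roi(gt.traces, image)
    cols = roi.columns
    rpe = gt.traces.rpe_at(cols)
    csb = gt.traces.csb_at(cols)
    # pixels with rpe < y <= csb per column
    expected = int((np.floor(csb) - np.floor(rpe)).sum())
    assert roi.roi_mask.sum() == expected


# --- find_lumen_components --------------------------------------------------

def test_empty_hypo_mask_gives_no_components():
    img, traces = _flat_setup()
    roi = ly.extract_roi(traces, img)
    bmap = _bmap_from_hypo(np.zeros_like(roi.roi_mask), roi.roi_mask)
    assert ly.find_lumen_components(bmap, roi) == []


def test_single_wide_ellipse_found_with_top_innermost_point():
    img, traces = _flat_setup()
    roi = ly.extract_roi(traces, img)
    hypo = np.zeros_like(roi.roi_mask)
    # lateral diameter 150 um = 30 px at 5 um/px, centred at depth 150 px
    _ellipse(hypo, x0=200, y0=150, a=15, b=10)
    comps = ly.find_lumen_components(_bmap_from_hypo(hypo, roi.roi_mask), roi)
    assert len(comps) == 1
    c = comps[0]
    assert c.lateral_extent_um >= 150.0
    x_in, y_in = c.innermost_point
    assert y_in == 140                      # top arc of the ellipse
    assert abs(x_in - 200) <= 1
    assert c.depth_um == pytest.approx((140 - 100) * 5.0)


def test_components_below_extent_cutoff_are_filtered():
    img, traces = _flat_setup()
    roi = ly.extract_roi(traces, img)
    hypo = np.zeros_like(roi.roi_mask)
    _ellipse(hypo, x0=150, y0=150, a=5, b=5)   # 55 um lateral
    _ellipse(hypo, x0=250, y0=150, a=5, b=5)
    comps = ly.find_lumen_components(_bmap_from_hypo(hypo, roi.roi_mask), roi)
    assert comps == []


# --- inner_outer_border -----------------------------------------------------

def _five_lumen_setup(depths_px):
    img, traces = _flat_setup()
    roi = ly.extract_roi(traces, img)
    hypo = np.zeros_like(roi.roi_mask)
    for i, d in enumerate(depths_px):
        # top of ellipse at row 100 + d; lateral radius 12 px = 120 um
        _ellipse(hypo, x0=80 + 60 * i, y0=100 + d + 8, a=12, b=8)
    return img, traces, roi, _bmap_from_hypo(hypo, roi.roi_mask)


def test_border_offset_is_mean_of_depths_and_flat_closed_form():
    # depths 12..20 px at 5 um/px -> {60, 70, 80, 90, 100} um, mean 80 um
    img, traces, roi, bmap = _five_lumen_setup([12, 14, 16, 18, 20])
    boundary = ly.inner_outer_border(bmap, traces, roi, seed=0)
    assert sorted(boundary.per_lumen_depths_um) == [60, 70, 80, 90, 100]
    assert boundary.offset_um == pytest.approx(80.0)
    # flat geometry: border row = rpe + offset / axial_scale exactly
    np.testing.assert_allclose(boundary.boundary_y, 100 + 80 / 5.0)


def test_border_is_seed_deterministic_and_depth_monotone():
    img, traces, roi, bmap = _five_lumen_setup([12, 14, 16, 18, 20])
    b1 = ly.inner_outer_border(bmap, traces, roi, seed=5)
    b2 = ly.inner_outer_border(bmap, traces, roi, seed=5)
    assert b1.offset_um == b2.offset_um
    np.testing.assert_array_equal(b1.boundary_y, b2.boundary_y)
    # push every lumen one pixel deeper: offset grows by one axial pixel
    img2, traces2, roi2, bmap2 = _five_lumen_setup([13, 15, 17, 19, 21])
    b3 = ly.inner_outer_border(bmap2, traces2, roi2, seed=5)
    assert b3.offset_um == pytest.approx(b1.offset_um + 5.0)


def test_too_few_lumens_is_unsegmentable():
    img, traces, roi, bmap = _five_lumen_setup([12, 14, 16])
    with pytest.raises(SegmentationError, match="need 5"):
        ly.inner_outer_border(bmap, traces, roi, seed=0)


def test_curved_border_matches_normal_displacement_oracle(phantom_speckle):
    """The border polyline equals an independently computed displacement
    of the smoothed RPE along its local normal."""
    _, image, gt = phantom_speckle
    gray = bz.to_grayscale(image.pixels)
    roi = ly.extract_roi(gt.traces, image)
    bmap = bz.niblack_binarize(gray, roi.roi_mask)
    boundary = ly.inner_outer_border(bmap, gt.traces, roi, seed=2)

    from scipy.ndimage import uniform_filter1d
    cols = roi.columns.astype(float)
    y_s = uniform_filter1d(gt.traces.rpe_at(cols), size=7, mode="nearest")
    X, Y = cols * image.lateral_scale, y_s * image.axial_scale
    # central differences in the interior
    bx = np.empty_like(X)
    by = np.empty_like(Y)
    for i in range(len(X)):
        lo, hi = max(i - 1, 0), min(i + 1, len(X) - 1)
        tx, ty = X[hi] - X[lo], Y[hi] - Y[lo]
        nrm = np.hypot(tx, ty)
        nx, ny = -ty / nrm, tx / nrm
        if ny < 0:
            nx, ny = -nx, -ny
        bx[i] = (X[i] + boundary.offset_um * nx) / image.lateral_scale
        by[i] = (Y[i] + boundary.offset_um * ny) / image.axial_scale
    expected = np.interp(cols, bx, by)
    np.testing.assert_allclose(boundary.boundary_y, expected, atol=1e-8)


# --- split_layers -----------------------------------------------------------

def test_split_flat_rectangle_counts():
    img, traces = _flat_setup()
    roi = ly.extract_roi(traces, img)
    boundary = ly.LayerBoundary(offset_um=150.0, boundary_x=roi.columns,
                                boundary_y=np.full(roi.width_px, 130.5),
                                sampled_lumens=[], per_lumen_depths_um=[])
    inner, outer = ly.split_layers(roi, boundary)
    # rows 101..130 above the border, 131..200 on/below it
    assert inner.sum() == 30 * roi.width_px
    assert outer.sum() == 70 * roi.width_px


def test_border_at_rpe_puts_everything_in_outer():
    img, traces = _flat_setup()
    roi = ly.extract_roi(traces, img)
    boundary = ly.LayerBoundary(0.0, roi.columns, np.full(roi.width_px, 100.0),
                                [], [])
    inner, outer = ly.split_layers(roi, boundary)
    assert inner.sum() == 0
    assert np.array_equal(outer, roi.roi_mask)


def test_split_conserves_roi_pixels(phantom_speckle):
    _, image, gt = phantom_speckle
    gray = bz.to_grayscale(image.pixels)
    roi = ly.extract_roi(gt.traces, image)
    bmap = bz.niblack_binarize(gray, roi.roi_mask)
    boundary = ly.inner_outer_border(bmap, gt.traces, roi, seed=0)
    inner, outer = ly.split_layers(roi, boundary)
    assert not (inner & outer).any()
    assert inner.sum() + outer.sum() == roi.roi_mask.sum()


def test_degenerate_border_below_csb_is_an_error():
    img, traces = _flat_setup()
    roi = ly.extract_roi(traces, img)
    boundary = ly.LayerBoundary(600.0, roi.columns,
                                np.full(roi.width_px, 250.0), [], [])
    with pytest.raises(SegmentationError, match="chorioscleral"):
        ly.split_layers(roi, boundary)
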