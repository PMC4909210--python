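"""Choroid binarization: grayscale conversion, vessel-based noise floor,
and Niblack local adaptive thresholding.

The processing order mirrors the standard choroidal binarization
protocol: the average reflectivity of three large (>=100 um) vascular
lumens is measured on the image, that average is set as the minimum
intensity (a noise floor that suppresses sub-lumen noise), the image is
converted to 8 bits, and every choroid pixel is classified as
hyporeflective (vascular lumen / fluid) or hyperreflective (stroma) by
the Niblack rule

    T(x, y) = mu_w(x, y) + k * sigma_w(x, y)

with the local mean and standard deviation taken over a
(2r+1) x (2r+1) window (edge-inclusive reflective padding at borders).
A pixel is hyporeflective iff its intensity is strictly below the local
threshold; intensity exactly equal to the threshold counts as
hyperreflective, which makes the constant-image case unambiguous.

Defaults ``window_radius=15`` and ``k=-0.2`` follow the common
auto-local-threshold implementation of this rule (negative k pushes
thresholds below the local mean so only clearly dark pixels are kept);
both are exposed in :class:`NiblackParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import InsufficientLumensError

__all__ = [
    "NiblackParams",
    "VesselSample",
    "BinaryChoroidMap",
    "to_grayscale",
    "detect_dark_components",
    "sample_vessel_floor",
    "clamp_floor",
    "niblack_binarize",
]


@dataclass(frozen=True)
class NiblackParams:
    """Niblack threshold parameters.

    window_radius : int
        Local window is the ``(2r+1) x (2r+1)`` square, ``r >= 1``.
    k : float
        Dimensionless weight on the local standard deviation.
    """

    window_radius: int = 15
    k: float = -0.2

    def __post_init__(self) -> None:
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")

    @property
    def window_size(self) -> int:
        return 2 * self.window_radius + 1


@dataclass
class VesselSample:
    """Reflectivity sample over oval regions inside large vascular lumens."""

    centers: list[tuple[float, float]]       # (x_px, y_px) per oval
    radii: list[tuple[float, float]]         # (a_px, b_px) per oval
    mean_reflectivity: float                 # pooled mean over all ovals


@dataclass
class BinaryChoroidMap:
    """Per-pixel hypo/hyper classification restricted to the choroid ROI."""

    hypo_mask: np.ndarray        # bool; True = hyporeflective
    roi_mask: np.ndarray         # bool; choroid band actually classified
    threshold_map: np.ndarray    # float64 per-pixel Niblack threshold

    def __post_init__(self) -> None:
        if (self.hypo_mask & ~self.roi_mask).any():
            raise ValueError("hypo_mask must be a subset of roi_mask")

    @property
    def hyper_mask(self) -> np.ndarray:
        """Hyperreflective pixels; complements hypo_mask within the ROI."""
        return self.roi_mask & ~self.hypo_mask


def to_grayscale(pixels: np.ndarray, weighted: bool = False) -> np.ndarray:
    """Convert an RGB raster to 8 bits; grayscale input passes through.

    The default is the unweighted channel mean ``round((R+G+B)/3)`` with
    round-half-up, matching the conventional unweighted 8-bit
    conversion; ``weighted=True`` uses ITU-R 601 luminance instead.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] == 3:
        w = (0.299, 0.587, 0.114) if weighted else (1 / 3, 1 / 3, 1 / 3)
        mean = arr[..., 0] * w[0] + arr[..., 1] * w[1] + arr[..., 2] * w[2]
        return np.floor(mean + 0.5).astype(np.uint8)
    raise ValueError(f"expected 1 or 3 channels, got shape {arr.shape}")


def detect_dark_components(gray: np.ndarray, region_mask: np.ndarray,
                           lateral_scale: float,
                           min_extent_um: float = 100.0) -> list[np.ndarray]:
    """Provisionally detect large dark (lumen-like) regions.

    Thresholds the region at Otsu's level, labels dark pixels
    (8-connected) and keeps components whose lateral extent is at least
    ``min_extent_um``.  Used to propose candidate lumens for
    :func:`sample_vessel_floor` when no manual selection is supplied.
    Returns a list of boolean masks.
    """
    vals = gray[region_mask]
    if vals.size == 0:
        return []
    try:
        level = threshold_otsu(vals)
    except ValueError:  # constant region
        return []
    # <= : on a two-level (noise-free) image Otsu returns the lower level
    dark = region_mask & (gray <= level)
    labels, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    out = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        width_px = sl[1].stop - sl[1].start
        if width_px * lateral_scale >= min_extent_um:
            out.append(labels == labels[sl][labels[sl] > 0][0])
    return out


def sample_vessel_floor(gray: np.ndarray,
                        candidate_lumens: list[np.ndarray],
                        lateral_scale: float,
                        axial_scale: float,
                        n: int = 3,
                        min_diameter_um: float = 100.0,
                        seed: int | np.random.Generator = 0) -> VesselSample:
    """Sample the mean reflectivity of ``n`` large vascular lumens.

    From the candidate lumen masks, those with lateral extent of at least
    ``min_diameter_um`` qualify; ``n`` of them are chosen uniformly
    without replacement (seeded).  Each is sampled with an oval centred
    on its centroid whose physical diameter is
    ``min(lateral extent, min_diameter_um)``, and the pooled mean
    intensity over all ovals is returned — this is the value used as the
    noise floor by :func:`clamp_floor`.

    Raises
    ------
    InsufficientLumensError
        Fewer than ``n`` qualifying lumens (image too thin or noisy).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qualifying = []
    for mask in candidate_lumens:
        rows, cols = np.nonzero(mask)
        if cols.size == 0:
            continue
        extent_um = (cols.max() - cols.min() + 1) * lateral_scale
        if extent_um >= min_diameter_um:
            qualifying.append((mask, rows, cols, extent_um))
    if len(qualifying) < n:
        raise InsufficientLumensError(
            f"only {len(qualifying)} lumens with lateral extent >= "
            f"{min_diameter_um} um; need {n}")
    chosen = rng.choice(len(qualifying), size=n, replace=False)

    h, w = gray.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pooled = np.zeros((h, w), dtype=bool)
    centers, radii = [], []
    for idx in sorted(int(i) for i in chosen):
        mask, rows, cols, extent_um = qualifying[idx]
        cx, cy = float(cols.mean()), float(rows.mean())
        d_um = min(extent_um, min_diameter_um)
        a = d_um / 2.0 / lateral_scale     # lateral radius, px
        b = d_um / 2.0 / axial_scale       # axial radius, px
        oval = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        # restrict to the lumen itself: a manual oval sits inside the
        # vessel; an automatic centroid oval may overhang its borders
        sample = oval & mask
        pooled |= sample if sample.any() else mask
        centers.append((cx, cy))
        radii.append((a, b))
    return VesselSample(centers=centers, radii=radii,
                        mean_reflectivity=float(gray[pooled].mean()))


def clamp_floor(gray: np.ndarray, floor: float) -> np.ndarray:
    """Raise every intensity below ``floor`` up to it (element-wise max).

    Implements "set the average vessel brightness as the minimum value":
    intensities already at or above the floor are unchanged, so the
    operation is idempotent.
    """
    if not 0 <= floor <= 255:
        raise ValueError("floor must be an 8-bit level in [0, 255]")
    level = int(np.floor(floor + 0.5))
    return np.maximum(gray, np.uint8(level))


def niblack_binarize(gray: np.ndarray, roi: np.ndarray,
                     params: NiblackParams = NiblackParams()) -> BinaryChoroidMap:
    """Classify every ROI pixel as hypo- or hyperreflective.

    The threshold map ``T = mu_w + k * sigma_w`` is computed over the
    full raster in float64 (windowed moments via separable uniform
    filters, reflective padding); classification is then restricted to
    the ROI.  Within the ROI, hypo and hyper masks partition the pixels:
    hypo iff ``intensity < T``.

    Raises
    ------
    ValueError
        Empty ROI, or window larger than the image.
    """
    gray = np.asarray(gray)
    roi = np.asarray(roi, dtype=bool)
    if gray.shape != roi.shape:
        raise ValueError("gray and roi shapes differ")
    if not roi.any():
        raise ValueError("ROI is empty")
    w = params.window_size
    if w > min(gray.shape):
        raise ValueError(f"window {w} larger than image {gray.shape}")
    img = gray.astype(np.float64)
    mean = ndimage.uniform_filter(img, size=w, mode="reflect")
    sqmean = ndimage.uniform_filter(img * img, size=w, mode="reflect")
    var = np.clip(sqmean - mean * mean, 0.0, None)
    threshold = mean + params.k * np.sqrt(var)
    hypo = (img < threshold) & roi
    return BinaryChoroidMap(hypo_mask=hypo, roi_mask=roi, threshold_map=threshold)
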