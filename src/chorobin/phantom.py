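"""Synthetic EDI-OCT choroid phantom generator.

Generates B-scan-like rasters with known ground truth so every downstream
stage (binarization, layer segmentation, quantification, cohort
statistics) can be validated without patient scans.  A phantom consists
of:

* a bright stromal background and dark elliptical vascular lumens whose
  size and packing density differ between an inner band (choriocapillaris
  plus Sattler's layer) and an outer band (Haller's layer);
* a shallow quadratic RPE curve (foveal geometry) with the chorioscleral
  border obtained by shifting the RPE down by the choroidal thickness;
* fully developed multiplicative speckle, modelled as gamma noise with
  shape equal to the number of averaged frames (mean 1, variance
  1/looks) — frame averaging during acquisition reduces speckle variance
  by exactly this factor.

Lumens are axis-aligned ellipses placed by rejection sampling, pixel
disjoint with at least one pixel of stroma between neighbours, so the
ground-truth luminal fraction of each band is exact and individual lumens
remain countable as 8-connected components.  When a band approaches its
packing limit the sampler progressively shrinks the lumen diameter range
so that dense targets remain reachable; a bounded attempt budget turns a
genuinely unreachable target into a :class:`~chorobin.errors.PlacementError`.

Coordinates are 0-based and row-major with y increasing downward
(deeper).  A pixel belongs to a region iff the region contains the pixel
centre.  The choroid band at column ``x`` is ``rpe(x) < y <= csb(x)``;
the inner band is ``y < rpe(x) + f*T`` within the band (boundary pixels
belong to the outer band), where ``f`` is the inner band fraction and
``T`` the thickness in pixels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .bscan_io import BScanImage, ChoroidTraces, save_bscan, save_traces
from .errors import PlacementError

__all__ = [
    "PhantomConfig",
    "PhantomGroundTruth",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "default_group_spec",
    "save_phantom_case",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a single synthetic B-scan.

    Defaults describe a control-like eye at typical Spectralis export
    scales (11.3 um/px lateral, 3.87 um/px axial): ~300 um subfoveal
    choroid of which ~20% is inner choroid, moderate luminal fractions,
    and 100-frame averaging.
    """

    width_px: int = 448
    height_px: int = 224
    lateral_scale: float = 11.3   # um / pixel, lateral
    axial_scale: float = 3.87     # um / pixel, axial
    #: polynomial coefficients (ascending, pixels) of the RPE depth as a
    #: function of (x - fovea_x) in pixels; default is a shallow quadratic.
    rpe_depth_profile: tuple[float, ...] = (40.0, 0.0, 2.5e-4)
    choroid_thickness_um: float = 300.0
    fovea_x_um: float | None = None          # default: image centre
    inner_band_fraction: float = 0.20
    inner_lumen_diameter_range_um: tuple[float, float] = (30.0, 90.0)
    outer_lumen_diameter_range_um: tuple[float, float] = (100.0, 220.0)
    target_luminal_fraction_inner: float = 0.45
    target_luminal_fraction_outer: float = 0.40
    stroma_intensity: int = 200
    lumen_intensity: int = 50
    #: number of averaged frames; ``None`` disables speckle entirely.
    speckle_looks: int | None = 100
    seed: int = 0
    max_placement_attempts: int = 200_000

    def __post_init__(self) -> None:
        for name in ("target_luminal_fraction_inner", "target_luminal_fraction_outer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.inner_band_fraction <= 1.0:
            raise ValueError("inner_band_fraction must be in [0, 1]")
        if self.lumen_intensity >= self.stroma_intensity:
            raise ValueError("lumen_intensity must be below stroma_intensity")
        if self.speckle_looks is not None and not (
                np.isinf(self.speckle_looks) or self.speckle_looks >= 1):
            raise ValueError("speckle_looks must be a positive integer, inf or None")
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise ValueError("pixel scales must be positive")

    @property
    def fovea_x_px(self) -> float:
        if self.fovea_x_um is None:
            return (self.width_px - 1) / 2.0
        return self.fovea_x_um / self.lateral_scale

    @property
    def thickness_px(self) -> float:
        return self.choroid_thickness_um / self.axial_scale


@dataclass
class PhantomGroundTruth:
    """Exact per-pixel truth accompanying a generated phantom."""

    lumen_mask: np.ndarray        # bool, True inside any vascular lumen
    inner_band_mask: np.ndarray   # bool, inner choroid band
    outer_band_mask: np.ndarray   # bool, outer choroid band
    true_luminal_fraction_inner: float
    true_luminal_fraction_outer: float
    traces: ChoroidTraces

    def recompute_fractions(self) -> tuple[float, float]:
        """Recount the luminal pixel fraction of each band from the masks."""
        fi = _fraction(self.lumen_mask, self.inner_band_mask)
        fo = _fraction(self.lumen_mask, self.outer_band_mask)
        return fi, fo


@dataclass
class PhantomCase:
    """One simulated eye of a synthetic cohort."""

    case_id: str
    group: str
    image: BScanImage
    truth: PhantomGroundTruth
    config: PhantomConfig


def _fraction(lumen: np.ndarray, band: np.ndarray) -> float:
    n = int(band.sum())
    return float((lumen & band).sum()) / n if n else 0.0


def _band_masks(cfg: PhantomConfig):
    """Choroid band geometry: traces and inner/outer boolean rasters."""
    x = np.arange(cfg.width_px)
    y_rpe = np.polynomial.polynomial.polyval(x - cfg.fovea_x_px,
                                             np.asarray(cfg.rpe_depth_profile))
    y_csb = y_rpe + cfg.thickness_px
    if y_rpe.min() < 1 or y_csb.max() > cfg.height_px - 2:
        raise ValueError(
            "choroid band does not fit inside the image "
            f"(rpe min {y_rpe.min():.1f}, csb max {y_csb.max():.1f}, H={cfg.height_px})")
    rows = np.arange(cfg.height_px)[:, None].astype(float)
    band = (rows > y_rpe) & (rows <= y_csb)
    y_split = y_rpe + cfg.inner_band_fraction * cfg.thickness_px
    inner = band & (rows < y_split)
    outer = band & (rows >= y_split)
    traces = ChoroidTraces(x, y_rpe, y_csb, fovea_x=cfg.fovea_x_px)
    return traces, inner, outer


def _ellipse_pixels(x0: float, y0: float, a: float, b: float, shape):
    """Integer pixel coordinates whose centres fall inside the ellipse."""
    h, w = shape
    xlo = max(int(np.floor(x0 - a)), 0)
    xhi = min(int(np.ceil(x0 + a)), w - 1)
    ylo = max(int(np.floor(y0 - b)), 0)
    yhi = min(int(np.ceil(y0 + b)), h - 1)
    if xhi < xlo or yhi < ylo:
        return None
    yy, xx = np.mgrid[ylo:yhi + 1, xlo:xhi + 1]
    inside = ((xx - x0) / a) ** 2 + ((yy - y0) / b) ** 2 <= 1.0
    return yy[inside], xx[inside]


def _fill_band(rng: np.random.Generator, band: np.ndarray, lumen: np.ndarray,
               diam_range_um: tuple[float, float], target: float,
               cfg: PhantomConfig, attempts_budget: int) -> int:
    """Place non-overlapping ellipses into ``band`` until the luminal
    fraction is within the placement tolerance of ``target``.

    Mutates ``lumen`` in place; returns attempts consumed.  Diameters are
    drawn uniformly from ``diam_range_um`` with aspect ratio (axial over
    lateral, in physical units) in [0.5, 1]; after 150 consecutive
    rejections the range shrinks by 25% so saturated bands can still be
    topped up with smaller vessels.
    """
    band_area = int(band.sum())
    if target <= 0.0 or band_area == 0:
        return 0
    shape = band.shape
    band_rows, band_cols = np.nonzero(band)
    # per-column vertical extent of the band, for fast centre sampling
    col_top = np.full(shape[1], np.inf)
    col_bot = np.full(shape[1], -np.inf)
    np.minimum.at(col_top, band_cols, band_rows)
    np.maximum.at(col_bot, band_cols, band_rows)
    cols_ok = np.nonzero(np.isfinite(col_top))[0]

    dmin, dmax = diam_range_um
    current = int((lumen & band).sum())
    fails = 0
    attempts = 0
    while current / band_area < target - 0.01:
        attempts += 1
        if attempts > attempts_budget:
            raise PlacementError(
                f"target luminal fraction {target:.2f} unreachable after "
                f"{attempts_budget} attempts (reached {current / band_area:.3f}); "
                "over-dense configuration")
        d = rng.uniform(dmin, dmax)
        aspect = rng.uniform(0.5, 1.0)
        a = max(d / 2.0 / cfg.lateral_scale, 1.0)
        b = max(d * aspect / 2.0 / cfg.axial_scale, 1.0)
        x0 = rng.uniform(cols_ok[0], cols_ok[-1])
        xc = int(round(x0))
        ylo, yhi = col_top[xc] + b, col_bot[xc] - b
        ok = ylo <= yhi
        if ok:
            y0 = rng.uniform(ylo, yhi)
            px = _ellipse_pixels(x0, y0, a, b, shape)
            # Require one pixel of stromal separation (keeps lumens
            # countable as 8-connected components) until the band is
            # nearly full; the last few percent may touch — still
            # pixel-disjoint, so the fraction stays exact.
            if current / band_area < target - 0.06:
                probe = _ellipse_pixels(x0, y0, a + 1.0, b + 1.0, shape)
            else:
                probe = px
            ok = (px is not None
                  and band[px].all()                       # entirely in this band
                  and not lumen[probe].any()
                  and (current + px[0].size) / band_area <= target + 0.015)
        if ok:
            lumen[px] = True
            current += px[0].size
            fails = 0
        else:
            fails += 1
            if fails >= 100:
                # band saturating at this vessel calibre: shrink
                dmin *= 0.7
                dmax *= 0.7
                floor = 2.2 * min(cfg.lateral_scale, cfg.axial_scale)
                dmin = max(dmin, floor)
                dmax = max(dmax, dmin * 1.5)
                fails = 0
    return attempts


def generate_phantom(config: PhantomConfig) -> tuple[BScanImage, PhantomGroundTruth]:
    """Generate one synthetic B-scan and its exact ground truth.

    The image equals the two-level base pattern (``stroma_intensity``
    outside lumens, ``lumen_intensity`` inside) multiplied by unit-mean
    gamma speckle with variance ``1/speckle_looks``, rounded and clipped
    to [0, 255].  Identical config (including seed) yields identical
    output.

    Raises
    ------
    PlacementError
        If a band's target luminal fraction cannot be reached within the
        attempt budget.
    """
    rng = np.random.default_rng(config.seed)
    traces, inner, outer = _band_masks(config)
    lumen = np.zeros((config.height_px, config.width_px), dtype=bool)
    budget = config.max_placement_attempts
    used = _fill_band(rng, inner, lumen, config.inner_lumen_diameter_range_um,
                      config.target_luminal_fraction_inner, config, budget)
    _fill_band(rng, outer, lumen, config.outer_lumen_diameter_range_um,
               config.target_luminal_fraction_outer, config, budget - used)

    base = np.where(lumen, float(config.lumen_intensity),
                    float(config.stroma_intensity))
    looks = config.speckle_looks
    if looks is None or np.isinf(looks):
        img = base
    else:
        speckle = rng.gamma(shape=float(looks), scale=1.0 / float(looks),
                            size=base.shape)
        img = base * speckle
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    truth = PhantomGroundTruth(
        lumen_mask=lumen,
        inner_band_mask=inner,
        outer_band_mask=outer,
        true_luminal_fraction_inner=_fraction(lumen, inner),
        true_luminal_fraction_outer=_fraction(lumen, outer),
        traces=traces,
    )
    image = BScanImage(pixels, config.lateral_scale, config.axial_scale)
    return image, truth


# --- cohort generation ------------------------------------------------------

def default_group_spec() -> dict[str, dict]:
    """Per-group parameter overrides emulating the clinical contrasts.

    CSC eyes get a thicker choroid, dilated outer lumens with a higher
    outer luminal fraction, and a thickened inner stroma (lower inner
    luminal fraction); fellow eyes sit between CSC and control.  Values
    are means; :func:`generate_cohort` adds per-eye jitter.
    """
    return {
        "control": dict(choroid_thickness_um=300.0,
                        inner_band_fraction=0.20,
                        target_luminal_fraction_inner=0.45,
                        target_luminal_fraction_outer=0.40,
                        outer_lumen_diameter_range_um=(100.0, 220.0)),
        "fellow": dict(choroid_thickness_um=380.0,
                       inner_band_fraction=0.18,
                       target_luminal_fraction_inner=0.44,
                       target_luminal_fraction_outer=0.44,
                       outer_lumen_diameter_range_um=(100.0, 240.0)),
        "CSC": dict(choroid_thickness_um=460.0,
                    inner_band_fraction=0.16,
                    target_luminal_fraction_inner=0.30,
                    target_luminal_fraction_outer=0.55,
                    outer_lumen_diameter_range_um=(120.0, 280.0)),
    }


#: Standard deviations of the per-eye jitter applied by generate_cohort.
_JITTER = {"choroid_thickness_um": 35.0,
           "target_luminal_fraction_inner": 0.02,
           "target_luminal_fraction_outer": 0.02}


def generate_cohort(group_spec: dict[str, dict] | None = None,
                    n_per_group: int = 20,
                    seed: int = 0,
                    base_config: PhantomConfig | None = None) -> list[PhantomCase]:
    """Generate a three-arm synthetic cohort of phantoms.

    Parameters
    ----------
    group_spec
        Mapping of group label to :class:`PhantomConfig` field overrides
        (defaults to :func:`default_group_spec`).
    n_per_group
        Eyes per group (>= 1).
    seed
        Master seed; every per-eye config seed is derived from it, so the
        whole cohort is reproducible.

    CSC and fellow eyes of the same index share a patient: the returned
    ``case_id`` is ``"<group>-<patient index>"``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    spec = default_group_spec() if group_spec is None else group_spec
    base = base_config or PhantomConfig()
    cases: list[PhantomCase] = []
    for gi, (group, overrides) in enumerate(spec.items()):
        for i in range(n_per_group):
            ss = np.random.SeedSequence(seed, spawn_key=(gi, i))
            jrng = np.random.default_rng(ss)
            params = dict(overrides)
            for key, sd in _JITTER.items():
                if key in params:
                    lo, hi = (0.05, 0.95) if "fraction" in key else (120.0, 700.0)
                    params[key] = float(np.clip(jrng.normal(params[key], sd), lo, hi))
            case_seed = int(jrng.integers(0, 2**31 - 1))
            cfg = dataclasses.replace(base, seed=case_seed, **params)
            image, truth = generate_phantom(cfg)
            cases.append(PhantomCase(f"{group}-{i:02d}", group, image, truth, cfg))
    return cases


def save_phantom_case(case: PhantomCase, out_dir: str | Path) -> dict:
    """Write one case to disk: 8-bit TIFF image, PNG ground-truth masks,
    CSV+JSON traces, and a JSON metadata record.  Returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = case.case_id
    files = {
        "image": out / f"{stem}.tif",
        "lumen_mask": out / f"{stem}_lumen.png",
        "inner_band": out / f"{stem}_inner_band.png",
        "outer_band": out / f"{stem}_outer_band.png",
        "traces": out / f"{stem}_traces.csv",
        "meta": out / f"{stem}_meta.json",
    }
    save_bscan(case.image, files["image"])
    for key, mask in (("lumen_mask", case.truth.lumen_mask),
                      ("inner_band", case.truth.inner_band_mask),
                      ("outer_band", case.truth.outer_band_mask)):
        Image.fromarray((mask.astype(np.uint8)) * 255).save(files[key])
    save_traces(case.truth.traces, files["traces"],
                case.image.lateral_scale, case.image.axial_scale)
    meta = {
        "case_id": case.case_id,
        "group": case.group,
        "true_luminal_fraction_inner": case.truth.true_luminal_fraction_inner,
        "true_luminal_fraction_outer": case.truth.true_luminal_fraction_outer,
        "config": {k: v for k, v in dataclasses.asdict(case.config).items()},
    }
    files["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in files.items()}
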