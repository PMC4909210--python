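# Methods

This note documents the models, conventions and parameter choices
behind `chorobin`, the assumptions they rest on, and what the synthetic
validation does and does not demonstrate.

## The measurement model

A subfoveal EDI-OCT B-scan of the choroid is treated as a 2-D intensity
raster with an anisotropic pixel calibration (µm/px laterally and
axially; the calibration is always user-supplied because exported TIFFs
carry no reliable scale metadata).  The choroid band is delimited by
two manually traced polylines — the RPE above and the chorioscleral
border (CSB) below — that are single-valued functions of x; values
between vertices are linearly interpolated.

**Pixel ownership.** Coordinates are 0-based, row-major, y increasing
with depth.  A pixel belongs to a region iff the region contains the
pixel centre.  The choroid band at column x is `rpe(x) < y <= csb(x)`;
with flat traces at rows 100 and 200 this yields exactly 100 rows, and
the band pixel count per column equals `floor(csb) - floor(rpe)`.  At
the inner/outer border, pixels exactly on the line belong to the outer
layer.  These half-open conventions make every partition exact: inner +
outer pixel counts equal the ROI count identically, which in turn makes
the area additivity identities (`hypo + hyper = total`,
`inner + outer = whole`) hold to float precision rather than
approximately.

**Region of interest.** The ROI spans `round(750 / lateral_scale)`
pixels nasal and temporal of the foveal centre column (half-open
interval, physical width 1500 µm to within one pixel) and the full
RPE-to-CSB depth.  The 750 µm span is measured horizontally, not along
the RPE contour; over 1.5 mm of a shallowly curved RPE the difference
is far below one pixel.  A fovea closer than 750 µm to the scan edge is
an error, not a silent truncation.

## Binarization

**Noise floor.** The mean reflectivity of three large vascular lumens
(lateral extent ≥ 100 µm, chosen uniformly at random with a recorded
seed) is set as the image minimum: every darker pixel is raised to that
level.  "Set as the minimum value" is interpreted as this clamp — a
computational floor applied before thresholding — rather than a
display-range adjustment, which would not alter any computed area.
Each lumen is sampled with an oval of physical diameter
`min(lateral extent, 100 µm)` centred on the component centroid and
intersected with the lumen itself, so the sample never includes stromal
pixels even when the centroid oval overhangs an irregular component.
When no manual selection is supplied, candidate lumens come from a
provisional Otsu threshold of the band (the `<=` convention matters on
noise-free two-level images, where Otsu returns the lower level
itself).

**Thresholding.** Per-pixel Niblack rule over a (2r+1)×(2r+1) window:

    T(x, y) = mu_w(x, y) + k * sigma_w(x, y),   hypo  iff  I(x, y) < T(x, y)

computed in float64 via separable uniform filters with edge-inclusive
symmetric ("reflect") padding.  A pixel exactly at threshold is
hyperreflective, which resolves the constant-image case: a uniform
raster has sigma = 0, T equals the intensity everywhere, and nothing is
classified dark.  Defaults are `window_radius = 15` px and `k = -0.2`,
mirroring the common auto-local-threshold implementation of this rule;
both are configuration parameters, not claims about any particular
study's settings, and the negative k keeps only clearly dark pixels
hyporeflective.  The threshold map is retained for auditing and is
tested against an explicit per-pixel windowed mean/SD recomputation
(agreement ≤ 1e-9 on rasters up to 64×64).

Niblack thresholds are only meaningful where windows straddle both
tissue classes.  In the vascular choroid at these window sizes
(~340 µm × 120 µm) essentially every window is bimodal; in a large
uniform region the rule would mark ~42% of pixels dark (the
probability mass below mu - 0.2 sigma of unimodal noise).  The vessel
floor mitigates the dark side of this failure mode, and the phantom
recovery results below bound its practical impact.

## Layer segmentation

Segmentation operates on the binarized image.  8-connected
hyporeflective components inside the ROI with lateral extent ≥ 100 µm
qualify; "≥ 100 µm luminal area" is read as lateral extent (vessel
calibre), since the axial direction is compressed by the anisotropic
scan geometry.  Five qualifying components are chosen uniformly without
replacement (seeded, logged).  Each contributes the perpendicular
distance, in physical units, from the RPE to its innermost point; the
innermost point is found by minimising Euclidean distance from the
component's top-of-column pixels to a densely sampled RPE curve, which
is equivalent to dropping a local normal but robust to jagged traces.
The RPE is smoothed with a 7-vertex moving average before normals or
distances are taken.

The border offset is the arithmetic mean of the five depths.  The
border polyline is the smoothed RPE displaced by the offset along its
local inward normal (tangents by central differences in physical
coordinates, resampled to one row per column); with flat traces this
reduces exactly to `rpe + offset / axial_scale`.  A horizontal-line
variant (`mode="horizontal"`) is available because the original
protocol does not state whether the border follows RPE curvature; the
normal-displacement reading is the default.  Fewer than five qualifying
lumens raises an error — the analogue of the protocol's image-quality
gate — and a border that falls below the CSB for more than half the
columns is reported as degenerate rather than silently clipped.

## Quantification

Areas are pixel counts times pixel area (µm²); pixel counts are kept
alongside so conservation can be asserted exactly.  An empty region
reports its ratio as missing (NaN), not zero.  The CSC index,

    CSC index = (outer hypo / outer hyper) / (inner hypo / inner hyper),

is unit-free and undefined (reported missing) when any denominator
vanishes.  Group-level percent ratios are ratios of group means rounded
to integer percent — the convention used in cohort summaries — and are
deliberately kept distinct from per-eye ratios, which feed the
statistics; mean-of-ratios and ratio-of-means differ, and conflating
them is a classic source of irreproducible percentages.  On the
bundled reference cohort summary (`chorobin.published`, a published
three-arm clinical cohort of 40 eyes per arm measured with this
protocol), the ratio-of-means arithmetic reproduces the reported
166% / 126% / 189% / 121% outer/inner contrasts, and the conservation
identities hold exactly except for a 1 µm² residual in two fellow-arm
columns caused by independent rounding of the printed means.

## Statistics

All tests are two-sided.  CSC and fellow eyes come from the same
patients and are compared with the Wilcoxon signed-rank test; contrasts
against controls use the unpaired Mann-Whitney U test by default, since
controls are different subjects — a `paired_controls` flag instead
pairs on the age-match index and uses the signed-rank test for all
three contrasts, reproducing the original labelling.  Bonferroni
correction (`min(1, 3p)`) is applied over the family of three pairwise
contrasts per measurement.  IA hyperpermeability grades are
dichotomised as {very severe, severe} = high vs {moderate, mild} = low;
the cut is a declared convention.

Exact p-values are literal enumerations — all 2^n sign assignments of
midranked |differences| for the signed-rank test (n ≤ 15 by default),
all C(n, n_a) labelings of pooled midranks for the U test
(n_a + n_b ≤ 12) — so ties are handled exactly; the reported statistics
are W+ and U_a.  Larger samples use scipy's tie-corrected normal
approximations, which agree with enumeration to within 0.02 at the
cutover sizes.  The chi-square test is Pearson's without continuity
correction (df = 1).  ICC estimation is delegated to
`pingouin.intraclass_corr`: ICC(1,1) for intra-rater (one-way random)
and single-measure absolute-agreement ICC (two-way model, McGraw-Wong
F-based CIs) for inter-rater designs; tests cross-check both against
hand-computed ANOVA mean squares.

## The phantom

The generator emulates what the measurement chain actually sees, not
retinal physics.  Geometry: a shallow quadratic RPE (polynomial in
pixels around the foveal column), CSB = RPE shifted down by the
choroidal thickness, an inner band occupying a configurable fraction of
the thickness.  Lumens are axis-aligned ellipses (lateral diameter from
a per-band range, axial/lateral aspect in [0.5, 1] in physical units),
placed by rejection sampling until each band's luminal pixel fraction
is within the placement tolerance of its target; ground-truth fractions
are recounted from the masks, never assumed.  Ellipses are pixel-
disjoint; a one-pixel stromal halo keeps them countable as separate
8-connected components until a band is within 0.06 of its target, after
which touching is allowed so dense bands remain fillable.  When a band
saturates at the configured calibre the diameter range shrinks by 25%
after every 100 consecutive rejections, emulating the small-vessel tail
that fills interstices in real tissue; a bounded attempt budget turns
genuinely unreachable targets into an explicit error.

Speckle is fully developed multiplicative gamma noise with shape equal
to the number of averaged frames (mean 1, variance 1/looks), the
standard model for multi-frame-averaged OCT; 100 looks is the default,
and `None` disables noise entirely, making the image exactly two-valued.
The noise model is a stand-in — the actual noise of any given
instrument is not characterised here.

Default study conditions: 448×224 px at 11.3 × 3.87 µm/px (typical
spectral-domain export scales), stroma 200, lumens 50.  The three arms
differ in thickness (300 / 380 / 460 µm for control / fellow / CSC),
inner-band share (0.20 / 0.18 / 0.16), target luminal fractions
(inner 0.45 / 0.44 / 0.30, outer 0.40 / 0.44 / 0.55) and outer lumen
calibre (up to 220 / 240 / 280 µm), with per-eye jitter (SD 35 µm on
thickness, 0.02 on fractions).  These values were chosen once to
preserve every qualitative contrast of the clinical cohort — thicker
CSC choroid, dilated outer lumens and a higher outer luminal share,
thickened inner stroma and a lower inner luminal share, CSC index
ordering control < fellow < CSC with control below and CSC above 1 —
while remaining reachable by non-overlapping ellipse packing, whose
jamming limit (~0.55 for same-sized discs, higher with a polydisperse
tail) rules out the clinical cohort's absolute per-band shares of
0.65-0.77.  Absolute areas of the clinical cohort are likewise out of
reach by construction (they require patient scans); the phantom
validates the *pipeline*, i.e. that measured quantities track known
ground truth and that group contrasts propagate through binarization,
segmentation and statistics in the right direction.

What passing phantom tests do **not** show: robustness to real-scan
nuisances absent from the phantom — retinal layers above the RPE,
depth-dependent signal attenuation, shadowing under large vessels,
serous detachments, motion artefacts, or tracing error in the manual
boundaries.

## Verified behaviour (computed by the test suite and acceptance script)

- Niblack threshold maps match brute-force windowed moments to ≤ 1e-9
  (observed ~2e-13).
- On noise-free phantoms the measured per-band luminal fractions match
  ground truth within 0.03 (observed ≤ 3e-4: with a two-level image and
  sub-window lumens, classification is essentially exact); with
  100-look speckle, within 0.05 (observed ~0.014).
- A 20-eyes-per-arm synthetic cohort processed end-to-end shows higher
  mean outer hyporeflective share and higher mean CSC index in the CSC
  arm than in controls.
- Exact signed-rank and U p-values equal scipy's exact null
  distributions on tie-free samples (n ≤ 10 battery, deviation 0).
- Both ICC estimators recover sigma_s²/(sigma_s²+sigma_e²) within ~0.05
  at 500 simulated subjects (Monte-Carlo SE ≈ 0.03, so individual draws
  can sit near that bound).
- Pipeline reruns from the same configuration are bit-identical
  (outputs contain no timestamps; all seeds derive from the master
  seed).

## Problem sizes

Unit tests use single phantoms and toy rasters; cohort-level checks use
20 eyes per arm at 448×224 px, enough for stable direction checks of
the group contrasts while keeping the full suite under a minute of
compute.  The acceptance script re-runs everything from scratch in
roughly 20 seconds on one CPU.

## Known limitations

- Niblack parameters, the noise-floor interpretation, the grayscale
  conversion (unweighted channel mean; luminance behind a flag) and the
  IA dichotomy are declared conventions; the original protocol leaves
  them unstated.
- The inner/outer border from five sampled lumens is noisy by design
  (it mirrors the manual protocol); on phantoms the measured border sits
  systematically above the generative band split whenever merged lumen
  clusters near the inner band qualify, so measured inner/outer shares
  are a *readout* correlated with truth rather than an unbiased
  estimate of it.
- Exact enumeration costs O(2^n) / O(C(n, n_a)) and is capped at the
  default cutoffs; beyond them the normal approximations apply.
- Proprietary scan containers (Heidelberg .e2e, DICOM) are not read;
  inputs are plain TIFF plus trace CSV/JSON.
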