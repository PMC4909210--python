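# chorobin

Binarization-based quantification of inner and outer choroidal structure
in EDI-OCT B-scans.

## The problem

In central serous chorioretinopathy (CSC), the choroid thickens — but a
thickness number alone does not say *which* structures change.  A widely
used answer is to binarize the subfoveal choroid of an enhanced-depth-
imaging OCT B-scan into **hyporeflective** area (vascular lumens and
fluid) and **hyperreflective** area (stroma), separately for the inner
choroid (choriocapillaris + Sattler's layer) and the outer choroid
(Haller's layer).  CSC eyes characteristically show dilated outer-layer
lumens and a swollen inner stroma.

`chorobin` implements that analysis as a tested, reproducible pipeline
for researchers who want to apply or scrutinise the method without
re-driving ImageJ by hand:

1. **Vessel noise floor** — the mean reflectivity of three randomly
   chosen large (≥ 100 µm) vascular lumens is set as the image minimum
   (`clamp_floor`), suppressing sub-lumen noise.
2. **Niblack local adaptive thresholding** — every choroid pixel is
   classified by the per-pixel threshold
   `T(x,y) = μ_w(x,y) + k·σ_w(x,y)` over a (2r+1)×(2r+1) window
   (defaults r = 15 px, k = −0.2); intensity < T ⇒ hyporeflective.
3. **Subfoveal ROI** — RPE to chorioscleral border, 750 µm nasal and
   temporal to the fovea, from manual boundary traces.
4. **Inner/outer split** — perpendiculars are dropped from the RPE to
   the innermost points of 5 randomly chosen large (≥ 100 µm)
   hyporeflective components; the mean depth, applied along the local
   RPE normal, is the layer border.
5. **Measurement** — total/hypo/hyper areas (µm²) for the whole, inner
   and outer compartments, the per-region hyporeflective ratio, and the
   **CSC index**

   ```
   CSC index = (outer hypo / outer hyper) / (inner hypo / inner hyper)
   ```

   which exceeds 1 when the outer choroid is relatively more luminal
   than the inner choroid.
6. **Cohort statistics** — paired Wilcoxon signed-rank (CSC vs fellow
   eyes), Mann-Whitney U (vs controls and for the indocyanine-green
   hyperpermeability dichotomy), Bonferroni correction over the three
   group contrasts, Pearson χ² for demographics, and intraclass
   correlation coefficients (one-way random; two-way absolute
   agreement) for rater agreement.

Because no patient scans ship with the package, a **synthetic phantom
generator** produces EDI-OCT-like B-scans with exact ground truth:
bright speckled stroma, dark elliptical lumens packed to prescribed
per-band luminal fractions, a curved RPE, and group-level contrasts
(thicker choroid, dilated outer lumens, thickened inner stroma in the
CSC arm).  Every downstream stage is validated against that ground
truth.

## Worked example

```python
from chorobin.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=7, n_per_group=5))
print(result.cohort.groupby("group")[
    ["whole_total_um2", "outer_hypo_ratio", "csc_index"]].mean().round(3))
```

prints

```
         whole_total_um2  outer_hypo_ratio  csc_index
group
CSC           696984.678             0.553      2.326
control       470650.514             0.428      1.602
fellow        572491.267             0.492      1.965
```

The synthetic CSC arm shows the expected signature: a larger total
choroidal cross-section, a higher outer-layer hyporeflective share, and
a higher CSC index than controls, with fellow eyes in between.  The
accompanying statistics report contains, e.g. for the outer
hyporeflective area:

```
csc_vs_fellow     p=0.0625  adjusted=0.1875  (wilcoxon signed-rank)
csc_vs_control    p=0.0079  adjusted=0.0238  (mann-whitney U)
fellow_vs_control p=0.0556  adjusted=0.1667  (mann-whitney U)
```

(five eyes per arm; only the CSC-control contrast survives Bonferroni at
this tiny sample size).

The same pipeline runs from a shell:

```
chorobin run-all --n-per-group 20 --seed 7 --out results/
chorobin simulate --n-per-group 5 --seed 3 --out phantoms/
chorobin binarize --image phantoms/CSC-00.tif --traces phantoms/CSC-00_traces.csv \
                  --seed 1 --out mask.png
```

Individual stages (`binarize`, `segment`, `measure`, `stats`) consume
and emit plain TIFF/PNG/CSV/JSON artifacts, and every run writes a
manifest of seeds and intermediate scalars that makes reruns
bit-identical.

## Layout

- `src/chorobin/phantom.py` — synthetic B-scan generator with ground truth
- `src/chorobin/bscan_io.py` — TIFF/trace/cohort-table I/O, unit conversion
- `src/chorobin/binarization.py` — grayscale, vessel floor, Niblack
- `src/chorobin/layers.py` — subfoveal ROI, inner/outer border, split
- `src/chorobin/quantification.py` — areas, ratios, CSC index
- `src/chorobin/cohort_stats.py` — Wilcoxon/MWU/χ²/ICC battery
- `src/chorobin/pipeline.py`, `cli.py` — orchestration and console script
- `docs/methods.md` — models, parameter choices and limitations
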