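# organoid-morph

Quantitative morphometry of organoids in brightfield microscopy.

Organoids imaged in transmitted light appear as dark, roughly convex
silhouettes on a bright background. This package turns such images into
three numbers per organoid — area *A*, perimeter *P*, and the
isoperimetric circularity

```
C = 4πA / P²
```

— and aggregates them into growth and roundness curves over a
differentiation time course. `C = 1` for a perfect circle; any other
shape gives `C < 1`, so declining `C` tracks the emergence of
morphological asymmetries as organoids grow. It is aimed at labs that
image one organoid per well on a routine schedule (e.g. daily during
differentiation) and want reproducible, scriptable measurements instead
of hand-drawn outlines.

## Pipeline

For each image, on the 0–255 intensity scale:

1. **Gaussian smoothing** (SD 6 px) to suppress texture and noise.
2. **Graph-based segmentation** (Felzenszwalb–Huttenlocher): a grid
   graph over pixels, edge weight = absolute intensity difference,
   edges processed in ascending order with a union-find; components
   merge while the connecting weight is within `Int(C) + k/|C|` of each
   component's internal difference. A final pass removes components
   smaller than 3 px.
3. **Background rejection**: segments whose mean intensity exceeds the
   threshold (90) are background — organoids are darker than the
   transmitted-light background.
4. **Mask extraction**: the largest connected non-background region,
   with a light level-set regularisation of its boundary.
5. **Morphometry**: `A` by pixel counting, `P` as the integral of the
   gradient magnitude of the mask indicator (calibrated on an
   axis-aligned square), `C` from the formula above. A microscope pixel
   size in mm/px converts `A` and `P` to physical units; `C` is
   dimensionless.

A synthetic phantom generator (dark perturbed disks with controllable
boundary irregularity, blur, noise and vignetting, plus exact
ground-truth masks) makes every stage testable without real data, and a
statistics module implements the one-way ANOVA + Tukey HSD and
fold-change responder calls used for drug-response secretion readouts
(e.g. serotonin release under SSRI treatment).

## Worked example

```python
from organoid_morph import (PhantomSpec, generate_phantom, measure_image,
                            segment_organoid, jaccard_index)

spec = PhantomSpec(radius_px=60, irregularity_amplitude=0.05,
                   image_size_px=200, seed=17)
image, truth = generate_phantom(spec)
result = measure_image(image)
mask = segment_organoid(image)
print(f"area        = {result.area:.0f} px^2")
print(f"perimeter   = {result.perimeter:.1f} px")
print(f"circularity = {result.circularity:.3f}")
print(f"jaccard vs ground truth = {jaccard_index(mask, truth):.3f}")
```

prints

```
area        = 10923 px^2
perimeter   = 392.2 px
circularity = 0.892
jaccard vs ground truth = 0.959
```

The phantom is a radius-60 disk with mild (5% RMS) boundary
irregularity; the measured area is within 4% of the ideal π·60² ≈
11310 px², the mask overlaps the ground truth at Jaccard 0.96, and the
5% irregularity pulls C down from ~1 to 0.89.

The same pipeline runs from the shell:

```
organoid-morph synth --out-dir synth/ --lines 6 --seed 17
organoid-morph measure --input synth/manifest.csv --out results.csv \
    --pixel-size-mm 0.005 --overlay-dir overlays/
organoid-morph growth-curves --results results.csv --out summary.csv --plot-dir plots/
organoid-morph response --simulate --seed 1 \
    --responders healthy_1,healthy_3,AD_1,AD_2 --out calls.csv
```

The `response` command prints the overall dose effect and per-line
calls, e.g.:

```
one-way ANOVA across doses: F=61.59 (df 2,105), p=2.005e-18
  Tukey ctrl vs 10 uM: diff=-0.4409 q=1.327 p_adj=0.6174
  Tukey ctrl vs 100 uM: diff=-4.721 q=14.21 p_adj=2.143e-14 *
  ...
  healthy_2: baseline 4.59 ng/mL, 0.873x @10uM, 1.09x @100uM -> non-responder
  healthy_3: baseline 4.07 ng/mL, 1.27x @10uM, 2.83x @100uM -> responder
```

## Layout

| module | contents |
|---|---|
| `organoid_morph.image_io` | loading/normalising PNG/TIFF, manifests, overlay output |
| `organoid_morph.segmentation` | smoothing, graph segmentation, background logic, mask extraction |
| `organoid_morph.morphometry` | area, gradient-integral perimeter, trace oracle, circularity |
| `organoid_morph.phantoms` | synthetic organoid images + ground truth, growth series |
| `organoid_morph.timeseries` | per-line mean ± SD growth/roundness curves, plots |
| `organoid_morph.response_stats` | ANOVA, Tukey HSD, fold-change responder calls, simulator |
| `organoid_morph.cli` | `organoid-morph {measure,synth,growth-curves,response}` |

See `docs/methods.md` for the model details, parameter choices and
known limitations.
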