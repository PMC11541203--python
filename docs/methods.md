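# Methods

This note documents the algorithms, the parameter choices that matter,
and what the synthetic validation does and does not demonstrate.

## Image model and normalisation

All computation happens on a 2-D intensity raster scaled to [0, 255].
The fixed scale matters because the background threshold (90) is an
absolute intensity: 8-bit input passes through unchanged, 16-bit input
is rescaled linearly by 255/65535 (never percentile-stretched, which
would make the threshold data-dependent), and RGB collapses through the
ITU-R 601 luma weights (0.299, 0.587, 0.114). Physical calibration is a
single pixel size in mm/px supplied by the user; burned-in scale bars
are not parsed.

## Segmentation chain

**Smoothing.** Isotropic Gaussian, SD 6 px, reflect padding, output
clipped to [0, 255]. This is deliberately heavy: it suppresses interior
texture so the organoid body behaves as one quasi-flat region.

**Graph segmentation.** The Felzenszwalb–Huttenlocher algorithm on the
smoothed image: grid graph (8-connectivity by default, 4 available),
edge weight = absolute intensity difference, edges sorted ascending and
processed with a union-find. Components merge when the edge weight is
at most `min(Int(C1) + k/|C1|, Int(C2) + k/|C2|)`, `Int(C)` being the
largest weight in the component's minimum spanning tree so far. A
final ascending-order pass merges any component below `min_size_px`
(default 3) into the neighbour joined by the cheapest edge, so no
segment smaller than 3 px survives. All ties (equal weights, equal
sizes) resolve by row-major construction order, purely for determinism;
with continuous-valued smoothed intensities ties are measure-zero, and
segmentation commutes with image mirroring.

**Merge scale `k`.** After SD-6 smoothing the intensity field is very
smooth; neighbouring-pixel differences inside quasi-flat regions are
far below 1 grey level while the organoid boundary ramp still rises by
several grey levels per pixel. `k` must therefore sit between those two
scales. The default is `k = 2.0`: components then grow freely across
sub-grey-level variation but cannot climb the boundary ramp. Large
values of `k` behave badly on this kind of image — at `k ≳ 500` the
organoid leaks into the background entirely (the smooth ramp can be
climbed in small increments), and intermediate values fragment the ramp
into wide annuli that misassign boundary territory. `k` is exposed in
`SegmentationParams` and the config file.

**Background classification.** Per-segment mean intensity, strictly
greater than the threshold (default 90) → background. Organoids in
transmitted light are darker than the background; `invert_polarity`
flips the rule for dark-background modalities. Means are computed on
the *original* (pre-smoothing) intensities by default. The alternative
(means on the SD-6 smoothed image, `classify_on="smoothed"`) biases the
cut systematically inward: with interior ≈ 40 and background ≈ 200 the
smoothed profile crosses 90 about `Φ⁻¹((90−40)/160)·σ ≈ 0.49 σ ≈ 3 px`
inside the true boundary, which alone caps the achievable mask overlap
(Jaccard ≈ 0.90 for a radius-60 organoid). Original-intensity means
avoid the bias because pixels well inside the optical transition band
are unambiguous.

**Mask extraction.** The union of all non-background segments is taken,
its largest connected component kept, and the boundary regularised by
thresholding a Gaussian-smoothed indicator (SD 3 px — half the
segmentation smoothing scale) at 0.5, followed by hole filling. The
union matters because the smoothed boundary ramp is fragmented into
annular segments: picking a single segment recovers only the flat
interior core (observed Jaccard ≈ 0.65 on phantoms). The level-set
regularisation is area-neutral to first order and removes
segment-granularity raggedness that would otherwise inflate the
perimeter estimate by several percent; if regularisation would erase a
tiny mask it is skipped. `region_mode="segment"` restores the strict
largest-single-segment behaviour, and `regularize_sigma_px=0` disables
the smoothing.

## Morphometry

**Area** is the foreground pixel count (× pixel_size² in mm²).

**Perimeter** is the integral of the gradient magnitude of the mask
indicator. Plain central differences on the raw 0/1 field are accurate
for axis-aligned boundaries but overestimate diagonal ones by ~5%, so
no single calibration can serve all orientations. The indicator is
therefore pre-smoothed with a SD-1 px Gaussian — by the coarea formula
the gradient integral of a smoothed indicator converges to the true
boundary length — and a single fixed calibration factor
(1.0092277652266166, pinned by a regression test) makes a 100-px
axis-aligned square measure exactly 4s. Discrete disks of radius 30–100
then measure within ~0.5% of 2πr and their circularity lies in
[0.95, 1.05]. Circularity is reported as computed, without clamping at
1; masks touching the image border raise an error (the perimeter would
be undefined along the cut) rather than being silently cropped. A
single-pixel mask has perimeter 4 by convention (its unit square), so
C = π/4 stays defined.

**Trace oracle.** An independent Moore-neighbour boundary tracer
(axial steps 1, diagonal steps √2, Jacob's stopping criterion) exists
solely as a cross-check; the two estimators agree within 8% on phantom
ground-truth masks of radius ≥ 30 px and irregularity ≤ 0.2. The
tracer overestimates smooth curves by ~4–5% (chain-code length bias),
which is why it is the oracle rather than the measurement.

## Phantom generator

The boundary is a perturbed circle in polar form,
`r(θ) = R · (1 + a · Σ_m a_m cos(mθ + φ_m))`, modes 2–8, coefficients
and phases drawn from a seeded RNG and normalised so the angular
perturbation has unit RMS; the amplitude `a` is then a single scalar
that monotonically controls true circularity, which the ordering and
monotonicity tests rely on. The interior is filled at intensity 40, the
exterior at 200, followed by optional multiplicative vignetting, optical
blur (SD 2 px), additive Gaussian noise (SD 5), and clipping to
[0, 255]. The ground truth is the unblurred interior. Because the
unit-RMS perturbation peaks above its RMS, auto-sized images leave a
3×-amplitude radial margin so the silhouette never contacts the border.

Default intensities put the threshold 90 between interior and
background means, exercising the polarity convention. Time series use a
saturating radius model `r(day) = r_max · day/(t_half + day)`
(defaults r_max 100 px, t_half 6 d) with irregularity growing linearly
(0.003/day): steep early growth that plateaus, and roundness that
slowly degrades. This is a rendering convenience for generating
plausible series, not a biological growth model. The default imaging
schedule is daily through day 21 then every 3 days to day 42
(28 timepoints).

What the phantoms do **not** emulate: internal texture (rosettes,
necrotic cores), debris and out-of-focus neighbours, uneven
illumination beyond a radial vignette, multiple organoids per frame,
and intensity drift across days. Passing the phantom suite therefore
demonstrates correctness of the algorithmic chain under controlled
contrast, not robustness to every real-world imaging artefact.

## Time-series summaries

Morphometry rows group by (cell_line, day); each image is one
observation. SDs are sample SDs (n−1), reported as 0 for singleton
groups, and no interpolation is done across missing days. Growth-rate
profiles are first differences of mean area over the observed day gaps.

## Dose-response statistics

The one-way ANOVA is the classic between/within mean-square F with
(k−1, N−k) degrees of freedom; its p value is the upper F tail
evaluated through the regularized incomplete beta function. Tukey's
HSD uses the Tukey–Kramer statistic
`q = |x̄_A − x̄_B| / √(MSW/2 · (1/n_A + 1/n_B))` and adjusted p values
from the studentized-range distribution, whose CDF is computed by
direct numerical double integration: a 128-node Gauss–Legendre rule
over the normal-range probability (|z| ≤ 9) inside an adaptive
quadrature over the `√(χ²_ν/ν)` scale variable (absolute tolerance
1e-8). The implementation agrees with an independent quadrature oracle
to ~1e-6 and is tested for conservativeness against unadjusted pairwise
t-tests.

Responder calls: fold change = mean treated / mean baseline per line
and dose; a line is a responder when the fold change at the highest
dose reaches the threshold (default 2.0, configurable — observed
responses in this assay class are 2–3-fold while non-responders show
essentially no change); the response is dose-dependent when fold
changes strictly increase with dose. Values below the assay detection
limit (default 0.49 ng/mL) are flagged but retained unmodified — no
imputation rule is applied. The secretion simulator draws log-normal
values (baseline mean 4.5 ng/mL, CV 0.15, n = 6 organoids per line and
dose by default) with responder lines scaled 1.2× at 10 µM and 2.5× at
100 µM; under these effect sizes responder labels are recovered with
>95% per-line accuracy, and all-null simulations keep the family-wise
false-positive rate of the Tukey procedure at the nominal level.

## Problem sizes and numerical choices

Validation batches use 20 seeded phantoms per condition at radii
40–100 px (images 164–280 px square) — large enough that discretisation
error in C is a few percent, small enough for quick turnaround. The
Type-I-error simulation uses 500 seeds; responder recovery uses 100.
Determinism throughout: every stochastic component takes an explicit
seed, ties in the segmentation resolve by fixed scan order, and batch
CSVs are formatted with fixed precision so reruns are byte-identical.

## Known limitations

- One organoid per frame: the largest-region rule silently prefers the
  biggest object and is wrong for multi-organoid fields.
- The absolute threshold 90 presumes brightfield exposure conventions
  in which background sits well above 90 and organoid interiors below
  it; heavily over- or under-exposed batches need the threshold (or
  polarity) adjusted.
- Perimeter (and hence C) carries a few percent of discretisation
  error below radius ~30 px; circularities slightly above 1 are
  possible for near-perfect small disks and are reported as computed.
- The union-of-segments mask extraction assumes the organoid is the
  largest dark connected region; large dark debris attached to the
  organoid will be absorbed into the mask.
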