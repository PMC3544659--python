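# Methods

## Image model and stain separation

A brightfield micrograph of a DAB + hematoxylin stained section is modeled
by Beer-Lambert absorption: for channel `c` with incident (background)
intensity `I0_c`, the transmitted intensity is `I_c = I0_c * 10^(-OD_c)`
and optical densities add across stains. With the unit-norm per-channel OD
vectors of hematoxylin, DAB and a residual stacked as columns of a 3x3
matrix `A`, the per-pixel OD vector is `od = A @ conc`, so concentrations
are recovered as `conc = A^-1 @ od` (color deconvolution). Negative
concentrations are clamped to zero: they are physical quantities, and
negative values only arise from noise below the stain plane.

**OD transform.** `OD_c = -log10(max(I_c, eps) / I0_c)` clamped at zero,
with `eps = 1` intensity unit. The floor (rather than an additive offset)
keeps the transform exactly unbiased for every intensity >= 1 while bounding
the OD of a fully black pixel at `log10(255) ≈ 2.4`; an additive `I + eps`
form would brighten recovered dark pixels by several intensity units and
break the round-trip quantization bound below.

**Stain vectors.** The default `hdab` preset uses the widely published
Ruifrok-derived vectors, hematoxylin (0.650, 0.704, 0.286) and DAB
(0.269, 0.568, 0.778), with the residual column their normalized cross
product. These are a configuration default, not a fitted quantity; a 3x3
matrix can be supplied from a text file and columns are renormalized on
load. Stain-vector estimation from the image itself is out of scope.

**Background.** Fixed at (255, 255, 255) by default — standard brightfield
slides have near-white background — with optional per-image estimation as
the 99th-percentile channel value (`estimate_background` config flag).

**Quantization.** All arithmetic is floating point; quantization to 8 bits
happens only when a stain channel image is produced,
`I = clamp(round(255 * 10^-conc), 0, 255)` with round-half-away-from-zero.
For a noise-free image rendered from known concentrations, the only errors
in a render → unmix round trip are the 8-bit roundings, which propagate
through `A^-1` (the DAB row has absolute sum ≈ 2.2). The recovered DAB
intensity stays within ±2 of the analytic `255 * 10^-c` provided the
counterstain is moderate (hematoxylin OD amount <= ~0.35 when co-occurring
with dark DAB); at stronger counterstain the rendered channels approach
black and the amplified rounding can exceed that bound. The synthetic
generator's default ranges respect this domain.

## Zone histogram and grading

The unmixed DAB channel is binned into four closed integer zones:
0–60 (grade 3+), 61–120 (2+), 121–170 (1+), 171–230 (0). Intensities
231–255 are excluded as non-informative bright material (fat, empty
glass); the five counts always sum to the pixel count. Grading applies two
rules in order:

1. **Dominance.** If one zone holds strictly more than 66% of the
   *scoreable* (non-excluded) pixels, its grade is assigned directly. The
   denominator is scoreable pixels, not all pixels: the excluded range is
   declared uninformative, so it should not dilute a dominant zone. The
   threshold is strict — exactly 66% does not trigger the rule.
2. **Weighted score.** Otherwise the grade is the zone-weighted mean
   `(3 n3 + 2 n2 + 1 n1 + 0 n0) / (n3 + n2 + n1 + n0)`, a value in [0, 3],
   rounded half up (1.5 → 2+). Half-up favors detection sensitivity and is
   configurable (`rounding = half_down`). The weighted-mean form is the
   simplest formula consistent with the dominance rule reducing to the
   same answer on one-zone images; it is isolated behind a single function
   (`scoring.weighted_score`) so an alternative formula is a one-line swap.

Both the histogram and the grade are permutation-invariant in the pixels,
hence invariant under rotation, flips and shuffling.

**Stained area.** Independently of the grade, the fraction of scoreable
pixels at or below intensity 170 (i.e. any positive-zone pixel; threshold
configurable) is reported in the pathologist's area categories. The
published category edges overlap ("20–70%", "more than 70–80%"); they are
implemented as half-open bins [0, 0.10) negative, [0.10, 0.20) focal,
[0.20, 0.70) patchy, [0.70, 1] diffused — a single 0.70 cut for diffused.

**Aggregation.** For sections photographed as several fields,
`average_grade` takes the arithmetic mean of per-image weighted scores and
rounds; the dominance rule applies within single images only.

**Degenerate inputs.** An image whose pixels are all excluded raises
`NoScoreablePixelsError` (a pure-white image is the canonical case); empty
images raise `EmptyInputError`. Ties need no special handling: two zones
cannot both exceed 66%, and the non-dominant path is decided by the
formula, not an argmax.

## Synthetic image generator

The generator exists so every stage is testable without slide images. It
emulates the tissue classes the scorer must face: DAB-stained tumor
calibrated to one intensity zone, hematoxylin-counterstained
nuclei/stroma, lightly stained stroma, and bright fatty background
(rendered DAB intensity > 230).

* **Geometry.** The image is partitioned into 8x8-pixel tiles assigned to
  regions by largest-remainder apportionment of the requested area
  fractions and shuffled by the seed — blocky patches, not per-pixel salt.
  Histogram scoring is geometry-blind, so simple shapes suffice; no
  attempt is made at nucleus-level morphology or realistic texture.
* **Calibration.** A region's DAB concentration range is computed by
  inverting the render equation, `c = -log10(I / 255)`, at the target
  zone's edges pulled in by a 5-intensity-unit margin (absorbing the ±2
  round-trip quantization error), so calibration stays correct if the
  stain matrix preset changes. Tumor counterstain defaults to hematoxylin
  OD 0.10–0.35 (moderate counterstain, inside the round-trip domain
  above); stroma 0.05–0.20 with DAB in the negative zone; background has
  zero concentrations.
* **Noise.** Additive Gaussian noise on the 8-bit channels, default
  sd = 2, applied before clamping/rounding. This exercises zone-boundary
  robustness while leaving aggregate grading intact.
* **Ground truth.** The true grade is computed analytically from the
  realized region areas via the same dominance/weighted rules, never by
  running the scorer on the rendered image.
* **Default single-sample layout.** 70% tumor in the target zone, 15%
  stroma, 15% background — the tumor holds ~82% of scoreable pixels, so
  the dominance rule decides, as it does for most real single-zone fields.
* **Cohorts.** `generate_cohort` maps (receptor subtype, true grade)
  counts to labelled records with rendered images; `tabulate_cohort`
  expands a count table into records alone. The default layout is the
  grade-by-subtype table of a published 108-case breast-cancer hNIS
  cohort (33 graded 2+, 43 graded 1+, 32 negative across four subtypes).
  Menopause/chemotherapy labels are drawn reproducibly from the seed at
  realistic marginal rates (44% premenopausal, 15% post-chemotherapy) and
  carry no association with grade.

What passing tests on this generator show — and what they do not: they
validate the algebra and the rule logic of the pipeline under a correct
absorption model with homogeneous regions. They do not show robustness to
real-slide phenomena the generator omits: stain-vector drift between
batches, chromatic camera noise, out-of-focus blur, tumor-to-stroma ratio
variation (the main source of manual/automated disagreement in practice),
or nuclear/membrane compartment effects.

## Cohort statistics

* **Positivity** is grade >= 1+, matching the positive/negative dichotomy
  used for such cohorts (1+ and 2+ are positive).
* **Agreement**: percent match, and Cohen's kappa over the four ordinal
  grades — unweighted by default (linear weights available), computed via
  scikit-learn with all four categories fixed as labels. When both raters
  are constant, chance agreement is 1: perfect constant agreement returns
  kappa = 1 by convention; constant disagreement raises.
* **Association**: Pearson chi-square on 2x2 tables (df = 1) via scipy,
  uncorrected by default with Yates correction behind a flag. Uncorrected
  Pearson is the common default of the spreadsheet/Prism-style software
  used for such cohorts; on the ER table expanded from the published
  counts ((32, 4) / (44, 28)) the uncorrected p is ≈ 0.0029 and the Yates
  p ≈ 0.0058, bracketing the published 0.0033, whose exact test variant is
  unstated. Both are reported; neither is tuned to match.
* **Summaries** recompute every percentage from their own counts
  (round-half-up; integer by default, one decimal where conventionally
  printed) and assert `n_positive = n(1+) + n(2+) + n(3+)` on every row.
  Percentages of empty strata are NaN, never 0.

## Problem sizes

Defaults keep everything desk-scale: synthetic images are 96x96 (a 48x48
option is used in cohort-level tests), acceptance recovery runs 200 images
per noise level, and the round-trip check uses 100 16x16 fields. The whole
suite runs in a few seconds on one CPU.

## Known limitations

* The weighted scoring formula is a documented reconstruction (see above),
  not a transcription; any alternative lives behind one function.
* Whole-slide pyramidal formats (SVS/NDPI), >3-stain unmixing, and
  stain-vector estimation are out of scope; inputs are plain 8-bit
  RGB PNG/TIFF/JPEG fields.
* The 66% dominance denominator (scoreable vs all pixels) is a documented
  choice; with the default layout the two readings rarely differ.
* No cell segmentation or compartment-specific scoring: the method grades
  bulk pixel intensity, so fields with low tumor-to-stroma ratio are
  under-graded — the motivation for `average_grade` and for capturing
  multiple fields per section.
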