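# ihcscore

Semi-automated, quantitative scoring of DAB-stained immunohistochemistry
(IHC) images, built for studies that grade marker expression — here modeled
on hNIS (human sodium iodide symporter) staining of breast-tumor sections —
on the standard four-tier scale (0, 1+, 2+, 3+) and then relate those
grades to receptor status across a patient cohort. It is aimed at digital
pathology and translational-research groups who want a reproducible,
bias-free alternative to visual scoring, plus the cohort statistics that
usually accompany it.

## Method

1. **Stain separation.** A brightfield RGB micrograph is converted to
   per-channel optical density, `OD_c = -log10(max(I_c, 1) / I0_c)`, and
   unmixed by Ruifrok-Johnston color deconvolution: with the 3x3 stain
   matrix `A` whose unit-norm columns are the OD vectors of hematoxylin,
   DAB and a residual, per-pixel concentrations are `c = A^-1 od`. The pure
   DAB plane is re-rendered as an 8-bit image, `I = round(255 * 10^-c)`
   (0 = darkest, 255 = unstained).
2. **Zone histogram.** DAB intensities are binned into four closed zones —
   0–60 → 3+, 61–120 → 2+, 121–170 → 1+, 171–230 → 0 — while pixels above
   230 are excluded as fatty tissue / bare background.
3. **Grading.** If one zone holds strictly more than 66% of the scoreable
   pixels, the image takes that zone's grade directly (dominance rule).
   Otherwise the grade is the zone-weighted mean
   `(3 n3 + 2 n2 + 1 n1) / (n3 + n2 + n1 + n0)` rounded half up. A
   pathologist-style stained-area category (negative < 10%, focal 10–20%,
   patchy 20–70%, diffused > 70%) is reported alongside.
4. **Cohort statistics.** Manual-vs-automated agreement (percent match and
   Cohen's kappa over the four grades), 2x2 receptor-status vs positivity
   association (Pearson chi-square, optional Yates correction), and
   subtype-stratified positivity summaries. A sample is *positive* when its
   grade is 1+ or higher.

Because the original slide images of such studies are rarely deposited,
the package ships a seeded synthetic-image generator (`ihcscore synth`)
that forward-renders DAB/hematoxylin fields through Beer-Lambert
absorption with analytic ground-truth grades, so the entire pipeline is
testable end to end.

## Worked example

Render one synthetic image per grade, then score them:

```sh
$ ihcscore synth --out demo --seed 7 --n-per-grade 1 --size 96
wrote 4 images to demo
$ ihcscore score demo/synth_g0_000.png demo/synth_g1_000.png \
                 demo/synth_g2_000.png demo/synth_g3_000.png
file,n3,n2,n1,n0,n_excluded,weighted_score,dominance_applied,grade,stained_fraction,area_category
demo/synth_g0_000.png,0,0,14,7844,1358,0.001782,True,0,0.001782,negative
demo/synth_g1_000.png,0,13,6441,1416,1346,0.821728,True,1+,0.820076,diffused
demo/synth_g2_000.png,2,6457,6,1405,1346,1.64244,True,2+,0.821474,diffused
demo/synth_g3_000.png,6463,1,3,1405,1344,2.463669,True,3+,0.821519,diffused
```

Each row lists the pixel counts of the four zones (`n3`..`n0`) and of the
excluded bright range, the weighted score, whether the >66% dominance rule
fired (here it always does: ~82% of scoreable pixels sit in the tumor
zone), the assigned grade, and the stained-area fraction with its
pathological category. The grade 2+ image, for instance, has 6457 of 7870
scoreable pixels in zone 2 — dominance applies and the image is graded 2+
directly; its weighted score 1.64 would have rounded to the same grade.

Cohort statistics run on a CSV with columns
`sample_id, er, pgr, her2, menopause, chemo, manual_grade, auto_grade`:

```sh
ihcscore cohort --in cohort.csv --stratify er
```

which prints the per-stratum positivity table, percent match and kappa
between the two grading columns, and the chi-square association of ER and
HER2 status with positivity.

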