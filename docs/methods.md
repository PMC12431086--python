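# Methods

## Estimation model

`bloomscale` implements single-plane 2-D photogrammetry: every object of
interest (open flowers and one reference object of known area) is assumed to
lie in one plane perpendicular to the camera axis, so one scale factor
(px/cm) applies to the whole scene and

    floral_area = F_pixels / R_pixels × R_area.

The estimator is exactly homogeneous in the counts (k·F, k·R give the same
area) and linear in F, which is what makes it robust to capture distance:
moving the camera rescales both counts by the same factor. Perspective
distortion, out-of-plane flowers and occlusion are outside the model; they
enter real images as segmentation error, not as estimator error.

Key constants, all configurable:

| parameter | default | units | note |
|---|---|---|---|
| reference area `R_area` | 58 | cm² | the published constant for the 7.6 cm cardboard square; the geometric value is 7.6² = 57.76 cm², so the default carries a deliberate +0.42% multiplicative offset |
| tile grid | 2×2 | — | sliced inference; tiles are non-overlapping half-open rectangles that cover the image exactly (ceil-first rule for non-divisible dimensions) |
| confidence threshold | 0.5 | — | inclusive (≥); applied after tile masks are lifted and merged |
| connectivity | 8 | — | connected components of the classical segmenter |
| morphology kernel | 3 | px | square footprint for the optional open/close step |

Pixel counts are totalled globally across tiles before the ratio is taken,
and same-class instance masks are counted as their **union**: a flower pixel
is a flower pixel once, however many overlapping detections cover it.
Double-counting would inflate the numerator of the ratio. An image with no
reference pixels has no scale; the pipeline raises a
reference-not-detected error rather than guessing. If more than one
reference component is found, all are unioned and a warning is recorded
(the protocol places exactly one reference object per image).

## Segmentation backends

Segmentation is behind a contract (image in, labelled masks plus confidence
out) with two class-specific backends, so a fine-tuned neural instance
segmenter can replace either backend independently. The built-in backend is
a deterministic HSV box classifier: threshold in hue/saturation/value
(hue may wrap through 0), optional opening/closing, 8-connected components,
one detection per component at confidence 1.0. The classical backend has no
calibrated score, so the 0.5 threshold is exercised through stub backends in
the tests; it is meaningful for probabilistic backends.

Because the threshold-only classifier is per-pixel, tiled and untiled runs
give bit-identical class pixel counts (a component split across a tile
boundary is reported as several detections, but the union is unchanged,
provided no minimum-component-size filter is active). With morphology or a
size filter, tile boundaries can change results within a kernel's reach —
the defaults therefore use neither.

## Evaluation metrics

Detection quality uses mask IoU with greedy confidence-ordered one-to-one
matching (ties to the lowest ground-truth index). AP is the area under the
precision-recall curve with the all-point precision envelope (the COCO
convention); mAP@0.5:0.95 averages AP over the ten IoU thresholds
0.50, 0.55, …, 0.95 with equal weights, and multi-class summaries average
per-class values with equal weights. The test suite checks the sweep
implementation against an independent brute-force oracle that enumerates
confidence cuts and integrates the envelope numerically.

Algorithm accuracy uses three views of predicted-vs-measured area pairs:

- **bias** = mean(predicted − measured), signed, per group; positive means
  over-estimation;
- **R²** from the OLS fit of predicted on measured; **RMSE** on identity
  residuals (predicted − measured), i.e. against ground truth rather than
  against the fitted line — the fitted-line reading is also defensible, but
  identity residuals measure the error a user actually makes;
- **one-way ANOVA** on per-image residuals grouped by a category factor.
  Running it on residuals (not on per-group bias values) gives the
  conventional degrees of freedom (k−1, n−k) over the pooled images, e.g.
  (4, 70) for 75 images in five color groups. The p-value comes from the
  regularized incomplete beta form of the F upper tail, independent of any
  particular stats routine's conventions; scipy's `f_oneway` is used only as
  a cross-check in tests. Degenerate inputs are flagged rather than NaN'd:
  all-identical data gives F = 0 with a flag, zero within-group variance
  with distinct means gives an infinite-F flag.

## Synthetic scenes

The generator renders what the estimator assumes: a planar scene at one
scale, a plain low-saturation background, an axis-aligned brown reference
square, and 3–6 flowers per scene drawn from the five color palettes
(T1 mixes red/orange/yellow on one plant; T2 pinkish-purple; T3 pink;
T4 red; T5 purple) and three petal-display shapes (C1 compound rosettes,
C2 continuous blobs, C3 clumps of loose petals, which may rasterize as
several components — deliberately, since loose clumps fragment real
detectors too). Flower footprints are unions of disks with geometry drawn
in centimeter coordinates, so one scene spec rendered at several scales
depicts the same physical layout. Placement keeps flowers clear of the
reference square and of each other (clearance 0.55 × flower size plus
0.5 cm). Flower diameters are uniform on 3–7 cm.

The mask channel is rasterized without anti-aliasing — the painted pixels
*are* the ground-truth masks — so `f_pixels_true / r_pixels_true ×
rendered_reference_area = true_floral_area` holds to machine precision for
every scene, which is the end-to-end recovery oracle. The visual channel
carries a per-pixel brightness jitter (RGB scale factor in [0.93, 1.05]),
which preserves hue and saturation; the HSV bands are chosen with margins
so jittered flower pixels stay inside the flower bands and outside the
reference band (brown is a dark orange, separated from warm flower colors
by value, and the gray background is excluded by saturation).

Capture distance maps to scale by inverse proportionality (pinhole
relation), px_per_cm = 600/distance, then snapped so the 7.6 cm reference
side rasterizes to a whole number of pixels (76/57/46 px for 60/80/100 cm;
snap error < 0.9%). Without the snap, the rendered reference area would
carry a scale-dependent quantization offset of up to −1.3% at the smallest
scale — a rasterization artifact, not a property of the planar model the
generator emulates — which would dominate the cross-scale comparison. With
it, the only systematic estimation error left in the synthetic conditions
is the uniform +0.42% offset from the nominal 58 cm² constant.

That choice has a visible consequence in the benchmark ANOVA: because the
residual of every scene is exactly 0.42% of its floral area, per-group bias
scales with mean floral area. The petal-display factor controls flower
footprint (rosettes cover more area than loose clumps of the same nominal
size), so its ANOVA strongly rejects — on absolute differences of a few
tenths of a cm² — while the color and distance factors, whose groups are
balanced in area, do not. The synthetic benchmark therefore demonstrates
distance robustness and color robustness, and shows that an
area-proportional bias is *detectable* by the category ANOVA when within-
group noise is near zero. Real images add segmentation noise several orders
larger, so passing these tests shows the apparatus is correct, not that any
particular detector is unbiased on real plants.

Benchmark scenes are assigned round-robin over the 5×3×3 category grid
(n = 75 gives 30 cells with two scenes and 15 with one); per-scene seeds
derive from the master seed via `SeedSequence`, so benchmarks are exactly
reproducible.

## Problem sizes and numerical choices

The default benchmark is 75 scenes on a 36 × 48 cm canvas (480 × 360 px at
the closest scale), which keeps a full generate-estimate-evaluate cycle
under ten seconds on one CPU while preserving the factorial structure of
the study design. The AP brute-force oracle integrates on a 200,000-point
recall grid (discretization error ≤ 5·10⁻⁵, compared at 10⁻⁴). ANOVA
calibration uses 1,000 null simulations of 3 groups × 8 observations;
the rejection-rate check uses the band [0.03, 0.07] around the nominal
α = 0.05. Floating-point SS conservation is asserted at 10⁻⁹ relative.

## Known limitations

- No photorealism: no shadows, occluding foliage, perspective, or complex
  backgrounds; the classical backend's color separability is by
  construction, so its near-perfect synthetic detection metrics say nothing
  about real-world detector quality.
- The reference constant ambiguity (58 vs 57.76 cm²) produces a small but
  systematic over-estimate; users wanting exactness can set
  `--ref-area 57.76`.
- Bounding-box metrics, model training and weight management are out of
  scope; masks are the unit of evaluation and backends arrive pre-trained.
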