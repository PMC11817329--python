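# Methods

## The problem

Given bounding-box predictions from two or more object detectors over the
same images — in the motivating application, impacted-tooth detections on
dental panoramic radiographs — produce a single fused prediction set that is
more accurate than any individual detector, choose the fusion
hyperparameters automatically, and quantify everything with the standard
detection metrics. `dentfuse` starts where detector training ends: its
inputs are label/prediction files, never pixels.

## Box model

Boxes are continuous real rectangles in normalized center form
(cx, cy, w, h), fractions of the image dimensions. This matches the YOLO
label convention and makes mixed image resolutions (e.g. 540×380 through
3100×1300 in the motivating datasets) interoperable with no resizing. No
pixel quantization is applied anywhere; center↔corner conversion is affine
and exact. Boxes whose extent overflows the frame (jittered synthetic boxes,
real detector output) are clipped to [0,1]² with a warning rather than
rejected; a box entirely outside the frame is an error.

## Weighted Boxes Fusion

For one image and one class, detections are processed in descending
confidence after two preliminaries:

1. detections with raw confidence below `skip_box_thr` are dropped — this is
   a per-detector quality floor, so it is applied **before** weight scaling;
2. each remaining confidence is scaled by wₘ / mean(w) for its model's
   weight wₘ, keeping scores comparable across weightings.

Each detection then joins the existing cluster whose *current fused box* it
overlaps with IoU strictly above `iou_thr` (highest IoU wins; ties go to the
earlier-created cluster), or opens a new cluster. After every join the
cluster's fused box is recomputed as the confidence-weighted mean of member
coordinates and its score as the plain mean of member (scaled) confidences,
clipped to [0,1]. Comparing candidates to the running fused box, rather than
to every member, follows the iterative formulation of the reference WBF
algorithm.

Design choices where the formulation is genuinely open:

* **How model weights enter.** The coordinate/score averaging formulas do
  not themselves contain weights, yet the weights are tuned. Weights enter
  by scaling each detection's confidence, so they influence both the greedy
  clustering order and the weighted coordinate means. This follows the
  reference WBF implementation while keeping the fused score a plain average
  of the (scaled) member scores.
* **Score rescaling by cluster size.** The reference algorithm optionally
  multiplies the fused score by min(T, M)/M (T members, M models),
  penalizing boxes seen by only one model. This is implemented behind
  `rescale_by_model_count` and **off by default**, keeping the plain-average
  definition literal.
* **Tie-breaking.** Equal scaled confidences are ordered by (model id, input
  order) so results are reproducible regardless of file enumeration order.
* Fusion is per-class; with a single class (the impacted-tooth task) this is
  invisible, but it is required for generality.

## Evaluation

Matching is the standard PASCAL/COCO greedy discipline: predictions in
descending confidence, each claiming the unclaimed same-class ground truth
with the highest IoU provided IoU ≥ 0.5 (inclusive). The PR curve sweeps the
confidence cutoff over all distinct prediction confidences; because greedy
matching of the top-k predictions is independent of lower-ranked ones, the
sweep is computed in one pass with cumulative TP/FP counts (the per-threshold
re-matching oracle in the tests verifies this equivalence). AP integrates
the precision envelope p̃(r) = max_{r′≥r} p(r′) over recall (all-point
interpolation, the modern estimator of the area under the curve); the
historical 11-point variant is available behind a flag. mAP@0.5 is the
unweighted mean of per-class APs.

Detection reports quote a single precision/recall/F1 triple without naming a
confidence threshold; `dentfuse` uses the max-F1 point of the pooled sweep
by default (ties resolved toward higher recall), with a fixed-threshold mode
as the alternative. Zero-denominator conventions: P = 0 when TP+FP = 0,
R = 0 when TP+FN = 0, F1 = 0 when P+R = 0.

## Dataset split

Ids are shuffled by a seeded RNG and partitioned by the floor rule:
|train| = ⌊f_train·n⌋, |test| = ⌊f_test·n⌋, validation takes the remainder.
This is the only integer rule consistent with the published 80/5/15 split of
407 radiographs into 325/21/61 (0.05·407 = 20.35, yet 21 validation images).
The split is performed once and persisted as a plain-text manifest that all
later phases consume. An optional stratified mode applies the rule within
caller-supplied strata (e.g. source sub-dataset); the default is
unstratified, since the original split's stratification is unknown.

## Bayesian optimization

The objective f(θ) — validation mAP@0.5 (or max-F1; configurable, mAP@0.5
default, since published descriptions are ambiguous between the two) of the
fused ensemble — is expensive relative to its 4-dimensional domain, so it is
modeled with a Gaussian-process surrogate over the search box min-max scaled
to the unit hypercube.

* **Kernel**: Matérn-5/2 with a single shared length-scale — a robust
  default for low-dimensional hyperparameter surfaces, rougher than a
  squared exponential but still twice differentiable.
* **Hyperparameter refit**: each round, length-scale (8 points, geometric in
  [0.05, 2]) and signal variance (score variance × {0.5, 1, 2}) maximize the
  log marginal likelihood on a grid; diagonal jitter 1e-6. The prior mean is
  the mean of the observations.
* **Acquisition**: closed-form Expected Improvement, maximized over 2048
  scrambled-Sobol candidates plus 256 Gaussian perturbations (σ = 0.05)
  around the incumbent. If EI is identically zero (flat posterior) the
  highest-variance candidate is proposed, keeping exploration alive.
* **Loop**: 10 Latin-hypercube initial evaluations, then fit → propose →
  evaluate, to a budget of 50 evaluations or 15 consecutive
  non-improvements (> 1e-4), whichever comes first. Published experiments
  name a stopping criterion without defining it; these defaults are the
  package's own.
* **Failed evaluations** are kept in the trace, scored as the worst observed
  value minus one empirical standard deviation, so the surrogate learns to
  avoid the region without aborting the run.

Everything is driven by one integer seed: the Latin hypercube, the Sobol
candidates and the local perturbations all derive from it, so a run is fully
reproducible.

## Synthetic benchmark

The generator emulates detector *behavior*, not radiograph pixels. Ground
truth: per image, 1–4 boxes (uniform), sizes N(0.08, 0.02²) clipped to
[0.02, 0.3], centers uniform in two horizontal bands (x ∈ [0.1, 0.9],
y ∈ [0.25, 0.45] and [0.55, 0.75]) standing in for the upper and lower jaw;
boxes overlapping an earlier box with IoU > 0.3 are resampled (annotated
teeth barely overlap). Each image draws from its own integer-indexed RNG
stream, so datasets are reproducible per seed and images are independent.

A simulated detector emits each ground-truth box with probability
1 − miss_rate, adds i.i.d. Gaussian jitter (std `loc_jitter`) to all four
coordinates, and draws confidence as clip(0.75·IoU + 0.15 + ε, 0.01, 1)
(recall_heavy; precision_heavy uses 0.85·IoU + 0.10) with Gaussian ε — the
simplest model that makes confidence informative for WBF's weighted
averages. Poisson(fp_rate) false boxes per image are placed uniformly in the
bands and scored at IoU = 0, i.e. from the low tail of the same model.

The two presets encode the asymmetry that makes fusion worthwhile, measured
at a matched confidence threshold:

| profile | miss rate | FP/image | jitter |
|---|---|---|---|
| recall_heavy | 0.03 | 0.9 | 0.006 |
| precision_heavy | 0.15 | 0.15 | 0.004 |

Jitter levels were chosen from the measured probability that a jittered box
falls below the IoU-0.5 match criterion (≈1.5% at 0.006, ≈0.1% at 0.004 for
0.08-sized boxes): large enough that recall_heavy is visibly the sloppier
localizer, small enough that localization noise does not overwhelm its
miss-rate advantage and invert the intended recall ordering.

What the simulator does **not** model: correlated errors between detectors
beyond sharing ground truth, confidence miscalibration drift, class
confusion, duplicate detections of one object by one model, and any
image-content effects (e.g. super-resolution preprocessing changing detector
behavior). Passing tests therefore demonstrate the correctness of the
fusion/optimization/evaluation machinery and the qualitative
ensemble-beats-individuals effect under these error statistics — not
performance on real radiographs.

## Problem sizes

The test suite and the acceptance script run the full pipeline on 200-image
benchmarks (about 500 ground-truth boxes, 30 test images) with a
50-evaluation optimization budget, and the optimizer-vs-random-search
comparison on a 4-D quadratic with 20 repeat seeds at budget 40 — sizes at
which every experiment completes in seconds on one CPU core while leaving
the measured effects (fusion margin ≈ 5–9 mAP points) far above sampling
noise.

## Known limitations

* The GP surrogate refits on a small grid rather than by gradient ascent on
  the marginal likelihood; for 4-D spaces and ≤ 50 observations this is
  accurate enough and trivially robust, but it would be the first thing to
  replace for higher-dimensional searches.
* The greedy PR sweep assumes confidences are comparable across images,
  as all standard detection evaluators do.
* `evaluate` reports the operating point from the class-pooled sweep; for
  strongly imbalanced multi-class data per-class operating points may be
  preferable.
* The optional preprocessing hook in the CLI config records an external
  image-enhancement command in the run manifest for provenance; dentfuse
  never executes it.
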