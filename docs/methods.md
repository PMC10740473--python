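# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `fundus-shift`, and what the synthetic experiments do and
do not demonstrate about real screening data.

## Task and protocol

The task is binary referable-DR screening: a scorer f maps a fundus image to
a confidence f(x) ∈ [0,1] that the image shows referable disease. A labeled
dataset is split 80/10/10 into train/validation/test (sizes
round(n·fraction), remainder to train; the split permutation is salted so a
generator seeded identically in another stage cannot produce a correlated
ordering). The test split is evaluated once clean ("in-distribution") and
once after each degradation is applied to its images; membership and labels
never change between the two evaluations, so any metric difference is
attributable to the pixels alone. Robustness is reported as
Δ = clean − shifted for every metric, with the sign convention recorded in
the report schema: positive ΔAUC means discrimination degraded, while a
*negative* Δ(ECE) means calibration error grew under the shift. Degradation
precedes preprocessing (corrupt raw → preprocess → score), modeling
acquisition-time noise that the deployed preprocessing stack would also see.

## Degradation operators

All smoothing uses explicit normalized Gaussian kernels
G(radius, σ)[u,v] ∝ exp(−(u²+v²)/2σ²) on a (2·radius+1)² support, applied as
two separable 1-D convolutions with reflect (half-sample symmetric) padding —
mathematically identical to the full 2-D kernel, and cheap enough that every
operator is verified against a direct double-loop convolution in the tests.

* **Light transmission disturbance** `x' = clip(α·(G_L∗J) + x + β; [0, s])`.
  J is a hard disc of signed amplitude `bias_level` (positive =
  over-illumination, negative = under-illumination) centered at (a, b) with
  radius r_L; the kernel G_L shares the panel radius (half-width round(r_L))
  and has spatial constant σ_L, so the panel edge softens on the scale of the
  panel itself. The clip bound s ≤ 1 models saturation; clipping applies to
  the full sum.
* **Image blurring** `x' = clip(G_B∗x + n; [0,1])` with kernel half-width
  r_B, spatial constant σ_B, and i.i.d. additive Gaussian noise n of
  standard deviation `noise_sigma` drawn from the operator's seeded stream.
* **Retinal artifact** `x' = clip(x + Σ_k o_k·(G_{σ_k}∗D_k); [0,1])` where
  D_k is a disc of radius r_k/4 at a center drawn uniformly from the fundus
  mask, σ_k the smoothing spread (kernel half-width max(1, ⌈3σ_k⌉), covering
  the Gaussian mass), and o_k a signed luminance bias. Artifacts act equally
  on all channels (they are luminance defects of the optics).

### Severity presets

No canonical parameter values exist for these operators, so the package ships
citable presets (`none/low/mid/high`). Pixel quantities are stated at a
128-px image side and scaled by min(H,W)/128; the light panel's center is
drawn uniformly from the central half of the frame and its sign (over- vs
under-illumination) is a per-image coin flip.

| shift | parameter | low | mid | high |
|---|---|---|---|---|
| light | β (brightness, signed) | 0.03 | 0.06 | 0.12 |
| light | bias_level (signed) | 0.08 | 0.18 | 0.35 |
| light | r_L / min(H,W); s | 0.30; 1.0 | 0.35; 1.0 | 0.40; 0.95 |
| blur | σ_B px; noise σ | 1.0; 0.005 | 3.0; 0.01 | 8.0; 0.02 |
| artifact | K; r_k px; σ_k px; o_k | 4; 8–16; 1–2; ±0.15 | 12; 10–24; 1.5–3; ±0.25 | 30; 12–40; 2–4; ±0.4 |

Blur-high (σ_B = 8 px) deliberately exceeds the planted lesion scale
(Gaussian σ = 2.5 px), so it must erase the class signal; this makes the
end-to-end ΔAUC > 0 check mechanistic rather than incidental. `none` is the
identity and is always available as a pipeline self-check.

Dataset-level application derives per-image seeds as base_seed + index, so a
corrupted dataset is reproducible item by item and any single image can be
regenerated in isolation.

## Calibration estimators

With per-bin mean confidence f̄_k and empirical frequency ȳ_k:

* **Fixed-bin ECE** partitions [0,1] into M equal-width intervals (last bin
  right-closed; default M = 15) and returns Σ_k (|B_k|/n)·|f̄_k − ȳ_k|;
  empty bins carry zero weight. This estimator is biased upward on calibrated
  data (the per-bin |·| accumulates sampling noise ~√(M/n)), which the test
  suite demonstrates against the sweep estimator.
* **Monotonic-sweep ECE** sorts the sample by score (stable in the original
  index, so tied scores may fall in different bins — determinism without
  score perturbation), forms b equal-mass bins (remainder to the earliest
  bins) for b = 1…n, and selects the largest b* such that ȳ_1 ≤ … ≤ ȳ_b′
  for every b′ ≤ b*; the reported value is the binned calibration error at
  b*. Because the condition is required for all prefixes, the first b whose
  own partition breaks monotonicity terminates the search; with prefix sums
  the estimator costs O(n log n + b*²). Only the non-decreasing direction is
  tested, matching the assumption of a monotone increasing true calibration
  curve.

ROC-AUC uses the tie-aware rank-sum identity, which equals the pairwise
Mann–Whitney definition P(f(X⁺) > f(X⁻)) + ½·P(=) exactly; single-class
inputs raise an error rather than returning a conventional value.

### Calibration-recovery scenarios

The prediction-set generator draws scores from a named distribution and
labels from Bernoulli(g(score)). For the identity link the sample is
perfectly calibrated by construction and the sweep estimator should approach
zero (observed ≲ 0.007 at n = 10⁵). For the shifted link
g(p) = clip(p − δ, 0, 1), the true calibration error depends on the score
mass below δ: with uniform scores it is δ − δ²/2, not δ. The recovery
scenarios therefore use Beta(2,1) scores — a plausibly overconfident scorer
whose density vanishes at 0 — giving TCE = δ − δ³/3, within 0.003 of δ for
δ ≤ 0.2, so the estimator can be held to |estimate − δ| ≤ 0.01.

## Synthetic fundus data

The generator is a geometric emulation, not a photorealistic one: a dark
background (0.05), a centered disc of 90% of the half-frame with reddish base
color (0.55, 0.30, 0.12), a per-image illumination gain U(0.85, 1.0), a mild
radial vignette, 6 dark curved vessel arcs, and — for positives — 1–4 bright
yellowish lesion blobs (additive Gaussian bumps, σ = 2.5 px, amplitude 0.3)
placed within 75% of the disc radius. Defaults are 128×128 px; resolution
and field of view of real screening datasets vary, so these are free
parameters. Labels equal "at least one lesion planted", and datasets realize
exactly round(positive_frac·n) positives (default 0.35, in the range typical
of screening cohorts enriched for disease).

What passing tests show: the pipeline's contracts hold — operators match
their defining equations, estimators match brute-force oracles, the planted
signal is detectable and destructible, reports are bit-reproducible. What
they do not show: anything about real DR morphology, camera optics, grader
noise, or the ranking of real architectures under shift; the toy scorer is a
contract fixture, not a model of clinical performance.

## Toy scorer

Logistic regression on three features of the preprocessed (contrast-enhanced,
resized) green channel inside the fundus mask: mean intensity, a high
percentile of intensity, and the count of connected components brighter than
0.7. The percentile ∈ {95, 99, 99.8} is the single "decision-feature
scaling" hyperparameter and is selected on the validation split by ROC-AUC
(training fit quality if the validation split is single-class). Features are
standardized by training-split moments; the solver (lbfgs, C = 1) is
deterministic given the data and seed. The scorer is exposed through
`ScorerContract`, the same interface an external deep model would use, and
serializes to JSON for the CLI round trip.

## Numerical conventions and degenerate inputs

* Every image operation clips to [0,1] and the container validates range and
  shape; masks follow images through every transform (nearest-neighbor under
  resize/rotation).
* Reflect padding everywhere; kernel half-widths are ⌈3σ⌉ unless the
  operator's definition fixes them (light: round(r_L); blur: r_B).
* PNG export scales by 255 and rounds half-even.
* Equal-mass binning distributes remainder samples to the earliest bins;
  equal-width binning closes the last bin on the right.
* Zero-parameter degradations (bias 0, r_B = 0 with no noise, K = 0) are
  exact identities, asserted in tests.
* Report JSON is serialized with sorted keys and no timestamps, so identical
  configurations produce byte-identical files.

## Problem sizes

The shipped experiments use n = 300 images (30 test) for the end-to-end
protocol, n = 10⁵ for calibration recovery, and ≤ 12-sample grids for the
exhaustive estimator oracles — sizes at which every stated check is sharp
(the planted signal gives clean ROC-AUC > 0.9; the sweep estimator's
sampling error at n = 10⁵ is well under the 0.01 tolerance) while the whole
suite runs in well under a minute apart from the five-seed end-to-end check.

## Known limitations

* The vessel model is decorative: it adds realistic clutter for the contrast
  enhancement to amplify but carries no class information.
* The sweep estimator assumes a non-decreasing calibration curve; a scorer
  whose calibration curve decreases would be collapsed toward b* = 1.
* Severity presets are package conventions, not field standards; robustness
  deltas are only comparable across runs that share them.
* The light-transmission operator applies one panel per image; compound or
  multi-source illumination defects are out of scope, as is applying several
  degradation types simultaneously (they are evaluated one at a time).
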