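# Methods

## Overview

`hcscreen` implements a high-content screening analysis chain for
two-channel fluorescence microscopy of fixed cells: a DAPI channel for
nuclei and a γH2AX immunostain for DNA double-strand-break signaling.
The chain is

1. a multi-scale Gaussian-derivative **feature bank** on the raw DAPI
   intensities,
2. a **random-forest pixel classifier** (nucleus vs background),
3. **segmentation**: binarize the nucleus-probability map at 0.5,
   8-connected component labeling, removal of objects below 200 px
   (20.8 µm²),
4. **per-nucleus measurement** of mean/total intensity in both channels,
5. **well/plate aggregation** with normalization of nuclei counts to
   same-plate PBS controls, and
6. **four-parameter-logistic (4PL) dose-response fitting** reporting
   pIC50 with 95% CI and the bottom plateau.

A seeded synthetic-scene generator supplies two-channel images with
exact ground truth so the whole chain is testable without microscope
data.

## Feature bank

Six filter families at fixed scales: Gaussian smoothing at
σ₀ = 0.3 px and σ₁₋₈ = 0.7, 1, 1.6, 3.5, 5, 10, 20, 35 px; Laplacian of
Gaussian (LoG), Gaussian gradient magnitude, difference of Gaussians
(DoG), structure-tensor eigenvalues, and Hessian-of-Gaussian
eigenvalues at σ₁₋₈. That gives 9 + 8 + 8 + 8 + 16 + 16 = 65 features
per pixel. Design choices where the convention was open:

- **DoG inner scale**: DoG(σ) = G(σ)·I − G(0.66σ)·I, the common
  pixel-classification convention.
- **Structure tensor**: gradient scale σ, integration scale 0.5σ;
  eigenvalues clamped at 0 to remove negative round-off (the tensor is
  positive semi-definite by construction).
- **Boundary handling**: `reflect` by default — avoids the dark rim a
  constant pad would create and therefore avoids biasing nuclei at the
  field border; `nearest` and `constant` are available.
- LoG is computed as the trace of the Gaussian Hessian, so the identity
  LoG = λ₁ + λ₂ holds to machine precision and is asserted in tests.
- Derivative kernels are sampled Gaussians truncated at 4σ and then
  corrected: the order-2 kernel is DC-corrected to sum exactly to zero
  and both derivative orders are moment-normalized, so derivative
  features vanish identically on constant images, the gradient of a
  ramp is exactly the slope, and second derivatives of affine images
  are exactly zero — identities the test suite asserts exactly rather
  than approximately.
- Features are computed on raw, unnormalized camera counts; no
  per-image rescaling is applied anywhere before measurement.

## Pixel classifier

A scikit-learn random forest (default 100 trees, explicit seed, one
job — fully deterministic) trained on labeled pixels only. Class
imbalance is left as-is, mirroring a sparse-annotation workflow where
the annotator controls the class mix. Interactive incremental
retraining is replaced by whole-batch retraining for reproducibility.
Models serialize to a single file embedding the ordered feature names
and a hash of the feature configuration; prediction refuses stacks
whose names or config hash do not match.

## Segmentation rules

- Threshold tie-break: probability exactly 0.5 is **foreground**
  (inclusive lower bound).
- Connectivity 8 by default (blob-like nuclei); 4 available.
- Size filter: strict inequality — objects with area < 200 px are
  removed; survivors are relabeled 1..K preserving order; the filter is
  idempotent and monotone in the threshold.
- Border-touching nuclei are retained; there is no hole filling, no
  watershed splitting of merged nuclei, and no local background
  correction of γH2AX means. These are deliberate: the pipeline is
  threshold → components → size filter, nothing more.

## Detection quality

Predicted objects are matched one-to-one to ground-truth objects
greedily by descending IoU among pairs with IoU ≥ 0.5, ties broken by
(gt, pred) label order. Precision, recall and F1 are object-level; the
Matthews correlation coefficient is computed at pixel level, where the
true-negative count is well defined (object-level TN is not).
Undefined metrics propagate as NaN; the single conventional exception
is MCC = 0 when a denominator factor vanishes.

## Dose-response model

R(c) = bottom + (top − bottom) / (1 + 10^{h·(log₁₀c − log₁₀IC50)})

fitted by bounded least squares on log₁₀ concentration with **top fixed
at 100%** (the data are control-normalized, so the top asymptote is
pinned by construction) and bottom, Hill slope h and IC50 free. The
Hill slope is variable rather than fixed at 1. Potency is reported as
pIC50 = −log₁₀(molar IC50); internally the fit parameterizes pIC50
directly, so its SE comes straight off the covariance diagonal.
95% CIs use Student-t critical values at n − 3 degrees of freedom on
the covariance-derived standard errors — the usual small-sample choice
for nonlinear regression. Zero-dose wells are used only for
normalization, never in the fit (log of zero is undefined).

Non-convergence is a status, not an exception and never fabricated
parameters. A curve is declared to show no measurable dose effect when
its fitted amplitude (top − bottom) falls below three residual
standard deviations: on flat data the IC50 is unidentifiable and any
value would be fabrication. Weakly identified but real transitions are
*not* rejected; they converge with honestly wide intervals.

Because the top asymptote is pinned at 100% by normalization, an error
in the control mean propagates into every point and biases pIC50 —
the practical reason plates carry several control wells and counts are
pooled over many fields. The simulated designs mirror this (six
control wells' worth of fields behind each normalization).

`compare_pIC50` is a two-sided z-test on the difference of two fitted
pIC50s with SEs from the fit covariances. It is plumbing for flagging
"mixture more potent than either component", not a substitute for a
designed multiple-comparison analysis.

Mixtures at fixed molar ratio are dosed on the axis of the first-listed
(reference, chemotherapy) component; co-component series follow from
the ratios, and one pIC50 is reported per mixture.

## Plate pipeline

Counts are summed over a well's fields; the well percentage is count /
mean(same-plate control counts) × 100. Normalization happens **within
each experiment before pooling**, so pooled percentages are invariant
to any single plate's global intensity gain. Wells whose total nucleus
count falls below a floor (default 50) are flagged `low_count` and
excluded from pooled γH2AX means — saturating doses can leave too few
nuclei for a stable mean; the floor value is a declared default, not a
recovered constant. Every output row carries plate/well/field
provenance and the hash of the full pipeline configuration. A field
that fails is quarantined and logged; the batch continues.

## Synthetic scenes

Each field is rendered as: ellipse nuclei (uniform semi-axes in
3.5–6.5 µm by default, uniform orientation) placed by rejection
sampling with a small separation margin (bounded attempts; error on
failure), DAPI foreground 8000–16000 counts over a 300-count
background, γH2AX at a basal nuclear level (2000 counts) times a gain
(default 4) for the positive subpopulation, γH2AX near zero outside
nuclei. Then a Gaussian PSF (σ = 1 px), Poisson shot noise on the
blurred signal (scaled by a photons-per-count factor), additive
Gaussian read noise, and 16-bit quantization. The default pixel pitch
is 0.3225 µm/px, the value at which 200 px ↔ 20.8 µm².

The generator emulates the statistical structure the pipeline must
handle — sub-resolution blur, mixed noise, density from empty to
confluent, a bright γH2AX subpopulation — but not photorealistic
texture: real chromatin texture, uneven illumination, focus drift,
debris and mitotic figures are absent. Benchmarks on these scenes
therefore establish correctness of the algorithms and an upper bound
on their behavior on clean data; they do not certify performance on
real microscopy.

Dose plates: the expected per-field nucleus count follows a generating
4PL of the reference-compound concentration; per-field counts are
Poisson draws. Defaults — pIC50 5.0, Hill 1.5, top 40 nuclei/field,
bottom 0 — are chosen so a sixfold dilution series starting at 100 µM
samples both plateaus of the curve, which is what makes desk-scale
parameter recovery statistically meaningful. Above a configurable
concentration threshold the γH2AX-positive fraction jumps to a
"damaged" level, emulating damage-marker activation at high dose.

## Problem sizes used in tests and benchmarks

- Segmentation benchmark: 12 fields of 256×256 px, 13 nuclei each
  (~150 total), classifier trained on 4 fields (100 trees, 4000
  labeled pixels per class per field), scored on 8.
- Dose-response recovery: three simulated replicate plates, sixfold
  series of 7 concentrations in duplicate wells, 4 fields/well of
  288×288 px with 2.7–3.8 µm semi-axis nuclei (~192 fields); counts
  pooled after per-plate normalization. Recovery of the generating
  pIC50 is asserted to ±0.1 log units, and a count-level simulation
  grid (pIC50 ∈ {4.5, 5.5, 6.5} × bottom ∈ {0, 20, 50}%, 4 replicates,
  5% noise, 100 seeds) is asserted for |bias| < 0.05 and CI coverage
  in [90%, 99%].

## Known limitations

- Merged (touching) nuclei are not split; the generator's non-overlap
  placement sidesteps this, real confluent cultures would not.
- The classifier is trained per intensity regime; it does not
  normalize inputs, so a model trained at one camera gain should not
  be applied at another (the config-hash guard catches configuration
  drift but not intensity drift).
- Asymptotic CIs can undercover for curves whose bottom plateau is
  unsampled; profile-likelihood intervals are out of scope.
- Object matching uses greedy IoU assignment, which in rare
  constellations differs from optimal (Hungarian) assignment.
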