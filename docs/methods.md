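# Methods

This note records the modelling and numerical choices behind `babykin`,
the assumptions they rest on, and what the synthetic benchmark does and
does not establish.

## Data model

A session is a `frames × markers × 3` array in millimetres at a nominal
100 Hz, with 12 canonical keypoints (Head, Center Pelvis, L/R Hip, L/R
Shoulder, L/R Hand, L/R Knee, L/R Foot). Missing coordinates are NaN
internally and empty fields in CSV; a coordinate is never silently zero.
Stage annotations are half-open frame intervals `[start, end)` with the
fixed label bijection B1→0, B2→1, CR1→2, CR2→3, DC→4 and at most one
segment per stage; half-open intervals make adjacent stages compose
without double counting. Extra markers beyond the canonical 12 pass
through untouched. Plain CSV (wide or long dialect) is the only on-disk
format: fixtures stay diffable and no binary-capture dependency is needed.

## Preprocessing

Cleaning is per coordinate stream (marker × axis), on whole-session
streams before any windowing:

* **Three-sigma rejection.** The mean and population standard deviation
  (ddof 0) are computed once over the observed values, contaminants
  included; values strictly outside mean ± 3σ become NaN. There is
  deliberately no iterative re-estimation: the threshold is defined by
  the sequence as recorded. A consequence, covered by a test, is masking —
  one enormous spike can inflate σ enough to shield a moderate one. With
  contamination ≤ 1 % at 6σ this removes ≥ 95 % of injected spikes.
* **Cubic spline gap filling.** A natural cubic spline through the
  observed samples fills interior gaps; observed samples are preserved
  bit-exactly. Leading/trailing gaps are filled by nearest-value
  extension, because cubic extrapolation diverges. At least 4 observed
  values are required; fewer is an error carrying the marker/axis
  identity. `max_gap_frames` (default unlimited) turns very long interior
  gaps into errors instead of silently bridging them.

Order matters and is asserted: rejection runs first so its NaNs feed the
spline; interpolating through a spike before rejecting it would bias the
fill.

## Body frame and HJD features

The per-frame body frame is anchored at the Center Pelvis: lateral axis
from left to right hip (dedicated pelvis markers are used when present),
longitudinal axis pelvis→head orthogonalised against the lateral,
normal axis the right-handed cross product. Coincident pelvis markers or
a head collinear with the lateral axis raise a geometry error. Body
coordinates of a joint are the projections of its pelvis-rooted
displacement on (lateral, longitudinal, normal); this is exactly
invariant to rigid motion of the capture volume, and the invariance is
tested bit-for-bit.

Displacement *direction* is quantised on an equal-angle spherical grid:
azimuth α = atan2(y, x) over [−π, π) in 8 arcs, elevation
θ = arcsin(z/‖v‖) over [−π/2, π/2] in 8 arcs, 64 bins, index =
elevation_bin × 8 + azimuth_bin. Radius is ignored — the descriptor is
about where a joint sits relative to the body, not how far. Intervals are
half-open on the upper edge except the top elevation bin, which is
closed, so every direction maps to exactly one bin; α = π wraps onto the
−π edge. The zero vector has no direction; it maps to the bin containing
(α=0, θ=0) and increments a warning counter rather than raising, since a
joint exactly at the root is degenerate but harmless.

An HJD is the per-bin frame count of one joint over one window; counts
sum to the window length by construction. Fusion concatenates per-joint
histograms (1D) or stacks them as rows (2D); the 2D matrix equals the
row-major reshape of the 1D vector, which is asserted for all inputs.
Raw counts are the default feature scale (a fixed 500-frame window makes
counts and proportions equivalent up to scale); a `proportion` flag
exists for variable-width use.

Windows are 500 frames with 100 frames of overlap (step 400), generated
independently inside each stage segment so no sample straddles a
boundary; segments shorter than 500 frames contribute nothing. The count
per segment is `floor((L − 500)/400) + 1`.

## Classifiers

kNN (Euclidean, k ∈ {1,3,5,7} searchable) and LDA run through
scikit-learn on the 1D fused vectors. The five neural families are
implemented in NumPy inside the package (`babykin._nn`) with manual
backpropagation and Adam; the models are small enough that a tensor
framework would add nothing but a dependency.

* **FCNet**: hidden layers (240, 60, 15), ReLU, dropout 0.5 after each,
  softmax over 5 classes, cross-entropy. The first-layer grid also offers
  150 and 100 units, and dropout 0.7/0.9.
* **1D conv**: two stride-1 'same' convolutions (16 then 32 filters,
  kernel 3), each followed by max pooling (kernel 3, stride 3), dropout,
  a 64-unit dense layer, softmax.
* **2D conv**: two 'same' convolutions (4 then 8 filters, kernel 3,
  stride 1), each followed by max pooling (kernel 3, stride 2), dropout,
  dense, softmax. On short inputs the pooling kernel is clamped to the
  available height so two-row (Feet) matrices remain usable.
* **Capsule networks** keep the convolutional front-end settings of their
  conv counterparts (kernel 3; 32 filters in 1D, 16 in 2D) but drop
  pooling entirely. The feature map is grouped into 8-dimensional primary
  capsules (spatial stride 2 when grouping, exposed in
  `CapsuleLayerSpec`), squashed, linearly mapped to per-class predictions
  û, and routed by agreement over 3 iterations into five 16-dimensional
  class capsules. Scores are class-capsule norms; training uses the
  margin loss with m⁺ = 0.9, m⁻ = 0.1, λ = 0.5 and no reconstruction
  decoder.

Routing initialises all logits at zero, so one iteration gives uniform
couplings; per primary capsule the couplings sum to 1 at every iteration
(tested to 1e-6 over random tensors). In the backward pass the coupling
coefficients are treated as constants of the forward pass — the gradient
flows through the weighted sums and the squash only. With one iteration
this is the exact gradient (verified against finite differences); with
3 iterations it is the standard inexpensive approximation. squash maps
‖s‖ = 1 to ‖v‖ = 0.5 exactly and is strictly monotone with norms in
[0, 1).

Training defaults: 50 epochs (20 in the headline benchmark), batch 32,
learning rate 1e-3, features standardised per element with training-set
statistics. Weight initialisation, batch order and dropout masks all
derive from the config seed, so identical configs produce identical
models. Prediction ties break toward the lowest class index. Families
consuming 2D matrices (`conv2d`, `caps2d`) reject 1D inputs and vice
versa.

Hyperparameter search is an exhaustive grid evaluated by inner
cross-validation that holds out whole subjects of the *training* set, so
evaluation subjects never influence the choice; ties break toward the
model with fewer trainable parameters, then grid order.

## Evaluation

Leave-one-subject-out: one fold per subject, fitted on the other
subjects' windows. The headline number is the unweighted mean of
per-fold window accuracies (subjects contribute equally regardless of
window count); confusion matrices pool all folds. Class imbalance from
unequal stage lengths is left as-is. Temporal traces order one subject's
predictions by window start and smooth with a centred moving average
(default span 5 windows; edges use the available shorter span).

Displacement rate is computed on raw lab-frame positions — it is an
absolute activity measure — as the summed frame-to-frame path length per
stage divided by the elapsed time (n − 1 inter-frame intervals),
converted to metres per minute; cohort summaries report the mean and the
across-subject standard error (n − 1 denominator).

## Synthetic cohort

The generator is phenomenological, not biomechanical: each marker is a
shared slow pelvis drift plus an anatomical rest offset plus a per-stage
band-limited oscillation (2–4 seeded random-phase sinusoids, per-axis
variance amp² × weight ⁄ 2 regardless of component count) plus Gaussian
jitter. Stage structure is imposed through the dynamics defaults:

* B2 damps all limb amplitudes to 0.45× (quiet watching);
* CR1/CR2 concentrate 75 %/70 % of the trigger foot's oscillation
  variance on the vertical axis and scale its amplitude 1.25×/1.35×
  (kicking the tether);
* DC scales the trigger foot 1.6× with dispersed axes (post-coupling
  activity burst).

These defaults put the feet movement-rate profile in the order
B2 < B1 ≈ CR1 < CR2 < DC at single-digit-to-low-teens m/min, and they
make the five stages learnable but not trivially separable (LOSO
accuracies sit around 60–67 %, far from both chance and ceiling).
Stage durations default to 2 min for B1/B2/DC and 1 min for CR1/CR2 at
100 Hz (48 000 frames, 115 windows per subject; irregular lengths are
supported). Trigger side alternates left, right, left, … across
subjects; between-subject jitter multiplies amplitudes and frequencies
by independent factors in 1 ± 0.15. Sub-seeds are derived counter-style
via `SeedSequence(entropy=seed, spawn_key=(subject, purpose))`, so adding
subjects never reshuffles existing ones.

What the generator does **not** emulate: joint limits and limb rigidity,
phase continuity across stage boundaries, marker soft-tissue artefacts
beyond white jitter, mobile-marker trajectories, and any within-stage
behavioural drift. Passing the benchmark therefore shows the pipeline
recovers stage structure of the assumed kind — amplitude, orientation
and dispersion contrasts localised in the trigger foot — not that it
would reach any particular accuracy on real infant recordings.

Missingness is injected as whole-marker occlusion bursts (Poisson count
per 1000 frames, uniform burst length) and outliers as isolated ±kσ
spikes per coordinate stream with a ground-truth mask, matching the
per-stream filter they exercise.

## Known limitations

* The routing backward pass is approximate beyond one iteration (see
  above); training still converges reliably on these problem sizes.
* The three-sigma filter's single-pass statistics are susceptible to
  masking under heavy contamination; that is a property of the method,
  not a defect of the implementation.
* Spline filling of very long gaps is oscillation-prone; `max_gap_frames`
  exists but defaults to unlimited.
* The benchmark uses reduced epochs (20) and the default cohort size;
  accuracies quoted in the README are specific to those problem sizes.
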