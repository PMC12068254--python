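# Methods

## Problem and scope

Cerebral aneurysm walls are not uniform: thin-walled (TW) regions are
rupture-prone, while hyperplastic-remodeling (HR) regions are thickened and
complicate surgery. Time-resolved CT angiography (4D-CTA) yields a 3D
trajectory for every observed wall point over one cardiac cycle, and the two
wall types move differently — TW regions are light and show fast, large
excursions; HR regions are stiff and move smoothly. `wallmotion` implements
a point-level classifier of wall status from these trajectories, together
with the full evaluation and diagnostic machinery around it. Because no
clinical 4D-CTA cohort is publicly available, the package ships a synthetic
cohort generator that emulates the relevant structure of such data and makes
every stage testable end to end.

## Data model

A trajectory is a T x 3 coordinate series (mm) sampled at 100 Hz for 1 s
(T = 100), tagged with a patient id and a label: 0 = TW, 1 = HR, -1 =
unlabeled. Labels originate from intraoperatively colored point clouds;
`nearest_point_label_transfer` attaches each primary 4D-CTA point the label
of its Euclidean-nearest colored point (ties to the lowest colored index —
deterministic and documentable). Which color (blue/red) denotes which wall
class is an annotation convention, so the color mapping is a mandatory
configuration field with no default; a channel must dominate both others by
a margin (default 50/255) to count as colored at all.

## Kinematic features

Each trajectory is reduced to a 5-channel feature series:

* **speed** `‖p_{t+1} − p_t‖ · rate` (mm/s, forward difference),
* **acceleration** `‖p_{t+1} − 2 p_t + p_{t−1}‖ · rate²` (mm/s², central
  second difference),
* **smoothness-of-motion angles**: the vertex angle at `p_t` between the
  segments to `p_{t−1}` and `p_{t+1}`, after projection onto the XY, XZ and
  YZ planes (radians).

Channels are aligned to length L = T − 2 by dropping the first speed sample.
Two conventions were genuinely open and are fixed here: angles are *vertex*
angles (π = straight, locally smooth motion), and a projected segment
shorter than 1e-9 mm yields π so that motionless points read as maximally
smooth. Optional cubic-spline upsampling by an integer factor is provided
(original samples are reproduced exactly); feature extraction defaults to
factor 1 so tests stay transparent, factor 5 is the suggested value when
higher temporal resolution is wanted. Speed and acceleration are invariant
to rigid motions of the frame; the planar angles are not (they are
projection-dependent by construction), and the test suite checks both facts.
Per-channel z-score normalization is computed from training data only and
stored with the trained model.

## Network

The scoring model is a 1-D CNN-LSTM regression network with additive
(Bahdanau-style) temporal attention: convolution blocks (ReLU, stride 1,
same padding) capture short-term dynamics, an LSTM over the conv features
captures long-term trends, and one attention layer pools each conv block's
output while another pools the LSTM sequence output. The pooled context
vectors are concatenated into the `dense_1` embedding layer (ReLU) — the
feature space the auxiliary loss terms act on — and a sigmoid unit emits a
score in [0, 1] (0 = TW, 1 = HR), thresholded at 0.5 (a score of exactly
0.5 is called TW; a probability-zero event fixed for determinism). All
weights are Glorot-uniform initialized, biases zero. `attention_map`
averages all attention layers' weights per time step (they share the
sequence length), giving a per-time-step importance profile for trajectory
coloring.

Convolutions use *edge-replicating* same padding rather than zero padding:
zero padding would inject spurious zero-motion samples at the window
boundary and break time-shift symmetry at the sequence edges (a constant
input would not receive uniform attention).

Reference layer sizes are 2 conv blocks of 64 filters (kernel 3), LSTM 64,
attention 32, embedding 32; every size is configurable. The experiments run
by the tests and the acceptance script use a compact configuration
(16 filters, LSTM 24, attention 16, embedding 16) chosen so the full
leave-one-patient-out protocol runs comfortably on a single CPU; on the
synthetic cohorts the compact model is not the accuracy bottleneck.

The network and its training loop run on a small in-repo reverse-mode
autodiff engine over numpy (`wallmotion.autodiff`). Its gradients are
verified against central finite differences, both per primitive and end to
end through the composite loss (1e-4 relative tolerance; probes are drawn
away from the non-differentiable points of ReLU/abs/min).

## Composite loss

With labels `y_i`, scores `ŷ_i`, and dense_1 embeddings:

```
E = w_err · err(y, ŷ) + w_p · L_p − w_m · L_m
```

* `err` is the mean absolute error by default; mean squared error is
  selectable (the two appear in different places in the method's own
  description — both are provided, neither silently privileged).
* `L_p` (patient invariance): mean Euclidean embedding distance over
  cross-patient same-label pairs within the batch; minimizing it makes
  same-class movement features agree across patients.
* `L_m` (unlabeled separation): mean embedding distance between labeled and
  unlabeled batch points, *subtracted*, pushing ambiguous unlabeled points
  away from the labeled classes. Subtracting an unbounded mean distance
  admits divergence, so each pair distance is capped at a margin m (default
  10); m = ∞ recovers the literal unbounded form, and the
  margin-monotonicity property is tested.

Three stabilization choices shape the default configuration; all were
adopted after observing and diagnosing training collapses (constant
predictors, F1 ≈ 33–50 on individual cross-validation folds), and each is
individually configurable:

1. **Normalized embedding space.** By default L_p and L_m are computed on
   row-wise L2-normalized embeddings. On raw embeddings the subtracted L_m
   is maximized by simply inflating embedding norms; the growing
   activations saturate the sigmoid output and the error term's gradient
   vanishes. On the unit sphere every pair distance is bounded by 2, so
   the margin cap becomes a safety net rather than the only brake
   (`normalize_embeddings=False` restores raw-space distances, and the
   hand-arithmetic tests exercise that mode).
2. **Small auxiliary weights (default w_p = w_m = 0.1).** L_p is pure
   attraction — the loss as described contains no repulsion between
   classes — so when its weight rivals the error term's, collapsing *all*
   embeddings to a single point is a strong local minimum (L_p = 0) that
   training repeatedly found. With weights ≈ 0.1 the error term remains
   the dominant objective and the auxiliary terms act as regularizers.
   Nothing in the source method fixes the balance; `sweep_loss_weights`
   reruns the cross-validation over a weight grid for sensitivity
   analysis.
3. **Warm-up (1 epoch).** Auxiliary weights ramp linearly from 0 over the
   first epoch so they regularize an embedding the error signal has
   already begun to shape rather than distorting a random one.

Zero-weight terms are skipped entirely, so the ablation identities are
bitwise: weights (1,0,0) give exactly the plain error loss. Pairs are
enumerated within-batch only; each batch is sampled to contain labeled
points from at least two patients (when available) plus a configurable
unlabeled fraction (default 25% of the batch size; unlabeled points are
not sampled at all when the L_m weight is zero).

Training uses Adam (lr 1e-3, β₁ 0.9, β₂ 0.999) with an early-stopping
validation split (10% of training labeled points, capped at 128 for cheap
per-epoch evaluation, patience 10); the weights with the best validation
error are restored, which also protects the final model if late training
degrades.

## Evaluation protocol

Leave-one-patient-out cross-validation: one fold per patient, the model
trained on all other patients' points (labeled and unlabeled),
normalization statistics from training patients only, and every labeled
point of the held-out patient scored exactly once. Five variants share
folds and seeds for paired comparison: `proposed`, `baseline` (plain LSTM +
two dense layers, error term only), `only-mae`, `no-patient`,
`no-unlabeled`. Metrics are accuracy and support-weighted
precision/recall/F1 in percent (2 decimals); support weighting is what pins
a constant single-class predictor on balanced labels to exactly
50.00 / 25.00 / 50.00 / 33.33, and it makes accuracy coincide with weighted
recall. Cohort metrics are unweighted means over patients. Taylor-diagram
statistics (population SDs, Pearson r, centered RMSE; law-of-cosines
identity tested to 1e-9) summarize score-vs-label correspondence. Patients
with accuracy below 80% under a reference variant (default `only-mae`) form
the "failed" stratum.

## Heterogeneity diagnostics

Per patient: two-sample KS statistic per feature channel between pooled TW
and HR values (asymptotic p-values — per-patient sample sizes are in the
hundreds); DTW distance (classic DP, absolute-difference cost, no window,
no normalization) between the patient's mean TW and mean HR speed series;
1-D Wasserstein distance between pooled TW and HR speed values. Group
comparison between failed and succeeded patients: a second KS test on the
per-patient KS statistics and classic mean-centered Levene's test on the
groups' pooled speed values. Which series feed DTW/Wasserstein is not fixed
by the source description; the per-patient aggregates above are this
package's fixed defaults. KS and Levene are delegated to scipy and verified
in tests against a brute-force ECDF-sup oracle and a type-I-error
simulation; DTW is implemented here (no suitable library is available in
the environment) and verified against exhaustive path enumeration.

## Synthetic cohort generator

The generator emulates quasi-periodic cardiac-driven wall motion. Each
trajectory is an anchor point (uniform in a 10 mm cube) plus `n_harmonics`
(default 3) sinusoids of a cardiac fundamental (default 1 Hz) along random
unit directions, amplitudes decaying as 1/k, plus isotropic Gaussian jitter
(default sd 0.05 mm), sampled at 100 Hz for 1 s. The class contrast is
governed by one separability dial δ:

* effective TW amplitude gain `1 + δ(g_tw − 1)` (default g_tw = 2, base
  amplitude 0.5 mm): TW points move more, so they differ in speed and
  acceleration;
* effective HR jitter divisor `1 + δ(g_hr − 1)` (default g_hr = 3): HR
  jitter is suppressed, so the classes differ in angle variability
  (smoothness);
* δ = 0 makes the two classes identically distributed (verified by a null
  calibration test: the TW-vs-HR KS test rejects at ≈5%);
* "hard" patients — emulating patients on whom an error-only classifier
  fails — have δ multiplied by 0.1, so their class distributions nearly
  coincide.

Unlabeled points draw an interpolation coefficient uniformly between the
TW and HR parameter sets, mirroring their role as ambiguous wall regions.
Patient heterogeneity enters through log-normal per-patient amplitude and
frequency multipliers (default sd 0.15 of log; 0.3–0.4 is used as the
"strongly heterogeneous" setting). Per-patient random streams are derived
from (master seed, patient index), so cohorts are bit-stable at the
serialized-CSV level and unchanged by adding patients.

What the generator does **not** emulate: wall biomechanics (no
finite-element or fluid coupling), imaging noise and voxel-tracking error
structure, spatial correlation between neighbouring wall points, and class
imbalance across the wall. Passing tests therefore demonstrate that the
pipeline recovers class structure of the kind described — not clinical
performance on real 4D-CTA data.

## Experiment sizes

All experiment scales are the package's own choices for a single-CPU
workflow:

* separable-cohort recovery: 8 patients × (200 TW + 200 HR + 100
  unlabeled), δ = 2, compact model, 8 epochs × 20 Adam steps, batch 24 —
  the proposed variant is expected to reach ≥ 90% mean LOPO accuracy;
* heterogeneity comparison: 8 patients × (80 + 80 + 40), δ = 1, patient
  scale sd 0.4, 25% hard patients, 8 epochs, 5 seeds — the proposed
  variant's mean F1 is compared with error-only training per seed. In this
  regime the composite loss is consistently *more stable* on hard patients
  (their per-fold F1 varies far less across seeds), while the per-seed mean
  comparison is close: hard patients are generated with δ shrunk to a tenth,
  i.e. their classes overlap almost irreducibly, so error-only training is
  already near the attainable ceiling and single-seed wins hinge on easy-fold
  noise;
* embedding contraction: 4 patients × (50 + 50 + 20), patient-invariance
  weight 10 vs 0 at a fixed seed — the weighted run must end with strictly
  smaller mean cross-patient same-class embedding distance.

## Numerical choices and edge cases

* Pairwise embedding distances add 1e-12 under the square root to keep
  gradients finite at coincident embeddings.
* Softmax subtracts the (detached) rowwise max for stability.
* Degenerate projected segments in the angle computation fall back to π.
* Trajectory CSV is written with 12 significant digits; round trips
  preserve coordinates to text precision. PLY clouds are ASCII with uchar
  RGB (float32 vertex precision).
* The nearest-point transfer evaluates the distance matrix in blocks with
  `argmin`, so the lowest-index tie rule is exact rather than dependent on
  a spatial index's internal ordering.
* Training determinism: given a seed, runs reproduce bit-for-bit on one
  platform; across BLAS implementations results may differ in the last few
  ulps.

## Known limitations

* The true layer sizes and attention placement of the reference
  architecture are not recoverable; the defaults here are the smallest
  standard stack matching its vocabulary, and everything is configurable.
* The unbounded form of the unlabeled-separation term is available
  (margin = ∞) but diverges by design if used for long training runs.
* Reported clinical-cohort numbers cannot be reproduced without the
  non-public clinical data; the synthetic cohorts validate mechanism, not
  clinical accuracy.
* DTW is O(nm) Python/numpy; it is meant for per-patient aggregate series,
  not for millions of pairs.
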