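# Methods

## The pretext task

The model assumes that each 3D timepoint of a resting-state fMRI scan
carries a persistent, subject-specific spatial pattern on top of temporal
noise — enough to identify who was scanned from a single volume. The
encoder makes that assumption operational: a stack of 3D convolutions is
trained to classify the subject from one timepoint, with softmax
cross-entropy against the one-hot subject index. Everything downstream
(identity features, precision@k, diagnosis/age probes) treats the trained
dense layer as a fixed feature extractor.

The three-way cohort split mirrors how the probes are meant to be read:
train1 subjects define the pretext task (and the meaning of each dense
output unit), train2 subjects fit the linear probes, test subjects are
touched only for the final metric. Identity features of train2/test
subjects live in the train1-defined feature space; each coordinate is
roughly "similarity to training subject j", so the space is meaningful for
subjects the encoder never saw.

## Architecture and its fixed conventions

The reference configuration takes an (80, 96, 80) volume through four
blocks of [conv(c→c), conv(c→2c), avg-pool], kernel 3, stride 1, pooling
2×2×2; channels start at 8 and double before each pooling, leaving 128
before the dense layer; two tail convolutions at constant width precede the
dense map onto the training subjects. Points the architecture description
leaves open are fixed as follows, each exposed as a config switch where the
alternative is defensible:

- **Padding.** Symmetric zero padding of 1 for k = 3, s = 1, so only
  pooling changes spatial size. This is the only convention under which
  (80, 96, 80) survives four halvings to (5, 6, 5) with the stated channel
  plan; input axes must be divisible by 2⁴ and the build errors otherwise,
  naming the axis.
- **Doubling position.** The second convolution of each block doubles the
  channels (`double_at_entry` flips this).
- **Dense input.** The final feature map is flattened (`dense_input =
  "global_pool"` selects global average pooling instead). Under flatten the
  reference parameter count computes to 3,340,585; the build reports the
  computed count rather than asserting any round number.
- **Activation.** ReLU after every convolution — the field default; no
  batch norm, dropout or augmentation anywhere.
- **Initialization.** Fan-in-scaled ("He") normal init, seeded.
- **Batch sampling.** Uniform with replacement over all (subject,
  timepoint) pairs, seeded; no per-subject balancing.

Training runs Adam under a piecewise-constant learning-rate schedule
(reference: 10⁻⁴ for 17,000 iterations, then 10⁻⁵ for 110,000, batch 32).
A non-finite loss aborts with a diagnostic instead of training on. The log
records (iteration, batch loss, batch accuracy) every `eval_every`
iterations; `training_accuracy` scores all timepoints, with argmax ties
broken toward the lowest subject index.

## The NumPy network

The package carries no deep-learning framework: `brainid.nn` implements 3D
convolution, average pooling, ReLU, flatten/global-pool, dense, softmax
cross-entropy and Adam directly in NumPy, channels-last. A k³ convolution
is evaluated as k³ shifted-slice GEMMs — for each kernel offset, a slice of
the zero-padded input is flattened and multiplied against that offset's
(C_in, C_out) weight slab — which keeps the hot path inside BLAS without
the k³-fold im2col memory blowup; the input gradient reuses the same
machinery with flipped offsets. All gradients are exact and are tested
against central finite differences in float64; forward convolution is
tested against `scipy.ndimage.correlate`. Weights are float32; Adam
moments are float64.

## Feature construction and precision@k

The dense-layer (pre-softmax) output is the *classification* feature; the
*classification+* variant subtracts each vector's element mean, a
projection onto the hyperplane orthogonal to the all-ones direction that
leaves the softmax output unchanged (asserted to 1e-12). Identity features
are plain arithmetic means over a subject's vectors; mean-subtraction and
temporal averaging commute, which the tests exercise as a linearity check.

precision@k ranks **all** pooled feature vectors (every subject, every
timepoint) by Euclidean distance to one identity feature and reports the
fraction of the k nearest that belong to that subject, then averages over
subjects (the per-identity-then-mean reading). Conventions:

- distances are taken in the raw feature space, with no standardization;
- the identity feature is a centroid, not an observation, and is never a
  member of the ranked pool;
- ties are broken stably by (distance, subject_id, timepoint), so
  degenerate inputs (identical vectors) stay deterministic;
- k defaults to the per-subject timepoint count (150 in the reference
  data, 40 in the desk configuration) but is a free parameter.

An O(N²) exhaustive-sort oracle validates the implementation on every
random instance up to 200 vectors.

## Baselines

ROI pooling averages voxels within each atlas label per timepoint; ROIs
with no voxels on the (possibly cropped) grid are excluded with a warning
rather than zero-filled, so correlation matrices never see constant
columns. PCA is fit once on the train1 timepoints (observations) over
cropped voxels (variables), mean-centered, and applied unchanged to all
splits — mirroring how the encoder learns from train1 only; the exact
LAPACK solver is used up to 100 components and a randomized solver beyond
(loadings then orthonormal to solver tolerance, ~1e-6). Functional
connectivity is the R×R Pearson matrix of the ROI time series over the full
scan (static, no windowing); its vectorized upper triangle is the subject's
downstream feature, entering the probes directly as that subject's identity
feature since it is already one vector per subject. All baselines flow
through the same FeatureSet/identity/precision code path as the encoder.

## Downstream probes and statistics

Diagnosis: L2-penalized logistic regression (deterministic lbfgs solver) on
train2 identity features; test predictions by the sign of the linear score,
with an exact 0 assigned to the control class. With D features and ~18
train2 subjects the problem is underdetermined, so the fixed default
penalty (C = 1) is part of the method; it is exposed in config. Accuracy is
tested with the exact one-sided binomial sign test against chance ½ —
one-sided because the question is whether accuracy is *above* chance. Age:
ridge regression (α = 1 by default, same rationale), summarized by Pearson
r with the two-sided p from t = r√(n−2)/√(1−r²); two-sided is the
conservative default. No cross-validation, no multiple-testing correction
across methods: the design is a single fixed split with raw per-method p
values.

## The synthetic cohort generator

`simulate_scan` draws voxel values

    v(x, t) = B(x) + a_sig·S_i(x) + a_grp·G(x)·1[patient_i]
            + a_age·A(x)·z(age_i) + ε(x, t)

with B a smooth ellipsoidal baseline (no anatomy), S_i a per-subject
Gaussian random field smoothed to unit variance (σ = 1.5 voxels by
default), G and A fixed smooth effect maps, z the cohort-standardized age,
and ε i.i.d. N(0, noise_sd²) per voxel and timepoint. The signature is
constant over time by design: that is precisely what makes a *single*
timepoint sufficient for identification, the premise the pretext task
needs. Signatures are keyed by (subject_id, seed), so regenerating a
subject — or simulating a second session via `rep` — reproduces the same
signature with fresh noise, and identical seeds give bit-identical
datasets. `signature_amplitude / noise_sd` is the identifiability knob: 0
puts a nearest-mean classifier at chance, large values drive it to 100%.

Default study conditions (the desk configuration): grid 24×28×24 at 3 mm,
40 timepoints per subject, signature amplitude 5 (i.e. 5× the unit noise
SD — a strong identity signal, so that success or failure reflects the
machinery rather than borderline SNR), group amplitude 3 (a group effect
somewhat weaker than identity, as in real data), age amplitude 1, cohort
24 patients + 24 controls split (6,6)/(9,9)/(9,9) into
train1/train2/test, ~70% male. The block atlas partitions the ellipsoid
into 3×3×3 rectangular cells (≈27 ROIs).

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation, physiological noise, scanner drift, motion, anatomy, and
any realistic connectivity structure — the group effect is an additive
spatial shift, which ROI correlations are invariant to, so the
connectivity baseline is at chance on synthetic data by construction.
Passing tests therefore demonstrate that the machinery recovers structure
that is present, not that real-data effect sizes are attainable; published
real-data numbers (e.g. precision@150 of 81.5%, diagnosis accuracy 77.8%)
are properties of a 147-subject clinical dataset and GPU-scale training
and are outside what the synthetic conditions can or should reproduce.

## Stratified splitting

Exact per-split (patients, controls) counts are required; age and sex are
balanced by dealing subjects within (group × sex × age-tertile) cells
across splits with probability proportional to each split's remaining
quota. Counts come out exact; age/sex balance holds in expectation.
Subjects are first sorted canonically by ID, so the assignment is
deterministic given the seed and invariant to input row order.

## Problem sizes, determinism, numerics

Desk-scale runs use a 2-block encoder with base 4 channels (~94k
parameters), batch 8, and 350 Adam iterations (10⁻³ for 250, 10⁻⁴ for
100) — on the strong-signature conditions the loss is below 10⁻⁵ well
before the schedule ends, and the full pipeline finishes in ~2 minutes on
one CPU. The Type-I-error study runs 100 null replicates on an 8×8×8 grid
with ROI identity features and an 18-subject test split, whose discrete
exact-binomial rejection level at α = 0.05 is 0.048.

One global seed derives per-stage sub-seeds as sha256("seed:stage") mod
2³¹, so stages can be rerun independently; per-subject signature seeds are
derived the same way from (cohort seed, subject id). The pipeline writes a
manifest of every artifact with its SHA-256 and resumes after the last
stage whose artifacts all verify. Degenerate inputs are rejected loudly
rather than patched: non-4D or non-finite NIfTI data, atlases with no
in-grid ROIs, constant ROI series in connectivity, single-class probe
training sets, constant vectors in the Pearson test.

## Known limitations

- The synthetic group effect is linear-additive; nonlinear or
  connectivity-borne group differences are not modeled, so the relative
  ordering of methods on synthetic data does not predict their ordering on
  real cohorts.
- The NumPy training loop is single-threaded BLAS-bound; the reference
  127k-iteration, 105-subject configuration is out of its intended range.
- `stratified_split` balances continuous age only in expectation (tertile
  cells), not by optimal matching.
- t-SNE plotting is a thin wrapper for qualitative inspection and is
  deliberately untested numerically.
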