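# Methods

`pulsepair` implements a self-supervised feature-learning pipeline for raw
two-channel pulse-oximeter (PPG) signals and exercises it end to end on a
bundled synthetic paediatric cohort.  This note records the models, the
tunable parameters that matter, the numerical conventions, and what the
synthetic experiments do and do not demonstrate.

## The pipeline

Recordings are ~60 s two-channel (red, infrared) waveforms at 80 Hz.  Each
channel is normalized with the mean and standard deviation pooled over the
labelled reference cohort, and recordings are cut into 10 s windows (800
samples) with 2 s overlap; a 60 s recording yields 7 segments.

**Pretext task.**  A 1-D convolutional encoder is trained so that two
segments from the same pseudo-patient embed closer, by dot product, than
segments from different pseudo-patients.  A mini-batch holds N pairs; for
query embedding q with positive partner k₊ among candidates k_i (the
positive plus the 2(N−1) in-batch negatives), the loss is noise-contrastive
estimation with temperature τ:

    l = −log [ exp(q·k₊/τ) / Σ_i exp(q·k_i/τ) ]

averaged over all 2N queries (both members of each pair serve as queries).
Chance level is ln(2N−1); top-1 retrieval chance is 1/(2N−1).  Admission and
discharge recordings of one child count as *different* pseudo-patients: a
hospital stay separates them, so the underlying physiology differs.
Training-time augmentations are additive Gaussian noise (SD log-uniform over
1e-5…1e-2 — log-uniform because the stated range spans three decades and
should be covered evenly) and window slicing with permutation (the segment
is split into contiguous blocks, the first n−1 of length ⌊L/n⌋ and the last
absorbing the remainder, then reordered; both channels move together).
Slicing runs before noise so block boundaries are not noise-free seams.
Time stretching is deliberately excluded: it would alter the heart rate the
representation is supposed to carry.

**Encoder.**  A ResNet50-like trunk of 1-D bottleneck stages (depth layout
3-4-6-3), two input channels, max-pooling after the stem and after every
stage, global average pooling, then two fully connected layers of 32 units.
The second head layer is what the contrastive loss sees ("projection"); it
is discarded after pretraining, and the 32-d output of the first head layer
is the representation used downstream.  The `full` preset's free dimensions
(stage widths 40/80/160/268, kernel 13, stem width 36 / kernel 15) were
fixed by an exhaustive search (`scripts/calibrate_full_preset.py`) under one
hard constraint: the single-output classifier variant must count exactly
9,218,369 trainable parameters.  A `small` preset (~64k parameters, basic
residual blocks, widths 8/16/32/64) is the desk-scale default for training
runs and tests.  Head output layers are initialized with a 0.1 gain so
initial similarities and logits start near zero and training starts at the
chance-level loss; without this, unnormalized dot products make early
optimization erratic.

The network engine (1-D convolution, batch normalization, pooling, residual
blocks, Adam, explicit backpropagation) is implemented in numpy in
`pulsepair.nn`; gradients are verified against finite differences in the
test suite.  Float64 is used throughout for bit-reproducible single-threaded
runs.

**Downstream probes.**  A patient's feature vector is the arithmetic mean of
their segments' representation-stage embeddings, optionally concatenated
with eight clinical covariates (weight, MUAC, temperature, measured heart
rate, measured SpO2, restlessness, ability to drink, difficulty breathing).
Probes are Bayesian regressions with a horseshoe prior,

    β_m = z_m·λ_m·τ_g,  z_m ~ N(0,1),  λ_m ~ C⁺(1),  τ_g ~ C⁺(τ₀),  α ~ N(0,10²),

logistic for hospitalization and Gaussian (with a C⁺(1) noise-scale prior)
for heart rate, respiratory rate and SpO2.  Features are standardized with
training-split statistics — horseshoe scales are only exchangeable for
comparably scaled features — and linear targets are internally standardized
for sampling, with coefficients and predictions mapped back.  Inference is
Hamiltonian Monte Carlo with analytic gradients in the unconstrained space
(log-scales with Jacobian terms), dual-averaging step-size adaptation to a
0.85 target acceptance rate, a diagonal mass matrix estimated from the first
warmup half, jittered leapfrog path length (0.6 time units, ≤256 steps), and
500 warmup / 500 kept draws by default.  Divergent (non-finite) trajectories
are rejected and their rate reported in the fit diagnostics.  Classification
reports AUC by the rank (Mann–Whitney) formulation with ties counted ½, plus
sensitivity/specificity/precision at the threshold maximizing Youden's J on
non-test scores (the smallest maximizer on observed-score candidates, with
prediction = score ≥ threshold); regression reports RMSE and R² about the
truth's mean.

**End-to-end classifier.**  The encoder with its last 32-unit layer replaced
by a single output, initialized randomly or by copying the pretrained trunk
and first head layer bit-for-bit (the new output layer is always fresh).
Training is segment level with binary cross-entropy on label-smoothed
targets y′ = y(1−ε) + ε/2 (ε default 0.1); the minority class is oversampled
at the patient level *before* segment expansion so a replicated child
contributes all segments again, preserving within-patient correlation.
Evaluation is patient level: mean sigmoid output over the child's segments.
All layers remain trainable during fine-tuning.

## The synthetic cohort

The generator emulates the structure the pipeline assumes, not paediatric
hemodynamics.  A latent severity s ~ N(0,1) drives heart rate
(130 + 22s ± 6 bpm), respiratory rate (36 + 11s ± 3 breaths/min) and SpO2
(97 − 3s ± 0.8 %), clipped to [60,220]/[15,90]/[70,100]; hospitalization is
Bernoulli with logit a + 2s, the intercept solved by quadrature so the
expected prevalence hits the 12% target; continuous clinical covariates are
linear in severity with Gaussian noise and binary ones Bernoulli with
logistic-in-severity probabilities, so clinical features carry genuine
predictive signal.  Each beat of the waveform is a two-lobe pulse (systolic
Gaussian at 0.30 of the beat interval, width 0.10; dicrotic bump of relative
amplitude 0.35 at 0.62, width 0.14), with three respiratory modulations at
the breathing frequency: beat-interval modulation (4%), amplitude modulation
(12%) and baseline wander (0.05 signal units), each with a per-recording
random phase.  Red and infrared channels share the cardiac waveform; their
AC/DC amplitudes are set so the ratio-of-ratios R satisfies the common
empirical calibration SpO2 = 110 − 25R, making SpO2 recoverable from the
generated channels by construction.  Additive Gaussian sensor noise
(default SD 0.02 against an infrared AC amplitude of 0.30) and optional
Poisson-timed 0.5–2 s high-amplitude ramp artifacts complete the model.
Unlabelled-cohort mode emits two admission and two discharge recordings per
child, the discharge copy with severity shrunk by 0.7 toward zero — the
recovered child the pretext task must treat as a different patient.

What it does **not** emulate: device transfer functions, pathological pulse
morphologies, non-stationary vitals within a recording, missing data, or
the weak, confounded link between waveform and outcome in real triage data.
Consequences are discussed under Limitations.

## Numerical conventions

- Normalization SD uses the population convention (divide by n), floored at
  1e-8 with a warning for constant channels; normalization is applied to
  full recordings before windowing (a global affine map commutes with
  windowing, so the order is observationally irrelevant but fixed).
- Windows are half-open [start, start+800) on 0-based sample indices;
  trailing samples that do not fill a window are dropped.
- Pair-retrieval accuracy is in-batch top-1 by dot product; argmax breaks
  exact ties toward the lowest index.
- Max-pooling is non-overlapping (kernel = stride = 2); odd tails drop.
- Seeds: every stochastic component takes an explicit seed or generator;
  derived seeds come from `SeedSequence` over (seed, fixed tag) tuples, and
  recordings are seeded by (cohort seed, CRC32 of patient id, phase, repeat),
  so cohorts are reproducible field-by-field and recordings bit-for-bit.

## Desk-scale reference studies

`pulsepair.studies` fixes the problem sizes used by the test suite and the
acceptance script: a 200-child labelled cohort (20% held out,
patient-stratified), the small encoder preset, 5 pretext epochs with N = 8
pairs and τ = 0.5, horseshoe probes at 400/400 warmup/draws, and — for the
initialization comparison — three replicate cohorts with two paired
fine-tuning seeds each at a 2-epoch budget.  At this scale the pretext loss
falls to ~1.2–1.4 against a 2.708 chance level, held-out pair retrieval
reaches ~8× chance, and horseshoe probes on the learned features recover
heart rate best (held-out R² ≈ 0.94–0.98), then SpO2, then respiratory rate
— the qualitative ordering the pipeline is designed to surface.

## Limitations

- The synthetic severity→waveform link is strong and clean, so absolute
  probe R² and AUC values are far higher than anything achievable on real
  triage data; only structural behaviour (losses beating chance, retrieval
  above chance, the HR > SpO2 > RR probe ordering, clinical features
  outranking waveform features) transfers as evidence.
- For the same reason, the end-to-end hospitalization task is learnable
  from random initialization to near its Bayes ceiling within a couple of
  epochs, and the SSL-vs-random warm-start comparison lands at parity
  (paired differences within ±0.1 AUC, centered near zero, occasionally
  mildly negative — instance-discrimination features carry some nuisance
  structure).  The full-scale warm-start advantage therefore does not
  reproduce at desk scale; the package runs the comparison faithfully and
  reports both means rather than asserting the ordering holds.
- HMC with a diagonal mass matrix explores the horseshoe's funnel geometry
  adequately at these sizes (recovery checks pass with no divergences) but
  is not a substitute for curvature-aware samplers at much larger feature
  counts.
- The `full` preset is pinned only by its parameter count; the true stage
  widths and kernel sizes of the original architecture are unrecoverable,
  so any preset satisfying the count is one member of an equivalence class.
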