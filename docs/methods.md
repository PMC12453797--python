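# Methods

This note documents the models, the numerical choices, and the synthetic-data
generator that makes the pipeline testable end to end, together with the
design decisions taken where more than one defensible option existed.

## Problem and model

The task is 3-class classification of a learner's state — Exhausted (0),
Negative (1), Active (2) — from short epochs of simultaneously recorded EEG,
galvanic skin response (GSR) and heart rate (HR).  Physiological rationale:
EEG band composition tracks cognitive load and drowsiness (slow-wave
theta/alpha dominance in fatigue, beta/gamma elevation in engaged states),
GSR phasic activity tracks sympathetic/emotional arousal, and HR level and
variability shift with activation.

Each epoch is summarised by a 14-dimensional feature vector: five EEG band
powers (delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz), three
Hjorth parameters, four GSR moments, and HR mean/sd.  The 5+3+4+2 layout is a
design choice: it is the minimal set that covers every feature family the
method calls for while matching the classifier's 14 input units, and it is
config-overridable.  EEG features are averaged across channels (not
concatenated) to keep the input width fixed at 14 regardless of montage.
Note the delta band is largely suppressed by the 4–45 Hz bandpass; it is
still computed (near zero) so the layout covers all five canonical bands.

## Preprocessing

Cleaning order: outlier masking (|z| > 3, per channel per trial) first, then
linear interpolation, because filters need gap-free input; filtering
(zero-phase forward–backward Butterworth, order 4 per pass, 4–45 Hz) and
per-channel z-scoring apply to EEG only — the band is an EEG convention, and
z-scoring GSR/HR would erase exactly the moment features the classifier uses.
Zero-phase filtering is chosen so no phase distortion leaks into the Hjorth
and moment features.  Whether the |z| > 3 rule should be applied per channel
per trial or globally is an open choice; per channel per trial is used.

Window lengths are per-modality configuration: EEG 4 s / 50 % overlap (512
samples at 128 Hz), GSR and HR 8 s / 50 % — the slower channels need longer
windows for stable moment estimates.  Each EEG epoch is paired with the
GSR/HR windows of maximal temporal overlap.

Conventions: population sd (n) for signal z-scoring, sample sd (n−1) for
feature moments; skewness/kurtosis are the standardized (excess) sample
moments; a constant window is degenerate and reports skew = kurt = 0 with a
flag.

Welch settings for band powers: Hann taper, segment length min(window, 256)
samples, 50 % overlap — a bias/variance balance appropriate at 128 Hz; band
powers are trapezoid integrals of the PSD over the band.

## Classifier

The MLP is written from first principles (no autodiff): ReLU hidden layers,
3-unit softmax output with categorical cross-entropy, He-initialized weights
(variance 2/fan-in), zero initial biases.  The loss is a choice — it is the
standard pairing for a softmax head and yields the clean (p − t)/m output
delta.  Dropout acts on the input layer only, in inverted form (retain with
probability P, scale by 1/P), so evaluation needs no rescaling.  Training is
plain minibatch gradient descent, deliberately without momentum or adaptive
steps, and stops at the iteration budget or when the maximum absolute
parameter change over a full pass drops below ε (max chosen as the stricter
reading of "change of all parameters").  A 1-unit linear-regression head
(`output_mode="regression"`, prediction by rounding) exists behind a flag for
configurations that specify a single output neuron; the softmax head is the
default because 3-state confusion matrices require 3 output scores.

Default hyperparameters: two hidden layers of 78 units, input dropout rate
0.14, batch size 95 — the swarm-optimized operating point — with learning
rate 0.05 and up to 150–200 iterations in the standard pipelines.

Gradient correctness is enforced by test: analytic gradients match central
finite differences (h = 1e−5) to < 1e−5 relative error across 20 random
architectures.  The checks perturb the zero initial biases to small random
values first: with exactly-zero biases a ReLU pre-activation can sit exactly
on the kink, where the loss is not differentiable and central differences
return the subgradient midpoint rather than either one-sided derivative.

## Particle swarm optimizer

Particles encode (hidden width ∈ [8, 128], dropout rate ∈ [0, 0.5], batch
size ∈ [16, 128]); integer dimensions decode by nearest-integer rounding.
The bounds contain the reported optimum (78, 0.14, 95).  The velocity update
uses the standard attraction signs (best − position); the repulsive variant
(position − best) that appears in one printed form of the update is available
behind `strict_paper_signs=True` for auditability but diverges from every
benchmark.  Coefficients are fixed (ω = 0.5, c1 = c2 = 1) by default — the
constants the experiments state — with quadratic-in-k schedules selectable.
Velocities are clamped to half the box width per dimension (standard
anti-explosion practice); positions are clamped to the box and a clamped
dimension's velocity is zeroed.  Initial velocities are zero.

The fitness — nowhere pinned down by the method description — is
1 − mean stratified inner-CV accuracy of the decoded MLP, with inner folds
grouped by trial (see below).  A mode that optimizes initial weights instead
of hyperparameters is deliberately not implemented: the experimental
configuration optimizes hidden-neuron count, dropout and batch size.

## GAN balancing

One GAN per class, trained on that class's feature vectors after per-feature
min/max scaling to [−1, 1] (the generator's tanh range; the scaler is stored
and inverted on sampling).  Generator 100 → 128 → 256 → 512 → d with
leaky-ReLU (slope 0.2) hidden units; discriminator mirrors it (512/256/128)
with dropout 0.3 and a sigmoid output.  Both use Adam (2e−4, β₁ = 0.5),
batch 64, binary cross-entropy; the generator uses the non-saturating form
(fakes scored against the real target).  Weights initialize from N(0, 0.02)
— the convention paired with this optimizer setup, and markedly more stable
across seeds here than fan-in-scaled init.  The noise prior is standard normal
— the field default; measured fit quality on the toy benchmark is
substantially better than under a uniform prior.  The Wasserstein distance is
a post-hoc similarity diagnostic only, never a training signal: the
configured sigmoid-plus-BCE discriminator is only consistent with the
minimax BCE objective.  Default 1000 epochs; diagnostic runs use 300
(adequate for the 2-d toy problem at a fraction of the cost).

Augmentation is applied inside training folds only, never across the
train/validation boundary, so synthetic rows can never leak label
information into evaluation.

`wasserstein_1d` computes the exact empirical W₁ from pooled ECDF
breakpoints; scipy's implementation serves as an independent cross-check in
the tests, not as the implementation.

## Evaluation

Precision/recall/F1 are one-vs-rest per class with unweighted macro
averages; an empty denominator scores 0 with a flag.  Cross-validation is
stratified and, whenever per-row trial metadata exists, grouped by trial:
adjacent windows cut from one recording share slow physiological structure,
and letting them straddle the split measures memorization, not recognition.
Aggregates report mean ± sd and a 95 % t-interval over folds.  Model
comparison is a paired two-sided t-test over matched fold accuracies; zero
variance of the paired differences is degenerate and reported as p = 1.

## Synthetic-data generator

The generator emulates the study's acquisition — multi-channel EEG, one GSR
and one HR channel at 128 Hz with 1–9 valence/arousal self-ratings — with a
single separability knob `effect_size` (0 = classes identical):

* **EEG**: white noise filtered into the five canonical bands and remixed
  with state-dependent log-gains (Active: beta/gamma up; Exhausted:
  theta/alpha up; Negative: mildly mixed), scaled by `effect_size`.
* **GSR**: tonic baseline with slow drift plus exponential-decay phasic
  events; the Poisson event rate is highest for the Negative state.
* **HR**: AR(1)-correlated beat-rate series whose mean rises with activation
  (Active +5 bpm, Exhausted −5 bpm per unit effect).
* **Ratings** are drawn inside the region the default rating-to-state rule
  assigns to the generating state, so the label map is exercised end to end.
* **Trial-to-trial variability**: every trial draws state-independent
  log-gain jitter (sd 0.25) on the EEG bands and baseline/rate jitter on GSR
  and HR.  This is the feature that makes the data realistic in the one way
  that matters here: no single modality is perfectly discriminative, so the
  multimodal combination genuinely helps, as it does in real recordings.
* Session periods (morning/afternoon/night) attach round-robin, enabling
  group-wise breakdowns; no period-dependent signal shift is injected by
  default.
* Missing samples (Bernoulli) and ±(8–12)·sd artifact spikes are injected on
  demand; spikes always exceed the |z| > 3 mask threshold by construction.

What the generator does **not** emulate: volume conduction and channel
covariance structure, ECG waveform morphology (HR is a beat-rate series),
non-stationary drift within a trial, subject-level idiosyncrasies beyond the
per-trial jitter, or any period-dependent effect.  Passing tests on this
corpus therefore demonstrate that the pipeline recovers class structure of
the stated spectral/autonomic kind at the stated noise level — not that it
attains any particular accuracy on externally recorded data.

## Statistical conventions in the tests

* At `effect_size = 0` features carry no label information, so cross-validated
  accuracy must sit at the 1/3 chance floor.  The binomial 95 % interval is
  computed at the number of independent *trials*, not windows: the 3–5
  windows of one recording are strongly correlated and share a fold by
  construction, so the window count would overstate the effective n.
* Distributional coincidence of classes at effect 0 is checked against the
  within-class split-half Wasserstein floor rather than an absolute
  threshold: the two-sample W₁ between *identical* distributions at a few
  hundred samples per class is itself ≈ 0.1–0.2 in z-scored units, so any
  absolute cutoff below that floor would be unattainable by construction.
* The "fixed default" MLP baseline in the comparison study is already the
  swarm-optimized operating point, so the expected outcome of the
  PSO-vs-default comparison is parity (within one sd), not a gap.

## Problem sizes

The shipped experiments use: n = 100 trials/class, 12 s/trial for the
effect-2 and effect-0 recovery checks; n = 25 trials/class, 8 s/trial over 5
seeds for the PSO-vs-default and modality-ablation studies (swarm Q = 10,
K = 20, 3 inner folds); (60, 30, 20) trials for the imbalanced augmentation
study (GAN 150 epochs inside folds); 512 training points for the toy-GAN
benchmark at 300 epochs.  These sizes give stable orderings and tight
chance-floor intervals while keeping a full run in the minutes range on one
CPU core.

## Known limitations

* The GAN operates on 14-d feature vectors, not raw signals; raw-waveform
  synthesis is out of scope.
* No artifact-subspace reconstruction, ICA or re-referencing for EEG; the
  cleaning model is thresholding + interpolation + bandpass only.
* Facial-expression and eye-tracking modalities are named in the problem
  domain but have no extraction operators here; the feature layout reserves
  no slots for them.
* The mapping from valence/arousal to the three states (Active = 2 …
  Exhausted = 0, thresholds 6/5/4) is a convention; thresholds are
  configurable.
* GAN training quality has noticeable seed-to-seed variance (adversarial
  training is not a convex fit); the augmentation diagnostics report
  distances, and seeds, for exactly this reason.
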