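# Methods

## The prediction problem

Each record is a multi-day, nominally 1 Hz, three-channel wrist-actigraphy
recording (physical activity, per-epoch angular change "angle", and spin)
from a patient admitted to a hospice care unit, together with a binary
outcome determined at discharge: died in hospital (1) or discharged in
stable condition (0). Only the first 24 or 48 hours of signal are used for
prediction, so the model is usable early in an admission; horizons shorter
than 24 h are allowed but warned against, because they cover less than one
circadian cycle. The clinical comparators are threshold rules on two
standard scores assessed at admission: KPS < 50 predicts death, PPI > 6.0
predicts death (both strict: a patient exactly at the boundary is classified
stable).

## Synthetic cohort generator

No public dataset exists for this design, so the package ships a first-class
generator whose defaults are the study conditions used throughout the tests.

Everything about a patient is driven by one latent frailty value
f ~ Normal(mu_group, 1), with mu = 2.6 for patients who die and 0.8 for
patients discharged stable:

* **Signal.** activity(t) = max(0, M·g(f) + A·g(f)·cos(2π(t − φ)/24 h) + ε(t)),
  a cosinor with mesor M, amplitude A, acrophase φ = 14:00, multiplied by a
  decreasing frailty modifier g(f) = exp(−0.25·(f − 1.7)) (unity for an
  average patient), plus stationary AR(1) noise (coefficient 0.9 per sample,
  marginal SD 0.5). Group cosinor parameters encode the qualitative contrast
  between outcome groups: death-group mesor is 0.5× and amplitude 0.3× the
  stable group's (M = 1.0 vs 2.0, A = 0.45 vs 1.5, in arbitrary activity
  units). Angle and spin are bounded noisy monotone transforms of activity
  (6·tanh(activity/2) and 10·tanh(activity/3) plus Gaussian noise): the
  device reports per-epoch angular-change statistics, which are near zero
  for a motionless wrist, not absolute posture.
* **Scores.** KPS = 100 − 25·f + Normal(0, 5), rounded to the 10-point
  scale and clipped to [0, 100]; PPI = 1.6 + 2.2·f + Normal(0, 0.8),
  rounded to the half-point scale and clipped to [0, 15]. The slopes and
  intercepts place the two clinical cutoffs near the midpoint of the two
  frailty distributions, so the KPS < 50 rule is correct for roughly 80–85%
  of simulated patients — the regime the cutoff classifiers operate in
  clinically. Score missingness is independent of everything else
  (KPS missing ~1/60 of the time, PPI ~40/60, matching typical partial
  enrolment of the composite score).
* **Device removal.** Off-wrist episodes arrive as a Poisson process
  (1.5/day) with uniform 15–65 min durations; off-wrist samples carry
  worn = False and NaN in all channels. The simulator never imputes:
  imputation policy belongs to preprocessing. With a 60-min gap tolerance
  these defaults exclude roughly a quarter of a 60-patient cohort, the
  calibration regime in which 44 of 60 recordings survive screening.
* **Composition.** A cohort of n patients contains exactly
  round(n·p_death) deaths (default 28/60) — composition is deterministic,
  not Bernoulli, so class counts are reproducible. Clinical metadata are
  drawn before any signal-sized draw, so metadata-only generation
  (`include_signals=False`) is cheap and bit-identical to the full
  simulation; large score-distribution sweeps use it.
* **Determinism.** One seed per cohort, spawned into independent per-patient
  substreams; identical parameters and seed give byte-identical output.

The generator emulates only the structure the analysis needs: circadian
modulation whose level and amplitude differ by outcome, shared latent
severity linking signal and scores, device-removal gaps, and realistic score
marginals. It does not model tumor sites, comorbidities, medication effects,
day-to-day rhythm drift, posture artifacts, or nonstationary deterioration
before death. Passing tests therefore demonstrate that the pipeline recovers
the encoded structure, not that the classifier would achieve any particular
accuracy on real patients.

## Preprocessing

Fixed order: truncate to the horizon → eligibility screen → block average →
zero-pad. Choices where the procedure is underdetermined:

* **Eligibility.** A recording is excluded if its span is shorter than the
  horizon ("data volume") or if any contiguous off-wrist/missing run within
  the horizon exceeds the gap tolerance ("tracking interruption"). Default
  tolerance 60 min: long enough to tolerate a shower or battery swap, short
  enough that a missing hour of circadian information disqualifies.
* **Block averaging.** Non-overlapping windows of 20 samples per channel; a
  trailing partial window is averaged over its actual count rather than
  dropped (data are scarce at these cohort sizes). Off-wrist samples are
  excluded from window means; a fully off-wrist window receives the pad
  value. A config flag (`offwrist_as_zero`) instead maps off-wrist samples
  to zero activity, for sensitivity analyses. At 1 Hz a 48-h recording
  becomes ceil(172800/20) = 8640 timesteps.
* **Padding.** To the batch maximum length, at the end of each sequence by
  default so the clinically earliest data sit at fixed positions;
  front-padding is available behind a flag. The observed length is kept on
  each tensor.
* **Splitting.** Stratified by outcome with a floor rule: each class
  contributes floor(ratio·n_class) to train, then floor(ratio·n_class) to
  validation, remainder to test, shuffled within class by seed. On a
  21-death / 23-stable cohort the 7:2:1 rule yields (14,4,3) and (16,4,3)
  per class — 30/8/6 overall. An explicit per-class count override exists
  for splits that follow no single ratio rule (e.g. a balanced 15/15
  training set with an 6/8 test remainder).

## Classifier

Architecture: LSTM (hidden width = `units`, returning the full sequence) →
per-timestep affine map to width 1 → flatten → affine map to a single
sigmoid output. Gate order i, f, g, o; forget-gate bias initialised to 1;
input and dense kernels Glorot-uniform; recurrent kernel orthogonal
per gate. Two named configurations: *preliminary* (64 units, batch 8,
50 epochs, 7:3 split) and *final* (256 units, batch 16, 100 epochs, 7:2:1
split). Training is Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7) on
mean-absolute-error between the sigmoid output and the binary label; the
sigmoid bounds the output so MAE against a 0/1 label is well behaved, and
its saturation gives MAE a usable gradient everywhere via the chain factor
y(1−y).

Implementation is pure numpy: a fused input+recurrent matrix multiply per
timestep in the forward pass, full backpropagation through time, float32
parameters. With a fixed seed (split into independent init and shuffle
streams) and single-threaded BLAS, training and prediction are
bit-reproducible; gradients are verified against central differences in the
test suite.

Defaults where the procedure is underdetermined: no masking of padded
timesteps (the zero-padded tail is genuine input, as in a plain
non-masking stack; a `mask_padding` flag freezes the recurrent state past
each sequence's observed length for sensitivity analyses); no input
normalization (`normalize` enables per-channel z-scoring fit on the
training set); classification threshold 0.5 with ties classified as death;
no early stopping or dropout. Per-epoch training loss/accuracy are running
minibatch statistics (the usual convention), validation metrics are
computed at epoch end.

## Evaluation

* 2×2-derived proportions carry Clopper–Pearson exact intervals
  (inverted binomial tails, via the beta quantile form). Exact intervals
  are the conservative standard at n ≤ 60; they also reproduce the CI
  widths typically reported for cohorts of this size. A proportion with a
  zero denominator is reported as missing, never as 0 or 1.
* Confusion matrices put the true class on rows; row-normalisation divides
  by row sums, and a row for an absent class is NaN rather than 0/0.
* ROC curves are empirical over the observed score set (no smoothing or
  binormal fit); AUC is the Mann–Whitney concordance probability with ties
  counted ½ (computed via scikit-learn, cross-checked in the tests against
  brute-force pair enumeration).
* The optimal cutoff maximises Youden's J = TPR − FPR; ties break toward
  the threshold classifying fewer patients as death (the higher threshold),
  the cautious choice when a death prediction triggers end-of-life
  conversations.

## Monte-Carlo problem sizes

The repeated-seed experiments (discriminability, null behaviour, horizon
comparison) simulate 44-patient cohorts (21 deaths / 23 stable — the
eligible-cohort composition) with 5-minute actigraphy epochs and 3–6 day
stays, preprocessed with the standard 20-sample blocks (48 h → 29 timesteps,
24 h → 15). Five-minute epochs are a standard aggregation in rest–activity
rhythm work, and they keep a from-scratch numpy LSTM trained for 100 epochs
per seed tractable: one seeded experiment takes ~10 s, so the full grids
(10 paired seeds at both horizons, 20 null seeds) run in minutes. The
discriminability property — mean held-out AUC ≥ 0.8 under the default group
contrast — and the null property — mean AUC near 0.5 when both groups share
all parameters — are calibration statements about the generator defaults and
the training recipe jointly. Metadata-only sweeps (score-coupling and
cutoff-accuracy distributions) use hundreds of cohorts, since no signal is
needed.

## Known limitations

* Synthetic validation only: no real actigraphy enters the tests, and the
  encoded group contrast is stylised (two fixed cosinor parameter sets and
  a single frailty axis).
* The held-out test set at n = 44 under a 7:2:1 split has six patients;
  single-seed test metrics are extremely coarse (AUC over 3×3 pairs), which
  is why all classifier claims are stated as means over seeds.
* MAE-on-sigmoid is a weak training signal compared to cross-entropy; with
  very small training sets the final configuration can plateau before
  reaching separability that a different loss would find. This mirrors the
  intended recipe rather than best practice.
* The per-timestep dense width, input normalisation, and padding masking are
  defaults chosen here (1 / off / off); all three are exposed in config for
  sensitivity analyses.
* The PPI comparator uses only the total score; item-level scoring (oral
  intake, edema, dyspnea, delirium) is out of scope, as are other prognostic
  indices (PaP, PiPS, Glasgow).
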