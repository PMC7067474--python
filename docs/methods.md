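# Methods

This note records the models, conventions and numerical choices behind
`wmdrift`, in the order data flows through the package.

## Orientation arithmetic

Grating orientation is axial: θ and θ+180° are the same stimulus. All
circular operations therefore work on the doubled angle 2θ (period 360°)
and halve the result. Orientations live in [0, 180); signed differences and
report errors in (−90, 90]. The similarity-profile axis is the signed
difference grid {−78.75, −67.5, …, 0, …, +78.75, +90}° in 11.25° steps; the
±90° endpoint is a single point stored at +90. The profile mirror
(Δ → −Δ) fixes 0 and 90 and swaps the 14 signed entries.

## The synthetic experiment

`synth.generate_dataset` emulates a retro-cue orientation task with two
delay-period impulses. Per participant it draws:

* a pair of tuning maps `(W_sin, W_cos)` per presentation side — i.i.d.
  standard-normal channels × samples patterns. The evoked signal of a trial
  holding orientation θ displaced by drift δ is
  `tuning_gain · (W_sin sin 2(θ+δ) + W_cos cos 2(θ+δ))`. Using independent
  maps per side makes the coding subspace location specific (the
  cross-location null); setting `location_specific=False` shares one pair.
* an additive impulse pattern per impulse epoch, constant over trials. By
  default (`orthogonal_time_axis=True`) these patterns are projected onto
  the orthogonal complement of the four tuning maps, making the "time" axis
  orthogonal to the mnemonic subspace, as in the hybrid
  stable-code/dynamic-population regime the analyses are designed to
  detect.
* an additive side pattern per presentation side (`location_offset_gain`),
  emulating the lateralised component of real evoked responses. Without a
  class-mean difference the cued location would be undecodable by a
  distance-to-class-mean classifier even though the coding subspaces
  differ; lateralised mean responses are what location decoders actually
  pick up in EEG.
* a random SPD channel covariance (AAᵀ, normalised to mean diagonal
  `noise_cov_scale²`) for spatially correlated Gaussian sensor noise,
  independent across samples.

**Drift model.** The remembered orientation performs a two-point random
walk: δ_array = 0, δ1 ~ N(0, drift_sd_impulse1²), δ2 = δ1 + N(0,
drift_step_sd²). The behavioural report error is
`wrap(report_coupling·δ2 + cardinal_bias_amp·sin 4θ + N(0, motor_noise_sd²))`.
The sin 4θ term is a cardinal-repulsion bias (oblique orientations reported
as more oblique); it is systematic in θ and is removed by the per-bin
median adjustment, isolating the random drift component that couples to the
CW/CCW labels. A two-point walk is the minimal structure that supports
"shift at the late impulse but not the early one"; a continuous-time
(e.g. Ornstein–Uhlenbeck) walk is deliberately not modelled.

**Defaults.** `n_participants=26`, `n_trials=1100` match the scale of the
emulated experiment; analyses and tests pass smaller sizes explicitly.
Signal and noise defaults (`tuning_gain=1`, `noise_cov_scale=3`,
`impulse_offset_gain=1`, `location_offset_gain=1`) give single-trial
decoding accuracies of a few hundredths — weak but reliably detectable with
a few hundred trials, like real posterior-channel EEG. Drift defaults
(`drift_sd_impulse1=5°`, `drift_step_sd=7°`, `motor_noise_sd=8°`,
`cardinal_bias_amp=5°`, `report_coupling=1`) were chosen once so that (a)
the total report-error spread gives a mean absolute adjusted deviation near
10° and (b) the late-delay shift is detectable at ~900 usable trials. Under
these defaults the expected conditional drift is E[δ2 | CW] =
√(2/π)·σ²_δ2/σ_err ≈ 5.5° at impulse 2 and ≈ 1.7° at impulse 1 — the
quantity the drift analyses estimate.

**What the generator does not emulate.** Biophysical structure (dipole
geometry, 1/f spectra, eye artefacts), the uncued item and its decay,
temporal autocorrelation of noise within an epoch, attractor-like
systematic drift towards oblique orientations, and trial-count imbalance
beyond random cueing. Passing tests therefore demonstrate the correctness
and calibration of the *analyses*, not that real EEG satisfies their
assumptions.

## Feature extraction

Half-open window [100, 400) ms so that 500 Hz yields exactly 150 samples →
30 bins; demeaning (per trial × channel over the window) precedes 10-ms
block averaging. Fractional samples per block raise an error rather than
interpolate. Consequently any per-trial/channel constant is removed
exactly, isolating the dynamic evoked signal from slow state differences.

## Orientation reconstruction

* **Bin spaces.** 16 centres, 11.25° apart, at 8 interleaved offsets
  (steps of 1.40625°). Trials are assigned the circularly closest centre;
  ties (exactly half a bin width away) break towards the lower index.
* **Folds.** Stratified by bin: within each bin the trials are shuffled and
  dealt round-robin into 8 folds (continuing the count across bins so fold
  sizes stay even). If some bin cannot be present in every training set —
  possible when a bin holds a single trial — folds are redrawn up to 100
  times, then an error is raised. With uniform random orientations this
  needs ≳200 trials to be reliable; the trial counts used in tests are
  chosen accordingly.
* **Templates.** Training bin counts are equalised by subsampling the
  minimum count, averaged, then pooled with the half-cosine basis
  `w[j,k] ∝ cos(πΔ_jk/180)^15`, rows normalised to sum 1 (the cosine is
  non-negative on |Δ| ≤ 90°, so no rectification is needed). Row
  normalisation fixes the profile scale; it does not affect signs or tests.
* **Covariance.** Ledoit–Wolf shrinkage (scikit-learn) on the full
  training rows — well conditioned for any n ≥ 2 in 510 dimensions.
  Distances are computed through the Cholesky factor (exact Mahalanobis,
  no inversion).
* **Accumulation.** Each trial is tested once per repeat per space:
  8 spaces × 100 repeats = 800 mean-centred 16-vectors, averaged and
  sign-reversed into the similarity profile. Profiles sum to 0 by
  construction. The subsample average converges quickly: reducing repeats
  100 → 10 moves mean accuracy by less than one SE.
* **Scalars.** Accuracy uses the 1/16-normalised cosine projection. The
  profile circular mean `arg(Σ p e^{i2Δ})/2` is exact for any rigidly
  shifted profile because it reads only the fundamental Fourier component;
  for a mixture of trial-wise shifts it returns the circular mean of the
  shift distribution. Its range is (−90, 90]; an all-zero profile has no
  defined mean and raises.
* **RNG.** One `numpy` Generator per call drives folds and subsampling;
  seeded calls are bit-reproducible.

## Generalisation analyses

Cross-impulse reconstruction keeps the shared trial indexing and takes
training rows from the other epoch, so a held-out trial never contributes
to its own templates in either epoch. Cross-location reconstruction has
independent train/test sets (no cross-validation); training bins are
balanced by subsampling, 100 repeats, with the covariance estimated once
from the full training side. Categorical decoding (impulse identity
leave-one-out, location 8-fold) scores `d(different) − d(same)`; a score of
exactly 0 counts as a miss (conservative, deterministic).

A measurement subtlety: even with a perfectly shared orientation code, the
orthogonal impulse-specific pattern plus trial-wise drift exact a small
(~10–15%) cross-epoch accuracy cost under the Mahalanobis metric, because
the epoch-difference vector adds a common component to every test-template
distance before mean-centring. Equality of cross- and within-decoding is
therefore exact only for fully exchangeable epochs, and the tests check it
in that regime; under study conditions they check that the cross accuracy
retains most of the within strength.

## Drift analyses

CW/CCW labels come from the sign of the bias-adjusted error; exact zeros
(trials at the bin median) are excluded rather than randomly assigned —
deterministic and unbiased. Medians are taken within participant × 11.25°
bin (bins anchored at 0°), so each participant's classes are balanced
within every bin up to ties, which the response-conditioned decoding
requires.

Approach A averages the trial profiles by class, mirrors the CCW average
and averages the two; a genuine shift s appears as s. Approach B trains on
one class and tests on the other; both sets are displaced in opposite
directions, so the shift appears doubled — *provided training and testing
patterns come from the same epoch*. When training instead uses the
impulse-averaged epoch (the power-improving variant, also implemented), the
training-side displacement is the average of the two epochs' conditional
drifts, and the expected ratio to approach A is
`1 + (E[δ1|CW] + E[δ2|CW]) / (2·E[δ2|CW])` ≈ 1.66 under the generator
defaults rather than 2. The doubling property is therefore verified in the
within-impulse-2 variant (measured ratio 1.99, bootstrap CI [1.95, 2.05]
over 12 simulated cohorts), and the averaged-epoch variant is tested
against its own wider expected band.

## Inference

* **Permutation t test.** Permutation b combines every participant's b-th
  label-permuted statistic into a group t value against the chance level;
  this pairing preserves exchangeability and yields exactly n group null
  statistics. Difference tests subtract paired nulls first.
* **Sign-flip circular-mean test.** Each iteration mirrors each
  participant's aligned profile with probability ½; one-sided p is the
  proportion of null circular means at least as positive as the observed.
* **p-value convention.** `p = (1 + #extreme)/(1 + n)` throughout, so p is
  never 0 and the test is exactly level-α under exchangeability (verified
  by calibration tests at ~5% rejection). Exactly mirror-symmetric profiles
  make every null statistic tie the observed 0, giving p = 1 — the
  conservative edge of the tie convention.
* **Bootstrap.** Percentile CIs of the mean, resampling participants.
  Values are sorted before resampling so the interval depends only on their
  multiset, not their order.

## State-space geometry

Condition patterns are the subsample-equalised averages of 4 orientation
quadrants ([0,45), [45,90), [90,135), [135,180)°) × impulse or × side;
Mahalanobis distances use the covariance of all contributing trials, are
averaged over 100 random half-splits/subsamples (and over sides for the
impulse scheme), symmetrised, and embedded by classical (Torgerson) MDS:
double-centre the squared distances, eigendecompose, keep the top axes;
negative eigenvalues are truncated to zero coordinates. Axis sign and
rotation are arbitrary; plots may align the condition axis to dimension 1
for display only.

## Problem sizes in the test suite

The canonical procedure (100 repeats, 1,100 trials, 26 participants) is
too large for routine testing; the suite runs the identical code paths at
reduced sizes chosen for statistical feasibility and speed: 96–512 trials
per synthetic participant, 4–17 channels, 1–20 fold/subsample repeats,
12–50 simulated cohorts for calibration and recovery checks, and a few
hundred iterations for permutation/sign-flip nulls. Structural counts (510
dimensions, 800 samples per trial) are verified at full repeat counts on
small feature spaces. Dataset-level statistics (mean accuracy, group
shift) are calibrated across independent simulated datasets rather than
via within-dataset trial SEs, because trials that share training folds and
templates are not independent.

## Known limitations

* The stratified-fold machinery requires every orientation bin of every
  bin space to hold ≥ 2 trials; sparse designs (< ~200 random-orientation
  trials) can fail stratification and raise.
* The exclusion rule and circular SD assume the doubled-angle mapping;
  report-error distributions wider than ~±60° would make the 3-SD rule
  ineffective (the circular SD saturates).
* `adjust_bias` subtracts medians computed on the analysed sample; with
  very few trials per bin the median estimate itself is noisy and the
  CW/CCW split correspondingly unbalanced.
* Bootstrap CIs are percentile-based and mildly anticonservative for
  n ≲ 30 participants.
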