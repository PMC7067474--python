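# wmdrift

Multivariate decoding and drift analysis of orientation working memory from
impulse-response EEG.

## The problem

During a visual working-memory delay the EEG carries little overt trace of
the stored item, but a task-neutral visual *impulse* ("ping") evokes a
response that depends on the hidden memory state. Decoding that evoked
response at different moments of the delay answers two questions about how a
remembered grating orientation is held:

* **Is the coding scheme stable over time?** If a decoder trained on the
  early-delay impulse response reads out the late-delay response equally
  well, the orientation code is time-invariant, even if a separate
  low-dimensional pattern distinguishes the impulses themselves.
* **Does the memory drift?** If the remembered orientation performs a random
  walk along the feature dimension, the late-delay neural code should be
  displaced towards the (bias-adjusted) behavioural report: trials reported
  clockwise of the true orientation should show a clockwise-shifted code.

`wmdrift` implements the complete analysis chain for these questions —
feature extraction, Mahalanobis-distance orientation reconstruction,
cross-condition generalisation, categorical state decoding, state-space
geometry, response-coupled drift statistics, and permutation/sign-flip/
bootstrap inference — together with a synthetic-data generator that
reproduces the statistical structure of such an experiment, so the entire
pipeline is testable end-to-end without any recordings. It is written for
cognitive/computational neuroscientists who want a tested, reusable
reference implementation of this family of analyses.

## The method

**Features.** For each event (memory array, impulse 1, impulse 2) the window
100–400 ms after onset is taken from 17 posterior channels, demeaned per
trial and channel, and down-sampled to 100 Hz by averaging 10-ms blocks:
30 values per channel, 510 dimensions per trial.

**Orientation reconstruction.** Trials are assigned the closest of 16 bin
centres (11.25° apart) and split into 8 stratified folds. Per fold, training
bins are balanced by subsampling, averaged, and pooled over neighbours with
a half-cosine basis raised to the 15th power. Each test trial's Mahalanobis
distances to the 16 templates — with a Ledoit–Wolf shrinkage covariance
estimated from the training trials — are mean-centred. Folds and subsamples
are redrawn 100 times for each of 8 interleaved bin spaces (offsets in steps
of 1.40625°), giving 800 distance samples per trial. The averaged,
sign-reversed distances ordered by signed orientation difference Δ form the
trial's *similarity profile* `p(Δ)`; its cosine vector mean

    accuracy = (1/16) Σ_k p(Δ_k) cos 2Δ_k

is the scalar decoding accuracy (positive ⇒ similar orientations evoke more
similar patterns).

**Generalisation.** The same reconstruction run with training folds from the
other impulse epoch (or the other cued location, with independent train/test
sets) probes whether the code transfers across time and space. Impulse
identity and cued location are decoded categorically from the
distance-difference score `d(other class) − d(own class)` (ties are misses),
with chance at 50%.

**Drift.** Report errors are bias-adjusted by subtracting the per-bin median
(removing the cardinal-repulsion bias), trials are labelled CW/CCW by the
sign of the adjusted error, and the response-aligned profile is the average
of the CW-profile and the mirrored CCW-profile. Its circular mean
`arg(Σ_k p(Δ_k) e^{i2Δ_k})/2` is the group shift; the participant-level
asymmetry score is `Σ p(+22.5°,+45°,+67.5°) − Σ p(−22.5°,−45°,−67.5°)`. A
second, more sensitive probe trains the decoder on CW trials and tests it on
CCW trials (and vice versa), doubling a genuine shift. Inference uses
label-permutation t-value nulls, a 0.5-probability profile sign-flip test
for the group circular mean, and participant-level bootstrap CIs.

## Worked example

`examples/04_drift_detection.py` simulates one participant (400 trials,
8 channels), runs behavioural QC and both drift probes, and prints:

```
excluded 0 likely-guess trials; max |median bias| 9.8 deg

approach A (response-dependent averaging):
  memory_array: shift  -0.30 deg, asymmetry -0.0061
      impulse1: shift  +1.82 deg, asymmetry +0.0250
      impulse2: shift  +4.68 deg, asymmetry +0.0640

approach B (split train/test, impulse 2): shift  +8.32 deg (~2x approach A)

ground-truth conditional drift at impulse 2: +5.01 deg
```

Reading: at encoding the neural code shows no response-aligned shift; by the
late impulse it is shifted ~5° towards the report, matching the generator's
ground-truth conditional drift, and the split-train probe roughly doubles
it. The other examples cover simulation + decoding (`01`), cross-impulse and
cross-location generalisation (`02`), state-space MDS (`03`) and group-level
inference (`05`). A thin CLI mirrors the library
(`wmdrift simulate|featurize|decode|generalise|drift|stats|mds`).

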