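# Methods

This note documents the generative model behind `cobci.synth`, the feature
and classification pipeline, the fusion rules, the evaluation protocol, and
the design decisions taken where the problem left genuine freedom. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The decoding problem

Two posterior-parietal EEG channels (`PPC_L`, `PPC_R`) are epoched around a
left/right direction cue. The discriminative signature is contralateral
negativity: components peaking near 210 ms and 320 ms after the cue are more
negative over the hemisphere opposite the planned reach direction. A
single-trial classifier sees one epoch and predicts the direction (+1 left,
−1 right). In a collaborative setting, `m` subjects receive the same
stimulus stream simultaneously, and one "collaborative trial" is the tuple
of their `m` simultaneous epochs.

## Generative trial model

One simulated trial for subject *i* under condition *c* is

```
x_ch(t) = g_i · Σ_n a_n · C_n(t − τ_n) · w_{n,ch,c}  +  noise(t)
```

- **C_n** — unit-amplitude Gaussian-windowed deflection, parameterized by
  peak latency (ms) and FWHM (ms). The waveform family is a deliberate
  choice: the real components are known only through their peak latencies
  and their sub-12 Hz spectral content, and a Gaussian bump is the simplest
  smooth, band-limited, two-parameter shape meeting both.
- **a_n** — per-trial amplitude, lognormal with mean `amplitude_mean_uv`
  (µV) and coefficient of variation `amplitude_cv`; lognormal keeps the
  component's sign fixed while allowing realistic right-skewed modulation.
- **τ_n** — per-trial latency jitter, Gaussian with SD
  `latency_jitter_sd_ms`, truncated at ±3 SD so components stay inside the
  epoch.
- **w_{n,ch,c}** — signed channel/condition gain. The default direction
  components use `left: (+1, −1)`, `right: (−1, +1)` over `(PPC_L, PPC_R)`,
  i.e. the *left* weights are the channel-swapped negation of the *right*
  weights (lateralization symmetry).
- **g_i** — subject gain (lognormal, log-SD 0.15).
- **noise(t)** — zero-mean background EEG, per channel. Default AR(1) with
  lag-1 coefficient 0.95 at 256 Hz (power concentrated at low frequencies,
  like background EEG); `white` and `pink` (1/f amplitude spectrum) are
  available for sensitivity checks. Marginal SD is `sd_uv`.

Default components: peaks 210/320 ms, FWHM 80/90 ms, mean amplitudes
2.0/1.5 µV, amplitude CV 0.3, jitter SD 20/25 ms.

Epochs cover [−100, 700] ms at 256 Hz on a grid locked so 0 ms (cue onset)
is a sample. Cohorts are balanced: 100 trials per condition by default, one
label sequence shared by all subjects (the collaborative contract), with
independent per-subject noise/amplitude/jitter substreams spawned from a
single seed; a cohort is bit-reproducible from its config.

### Individual differences (why fusion methods separate)

If every subject had identical component latencies and shapes, cross-subject
feature averaging would gain √m in SNR with no cancellation and fusion
methods would hardly differ. Real cohorts are not like that, and neither is
the default simulated cohort:

- component peak latencies shift per subject (Gaussian SD 35 ms, truncated
  ±2 SD) — the between-subject analogue of latency jitter, in the range ERP
  studies report for inter-individual component-latency variability;
- component amplitudes scale per subject (lognormal log-SD 0.4, roughly a
  factor-two spread);
- background noise power fluctuates across trials (lognormal scale,
  mean 1, log-SD 0.6), emulating alpha bursts and vigilance drift; this
  gives single-trial amplitudes the heavy tails of real EEG and is what
  makes per-timepoint min–max normalization compress typical trials.

These three are the mechanism, visible in the sweep results, by which
averaging loses signal to cancellation and large concatenated feature
spaces become hard to estimate — while decision-level voting, which never
mixes raw features across subjects, is insensitive to them.

### Calibration to target decodability

Real recordings of this paradigm publish accuracies, not SNRs, so the
simulator is calibrated in accuracy space: `calibrate_noise` bisects the
noise SD (geometrically, since plausible SDs span decades) until the
standard single-subject pipeline's cross-validated accuracy hits a target in
(0.5, 1). The signal realization and a unit-SD noise realization (including
trial-power modulation) are drawn once and only rescaled between iterations,
making accuracy a deterministic, near-monotone function of the SD — the
bisection then converges in a handful of steps. An unattainable target
(accuracy below target even at vanishing noise) is reported with a
`converged=False` flag, never silently.

`calibrated_cohort` assigns per-subject targets evenly spaced over
[0.56, 0.76] (mean 0.66, shuffled across subjects), reproducing the reported
spread of single-trial decodability (a few subjects below 60%, most between
60 and 70%, several above 70%). Calibration tolerance is 0.02 by default;
note the cross-validated accuracy of a *fresh* realization of a calibrated
subject still varies with ~0.04 SD (finite 200-trial datasets), so
cohort-level means are accurate to ~0.01–0.02 while individual subjects
scatter more.

## Feature pipeline

Per trial and channel: subtract the mean of the [−100, 0) ms baseline;
select a half-open analysis window [onset, offset) (a sample at time t
belongs iff onset ≤ t < offset); replace each non-overlapping block of 5
samples by its mean (dropping a trailing partial block — "complete blocks
only"); then normalize each resulting timepoint to [−1, 1] by the min/max
over all *training* trials pooled across conditions (degenerate timepoints
with max = min map to 0); finally concatenate the two channel blocks. At
256 Hz a [0, 500) ms window gives 128 samples → 25 block means per channel
→ a length-50 vector; [0, 400) gives 40.

Normalization statistics carry window/channel/factor provenance and refuse
to be applied to a mismatched extraction — this guards against silent
train/test leakage. Whether the original analysis normalized per fold or
globally is not documented; the default here is fold-wise fitting (standard
CV hygiene), with `normalize_mode="pooled"` available to reproduce the
pooled alternative in sensitivity analyses. The sub-12 Hz band observation
is treated as the motivation for block-mean downsampling, not as an extra
filter; no band-pass is applied to synthetic data.

## Classifier and fusion rules

The base classifier is an SVM with RBF kernel
`K(u,v) = exp(−‖u−v‖²/(2σ²))`, σ = 10, C = 1 (both configurable). Two
conventions follow the classic MATLAB-style SVM toolboxes this setup
mirrors: σ is the *kernel scale* (scikit-learn `gamma = 1/(2σ²)`), and each
feature is standardized to zero mean/unit variance on the training data
before the kernel (`autoscale=True`, the toolbox default; the scaler is
part of the model so test trials are scaled with training statistics only).
With unit-variance features, expected squared distances grow as ~2·dim:
σ = 10 is well matched at ~50 dimensions and saturates
(`K → exp(−dim/100)`) as concatenation pushes the dimension into the
hundreds — the overfitting regime that caps the concatenation method at
large ensembles. C is not documented in the original setting; the toolbox
default C = 1 is used.

- **Averaging**: elementwise mean of the m aligned per-subject feature
  matrices, then one classifier.
- **Concatenating**: horizontal concatenation in fixed subject order
  (width Σ widths), then one classifier.
- **Voting**: per-subject classifiers; ensemble decision
  `y = sign(Σ wᵢ yᵢ)` over hard labels yᵢ ∈ {−1, +1}, with wᵢ = the
  sub-classifier's training accuracy, used raw (no renormalization and no
  accuracy−0.5 shift; any positive rescaling of all weights leaves every
  decision unchanged anyway, which the tests verify). A vote score of
  exactly zero defers to the highest-weight sub-classifier, weight ties
  breaking by subject order — deterministic and seed-free. Sub-decisions
  are hard labels by design (the distributed contract: only decisions and
  weights cross subject boundaries); a margin-based soft vote would be a
  different method and is not provided.

## Evaluation protocol

Accuracy is estimated by repeated stratified k-fold cross-validation
(10×10 by default; folds partition trials exactly, class balance within ±1).
Everything fitted — normalization ranges, scalers, sub-classifiers, voting
weights — is computed inside each training fold. One fold layout is shared
across methods within a repeat, so method comparisons are paired.

**Subject sweep** (`subject_sweep`): for each ensemble size n, draw random
subject subsets (uniform without replacement within a subset; subsets repeat
across draws — for n = 1 only N distinct subsets exist, so sampling with
repetition is the only consistent reading) and record each subset's mean CV
accuracy. Each draw uses its own fold layout, so the spread at n = N
reflects CV variability rather than collapsing to zero. For voting, a
subset's decision depends only on each member's fold predictions and
training-fold weight; per-subject fold predictions are therefore cached per
layout and reused across all draws — the same decomposition a distributed
deployment uses, and the reason the voting sweep costs `subjects × folds`
model fits per layout rather than `draws × subjects × folds`.

**Window sweep** (`window_sweep`): windows [0, offset) for offsets 100–500 ms
in 10 ms steps by default, for ensemble sizes {1, 5, 10, 15, 20}; one fold
layout and one set of subject draws shared across offsets (paired curves).
The 464 ms mean manual reaction time of the reaching task is attached to
curves as plot metadata — a printed benchmark, never computed here.

**Statistics** (`summarize_stats`): one-way ANOVA for the effect of the
swept parameter across draws, and per-level Welch two-sample t-tests of
collaborative draws against the N individual accuracies, p-values
unadjusted. The draws at different levels share subjects and trials, so
independence assumptions hold only approximately; the summary mirrors the
field's reporting convention and should be read descriptively.

### Problem sizes used in tests and the acceptance script

The packaged runs scale the protocol to desk size as the package's own
default study conditions: sweeps use 15–30 resamples (100 in the heaviest
qualitative test) with 1×10-fold CV per draw, rather than 500 resamples of
10×10-fold; cohort size (20), trials per condition (100), the [0, 400) ms
sweep window, and all model hyper-parameters are unchanged. At these sizes
the voting curve's mean values are stable to ~1 percentage point.

## Archives, configuration, CLI

Cohorts are stored one subject per HDF5 file (`channels × samples × trials`,
float32 µV) with a plain-JSON sidecar (subject, rate, grid, channels,
labels, provenance); payload/sidecar mismatches raise integrity errors
rather than partial reads, and a schema version gate refuses unknown
layouts. Run configuration is a pydantic-validated YAML/JSON schema that
rejects unknown keys. The `cobci` CLI exposes `simulate`, `features`,
`evaluate`, `sweep-subjects`, `sweep-window`; every run writes a manifest
(config + seed + content hash) sufficient to reproduce it. Externally
recorded epochs can be imported from EDF/BDF via the optional `mne`
dependency.

## What the simulator does and does not capture

It captures: the two-component lateralized ERP structure, trial-to-trial
amplitude/latency variability, between-subject latency/amplitude/SNR
differences, low-frequency-dominated autocorrelated noise with
non-stationary power, the shared-stimulus trial alignment, and
accuracy-calibrated per-subject decodability.

It does not capture: ocular or muscle artifacts (and hence no artifact
removal), volume-conduction topography beyond two channels, continuous
recordings (epochs are generated directly), cross-channel noise
correlation, task conditions other than left/right, or learning/fatigue
trends within a session. Consequently, passing tests show that the
*methods* behave as expected under realistic ERP statistics — they are not
evidence about any particular real cohort, and absolute accuracies on real
recordings will differ with electrode placement, artifact handling, and
population.

## Numerical choices and degenerate inputs

- Time grid: `t_k = k·1000/fs`, 0 ms always on-grid; window membership uses
  a 1 ns tolerance against float drift.
- Downsampling drops trailing partial blocks; an empty signal downsamples
  to an empty vector (not an error).
- Degenerate (constant) feature timepoints normalize to 0; zero-variance
  features pass through the standardizer unscaled.
- Bisection in calibration is geometric over the SD with at most 25
  accuracy evaluations; targets outside (0.5, 1) are rejected up front.
- All randomness flows through `numpy.random.SeedSequence` spawns keyed by
  integers — never Python's process-randomized `hash()` — so every result
  is bit-reproducible across processes from one seed.
- Vote ties and weight ties resolve deterministically (see above).

## Known limitations

- Training accuracy is an optimistic weight (near 1 for overfit
  sub-classifiers); inner-CV weights would discriminate subject quality
  better but are not what the voting rule specifies.
- The concatenation method's behavior at large m depends strongly on the
  fixed kernel scale convention; with per-dimension-adaptive kernels it
  would degrade more slowly.
- Calibration targets accuracy on one simulated dataset per subject;
  fresh-realization accuracy scatters by a few points (see above).
- The ANOVA/t-test summaries inherit the resampling dependence noted above.
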