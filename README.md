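# cobci — collaborative ERP decoding

`cobci` is a simulation and evaluation toolkit for *collaborative*
brain–computer interfaces: systems that decode a decision from the
single-trial EEG of **several people performing the same task at the same
time**, rather than from one user alone. The motivating setting is
movement-intention decoding — predicting whether an upcoming reach goes left
or right from the direction-selective event-related potentials (ERPs) that
arise over posterior parietal cortex (PPC) after a direction cue, earlier
than the overt motor response.

Single-trial ERP classification is hard (typical accuracy 55–75% per
subject), but errors across subjects are largely independent, so fusing a
group recovers reliable decisions. The package implements and compares the
three standard fusion strategies:

- **ERP/feature averaging** — average the per-subject feature vectors of a
  trial, classify once. Simple, but between-subject latency and amplitude
  differences cancel signal.
- **Feature concatenation** — concatenate per-subject feature vectors
  (dimension `m·k` for `m` subjects, `k` features each) and classify once.
  Keeps all information but overfits: the trial count stays fixed while the
  dimension grows.
- **Weighted sign voting** — one RBF-SVM per subject; fuse hard decisions as
  `y = sign(Σᵢ wᵢ yᵢ)` with each sub-classifier's training accuracy as its
  weight `wᵢ`. Needs only per-subject decisions (no raw-data sharing), so it
  is the one method compatible with a distributed deployment.

The classification pipeline is the classic ERP recipe: epochs of
[−100, 700] ms around the cue at 256 Hz, baseline correction on
[−100, 0) ms, a post-cue analysis window, block means of 5 consecutive
samples (the discriminative energy lies below 12 Hz), per-timepoint min–max
normalization to [−1, 1] across trials and conditions, and concatenation of
the two PPC channels into one feature vector — classified by an SVM with RBF
kernel `K(u,v) = exp(−‖u−v‖²/(2σ²))`, σ = 10, C = 1, on per-feature
standardized inputs.

Because no public multi-subject recording of this paradigm exists, the
package ships a generative ERP simulator (`cobci.synth`): Gaussian-windowed
direction-selective components (contralateral-negative / ipsilateral-positive,
peaks near 210 and 320 ms) with per-trial lognormal amplitude modulation and
truncated-Gaussian latency jitter, per-subject latency/amplitude individual
differences, and autocorrelated background noise whose level is *calibrated*
per subject to a target single-trial decodability.

## Worked example

```python
import numpy as np
from cobci import synth, features, evaluate

# 6 simulated subjects, 100 trials/condition, noise calibrated so
# single-subject decodability spans ~0.56-0.76
config = synth.SimConfig(n_subjects=6, trials_per_condition=100, seed=3)
cohort, profiles, reports = synth.calibrated_cohort(config)

mats = [features.raw_feature_matrix(es, (0.0, 400.0)) for es in cohort]
labels = cohort[0].labels   # shared trial sequence, +1 left / -1 right
scheme = evaluate.CVScheme(repeats=2, folds=10, seed=0)

singles = [evaluate.cross_validate("single", [m], labels, scheme).mean() for m in mats]
print(f"single-subject mean: {np.mean(singles):.3f} "
      f"(range {min(singles):.3f}-{max(singles):.3f})")
for method in ("averaging", "concatenating", "voting"):
    acc = evaluate.cross_validate(method, mats, labels, scheme)
    print(f"{method:>19}: {acc.mean():.3f} +- {acc.std(ddof=1):.3f}")
```

prints (reproducibly, for this seed):

```
single-subject mean: 0.649 (range 0.550-0.790)
          averaging: 0.725 +- 0.073
      concatenating: 0.732 +- 0.102
             voting: 0.795 +- 0.093
```

An average subject sits near 65% — barely useful alone — while six
collaborating subjects reach ~80% by voting. On larger cohorts (`evaluate.subject_sweep`)
voting keeps climbing (~94% at 20 subjects) while concatenation peaks and
then degrades as the feature dimension outgrows the fixed trial count, and
averaging lands in between; `evaluate.window_sweep` shows how decoding
accuracy grows with the analysis-window length, reaching useful levels well
before the ~464 ms mean manual reaction time.

The same pipeline is scriptable from the shell:

```bash
cobci simulate --config cohort.yaml --out data/ --seed 3
cobci evaluate --config cohort.yaml --data data/ --out results/
cobci sweep-subjects --config cohort.yaml --data data/ --out results/ --plot
cobci sweep-window  --config cohort.yaml --data data/ --out results/ --plot
```

Every run writes a `manifest.json` (config + seed + content hash) that
reproduces its outputs exactly.

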