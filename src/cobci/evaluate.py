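"""Evaluation protocol: repeated cross-validation, ensemble-size and
prediction-time sweeps, and their statistical summaries.

Accuracy is always estimated by stratified, repeated k-fold cross-validation
(10 x 10-fold by default). Everything fitted — per-subject normalization
ranges, sub-classifiers, voting weights — is computed on training folds only
and applied to held-out folds, so reported accuracies are out-of-sample.

Two sweeps characterize a collaborative decoder:

* :func:`subject_sweep` — accuracy versus ensemble size ``n``: for each ``n``
  it draws random subsets of ``n`` subjects (with repetition at the subset
  level) and cross-validates each fusion method on the subset;
* :func:`window_sweep` — accuracy versus analysis-window offset (prediction
  time): how early after the direction cue a reliable decision is available,
  compared against the overt manual reaction time.

For voting, a subset's ensemble decision depends only on each member's fold
predictions and training-fold weight, so per-subject fold predictions are
computed once per fold layout and reused across the hundreds of subset
draws; this is exactly the decomposition a distributed deployment uses, and
it makes the sweeps tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.model_selection import KFold, StratifiedKFold

from . import features as feat
from . import fusion

__all__ = [
    "METHODS",
    "DEFAULT_REFERENCE_RT_MS",
    "CVScheme",
    "AccuracyCurve",
    "cross_validate",
    "single_subject_accuracy",
    "subject_sweep",
    "window_sweep",
    "summarize_stats",
]

METHODS = ("single", "averaging", "concatenating", "voting")

# Mean manual reaction time (ms) of the reaching task, drawn as a reference
# line on prediction-time plots; a printed benchmark, never computed here.
DEFAULT_REFERENCE_RT_MS = 464.0


class StratificationError(ValueError):
    """A fold cannot be formed with both classes present."""


@dataclass
class CVScheme:
    """Repeated (stratified) k-fold layout, reproducible from its seed."""

    repeats: int = 10
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def split(self, labels: np.ndarray) -> list[list[tuple[np.ndarray, np.ndarray]]]:
        """Fold layouts: one list of (train_idx, test_idx) per repeat.

        Every trial appears in exactly one test fold per repeat; stratified
        folds keep the class balance within +-1 trial.
        """
        y = np.asarray(labels)
        if self.stratified:
            _, counts = np.unique(y, return_counts=True)
            if counts.min() < self.folds:
                raise StratificationError(
                    f"cannot stratify {self.folds} folds with a class of "
                    f"{counts.min()} trials"
                )
        layouts = []
        for r in range(self.repeats):
            rs = int(
                np.random.SeedSequence((self.seed, r)).generate_state(1)[0] % (2**31)
            )
            cls = StratifiedKFold if self.stratified else KFold
            splitter = cls(n_splits=self.folds, shuffle=True, random_state=rs)
            layouts.append([(tr, te) for tr, te in splitter.split(np.zeros_like(y), y)])
        return layouts


@dataclass
class AccuracyCurve:
    """Accuracy as a function of a swept parameter (subject count or window).

    ``samples[i]`` holds the per-draw accuracies at ``x[i]``; ``mean`` and
    ``sd`` summarize them.
    """

    x: np.ndarray
    samples: list[np.ndarray]
    method: str = ""
    x_name: str = "x"
    meta: dict = field(default_factory=dict)

    @property
    def mean(self) -> np.ndarray:
        return np.array([s.mean() for s in self.samples])

    @property
    def sd(self) -> np.ndarray:
        return np.array([s.std(ddof=1) if s.size > 1 else 0.0 for s in self.samples])

    @property
    def n_resamples(self) -> np.ndarray:
        return np.array([s.size for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                self.x_name: self.x,
                "mean_accuracy": self.mean,
                "sd_accuracy": self.sd,
                "n_resamples": self.n_resamples,
            }
        )


# ---------------------------------------------------------------------------
# Core cross-validation
# ---------------------------------------------------------------------------

def _normalize_fold(
    per_subject_raw: Sequence[np.ndarray],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    normalize_mode: str,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-subject min-max normalization fitted on the training fold.

    ``pooled`` fits the range on all trials instead (the leakage-prone
    variant, kept for sensitivity analysis only).
    """
    Xtr, Xte = [], []
    for raw in per_subject_raw:
        fit_rows = raw if normalize_mode == "pooled" else raw[train_idx]
        stats = feat.fit_normalization(fit_rows)
        Xtr.append(feat.apply_normalization(raw[train_idx], stats))
        Xte.append(feat.apply_normalization(raw[test_idx], stats))
    return Xtr, Xte


def cross_validate(
    method: str,
    per_subject_raw: Sequence[np.ndarray],
    labels: Sequence[int],
    scheme: CVScheme | None = None,
    normalize_mode: str = "fold",
    sigma: float = fusion.DEFAULT_SIGMA,
    C: float = fusion.DEFAULT_C,
) -> np.ndarray:
    """Out-of-sample accuracy of one fusion method, per repeat x fold.

    ``per_subject_raw`` are aligned, *un-normalized* trials x features
    matrices (one per subject) sharing one label sequence; normalization and
    all model fitting happen inside each training fold.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    mats = [np.asarray(m, dtype=float) for m in per_subject_raw]
    y = np.asarray(labels, dtype=int)
    if any(m.shape[0] != y.size for m in mats):
        raise fusion.AlignmentError("per-subject trial counts must match labels")
    if method == "single" and len(mats) != 1:
        raise ValueError("method 'single' expects exactly one subject")
    if normalize_mode not in ("fold", "pooled"):
        raise ValueError(f"normalize_mode must be 'fold' or 'pooled', got {normalize_mode!r}")
    scheme = scheme or CVScheme()
    acc = np.empty((scheme.repeats, scheme.folds))
    for r, layout in enumerate(scheme.split(y)):
        for f, (tr, te) in enumerate(layout):
            Xtr, Xte = _normalize_fold(mats, tr, te, normalize_mode)
            if method in ("single", "averaging", "concatenating"):
                combine = {
                    "single": lambda ms: ms[0],
                    "averaging": fusion.fuse_average,
                    "concatenating": fusion.fuse_concat,
                }[method]
                clf = fusion.train_subject(combine(Xtr), y[tr], sigma=sigma, C=C)
                pred = clf.predict(combine(Xte))
            else:  # voting
                subs = [
                    fusion.train_subject(Xtr[s], y[tr], sigma=sigma, C=C)
                    for s in range(len(mats))
                ]
                ensemble = fusion.EnsembleModel(subs)
                pred, _ = fusion.predict_vote(ensemble, Xte)
            acc[r, f] = np.mean(pred == y[te])
    return acc


def single_subject_accuracy(
    epoch_set: feat.EpochSet,
    window_ms: tuple[float, float] = (0.0, 400.0),
    scheme: CVScheme | None = None,
    factor: int = 5,
    channels: Sequence[str] | None = None,
    sigma: float = fusion.DEFAULT_SIGMA,
    C: float = fusion.DEFAULT_C,
) -> float:
    """Mean CV accuracy of the standard single-subject pipeline on one epoch set."""
    raw = feat.raw_feature_matrix(epoch_set, window_ms, channels, factor)
    return float(
        cross_validate("single", [raw], epoch_set.labels, scheme, sigma=sigma, C=C).mean()
    )


# ---------------------------------------------------------------------------
# Voting fast path: per-subject fold predictions, reusable across subsets
# ---------------------------------------------------------------------------

@dataclass
class _VotingCache:
    """Per repeat x fold: test indices, per-subject votes, per-subject weights."""

    folds: list[tuple[np.ndarray, np.ndarray, np.ndarray]]  # (test_idx, votes m x t, weights m)
    labels: np.ndarray


def _voting_cache(
    mats: Sequence[np.ndarray],
    y: np.ndarray,
    scheme: CVScheme,
    normalize_mode: str = "fold",
    sigma: float = fusion.DEFAULT_SIGMA,
    C: float = fusion.DEFAULT_C,
) -> _VotingCache:
    folds = []
    for layout in scheme.split(y):
        for tr, te in layout:
            Xtr, Xte = _normalize_fold(mats, tr, te, normalize_mode)
            votes = np.empty((len(mats), te.size), dtype=int)
            weights = np.empty(len(mats))
            for s in range(len(mats)):
                clf = fusion.train_subject(Xtr[s], y[tr], sigma=sigma, C=C)
                votes[s] = clf.predict(Xte[s])
                weights[s] = clf.training_accuracy
            folds.append((te, votes, weights))
    return _VotingCache(folds, y)


def _voting_accuracy_for_subset(cache: _VotingCache, subset: np.ndarray) -> float:
    correct = total = 0
    for te, votes, weights in cache.folds:
        pred = fusion.predict_vote_from_labels(votes[subset], weights[subset])
        correct += int(np.sum(pred == cache.labels[te]))
        total += te.size
    return correct / total


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def subject_sweep(
    per_subject_raw: Sequence[np.ndarray],
    labels: Sequence[int],
    n_range: Iterable[int] | None = None,
    resamples: int = 500,
    methods: Sequence[str] = ("averaging", "concatenating", "voting"),
    scheme: CVScheme | None = None,
    seed: int = 0,
    normalize_mode: str = "fold",
) -> dict[str, AccuracyCurve]:
    """Accuracy versus number of collaborating subjects.

    For each ``n`` in ``n_range``, ``resamples`` subject subsets are drawn
    uniformly without replacement *within* a subset (subsets may repeat
    across draws — for small ``n`` fewer distinct subsets exist than draws).
    Each draw uses its own fold layout, so the spread at ``n = N`` reflects
    cross-validation variability; each draw's value is that subset's mean CV
    accuracy. All methods share subsets and fold layouts, making method
    comparisons paired.
    """
    mats = [np.asarray(m, dtype=float) for m in per_subject_raw]
    y = np.asarray(labels, dtype=int)
    N = len(mats)
    ns = np.array(sorted(n_range) if n_range is not None else range(1, N + 1))
    if ns.max() > N or ns.min() < 1:
        raise ValueError(f"subject counts must lie in 1..{N}, got {ns.min()}..{ns.max()}")
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    for m in methods:
        if m not in ("single", "averaging", "concatenating", "voting"):
            raise ValueError(f"unknown method {m!r}")
    scheme = scheme or CVScheme(repeats=1)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5B)))
    samples: dict[str, list[list[float]]] = {m: [[] for _ in ns] for m in methods}
    for r in range(resamples):
        layout_seed = int(
            np.random.SeedSequence((seed, 0xF01D, r)).generate_state(1)[0] % (2**31)
        )
        scheme_r = CVScheme(scheme.repeats, scheme.folds, scheme.stratified, layout_seed)
        cache = (
            _voting_cache(mats, y, scheme_r, normalize_mode)
            if "voting" in methods
            else None
        )
        for j, n in enumerate(ns):
            subset = np.sort(rng.choice(N, size=int(n), replace=False))
            for m in methods:
                if m == "voting":
                    acc = _voting_accuracy_for_subset(cache, subset)
                elif m == "single":
                    acc = float(
                        cross_validate(
                            "single", [mats[subset[0]]], y, scheme_r,
                            normalize_mode,
                        ).mean()
                    )
                else:
                    acc = float(
                        cross_validate(
                            m, [mats[s] for s in subset], y, scheme_r, normalize_mode
                        ).mean()
                    )
                samples[m][j].append(acc)
    return {
        m: AccuracyCurve(
            ns.astype(int),
            [np.asarray(v) for v in samples[m]],
            method=m,
            x_name="n_subjects",
        )
        for m in methods
    }


def window_sweep(
    cohort: Sequence[feat.EpochSet],
    offsets_ms: Iterable[float] | None = None,
    subject_counts: Sequence[int] = (1, 5, 10, 15, 20),
    method: str = "voting",
    resamples: int = 20,
    scheme: CVScheme | None = None,
    seed: int = 0,
    factor: int = 5,
    reference_rt_ms: float = DEFAULT_REFERENCE_RT_MS,
) -> dict[int, AccuracyCurve]:
    """Accuracy versus analysis-window offset, for several ensemble sizes.

    Windows all start at cue onset (0 ms) and end at each offset; by default
    the offsets run from 100 to 500 ms in 10 ms steps. One fold layout (from
    ``scheme.seed``) and one set of subject subsets per count are shared
    across offsets, so curves are paired along the x-axis. The overt manual
    reaction time is attached as plot metadata, never computed.
    """
    if method != "voting":
        raise ValueError("window_sweep currently supports the voting method only")
    offsets = np.array(
        sorted(offsets_ms) if offsets_ms is not None else np.arange(100.0, 500.1, 10.0)
    )
    N = len(cohort)
    if max(subject_counts) > N:
        raise ValueError(f"subject_counts up to {max(subject_counts)} but cohort has {N}")
    epoch_end = cohort[0].times_ms[-1]
    if offsets.max() > epoch_end + 1e-9:
        raise feat.WindowError(
            f"offset {offsets.max()} ms beyond epoch end {epoch_end:.1f} ms"
        )
    scheme = scheme or CVScheme(repeats=1)
    y = cohort[0].labels
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x77D0)))
    subsets = {
        n: [np.sort(rng.choice(N, size=n, replace=False)) for _ in range(resamples)]
        for n in subject_counts
    }
    curves: dict[int, list[list[float]]] = {n: [] for n in subject_counts}
    for off in offsets:
        mats = [
            feat.raw_feature_matrix(es, (0.0, float(off)), factor=factor)
            for es in cohort
        ]
        cache = _voting_cache(mats, y, scheme)
        for n in subject_counts:
            accs = [_voting_accuracy_for_subset(cache, sub) for sub in subsets[n]]
            curves[n].append(accs)
    return {
        n: AccuracyCurve(
            offsets,
            [np.asarray(v) for v in curves[n]],
            method=method,
            x_name="window_offset_ms",
            meta={"n_subjects": n, "reference_rt_ms": reference_rt_ms},
        )
        for n in subject_counts
    }


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def summarize_stats(
    curve: AccuracyCurve,
    individual_samples: np.ndarray | None = None,
) -> dict:
    """One-way ANOVA over the swept levels plus per-level comparisons.

    The ANOVA tests the effect of the swept parameter (e.g. number of
    subjects) on accuracy across the resampled draws. If per-subject
    individual accuracies are given, each collaborative level is compared
    against them with a two-sample t-test. P-values are reported unadjusted.
    Note the resampled draws at different levels share underlying subjects
    and trials, so the independence assumptions of both tests are only
    approximate; the summary is descriptive.
    """
    groups = [np.asarray(s, dtype=float) for s in curve.samples]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 levels with >= 2 samples each")
    out: dict = {"x_name": curve.x_name, "levels": [int(x) for x in np.asarray(curve.x)]}
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        out["anova"] = {"flag": "degenerate: zero variance in every group"}
    else:
        F, p = sp_stats.f_oneway(*groups)
        df_between = len(groups) - 1
        df_within = sum(g.size for g in groups) - len(groups)
        out["anova"] = {"F": float(F), "p": float(p), "df": (df_between, df_within)}
    if individual_samples is not None:
        ind = np.asarray(individual_samples, dtype=float)
        tests = []
        for x, g in zip(out["levels"], groups):
            if np.ptp(g) == 0 and np.ptp(ind) == 0:
                tests.append({"x": x, "flag": "degenerate variance, test skipped"})
                continue
            t, p = sp_stats.ttest_ind(g, ind, equal_var=False)
            tests.append({"x": x, "t": float(t), "p": float(p),
                          "n_collab": int(g.size), "n_individual": int(ind.size)})
        out["t_tests_vs_individual"] = tests
    return out
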