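"""Single-subject classification and multi-subject fusion.

Three ways to combine single-trial information across subjects performing the
same task simultaneously:

* **averaging** — elementwise mean of the per-subject feature vectors of a
  trial, then one classifier (cross-subject ensemble averaging moved into
  feature space);
* **concatenating** — horizontal concatenation of the per-subject feature
  vectors, then one classifier (keeps all information, but feature dimension
  grows as ``m * k`` while the trial count stays fixed, inviting overfitting);
* **voting** — one RBF-SVM sub-classifier per subject, decisions fused by a
  weighted sign vote ``y = sign(sum_i w_i y_i)`` with the sub-classifier's
  training accuracy as its weight ``w_i``. Voting needs only per-subject
  decisions, never raw data from other subjects, so it is the one method that
  works in a distributed deployment.

The base classifier is a support vector machine with an RBF kernel
``K(u, v) = exp(-||u - v||^2 / (2 sigma^2))``, kernel scale ``sigma = 10``
(so scikit-learn's ``gamma = 1 / (2 sigma^2)``), regularization ``C = 1``.
Following the convention of the classic SVM toolboxes this setup mirrors,
each feature is standardized to zero mean and unit variance on the training
data before the kernel is applied (``autoscale``); with unit-variance
features the fixed kernel scale is well matched to ~50-dimensional inputs
and saturates as the concatenated dimension grows into the hundreds — the
overfitting regime that caps the concatenation method at large ensembles.
Labels are coded +1 (left) / -1 (right).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_SIGMA",
    "DEFAULT_C",
    "SubjectClassifier",
    "EnsembleModel",
    "train_subject",
    "fuse_average",
    "fuse_concat",
    "predict_vote",
    "vote_scores",
]

DEFAULT_SIGMA = 10.0
DEFAULT_C = 1.0


class AlignmentError(ValueError):
    """Per-subject inputs disagree in shape or trial alignment."""


class TrainingError(ValueError):
    """Classifier cannot be trained on the given data."""


def _gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma * sigma)


@dataclass
class SubjectClassifier:
    """A trained sub-classifier and its voting weight.

    ``training_accuracy`` — the fraction of its own training trials the
    fitted model re-predicts correctly — doubles as the voting weight, so a
    subject whose signal is barely decodable contributes less to the
    ensemble decision.
    """

    model: object  # fitted sklearn estimator (SVC or scaler+SVC pipeline)
    training_accuracy: float
    subject_id: str = ""
    sigma: float = DEFAULT_SIGMA
    C: float = DEFAULT_C
    autoscale: bool = True

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict(np.atleast_2d(features)).astype(int)

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        return self.model.decision_function(np.atleast_2d(features))


def train_subject(
    features: np.ndarray,
    labels: Sequence[int],
    sigma: float = DEFAULT_SIGMA,
    C: float = DEFAULT_C,
    subject_id: str = "",
    autoscale: bool = True,
) -> SubjectClassifier:
    """Fit the RBF-SVM for one subject and record its training accuracy.

    ``autoscale`` standardizes each feature on the training data before the
    kernel (the toolbox convention the fixed ``sigma`` belongs to); the
    scaler is part of the model, so test trials are scaled with training
    statistics only.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise TrainingError(
            f"features {X.shape} do not align with {y.size} labels"
        )
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainingError("training data contains a single class")
    if not set(classes).issubset({-1, 1}):
        raise TrainingError(f"labels must be coded +-1, got classes {classes}")
    svc = SVC(kernel="rbf", gamma=_gamma(sigma), C=C)
    model = make_pipeline(StandardScaler(), svc) if autoscale else svc
    model.fit(X, y)
    return SubjectClassifier(
        model, float(model.score(X, y)), subject_id, sigma, C, autoscale
    )


def _check_aligned(per_subject: Sequence[np.ndarray]) -> list[np.ndarray]:
    if len(per_subject) == 0:
        raise AlignmentError("need at least one subject")
    mats = [np.asarray(m, dtype=float) for m in per_subject]
    n_trials = {m.shape[0] for m in mats}
    if len(n_trials) != 1:
        raise AlignmentError(f"trial counts differ across subjects: {sorted(n_trials)}")
    return mats


def fuse_average(per_subject_features: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of aligned per-subject feature matrices (per trial)."""
    mats = _check_aligned(per_subject_features)
    widths = {m.shape[1] for m in mats}
    if len(widths) != 1:
        raise AlignmentError(f"feature widths differ across subjects: {sorted(widths)}")
    return np.mean(np.stack(mats, axis=0), axis=0)


def fuse_concat(per_subject_features: Sequence[np.ndarray]) -> np.ndarray:
    """Per-trial horizontal concatenation in fixed subject order."""
    mats = _check_aligned(per_subject_features)
    return np.hstack(mats)


@dataclass
class EnsembleModel:
    """Ordered sub-classifiers with nonnegative voting weights.

    Ties (vote score exactly zero) defer to the highest-weight
    sub-classifier's own decision; weight ties break by subject order.
    The rule is deterministic and needs no random state.
    """

    classifiers: list[SubjectClassifier]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.array(
                [c.training_accuracy for c in self.classifiers], dtype=float
            )
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != len(self.classifiers):
            raise AlignmentError("one weight per sub-classifier required")
        if np.any(self.weights < 0):
            raise ValueError("voting weights must be >= 0")

    def __len__(self) -> int:
        return len(self.classifiers)

    def predict(self, per_subject_features: Sequence[np.ndarray]) -> np.ndarray:
        """Weighted sign vote over the sub-classifiers' hard decisions."""
        if len(per_subject_features) != len(self.classifiers):
            raise AlignmentError(
                f"got features for {len(per_subject_features)} subjects, "
                f"ensemble has {len(self.classifiers)}"
            )
        votes = np.stack(
            [
                clf.predict(feats)
                for clf, feats in zip(self.classifiers, per_subject_features)
            ],
            axis=0,
        )  # m x trials
        return predict_vote_from_labels(votes, self.weights)


def vote_scores(votes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted vote score ``sum_i w_i y_i`` per trial (diagnostic)."""
    votes = np.atleast_2d(np.asarray(votes))
    weights = np.asarray(weights, dtype=float)
    if votes.shape[0] != weights.size:
        raise AlignmentError(
            f"{votes.shape[0]} vote rows vs {weights.size} weights"
        )
    return weights @ votes


def predict_vote_from_labels(votes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Fuse hard +-1 sub-decisions: ``sign(sum w_i y_i)`` with deterministic
    tie-break (highest-weight sub-classifier decides; weight ties by order)."""
    votes = np.atleast_2d(np.asarray(votes))
    scores = vote_scores(votes, weights)
    out = np.sign(scores).astype(int)
    ties = out == 0
    if np.any(ties):
        leader = int(np.argmax(weights))  # argmax takes the first maximum
        out[ties] = votes[leader, ties]
    return out


def predict_vote(
    ensemble: EnsembleModel, per_subject_features: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble decision and vote score for aligned per-subject features.

    Returns ``(labels, scores)``; each input element holds one subject's
    feature row(s) for the same trial(s).
    """
    if len(per_subject_features) != len(ensemble.classifiers):
        raise AlignmentError(
            f"got features for {len(per_subject_features)} subjects, "
            f"ensemble has {len(ensemble)}"
        )
    votes = np.stack(
        [
            clf.predict(feats)
            for clf, feats in zip(ensemble.classifiers, per_subject_features)
        ],
        axis=0,
    )
    scores = vote_scores(votes, ensemble.weights)
    return predict_vote_from_labels(votes, ensemble.weights), scores


def ensemble_summary(ensemble: EnsembleModel) -> dict:
    """JSON-ready description of an ensemble (weights, kernel settings).

    This is all a distributed deployment needs to share: per-subject
    decisions are fused from weights alone, never from raw features.
    """
    return {
        "n_subjects": len(ensemble),
        "subjects": [
            {
                "subject_id": c.subject_id,
                "training_accuracy": c.training_accuracy,
                "weight": float(w),
                "sigma": c.sigma,
                "C": c.C,
            }
            for c, w in zip(ensemble.classifiers, ensemble.weights)
        ],
    }
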