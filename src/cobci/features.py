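"""Single-trial ERP feature extraction.

Turns epoched EEG into the feature vectors used for left/right movement
decoding: per-trial baseline correction, selection of a post-cue analysis
window, block-mean downsampling (mean of five consecutive samples, no
overlap), per-timepoint min-max normalization to [-1, 1] across trials and
conditions, and concatenation of the two posterior-parietal channels into a
single vector.

Conventions
-----------
* Time is in milliseconds relative to direction-cue onset; the sample grid
  is ``t_k = k * 1000 / fs`` for integer ``k`` (0 ms is always on the grid).
* Analysis windows are half-open ``[onset, offset)``: a sample at time ``t``
  belongs to the window iff ``onset <= t < offset``.
* Condition labels are coded ``+1`` (left) and ``-1`` (right).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LABEL_LEFT",
    "LABEL_RIGHT",
    "Epoch",
    "EpochSet",
    "NormalizationStats",
    "baseline_correct",
    "downsample_mean",
    "fit_normalization",
    "apply_normalization",
    "extract_features",
    "epoch_grid",
]

LABEL_LEFT = 1
LABEL_RIGHT = -1


class WindowError(ValueError):
    """Requested time interval does not fit the epoch grid."""


class ProvenanceError(ValueError):
    """Normalization stats do not match the extraction they are applied to."""


def epoch_grid(window_ms: tuple[float, float], sampling_rate_hz: float) -> np.ndarray:
    """Sample times (ms) covering ``window_ms``, locked so that 0 ms is a sample.

    The grid extends to ``floor`` on the left and ``ceil`` on the right so the
    requested interval is fully contained.
    """
    if sampling_rate_hz <= 0:
        raise ValueError(f"sampling_rate_hz must be positive, got {sampling_rate_hz}")
    lo, hi = window_ms
    if hi <= lo:
        raise WindowError(f"empty epoch window {window_ms}")
    step = 1000.0 / sampling_rate_hz
    k0 = int(np.floor(lo / step))
    k1 = int(np.ceil(hi / step))
    return np.arange(k0, k1 + 1) * step


@dataclass
class Epoch:
    """One trial: a channels-by-samples matrix of EEG amplitudes in microvolts."""

    data: np.ndarray
    times_ms: np.ndarray
    label: int
    subject_id: str = ""
    trial_index: int = -1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        if self.data.shape[1] != self.times_ms.size:
            raise ValueError(
                f"data has {self.data.shape[1]} samples but times_ms has "
                f"{self.times_ms.size}"
            )
        d = np.diff(self.times_ms)
        if self.times_ms.size > 1 and not (np.all(d > 0) and np.allclose(d, d[0])):
            raise ValueError("times_ms must be strictly increasing and uniform")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class EpochSet:
    """Ordered collection of epochs from one subject on a shared grid."""

    epochs: list[Epoch]
    sampling_rate_hz: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.epochs:
            first = self.epochs[0]
            for ep in self.epochs:
                if ep.n_channels != len(self.channel_names):
                    raise ValueError("epoch channel count does not match channel_names")
                if ep.times_ms.shape != first.times_ms.shape or not np.array_equal(
                    ep.times_ms, first.times_ms
                ):
                    raise ValueError("all epochs must share one time grid")
                if ep.subject_id != first.subject_id:
                    raise ValueError("all epochs in a set must share subject_id")

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def subject_id(self) -> str:
        return self.epochs[0].subject_id if self.epochs else ""

    @property
    def times_ms(self) -> np.ndarray:
        return self.epochs[0].times_ms

    @property
    def labels(self) -> np.ndarray:
        return np.array([ep.label for ep in self.epochs], dtype=int)

    def to_array(self) -> np.ndarray:
        """Stack into channels x samples x trials."""
        return np.stack([ep.data for ep in self.epochs], axis=-1)

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        times_ms: np.ndarray,
        labels: Sequence[int],
        sampling_rate_hz: float,
        channel_names: Sequence[str],
        subject_id: str = "",
    ) -> "EpochSet":
        """Build from a channels x samples x trials array."""
        data = np.asarray(data, dtype=float)
        if data.ndim != 3:
            raise ValueError("expected channels x samples x trials array")
        epochs = [
            Epoch(data[:, :, i], times_ms, int(labels[i]), subject_id, i)
            for i in range(data.shape[2])
        ]
        return cls(epochs, sampling_rate_hz, list(channel_names))


def _window_mask(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    lo, hi = window_ms
    # tolerance absorbs float error in the ms grid (multiples of 1000/fs)
    eps = 1e-9
    return (times_ms >= lo - eps) & (times_ms < hi - eps)


def baseline_correct(epoch: Epoch, baseline_ms: tuple[float, float] = (-100.0, 0.0)) -> Epoch:
    """Subtract the per-channel mean over the baseline interval.

    The baseline window is half-open ``[start, stop)`` on the sample grid,
    conventionally the 100 ms preceding the direction cue.
    """
    lo, hi = baseline_ms
    eps = 1e-9
    if lo < epoch.times_ms[0] - eps or hi > epoch.times_ms[-1] + eps:
        raise WindowError(
            f"baseline {baseline_ms} outside epoch range "
            f"[{epoch.times_ms[0]:.2f}, {epoch.times_ms[-1]:.2f}] ms"
        )
    mask = _window_mask(epoch.times_ms, baseline_ms)
    if not mask.any():
        raise WindowError(f"baseline {baseline_ms} contains no samples")
    mean = epoch.data[:, mask].mean(axis=1, keepdims=True)
    return Epoch(
        epoch.data - mean, epoch.times_ms, epoch.label, epoch.subject_id, epoch.trial_index
    )


def downsample_mean(signal: np.ndarray, factor: int = 5) -> np.ndarray:
    """Block-mean downsampling: mean of ``factor`` consecutive samples, no overlap.

    Trailing samples that do not fill a complete block are dropped. Acts on the
    last axis. The factor-of-five default halves the effective bandwidth enough
    for ERP work (discriminative energy sits below 12 Hz at 256 Hz sampling)
    while cutting feature dimension five-fold.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1] // factor
    if n == 0:
        return signal[..., :0]
    trimmed = signal[..., : n * factor]
    return trimmed.reshape(*signal.shape[:-1], n, factor).mean(axis=-1)


@dataclass
class NormalizationStats:
    """Per-timepoint min/max of a training set, with extraction provenance.

    ``degenerate`` flags timepoints where max == min; those are mapped to 0
    rather than dividing by zero.
    """

    minimum: np.ndarray
    maximum: np.ndarray
    window_ms: tuple[float, float] | None = None
    channels: tuple[str, ...] | None = None
    factor: int | None = None
    degenerate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.maximum < self.minimum):
            raise ValueError("maximum must be >= minimum elementwise")
        self.degenerate = self.maximum == self.minimum


def fit_normalization(training_features_raw: np.ndarray, **provenance) -> NormalizationStats:
    """Per-timepoint range over all training trials, pooled across conditions.

    Scaling each timepoint to span [-1, 1] across the training trials puts
    every feature on a common scale regardless of absolute amplitude.
    """
    X = np.asarray(training_features_raw, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a trials x timepoints matrix with >= 2 trials")
    return NormalizationStats(X.min(axis=0), X.max(axis=0), **provenance)


def apply_normalization(features_raw: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Affine map sending the training min/max to -1/+1; degenerate points to 0."""
    X = np.asarray(features_raw, dtype=float)
    if X.shape[-1] != stats.minimum.size:
        raise ProvenanceError(
            f"feature width {X.shape[-1]} does not match stats width {stats.minimum.size}"
        )
    span = stats.maximum - stats.minimum
    safe = np.where(stats.degenerate, 1.0, span)
    out = 2.0 * (X - stats.minimum) / safe - 1.0
    return np.where(stats.degenerate, 0.0, out)


def raw_feature_matrix(
    epoch_set: EpochSet,
    window_ms: tuple[float, float],
    channels: Sequence[str] | None = None,
    factor: int = 5,
    baseline_ms: tuple[float, float] | None = (-100.0, 0.0),
) -> np.ndarray:
    """Un-normalized trials x features matrix (channel blocks concatenated).

    Ordering within a row is all downsampled points of the first channel,
    then all points of the second, and so on.
    """
    if channels is None:
        channels = epoch_set.channel_names
    missing = [c for c in channels if c not in epoch_set.channel_names]
    if missing:
        raise ValueError(f"unknown channels {missing}; have {epoch_set.channel_names}")
    idx = [epoch_set.channel_names.index(c) for c in channels]
    times = epoch_set.times_ms
    eps = 1e-9
    if window_ms[0] < times[0] - eps or window_ms[1] > times[-1] + 1000.0 / epoch_set.sampling_rate_hz:
        raise WindowError(f"window {window_ms} outside epoch range")
    mask = _window_mask(times, window_ms)
    rows = []
    for ep in epoch_set.epochs:
        if baseline_ms is not None:
            ep = baseline_correct(ep, baseline_ms)
        seg = ep.data[np.ix_(idx, np.flatnonzero(mask))]
        rows.append(downsample_mean(seg, factor).ravel())
    return np.asarray(rows)


def extract_features(
    epoch_set: EpochSet,
    window_ms: tuple[float, float],
    channels: Sequence[str] | None = None,
    factor: int = 5,
    stats: NormalizationStats | None = None,
    baseline_ms: tuple[float, float] | None = (-100.0, 0.0),
) -> tuple[np.ndarray, np.ndarray, NormalizationStats]:
    """Full feature pipeline for one subject's epochs.

    With ``stats=None`` (fit mode) the normalization range is computed from
    these epochs; otherwise ``stats`` must carry matching window/channel/factor
    provenance (guards against silently normalizing test trials with ranges
    from a different extraction).

    Returns ``(features, labels, stats)`` where ``features`` is trials x
    ``n_channels * floor(window_samples / factor)``.
    """
    if channels is None:
        channels = epoch_set.channel_names
    raw = raw_feature_matrix(epoch_set, window_ms, channels, factor, baseline_ms)
    if stats is None:
        stats = fit_normalization(
            raw, window_ms=tuple(window_ms), channels=tuple(channels), factor=factor
        )
    else:
        if (
            (stats.window_ms is not None and tuple(stats.window_ms) != tuple(window_ms))
            or (stats.channels is not None and tuple(stats.channels) != tuple(channels))
            or (stats.factor is not None and stats.factor != factor)
        ):
            raise ProvenanceError(
                f"stats fitted for window={stats.window_ms}, channels={stats.channels}, "
                f"factor={stats.factor}; requested window={tuple(window_ms)}, "
                f"channels={tuple(channels)}, factor={factor}"
            )
    return apply_normalization(raw, stats), epoch_set.labels, stats
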