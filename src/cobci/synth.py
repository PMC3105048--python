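"""Synthetic multi-subject ERP cohort generator.

Emulates the data a cue-guided reaching experiment produces: each simulated
subject has a pair of direction-selective ERP components over left/right
posterior parietal cortex (PPC) — contralateral-negative, ipsilateral-positive
— superimposed on autocorrelated background EEG. The generative model for a
single trial is

    x_ch(t) = gain * sum_n  a_n * C_n(t - tau_n) * w_{n, ch, cond}  +  noise(t)

where ``C_n`` is a Gaussian-windowed deflection, ``a_n`` a per-trial lognormal
amplitude (independent amplitude modulation), ``tau_n`` a per-trial Gaussian
latency jitter truncated at three standard deviations, ``w`` the signed
per-channel/per-condition gain implementing the lateralization, and ``noise``
zero-mean background activity (AR(1) by default, white or pink for
sensitivity checks).

All subjects of a cohort see the *same* trial/label sequence — the
collaborative setting where one stimulus stream drives every subject — while
amplitudes, jitters, and noise are drawn independently per subject.

Defaults mirror a two-component response peaking near 210 ms and 320 ms after
the direction cue, sampled at 256 Hz on epochs of [-100, 700] ms, 100 trials
per direction. The default cohort adds the individual differences real
cohorts show — per-subject shifts of component latency and amplitude, and
trial-to-trial fluctuation of background noise power (see
:func:`default_profiles`) — which is what makes cross-subject averaging
lossy and concatenated feature spaces hard to fit. Because real recordings
publish accuracies rather than signal-to-noise ratios, per-subject noise is
calibrated to a target single-trial decodability (see
:func:`calibrate_noise`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats

from .features import LABEL_LEFT, LABEL_RIGHT, Epoch, EpochSet, epoch_grid

__all__ = [
    "ERPComponent",
    "NoiseModel",
    "SubjectProfile",
    "SimConfig",
    "CalibrationReport",
    "simulate_trial",
    "simulate_cohort",
    "calibrate_noise",
    "default_components",
    "default_profiles",
    "calibrated_cohort",
    "design_session",
    "condition_labels",
]

CONDITIONS = ("left", "right")
LABEL_OF_CONDITION = {"left": LABEL_LEFT, "right": LABEL_RIGHT}


class ConditionError(ValueError):
    """Condition label outside the configured condition set."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class ERPComponent:
    """One Gaussian-windowed ERP deflection with trial-to-trial variability.

    ``channel_weights`` maps condition label -> per-channel signed gain; for
    the default direction components the *left* weights are the
    channel-swapped negation of the *right* weights (contralateral-negative /
    ipsilateral-positive symmetry).
    """

    peak_latency_ms: float
    width_ms: float  # full width at half maximum of the deflection
    amplitude_mean_uv: float
    amplitude_cv: float = 0.0
    latency_jitter_sd_ms: float = 0.0
    channel_weights: dict[str, np.ndarray] = field(default_factory=dict)
    shape_kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if self.latency_jitter_sd_ms < 0:
            raise ValueError("latency_jitter_sd_ms must be >= 0")
        self.channel_weights = {
            k: np.asarray(v, dtype=float) for k, v in self.channel_weights.items()
        }

    @property
    def sigma_ms(self) -> float:
        """Gaussian SD equivalent of the FWHM."""
        return self.width_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def waveform(self, times_ms: np.ndarray, latency_shift_ms: float = 0.0) -> np.ndarray:
        """Unit-amplitude deflection on the given time grid."""
        center = self.peak_latency_ms + latency_shift_ms
        return np.exp(-0.5 * ((times_ms - center) / self.sigma_ms) ** 2)


@dataclass
class NoiseModel:
    """Zero-mean background EEG model with marginal SD ``sd_uv``.

    ``ar1`` (the default elsewhere) is a lag-1 autoregressive process whose
    coefficient near 1 concentrates power at low frequencies, the dominant
    regime of background EEG; ``pink`` shapes white noise to a 1/f amplitude
    spectrum; ``white`` is flat.

    ``trial_scale_sd_log`` adds non-stationarity across trials: each epoch's
    noise is multiplied by a lognormal factor with mean 1 (log-SD as given),
    emulating the slow waxing and waning of background power (alpha bursts,
    vigilance drift) that makes single-trial EEG amplitudes heavy-tailed.
    Zero disables it.
    """

    kind: str = "ar1"
    sd_uv: float = 1.0
    ar_coefficient: float = 0.95
    trial_scale_sd_log: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "ar1", "pink"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd_uv < 0:
            raise ValueError("sd_uv must be >= 0")
        if self.kind == "ar1" and not (-1.0 < self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if self.trial_scale_sd_log < 0:
            raise ValueError("trial_scale_sd_log must be >= 0")

    def sample(self, rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
        """One epoch's noise: unit realization scaled by ``sd_uv`` and, when
        non-stationarity is on, by a per-epoch lognormal power factor."""
        if self.sd_uv == 0:
            return np.zeros(shape)
        scale = self.sd_uv
        if self.trial_scale_sd_log > 0:
            s = self.trial_scale_sd_log
            scale *= rng.lognormal(-s * s / 2.0, s)  # mean-1 modulation
        return scale * self.sample_unit(rng, shape)

    def sample_unit(self, rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
        """Unit-marginal-SD realization (so scaling by sd is exact and cheap)."""
        if self.kind == "white":
            return rng.standard_normal(shape)
        if self.kind == "ar1":
            phi = self.ar_coefficient
            innov_sd = math.sqrt(1.0 - phi * phi)
            eps = rng.standard_normal(shape)
            out = np.empty(shape)
            out[..., 0] = eps[..., 0]  # stationary start: marginal SD 1
            for t in range(1, shape[-1]):
                out[..., t] = phi * out[..., t - 1] + innov_sd * eps[..., t]
            return out
        # pink: shape a white spectrum by 1/sqrt(f), renormalize to unit SD
        n = shape[-1]
        white = rng.standard_normal(shape)
        spec = np.fft.rfft(white, axis=-1)
        freqs = np.fft.rfftfreq(n)
        scale = np.ones_like(freqs)
        scale[1:] = 1.0 / np.sqrt(freqs[1:])
        shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
        sd = shaped.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        return shaped / sd


@dataclass
class SubjectProfile:
    """Generative description of one simulated subject."""

    subject_id: str
    components: list[ERPComponent]
    noise: NoiseModel
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def template(self, times_ms: np.ndarray, condition: str, n_channels: int) -> np.ndarray:
        """Noise-free, jitter-free mean response (channels x samples)."""
        out = np.zeros((n_channels, times_ms.size))
        for comp in self.components:
            if condition not in comp.channel_weights:
                raise ConditionError(
                    f"component has no weights for condition {condition!r}"
                )
            w = comp.channel_weights[condition]
            if w.size != n_channels:
                raise ConfigError(
                    f"channel_weights length {w.size} != n_channels {n_channels}"
                )
            out += comp.amplitude_mean_uv * np.outer(w, comp.waveform(times_ms))
        return self.gain * out


@dataclass
class SimConfig:
    """Cohort-level simulation parameters."""

    n_subjects: int
    trials_per_condition: int = 100
    conditions: tuple[str, str] = CONDITIONS
    sampling_rate_hz: float = 256.0
    epoch_window_ms: tuple[float, float] = (-100.0, 700.0)
    n_channels: int = 2
    channel_names: tuple[str, ...] = ("PPC_L", "PPC_R")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.trials_per_condition < 1:
            raise ConfigError("trials_per_condition must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        lo, hi = self.epoch_window_ms
        if lo > -100.0 or hi < 700.0:
            raise ConfigError(
                "epoch_window_ms must contain the baseline [-100, 0] and the "
                "response-delay period [0, 700]"
            )
        if len(self.channel_names) != self.n_channels:
            raise ConfigError("channel_names length must equal n_channels")

    @property
    def times_ms(self) -> np.ndarray:
        return epoch_grid(self.epoch_window_ms, self.sampling_rate_hz)


def _draw_amplitude(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal amplitude with given mean and CV; the sign of the mean is kept."""
    if cv == 0 or mean == 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(abs(mean)) - sigma2 / 2.0
    return math.copysign(rng.lognormal(mu, math.sqrt(sigma2)), mean)


def _draw_latency_shift(rng: np.random.Generator, sd: float) -> float:
    """Gaussian jitter truncated at +-3 SD (keeps components inside the epoch)."""
    if sd == 0:
        return 0.0
    return float(
        sp_stats.truncnorm.rvs(-3.0, 3.0, loc=0.0, scale=sd, random_state=rng)
    )


def simulate_trial(
    profile: SubjectProfile,
    condition: str,
    rng: np.random.Generator,
    config: SimConfig | None = None,
    times_ms: np.ndarray | None = None,
) -> Epoch:
    """One trial from the generative model; deterministic given ``rng`` state."""
    config = config or SimConfig(n_subjects=1)
    if condition not in config.conditions:
        raise ConditionError(
            f"condition {condition!r} not in configured conditions {config.conditions}"
        )
    if times_ms is None:
        times_ms = config.times_ms
    signal = _trial_signal(profile, condition, rng, times_ms, config.n_channels)
    noise = profile.noise.sample(rng, (config.n_channels, times_ms.size))
    return Epoch(signal + noise, times_ms, LABEL_OF_CONDITION.get(condition, 0))


def _trial_signal(
    profile: SubjectProfile,
    condition: str,
    rng: np.random.Generator,
    times_ms: np.ndarray,
    n_channels: int,
) -> np.ndarray:
    out = np.zeros((n_channels, times_ms.size))
    for comp in _components_for(profile, condition):
        w = comp.channel_weights[condition]
        if w.size != n_channels:
            raise ConfigError(
                f"channel_weights length {w.size} != n_channels {n_channels}"
            )
        a = _draw_amplitude(rng, comp.amplitude_mean_uv, comp.amplitude_cv)
        tau = _draw_latency_shift(rng, comp.latency_jitter_sd_ms)
        out += a * np.outer(w, comp.waveform(times_ms, tau))
    return profile.gain * out


def _components_for(profile: SubjectProfile, condition: str) -> list[ERPComponent]:
    for comp in profile.components:
        if condition not in comp.channel_weights:
            raise ConditionError(f"component has no weights for condition {condition!r}")
    return profile.components


def _label_sequence(config: SimConfig, rng: np.random.Generator) -> list[str]:
    seq = [c for c in config.conditions for _ in range(config.trials_per_condition)]
    rng.shuffle(seq)
    return seq


def simulate_cohort(
    config: SimConfig,
    profiles: Sequence[SubjectProfile],
    conditions_seq: Sequence[str] | None = None,
) -> list[EpochSet]:
    """Simulate every subject on one shared, balanced trial sequence.

    The label sequence is drawn once from ``config.seed``; each subject gets an
    independent substream for amplitudes, jitters, and noise. Reproducible
    bit-for-bit from the config.
    """
    if len(profiles) != config.n_subjects:
        raise ConfigError(
            f"got {len(profiles)} profiles for n_subjects={config.n_subjects}"
        )
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ConfigError("subject_id values must be unique within a cohort")
    ss = np.random.SeedSequence(config.seed)
    label_child, *subject_children = ss.spawn(1 + len(profiles))
    if conditions_seq is None:
        conditions_seq = _label_sequence(config, np.random.default_rng(label_child))
    else:
        unknown = set(conditions_seq) - set(config.conditions)
        if unknown:
            raise ConditionError(f"unknown conditions in sequence: {sorted(unknown)}")
    times = config.times_ms
    cohort = []
    for profile, child in zip(profiles, subject_children):
        rng = np.random.default_rng(child)
        epochs = []
        for i, cond in enumerate(conditions_seq):
            sig = _trial_signal(profile, cond, rng, times, config.n_channels)
            noi = profile.noise.sample(rng, (config.n_channels, times.size))
            epochs.append(
                Epoch(sig + noi, times, LABEL_OF_CONDITION.get(cond, 0),
                      profile.subject_id, i)
            )
        cohort.append(EpochSet(epochs, config.sampling_rate_hz, list(config.channel_names)))
    return cohort


# ---------------------------------------------------------------------------
# Default cohort
# ---------------------------------------------------------------------------

def default_components(
    amp1_uv: float = 2.0,
    amp2_uv: float = 1.5,
    amplitude_cv: float = 0.3,
    jitter1_ms: float = 20.0,
    jitter2_ms: float = 25.0,
) -> list[ERPComponent]:
    """The two direction-selective PPC components (peaks 210 ms and 320 ms).

    Weights encode contralateral negativity: a *left* reach drives the right
    PPC negative and the left PPC positive, and vice versa, so *left* weights
    are the channel-swapped negation of *right* weights. Channel order is
    (PPC_L, PPC_R).
    """
    w = {"left": np.array([1.0, -1.0]), "right": np.array([-1.0, 1.0])}
    return [
        ERPComponent(210.0, 80.0, amp1_uv, amplitude_cv, jitter1_ms, dict(w)),
        ERPComponent(320.0, 90.0, amp2_uv, amplitude_cv, jitter2_ms, dict(w)),
    ]


def default_profiles(
    n_subjects: int,
    seed: int = 0,
    noise_sd_uv: float = 6.0,
    noise_kind: str = "ar1",
    gain_sd_log: float = 0.15,
    latency_between_sd_ms: float = 35.0,
    amplitude_between_sd_log: float = 0.4,
    noise_trial_scale_sd_log: float = 0.6,
) -> list[SubjectProfile]:
    """A heterogeneous cohort sharing the two-component response structure.

    Individual differences — the reason cross-subject averaging loses
    information while per-subject classifiers do not — enter three ways:

    * component peak latencies shift per subject (Gaussian, SD
      ``latency_between_sd_ms``, truncated at two SD so components stay
      inside the analysis window), the between-subject analogue of
      within-subject latency jitter;
    * component amplitudes scale per subject (lognormal,
      ``amplitude_between_sd_log``), on top of a subject-wide ``gain``;
    * background noise power waxes and wanes across trials
      (``noise_trial_scale_sd_log``), giving single-trial amplitudes the
      heavy tails of real EEG.

    The latency and amplitude spreads are in the range ERP studies report
    for inter-individual component variability (tens of ms, factor-of-two
    amplitudes).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
    profiles = []
    for i in range(n_subjects):
        gain = float(rng.lognormal(0.0, gain_sd_log))
        comps = default_components()
        for comp in comps:
            if latency_between_sd_ms > 0:
                shift = rng.normal(0.0, latency_between_sd_ms)
                bound = 2.0 * latency_between_sd_ms
                comp.peak_latency_ms += float(np.clip(shift, -bound, bound))
            if amplitude_between_sd_log > 0:
                comp.amplitude_mean_uv *= float(
                    rng.lognormal(0.0, amplitude_between_sd_log)
                )
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                components=comps,
                noise=NoiseModel(
                    kind=noise_kind,
                    sd_uv=noise_sd_uv,
                    trial_scale_sd_log=noise_trial_scale_sd_log,
                ),
                gain=gain,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Calibration to target decodability
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    """Outcome of a noise calibration run."""

    subject_id: str
    target_accuracy: float
    achieved_accuracy: float
    noise_sd_uv: float
    iterations: int
    converged: bool
    message: str = ""


def calibrate_noise(
    profile: SubjectProfile,
    target_accuracy: float,
    config: SimConfig | None = None,
    window_ms: tuple[float, float] = (0.0, 400.0),
    tolerance: float = 0.02,
    max_iterations: int = 25,
    cv_repeats: int = 2,
    seed: int = 0,
) -> tuple[SubjectProfile, CalibrationReport]:
    """Bisection on the noise SD so single-subject CV accuracy hits a target.

    The signal realization and a unit-SD noise realization are drawn once;
    only the noise scale changes between iterations, so accuracy is a
    deterministic, near-monotone function of the SD and bisection converges
    cleanly. Accuracy is measured with the standard single-subject pipeline
    (baseline correction, the given window, factor-5 block means, fold-wise
    normalization, RBF-SVM, repeated stratified 10-fold CV).

    An unattainable target (accuracy below target even at vanishing noise) is
    reported with ``converged=False``, never silently.
    """
    from .evaluate import CVScheme, single_subject_accuracy

    if not (0.5 < target_accuracy < 1.0):
        raise ValueError(
            f"target_accuracy must lie in (0.5, 1.0), got {target_accuracy}"
        )
    config = config or SimConfig(n_subjects=1, seed=seed)
    times = config.times_ms
    ss = np.random.SeedSequence((seed, 0xCA11))
    sig_child, noise_child, cv_child, label_child = ss.spawn(4)
    sig_rng = np.random.default_rng(sig_child)
    noise_rng = np.random.default_rng(noise_child)
    cv_ss = cv_child
    conds = _label_sequence(config, np.random.default_rng(label_child))
    labels = [LABEL_OF_CONDITION.get(c, 0) for c in conds]
    signals = np.stack(
        [_trial_signal(profile, c, sig_rng, times, config.n_channels) for c in conds],
        axis=-1,
    )
    # unit-SD noise including any trial-level power modulation, so accuracy is
    # an exactly scalable (and hence cleanly bisectable) function of the SD
    unit_model = replace(profile.noise, sd_uv=1.0)
    unit_noise = np.stack(
        [
            unit_model.sample(noise_rng, (config.n_channels, times.size))
            for _ in conds
        ],
        axis=-1,
    )
    scheme = CVScheme(repeats=cv_repeats, folds=10, seed=int(cv_ss.generate_state(1)[0] % (2**31)))

    def accuracy_at(sd: float) -> float:
        data = signals + sd * unit_noise
        es = EpochSet.from_array(
            data, times, labels, config.sampling_rate_hz,
            list(config.channel_names), profile.subject_id,
        )
        return single_subject_accuracy(es, window_ms=window_ms, scheme=scheme)

    lo_sd = 1e-3
    acc_lo = accuracy_at(lo_sd)
    iterations = 1
    if acc_lo < target_accuracy - tolerance:
        report = CalibrationReport(
            profile.subject_id, target_accuracy, acc_lo, lo_sd, iterations, False,
            "target unattainable: accuracy below target even at vanishing noise",
        )
        return replace(profile, noise=replace(profile.noise, sd_uv=lo_sd)), report

    hi_sd = max(profile.noise.sd_uv, 1.0)
    acc_hi = accuracy_at(hi_sd)
    iterations += 1
    while acc_hi > target_accuracy and hi_sd < 1e4:
        hi_sd *= 2.0
        acc_hi = accuracy_at(hi_sd)
        iterations += 1

    best_sd, best_acc = (lo_sd, acc_lo) if abs(acc_lo - target_accuracy) < abs(
        acc_hi - target_accuracy
    ) else (hi_sd, acc_hi)
    while iterations < max_iterations and abs(best_acc - target_accuracy) > tolerance:
        mid = math.sqrt(lo_sd * hi_sd)  # geometric: SD spans decades
        acc_mid = accuracy_at(mid)
        iterations += 1
        if abs(acc_mid - target_accuracy) < abs(best_acc - target_accuracy):
            best_sd, best_acc = mid, acc_mid
        if acc_mid > target_accuracy:
            lo_sd = mid
        else:
            hi_sd = mid

    converged = abs(best_acc - target_accuracy) <= tolerance
    report = CalibrationReport(
        profile.subject_id, target_accuracy, best_acc, best_sd, iterations, converged,
        "" if converged else "max_iterations reached outside tolerance",
    )
    return replace(profile, noise=replace(profile.noise, sd_uv=best_sd)), report


def calibrated_cohort(
    config: SimConfig,
    target_accuracies: Sequence[float] | None = None,
    tolerance: float = 0.02,
    cv_repeats: int = 2,
) -> tuple[list[EpochSet], list[SubjectProfile], list[CalibrationReport]]:
    """Default cohort with per-subject noise calibrated to target accuracies.

    Default targets are evenly spaced over [0.56, 0.76] (mean 0.66), matching
    the reported spread of single-trial decodability across subjects; the
    assignment of targets to subjects is shuffled by the config seed.
    """
    if target_accuracies is None:
        targets = np.linspace(0.56, 0.76, config.n_subjects)
        np.random.default_rng(np.random.SeedSequence((config.seed, 0x7A66))).shuffle(targets)
    else:
        targets = np.asarray(target_accuracies, dtype=float)
        if targets.size != config.n_subjects:
            raise ConfigError("need one target accuracy per subject")
    profiles = default_profiles(config.n_subjects, seed=config.seed)
    calibrated, reports = [], []
    for i, (profile, target) in enumerate(zip(profiles, targets)):
        # process-stable per-subject seed (never Python's randomized hash())
        sub_seed = int(
            np.random.SeedSequence((config.seed, 0xCA1B, i)).generate_state(1)[0]
            % (2**31)
        )
        prof, rep = calibrate_noise(
            profile, float(target), config=config, tolerance=tolerance,
            cv_repeats=cv_repeats, seed=sub_seed,
        )
        calibrated.append(prof)
        reports.append(rep)
    cohort = simulate_cohort(config, calibrated)
    return cohort, calibrated, reports


# ---------------------------------------------------------------------------
# Session design (task bookkeeping)
# ---------------------------------------------------------------------------

EFFECTORS = ("hand", "eye", "both")
DIRECTIONS = ("left", "right", "center")


def design_session(
    n_trials: int = 900, seed: int = 0
) -> list[tuple[str, str]]:
    """Pseudorandom session of (effector, direction) tasks, balanced over the
    nine effector x direction combinations (100 each at the 900-trial default)."""
    if n_trials % (len(EFFECTORS) * len(DIRECTIONS)) != 0:
        raise ConfigError(
            f"n_trials must be a multiple of {len(EFFECTORS) * len(DIRECTIONS)}"
        )
    per_task = n_trials // (len(EFFECTORS) * len(DIRECTIONS))
    tasks = [(e, d) for e in EFFECTORS for d in DIRECTIONS for _ in range(per_task)]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5E55)))
    rng.shuffle(tasks)
    return tasks


def condition_labels(
    session: Sequence[tuple[str, str]],
    effector: str = "hand",
    directions: tuple[str, str] = ("left", "right"),
) -> list[str]:
    """Filter a session to one effector's lateral trials, preserving order.

    The analysis conditions are the left/right trials of a single effector;
    center trials and other effectors are dropped.
    """
    return [d for e, d in session if e == effector and d in directions]
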