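"""Generative ERP simulator: trial model, cohort bookkeeping, reproducibility,
and calibration of noise to a target decodability."""

import numpy as np
import pytest

from cobci import synth
from cobci.features import LABEL_LEFT, LABEL_RIGHT


def _quiet_profile(**noise_kw):
    return synth.SubjectProfile(
        "s", synth.default_components(amplitude_cv=0.0, jitter1_ms=0.0, jitter2_ms=0.0),
        synth.NoiseModel(**noise_kw),
    )


class TestSimulateTrial:
    def test_zero_signal_gives_zero_mean_noise(self, rng):
        prof = synth.SubjectProfile(
            "s", synth.default_components(amp1_uv=0.0, amp2_uv=0.0),
            synth.NoiseModel(kind="white", sd_uv=2.0),
        )
        eps = [synth.simulate_trial(prof, "left", rng) for _ in range(400)]
        grand = np.mean([e.data for e in eps], axis=0)
        assert np.abs(grand).max() < 4 * 2.0 / np.sqrt(400)

    def test_noise_free_trial_is_deterministic_template(self, rng):
        prof = _quiet_profile(sd_uv=0.0)
        cfg = synth.SimConfig(n_subjects=1)
        a = synth.simulate_trial(prof, "left", rng, cfg)
        b = synth.simulate_trial(prof, "left", rng, cfg)
        template = prof.template(cfg.times_ms, "left", 2)
        assert np.array_equal(a.data, b.data)
        assert np.allclose(a.data, template)

    def test_unknown_condition_raises(self, rng):
        with pytest.raises(synth.ConditionError):
            synth.simulate_trial(_quiet_profile(sd_uv=0.0), "up", rng)

    def test_negative_sampling_rate_rejected(self):
        with pytest.raises(synth.ConfigError):
            synth.SimConfig(n_subjects=1, sampling_rate_hz=-5.0)

    def test_condition_symmetry_of_templates(self):
        # lateralized weights: the left template is both the negation and the
        # channel swap of the right template (so swap+negate is the identity)
        prof = _quiet_profile(sd_uv=0.0)
        t = synth.SimConfig(n_subjects=1).times_ms
        left = prof.template(t, "left", 2)
        right = prof.template(t, "right", 2)
        assert np.allclose(left, -right)
        assert np.allclose(left, right[::-1, :])

    def test_difference_wave_extrema_near_configured_peaks(self):
        """Grand average of jittered trials peaks within +-10 ms of 210/320."""
        prof = synth.SubjectProfile(
            "s", synth.default_components(), synth.NoiseModel(kind="white", sd_uv=1.0)
        )
        cfg = synth.SimConfig(n_subjects=1)
        rng = np.random.default_rng(7)
        t = cfg.times_ms
        left = np.mean(
            [synth.simulate_trial(prof, "left", rng, cfg).data for _ in range(200)],
            axis=0,
        )
        right = np.mean(
            [synth.simulate_trial(prof, "right", rng, cfg).data for _ in range(200)],
            axis=0,
        )
        diff = (left - right)[0]  # PPC_L difference wave, two positive bumps
        # jitter-free oracle: analytic two-Gaussian sum on the same grid
        oracle = prof.template(t, "left", 2)[0] - prof.template(t, "right", 2)[0]
        for peak_ms in (210.0, 320.0):
            zone = (t > peak_ms - 60) & (t < peak_ms + 60)
            assert abs(t[zone][np.argmax(oracle[zone])] - peak_ms) <= 4.0
            assert abs(t[zone][np.argmax(diff[zone])] - peak_ms) <= 10.0

    def test_latency_jitter_bounded_at_three_sd(self, rng):
        shifts = [synth._draw_latency_shift(rng, 10.0) for _ in range(2000)]
        assert max(np.abs(shifts)) <= 30.0 + 1e-9
        assert np.std(shifts) == pytest.approx(10.0, rel=0.15)

    def test_lognormal_amplitude_moments(self, rng):
        draws = [synth._draw_amplitude(rng, -2.0, 0.5) for _ in range(20_000)]
        draws = np.asarray(draws)
        assert np.all(draws < 0)  # sign of the mean is kept
        assert draws.mean() == pytest.approx(-2.0, rel=0.03)
        assert draws.std() / abs(draws.mean()) == pytest.approx(0.5, rel=0.05)


class TestNoiseModel:
    @pytest.mark.parametrize("kind", ["white", "ar1", "pink"])
    def test_marginal_sd_and_zero_mean(self, kind, rng):
        nm = synth.NoiseModel(kind=kind, sd_uv=3.0)
        x = nm.sample(rng, (4, 20_000))
        assert abs(x.mean()) < 0.15
        assert x.std() == pytest.approx(3.0, rel=0.1)

    def test_ar1_autocorrelation(self, rng):
        nm = synth.NoiseModel(kind="ar1", sd_uv=1.0, ar_coefficient=0.95)
        x = nm.sample(rng, (1, 50_000))[0]
        rho = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert rho == pytest.approx(0.95, abs=0.02)

    def test_trial_scale_modulation_preserves_mean_power(self, rng):
        nm = synth.NoiseModel(kind="white", sd_uv=2.0, trial_scale_sd_log=0.6)
        vars_ = [nm.sample(rng, (1, 500)).var() for _ in range(2000)]
        # lognormal(mean 1) scale on the SD => E[var] = sd^2 * E[scale^2]
        expected = 4.0 * np.exp(0.6**2)
        assert np.mean(vars_) == pytest.approx(expected, rel=0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            synth.NoiseModel(kind="blue")
        with pytest.raises(ValueError):
            synth.NoiseModel(kind="ar1", ar_coefficient=1.5)
        with pytest.raises(ValueError):
            synth.NoiseModel(sd_uv=-1.0)


class TestSimulateCohort:
    def test_counts_single_subject(self):
        cfg = synth.SimConfig(n_subjects=1, trials_per_condition=5, seed=3)
        (es,) = synth.simulate_cohort(cfg, synth.default_profiles(1, seed=3))
        assert len(es) == 10
        assert np.sum(es.labels == LABEL_LEFT) == 5
        assert np.sum(es.labels == LABEL_RIGHT) == 5

    def test_shared_labels_independent_noise(self):
        cfg = synth.SimConfig(n_subjects=2, trials_per_condition=25, seed=9)
        # white noise keeps the correlation estimator's variance ~1/sqrt(N);
        # signal amplitudes zeroed so only noise remains
        profiles = synth.default_profiles(
            2, seed=9, latency_between_sd_ms=0.0, amplitude_between_sd_log=0.0,
            noise_kind="white", noise_trial_scale_sd_log=0.0,
        )
        for p in profiles:
            for c in p.components:
                c.amplitude_mean_uv = 0.0
        a, b = synth.simulate_cohort(cfg, profiles)
        assert np.array_equal(a.labels, b.labels)
        xa = a.to_array().ravel()
        xb = b.to_array().ravel()
        assert xa.size > 10_000
        assert abs(np.corrcoef(xa, xb)[0, 1]) < 0.05

    def test_seed_reproducibility_bit_identical(self):
        cfg = synth.SimConfig(n_subjects=2, trials_per_condition=5, seed=77)
        run = lambda: synth.simulate_cohort(cfg, synth.default_profiles(2, seed=77))
        for x, y in zip(run(), run()):
            assert np.array_equal(x.to_array(), y.to_array())
            assert np.array_equal(x.labels, y.labels)

    def test_profile_count_mismatch_raises(self):
        cfg = synth.SimConfig(n_subjects=2)
        with pytest.raises(synth.ConfigError):
            synth.simulate_cohort(cfg, synth.default_profiles(3))

    def test_template_recovery_with_noise(self):
        """Mean of N deterministic-signal epochs -> template at O(sd/sqrt(N))."""
        prof = _quiet_profile(kind="white", sd_uv=2.0)
        cfg = synth.SimConfig(n_subjects=1, trials_per_condition=500, seed=5)
        (es,) = synth.simulate_cohort(cfg, [prof])
        left = es.to_array()[:, :, es.labels == LABEL_LEFT]
        template = prof.template(cfg.times_ms, "left", 2)
        err = left.mean(axis=-1) - template
        n = left.shape[-1]
        assert np.sqrt((err**2).mean()) < 3 * 2.0 / np.sqrt(n)


class TestCalibration:
    def test_near_perfect_target_converges_at_small_sd(self):
        prof = _quiet_profile(sd_uv=1.0)
        cfg = synth.SimConfig(n_subjects=1, trials_per_condition=30)
        out, rep = synth.calibrate_noise(prof, 0.999, config=cfg, tolerance=0.005, seed=1)
        assert rep.converged
        assert out.noise.sd_uv < 1.0

    def test_boundary_target_rejected(self):
        with pytest.raises(ValueError):
            synth.calibrate_noise(_quiet_profile(sd_uv=1.0), 0.50)

    def test_unattainable_target_flagged_not_silent(self):
        # no signal at all: accuracy stays at chance for any noise level
        prof = synth.SubjectProfile(
            "s", synth.default_components(amp1_uv=0.0, amp2_uv=0.0),
            synth.NoiseModel(kind="white", sd_uv=1.0),
        )
        cfg = synth.SimConfig(n_subjects=1, trials_per_condition=20)
        _, rep = synth.calibrate_noise(prof, 0.95, config=cfg, seed=2)
        assert not rep.converged
        assert "unattainable" in rep.message

    def test_hits_typical_target_within_tolerance(self):
        prof = synth.default_profiles(1, seed=6)[0]
        cfg = synth.SimConfig(n_subjects=1, trials_per_condition=100)
        _, rep = synth.calibrate_noise(prof, 0.66, config=cfg, tolerance=0.02, seed=6)
        assert rep.converged
        assert abs(rep.achieved_accuracy - 0.66) <= 0.02


class TestSessionDesign:
    def test_balanced_nine_task_design(self):
        session = synth.design_session(900, seed=0)
        assert len(session) == 900
        from collections import Counter

        counts = Counter(session)
        assert len(counts) == 9
        assert all(v == 100 for v in counts.values())

    def test_non_multiple_rejected(self):
        with pytest.raises(synth.ConfigError):
            synth.design_session(901)

    def test_hand_direction_filter(self):
        session = synth.design_session(900, seed=0)
        conds = synth.condition_labels(session, "hand")
        assert len(conds) == 200
        assert conds.count("left") == 100 and conds.count("right") == 100
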