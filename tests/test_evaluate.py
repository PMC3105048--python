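"""Cross-validation hygiene, sweep bookkeeping, and statistical summaries."""

import numpy as np
import pytest

from cobci import evaluate, features as feat, fusion, synth


@pytest.fixture(scope="module")
def toy_features(rng_seed=0):
    """Four 'subjects' with weakly informative Gaussian features, 60 trials."""
    rng = np.random.default_rng(21)
    y = rng.permutation(np.r_[np.ones(30), -np.ones(30)]).astype(int)
    mats = [rng.normal(size=(60, 10)) + 0.4 * y[:, None] for _ in range(4)]
    return mats, y


class TestCVScheme:
    def test_folds_partition_trials_exactly(self):
        y = np.r_[np.ones(25), -np.ones(25)].astype(int)
        scheme = evaluate.CVScheme(repeats=3, folds=5, seed=2)
        for layout in scheme.split(y):
            seen = np.concatenate([te for _, te in layout])
            assert np.array_equal(np.sort(seen), np.arange(50))
            for tr, te in layout:
                assert np.intersect1d(tr, te).size == 0

    def test_stratified_balance_within_one(self):
        y = np.r_[np.ones(30), -np.ones(30)].astype(int)
        for layout in evaluate.CVScheme(repeats=2, folds=10, seed=0).split(y):
            for _, te in layout:
                pos = np.sum(y[te] == 1)
                assert abs(pos - (te.size - pos)) <= 1

    def test_too_few_per_class_raises(self):
        y = np.r_[np.ones(4), -np.ones(40)].astype(int)
        with pytest.raises(evaluate.StratificationError):
            evaluate.CVScheme(repeats=1, folds=10).split(y)

    def test_same_seed_same_layout(self):
        y = np.r_[np.ones(20), -np.ones(20)].astype(int)
        a = evaluate.CVScheme(repeats=2, folds=4, seed=5).split(y)
        b = evaluate.CVScheme(repeats=2, folds=4, seed=5).split(y)
        for la, lb in zip(a, b):
            for (tra, tea), (trb, teb) in zip(la, lb):
                assert np.array_equal(tra, trb) and np.array_equal(tea, teb)


class TestCrossValidate:
    def test_separable_data_gives_perfect_folds(self):
        rng = np.random.default_rng(4)
        y = rng.permutation(np.r_[np.ones(30), -np.ones(30)]).astype(int)
        X = np.zeros((60, 4)) + 5.0 * y[:, None] + rng.normal(size=(60, 4)) * 0.1
        acc = evaluate.cross_validate(
            "single", [X], y, evaluate.CVScheme(repeats=2, folds=5, seed=1)
        )
        assert np.all(acc == 1.0)

    @pytest.mark.parametrize("method", ["averaging", "concatenating", "voting"])
    def test_shuffled_labels_stay_at_chance(self, toy_features, method):
        mats, y = toy_features
        y_shuf = np.random.default_rng(5).permutation(y)
        acc = evaluate.cross_validate(
            method, mats, y_shuf, evaluate.CVScheme(repeats=2, folds=10, seed=3)
        )
        assert abs(acc.mean() - 0.5) < 1.96 * np.sqrt(0.25 / 60)

    def test_single_member_voting_equals_single_pipeline(self, toy_features):
        mats, y = toy_features
        scheme = evaluate.CVScheme(repeats=2, folds=5, seed=7)
        a = evaluate.cross_validate("voting", [mats[0]], y, scheme)
        b = evaluate.cross_validate("single", [mats[0]], y, scheme)
        assert np.array_equal(a, b)

    def test_averaging_and_concat_beat_single_on_independent_subjects(self, toy_features):
        mats, y = toy_features
        scheme = evaluate.CVScheme(repeats=1, folds=5, seed=7)
        single = evaluate.cross_validate("single", [mats[0]], y, scheme).mean()
        for method in ("averaging", "concatenating", "voting"):
            fused = evaluate.cross_validate(method, mats, y, scheme).mean()
            assert fused > single - 0.05

    def test_unknown_method_rejected(self, toy_features):
        mats, y = toy_features
        with pytest.raises(ValueError):
            evaluate.cross_validate("stacking", mats, y)

    def test_misaligned_subjects_rejected(self, toy_features):
        mats, y = toy_features
        with pytest.raises(fusion.AlignmentError):
            evaluate.cross_validate("voting", [mats[0], mats[1][:-1]], y)


class TestSubjectSweep:
    def test_n_equal_cohort_size_draws_are_degenerate(self, toy_features):
        mats, y = toy_features
        curves = evaluate.subject_sweep(
            mats, y, n_range=[4], resamples=4, methods=("voting",),
            scheme=evaluate.CVScheme(repeats=1, folds=5), seed=0,
        )
        c = curves["voting"]
        # all draws pick the full cohort; spread comes from fold layouts only
        assert c.n_resamples[0] == 4
        assert c.sd[0] < 0.1

    def test_n1_samples_come_from_single_subject_distribution(self, toy_features):
        mats, y = toy_features
        seed = 13
        curves = evaluate.subject_sweep(
            mats, y, n_range=[1], resamples=6, methods=("voting",),
            scheme=evaluate.CVScheme(repeats=1, folds=5), seed=seed,
        )
        sampled = set(np.round(curves["voting"].samples[0], 10))
        # all single-subject accuracies under the same per-draw layouts
        possible = set()
        for r in range(6):
            layout_seed = int(
                np.random.SeedSequence((seed, 0xF01D, r)).generate_state(1)[0]
                % (2**31)
            )
            scheme_r = evaluate.CVScheme(1, 5, True, layout_seed)
            for m in mats:
                possible.add(
                    round(float(evaluate.cross_validate("single", [m], y, scheme_r).mean()), 10)
                )
        assert sampled <= possible

    def test_out_of_range_n_rejected(self, toy_features):
        mats, y = toy_features
        with pytest.raises(ValueError):
            evaluate.subject_sweep(mats, y, n_range=[5], resamples=1)

    def test_curve_frame_layout(self, toy_features):
        mats, y = toy_features
        curves = evaluate.subject_sweep(
            mats, y, n_range=[1, 2], resamples=3,
            methods=("averaging", "voting"),
            scheme=evaluate.CVScheme(repeats=1, folds=5), seed=1,
        )
        frame = curves["voting"].to_frame()
        assert list(frame["n_subjects"]) == [1, 2]
        assert set(frame.columns) >= {"method", "mean_accuracy", "sd_accuracy"}


class TestWindowSweep:
    @pytest.fixture(scope="class")
    def mini_cohort(self):
        cfg = synth.SimConfig(n_subjects=3, trials_per_condition=30, seed=15)
        profiles = synth.default_profiles(3, seed=15, noise_sd_uv=3.0)
        return synth.simulate_cohort(cfg, profiles)

    def test_pre_component_windows_sit_at_chance(self, mini_cohort):
        curves = evaluate.window_sweep(
            mini_cohort, offsets_ms=[100.0], subject_counts=[3], resamples=2,
            scheme=evaluate.CVScheme(repeats=1, folds=5), seed=0,
        )
        # components peak at/after ~210 ms: a [0,100) window carries no signal
        assert abs(curves[3].mean[0] - 0.5) < 0.2

    def test_information_grows_with_window_length(self, mini_cohort):
        curves = evaluate.window_sweep(
            mini_cohort, offsets_ms=[150.0, 500.0], subject_counts=[3], resamples=3,
            scheme=evaluate.CVScheme(repeats=1, folds=5), seed=0,
        )
        assert curves[3].mean[1] >= curves[3].mean[0]
        assert curves[3].meta["reference_rt_ms"] == 464.0

    def test_offset_past_epoch_end_raises(self, mini_cohort):
        with pytest.raises(feat.WindowError):
            evaluate.window_sweep(mini_cohort, offsets_ms=[900.0], subject_counts=[1])


class TestSummarizeStats:
    def _curve(self, samples_by_x):
        xs = sorted(samples_by_x)
        return evaluate.AccuracyCurve(
            np.array(xs), [np.asarray(samples_by_x[x], dtype=float) for x in xs],
            method="voting", x_name="n_subjects",
        )

    def test_identical_constant_groups_flagged(self):
        curve = self._curve({1: [0.7] * 5, 2: [0.7] * 5})
        out = evaluate.summarize_stats(curve)
        assert "flag" in out["anova"]

    def test_separated_groups_give_tiny_p(self, rng):
        curve = self._curve(
            {1: rng.normal(0.6, 0.005, 50), 2: rng.normal(0.9, 0.005, 50)}
        )
        out = evaluate.summarize_stats(curve, individual_samples=rng.normal(0.6, 0.005, 20))
        assert out["anova"]["p"] < 1e-12
        assert out["t_tests_vs_individual"][1]["p"] < 1e-12

    def test_null_type_one_error_rate(self, rng):
        """The per-level comparison rejects ~5% of true nulls at alpha=0.05."""
        reps = 2000
        hits = 0
        for _ in range(reps):
            curve = self._curve({1: rng.normal(0.7, 0.05, 20), 2: rng.normal(0.7, 0.05, 20)})
            out = evaluate.summarize_stats(curve, individual_samples=rng.normal(0.7, 0.05, 20))
            hits += out["t_tests_vs_individual"][0]["p"] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.015)

    def test_requires_two_levels(self):
        with pytest.raises(ValueError):
            evaluate.summarize_stats(self._curve({1: [0.5, 0.6]}))
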