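"""Decoding-engine contracts: the min-max normalization rules, sub-sampling
schedule, max-margin classification against a brute-force oracle,
leave-one-run-out structure and leakage guards, null calibration and
signal-ordering properties."""

import warnings

import numpy as np
import pytest

from v1facedecode import mvpa


def _patterns(betas, labels, runs, **kw):
    return mvpa.TrialPatternSet(betas=np.asarray(betas, float), labels=np.asarray(labels), run_ids=np.asarray(runs), **kw)


class TestNormalizer:
    def test_minmax_formula(self):
        params = mvpa.fit_normalizer(np.array([[2.0], [4.0], [6.0]]))
        out = params.transform(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_feature_maps_to_zero(self):
        params = mvpa.fit_normalizer(np.array([[5.0, 1.0], [5.0, 3.0]]))
        out = params.transform(np.array([[5.0, 2.0], [99.0, 3.0]]))
        assert np.all(out[:, 0] == 0.0)

    def test_training_extrema_map_to_unit_interval(self, rng):
        X = rng.normal(size=(40, 7))
        params = mvpa.fit_normalizer(X)
        Z = params.transform(X)
        assert np.allclose(Z.max(axis=0), 1.0)
        assert np.allclose(Z.min(axis=0), -1.0)

    def test_test_data_uses_training_parameters(self):
        params = mvpa.fit_normalizer(np.array([[0.0], [2.0]]))
        assert params.transform(np.array([[2.0]]))[0, 0] == pytest.approx(1.0)
        # train min minus one range -> -3 by affine arithmetic
        assert params.transform(np.array([[-2.0]]))[0, 0] == pytest.approx(-3.0)

    def test_roundtrip_equals_fit_transform(self, rng):
        X = rng.normal(size=(10, 3))
        pats = _patterns(X, ["a"] * 5 + ["b"] * 5, [0] * 5 + [1] * 5)
        params = mvpa.fit_normalizer(pats)
        out = mvpa.apply_normalizer(params, pats)
        assert np.allclose(out.betas, params.transform(X))

    def test_feature_mismatch_rejected(self):
        params = mvpa.fit_normalizer(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="feature count"):
            params.transform(np.zeros((2, 4)))


class TestSubsampleSchedule:
    def test_default_schedule_spans_1_to_160(self):
        sizes = mvpa.subsample_schedule(160)
        assert sizes.size == 15
        assert sizes[0] == 1 and sizes[-1] == 160
        assert np.all(np.diff(sizes) > 0)

    def test_single_feature(self):
        assert list(mvpa.subsample_schedule(1)) == [1]

    def test_small_feature_count_warns_and_caps(self):
        with pytest.warns(UserWarning, match="distinct"):
            sizes = mvpa.subsample_schedule(9)
        assert sizes[-1] == 9 and np.all(np.diff(sizes) > 0)

    def test_cap_applies_above_160(self):
        assert mvpa.subsample_schedule(500)[-1] == 160


class TestDrawSubsets:
    def test_full_size_draws_everything(self):
        draws = mvpa.draw_subsets(6, 6, n_draws=5, seed=0)
        for d in draws:
            assert np.array_equal(d, np.arange(6))

    def test_default_thirty_draws_reproducible(self):
        a = mvpa.draw_subsets(50, 10, seed=7)
        b = mvpa.draw_subsets(50, 10, seed=7)
        assert len(a) == 30
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert all(np.unique(d).size == 10 for d in a)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            mvpa.draw_subsets(5, 6)


class TestLinearClassifier:
    def test_separated_points_classified(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        clf = mvpa.train_linear_classifier(X, np.array(["a", "b"]))
        assert list(clf.predict(X)) == ["a", "b"]

    def test_margin_matches_brute_force_oracle(self):
        """Maximum margin on a 2-D separable toy set against a grid search
        over unit normal directions."""
        X = np.array([[0.0, 0.0], [1.0, 0.2], [3.0, 3.0], [2.5, 4.0]])
        y = np.array([-1, -1, 1, 1])
        clf = mvpa.train_linear_classifier(X, y, cost=1e6)  # hard margin
        w = clf.coef_[0]
        svm_margin = 1.0 / np.linalg.norm(w)
        best = 0.0
        for theta in np.linspace(0, np.pi, 20001):
            u = np.array([np.cos(theta), np.sin(theta)])
            proj = X @ u
            m = (proj[y == 1].min() - proj[y == -1].max()) / 2.0
            best = max(best, m)
        assert svm_margin == pytest.approx(best, rel=1e-3)

    def test_duplicating_points_leaves_decision_unchanged(self, rng):
        """On separable data the max-margin solution is determined by the
        support set, so duplicating every training point changes nothing."""
        X = np.vstack([rng.normal(size=(5, 3)) - 3.0, rng.normal(size=(5, 3)) + 3.0])
        y = np.array([0] * 5 + [1] * 5)
        c1 = mvpa.train_linear_classifier(X, y, cost=1e6)
        c2 = mvpa.train_linear_classifier(np.vstack([X, X]), np.concatenate([y, y]), cost=1e6)
        assert np.allclose(c1.coef_, c2.coef_, atol=1e-6)
        assert np.allclose(c1.intercept_, c2.intercept_, atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            mvpa.train_linear_classifier(np.zeros((3, 2)), np.array(["a", "a", "a"]))


def _separable_set(n_runs=6, per_class=4, n_features=10, gap=5.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels, runs = [], [], []
    centers = {"a": np.full(n_features, -gap / 2), "b": np.full(n_features, gap / 2)}
    for r in range(n_runs):
        for c in ("a", "b"):
            for _ in range(per_class):
                rows.append(centers[c] + rng.normal(0, noise, n_features) if noise else centers[c])
                labels.append(c)
                runs.append(r)
    return _patterns(np.array(rows), labels, runs)


class TestLoroCv:
    def test_six_runs_six_folds_each_tested_once(self):
        res = mvpa.loro_cv(_separable_set())
        assert len(res.folds) == 6
        assert sorted(f.test_run for f in res.folds) == list(range(6))

    def test_no_run_leakage_and_normalization_from_training_only(self):
        pats = _separable_set(noise=1.0, seed=3)
        res = mvpa.loro_cv(pats)
        for fold in res.folds:
            assert fold.test_run not in fold.train_runs
            assert set(pats.run_ids[fold.train_rows]) == set(fold.train_runs)
            refit = mvpa.fit_normalizer(pats.betas[fold.train_rows])
            assert np.array_equal(fold.normalization.feature_min, refit.feature_min)
            assert np.array_equal(fold.normalization.feature_max, refit.feature_max)

    @pytest.mark.parametrize("mode", ["single_trial", "averaged"])
    def test_perfectly_separable_patterns_decode_fully(self, mode):
        res = mvpa.loro_cv(_separable_set(noise=0.5, seed=1), test_mode=mode)
        assert res.accuracy == 100.0

    def test_shuffled_label_null_near_chance(self):
        """Labels shuffled within run: mean accuracy over seeds within 3 SE
        of 50% for two classes."""
        accs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            pats = _separable_set(noise=1.0, gap=0.0, seed=seed)
            labels = pats.labels.copy()
            for r in range(6):
                rows = np.flatnonzero(pats.run_ids == r)
                labels[rows] = rng.permutation(labels[rows])
            shuffled = _patterns(pats.betas, labels, pats.run_ids)
            accs.append(mvpa.loro_cv(shuffled).accuracy)
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(accs.size)
        assert abs(accs.mean() - 50.0) < 3 * se

    def test_three_class_null_near_chance(self):
        accs = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            betas = rng.normal(size=(6 * 9, 8))
            labels = np.tile(np.repeat(["a", "b", "c"], 3), 6)
            runs = np.repeat(np.arange(6), 9)
            accs.append(mvpa.loro_cv(_patterns(betas, labels, runs)).accuracy)
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(accs.size)
        assert abs(accs.mean() - 100.0 / 3) < 3 * se

    def test_missing_class_in_training_skips_fold(self):
        betas = np.random.default_rng(0).normal(size=(6, 2))
        labels = np.array(["a", "b", "a", "a", "a", "a"])
        runs = np.array([0, 0, 1, 1, 2, 2])  # class b only in run 0
        with pytest.warns(UserWarning, match="skipped"):
            res = mvpa.loro_cv(_patterns(betas, labels, runs))
        # the fold holding out run 0 would train without class b, so it is
        # dropped; the other two folds remain
        assert sorted(f.test_run for f in res.folds) == [1, 2]

    def test_fewer_than_two_runs_rejected(self):
        pats = _patterns(np.zeros((4, 2)), ["a", "b", "a", "b"], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="two runs"):
            mvpa.loro_cv(pats)

    def test_determinism(self):
        pats = _separable_set(noise=1.2, seed=5)
        a = mvpa.loro_cv(pats).accuracies
        b = mvpa.loro_cv(pats).accuracies
        assert np.array_equal(a, b)


class TestSubsampleCurve:
    def test_deterministic_given_seed(self):
        pats = _separable_set(noise=2.0, seed=2)
        a = mvpa.subsample_curve(pats, sizes=np.array([2, 5]), n_draws=5, seed=9)
        b = mvpa.subsample_curve(pats, sizes=np.array([2, 5]), n_draws=5, seed=9)
        assert a.equals(b)

    def test_accuracy_monotone_in_cnr(self):
        """Mean accuracy is non-decreasing in injected signal over
        {0, 0.25, 0.5, 1.0} within 1 SE."""
        means, ses = [], []
        for gap in (0.0, 0.25, 0.5, 1.0):
            accs = [
                mvpa.loro_cv(_separable_set(gap=gap, noise=1.0, seed=100 + s)).accuracy
                for s in range(12)
            ]
            means.append(np.mean(accs))
            ses.append(np.std(accs, ddof=1) / np.sqrt(len(accs)))
        for i in range(len(means) - 1):
            assert means[i + 1] >= means[i] - ses[i + 1]

    def test_accuracy_tends_up_with_set_size(self):
        pats = _separable_set(n_features=40, gap=0.8, noise=1.0, seed=8)
        curve = mvpa.subsample_curve(pats, sizes=np.array([1, 10, 40]), n_draws=10, seed=0)
        single = curve[curve.test_mode == "single_trial"].sort_values("set_size")["accuracy"].to_numpy()
        assert single[-1] >= single[0]

    def test_averaged_usually_beats_single_trial(self):
        """On noisy separable data the class-averaged test patterns are
        easier than single trials in >= 80% of seeds."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            pats = _separable_set(gap=1.2, noise=1.5, seed=300 + seed)
            avg = mvpa.loro_cv(pats, test_mode="averaged").accuracy
            single = mvpa.loro_cv(pats, test_mode="single_trial").accuracy
            wins += avg >= single
        assert wins / n_seeds >= 0.8


class TestGroupTest:
    def test_all_at_chance(self):
        res = mvpa.group_performance_test([50.0, 50.0, 50.0], 50.0)
        assert res.t == 0.0 and res.p == 0.5 and res.dof == 2

    def test_closed_form_oracle(self):
        res = mvpa.group_performance_test([60.0, 70.0, 80.0], 50.0)
        assert res.t == pytest.approx(20.0 / (10.0 / np.sqrt(3.0)), abs=1e-9)
        assert res.p == pytest.approx(float(__import__("scipy.stats", fromlist=["t"]).t.sf(res.t, 2)))

    def test_nine_subjects_have_eight_dof(self, rng):
        res = mvpa.group_performance_test(rng.normal(55, 5, 9), 50.0)
        assert res.dof == 8

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            mvpa.group_performance_test([55.0], 50.0)
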