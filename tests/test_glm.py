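"""GLM contracts: HRF shape, design-matrix construction, OLS against a
normal-equations oracle, t-contrasts against closed-form hand calculations,
noiseless parameter recovery and peak/window summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from v1facedecode import synthkit as sk
from v1facedecode.glm import (
    DesignMatrix,
    HrfParams,
    build_fir_design,
    build_single_trial_design,
    double_gamma_hrf,
    fit_ols,
    fixed_effects_design,
    peak_and_window,
    t_contrast,
)


class TestDoubleGammaHrf:
    def test_peak_near_five_seconds_on_fine_grid(self):
        fine = double_gamma_hrf(tr=0.1)
        t_peak = fine.times[np.argmax(fine.samples)]
        assert 4.0 <= t_peak <= 6.0
        assert fine.samples.max() == pytest.approx(1.0)

    def test_zero_at_onset(self, hrf):
        assert hrf.samples[0] == 0.0

    def test_late_undershoot_is_negative(self, hrf):
        """Beyond 10 s the undershoot pulls the kernel below the
        undershoot-free (single-gamma) version."""
        p = hrf.params
        single = sps.gamma.pdf(hrf.times, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
        single = single / single.max()
        tail = hrf.times >= 10.0
        assert np.trapezoid(hrf.samples[tail] - single[tail], hrf.times[tail]) < 0
        assert hrf.samples[hrf.times >= 14].min() < 0

    @pytest.mark.parametrize("bad", [
        HrfParams(peak_delay=-1), HrfParams(ratio=0), HrfParams(peak_dispersion=0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            double_gamma_hrf(1.0, bad)

    def test_invalid_tr_rejected(self):
        with pytest.raises(ValueError):
            double_gamma_hrf(tr=0.0)


def _events(onsets, types, durations=None):
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": durations if durations is not None else [1.0] * len(onsets),
            "trial_type": types,
        }
    )


class TestFirDesign:
    def test_twenty_predictors_per_condition(self):
        ev = _events(np.arange(5) * 4.0, list("abcde"))
        X = build_fir_design(ev, n_bins=20, n_volumes=120)
        assert len(X.columns("cond")) == 100
        assert len(X.columns("confound")) == 1

    def test_condition_without_events_gives_zero_columns(self):
        ev = _events([0.0], ["a"])
        X = build_fir_design(ev, n_bins=4, n_volumes=20, conditions=["a", "b"])
        b_cols = [i for i, lab in enumerate(X.column_labels) if lab[:2] == ("cond", "b")]
        assert len(b_cols) == 4
        assert np.all(X.matrix[:, b_cols] == 0.0)

    def test_stick_placement(self):
        ev = _events([7.0], ["a"])
        X = build_fir_design(ev, n_bins=5, n_volumes=20)
        col = X.matrix[:, X.column_labels.index(("cond", "a", 3))]
        assert col[10] == 1.0 and col.sum() == 1.0

    def test_event_beyond_run_end_rejected(self):
        with pytest.raises(ValueError, match="outside the run"):
            build_fir_design(_events([25.0], ["a"]), n_bins=2, n_volumes=20)


class TestSingleTrialDesign:
    def test_one_column_per_trial_plus_mean(self, hrf):
        ev = _events([0.0, 4.0, 8.0], ["a", "b", "a"])
        X = build_single_trial_design(ev, hrf, n_volumes=60)
        assert X.n_predictors == 4
        mean_col = X.matrix[:, X.column_labels.index(("confound", "mean"))]
        assert np.all(mean_col == 1.0)

    def test_duplicate_onsets_rejected(self, hrf):
        with pytest.raises(ValueError, match="overlapping"):
            build_single_trial_design(_events([4.0, 4.0], ["a", "b"]), hrf, n_volumes=40)

    def test_recovers_injected_trial_amplitudes(self, hrf):
        """Forward-model inversion oracle: simulate noiseless responses with
        known per-trial amplitudes and invert with OLS."""
        amps = np.array([1.0, 2.0, 0.5])
        ev = _events([2.0, 6.0, 10.0], ["a", "a", "a"])
        n_vol = 50
        X = build_single_trial_design(ev, hrf, n_volumes=n_vol)
        y = X.matrix[:, :3] @ amps
        est = fit_ols(X, y[None, :])
        assert np.allclose(est.betas[:3, 0], amps, atol=1e-6)


class TestFitOls:
    def test_orthonormal_design_closed_form(self, rng):
        M = np.linalg.qr(rng.normal(size=(30, 4)))[0]
        X = DesignMatrix(matrix=M, column_labels=[("cond", i) for i in range(4)])
        Y = rng.normal(size=(3, 30))
        est = fit_ols(X, Y)
        assert np.allclose(est.betas, M.T @ Y.T, atol=1e-12)

    def test_matches_normal_equations_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n, p = 8, 3
            M = rng.normal(size=(n, p))
            y = rng.normal(size=(1, n))
            X = DesignMatrix(matrix=M, column_labels=[("cond", i) for i in range(p)])
            est = fit_ols(X, y)
            oracle = np.linalg.solve(M.T @ M, M.T @ y[0])
            assert np.allclose(est.betas[:, 0], oracle, atol=1e-10)
            assert est.dof == n - p

    def test_exact_fit_has_zero_residual_variance(self, rng):
        M = rng.normal(size=(12, 2))
        X = DesignMatrix(matrix=M, column_labels=[("cond", 0), ("cond", 1)])
        y = (M @ np.array([2.0, -1.0]))[None, :]
        est = fit_ols(X, y)
        assert est.residual_variance[0] == pytest.approx(0.0, abs=1e-20)

    def test_volume_mismatch_rejected(self, rng):
        X = DesignMatrix(matrix=rng.normal(size=(10, 2)), column_labels=[("cond", 0), ("cond", 1)])
        with pytest.raises(ValueError, match="mismatch"):
            fit_ols(X, rng.normal(size=(1, 12)))

    def test_rank_deficient_design_warns(self, rng):
        col = rng.normal(size=10)
        X = DesignMatrix(matrix=np.column_stack([col, col]), column_labels=[("cond", 0), ("cond", 1)])
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_ols(X, rng.normal(size=(1, 10)))


class TestTContrast:
    def _two_sample_design(self, na, nb):
        M = np.zeros((na + nb, 2))
        M[:na, 0] = 1.0
        M[na:, 1] = 1.0
        return DesignMatrix(matrix=M, column_labels=[("cond", "a"), ("cond", "b")])

    def test_matches_two_sample_t_oracle(self, rng):
        a, b = rng.normal(size=8), rng.normal(loc=1.0, size=8)
        X = self._two_sample_design(8, 8)
        est = fit_ols(X, np.concatenate([a, b])[None, :])
        tmap = t_contrast(est, X, [1.0, -1.0])
        t_ref, _ = sps.ttest_ind(a, b)  # pooled-variance two-sample t
        assert tmap.t[0] == pytest.approx(t_ref, abs=1e-8)
        assert tmap.dof == 14

    def test_zero_weights_give_zero_t(self, rng):
        X = self._two_sample_design(4, 4)
        est = fit_ols(X, rng.normal(size=(2, 8)))
        assert np.all(t_contrast(est, X, [0.0, 0.0]).t == 0.0)

    def test_sign_flip_negates_t(self, rng):
        X = self._two_sample_design(5, 5)
        est = fit_ols(X, rng.normal(size=(3, 10)))
        t_pos = t_contrast(est, X, [1.0, -1.0]).t
        t_neg = t_contrast(est, X, [-1.0, 1.0]).t
        assert np.allclose(t_pos, -t_neg)

    def test_null_tail_calibration(self, rng):
        """Under white noise the empirical |t| > threshold rate matches the
        nominal two-sided tail within binomial error."""
        n_vox, n_vol = 4000, 40
        X = self._two_sample_design(20, 20)
        est = fit_ols(X, rng.normal(size=(n_vox, n_vol)))
        tmap = t_contrast(est, X, [1.0, -1.0])
        thr = 2.0
        nominal = 2 * sps.t.sf(thr, tmap.dof)
        rate = np.mean(np.abs(tmap.t) > thr)
        se = np.sqrt(nominal * (1 - nominal) / n_vox)
        assert abs(rate - nominal) < 4 * se


class TestNoiselessRecovery:
    """Deconvolution and beta-series estimators invert the forward model
    exactly at zero noise."""

    def _simulate(self, hrf20, seed=3):
        conds = ("happy", "fearful", "neutral", "fixation")
        design = sk.make_design(n_runs=1, trials_per_condition=8, conditions=conds, seed=seed)
        region = sk.make_region_truth(n_eye=2, n_mouth=2, n_rest=4, n_outside=2, seed=1)
        pattern = sk.make_pattern_truth(
            region, conditions=conds, expression_cnr=0.8, gender_cnr=0.0, seed=2
        )
        run = sk.simulate_run(design, 0, region, pattern, sk.NoiseModel(sigma=0.0), hrf20)
        return design, pattern, run

    def test_fir_recovers_kernel_times_amplitude(self, hrf20):
        design, pattern, run = self._simulate(hrf20)
        ev = design.run_events(0)
        modelled = ev[ev["trial_type"] != "fixation"]
        X = build_fir_design(modelled, n_bins=20, n_volumes=design.n_volumes(0))
        est = fit_ols(X, run)
        amps = pattern.trial_amplitudes(ev, design.task_per_run[0])
        labels = ev["trial_type"].to_numpy()
        for c in ("happy", "fearful", "neutral"):
            a = amps[labels == c].mean(axis=0)
            for k in range(20):
                b = est.betas[est.column_labels.index(("cond", c, k))]
                assert np.allclose(b, a * hrf20.samples[k], atol=1e-6)

    def test_single_trial_recovers_per_trial_amplitudes(self, hrf20):
        design, pattern, run = self._simulate(hrf20)
        ev = design.run_events(0)
        modelled = ev[ev["trial_type"] != "fixation"].reset_index(drop=True)
        X = build_single_trial_design(modelled, hrf20, n_volumes=design.n_volumes(0))
        est = fit_ols(X, run)
        amps = pattern.trial_amplitudes(modelled, design.task_per_run[0])
        assert np.allclose(est.betas[: len(modelled)], amps, atol=1e-6)

    def test_single_trial_estimator_unbiased_under_noise(self, hrf20):
        """Mean estimation error over many noise seeds is within 2 SE of 0."""
        design, pattern, _ = self._simulate(hrf20)
        ev = design.run_events(0)
        modelled = ev[ev["trial_type"] != "fixation"].reset_index(drop=True)
        region = sk.make_region_truth(n_eye=2, n_mouth=2, n_rest=4, n_outside=2, seed=1)
        X = build_single_trial_design(modelled, hrf20, n_volumes=design.n_volumes(0))
        amps = pattern.trial_amplitudes(modelled, design.task_per_run[0])
        errors = []
        for seed in range(200):
            run = sk.simulate_run(design, 0, region, pattern, sk.NoiseModel(sigma=1.0, seed=seed), hrf20)
            est = fit_ols(X, run)
            errors.append((est.betas[: len(modelled)] - amps).mean())
        errors = np.asarray(errors)
        se = errors.std(ddof=1) / np.sqrt(errors.size)
        assert abs(errors.mean()) < 2 * se


class TestPeakAndWindow:
    def test_constant_series(self):
        out = peak_and_window(np.full(20, 3.5), np.arange(20.0))
        assert out.peak_value == pytest.approx(3.5)
        assert out.window_mean == pytest.approx(3.5)

    def test_unique_max_at_six_seconds_selected(self):
        series = np.zeros(20)
        series[6] = 2.0
        out = peak_and_window(series, np.arange(20.0))
        assert out.peak_time == 6.0
        assert out.peak_value == pytest.approx(2.0)

    def test_window_mean_arithmetic(self):
        out = peak_and_window(np.arange(20.0), np.arange(20.0))
        assert out.window_mean == pytest.approx(6.0)  # mean of bins 3..9

    def test_window_outside_bins_rejected(self):
        with pytest.raises(ValueError, match="window"):
            peak_and_window(np.arange(4.0), np.arange(4.0))

    def test_peak_bin_shared_across_series(self):
        B = np.zeros((20, 2))
        B[5, 0], B[7, 1] = 5.0, 4.0  # grand mean peaks at bin 5
        out = peak_and_window(B, np.arange(20.0))
        assert out.peak_bin == 5
        assert np.allclose(out.peak_value, [5.0, 0.0])


class TestFixedEffectsDesign:
    def _events(self, n_subjects, n_runs):
        rows = []
        for s in range(n_subjects):
            for r in range(n_runs):
                rows.append({"onset": 2.0, "duration": 1.0, "trial_type": "a", "subject": s, "run": r})
                rows.append({"onset": 6.0, "duration": 1.0, "trial_type": "b", "subject": s, "run": r})
        return pd.DataFrame(rows)

    def test_one_confound_per_subject_run(self):
        ev = self._events(9, 6)
        n_vol = {(s, r): 12 for s in range(9) for r in range(6)}
        X = fixed_effects_design(ev, n_vol)
        assert len(X.columns("confound")) == 54
        assert len(X.columns("cond")) == 2
        assert X.n_volumes == 9 * 6 * 12

    def test_boxcar_rows_sum_to_at_most_one(self):
        ev = self._events(2, 2)
        X = fixed_effects_design(ev, {(s, r): 12 for s in range(2) for r in range(2)})
        assert X.matrix[:, X.columns("cond")].sum(axis=1).max() <= 1.0

    def test_single_subject_single_run_reduces(self):
        ev = self._events(1, 1)
        X = fixed_effects_design(ev, {(0, 0): 12})
        assert len(X.columns("confound")) == 1
        assert X.n_volumes == 12

    def test_missing_labels_rejected(self):
        ev = self._events(1, 1).drop(columns=["subject"])
        with pytest.raises(ValueError, match="subject"):
            fixed_effects_design(ev, {(0, 0): 12})
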