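"""The four classifiers: two-model MVB, one-model MVB, GLM T-weighted
correlation, and SVM on trial-wise betas with RFE."""

import numpy as np
import pytest

from mvbdecode import (SimConfig, TrialBetaSet, ar1_covariance,
                       classify_glm_weighted, classify_one_model,
                       classify_svm, classify_two_model, default_confounds,
                       estimate_trialwise_betas, rfe_select)
from mvbdecode.classify import _decide
from mvbdecode.design import residual_forming
from mvbdecode.mvb import MVBOperator
from mvbdecode.simulate import BoldDataset, simulate_bold, simulate_events


def _noisefree_dataset(seed=5, n_voxels=20, n_trials=6):
    cfg = SimConfig(n_voxels=n_voxels, n_trials_per_class=n_trials,
                    snr=1.0, drift_amplitude=0.0, amplitude_sd=0.0,
                    pattern_overlap=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    trials = simulate_events(cfg, rng)
    bold, truth = simulate_bold(trials, cfg, rng)
    clean = BoldDataset(data=truth.noiseless, TR=bold.TR)
    return cfg, trials, clean, truth


class TestDecisionRule:
    def test_exact_tie_breaks_lexicographically(self):
        res = _decide({"B": 1.0, "A": 1.0}, "mvb2")
        assert res.predicted == "A"
        assert res.tie_broken
        assert res.margin == 0.0

    def test_margin_is_score_difference(self):
        res = _decide({"A": -10.0, "B": -4.0}, "mvb2")
        assert res.predicted == "B"
        assert res.margin == pytest.approx(6.0)


class TestTwoModel:
    def test_noise_free_target_recovered_with_margin(self):
        cfg, trials, clean, _ = _noisefree_dataset()
        conf = default_confounds(clean.n_scans, clean.TR)
        noise = ar1_covariance(clean.n_scans, 0.2)
        idx = 3
        res = classify_two_model(trials.with_targets([idx]), clean, conf, noise)
        assert res.predicted == trials.labels[idx]
        assert res.margin > 0
        assert res.method == "mvb2"

    def test_refuses_single_class_known_trials(self):
        cfg, trials, clean, _ = _noisefree_dataset()
        t = trials.with_targets([0])
        t.labels[1:] = "A"
        conf = default_confounds(clean.n_scans, clean.TR)
        noise = ar1_covariance(clean.n_scans, 0.2)
        with pytest.raises(ValueError, match="two classes"):
            classify_two_model(t, clean, conf, noise)

    def test_requires_a_target(self):
        cfg, trials, clean, _ = _noisefree_dataset()
        conf = default_confounds(clean.n_scans, clean.TR)
        noise = ar1_covariance(clean.n_scans, 0.2)
        with pytest.raises(ValueError, match="target"):
            classify_two_model(trials, clean, conf, noise)

    def test_label_symmetry(self):
        # renaming the classes renames the prediction, nothing else
        cfg, trials, clean, _ = _noisefree_dataset(seed=7)
        conf = default_confounds(clean.n_scans, clean.TR)
        noise = ar1_covariance(clean.n_scans, 0.2)
        idx = 2
        res1 = classify_two_model(trials.with_targets([idx]), clean, conf, noise)
        swapped = trials.with_targets([idx])
        swapped.labels = np.where(swapped.labels == "A", "Z", "A").astype(object)
        res2 = classify_two_model(swapped, clean, conf, noise)
        rename = {"A": "Z", "B": "A"}
        assert res2.predicted == rename[res1.predicted]
        assert res2.margin == pytest.approx(res1.margin, rel=1e-6)


class TestOneModel:
    def test_agrees_with_two_model_at_high_snr(self):
        cfg, trials, clean, _ = _noisefree_dataset(seed=5)
        conf = default_confounds(clean.n_scans, clean.TR)
        noise = ar1_covariance(clean.n_scans, 0.2)
        op = MVBOperator(clean.data, conf.R, noise.V)
        for idx in (1, 4):
            t = trials.with_targets([idx])
            r1 = classify_one_model(t, clean, conf, noise, operator=op)
            r2 = classify_two_model(t, clean, conf, noise, operator=op)
            assert r1.predicted == r2.predicted == trials.labels[idx]

    def test_zero_data_raises_zero_variance(self):
        cfg, trials, clean, _ = _noisefree_dataset()
        zero = BoldDataset(data=np.zeros_like(clean.data), TR=clean.TR)
        conf = default_confounds(clean.n_scans, clean.TR)
        noise = ar1_covariance(clean.n_scans, 0.2)
        with pytest.raises(ValueError, match="zero-variance"):
            classify_one_model(trials.with_targets([0]), zero, conf, noise)

    def test_correlation_matches_direct_formula(self):
        from mvbdecode.classify import _pearson
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        direct = (np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1)))
        assert _pearson(x, y) == pytest.approx(direct, abs=1e-12)


class TestGLMWeighted:
    def _setup(self, seed=5):
        cfg, trials, clean, truth = _noisefree_dataset(seed=seed)
        conf = default_confounds(clean.n_scans, clean.TR)
        return cfg, trials, clean, truth, conf

    def test_single_voxel_unit_weight_uses_that_series(self):
        cfg, trials, clean, truth, conf = self._setup()
        vox = truth.support_A[0]
        one = BoldDataset(data=clean.data[:, [vox]], TR=clean.TR)
        res = classify_glm_weighted(trials.with_targets([0]), one,
                                    np.array([1.0]), conf)
        assert res.method == "glm"

    def test_zero_tmap_rejected(self):
        cfg, trials, clean, truth, conf = self._setup()
        with pytest.raises(ValueError, match="degenerate"):
            classify_glm_weighted(trials.with_targets([0]), clean,
                                  np.zeros(clean.n_voxels), conf)

    def test_discriminative_tmap_classifies_at_high_snr(self):
        cfg, trials, clean, truth, conf = self._setup(seed=9)
        # ideal weighting: the true discriminative pattern
        tmap = truth.discriminative
        correct = 0
        for idx in range(6):
            res = classify_glm_weighted(trials.with_targets([idx]), clean,
                                        tmap, conf)
            correct += res.predicted == trials.labels[idx]
        assert correct >= 5


class TestTrialwiseBetas:
    def test_unit_amplitude_single_class_recovered(self):
        cfg = SimConfig(n_voxels=1, n_trials_per_class=4, amplitude_sd=0.0,
                        drift_amplitude=0.0, pattern_sparsity=1.0,
                        pattern_overlap=1.0, identical_patterns=True, seed=2)
        rng = np.random.default_rng(2)
        trials = simulate_events(cfg, rng)
        bold, truth = simulate_bold(trials, cfg, rng)
        clean = BoldDataset(data=truth.noiseless, TR=bold.TR)
        conf = residual_forming(np.ones((clean.n_scans, 1)))
        betas = estimate_trialwise_betas(trials, clean, conf)
        expected = truth.w_A[0] * cfg.amplitude_mean
        np.testing.assert_allclose(betas.betas[:, 0], expected, atol=1e-6)

    def test_row_count_matches_known_trials(self, small_dataset, small_context):
        cfg, trials, bold, _ = small_dataset
        conf, _, _ = small_context
        betas = estimate_trialwise_betas(trials, bold, conf)
        assert betas.betas.shape == (len(trials), bold.n_voxels)
        assert np.array_equal(betas.labels, trials.labels)

    def test_ls_a_variant_runs(self, small_dataset, small_context):
        cfg, trials, bold, _ = small_dataset
        conf, _, _ = small_context
        betas = estimate_trialwise_betas(trials, bold, conf, method="ls_a")
        assert betas.betas.shape[0] == len(trials)

    def test_too_few_trials_rejected(self, small_dataset, small_context):
        cfg, trials, bold, _ = small_dataset
        conf, _, _ = small_context
        from mvbdecode import TrialTable
        t1 = TrialTable(onsets=[1.0], durations=[2.0], labels=["A"],
                        target_flags=[False])
        with pytest.raises(ValueError, match="two trials"):
            estimate_trialwise_betas(t1, bold, conf)


class TestRFE:
    def test_halving_arithmetic(self):
        rng = np.random.default_rng(9)
        n_feat, target = 160, 20
        X = rng.normal(size=(40, n_feat))
        labels = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        betas = TrialBetaSet(betas=X, labels=labels,
                             trial_indices=np.arange(40))
        out = rfe_select(betas, target_count=target)
        assert len(out) == target  # 160 -> 80 -> 40 -> 20: exactly 3 halvings

    def test_identity_when_already_small(self):
        rng = np.random.default_rng(9)
        betas = TrialBetaSet(betas=rng.normal(size=(10, 8)),
                             labels=np.array(["A"] * 5 + ["B"] * 5, object),
                             trial_indices=np.arange(10))
        assert np.array_equal(rfe_select(betas, 8), np.arange(8))

    def test_informative_features_survive(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            n = 80
            y = np.array(["A"] * 40 + ["B"] * 40, dtype=object)
            X = rng.normal(size=(n, 128))
            sgn = np.where(y == "A", 1.0, -1.0)
            X[:, 0] += 2.0 * sgn
            X[:, 1] -= 2.0 * sgn
            betas = TrialBetaSet(betas=X, labels=y, trial_indices=np.arange(n))
            sel = rfe_select(betas, target_count=16)
            hits += (0 in sel) and (1 in sel)
        assert hits >= int(0.9 * n_rep)

    def test_single_class_rejected(self):
        betas = TrialBetaSet(betas=np.ones((4, 8)),
                             labels=np.array(["A"] * 4, object),
                             trial_indices=np.arange(4))
        with pytest.raises(ValueError, match="two classes"):
            rfe_select(betas, 2)


class TestSVMClassifier:
    def _toy(self):
        X = np.array([[1.0, 1.0], [2.0, 1.5], [-1.0, -1.0], [-2.0, -0.5]])
        y = np.array(["A", "A", "B", "B"], dtype=object)
        return TrialBetaSet(betas=X, labels=y, trial_indices=np.arange(4))

    def test_separable_toy_set_zero_training_error(self):
        train = self._toy()
        for row, lab in zip(train.betas, train.labels):
            assert classify_svm(train, row).predicted == lab

    def test_zero_decision_value_goes_to_second_class(self):
        train = self._toy()
        res = classify_svm(train, np.zeros(2))
        # symmetric toy set: decision value at the origin is ~0
        assert abs(res.diagnostics["decision_value"]) < 1e-9
        assert res.predicted == "B"

    def test_feature_scaling_does_not_flip_predictions(self):
        train = self._toy()
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=2)
            p1 = classify_svm(train, x).predicted
            scaled = TrialBetaSet(betas=2.0 * train.betas, labels=train.labels,
                                  trial_indices=train.trial_indices)
            p2 = classify_svm(scaled, 2.0 * x).predicted
            assert p1 == p2
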