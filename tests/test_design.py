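"""Design-side construction: HRF, design matrices, confound projection,
target variables, serial correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvbdecode import (HRFModel, TrialTable, ar1_covariance,
                       build_design_matrix, canonical_hrf, dct_drift_basis,
                       default_confounds, make_target_variable,
                       residual_forming)


class TestCanonicalHRF:
    def test_vanishes_at_origin(self):
        assert canonical_hrf(np.array([0.0]))[0] == 0.0

    def test_peak_location_near_stated_delay(self):
        t = np.arange(0.0, 32.0, 0.01)
        h = canonical_hrf(t)
        assert abs(t[np.argmax(h)] - 6.0) < 0.5
        assert h.max() == pytest.approx(1.0, abs=1e-4)

    def test_returns_to_baseline_at_support_end(self):
        assert abs(canonical_hrf(np.array([32.0]))[0]) < 0.01

    def test_undershoot_is_negative(self):
        h = canonical_hrf(np.arange(10.0, 20.0, 0.5))
        assert h.min() < 0

    def test_rejects_negative_times(self):
        with pytest.raises(ValueError, match="non-negative"):
            canonical_hrf(np.array([-1.0]))

    def test_finite_everywhere(self):
        h = canonical_hrf(np.linspace(0, 64, 1000))
        assert np.all(np.isfinite(h))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HRFModel(peak_delay=-1.0)
        with pytest.raises(ValueError):
            HRFModel(duration=10.0)  # shorter than the undershoot delay


def _table(onsets, labels, durations=None, targets=None):
    n = len(onsets)
    return TrialTable(
        onsets=np.asarray(onsets, float),
        durations=np.zeros(n) if durations is None else np.asarray(durations, float),
        labels=np.asarray(labels, object),
        target_flags=np.zeros(n, bool) if targets is None else np.asarray(targets, bool))


class TestBuildDesignMatrix:
    def test_empty_table_gives_zero_columns(self):
        t = _table([], [])
        X = build_design_matrix(t, {}, TR=2.0, M=16)
        assert X.X.shape == (16, 0)

    def test_impulse_regressor_equals_sampled_hrf(self):
        # zero-duration event at onset 0: the convolved column IS the HRF
        t = _table([0.0], ["A"], durations=[0.0])
        X = build_design_matrix(t, {}, TR=2.0, M=16)
        expected = canonical_hrf(np.arange(16) * 2.0)
        assert np.max(np.abs(X.X[:, 0] - expected)) < 1e-10

    def test_hypotheses_differ_only_in_touched_columns(self):
        t = _table([0, 10, 20, 30], ["A", "B", "A", "B"],
                   durations=[2, 2, 2, 2], targets=[0, 0, 1, 0])
        Xa = build_design_matrix(t, {2: "A"}, TR=2.0, M=40)
        Xb = build_design_matrix(t, {2: "B"}, TR=2.0, M=40)
        assert Xa.regressor_names == Xb.regressor_names == ["A", "B"]
        # difference localized to the trial's response support
        diff = Xa.X - Xb.X
        assert np.any(diff != 0)
        onset_scan = 10
        assert np.allclose(diff[:onset_scan], 0.0)

    def test_superposition_of_trials(self):
        # overlapping responses add linearly (the overlap phenomenon)
        t2 = _table([0.0, 4.0], ["A", "A"], durations=[0, 0])
        t_first = _table([0.0], ["A"], durations=[0])
        t_second = _table([4.0], ["A"], durations=[0])
        M = 20
        X2 = build_design_matrix(t2, {}, 2.0, M).X[:, 0]
        X0 = build_design_matrix(t_first, {}, 2.0, M).X[:, 0]
        X1 = build_design_matrix(t_second, {}, 2.0, M).X[:, 0]
        assert np.allclose(X2, X0 + X1, atol=1e-12)
        # response at the second onset already carries the first event
        assert X0[2] > 0.1

    def test_shift_covariance(self):
        t0 = _table([2.0], ["A"], durations=[2.0])
        t1 = _table([6.0], ["A"], durations=[2.0])
        M = 30
        X0 = build_design_matrix(t0, {}, 2.0, M).X[:, 0]
        X1 = build_design_matrix(t1, {}, 2.0, M).X[:, 0]
        assert np.allclose(X1[2:], X0[:-2], atol=1e-12)

    def test_resampling_consistency(self):
        t = _table([3.4, 11.8], ["A", "B"], durations=[2.0, 2.0])
        M = 20
        X1 = build_design_matrix(t, {}, 2.0, M, dt=0.1).X
        X2 = build_design_matrix(t, {}, 2.0, M, dt=0.05).X
        rel = np.linalg.norm(X1 - X2) / np.linalg.norm(X2)
        assert rel < 1e-3

    def test_omit_target_removes_event(self):
        t = _table([0, 10, 20], ["A", "B", "A"], durations=[2, 2, 2],
                   targets=[0, 0, 1])
        X = build_design_matrix(t, {2: "omit"}, 2.0, 20)
        t_wo = _table([0, 10], ["A", "B"], durations=[2, 2])
        X_wo = build_design_matrix(t_wo, {}, 2.0, 20)
        assert np.allclose(X.X, X_wo.X)

    def test_hypothesis_for_non_target_rejected(self):
        t = _table([0, 10], ["A", "B"], durations=[2, 2])
        with pytest.raises(ValueError, match="non-target"):
            build_design_matrix(t, {0: "A"}, 2.0, 20)

    def test_event_past_last_scan_truncated_with_warning(self, caplog):
        t = _table([0.0, 100.0], ["A", "B"], durations=[2, 2])
        with caplog.at_level("WARNING", logger="mvbdecode"):
            X = build_design_matrix(t, {}, 2.0, 10)
        assert "truncated" in caplog.text
        assert np.allclose(X.X[:, X.regressor_names.index("B")], 0.0)


class TestResidualForming:
    def test_intercept_annihilated(self):
        conf = residual_forming(np.ones((10, 1)))
        assert conf.R.shape == (9, 10)
        assert np.linalg.norm(conf.R @ np.ones(10)) < 1e-10

    def test_no_confounds_gives_identity(self):
        conf = residual_forming(None, M=7)
        assert np.allclose(conf.R, np.eye(7))

    def test_intercept_plus_trend_svd_oracle(self):
        M = 20
        G = np.column_stack([np.ones(M), np.arange(M, dtype=float)])
        conf = residual_forming(G)
        assert conf.R.shape == (18, M)
        assert np.linalg.matrix_rank(conf.R) == 18
        assert np.max(np.abs(conf.R @ conf.R.T - np.eye(18))) < 1e-10
        assert np.max(np.abs(conf.R @ G)) < 1e-10

    def test_more_columns_than_rows_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            residual_forming(np.ones((3, 5)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_confound_annihilation_property(self, seed):
        rng = np.random.default_rng(seed)
        M = 30
        G = rng.normal(size=(M, 3))
        conf = residual_forming(G)
        a = rng.normal(size=3)
        assert np.linalg.norm(conf.R @ (G @ a)) < 1e-8 * max(1, np.linalg.norm(G @ a))


class TestTargetVariable:
    def test_unit_contrast_selects_column(self):
        rng = np.random.default_rng(7)
        M = 20
        X = build_design_matrix(
            _table([0, 8], ["A", "B"], durations=[2, 2]), {}, 2.0, M)
        conf = residual_forming(np.ones((M, 1)))
        tv = make_target_variable(X, np.array([1.0, 0.0]), conf)
        assert np.allclose(tv.v, conf.R @ X.X[:, 0])
        assert tv.w_dim == M - 1

    def test_confound_subspace_maps_to_zero(self):
        M = 12
        conf = residual_forming(np.ones((M, 1)))
        from mvbdecode.design import DesignMatrix
        X = DesignMatrix(X=np.ones((M, 1)) * 3.2, regressor_names=["A"], TR=2.0)
        tv = make_target_variable(X, np.array([1.0]), conf)
        assert np.max(np.abs(tv.v)) < 1e-10

    def test_matches_pseudoinverse_projection(self):
        rng = np.random.default_rng(7)
        M = 25
        from mvbdecode.design import DesignMatrix
        Xm = rng.normal(size=(M, 2))
        X = DesignMatrix(X=Xm, regressor_names=["A", "B"], TR=2.0)
        G = np.ones((M, 1))
        conf = residual_forming(G)
        tv = make_target_variable(X, np.array([1.0, -1.0]), conf)
        brute = (np.eye(M) - G @ np.linalg.pinv(G)) @ (Xm @ [1.0, -1.0])
        # R re-expresses the projection in an orthonormal row basis:
        # the vector itself differs but the norm and back-projection agree
        assert np.linalg.norm(tv.v) == pytest.approx(np.linalg.norm(brute), rel=1e-10)
        assert np.allclose(conf.R.T @ tv.v, brute, atol=1e-10)

    def test_zero_contrast_rejected(self):
        M = 10
        X = build_design_matrix(
            _table([0], ["A"], durations=[2]), {}, 2.0, M)
        conf = residual_forming(np.ones((M, 1)))
        with pytest.raises(ValueError, match="nonzero"):
            make_target_variable(X, np.array([0.0]), conf)


class TestNoiseModel:
    def test_rho_zero_is_identity(self):
        assert np.allclose(ar1_covariance(5, 0.0).V, np.eye(5))

    def test_explicit_small_case(self):
        V = ar1_covariance(3, 0.5).V
        assert np.allclose(V, [[1, .5, .25], [.5, 1, .5], [.25, .5, 1]])

    @pytest.mark.parametrize("rho", [0.1, 0.5, 0.9])
    def test_positive_definite(self, rho):
        V = ar1_covariance(50, rho).V
        assert np.linalg.eigvalsh(V).min() > 0

    def test_invalid_rho_rejected(self):
        for rho in (-0.1, 1.0):
            with pytest.raises(ValueError):
                ar1_covariance(5, rho)


class TestDriftBasis:
    def test_cutoff_controls_order(self):
        M, TR = 200, 2.0
        B = dct_drift_basis(M, TR, cutoff_s=128.0)
        assert B.shape == (M, int(2 * M * TR / 128.0))

    def test_default_confounds_include_intercept(self):
        conf = default_confounds(100, 2.0)
        assert np.allclose(conf.G[:, 0], 1.0)
        assert np.max(np.abs(conf.R @ conf.G)) < 1e-10
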