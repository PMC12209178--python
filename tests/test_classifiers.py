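"""Broad learning system, margin classifier, and the λ ensemble."""

import numpy as np
import pytest
from scipy.special import expit, softmax

from wbovw.classifiers import (
    MarginClassifier,
    bls_scores,
    ensemble_probability,
    fit_bls,
    fit_ensemble,
    svm_distance_to_prob,
)


def make_blobs(rng, n=60, sep=4.0, dim=5):
    X0 = rng.normal(size=(n // 2, dim))
    X1 = rng.normal(size=(n // 2, dim)) + sep
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n // 2)
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestFitBls:
    def test_ridge_solution_matches_pseudoinverse_oracle(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        eps = 1e-3
        model = fit_bls(X, y, n_map=3, map_dim=4, m_enh=10, eps=eps, seed=2)
        from wbovw.classifiers import _expand

        A = _expand(model, X)
        Y = np.zeros((20, 2))
        Y[np.arange(20), y] = 1.0
        # independent route: the explicit normal-equations closed form
        oracle = np.linalg.solve(A.T @ A + eps * np.eye(A.shape[1]), A.T @ Y)
        np.testing.assert_allclose(model.output_weights, oracle, atol=1e-8)

    def test_small_eps_approaches_interpolation(self, rng):
        """With a square full-rank expansion the ridge solution tends to the
        exact interpolant A⁻¹Y as ε → 0: the training residual shrinks
        monotonically and becomes negligible."""
        # affine Z has rank <= d+1 = 7, so use one 7-node mapping group plus
        # 23 tanh enhancement nodes -> a square 30x30 expansion
        X = rng.normal(size=(30, 6))
        y = np.tile([0, 1], 15)
        from wbovw.classifiers import _expand

        Y = np.zeros((30, 2))
        Y[np.arange(30), y] = 1.0
        residuals = []
        for eps in (1e-3, 1e-6, 1e-9, 1e-12):
            model = fit_bls(X, y, n_map=1, map_dim=7, m_enh=23, eps=eps, seed=0)
            A = _expand(model, X)
            assert A.shape == (30, 30)
            residuals.append(np.linalg.norm(A @ model.output_weights - Y))
        assert np.all(np.diff(residuals) < 0)
        assert residuals[-1] < 1e-2 * np.linalg.norm(Y)

    def test_weight_norm_non_increasing_in_eps(self, rng):
        X = rng.normal(size=(25, 6))
        y = np.tile([0, 1], 13)[:25]
        norms = []
        for eps in (1e-4, 1e-2, 1.0, 100.0):
            m = fit_bls(X, y, n_map=3, map_dim=5, m_enh=10, eps=eps, seed=9)
            norms.append(np.linalg.norm(m.output_weights))
        assert np.all(np.diff(norms) <= 1e-12)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            fit_bls(rng.normal(size=(10, 4)), np.zeros(10, dtype=int))

    def test_nonpositive_eps_rejected(self, rng):
        with pytest.raises(ValueError, match="eps"):
            fit_bls(rng.normal(size=(10, 4)), np.tile([0, 1], 5), eps=0.0)


class TestBlsScores:
    def test_training_scores_reproduce_fit(self, rng):
        X, y = make_blobs(rng)
        model = fit_bls(X, y, seed=1)
        from wbovw.classifiers import _expand

        np.testing.assert_allclose(
            bls_scores(model, X), _expand(model, X) @ model.output_weights, atol=1e-12
        )

    def test_duplicate_rows_identical_scores(self, rng):
        X, y = make_blobs(rng)
        model = fit_bls(X, y, seed=1)
        dup = np.vstack([X[0], X[0]])
        s = bls_scores(model, dup)
        np.testing.assert_array_equal(s[0], s[1])

    def test_forward_pass_oracle(self, rng):
        """Recompute mapping/enhancement/output by hand from stored weights."""
        X, y = make_blobs(rng, n=20)
        model = fit_bls(X, y, n_map=2, map_dim=3, m_enh=4, seed=5)
        Z = np.hstack(
            [X @ W + b for W, b in zip(model.map_weights, model.map_offsets)]
        )
        H = np.tanh(Z @ model.enh_weights + model.enh_offsets)
        want = np.hstack([Z, H]) @ model.output_weights
        np.testing.assert_allclose(bls_scores(model, X), want, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = make_blobs(rng)
        model = fit_bls(X, y, seed=1)
        with pytest.raises(ValueError, match="columns"):
            bls_scores(model, np.zeros((3, 2)))

    def test_deterministic_given_seed(self, rng):
        X, y = make_blobs(rng)
        a = fit_bls(X, y, seed=11)
        b = fit_bls(X, y, seed=11)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)


class TestSigmoidDistance:
    def test_zero_distance_is_half(self):
        assert svm_distance_to_prob(0.0) == 0.5

    def test_log3_gives_three_quarters(self):
        assert svm_distance_to_prob(np.log(3.0)) == pytest.approx(0.75, abs=1e-12)

    def test_monotone_and_bounded(self):
        d = np.linspace(-50, 50, 101)
        p = svm_distance_to_prob(d)
        assert np.all(np.diff(p) >= 0)
        assert p[0] >= 0 and p[-1] <= 1
        assert svm_distance_to_prob(1e6) == pytest.approx(1.0)
        assert svm_distance_to_prob(-1e6) == pytest.approx(0.0)


class TestEnsembleProbability:
    def test_lambda_endpoints(self):
        y_bls = np.array([1.0, -0.5])
        dists = np.array([-0.7, 0.7])
        np.testing.assert_allclose(
            ensemble_probability(y_bls, dists, 1.0), softmax(y_bls), atol=1e-12
        )
        np.testing.assert_allclose(
            ensemble_probability(y_bls, dists, 0.0), expit(dists), atol=1e-12
        )

    def test_symmetric_inputs_give_half_half(self):
        out = ensemble_probability(np.zeros(2), np.zeros(2), 0.42)
        np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-12)

    def test_hand_evaluated_blend(self):
        y_bls = np.array([1.0, 0.0])
        dists = np.array([np.log(3.0), -np.log(3.0)])
        want = 0.3 * softmax(y_bls) + 0.7 * np.array([0.75, 0.25])
        np.testing.assert_allclose(
            ensemble_probability(y_bls, dists, 0.3), want, atol=1e-12
        )

    def test_term_bounds(self, rng):
        for _ in range(20):
            y_bls = rng.normal(size=2) * 10
            dists = rng.normal(size=2) * 10
            lam = rng.uniform()
            out = ensemble_probability(y_bls, dists, lam)
            assert np.all(out >= 0) and np.all(out <= 1)
            assert np.all(lam * softmax(y_bls) <= lam + 1e-12)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            ensemble_probability(np.zeros(2), np.zeros(2), 1.2)


class TestMarginClassifier:
    def test_sign_of_distance_predicts_class(self, rng):
        X, y = make_blobs(rng, sep=6.0)
        clf = MarginClassifier().fit(X, y)
        d = clf.distance(X)
        assert np.mean((d > 0).astype(int) == y) > 0.95

    def test_unfitted_distance_raises(self):
        with pytest.raises(RuntimeError):
            MarginClassifier().distance(np.zeros((2, 3)))


class TestFitEnsemble:
    def test_separable_data_selects_lambda_zero_by_tie_rule(self, rng):
        X, y = make_blobs(rng, n=80, sep=8.0)
        model = fit_ensemble(X[:60], y[:60], X[60:], y[60:], seed=4)
        assert set(model.lam_trace.values()) == {1.0}
        assert model.lam == 0.0

    def test_endpoint_lambdas_reproduce_single_models(self, rng):
        X, y = make_blobs(rng, n=80, sep=3.0)
        model = fit_ensemble(X[:60], y[:60], X[60:], y[60:], seed=4)
        probe = X[60:]
        scores = bls_scores(model.bls, probe)
        d = model.svm.distance(probe)
        model.lam = 1.0
        np.testing.assert_allclose(
            model.predict_proba(probe), softmax(scores, axis=1), atol=1e-12
        )
        model.lam = 0.0
        np.testing.assert_allclose(
            model.predict_proba(probe), expit(np.column_stack([-d, d])), atol=1e-12
        )

    def test_same_seed_same_lambda(self, rng):
        X, y = make_blobs(rng, n=80, sep=2.0)
        a = fit_ensemble(X[:60], y[:60], X[60:], y[60:], seed=8)
        b = fit_ensemble(X[:60], y[:60], X[60:], y[60:], seed=8)
        assert a.lam == b.lam
        assert a.lam_trace == b.lam_trace

    def test_degraded_bls_pushes_lambda_toward_svm(self, rng):
        """When BLS trains on heavily label-noised data and the SVM on clean
        data, validation selection should favour the SVM side (λ < 0.5)."""
        X, y = make_blobs(rng, n=120, sep=4.0)
        X_tr, y_tr = X[:80], y[:80].copy()
        X_val, y_val = X[80:], y[80:]
        y_noisy = y_tr.copy()
        flip = rng.choice(80, size=40, replace=False)
        y_noisy[flip] = 1 - y_noisy[flip]
        from wbovw.classifiers import MarginClassifier as MC

        bls = fit_bls(X_tr, y_noisy, seed=3)
        svm = MC(seed=3).fit(X_tr, y_tr)
        scores = bls_scores(bls, X_val)
        d = svm.distance(X_val)
        dists = np.column_stack([-d, d])
        best_lam, best_acc = None, -1.0
        for lam in np.round(np.arange(0, 1.01, 0.1), 10):
            proba = lam * softmax(scores, axis=1) + (1 - lam) * expit(dists)
            acc = np.mean(np.argmax(proba, axis=1) == y_val)
            if acc > best_acc:
                best_lam, best_acc = lam, acc
        assert best_lam < 0.5

    def test_empty_validation_falls_back_to_default_lambda(self, rng):
        X, y = make_blobs(rng)
        with pytest.warns(UserWarning, match="lambda"):
            model = fit_ensemble(X, y, np.zeros((0, X.shape[1])), np.zeros(0), seed=0)
        assert model.lam == 0.3
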