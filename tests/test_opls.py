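"""OPLS regression: component orthogonality, PLS1 equivalence, CV behavior."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from nirhist import opls


def make_instance(rng, n=None, p=None, noise=0.05):
    n = n or rng.integers(10, 51)
    p = p or rng.integers(20, 201)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


def make_orthogonal_instance(rng, n=60, p=40, n_orth=1, amplitude=5.0, overlap=0.0):
    """y-predictive rank-1 signal plus planted y-orthogonal variance.

    Orthogonal loadings are orthogonal to the predictive loading unless
    ``overlap`` mixes some of it back in.
    """
    basis = np.linalg.qr(rng.standard_normal((p, n_orth + 1)))[0].T
    wy, orth_loadings = basis[0], basis[1:]
    t = rng.standard_normal(n)
    y = t.copy()
    X = np.outer(t, wy)
    for k in range(n_orth):
        t_o = rng.standard_normal(n)
        t_o -= (t_o @ y) / (y @ y) * y  # exactly y-orthogonal scores
        X += amplitude * np.outer(t_o, orth_loadings[k] + overlap * wy)
    return X, y, wy, orth_loadings


class TestFit:
    def test_exact_rank_one_recovery(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(30)
        p_vec = rng.standard_normal(15)
        X = np.outer(t, p_vec)
        model = opls.fit(X, t, n_orth=0)
        np.testing.assert_allclose(opls.predict(model, X), t, atol=1e-10)
        assert model.r2y == pytest.approx(1.0, abs=1e-12)

    def test_zero_orth_matches_one_component_pls1(self):
        """With no orthogonal filtering, OPLS is exactly 1-component PLS1."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            X, y = make_instance(rng)
            model = opls.fit(X, y, n_orth=0)
            sk = PLSRegression(n_components=1, scale=False).fit(X, y)
            np.testing.assert_allclose(
                opls.predict(model, X), sk.predict(X).ravel(), atol=1e-8
            )

    def test_planted_orthogonal_structure_filtered(self):
        rng = np.random.default_rng(3)
        X, y, _, _ = make_orthogonal_instance(rng, overlap=0.3)
        m0 = opls.fit(X, y, n_orth=0)
        m1 = opls.fit(X, y, n_orth=1)
        assert abs(m1.weight @ m1.orth_weights[0]) < 1e-10
        assert m1.r2y >= m0.r2y

    def test_r2y_monotone_in_orth_count(self):
        rng = np.random.default_rng(4)
        X, y = make_instance(rng, n=40, p=30)
        r2 = [opls.fit(X, y, k).r2y for k in range(4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_component_norms_and_orthogonality(self):
        rng = np.random.default_rng(5)
        X, y = make_instance(rng, n=50, p=60)
        model = opls.fit(X, y, n_orth=3)
        assert np.linalg.norm(model.weight) == pytest.approx(1.0, abs=1e-10)
        for w_o in model.orth_weights:
            assert np.linalg.norm(w_o) == pytest.approx(1.0, abs=1e-10)
            assert abs(model.weight @ w_o) < 1e-10

    def test_deflation_conserves_sum_of_squares(self):
        rng = np.random.default_rng(6)
        X, y = make_instance(rng, n=40, p=50)
        n_orth = 2
        model = opls.fit(X, y, n_orth)
        Xc = X - X.mean(axis=0)
        total = np.sum(Xc**2)
        captured = model.r2x * total
        # reconstruct the residual by explicit sequential deflation
        Xw = Xc.copy()
        for w_o, p_o in zip(model.orth_weights, model.orth_loadings):
            t_o = Xw @ w_o
            Xw = Xw - np.outer(t_o, p_o)
        t = Xw @ model.weight
        resid = Xw - np.outer(t, model.loading)
        assert captured + np.sum(resid**2) == pytest.approx(total, rel=1e-8)

    def test_zero_variance_response_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 10))
        with pytest.raises(ValueError, match="zero-variance"):
            opls.fit(X, np.ones(20), 0)

    def test_n_orth_beyond_rank_rejected(self):
        rng = np.random.default_rng(8)
        t = rng.standard_normal(20)
        X = np.outer(t, rng.standard_normal(10))  # rank 1: no orthogonal variance
        with pytest.raises(ValueError, match="rank"):
            opls.fit(X, t, n_orth=2)


class TestPredict:
    def test_training_predictions_reproduced(self):
        rng = np.random.default_rng(11)
        X, y, _, _ = make_orthogonal_instance(rng, n_orth=2)
        model = opls.fit(X, y, 2)
        fitted = opls.predict(model, X)
        again = opls.predict(model, X)
        np.testing.assert_array_equal(fitted, again)

    def test_orthogonal_weight_shift_changes_prediction_only_via_loading_overlap(self):
        """Perturbing a spectrum by c*w_o moves the prediction by exactly
        -c*q*(p_o . w); when that overlap term is projected out, the
        prediction is invariant to machine precision."""
        rng = np.random.default_rng(12)
        X, y, _, _ = make_orthogonal_instance(rng, n_orth=1, overlap=0.3)
        model = opls.fit(X, y, 1)
        w_o, p_o = model.orth_weights[0], model.orth_loadings[0]
        x = rng.standard_normal(X.shape[1])
        base = opls.predict(model, x)[0]
        b = model.prediction_vector
        for c in (-2.0, 0.5, 10.0):
            shifted = opls.predict(model, x + c * w_o)[0]
            expected = -c * model.q * (p_o @ model.weight)
            assert shifted - base == pytest.approx(expected, abs=1e-10)
            # remove the overlap leak: the cleaned direction is invariant
            d = w_o - (b @ w_o) / (b @ b) * b
            cleaned = opls.predict(model, x + c * d)[0]
            assert cleaned == pytest.approx(base, abs=1e-8)

    def test_mean_spectrum_predicts_mean_response(self):
        rng = np.random.default_rng(13)
        X, y = make_instance(rng, n=30, p=20)
        model = opls.fit(X, y, 1)
        pred = opls.predict(model, X.mean(axis=0))[0]
        assert pred == pytest.approx(y.mean(), abs=1e-10)

    def test_feature_count_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        X, y = make_instance(rng, n=20, p=30)
        model = opls.fit(X, y, 0)
        with pytest.raises(ValueError, match="mismatch"):
            opls.predict(model, np.zeros(29))


class TestCrossValidate:
    def test_perfect_rank_one_relation_q2_near_one(self):
        rng = np.random.default_rng(21)
        t = rng.standard_normal(50)
        X = np.outer(t, rng.standard_normal(30))
        res = opls.cross_validate(X, t, 0, folds=7, seed=0)
        assert res.q2 >= 0.999

    def test_per_fold_press_sums_to_press(self):
        rng = np.random.default_rng(22)
        X, y = make_instance(rng, n=35, p=25)
        res = opls.cross_validate(X, y, 1, folds=7, seed=3)
        assert res.press == pytest.approx(res.per_fold_press.sum(), rel=1e-12)
        assert res.rmsecv == pytest.approx(np.sqrt(res.press / len(y)), rel=1e-12)

    def test_fold_assignment_stratified_over_response(self):
        rng = np.random.default_rng(23)
        X, y = make_instance(rng, n=70, p=10)
        res = opls.cross_validate(X, y, 0, folds=7, seed=1)
        # the 7 largest responses land in 7 different folds
        top = np.argsort(y)[-7:]
        assert len(set(res.fold_assignment[top])) == 7

    def test_too_many_folds_rejected(self):
        rng = np.random.default_rng(24)
        X, y = make_instance(rng, n=5, p=10)
        with pytest.raises(ValueError, match="folds"):
            opls.cross_validate(X, y, 0, folds=7)


class TestSelectComponents:
    def test_no_orthogonal_structure_selects_zero(self):
        rng = np.random.default_rng(31)
        t = rng.standard_normal(50)
        X = np.outer(t, rng.standard_normal(30)) + 0.001 * rng.standard_normal((50, 30))
        best, results = opls.select_components(X, t, max_orth=3, folds=7, seed=0)
        assert best == 0
        assert len(results) == 4

    def test_two_planted_directions_select_two(self):
        rng = np.random.default_rng(32)
        X, y, _, _ = make_orthogonal_instance(
            rng, n=80, p=50, n_orth=2, amplitude=20.0, overlap=0.5
        )
        X += 0.01 * rng.standard_normal(X.shape)
        best, _ = opls.select_components(X, y, max_orth=4, folds=7, seed=0)
        assert best == 2

    def test_candidate_list_length(self):
        rng = np.random.default_rng(33)
        X, y = make_instance(rng, n=30, p=20)
        _, results = opls.select_components(X, y, max_orth=5, folds=5, seed=0)
        assert [r.n_orth for r in results] == list(range(6))


class TestPredictionVector:
    def test_coefficients_reproduce_predict(self):
        rng = np.random.default_rng(41)
        X, y, _, _ = make_orthogonal_instance(rng, n_orth=2, overlap=0.4)
        model = opls.fit(X, y, 2)
        X_new = rng.standard_normal((5, X.shape[1]))
        manual = (X_new - model.x_mean) @ model.prediction_vector + model.y_mean
        np.testing.assert_allclose(manual, opls.predict(model, X_new), atol=1e-10)

    def test_wavelength_annotation(self):
        rng = np.random.default_rng(42)
        X, y = make_instance(rng, n=20, p=11)
        model = opls.fit(X, y, 0)
        wl = np.arange(1000, 1011)
        series = opls.extract_prediction_vector(model, wl)
        assert list(series.index) == list(wl)


class TestSerialization:
    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(51)
        X, y, _, _ = make_orthogonal_instance(rng, n_orth=2)
        model = opls.fit(X, y, 2, metadata={"matrix_kind": "raw"})
        path = tmp_path / "model.json"
        opls.save_model(model, path)
        back = opls.load_model(path)
        X_new = rng.standard_normal((4, X.shape[1]))
        np.testing.assert_array_equal(opls.predict(back, X_new), opls.predict(model, X_new))
        np.testing.assert_array_equal(back.x_mean, model.x_mean)
        assert back.metadata["matrix_kind"] == "raw"

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format": "other"}')
        with pytest.raises(ValueError, match="model file"):
            opls.load_model(path)
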