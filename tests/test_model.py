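import numpy as np
import pytest

from vtlocate import (
    LEAD_ORDER,
    IntegralVector,
    PopulationCoefficients,
    QRSSiteModel,
    TrainingSample,
    fit_population_coefficients,
    load_coefficients,
    predict_site,
    save_coefficients,
)
from vtlocate.model import (
    CoefficientsIOError,
    LeadOrderError,
    RankDeficientWarning,
)


def samples_from_arrays(X, Y):
    return [
        TrainingSample(IntegralVector(x), y) for x, y in zip(X, Y)
    ]


def random_full_rank_problem(seed=0, n=20):
    """Targets generated exactly by known 9x3 coefficients from random
    full-dimensional integrals."""
    rng = np.random.default_rng(seed)
    W = rng.normal(0, 2, (9, 3))
    X = rng.normal(0, 30, (n, 8))
    Y = W[0] + X @ W[1:]
    return W, X, Y


class TestFitting:
    def test_exact_recovery_on_noiseless_full_rank_data(self):
        W, X, Y = random_full_rank_problem()
        coeffs = fit_population_coefficients(samples_from_arrays(X, Y))
        np.testing.assert_allclose(coeffs.as_matrix(), W, rtol=1e-8, atol=1e-8)

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X = rng.normal(0, 20, (60, 8))
        Y = rng.normal(0, 10, (60, 3))
        coeffs = fit_population_coefficients(samples_from_arrays(X, Y))
        Xc = sm.add_constant(X)
        for j, arr in enumerate((coeffs.alpha, coeffs.beta, coeffs.gamma)):
            ref = sm.OLS(Y[:, j], Xc).fit().params
            np.testing.assert_allclose(arr, ref, rtol=1e-7, atol=1e-8)

    def test_single_sample_min_norm_reproduces_target(self):
        x = np.array([5.0, -3, 2, 1, 0, 4, -2, 7])
        tgt = np.array([10.0, -4.0, 3.0])
        with pytest.warns(RankDeficientWarning):
            coeffs = fit_population_coefficients(
                [TrainingSample(IntegralVector(x), tgt)]
            )
        pred = predict_site(coeffs, IntegralVector(x))
        np.testing.assert_allclose(pred.point, tgt, atol=1e-9)

    def test_constant_targets_give_intercept_only_min_norm_fit(self):
        rng = np.random.default_rng(2)
        X = np.tile(rng.normal(0, 10, 8), (5, 1))  # identical integrals
        Y = np.tile([4.0, -1.0, 2.5], (5, 1))
        with pytest.warns(RankDeficientWarning):
            res = QRSSiteModel(Y, X).fit()
        pred = res.predict(X[0])
        np.testing.assert_allclose(pred, [4.0, -1.0, 2.5], atol=1e-9)

    def test_normal_equations_zero_gradient(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 15, (40, 8))
        Y = rng.normal(0, 20, (40, 3))
        res = QRSSiteModel(Y, X).fit()
        Xc = np.column_stack([np.ones(40), X])
        grad = Xc.T @ (Xc @ res.coefficients.as_matrix() - Y)
        np.testing.assert_allclose(grad, 0.0, atol=1e-8)

    def test_translation_and_scaling_equivariance(self):
        W, X, Y = random_full_rank_problem(seed=3)
        base = fit_population_coefficients(samples_from_arrays(X, Y))
        d = np.array([5.0, -7.0, 11.0])
        shifted = fit_population_coefficients(samples_from_arrays(X, Y + d))
        np.testing.assert_allclose(
            shifted.as_matrix()[0], base.as_matrix()[0] + d, rtol=1e-8
        )
        np.testing.assert_allclose(
            shifted.as_matrix()[1:], base.as_matrix()[1:], rtol=1e-8
        )
        s = 4.0
        scaled = fit_population_coefficients(samples_from_arrays(X * s, Y))
        np.testing.assert_allclose(
            scaled.as_matrix()[1:], base.as_matrix()[1:] / s, rtol=1e-8
        )
        np.testing.assert_allclose(
            scaled.as_matrix()[0], base.as_matrix()[0], rtol=1e-7, atol=1e-8
        )

    def test_empty_and_non_finite_training_rejected(self):
        with pytest.raises(ValueError):
            fit_population_coefficients([])
        with pytest.raises(ValueError):
            QRSSiteModel(np.full((3, 3), np.inf), np.zeros((3, 8)))

    def test_summary_mentions_fit_shape(self):
        _, X, Y = random_full_rank_problem(seed=4)
        text = QRSSiteModel(Y, X).fit().summary()
        assert "n = 20" in text and "rank = 9/9" in text
        assert "slope[V6]" in text


class TestPrediction:
    def test_zero_slopes_return_intercepts(self):
        coeffs = PopulationCoefficients(
            [1] + [0] * 8, [2] + [0] * 8, [3] + [0] * 8
        )
        pred = predict_site(coeffs, IntegralVector(np.random.normal(size=8)))
        np.testing.assert_array_equal(pred.point, [1.0, 2.0, 3.0])

    def test_zero_integrals_return_intercepts(self):
        W, X, Y = random_full_rank_problem(seed=8)
        coeffs = fit_population_coefficients(samples_from_arrays(X, Y))
        pred = predict_site(coeffs, IntegralVector(np.zeros(8)))
        np.testing.assert_allclose(pred.point, coeffs.as_matrix()[0], rtol=1e-8)

    def test_noiseless_synthetic_held_out_prediction_exact(self, noiseless_dataset, default_mesh):
        train = noiseless_dataset.samples[:100]
        test = noiseless_dataset.samples[100:]
        with pytest.warns(RankDeficientWarning):
            res = QRSSiteModel.from_samples(
                [s.training_sample(default_mesh) for s in train]
            ).fit()
        for s in test:
            pred = res.predict(s.integrals)
            np.testing.assert_allclose(
                pred, default_mesh.centroid_of(s.true_element), atol=1e-6
            )

    def test_lead_order_mismatch_refused(self):
        coeffs = PopulationCoefficients(np.zeros(9), np.zeros(9), np.zeros(9))
        wrong = IntegralVector(
            np.zeros(8), lead_order=tuple(reversed(LEAD_ORDER))
        )
        with pytest.raises(LeadOrderError):
            predict_site(coeffs, wrong)


class TestCoefficientIO:
    def test_round_trip_full_precision(self, tmp_path):
        W, X, Y = random_full_rank_problem(seed=11)
        coeffs = fit_population_coefficients(samples_from_arrays(X, Y))
        path = tmp_path / "coeffs.json"
        save_coefficients(coeffs, path)
        back = load_coefficients(path)
        np.testing.assert_array_equal(back.as_matrix(), coeffs.as_matrix())
        assert back.n == coeffs.n and back.lead_order == coeffs.lead_order

    def test_missing_intercept_schema_error(self, tmp_path):
        path = tmp_path / "coeffs.json"
        coeffs = PopulationCoefficients(np.ones(9), np.ones(9), np.ones(9))
        save_coefficients(coeffs, path)
        doc = path.read_text().replace(
            '"alpha": [\n  1.0,', '"alpha": ['
        )
        path.write_text(doc)
        with pytest.raises(CoefficientsIOError):
            load_coefficients(path)

    def test_tampered_lead_order_refused(self, tmp_path):
        path = tmp_path / "coeffs.json"
        save_coefficients(
            PopulationCoefficients(np.ones(9), np.ones(9), np.ones(9)), path
        )
        path.write_text(path.read_text().replace('"V6"', '"V9"'))
        with pytest.raises(CoefficientsIOError, match="lead order"):
            load_coefficients(path)

    def test_bad_version_refused(self, tmp_path):
        path = tmp_path / "coeffs.json"
        save_coefficients(
            PopulationCoefficients(np.ones(9), np.ones(9), np.ones(9)), path
        )
        path.write_text(path.read_text().replace('"format_version": 1', '"format_version": 99'))
        with pytest.raises(CoefficientsIOError, match="version"):
            load_coefficients(path)
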