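"""Quadratic decomposition, evaluation, minimization and PSD repair."""

import numpy as np
import pytest

from gaussfm import (
    LabeledDataset,
    QuadraticObjective,
    UnboundedObjectiveError,
    decompose_linear,
    decompose_logistic,
    evaluate,
    minimize,
    repair_psd,
    symmetric_gaussian_matrix,
)
from gaussfm.data import CLASSIFICATION, REGRESSION
from gaussfm.objective import LOGISTIC_TAYLOR_COEFFS


def _loop_linear_coeffs(ds):
    """Independent loop-based evaluation of the squared-error coefficient sums."""
    n, d = ds.n_samples, ds.n_features
    beta = sum(y * y for y in ds.labels) / n
    alpha = np.zeros(d)
    quad = np.zeros((d, d))
    for x, y in zip(ds.features, ds.labels):
        alpha += -2.0 * y * x / n
        quad += np.outer(x, x) / n
    return beta, alpha, quad


def _direct_linear_cost(ds, w):
    return np.mean([(y - x @ w) ** 2 for x, y in zip(ds.features, ds.labels)])


def _direct_logistic_cost(ds, w):
    z = ds.features @ w
    return np.mean(np.log1p(np.exp(z)) - ds.labels * z)


def _random_regression(rng, n, d):
    x = rng.uniform(-1, 1, size=(n, d))
    x /= np.maximum(1.0, np.linalg.norm(x, axis=1))[:, None]
    return LabeledDataset(x, rng.uniform(-1, 1, size=n), REGRESSION)


class TestDecomposeLinear:
    def test_all_zero_dataset(self):
        ds = LabeledDataset(np.zeros((3, 2)), np.zeros(3), REGRESSION)
        obj = decompose_linear(ds)
        assert obj.constant == 0.0
        np.testing.assert_array_equal(obj.linear, 0.0)
        np.testing.assert_array_equal(obj.quadratic, 0.0)

    def test_hand_worked_example(self, toy_linear):
        obj = decompose_linear(toy_linear)
        assert obj.constant == pytest.approx(1.0)
        np.testing.assert_allclose(obj.linear, [-1.0, 1.0])
        np.testing.assert_allclose(obj.quadratic, np.diag([0.5, 0.5]))
        # cross-check against the loop oracle
        beta, alpha, quad = _loop_linear_coeffs(toy_linear)
        assert obj.constant == pytest.approx(beta)
        np.testing.assert_allclose(obj.linear, alpha)
        np.testing.assert_allclose(obj.quadratic, quad)

    def test_matches_direct_cost_on_random_data(self, rng):
        for _ in range(100):
            ds = _random_regression(rng, int(rng.integers(2, 200)), int(rng.integers(1, 10)))
            w = rng.normal(size=ds.n_features)
            obj = decompose_linear(ds)
            assert evaluate(obj, w) == pytest.approx(
                _direct_linear_cost(ds, w), abs=1e-10
            )

    def test_quadratic_is_gram_matrix(self, rng):
        ds = _random_regression(rng, 40, 6)
        obj = decompose_linear(ds)
        np.testing.assert_allclose(
            obj.quadratic, ds.features.T @ ds.features / 40, atol=1e-14
        )

    def test_rejects_classification(self):
        ds = LabeledDataset(np.zeros((2, 1)), np.array([0.0, 1.0]), CLASSIFICATION)
        with pytest.raises(ValueError):
            decompose_linear(ds)


class TestDecomposeLogistic:
    def test_constant_is_log2(self, rng):
        for _ in range(5):
            n = int(rng.integers(1, 30))
            x = rng.uniform(-0.5, 0.5, size=(n, 3))
            y = rng.integers(0, 2, size=n).astype(float)
            obj = decompose_logistic(LabeledDataset(x, y, CLASSIFICATION))
            assert obj.constant == pytest.approx(np.log(2.0), abs=0)

    def test_single_sample_hand_example(self):
        ds = LabeledDataset(np.array([[1.0, 0.0]]), np.array([1.0]), CLASSIFICATION)
        obj = decompose_logistic(ds)
        np.testing.assert_allclose(obj.linear, [-0.5, 0.0])
        np.testing.assert_allclose(obj.quadratic, [[0.125, 0.0], [0.0, 0.0]])

    def test_taylor_surrogate_remainder(self, rng):
        # the surrogate is the order-2 expansion of the exact cross-entropy at
        # w = 0; the remainder must vanish at cubic (or better) rate
        x = rng.uniform(-1, 1, size=(50, 4))
        x /= np.maximum(1.0, np.linalg.norm(x, axis=1))[:, None]
        y = rng.integers(0, 2, size=50).astype(float)
        ds = LabeledDataset(x, y, CLASSIFICATION)
        obj = decompose_logistic(ds)
        ratios = []
        for _ in range(50):
            w = rng.normal(size=4)
            w *= rng.uniform(0.001, 0.01) / np.linalg.norm(w)
            diff = abs(evaluate(obj, w) - _direct_logistic_cost(ds, w))
            ratios.append(diff / np.linalg.norm(w) ** 3)
        assert max(ratios) < 1.0

    def test_surrogate_at_zero_equals_exact_cost(self, rng):
        x = rng.uniform(-0.5, 0.5, size=(20, 3))
        y = rng.integers(0, 2, size=20).astype(float)
        ds = LabeledDataset(x, y, CLASSIFICATION)
        obj = decompose_logistic(ds)
        assert evaluate(obj, np.zeros(3)) == pytest.approx(
            _direct_logistic_cost(ds, np.zeros(3)), abs=1e-12
        )

    def test_taylor_coefficients(self):
        assert LOGISTIC_TAYLOR_COEFFS[0] == pytest.approx(np.log(2.0))
        assert LOGISTIC_TAYLOR_COEFFS[1] == 0.5
        assert LOGISTIC_TAYLOR_COEFFS[2] == 0.125  # f''(0)/2! = (1/4)/2


class TestEvaluateAndMinimize:
    def test_evaluate_at_zero_returns_constant(self, toy_linear):
        obj = decompose_linear(toy_linear)
        assert evaluate(obj, np.zeros(2)) == obj.constant

    def test_toy_minimum(self, toy_linear):
        obj = decompose_linear(toy_linear)
        assert evaluate(obj, np.array([1.0, -1.0])) == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(minimize(obj), [1.0, -1.0], atol=1e-12)

    def test_dimension_mismatch(self, toy_linear):
        obj = decompose_linear(toy_linear)
        with pytest.raises(ValueError):
            evaluate(obj, np.zeros(3))

    def test_zero_linear_part_minimizer_is_zero(self):
        obj = QuadraticObjective(0.5, np.zeros(3), np.eye(3), "linear")
        np.testing.assert_array_equal(minimize(obj), 0.0)

    def test_unbounded_objective_raises(self):
        obj = QuadraticObjective(0.0, np.array([1.0, 0.0]), np.zeros((2, 2)), "linear")
        with pytest.raises(UnboundedObjectiveError):
            minimize(obj)

    def test_agrees_with_coordinate_descent_oracle(self, rng):
        def cd_minimize(obj, sweeps=4000):
            # exact coordinate updates on a strictly convex quadratic
            d = obj.dim
            w = np.zeros(d)
            m, a = obj.quadratic, obj.linear
            for _ in range(sweeps):
                for i in range(d):
                    # df/dw_i = a_i + 2 sum_j m_ij w_j = 0
                    w[i] = -(a[i] + 2 * (m[i] @ w - m[i, i] * w[i])) / (2 * m[i, i])
            return w

        for _ in range(50):
            d = int(rng.integers(2, 6))
            root = rng.normal(size=(d, d))
            m = root @ root.T / d + 0.1 * np.eye(d)  # strictly PD
            a = rng.normal(size=d)
            obj = QuadraticObjective(0.0, a, m, "linear")
            np.testing.assert_allclose(minimize(obj), cd_minimize(obj), atol=1e-6)

    def test_gradient_norm_at_solution(self, rng):
        ds = _random_regression(rng, 80, 5)
        obj = decompose_linear(ds)
        w = minimize(obj)
        grad = 2 * obj.quadratic @ w + obj.linear
        assert np.linalg.norm(grad) <= 1e-8 * max(1.0, np.linalg.norm(obj.linear))

    def test_noiseless_minimize_matches_least_squares(self, rng):
        for _ in range(10):
            ds = _random_regression(rng, 60, 4)
            obj = repair_psd(decompose_linear(ds))
            w_ls, *_ = np.linalg.lstsq(ds.features, ds.labels, rcond=None)
            np.testing.assert_allclose(minimize(obj), w_ls, atol=1e-8)


class TestSymmetricNoise:
    def test_zero_sd_gives_zero_matrix(self, rng):
        np.testing.assert_array_equal(symmetric_gaussian_matrix(4, 0.0, rng), 0.0)

    def test_exact_symmetry(self, rng):
        m = symmetric_gaussian_matrix(6, 2.5, rng)
        np.testing.assert_array_equal(m, m.T)

    def test_entry_variance(self, rng):
        sd = 1.7
        draws = np.array(
            [symmetric_gaussian_matrix(3, sd, rng)[0, 1] for _ in range(100_000)]
        )
        assert draws.var() == pytest.approx(sd**2, rel=0.05)

    def test_evaluate_invariant_under_symmetrization(self, rng):
        # the quadratic form only sees the symmetric part of M
        m = symmetric_gaussian_matrix(3, 1.0, rng)
        obj = QuadraticObjective(0.3, rng.normal(size=3), m, "linear")
        w = rng.normal(size=3)
        sym = QuadraticObjective(0.3, obj.linear, 0.5 * (m + m.T), "linear")
        assert evaluate(obj, w) == pytest.approx(evaluate(sym, w), abs=1e-12)


class TestRepairPsd:
    def test_psd_input_unchanged(self, rng):
        root = rng.normal(size=(4, 4))
        m = root @ root.T
        obj = QuadraticObjective(1.0, np.zeros(4), m, "linear")
        np.testing.assert_allclose(repair_psd(obj).quadratic, m, atol=1e-12)
        assert not repair_psd(obj).psd_clipped

    def test_offdiagonal_example(self):
        obj = QuadraticObjective(
            0.0, np.zeros(2), np.array([[0.0, 1.0], [1.0, 0.0]]), "linear"
        )
        fixed = repair_psd(obj)
        np.testing.assert_allclose(fixed.quadratic, [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)
        assert fixed.psd_clipped

    def test_diagonal_example(self):
        obj = QuadraticObjective(0.0, np.zeros(2), np.diag([1.0, -2.0]), "linear")
        np.testing.assert_allclose(
            repair_psd(obj).quadratic, np.diag([1.0, 0.0]), atol=1e-14
        )

    def test_idempotent_and_eigenvalues_never_decrease(self, rng):
        for _ in range(20):
            m = symmetric_gaussian_matrix(5, 1.0, rng)
            obj = QuadraticObjective(0.0, np.zeros(5), m, "linear")
            once = repair_psd(obj)
            twice = repair_psd(once)
            np.testing.assert_allclose(twice.quadratic, once.quadratic, atol=1e-12)
            assert np.all(
                np.sort(np.linalg.eigvalsh(once.quadratic))
                >= np.sort(np.linalg.eigvalsh(m)) - 1e-12
            )
            assert np.linalg.eigvalsh(once.quadratic).min() >= -1e-10

    def test_all_negative_eigenvalues_flagged(self):
        obj = QuadraticObjective(0.0, np.ones(2), -np.eye(2), "linear")
        with pytest.warns(RuntimeWarning, match="all eigenvalues"):
            fixed = repair_psd(obj)
        assert fixed.psd_warning
        with pytest.raises(UnboundedObjectiveError):
            minimize(fixed)

    def test_constant_and_linear_untouched(self, rng):
        obj = QuadraticObjective(
            0.7, rng.normal(size=3), symmetric_gaussian_matrix(3, 1.0, rng), "linear"
        )
        fixed = repair_psd(obj)
        assert fixed.constant == obj.constant
        np.testing.assert_array_equal(fixed.linear, obj.linear)


class TestSerialization:
    def test_json_roundtrip(self, toy_linear):
        obj = decompose_linear(toy_linear)
        back = QuadraticObjective.from_json(obj.to_json())
        assert back.constant == obj.constant
        np.testing.assert_array_equal(back.linear, obj.linear)
        np.testing.assert_array_equal(back.quadratic, obj.quadratic)
        assert back.model == obj.model

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            QuadraticObjective(0.0, np.zeros(2), np.array([[0.0, 1.0], [0.0, 0.0]]), "linear")
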