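import numpy as np
import pytest

from gosvm import kernel_svm as ks
from oracles import oracle_svm


class TestSigmaHeuristic:
    def test_median_of_nearest_negative_distances(self):
        X = np.array([[0, 0], [4, 0], [1, 0], [2, 0], [9, 0]], float)
        y = np.array([1, 1, -1, -1, -1], float)
        # nearest-negative distances are {1, 2}; even count -> mean of the two
        assert ks.sigma_heuristic(X, y) == 1.5

    def test_single_positive(self):
        X = np.array([[0.0], [3.0], [7.0]])
        y = np.array([1, -1, -1], float)
        assert ks.sigma_heuristic(X, y) == 3.0

    def test_coincident_point_falls_back_to_smallest_nonzero(self):
        # positives {0, 0, 5}, negatives {0, 9}: nearest distances {0, 0, 4}
        # -> median 0 -> fall back to the smallest strictly positive distance
        X = np.array([[0.0], [0.0], [5.0], [0.0], [9.0]])
        y = np.array([1, 1, 1, -1, -1], float)
        assert ks.sigma_heuristic(X, y) == 4.0

    def test_all_coincident_errors(self):
        X = np.zeros((4, 2))
        y = np.array([1, 1, -1, -1], float)
        with pytest.raises(ValueError):
            ks.sigma_heuristic(X, y)

    def test_scale_equivariance(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.r_[np.ones(6), -np.ones(14)]
        s1 = ks.sigma_heuristic(X, y)
        s2 = ks.sigma_heuristic(3.5 * X, y)
        assert s2 == pytest.approx(3.5 * s1, rel=1e-12)
        K1 = ks.rbf_kernel(X, X, s1)
        K2 = ks.rbf_kernel(3.5 * X, 3.5 * X, s2)
        assert np.allclose(K1, K2, atol=1e-12)


class TestRbfKernel:
    def test_self_similarity_is_one(self):
        X = np.array([[1.0, 2.0]])
        assert ks.rbf_kernel(X, X, 2.0)[0, 0] == 1.0

    def test_distance_sigma_gives_exp_minus_one(self):
        a = np.array([[0.0]])
        b = np.array([[2.0]])
        assert ks.rbf_kernel(a, b, 2.0)[0, 0] == pytest.approx(np.exp(-1), rel=1e-12)

    def test_large_sigma_limit(self):
        a, b = np.array([[0.0]]), np.array([[1.0]])
        assert ks.rbf_kernel(a, b, 1e8)[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_sigma_errors(self):
        with pytest.raises(ValueError):
            ks.rbf_kernel(np.zeros((1, 1)), np.zeros((1, 1)), 0.0)


class TestAugmentDiagonal:
    def make_kernel(self, rng, n_pos, n_neg):
        X = rng.normal(size=(n_pos + n_neg, 4))
        y = np.r_[np.ones(n_pos), -np.ones(n_neg)]
        K = ks.KernelMatrix(values=ks.rbf_kernel(X, X, 2.0), sigma=2.0)
        return K, y

    def test_imbalanced_diagonals(self, rng):
        K, y = self.make_kernel(rng, 20, 80)
        Ka = ks.augment_diagonal(K, y)
        d = np.diag(Ka.values)
        assert np.allclose(d[:20], 1.10, atol=1e-12)
        assert np.allclose(d[20:], 1.40, atol=1e-12)
        assert Ka.lam == 0.5 and Ka.m == 1.0
        # with a 1:4 ratio the negative augmentation is exactly 4x the positive
        assert (d[20:] - 1.0)[0] == pytest.approx(4 * (d[:20] - 1.0)[0], rel=1e-12)

    def test_balanced_diagonals(self, rng):
        K, y = self.make_kernel(rng, 10, 10)
        d = np.diag(ks.augment_diagonal(K, y).values)
        assert np.allclose(d, 1.25, atol=1e-12)

    def test_off_diagonal_untouched(self, rng):
        K, y = self.make_kernel(rng, 5, 15)
        before = K.values.copy()
        after = ks.augment_diagonal(K, y).values
        off = ~np.eye(20, dtype=bool)
        assert np.array_equal(after[off], before[off])

    def test_augmented_kernel_positive_semidefinite(self, rng):
        for _ in range(10):
            n_pos = int(rng.integers(2, 10))
            n_neg = int(rng.integers(2, 30))
            K, y = self.make_kernel(rng, n_pos, n_neg)
            Ka = ks.augment_diagonal(K, y)
            assert np.linalg.eigvalsh(Ka.values).min() >= -1e-10

    def test_label_length_mismatch_errors(self, rng):
        K, y = self.make_kernel(rng, 5, 5)
        with pytest.raises(ValueError):
            ks.augment_diagonal(K, y[:-1])


class TestTrainSvm:
    def test_two_point_closed_form(self):
        k = 0.5
        K = np.array([[1.25, k], [k, 1.25]])
        y = np.array([1.0, -1.0])
        model = ks.train_svm(K, y)
        assert model.alphas == pytest.approx([1 / (1.25 - k)] * 2, rel=1e-10)
        assert model.bias == pytest.approx(0.0, abs=1e-10)

    def test_separable_1d_task_classified_correctly(self):
        X = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
        y = np.array([-1, -1, -1, 1, 1, 1], float)
        sigma = ks.sigma_heuristic(X, y)
        Ka = ks.augment_diagonal(
            ks.KernelMatrix(ks.rbf_kernel(X, X, sigma), sigma), y)
        model = ks.train_svm(Ka, y)
        f = ks.discriminants(model, ks.rbf_kernel(X, X, sigma))
        assert np.all(np.sign(f) == y)

    def test_dual_equality_constraint(self, rng):
        for _ in range(5):
            n = int(rng.integers(6, 30))
            n_pos = int(rng.integers(1, n))
            y = np.r_[np.ones(n_pos), -np.ones(n - n_pos)]
            X = rng.normal(size=(n, 3))
            try:
                sigma = ks.sigma_heuristic(X, y)
            except ValueError:
                continue
            Ka = ks.augment_diagonal(
                ks.KernelMatrix(ks.rbf_kernel(X, X, sigma), sigma), y)
            model = ks.train_svm(Ka, y)
            assert abs(model.alphas @ y) <= 1e-8
            assert np.all(model.alphas >= 0)

    def test_oracle_equivalence_small_tasks(self, rng):
        """Objective and discriminants match exhaustive enumeration."""
        for _ in range(40):
            n = int(rng.integers(4, 13))
            n_pos = int(rng.integers(1, n))
            y = np.r_[np.ones(n_pos), -np.ones(n - n_pos)]
            X = rng.normal(size=(n, 3))
            sigma = ks.sigma_heuristic(X, y)
            Ka = ks.augment_diagonal(
                ks.KernelMatrix(ks.rbf_kernel(X, X, sigma), sigma), y).values
            model = ks.train_svm(Ka, y)
            a_o, b_o = oracle_svm(Ka, y)
            assert ks.dual_objective(Ka, y, model.alphas) == pytest.approx(
                ks.dual_objective(Ka, y, a_o), abs=1e-6)
            X_test = rng.normal(size=(4, 3))
            Kc = ks.rbf_kernel(X_test, X, sigma)
            f_mine = ks.discriminants(model, Kc)
            f_oracle = Kc @ (a_o * y) + b_o
            assert np.allclose(f_mine, f_oracle, atol=1e-6)

    def test_against_libsvm_large_box(self, rng):
        """Independent cross-check: libsvm with a precomputed augmented kernel
        and an effectively unbounded box approaches the hard-margin dual."""
        sklearn_svm = pytest.importorskip("sklearn.svm")
        n_pos, n_neg = 8, 32
        y = np.r_[np.ones(n_pos), -np.ones(n_neg)]
        X = rng.normal(size=(n_pos + n_neg, 5))
        sigma = ks.sigma_heuristic(X, y)
        Ka = ks.augment_diagonal(
            ks.KernelMatrix(ks.rbf_kernel(X, X, sigma), sigma), y).values
        model = ks.train_svm(Ka, y)
        clf = sklearn_svm.SVC(kernel="precomputed", C=1e8, tol=1e-10)
        clf.fit(Ka, y)
        f_ref = clf.decision_function(Ka)
        f_mine = Ka @ (model.alphas * y) + model.bias
        assert np.allclose(f_mine, f_ref, atol=1e-3)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ks.train_svm(np.eye(3) * 1.25, np.ones(3))


class TestDiscriminants:
    def test_consistency_on_training_points(self, rng):
        n_pos, n_neg = 5, 20
        y = np.r_[np.ones(n_pos), -np.ones(n_neg)]
        X = rng.normal(size=(n_pos + n_neg, 4))
        sigma = ks.sigma_heuristic(X, y)
        K = ks.rbf_kernel(X, X, sigma)
        Ka = ks.augment_diagonal(ks.KernelMatrix(K, sigma), y)
        model = ks.train_svm(Ka, y)
        f_train = K @ (model.alphas * y) + model.bias
        f_again = ks.discriminants(model, K)
        assert np.allclose(f_train, f_again, atol=1e-8)

    def test_degenerate_all_zero_alphas(self):
        model = ks.SvmModel(alphas=np.zeros(3), bias=0.7,
                            labels=np.array([1.0, -1.0, 1.0]))
        f = ks.discriminants(model, np.random.default_rng(0).random((5, 3)))
        assert np.allclose(f, 0.7)

    def test_shape_mismatch_errors(self):
        model = ks.SvmModel(alphas=np.ones(3), bias=0.0,
                            labels=np.array([1.0, -1.0, 1.0]))
        with pytest.raises(ValueError):
            ks.discriminants(model, np.ones((2, 4)))
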