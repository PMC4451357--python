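import numpy as np
import pytest
from scipy.optimize import minimize

from eigenbrain import (
    ConfigurationError,
    DataError,
    KernelSpec,
    PSOConfig,
    SingleClassError,
    cross_validate,
    decision_function,
    kernel_eval,
    metrics_from_counts,
    predict,
    pso_minimize,
    pso_tune,
    train_svm_smo,
)
from eigenbrain.svm import dual_objective, gram_matrix


def qp_dual_oracle(X, y01, spec):
    """Generic box-constrained QP solution of the SVM dual (SLSQP, multistart)."""
    y = 2.0 * np.asarray(y01, dtype=float) - 1.0
    K = gram_matrix(spec, X)
    n = len(y)
    Q = K * np.outer(y, y)

    def fun(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def jac(a):
        return -(np.ones(n) - Q @ a)

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    best = None
    for s in range(3):
        a0 = np.clip(
            np.random.default_rng(s).uniform(0, min(spec.C, 1.0), n), 0, spec.C
        )
        res = minimize(
            fun, a0, jac=jac, bounds=[(0, spec.C)] * n, constraints=cons,
            method="SLSQP", options={"maxiter": 1000, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


TIGHT = dict(tol=1e-8, max_passes=200, max_sweeps=20000)


class TestKernels:
    def test_rbf_at_zero_distance(self):
        assert kernel_eval(KernelSpec("rbf", sigma=2.0), [1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_pol_reduces_to_linear(self):
        spec = KernelSpec("pol", degree=1, coef0=0.0)
        x, y = np.array([1.0, 2.0, 3.0]), np.array([-1.0, 0.5, 2.0])
        assert kernel_eval(spec, x, y) == pytest.approx(x @ y)

    def test_rbf_unit_sigma_closed_form(self):
        val = kernel_eval(KernelSpec("rbf", sigma=1.0), [1.0, 0.0], [0.0, 0.0])
        assert val == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ConfigurationError):
            kernel_eval(KernelSpec("linear"), [1.0], [1.0, 2.0])

    def test_gram_properties(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        for kind in ("linear", "rbf", "pol"):
            G = gram_matrix(KernelSpec(kind, sigma=1.3, degree=2, coef0=0.5), X)
            assert np.allclose(G, G.T)
        G = gram_matrix(KernelSpec("rbf", sigma=1.0), X)
        assert (G > 0).all() and (G <= 1.0).all()
        assert np.linalg.eigvalsh(G).min() > -1e-10

    def test_invalid_spec(self):
        with pytest.raises(ConfigurationError):
            KernelSpec("rbf", sigma=0.0)
        with pytest.raises(ConfigurationError):
            KernelSpec("linear", C=-1.0)
        with pytest.raises(ConfigurationError):
            KernelSpec("gauss")


class TestSMO:
    def test_symmetric_pair(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        model = train_svm_smo(X, y, KernelSpec("linear", C=1e6), **TIGHT)
        assert model.n_support == 2
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        assert np.array_equal(predict(model, X), y)
        # decision boundary at 0
        assert decision_function(model, [[0.0]])[0] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "spec",
        [
            KernelSpec("linear", C=2.0),
            KernelSpec("rbf", C=5.0, sigma=1.5),
            KernelSpec("pol", C=1.0, degree=3, coef0=1.0),
        ],
        ids=["linear", "rbf", "pol"],
    )
    def test_dual_objective_matches_qp_oracle(self, spec):
        rng = np.random.default_rng(1)
        for _ in range(4):
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(n, 2))
            y = rng.integers(0, 2, n)
            while len(set(y)) < 2:
                y = rng.integers(0, 2, n)
            model = train_svm_smo(X, y, spec, seed=1, **TIGHT)
            ys = 2.0 * y - 1.0
            obj = dual_objective(model.alpha, ys, gram_matrix(spec, X))
            assert obj == pytest.approx(qp_dual_oracle(X, y, spec), abs=1e-4)
            # dual feasibility
            assert abs(model.alpha @ ys) < 1e-6
            assert (model.alpha >= -1e-12).all()
            assert (model.alpha <= spec.C + 1e-12).all()

    def test_single_class_errors(self):
        with pytest.raises(SingleClassError):
            train_svm_smo(np.zeros((3, 1)), [1, 1, 1], KernelSpec("linear"))

    def test_non_finite_errors(self):
        with pytest.raises(DataError):
            train_svm_smo(np.array([[np.nan], [1.0]]), [0, 1], KernelSpec("linear"))


class TestPredict:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.X = np.vstack([rng.normal(-3, 0.5, (10, 2)), rng.normal(3, 0.5, (10, 2))])
        self.y = np.array([0] * 10 + [1] * 10)

    def test_training_labels_reproduced(self):
        model = train_svm_smo(self.X, self.y, KernelSpec("linear", C=10.0), **TIGHT)
        assert np.array_equal(predict(model, self.X), self.y)

    def test_duplicate_non_support_points_irrelevant(self):
        spec = KernelSpec("linear", C=10.0)
        model = train_svm_smo(self.X, self.y, spec, **TIGHT)
        # duplicate two interior (non-support) points far from the margin
        inner = np.array([[-3.2, -3.1], [3.1, 3.2]])
        X2 = np.vstack([self.X, inner, inner])
        y2 = np.concatenate([self.y, [0, 1, 0, 1]])
        model2 = train_svm_smo(X2, y2, spec, **TIGHT)
        grid = np.random.default_rng(3).normal(scale=3.0, size=(30, 2))
        d1 = decision_function(model, grid)
        d2 = decision_function(model2, grid)
        assert np.allclose(d1, d2, atol=1e-3)

    def test_label_flip_antisymmetry(self):
        spec = KernelSpec("rbf", C=5.0, sigma=3.0)
        model = train_svm_smo(self.X, self.y, spec, **TIGHT)
        flipped = train_svm_smo(self.X, 1 - self.y, spec, **TIGHT)
        grid = np.random.default_rng(4).normal(scale=3.0, size=(20, 2))
        assert np.array_equal(
            predict(model, grid), 1 - predict(flipped, grid)
        )

    def test_dimension_mismatch(self):
        model = train_svm_smo(self.X, self.y, KernelSpec("linear"))
        with pytest.raises(ConfigurationError):
            predict(model, np.zeros((2, 5)))


class TestPSO:
    def test_constant_surface(self):
        x, f, hist = pso_minimize(
            lambda p: 3.5, [(-1, 1), (-1, 1)], PSOConfig(n_particles=5, n_iter=5)
        )
        assert f == 3.5
        assert (-1 <= x).all() and (x <= 1).all()

    def test_sphere_function(self):
        x, f, hist = pso_minimize(
            lambda p: float((p**2).sum()),
            [(-5, 5), (-5, 5)],
            PSOConfig(n_particles=20, n_iter=100, seed=0),
        )
        assert f < 1e-3

    def test_history_non_increasing(self):
        _, _, hist = pso_minimize(
            lambda p: float((p**2).sum()),
            [(-5, 5)],
            PSOConfig(n_particles=6, n_iter=30, seed=1),
        )
        assert np.all(np.diff(hist) <= 0)

    def test_seed_determinism(self):
        cfg = PSOConfig(n_particles=8, n_iter=20, seed=7)
        f = lambda p: float(np.sin(p).sum() + (p**2).sum())
        a = pso_minimize(f, [(-3, 3), (-3, 3)], cfg)
        b = pso_minimize(f, [(-3, 3), (-3, 3)], cfg)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_empty_bounds_errors(self):
        with pytest.raises(ConfigurationError):
            pso_minimize(lambda p: 0.0, [], PSOConfig())

    def test_tune_returns_valid_spec_deterministically(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-2, 1, (12, 2)), rng.normal(2, 1, (12, 2))])
        y = np.array([0] * 12 + [1] * 12)
        cfg = PSOConfig(n_particles=4, n_iter=3, seed=9)
        a = pso_tune(X, y, "rbf", pso=cfg, inner_folds=3)
        b = pso_tune(X, y, "rbf", pso=cfg, inner_folds=3)
        assert a == b
        assert a.kind == "rbf" and a.sigma > 0 and a.C > 0


class TestMetricsAndCV:
    def test_confusion_arithmetic(self):
        m = metrics_from_counts(tp=25, fp=8, tn=90, fn=3)
        assert m["accuracy"] * 100 == pytest.approx(91.27, abs=0.005)
        assert m["sensitivity"] * 100 == pytest.approx(89.29, abs=0.005)
        assert m["specificity"] * 100 == pytest.approx(91.84, abs=0.005)
        assert m["precision"] * 100 == pytest.approx(75.76, abs=0.005)

    def test_metric_identity(self):
        m = metrics_from_counts(tp=10, fp=5, tn=20, fn=7)
        assert m["accuracy"] * 42 == pytest.approx(30)

    def test_separable_features_perfect(self):
        rng = np.random.default_rng(6)
        X = np.concatenate([rng.normal(-5, 0.3, 20), rng.normal(5, 0.3, 12)])[:, None]
        y = np.array([0] * 20 + [1] * 12)
        rep = cross_validate(X, y, "linear", n_folds=4, reps=3, seed=0)
        s = rep.summary(percent=True)
        assert s.loc["accuracy", "mean"] == 100.0
        assert s.loc["accuracy", "sd"] == 0.0
        assert rep.tp.sum() + rep.fn.sum() == 3 * 12

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 2))
        y = np.array([0] * 18 + [1] * 12)
        rep = cross_validate(X, y, "rbf", n_folds=3, reps=4, seed=1)
        assert np.all(rep.tp + rep.fp + rep.tn + rep.fn == 30)

    def test_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(24, 3))
        y = np.array([0, 1] * 12)
        a = cross_validate(X, y, "pol", n_folds=3, reps=1, seed=5)
        b = cross_validate(X, y, "pol", n_folds=3, reps=1, seed=5)
        assert np.array_equal(a.tp, b.tp) and np.array_equal(a.fn, b.fn)
        assert np.array_equal(a.fp, b.fp) and np.array_equal(a.tn, b.tn)

    def test_minority_smaller_than_folds_errors(self):
        X = np.zeros((10, 1))
        y = np.array([0] * 8 + [1] * 2)
        with pytest.raises(DataError):
            cross_validate(X, y, "linear", n_folds=5, reps=1)

    def test_single_class_errors(self):
        with pytest.raises(SingleClassError):
            cross_validate(np.zeros((10, 1)), np.zeros(10, dtype=int), "linear", n_folds=2)
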