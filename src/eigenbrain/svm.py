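"""Soft-margin kernel SVM trained by SMO, PSO tuning, and repeated k-fold CV.

Kernels: linear x.y, polynomial (x.y + c)^d, and a radial basis function
exp(-||x - y||^2 / sigma^2) — note the sigma^2 (not 2 sigma^2) denominator.
Training solves the dual with a sequential-minimal-optimization sweep;
hyperparameters can be tuned by particle swarm optimization against inner
cross-validated accuracy. Model assessment uses repeated stratified K-fold
cross-validation with confusion counts summed per repetition; the disease
class (label 1) is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, DataError, SingleClassError

__all__ = [
    "KernelSpec",
    "SVMModel",
    "PSOConfig",
    "CVReport",
    "kernel_eval",
    "gram_matrix",
    "train_svm_smo",
    "decision_function",
    "predict",
    "dual_objective",
    "pso_minimize",
    "pso_tune",
    "metrics_from_counts",
    "cross_validate",
    "DEFAULT_TUNE_BOUNDS",
]

KERNEL_KINDS = ("linear", "rbf", "pol")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its parameters and the soft-margin penalty C."""

    kind: str = "linear"
    C: float = 1.0
    sigma: float = 1.0  # rbf scale; denominator is sigma**2
    degree: int = 3  # pol degree d
    coef0: float = 1.0  # pol offset c

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ConfigurationError(f"unknown kernel kind {self.kind!r}")
        if self.C <= 0:
            raise ConfigurationError("penalty C must be positive")
        if self.sigma <= 0:
            raise ConfigurationError("rbf sigma must be positive")
        if self.degree < 1 or int(self.degree) != self.degree:
            raise ConfigurationError("pol degree must be a positive integer")
        if self.coef0 < 0:
            raise ConfigurationError("pol offset c must be nonnegative")


def kernel_eval(spec: KernelSpec, x, y) -> float:
    """Evaluate the kernel on a single pair of vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if spec.kind == "linear":
        return float(x @ y)
    if spec.kind == "pol":
        return float((x @ y + spec.coef0) ** spec.degree)
    d2 = float(((x - y) ** 2).sum())
    return float(np.exp(-d2 / spec.sigma**2))


def gram_matrix(spec: KernelSpec, X, Y=None) -> np.ndarray:
    """Kernel matrix K[i, j] = kernel(X[i], Y[j]) (Y defaults to X)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ConfigurationError("dimension mismatch between X and Y")
    G = X @ Y.T
    if spec.kind == "linear":
        return G
    if spec.kind == "pol":
        return (G + spec.coef0) ** spec.degree
    sq = (X**2).sum(axis=1)[:, None] + (Y**2).sum(axis=1)[None, :] - 2 * G
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / spec.sigma**2)


@dataclass
class SVMModel:
    """Trained soft-margin SVM in dual form.

    ``dual_coef`` holds alpha_i * y_i for the support vectors only; ``alpha``
    keeps the full training multipliers for diagnostics. Optional scaling
    stats (fitted on the training fold) are applied inside
    :func:`decision_function`.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    spec: KernelSpec
    alpha: np.ndarray = field(repr=False, default=None)
    scale_mu: np.ndarray | None = None
    scale_sd: np.ndarray | None = None

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]


def dual_objective(alpha, y_signed, K) -> float:
    """SVM dual objective sum(alpha) - 1/2 (alpha y)' K (alpha y)."""
    ay = alpha * y_signed
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


def train_svm_smo(
    features,
    labels,
    spec: KernelSpec,
    tol: float = 1e-3,
    max_passes: int = 5,
    max_sweeps: int = 500,
    seed: int = 0,
) -> SVMModel:
    """Train by sequential minimal optimization on the precomputed Gram matrix.

    Sweeps all examples, fixing KKT violators by pairwise updates with a
    randomly drawn partner (seeded, so training is deterministic); stops after
    ``max_passes`` consecutive sweeps without a change or ``max_sweeps`` total.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y01 = np.asarray(labels, dtype=int)
    if not np.isfinite(X).all():
        raise DataError("non-finite feature values")
    if len(np.unique(y01)) < 2:
        raise SingleClassError("training requires both classes")
    n = X.shape[0]
    y = 2.0 * y01 - 1.0
    C = spec.C
    K = gram_matrix(spec, X)
    alpha = np.zeros(n)
    b = 0.0
    rng = np.random.default_rng(seed)

    def f(i):
        return (alpha * y) @ K[:, i] + b

    passes = 0
    sweeps = 0
    while passes < max_passes and sweeps < max_sweeps:
        changed = 0
        for i in range(n):
            e_i = f(i) - y[i]
            if (y[i] * e_i < -tol and alpha[i] < C) or (y[i] * e_i > tol and alpha[i] > 0):
                j = int(rng.integers(n - 1))
                if j >= i:
                    j += 1
                e_j = f(j) - y[j]
                ai_old, aj_old = alpha[i], alpha[j]
                if y[i] != y[j]:
                    lo = max(0.0, aj_old - ai_old)
                    hi = min(C, C + aj_old - ai_old)
                else:
                    lo = max(0.0, ai_old + aj_old - C)
                    hi = min(C, ai_old + aj_old)
                if lo >= hi:
                    continue
                eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
                if eta >= 0:
                    continue
                aj = aj_old - y[j] * (e_i - e_j) / eta
                aj = min(hi, max(lo, aj))
                if abs(aj - aj_old) < 1e-12:
                    continue
                ai = ai_old + y[i] * y[j] * (aj_old - aj)
                alpha[i], alpha[j] = ai, aj
                b1 = b - e_i - y[i] * (ai - ai_old) * K[i, i] - y[j] * (aj - aj_old) * K[i, j]
                b2 = b - e_j - y[i] * (ai - ai_old) * K[i, j] - y[j] * (aj - aj_old) * K[j, j]
                if 0 < ai < C:
                    b = b1
                elif 0 < aj < C:
                    b = b2
                else:
                    b = (b1 + b2) / 2.0
                changed += 1
        passes = passes + 1 if changed == 0 else 0
        sweeps += 1

    sv = alpha > 1e-10
    return SVMModel(
        support_vectors=X[sv].copy(),
        dual_coef=(alpha * y)[sv].copy(),
        bias=float(b),
        spec=spec,
        alpha=alpha,
    )


def decision_function(model: SVMModel, features) -> np.ndarray:
    """Signed distance-like decision values for a batch of feature rows."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.support_vectors.shape[1]:
        raise ConfigurationError(
            f"feature dimension {X.shape[1]} != training dimension "
            f"{model.support_vectors.shape[1]}"
        )
    if model.scale_mu is not None:
        X = (X - model.scale_mu) / model.scale_sd
    K = gram_matrix(model.spec, X, model.support_vectors)
    return K @ model.dual_coef + model.bias


def predict(model: SVMModel, features) -> np.ndarray:
    """Binary labels: 1 (disease, positive class) where the decision value > 0."""
    return (decision_function(model, features) > 0).astype(int)


# ---------------------------------------------------------------------------
# Particle swarm optimization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSOConfig:
    n_particles: int = 20
    n_iter: int = 50
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 2:
            raise ConfigurationError("swarm needs at least 2 particles")
        if self.n_iter < 1:
            raise ConfigurationError("need at least 1 iteration")


def pso_minimize(
    func: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: PSOConfig,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Global-best PSO on a box; returns (best x, best f, best-so-far history).

    Positions are clamped to the bounds; the best-so-far history is
    non-increasing by construction. Deterministic for a fixed config seed.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.size == 0:
        raise ConfigurationError("empty bounds")
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ConfigurationError("bounds must be a sequence of (lo, hi) pairs")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.isfinite(bounds).all() or (lo > hi).any():
        raise ConfigurationError("bounds must be finite and ordered")
    rng = np.random.default_rng(config.seed)
    dim = len(bounds)
    span = hi - lo
    x = lo + rng.uniform(size=(config.n_particles, dim)) * span
    v = rng.uniform(-1, 1, size=(config.n_particles, dim)) * span * 0.1
    fx = np.array([func(p) for p in x])
    pbest_x = x.copy()
    pbest_f = fx.copy()
    g = int(pbest_f.argmin())
    gbest_x = pbest_x[g].copy()
    gbest_f = float(pbest_f[g])
    history = [gbest_f]
    for _ in range(config.n_iter):
        r1 = rng.uniform(size=(config.n_particles, dim))
        r2 = rng.uniform(size=(config.n_particles, dim))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x - x)
        )
        x = np.clip(x + v, lo, hi)
        fx = np.array([func(p) for p in x])
        better = fx < pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = fx[better]
        g = int(pbest_f.argmin())
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        history.append(gbest_f)
    return gbest_x, gbest_f, np.asarray(history)


#: log2/linear search boxes per kernel kind: C on a log2 scale for all kinds,
#: rbf sigma on log2 scale, pol offset c linear and degree d in {2..5}.
DEFAULT_TUNE_BOUNDS = {
    "linear": [(-5.0, 15.0)],
    "rbf": [(-5.0, 15.0), (-15.0, 3.0)],
    "pol": [(-5.0, 15.0), (0.0, 10.0), (2.0, 5.0)],
}


def _spec_from_vector(kind: str, x: np.ndarray) -> KernelSpec:
    if kind == "linear":
        return KernelSpec(kind="linear", C=2.0 ** x[0])
    if kind == "rbf":
        return KernelSpec(kind="rbf", C=2.0 ** x[0], sigma=2.0 ** x[1])
    return KernelSpec(
        kind="pol", C=2.0 ** x[0], coef0=float(x[1]), degree=int(round(x[2]))
    )


def _fold_accuracy(features, labels, spec, n_folds, seed) -> float:
    """Mean accuracy of a single stratified n_fold CV with fixed folds."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        model = train_svm_smo((X[tr] - mu) / sd, y[tr], spec, seed=seed)
        pred = predict(model, (X[te] - mu) / sd)
        correct += int((pred == y[te]).sum())
    return correct / len(y)


def pso_tune(
    features,
    labels,
    kind: str,
    pso: PSOConfig | None = None,
    inner_folds: int = 5,
    bounds: Sequence[tuple[float, float]] | None = None,
) -> KernelSpec:
    """PSO search for the kernel spec maximizing inner-CV accuracy."""
    if kind not in KERNEL_KINDS:
        raise ConfigurationError(f"unknown kernel kind {kind!r}")
    pso = pso or PSOConfig()
    if bounds is None:
        bounds = DEFAULT_TUNE_BOUNDS[kind]

    def loss(x):
        spec = _spec_from_vector(kind, x)
        return 1.0 - _fold_accuracy(features, labels, spec, inner_folds, pso.seed)

    best_x, _, _ = pso_minimize(loss, bounds, pso)
    return _spec_from_vector(kind, best_x)


# ---------------------------------------------------------------------------
# Repeated stratified K-fold cross-validation
# ---------------------------------------------------------------------------

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision")


def metrics_from_counts(tp, fp, tn, fn) -> dict[str, float]:
    """The four confusion-matrix metrics, as fractions in [0, 1]."""
    total = tp + fp + tn + fn
    if total == 0:
        raise DataError("empty confusion counts")

    def safe(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": safe(tp + tn, total),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "precision": safe(tp, tp + fp),
    }


@dataclass
class CVReport:
    """Confusion counts per repetition plus mean/SD metric aggregation."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    spec: KernelSpec
    n_folds: int
    seed: int

    @property
    def n_reps(self) -> int:
        return len(self.tp)

    def per_rep_metrics(self) -> pd.DataFrame:
        rows = [
            metrics_from_counts(self.tp[r], self.fp[r], self.tn[r], self.fn[r])
            for r in range(self.n_reps)
        ]
        return pd.DataFrame(rows)

    def summary(self, percent: bool = True) -> pd.DataFrame:
        """Mean and SD of the four metrics across repetitions."""
        per = self.per_rep_metrics()
        scale = 100.0 if percent else 1.0
        return pd.DataFrame(
            {
                "mean": per.mean() * scale,
                "sd": per.std(ddof=1 if self.n_reps > 1 else 0) * scale,
            }
        )


def cross_validate(
    features,
    labels,
    spec: KernelSpec | str = "linear",
    n_folds: int = 10,
    reps: int = 50,
    seed: int = 0,
    tune: PSOConfig | None = None,
    nested: bool = True,
    inner_folds: int = 5,
) -> CVReport:
    """Repeated stratified K-fold CV with per-repetition summed confusion counts.

    Features are standardized inside each fold by training-fold statistics.
    If ``tune`` is given, hyperparameters are PSO-tuned: nested mode re-tunes
    on each training fold; non-nested mode tunes once on the full data before
    splitting.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if isinstance(spec, str):
        spec = KernelSpec(kind=spec)
    if len(y) < n_folds:
        raise DataError(f"need at least n_folds={n_folds} subjects")
    if len(np.unique(y)) < 2:
        raise SingleClassError("both classes required for cross-validation")
    if np.bincount(y).min() < n_folds:
        raise DataError("minority class smaller than n_folds: stratification fails")

    if tune is not None and not nested:
        spec = pso_tune(X, y, spec.kind, pso=tune, inner_folds=inner_folds)

    rng = np.random.default_rng(seed)
    tp = np.zeros(reps, dtype=int)
    fp = np.zeros(reps, dtype=int)
    tn = np.zeros(reps, dtype=int)
    fn = np.zeros(reps, dtype=int)
    for rep in range(reps):
        fold_seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        for tr, te in skf.split(X, y):
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0, ddof=1)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr = (X[tr] - mu) / sd
            Xte = (X[te] - mu) / sd
            fold_spec = spec
            if tune is not None and nested:
                fold_spec = pso_tune(
                    Xtr, y[tr], spec.kind, pso=replace(tune, seed=fold_seed),
                    inner_folds=inner_folds,
                )
            model = train_svm_smo(Xtr, y[tr], fold_spec, seed=fold_seed)
            pred = predict(model, Xte)
            truth = y[te]
            tp[rep] += int(((pred == 1) & (truth == 1)).sum())
            fp[rep] += int(((pred == 1) & (truth == 0)).sum())
            tn[rep] += int(((pred == 0) & (truth == 0)).sum())
            fn[rep] += int(((pred == 0) & (truth == 1)).sum())
    return CVReport(tp=tp, fp=fp, tn=tn, fn=fn, spec=spec, n_folds=n_folds, seed=seed)
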