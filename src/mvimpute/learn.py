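"""Feature selection and classification.

Feature selection is either a plain two-sample t-test filter or a two-stage
wrapper: t-test down to a manageable pool, then sequential forward floating
search (SFFS) driven by bolstered resubstitution error.  Three
classification rules are supported: pooled-covariance LDA, 3-nearest
neighbours, and a linear soft-margin SVM (C = 1).

Bolstered resubstitution replaces each training point by a spherical
Gaussian kernel whose width is set from the class's mean nearest-neighbour
distance (the kernel's median radial distance equals that mean distance);
the error is the average kernel mass on the wrong side of the decision
boundary — closed form for linear rules, Monte Carlo for 3NN.  This
smooths the optimistic bias of plain resubstitution at small sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .impute import ImputationConfig
from .types import ClassLabels, ExpressionMatrix, MissingMask

__all__ = [
    "FeatureSet",
    "TrainedClassifier",
    "t_statistics",
    "select_top_t",
    "bolstered_error",
    "sffs_select",
    "two_stage_select",
    "train",
    "predict",
]

RULES = ("lda", "3nn", "svm")


@dataclass
class FeatureSet:
    """Ordered gene indices with optional per-feature criterion values."""

    indices: list[int]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        self.indices = [int(i) for i in self.indices]
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("feature indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class TrainedClassifier:
    """A fitted decision rule plus everything needed to apply it later.

    For linear rules the decision is ``label 1 iff w.x + b > 0`` (ties go
    to class 0).  ``training_reference`` optionally keeps the measured
    training matrix, mask and imputation config so future test points can
    be completed using the training data alone.
    """

    rule: str
    features: FeatureSet
    w: np.ndarray | None = None
    b: float | None = None
    knn: KNeighborsClassifier | None = None
    training_reference: tuple[ExpressionMatrix, MissingMask, ImputationConfig] | None = None
    extra: dict = field(default_factory=dict)


def t_statistics(matrix: ExpressionMatrix, labels: ClassLabels) -> np.ndarray:
    """Two-sample pooled-variance t statistic per gene (class 0 minus 1)."""
    labels.require_two_classes()
    y = labels.labels
    X0, X1 = matrix.values[:, y == 0], matrix.values[:, y == 1]
    n0, n1 = X0.shape[1], X1.shape[1]
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 samples")
    m0, m1 = X0.mean(axis=1), X1.mean(axis=1)
    sp2 = ((n0 - 1) * X0.var(axis=1, ddof=1)
           + (n1 - 1) * X1.var(axis=1, ddof=1)) / (n0 + n1 - 2)
    denom = np.sqrt(sp2 * (1 / n0 + 1 / n1)) + 1e-12
    return (m0 - m1) / denom


def select_top_t(matrix: ExpressionMatrix, labels: ClassLabels,
                 n_features: int) -> FeatureSet:
    """Genes with largest |t|, ordered decreasing, ties to the lower index."""
    n_genes = matrix.shape[0]
    if not 1 <= n_features <= n_genes:
        raise ValueError(f"n_features must be in [1, {n_genes}]")
    t = t_statistics(matrix, labels)
    order = np.lexsort((np.arange(n_genes), -np.abs(t)))[:n_features]
    return FeatureSet(order.tolist(), scores=np.abs(t)[order].tolist())


def _bolster_sigmas(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-point kernel SDs: class mean same-class nearest-neighbour
    distance divided by the median of the chi(D) distribution."""
    D = X.shape[1]
    c_d = float(stats.chi.median(D))
    sigmas = np.zeros(len(y))
    for c in (0, 1):
        pts = X[y == c]
        if len(pts) < 2:
            raise ValueError("each class needs at least 2 samples")
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        mean_nn = float(np.sqrt(d2.min(axis=1)).mean())
        sigmas[y == c] = mean_nn / c_d
    return sigmas


def _linear_decision(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    return X @ clf.w + clf.b


def bolstered_error(matrix: ExpressionMatrix, labels: ClassLabels,
                    features: FeatureSet, rule: str,
                    mc_points: int = 200,
                    rng: np.random.Generator | None = None,
                    classifier: TrainedClassifier | None = None) -> float:
    """Bolstered resubstitution error of ``rule`` on the selected features.

    Linear rules use the closed-form Gaussian tail mass; 3NN uses
    ``mc_points`` Monte-Carlo draws per training point from ``rng``.
    Zero kernel width (identical points) degrades to plain resubstitution.
    """
    y = labels.labels
    X = matrix.values[features.indices].T
    clf = classifier or train(rule, matrix, labels, features)
    sigmas = _bolster_sigmas(X, y)

    if clf.rule in ("lda", "svm"):
        score = _linear_decision(clf, X)
        norm_w = float(np.linalg.norm(clf.w))
        if norm_w == 0:
            # degenerate rule: constant decision (score = b everywhere)
            wrong = (score > 0) != (y == 1)
            return float(wrong.mean())
        margin = score / norm_w
        errs = np.empty(len(y))
        for i in range(len(y)):
            s = sigmas[i]
            if s == 0:
                pred1 = score[i] > 0
                errs[i] = float(pred1 != (y[i] == 1))
            elif y[i] == 1:
                errs[i] = stats.norm.cdf(-margin[i] / s)
            else:
                errs[i] = stats.norm.cdf(margin[i] / s)
        return float(errs.mean())

    # 3NN: Monte Carlo
    if rng is None:
        rng = np.random.default_rng(0)
    errs = np.empty(len(y))
    for i in range(len(y)):
        if sigmas[i] == 0:
            pred = clf.knn.predict(X[i][None, :])
            errs[i] = float(pred[0] != y[i])
            continue
        draws = X[i] + sigmas[i] * rng.standard_normal((mc_points, X.shape[1]))
        preds = clf.knn.predict(draws)
        errs[i] = float((preds != y[i]).mean())
    return float(errs.mean())


def _criterion_cache(matrix: ExpressionMatrix, labels: ClassLabels,
                     rule: str, mc_points: int, seed: int):
    cache: dict[tuple[int, ...], float] = {}

    def J(subset: list[int]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            rng = np.random.default_rng(seed)
            cache[key] = bolstered_error(matrix, labels, FeatureSet(list(key)),
                                         rule, mc_points=mc_points, rng=rng)
        return cache[key]

    return J


def sffs_select(matrix: ExpressionMatrix, labels: ClassLabels,
                pool: FeatureSet, target_size: int, rule: str,
                mc_points: int = 200, seed: int = 0) -> FeatureSet:
    """Sequential forward floating search over ``pool``.

    Greedy forward additions minimising bolstered error, with conditional
    backward removals: after each addition, the least significant feature
    is removed if it is not the one just added and the reduced set beats
    the best set of that size found so far.  Criterion ties break toward
    the lower feature index.  Returns the best set of ``target_size``.
    """
    pool_idx = list(pool.indices)
    if target_size > len(pool_idx):
        raise ValueError("target_size exceeds pool size")
    if target_size == len(pool_idx):
        return FeatureSet(list(pool_idx))
    J = _criterion_cache(matrix, labels, rule, mc_points, seed)

    A: list[int] = []
    best: dict[int, tuple[float, list[int]]] = {}

    def record(S: list[int]) -> None:
        c = J(S)
        k = len(S)
        if k not in best or c < best[k][0]:
            best[k] = (c, list(S))

    max_steps = 20 * len(pool_idx)
    steps = 0
    while steps < max_steps:
        steps += 1
        # forward: add the feature minimising the criterion
        cands = [f for f in pool_idx if f not in A]
        scored = sorted((J(A + [f]), f) for f in cands)
        last_added = scored[0][1]
        A.append(last_added)
        record(A)
        # backward: conditional exclusions
        removed = False
        guard = last_added
        while len(A) > 2:
            rem = sorted((J([f for f in A if f != g]), g) for g in A)
            c_red, g = rem[0]
            if guard is not None and g == guard:
                break
            k = len(A) - 1
            if k in best and c_red < best[k][0]:
                A = [f for f in A if f != g]
                record(A)
                removed = True
                guard = None
            else:
                break
        if len(A) == target_size and not removed:
            break
    c, S = best[target_size]
    return FeatureSet(S, scores=[c] * len(S))


def two_stage_select(matrix: ExpressionMatrix, labels: ClassLabels,
                     stage1_size: int, target_size: int, rule: str,
                     mc_points: int = 200, seed: int = 0) -> FeatureSet:
    """t-test filter to ``stage1_size`` genes, then SFFS to ``target_size``."""
    if not target_size <= stage1_size <= matrix.shape[0]:
        raise ValueError("need target_size <= stage1_size <= n_genes")
    pool = select_top_t(matrix, labels, stage1_size)
    return sffs_select(matrix, labels, pool, target_size, rule,
                       mc_points=mc_points, seed=seed)


def train(rule: str, matrix: ExpressionMatrix, labels: ClassLabels,
          features: FeatureSet,
          training_reference=None) -> TrainedClassifier:
    """Fit a decision rule on the selected features.

    lda
        Pooled-covariance linear discriminant, equal priors, with a small
        ridge (1e-6 * trace/D) on the covariance diagonal; ties at the
        boundary go to class 0.
    3nn
        Euclidean 3-nearest neighbours on the stored training points.
    svm
        Linear soft-margin SVM with cost parameter 1.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {RULES}")
    labels.require_two_classes()
    y = labels.labels
    X = matrix.values[features.indices].T
    D = X.shape[1]

    if rule == "lda":
        X0, X1 = X[y == 0], X[y == 1]
        if len(X0) < 2 or len(X1) < 2:
            raise ValueError("each class needs at least 2 samples")
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        n0, n1 = len(X0), len(X1)
        S = ((n0 - 1) * np.cov(X0, rowvar=False)
             + (n1 - 1) * np.cov(X1, rowvar=False)) / (n0 + n1 - 2)
        S = np.atleast_2d(S)
        S = S + np.eye(D) * (1e-6 * np.trace(S) / D)
        try:
            Sinv = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("pooled covariance singular after ridge") from exc
        a = Sinv @ (m0 - m1)
        mid = (m0 + m1) / 2
        # g(x) = a.(x - mid) >= 0 -> class 0; normalise to w.x + b > 0 -> 1
        w, b = -a, float(a @ mid)
        return TrainedClassifier("lda", features, w=w, b=b,
                                 training_reference=training_reference,
                                 extra={"means": (m0, m1)})

    if rule == "svm":
        svc = SVC(kernel="linear", C=1.0)
        svc.fit(X, y)
        return TrainedClassifier("svm", features,
                                 w=svc.coef_.ravel().copy(),
                                 b=float(svc.intercept_[0]),
                                 training_reference=training_reference)

    knn = KNeighborsClassifier(n_neighbors=3)
    knn.fit(X, y)
    return TrainedClassifier("3nn", features, knn=knn,
                             training_reference=training_reference)


def predict(classifier: TrainedClassifier, x: np.ndarray) -> np.ndarray | int:
    """Predict 0/1 labels for one complete feature vector or a batch
    (rows = points), already restricted to ``classifier.features``."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    D = len(classifier.features)
    if X.shape[1] != D:
        raise ValueError(f"expected {D} features, got {X.shape[1]}")
    if classifier.rule in ("lda", "svm"):
        out = (_linear_decision(classifier, X) > 0).astype(int)
    else:
        out = classifier.knn.predict(X).astype(int)
    return int(out[0]) if np.asarray(x).ndim == 1 else out
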