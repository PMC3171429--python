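"""Missing-value imputation: RAVG, KNNimpute, LLS.L2, LLS.PC, LS, BPCA.

All methods share one contract: the returned matrix is complete and equals
the input at every unmasked cell.  A gene whose missing entries are being
estimated is the *target*; the genes used to estimate it form its *candidate
set*.  The local methods differ in how candidates are chosen (Euclidean
distance or |Pearson correlation|) and how their values are combined
(convex weighted average, unconstrained least squares, or a correlation-
weighted mixture of single-gene regressions); BPCA instead fits one global
probabilistic PCA model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import ExpressionMatrix, MissingMask, check_aligned

logger = logging.getLogger("mvimpute")

__all__ = [
    "ImputationConfig",
    "TargetContext",
    "impute",
    "impute_ravg",
    "knn_candidates",
    "impute_knn",
    "impute_lls",
    "impute_ls",
    "impute_bpca",
]

METHODS = ("RAVG", "KNN", "LLS_L2", "LLS_PC", "LS", "BPCA")


def normalize_method(token: str) -> str:
    name = token.strip().upper().replace("-", "_").replace(".", "_")
    if name not in METHODS:
        raise ValueError(f"unknown imputation method {token!r}; "
                         f"choose from {METHODS}")
    return name


@dataclass(frozen=True)
class ImputationConfig:
    """Settings shared by the imputation algorithms.

    k_neighbors
        Neighbours for KNNimpute (values of 10-20 work well in practice).
    k_candidates
        Candidate-set size for LLS and LS; keep well below the number of
        observed positions per gene or the local regression saturates.
    distance_epsilon
        Added to every distance before reciprocal weighting, so exact
        duplicates dominate without dividing by zero.
    bpca_max_iter / bpca_tol
        Variational-Bayes iteration cap and RMS-change convergence tolerance
        on the imputed entries.
    """

    method: str = "RAVG"
    k_neighbors: int = 10
    k_candidates: int = 10
    distance_epsilon: float = 1e-6
    bpca_max_iter: int = 200
    bpca_tol: float = 1e-3

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", normalize_method(self.method))
        if self.k_neighbors < 1 or self.k_candidates < 1:
            raise ValueError("neighbour/candidate counts must be >= 1")
        if self.distance_epsilon <= 0 or self.bpca_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.bpca_max_iter < 1:
            raise ValueError("bpca_max_iter must be >= 1")


@dataclass
class TargetContext:
    """Bookkeeping for one target gene during imputation."""

    target_index: int
    observed_positions: np.ndarray
    missing_positions: np.ndarray
    candidates: list = field(default_factory=list)  # (gene index, score)


def _validate(matrix: ExpressionMatrix, mask: MissingMask) -> None:
    check_aligned(matrix, mask)
    mask.validate_no_empty_gene()
    if matrix.shape[0] < 2:
        raise ValueError("imputation needs at least 2 genes")


def _result(matrix: ExpressionMatrix, values: np.ndarray) -> ExpressionMatrix:
    return ExpressionMatrix(values, list(matrix.gene_ids), list(matrix.sample_ids))


def impute(matrix: ExpressionMatrix, mask: MissingMask,
           config: ImputationConfig,
           target_rows: np.ndarray | None = None) -> ExpressionMatrix:
    """Dispatch to the configured method and return a completed matrix.

    ``target_rows`` optionally restricts the local methods (everything except
    BPCA) to filling only those gene rows; remaining masked cells keep their
    row-average fill.  This is used when only part of the completion is
    consumed, e.g. completing a single adjoined test sample.
    """
    method = config.method
    if method == "RAVG":
        return impute_ravg(matrix, mask)
    if method == "KNN":
        return impute_knn(matrix, mask, config, target_rows=target_rows)
    if method in ("LLS_L2", "LLS_PC"):
        return impute_lls(matrix, mask, config,
                          metric="L2" if method == "LLS_L2" else "PC",
                          target_rows=target_rows)
    if method == "LS":
        return impute_ls(matrix, mask, config, target_rows=target_rows)
    if method == "BPCA":
        from .bpca import impute_bpca
        return impute_bpca(matrix, mask, config)
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover


def _row_means(values: np.ndarray, flags: np.ndarray) -> np.ndarray:
    obs = ~flags
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("gene with no observed values")
    # per-row slice + mean, so fills agree bitwise with np.mean of the
    # observed entries
    return np.array([values[i, obs[i]].mean() for i in range(values.shape[0])])


def ravg_fill(values: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Row-average fill of a bare array (helper shared by several methods)."""
    means = _row_means(values, flags)
    out = values.copy()
    rows, cols = np.nonzero(flags)
    out[rows, cols] = means[rows]
    return out


def impute_ravg(matrix: ExpressionMatrix, mask: MissingMask) -> ExpressionMatrix:
    """Fill each gene's missing entries with its observed mean."""
    _validate(matrix, mask)
    return _result(matrix, ravg_fill(matrix.values, mask.flags))


def _target_rows(mask: MissingMask, target_rows: np.ndarray | None) -> np.ndarray:
    rows = np.flatnonzero(mask.flags.any(axis=1))
    if target_rows is not None:
        rows = np.intersect1d(rows, np.asarray(target_rows, dtype=int))
    return rows


def knn_candidates(matrix: ExpressionMatrix, mask: MissingMask,
                   target: TargetContext, K: int) -> list[tuple[int, float]]:
    """K nearest eligible genes to a target.

    Eligible genes are observed at every one of the target's missing
    positions.  Distance is Euclidean over positions where both target and
    candidate are observed, scaled by the number of such positions (so genes
    with different observation patterns are comparable).  Ties break toward
    the lower gene index; fewer than K eligible genes are all returned.
    An empty eligible set returns [] (callers fall back to row average).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    V, F = matrix.values, mask.flags
    i = target.target_index
    obs = ~F
    eligible = obs[:, target.missing_positions].all(axis=1)
    eligible[i] = False
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return []
    joint = obs[idx] & obs[i]
    counts = joint.sum(axis=1)
    keep = counts > 0
    idx, joint, counts = idx[keep], joint[keep], counts[keep]
    if idx.size == 0:
        return []
    diffs = np.where(joint, V[idx] - V[i], 0.0)
    dists = np.sqrt((diffs ** 2).sum(axis=1) / counts)
    order = np.lexsort((idx, dists))[:K]
    return [(int(idx[o]), float(dists[o])) for o in order]


def impute_knn(matrix: ExpressionMatrix, mask: MissingMask,
               config: ImputationConfig,
               target_rows: np.ndarray | None = None) -> ExpressionMatrix:
    """KNNimpute: convex combination of the K nearest genes' values with
    weights proportional to 1/(distance + epsilon)."""
    _validate(matrix, mask)
    V, F = matrix.values, mask.flags
    out = V.copy()
    for i in _target_rows(mask, target_rows):
        miss = np.flatnonzero(F[i])
        ctx = TargetContext(i, np.flatnonzero(~F[i]), miss)
        cands = knn_candidates(matrix, mask, ctx, config.k_neighbors)
        if not cands:
            logger.info("gene %s: no eligible KNN candidates; "
                        "falling back to row average", matrix.gene_ids[i])
            out[i, miss] = V[i, ~F[i]].mean()
            continue
        if len(cands) < config.k_neighbors:
            logger.debug("gene %s: only %d eligible candidates (K=%d)",
                         matrix.gene_ids[i], len(cands), config.k_neighbors)
        g_idx = np.array([g for g, _ in cands])
        w = 1.0 / (np.array([d for _, d in cands]) + config.distance_epsilon)
        w /= w.sum()
        out[i, miss] = w @ V[np.ix_(g_idx, miss)]
    return _result(matrix, out)


def _abs_pearson(filled: np.ndarray, obs: np.ndarray, i: int) -> np.ndarray:
    """|Pearson correlation| of every gene with target i over jointly
    observed positions (on the row-average-filled matrix for values, but the
    joint-observation pattern comes from the true mask).  Genes with fewer
    than 3 joint positions or zero variance get correlation 0."""
    n = filled.shape[0]
    r = np.zeros(n)
    joint = obs & obs[i]
    counts = joint.sum(axis=1)
    ok = counts >= 3
    ok[i] = False
    x = filled[i]
    for g in np.flatnonzero(ok):
        j = joint[g]
        xg, yg = x[j], filled[g, j]
        sx, sy = xg.std(), yg.std()
        if sx == 0 or sy == 0:
            continue
        r[g] = abs(np.corrcoef(xg, yg)[0, 1])
    return r


def _abs_pearson_fast(filled: np.ndarray, obs: np.ndarray, i: int) -> np.ndarray:
    """Vectorised version of :func:`_abs_pearson`."""
    joint = obs & obs[i]
    counts = joint.sum(axis=1).astype(float)
    x = filled[i]
    xj = np.where(joint, x[None, :], 0.0)
    yj = np.where(joint, filled, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = xj.sum(1) / counts
        sy = yj.sum(1) / counts
        sxy = (xj * yj).sum(1) / counts - sx * sy
        sxx = (xj ** 2).sum(1) / counts - sx ** 2
        syy = (yj ** 2).sum(1) / counts - sy ** 2
        r = np.abs(sxy) / np.sqrt(sxx * syy)
    r[~np.isfinite(r)] = 0.0
    r[counts < 3] = 0.0
    r[i] = 0.0
    return np.clip(r, 0.0, 1.0)


def _select_candidates(score: np.ndarray, k: int, largest: bool) -> np.ndarray:
    """Top-k gene indices by score; ties toward the lower index."""
    key = -score if largest else score
    order = np.lexsort((np.arange(score.size), key))
    return order[:k]


def impute_lls(matrix: ExpressionMatrix, mask: MissingMask,
               config: ImputationConfig, metric: str = "L2",
               target_rows: np.ndarray | None = None) -> ExpressionMatrix:
    """Local least squares: regress the target's observed part on its
    candidates' observed parts and apply the weights to their missing parts.

    Candidates (row-average pre-filled) are the ``k_candidates`` genes
    closest in Euclidean distance over the target's observed positions
    (LLS.L2) or with largest |Pearson correlation| over jointly observed
    positions (LLS.PC).  The weight vector is the minimum-norm least-squares
    solution (pseudoinverse), so the combination need not be convex.
    """
    if metric not in ("L2", "PC"):
        raise ValueError("metric must be 'L2' or 'PC'")
    _validate(matrix, mask)
    V, F = matrix.values, mask.flags
    obs = ~F
    filled = ravg_fill(V, F)
    out = V.copy()
    k = min(config.k_candidates, matrix.shape[0] - 1)
    for i in _target_rows(mask, target_rows):
        miss = np.flatnonzero(F[i])
        ob = np.flatnonzero(obs[i])
        if metric == "L2":
            d = np.sqrt(((filled[:, ob] - V[i, ob]) ** 2).sum(axis=1))
            d[i] = np.inf
            cands = _select_candidates(d, k, largest=False)
        else:
            r = _abs_pearson_fast(filled, obs, i)
            cands = _select_candidates(r, k, largest=True)
        A_obs = filled[np.ix_(cands, ob)]      # k x |obs|
        A_miss = filled[np.ix_(cands, miss)]   # k x |miss|
        w, *_ = np.linalg.lstsq(A_obs.T, V[i, ob], rcond=None)
        out[i, miss] = A_miss.T @ w
    return _result(matrix, out)


def ls_weight(r: np.ndarray) -> np.ndarray:
    """Unnormalised LS combination weight, ``(r^2 / (1 - r^2 + 1e-6))^2``."""
    return (r ** 2 / (1.0 - r ** 2 + 1e-6)) ** 2


def impute_ls(matrix: ExpressionMatrix, mask: MissingMask,
              config: ImputationConfig,
              target_rows: np.ndarray | None = None) -> ExpressionMatrix:
    """LS imputation: convex combination of single-gene regression estimates.

    Each of the ``k_candidates`` most |correlated| genes yields a univariate
    regression estimate of the target at its missing positions; the
    estimates are averaged with normalised weights that grow steeply with
    |correlation|.  Zero-variance candidates get correlation 0 and weight 0.
    """
    _validate(matrix, mask)
    V, F = matrix.values, mask.flags
    obs = ~F
    filled = ravg_fill(V, F)
    out = V.copy()
    k = min(config.k_candidates, matrix.shape[0] - 1)
    for i in _target_rows(mask, target_rows):
        miss = np.flatnonzero(F[i])
        ob = np.flatnonzero(obs[i])
        r_all = _abs_pearson_fast(filled, obs, i)
        cands = _select_candidates(r_all, k, largest=True)
        x_obs = V[i, ob]
        x_mean = x_obs.mean()
        estimates = np.empty((len(cands), miss.size))
        r_sel = r_all[cands]
        for c, g in enumerate(cands):
            yg = filled[g, ob]
            var = yg.var()
            if var == 0 or r_sel[c] == 0:
                estimates[c] = x_mean
                continue
            slope = np.cov(x_obs, yg, bias=True)[0, 1] / var
            intercept = x_mean - slope * yg.mean()
            estimates[c] = intercept + slope * filled[g, miss]
        w = ls_weight(r_sel)
        total = w.sum()
        if total <= 0:
            out[i, miss] = x_mean
        else:
            out[i, miss] = (w / total) @ estimates
    return _result(matrix, out)


def impute_bpca(matrix: ExpressionMatrix, mask: MissingMask,
                config: ImputationConfig) -> ExpressionMatrix:
    """BPCA imputation (see :mod:`mvimpute.bpca` for the model)."""
    from .bpca import impute_bpca as _impute_bpca
    return _impute_bpca(matrix, mask, config)
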