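"""Bayesian PCA imputation.

Each gene row is treated as one observation of dimension ``d`` (the number
of samples), modelled as ``y = W x + mu + eps`` with ``q = d - 1`` latent
factors, isotropic Gaussian residual of precision ``tau``, and an automatic
relevance determination (ARD) prior on the factor loadings: each loading
column has its own Gaussian prior precision ``alpha_j``, estimated from the
data, so redundant factors are driven to zero and the effective
dimensionality is inferred rather than chosen.  A variational (EM-like)
loop alternates posterior expectations of the factor scores and missing
entries with updates of ``W``, ``mu``, ``tau`` and ``alpha``; missing
entries are filled with their posterior means.

Initialisation is deterministic: row-average fill followed by an
eigendecomposition of the sample covariance, so repeated runs are bitwise
identical without a random seed.

Implementation notes.  The per-row posterior precision differs from the
shared ``Rx = I + tau W'W + SigW`` only by the row's missing coordinates,
``Rx_i = Rx - tau Wm' Wm``, so its inverse is formed with the Woodbury
identity from small per-row m x m systems; rows are processed in batches
bucketed by their missing count so that padding stays tight.  When a
single extra sample column is adjoined to an already-fitted matrix (test-
point completion), :func:`extend_model` grafts a loading row for the new
column onto the fitted model by regressing the column's observed values on
the training factor scores, after which a couple of refinement iterations
suffice.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import warnings

import numpy as np

from .types import ExpressionMatrix, MissingMask, check_aligned
from .impute import ImputationConfig, ravg_fill

logger = logging.getLogger("mvimpute")

__all__ = ["BPCAModel", "bpca_fit", "impute_bpca", "effective_factors",
           "extend_model"]

# hyperpriors (broad / weakly informative), and bounds keeping tau finite
_GALPHA0 = 1e-10
_BALPHA0 = 1.0
_GMU0 = 1e-3
_GTAU0 = 1e-10
_BTAU0 = 1.0
_TAU_MIN = 1e-10
_TAU_MAX = 1e10

# a factor counts as retained while its loading column explains more
# variance than the residual noise: ||w_j||^2 * tau > _EFFECTIVE_RATIO
_EFFECTIVE_RATIO = 1.0


@dataclass
class BPCAModel:
    """Fitted parameter state (reusable as a warm start)."""

    W: np.ndarray          # d x q loadings
    mu: np.ndarray         # d mean vector
    tau: float             # residual precision
    alpha: np.ndarray      # q ARD precisions
    SigW: np.ndarray       # q x q shared loading posterior covariance
    n_iter: int = 0
    converged: bool = False

    @property
    def q(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "BPCAModel":
        return BPCAModel(self.W.copy(), self.mu.copy(), self.tau,
                         self.alpha.copy(), self.SigW.copy(),
                         self.n_iter, self.converged)


def effective_factors(model: BPCAModel) -> int:
    """Number of loading columns whose explained variance exceeds the
    residual noise variance (ARD-suppressed columns fall far below it)."""
    norms2 = (model.W ** 2).sum(axis=0)
    return int((norms2 * model.tau > _EFFECTIVE_RATIO).sum())


def factor_scores(model: BPCAModel, filled: np.ndarray) -> np.ndarray:
    """Posterior-mean factor scores of each (completed) row."""
    Rx = (np.eye(model.q) + model.tau * (model.W.T @ model.W) + model.SigW)
    Rxinv = np.linalg.inv(Rx)
    return model.tau * (filled - model.mu) @ model.W @ Rxinv.T


def extend_model(model: BPCAModel, train_filled: np.ndarray,
                 new_col: np.ndarray, new_col_mask: np.ndarray,
                 scores: np.ndarray | None = None) -> BPCAModel:
    """Extend a fitted model with one adjoined sample column.

    The new column's loading row and mean are estimated by regressing its
    observed values on the training rows' factor scores, ridge-regularised
    by the model's own ARD precisions (the MAP estimate of a loading row,
    which keeps suppressed factors' coefficients at zero); all other
    parameters carry over unchanged.
    """
    X = factor_scores(model, train_filled) if scores is None else scores
    obs = ~np.asarray(new_col_mask, dtype=bool)
    y = np.asarray(new_col)[obs]
    mu_new = float(y.mean())
    Xo = X[obs]
    A = Xo.T @ Xo + np.diag(model.alpha) / max(model.tau, 1e-10)
    w_new = np.linalg.solve(A, Xo.T @ (y - mu_new))
    return BPCAModel(W=np.vstack([model.W, w_new]),
                     mu=np.append(model.mu, mu_new),
                     tau=model.tau, alpha=model.alpha.copy(),
                     SigW=model.SigW.copy())


def _init_model(yest: np.ndarray, q: int) -> BPCAModel:
    N, d = yest.shape
    mu = yest.mean(axis=0)
    covy = np.cov(yest, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(covy)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    W = evecs[:, :q] * np.sqrt(evals[:q])
    resid = max(float(np.trace(covy) - evals[:q].sum()), 1e-8)
    tau = float(np.clip(1.0 / resid, _TAU_MIN, _TAU_MAX))
    alpha = (2 * _GALPHA0 + d) / (tau * (W ** 2).sum(axis=0)
                                  + 2 * _GALPHA0 / _BALPHA0)
    return BPCAModel(W=W, mu=mu, tau=tau, alpha=alpha, SigW=np.eye(q))


def _plan_rows(flags: np.ndarray):
    """Complete-row indices plus incomplete rows bucketed by missing count
    (payload per bucket: rows, padded missing indices, pad mask)."""
    counts = flags.sum(axis=1)
    comp = np.flatnonzero(counts == 0)
    groups = []
    bounds = [1, 2, 4, 8, 16, 32, 64, 128, 256, 1 << 30]
    lo = 1
    for hi in bounds:
        sel = np.flatnonzero((counts >= lo) & (counts <= hi))
        lo = hi + 1
        if sel.size == 0:
            continue
        m_max = int(counts[sel].max())
        idx = np.zeros((sel.size, m_max), dtype=int)
        pad = np.zeros((sel.size, m_max), dtype=bool)
        for r, i in enumerate(sel):
            mi = np.flatnonzero(flags[i])
            idx[r, :mi.size] = mi
            pad[r, :mi.size] = True
        groups.append((sel, idx, pad))
    return comp, groups


def _do_step(model: BPCAModel, yest: np.ndarray, flags: np.ndarray,
             comp: np.ndarray, groups) -> None:
    """One variational update; fills missing entries of ``yest`` in place."""
    N, d = yest.shape
    q = model.q
    W, mu, tau = model.W, model.mu, model.tau

    Rx = np.eye(q) + tau * (W.T @ W) + model.SigW
    Rxinv = np.linalg.inv(Rx)
    WRx = W @ Rxinv                                       # (d, q)
    RxWt = Rxinv @ W.T                                    # (q, d)

    T = np.zeros((d, q))
    trS = 0.0
    if comp.size:
        dyc = yest[comp] - mu
        xc = tau * (dyc @ W) @ Rxinv.T
        T += dyc.T @ xc
        trS += float((dyc ** 2).sum())

    for rows, midx, mpad in groups:
        # Woodbury pieces for Rx_i = Rx - tau Wm' Wm per incomplete row;
        # C = Wm Rxinv and P = Rxinv Wm' are gathers of precomputed products
        Wm = W[midx] * mpad[..., None]                    # (r, m, q)
        C = WRx[midx] * mpad[..., None]                   # (r, m, q)
        P = RxWt[:, midx].transpose(1, 0, 2) * mpad[:, None, :]  # (r, q, m)
        m_max = Wm.shape[1]
        WmP = np.matmul(Wm, P)                            # Wm Rxinv Wm'
        S = np.eye(m_max)[None] - tau * WmP
        Sinv = np.linalg.inv(S)

        # factor scores: x = tau Rxinv_i (W' dyo)
        dyo = np.where(flags[rows], 0.0, yest[rows] - mu)
        v = dyo @ W                                       # (r, q)
        u = np.einsum("ab,rb->ra", Rxinv, v)
        e = np.einsum("rmn,rn->rm", Sinv, np.einsum("rma,ra->rm", Wm, u))
        x = tau * (u + tau * np.einsum("ram,rm->ra", P, e))

        # posterior mean of missing coordinates, scattered into yest
        dym = np.einsum("rma,ra->rm", Wm, x)
        flat = (rows[:, None] * d + midx)[mpad]
        yest.ravel()[flat] = (mu[midx] + dym)[mpad]

        dyr = yest[rows] - mu
        T += dyr.T @ x
        # posterior-covariance corrections: Wm Rxinv_i rows add into T,
        # and tr(Wm Rxinv_i Wm') into trS
        WmR = C + tau * np.matmul(np.matmul(WmP, Sinv), C)
        np.add.at(T, midx[mpad], WmR[mpad])
        trS += float((dyr ** 2).sum())
        trS += float(mpad.sum()) / tau
        trS += float(np.einsum("rmb,rmb->", WmR, Wm))

    T /= N
    trS /= N

    Dw = Rxinv + tau * (T.T @ W) @ Rxinv + np.diag(model.alpha) / N
    Dwinv = np.linalg.inv(Dw)
    W_new = T @ Dwinv
    tau_new = ((d + 2 * _GTAU0 / N)
               / (trS - float(np.trace(T.T @ W_new))
                  + (float(mu @ mu) * _GMU0 + 2 * _GTAU0 / _BTAU0) / N))
    model.W = W_new
    model.tau = float(np.clip(tau_new, _TAU_MIN, _TAU_MAX))
    model.SigW = Dwinv * (d / N)
    model.alpha = ((2 * _GALPHA0 + d)
                   / (model.tau * (W_new ** 2).sum(axis=0)
                      + np.diag(model.SigW) + 2 * _GALPHA0 / _BALPHA0))
    model.mu = yest.mean(axis=0)


def bpca_fit(matrix: ExpressionMatrix, mask: MissingMask,
             config: ImputationConfig | None = None,
             warm_start: BPCAModel | None = None,
             max_iter: int | None = None,
             tol: float | None = None,
             init_values: np.ndarray | None = None,
             watch: np.ndarray | None = None) -> tuple[ExpressionMatrix, BPCAModel]:
    """Fit the BPCA model and return (completed matrix, fitted model).

    ``warm_start`` resumes from previously fitted parameters (any factor
    count up to d - 1 is accepted, so a model extended with
    :func:`extend_model` can seed the fit of an augmented matrix);
    ``init_values`` optionally provides a complete matrix whose values
    initialise the missing entries instead of the row-average fill;
    ``watch`` optionally restricts the convergence check to a boolean
    subset of entries (those the caller will consume).
    """
    config = config or ImputationConfig(method="BPCA")
    check_aligned(matrix, mask)
    mask.validate_no_empty_gene()
    flags = mask.flags
    N, d = matrix.shape
    if d < 3:
        raise ValueError("BPCA needs at least 3 samples")
    max_iter = config.bpca_max_iter if max_iter is None else max_iter
    tol = config.bpca_tol if tol is None else tol

    if init_values is not None:
        yest = matrix.values.copy()
        yest[flags] = np.asarray(init_values)[flags]
    else:
        yest = ravg_fill(matrix.values, flags)
    if not flags.any():
        model = warm_start.copy() if warm_start else _init_model(yest, d - 1)
        model.converged = True
        return ExpressionMatrix(yest, list(matrix.gene_ids),
                                list(matrix.sample_ids)), model

    warm_ok = (warm_start is not None and warm_start.W.shape[0] == d
               and 1 <= warm_start.q <= d - 1)
    model = warm_start.copy() if warm_ok else _init_model(yest, d - 1)
    comp, groups = _plan_rows(flags)

    conv_flags = flags if watch is None else (flags & watch)
    if not conv_flags.any():
        conv_flags = flags
    prev = yest[conv_flags].copy()
    model.converged = False
    change = np.inf
    for it in range(1, max_iter + 1):
        _do_step(model, yest, flags, comp, groups)
        cur = yest[conv_flags]
        change = float(np.sqrt(np.mean((cur - prev) ** 2)))
        prev = cur.copy()
        model.n_iter = it
        if change < tol:
            model.converged = True
            break
    if not model.converged:
        warnings.warn("BPCA did not converge within "
                      f"{max_iter} iterations (last change {change:.2e}); "
                      "returning best iterate", RuntimeWarning)
    logger.debug("BPCA: %d iterations, %d effective factors, tau=%.3g",
                 model.n_iter, effective_factors(model), model.tau)
    out = matrix.values.copy()
    out[flags] = yest[flags]
    return ExpressionMatrix(out, list(matrix.gene_ids),
                            list(matrix.sample_ids)), model


def impute_bpca(matrix: ExpressionMatrix, mask: MissingMask,
                config: ImputationConfig | None = None,
                warm_start: BPCAModel | None = None,
                max_iter: int | None = None) -> ExpressionMatrix:
    """BPCA imputation returning just the completed matrix."""
    completed, _ = bpca_fit(matrix, mask, config, warm_start=warm_start,
                            max_iter=max_iter)
    return completed
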