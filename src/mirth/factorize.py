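"""Masked nonnegative matrix factorization of the aggregate rank matrix.

The aggregate matrix X (m samples x n features, entries in (0,1), missing
where a batch did not measure a feature) is factorized as X ~ W H with
W (m x k) and H (k x n) nonnegative, minimizing the sum of squared residuals
over *observed* entries only:

    min_{W,H >= 0}  sum_{(i,j) observed} (x_ij - w_i . h_j)^2

Unobserved entries are simply dropped from the loss, so the reconstruction
W H fills them in.  The reconstruction is then re-ranked per feature within
each batch so imputed values remain uniform ranks on (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata

from .datasets_io import AggregateMatrix, MirthError, RawDataset, aggregate
from .preprocess import preprocess

logger = logging.getLogger("mirth")

SOLVERS = ("lbfgs", "mu")


@dataclass
class FactorModel:
    """Fitted nonnegative factors of the aggregate rank matrix."""

    W: np.ndarray          # m x k sample embeddings
    H: np.ndarray          # k x n feature embeddings
    k: int
    final_loss: float
    converged: bool
    seed: int
    n_iter: int = 0
    backend: str = "lbfgs"

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise MirthError("factor matrices must be nonnegative")


@dataclass
class ImputedMatrix:
    """Complete matrix of (re-ranked) predicted ranks with provenance."""

    values: np.ndarray               # m x n, entries in (0, 1), no missing
    observed_mask: np.ndarray        # True where the entry was measured
    batch_of_sample: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def rows_of_batch(self, batch_id: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.batch_of_sample, dtype=object) == batch_id)


def masked_loss(X0: np.ndarray, M: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Sum of squared residuals over observed entries (M is the float mask)."""
    R = (W @ H - X0) * M
    return float(np.sum(R * R))


def _check_inputs(values: np.ndarray, mask: np.ndarray, k: int,
                  feature_ids: Sequence[str] | None,
                  allow_empty_features: bool) -> None:
    m, n = values.shape
    if not (1 <= k <= min(m, n)):
        raise MirthError(f"k={k} out of range [1, {min(m, n)}]")
    row_ok = mask.any(axis=1)
    col_ok = mask.any(axis=0)
    if not row_ok.all():
        raise MirthError(f"sample row {int(np.flatnonzero(~row_ok)[0])} has no observed entry")
    if not col_ok.all() and not allow_empty_features:
        j = int(np.flatnonzero(~col_ok)[0])
        name = feature_ids[j] if feature_ids is not None else str(j)
        raise MirthError(f"feature {name!r} has no observed entry")


def _init_factors(rng: np.random.Generator, m: int, n: int, k: int,
                  mean_obs: float) -> tuple[np.ndarray, np.ndarray]:
    # uniform(0,1) entries scaled so E[(WH)_ij] matches the observed mean
    scale = 2.0 * np.sqrt(max(mean_obs, 1e-12) / k)
    return rng.uniform(0, scale, (m, k)), rng.uniform(0, scale, (k, n))


def _fit_lbfgs(X0, M, W0, H0, max_iter, tol):
    m, n = X0.shape
    k = W0.shape[1]

    def fun(x):
        W = x[: m * k].reshape(m, k)
        H = x[m * k:].reshape(k, n)
        R = (W @ H - X0) * M
        loss = np.sum(R * R)
        gW = 2.0 * R @ H.T
        gH = 2.0 * W.T @ R
        return loss, np.concatenate([gW.ravel(), gH.ravel()])

    x0 = np.concatenate([W0.ravel(), H0.ravel()])
    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * x0.size,
        options={"maxiter": max_iter, "ftol": tol, "maxfun": 10 * max_iter},
    )
    W = res.x[: m * k].reshape(m, k)
    H = res.x[m * k:].reshape(k, n)
    return W, H, float(res.fun), bool(res.success), int(res.nit)


def _fit_mu(X0, M, W0, H0, max_iter, tol):
    # alternating multiplicative updates on the masked squared loss
    eps = 1e-12
    W, H = W0.copy() + eps, H0.copy() + eps
    prev = masked_loss(X0, M, W, H)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = (W @ H) * M
        W *= (X0 @ H.T) / (WH @ H.T + eps)
        WH = (W @ H) * M
        H *= (W.T @ X0) / (W.T @ WH + eps)
        loss = masked_loss(X0, M, W, H)
        if prev - loss <= tol * max(prev, 1e-30):
            converged = True
            prev = loss
            break
        prev = loss
    return W, H, prev, converged, it


def fit_nmf_masked(
    X: AggregateMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 1,
    solver: str = "lbfgs",
    observed_mask: np.ndarray | None = None,
    allow_empty_features: bool = False,
) -> FactorModel:
    """Fit W, H >= 0 minimizing the squared loss over observed entries.

    The default backend runs bound-constrained L-BFGS on the concatenated
    (W, H) vector with an analytic gradient; ``solver="mu"`` uses alternating
    masked multiplicative updates instead.  Initialization draws W and H
    i.i.d. uniform (scaled to the observed mean) from ``seed``; with
    ``n_restarts > 1`` the lowest-loss restart is kept.  Deterministic given
    the seed.

    A feature column with zero observed entries is normally rejected; during
    cross-validation (``allow_empty_features=True``) such columns are
    tolerated — their embedding stays unconstrained by data, mirroring the
    fold-masking procedure which hides a fold's features in every batch where
    they appear.
    """
    if isinstance(X, AggregateMatrix):
        values, mask, feature_ids = X.values, X.observed_mask, X.feature_ids
    else:
        values = np.asarray(X, dtype=float)
        mask = observed_mask if observed_mask is not None else ~np.isnan(values)
        feature_ids = None
    if solver not in SOLVERS:
        raise MirthError(f"unknown solver {solver!r}; expected one of {SOLVERS}")
    _check_inputs(values, mask, k, feature_ids, allow_empty_features)

    m, n = values.shape
    M = mask.astype(float)
    X0 = np.where(mask, values, 0.0)
    mean_obs = float(X0.sum() / max(mask.sum(), 1))
    fit = _fit_lbfgs if solver == "lbfgs" else _fit_mu

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        W0, H0 = _init_factors(rng, m, n, k, mean_obs)
        init_loss = masked_loss(X0, M, W0, H0)
        W, H, loss, converged, n_iter = fit(X0, M, W0, H0, max_iter, tol)
        if loss > init_loss:  # never accept an uphill "solution"
            W, H, loss, converged = W0, H0, init_loss, False
        if best is None or loss < best[2]:
            best = (W, H, loss, converged, n_iter)
    W, H, loss, converged, n_iter = best
    W = np.maximum(W, 0.0)
    H = np.maximum(H, 0.0)
    logger.debug("NMF k=%d solver=%s loss=%.6g converged=%s iter=%d",
                 k, solver, loss, converged, n_iter)
    return FactorModel(W=W, H=H, k=k, final_loss=loss, converged=converged,
                       seed=seed, n_iter=n_iter, backend=solver)


def reconstruct(model: FactorModel) -> np.ndarray:
    """Dense nonnegative reconstruction W H (no missing entries)."""
    return model.W @ model.H


def rerank(
    X_hat: np.ndarray,
    batch_of_sample: np.ndarray | Sequence[str],
    observed_mask: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
    feature_ids: Sequence[str] | None = None,
    scope: str = "batch",
) -> ImputedMatrix:
    """Re-rank the reconstruction so each feature is uniform on (0, 1).

    Each feature column is replaced, within each batch's samples (or globally
    with ``scope="global"``), by ranks ``i/(N+1)`` (ties averaged).  This is
    idempotent and restores the rank scale of the input transform.
    """
    X_hat = np.asarray(X_hat, dtype=float)
    if np.isnan(X_hat).any():
        raise MirthError("reconstruction passed to rerank contains missing entries")
    batch_of_sample = np.asarray(batch_of_sample, dtype=object)
    m, n = X_hat.shape
    out = np.empty_like(X_hat)
    if scope == "global":
        groups = [np.arange(m)]
    elif scope == "batch":
        seen: dict[object, None] = {}
        for b in batch_of_sample:
            seen.setdefault(b)
        groups = [np.flatnonzero(batch_of_sample == b) for b in seen]
    else:
        raise MirthError(f"unknown rerank scope {scope!r}")
    for rows in groups:
        nb = rows.size
        out[rows] = rankdata(X_hat[rows], method="average", axis=0) / (nb + 1)
    if observed_mask is None:
        observed_mask = np.ones((m, n), dtype=bool)
    return ImputedMatrix(
        values=out,
        observed_mask=np.asarray(observed_mask, dtype=bool),
        batch_of_sample=batch_of_sample,
        sample_ids=list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(m)],
        feature_ids=list(feature_ids) if feature_ids is not None else [f"f{j}" for j in range(n)],
    )


def impute_aggregate(
    agg: AggregateMatrix,
    k: int,
    seed: int = 0,
    solver: str = "lbfgs",
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 1,
    rerank_scope: str = "batch",
) -> tuple[ImputedMatrix, FactorModel]:
    """Factorize an already-aggregated rank matrix and return re-ranked imputations."""
    model = fit_nmf_masked(agg, k, seed=seed, max_iter=max_iter, tol=tol,
                           n_restarts=n_restarts, solver=solver)
    X_hat = reconstruct(model)
    imputed = rerank(X_hat, agg.batch_of_sample, observed_mask=agg.observed_mask,
                     sample_ids=agg.sample_ids, feature_ids=agg.feature_ids,
                     scope=rerank_scope)
    return imputed, model


def impute(
    datasets: Sequence[RawDataset],
    k: int | str = "auto",
    normalization: str = "tic",
    seed: int = 0,
    solver: str = "lbfgs",
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 1,
    rerank_scope: str = "batch",
    k_grid: Sequence[int] | None = None,
    cv_folds: int = 5,
) -> tuple[ImputedMatrix, FactorModel]:
    """Full pipeline: normalize, rank, aggregate, factorize, reconstruct, re-rank.

    With ``k="auto"`` the embedding dimension is chosen by v-fold
    dataset-wise cross-validation over ``k_grid``.
    """
    if not datasets:
        raise MirthError("impute requires at least one dataset")
    ranked = [preprocess(ds, normalization) for ds in datasets]
    agg = aggregate(ranked)
    if k == "auto":
        from .crossval import cv_select_k

        grid = list(k_grid) if k_grid is not None else None
        cv = cv_select_k(ranked, k_grid=grid, v=cv_folds, seed=seed, solver=solver)
        k = cv.k_opt
        logger.info("cross-validation selected k=%d", k)
    return impute_aggregate(agg, int(k), seed=seed, solver=solver, max_iter=max_iter,
                            tol=tol, n_restarts=n_restarts, rerank_scope=rerank_scope)
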