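"""Selection of the embedding dimension k by v-fold, dataset-wise feature masking.

For each candidate k, the eligible features of every batch (those also
measured in at least one other batch) are randomly partitioned into v folds
per batch.  Each fold in turn is treated as unmeasured — masked in every
batch where its features appear — the masked matrix is factorized, imputed
ranks are recovered, and the mean absolute error (MAE) between true and
imputed ranks over the masked entries scores the fold.  Fold scores are
averaged per k and the k with the lowest MAE wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets_io import AggregateMatrix, MirthError, RankedDataset, aggregate
from .factorize import fit_nmf_masked, reconstruct, rerank

logger = logging.getLogger("mirth")

DEFAULT_K_RANGE_WITHIN = (1, 80)   # single-batch imputation
DEFAULT_K_RANGE_ACROSS = (1, 60)   # multi-batch imputation
DEFAULT_STRIDE = 5


@dataclass
class FoldAssignment:
    """Per-batch partition of eligible features into v folds."""

    folds: dict[str, list[list[str]]]           # batch_id -> v feature lists
    eligible: dict[str, list[str]]              # batch_id -> eligible features
    v: int
    seed: int

    def features_of_fold(self, fold: int) -> dict[str, list[str]]:
        return {b: fs[fold] for b, fs in self.folds.items()}


@dataclass
class CVResult:
    k_grid: list[int]
    mae_per_k: np.ndarray
    k_opt: int
    mae_table: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mae_per_k = np.asarray(self.mae_per_k, dtype=float)
        self.mae_table = dict(zip(self.k_grid, self.mae_per_k.tolist()))


def eligible_features(datasets: Sequence[RankedDataset]) -> dict[str, list[str]]:
    """Features of each batch that are measured in at least one other batch.

    With a single batch every feature is eligible (within-set CV masks sample
    subsets of a fold's features rather than whole columns).
    """
    if len(datasets) == 1:
        ds = datasets[0]
        return {ds.batch_id: list(ds.feature_ids)}
    out: dict[str, list[str]] = {}
    for ds in datasets:
        others: set[str] = set()
        for other in datasets:
            if other.batch_id != ds.batch_id:
                others |= other.measured_features
        out[ds.batch_id] = [f for f in ds.feature_ids if f in others]
    return out


def assign_folds(
    eligible: dict[str, list[str]],
    v: int,
    seed: int = 0,
) -> FoldAssignment:
    """Randomly partition each batch's eligible features into v near-equal folds.

    Randomization is independent per batch so folds overlap as little as
    possible across batches; deterministic given the seed.
    """
    if v < 2:
        raise MirthError(f"v={v}: need at least 2 folds")
    rng = np.random.default_rng(seed)
    folds: dict[str, list[list[str]]] = {}
    for batch_id in eligible:
        feats = list(eligible[batch_id])
        if len(feats) < v:
            logger.warning("batch %s has %d eligible features for v=%d folds; "
                           "folds will be uneven", batch_id, len(feats), v)
        perm = rng.permutation(len(feats))
        shuffled = [feats[i] for i in perm]
        folds[batch_id] = [shuffled[i::v] for i in range(v)]
    return FoldAssignment(folds=folds, eligible=eligible, v=v, seed=seed)


def _mask_fold(
    agg: AggregateMatrix,
    fold_features: dict[str, list[str]],
    within_rows: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Training mask with one fold's cells hidden, plus the hidden-cell mask.

    A fold's features are hidden in every batch where they appear, so a
    feature shared by few batches may end up with an entirely unobserved
    column — tolerated downstream.  The boolean flags whether every *sample*
    still has at least one observed training entry (a stranded sample makes
    the fold unscorable).
    """
    col_of = {f: j for j, f in enumerate(agg.feature_ids)}
    hide = np.zeros(agg.observed_mask.shape, dtype=bool)
    for batch_id, feats in fold_features.items():
        rows = (within_rows[batch_id] if within_rows is not None
                else agg.rows_of_batch(batch_id))
        cols = [col_of[f] for f in feats]
        if len(cols) == 0 or rows.size == 0:
            continue
        hide[np.ix_(rows, cols)] = True
    hide &= agg.observed_mask
    new_mask = agg.observed_mask & ~hide
    return new_mask, hide, bool(new_mask.any(axis=1).all())


def cv_select_k(
    datasets: Sequence[RankedDataset],
    k_grid: Sequence[int] | None = None,
    v: int = 10,
    seed: int = 0,
    solver: str = "lbfgs",
    max_iter: int = 2000,
    tol: float = 1e-6,
    stride: int | None = DEFAULT_STRIDE,
    rerank_scope: str = "batch",
) -> CVResult:
    """Choose the embedding dimension minimizing cross-validated rank MAE.

    The default grid spans 1..80 (one batch) or 1..60 (several batches) with a
    coarse stride for desk-scale runs; pass an explicit ``k_grid`` (or
    ``stride=None`` for the full grid) to override.  Ties in MAE resolve to
    the smallest k.  Folds that strand a sample or feature with no observed
    training entry are skipped with a warning.
    """
    if not datasets:
        raise MirthError("cv_select_k requires at least one dataset")
    agg = aggregate(datasets)
    if k_grid is None:
        lo, hi = (DEFAULT_K_RANGE_WITHIN if len(datasets) == 1
                  else DEFAULT_K_RANGE_ACROSS)
        hi = min(hi, min(agg.shape))
        step = stride if stride else 1
        k_grid = sorted(set(range(lo, hi + 1, step)) | {hi})
    k_grid = [int(k) for k in k_grid]
    if any(k < 1 or k > min(agg.shape) for k in k_grid):
        raise MirthError(f"k grid {k_grid} exceeds matrix rank bound {min(agg.shape)}")

    elig = eligible_features(datasets)
    assignment = assign_folds(elig, v=v, seed=seed)

    # single-batch CV masks each fold's features in a random half of samples
    within_rows: dict[str, np.ndarray] | None = None
    if len(datasets) == 1:
        ds = datasets[0]
        rng = np.random.default_rng(seed + 1)
        rows = agg.rows_of_batch(ds.batch_id)
        within_rows = {ds.batch_id: rng.permutation(rows)[: max(1, rows.size // 2)]}

    mae_per_k = np.full(len(k_grid), np.nan)
    for ki, k in enumerate(k_grid):
        fold_scores = []
        for fold in range(v):
            fold_features = assignment.features_of_fold(fold)
            if sum(len(fs) for fs in fold_features.values()) == 0:
                continue
            train_mask, hide, rows_ok = _mask_fold(agg, fold_features, within_rows)
            if not rows_ok:
                logger.warning("fold %d at k=%d leaves a sample with no observed "
                               "entry; skipped", fold, k)
                continue
            # a column hidden in every batch carries no signal about k: its
            # embedding is unconstrained, so its entries are excluded from MAE
            col_has_obs = train_mask.any(axis=0)
            score_cells = hide & col_has_obs[None, :]
            if not score_cells.any():
                logger.warning("fold %d at k=%d has no imputable masked entry; skipped",
                               fold, k)
                continue
            model = fit_nmf_masked(agg.values, k, seed=seed + fold, solver=solver,
                                   max_iter=max_iter, tol=tol,
                                   observed_mask=train_mask,
                                   allow_empty_features=True)
            imputed = rerank(reconstruct(model), agg.batch_of_sample,
                             observed_mask=train_mask,
                             sample_ids=agg.sample_ids, feature_ids=agg.feature_ids,
                             scope=rerank_scope)
            err = np.abs(imputed.values[score_cells] - agg.values[score_cells])
            fold_scores.append(float(np.mean(err)))
        if not fold_scores:
            raise MirthError(f"no scorable folds at k={k}")
        mae_per_k[ki] = float(np.mean(fold_scores))
        logger.info("cv k=%d mae=%.5f (%d folds)", k, mae_per_k[ki], len(fold_scores))

    best = np.min(mae_per_k)
    k_opt = int(min(k for k, mae in zip(k_grid, mae_per_k) if mae == best))
    return CVResult(k_grid=list(k_grid), mae_per_k=mae_per_k, k_opt=k_opt)
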