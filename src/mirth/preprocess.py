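"""Per-batch normalization and censoring-aware rank transformation.

Raw ion counts are only comparable between samples within one feature of one
batch.  Normalization controls for sample loading; the rank transform then
maps every feature of every batch onto (0, 1), where batch effects of the
form ``y = f(alpha * y_true + beta)`` with monotone ``f`` vanish entirely.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .datasets_io import MirthError, NormalizedDataset, RankedDataset, RawDataset

NORMALIZATIONS = ("tic", "pqn", "none")


def tic_normalize(ds: RawDataset, minimum: str = "batch") -> NormalizedDataset:
    """Total-ion-count normalization with a half-minimum censoring term.

    Each sample vector is divided by

        f_i = sum_j d_ij + 0.5 * min(D) * N_censored(i)

    where the sum runs over the sample's uncensored entries and ``min(D)`` is
    the smallest uncensored value in the batch (``minimum="sample"`` uses the
    sample's own minimum instead).  Censored entries thus contribute half the
    minimum to the total ion count.
    """
    present = ~ds.censored_mask
    if not present.any():
        raise MirthError(f"batch {ds.batch_id!r}: no uncensored value anywhere, "
                         "TIC minimum undefined")
    if minimum == "batch":
        min_val = np.full(ds.n_samples, np.nanmin(ds.values))
    elif minimum == "sample":
        with np.errstate(all="ignore"):
            min_val = np.nanmin(ds.values, axis=1)
        if np.isnan(min_val).any():
            i = int(np.flatnonzero(np.isnan(min_val))[0])
            raise MirthError(
                f"batch {ds.batch_id!r}: sample {ds.sample_ids[i]!r} is fully "
                "censored, per-sample minimum undefined"
            )
    else:
        raise MirthError(f"unknown minimum policy {minimum!r}")
    n_cens = ds.censored_mask.sum(axis=1)
    f = np.nansum(ds.values, axis=1) + 0.5 * min_val * n_cens
    if np.any(f <= 0):
        i = int(np.flatnonzero(f <= 0)[0])
        raise MirthError(f"batch {ds.batch_id!r}: nonpositive TIC normalizer for "
                         f"sample {ds.sample_ids[i]!r}")
    return NormalizedDataset(
        batch_id=ds.batch_id,
        sample_ids=ds.sample_ids,
        feature_ids=ds.feature_ids,
        values=ds.values / f[:, None],
        censored_mask=ds.censored_mask,
        normalizer_per_sample=f,
    )


def pqn_normalize(ds: RawDataset) -> NormalizedDataset:
    """Probabilistic quotient normalization.

    The reference spectrum is the per-feature median over uncensored values;
    each sample is divided by the median of its entrywise quotients against
    the reference.  Censored entries are excluded from both computations since
    their magnitude is unknown.
    """
    if ds.n_samples < 2:
        raise MirthError(f"batch {ds.batch_id!r}: PQN needs at least 2 samples")
    with np.errstate(all="ignore"):
        reference = np.nanmedian(ds.values, axis=0)
    quotients = ds.values / reference  # NaN where censored or reference undefined/zero
    quotients[:, ~(reference > 0)] = np.nan
    f = np.full(ds.n_samples, np.nan)
    for i in range(ds.n_samples):
        q = quotients[i][~np.isnan(quotients[i])]
        if q.size == 0:
            raise MirthError(
                f"batch {ds.batch_id!r}: sample {ds.sample_ids[i]!r} shares no "
                "uncensored feature with the reference spectrum"
            )
        f[i] = np.median(q)
    if np.any(f <= 0):
        i = int(np.flatnonzero(f <= 0)[0])
        raise MirthError(f"batch {ds.batch_id!r}: nonpositive PQN normalizer for "
                         f"sample {ds.sample_ids[i]!r}")
    return NormalizedDataset(
        batch_id=ds.batch_id,
        sample_ids=ds.sample_ids,
        feature_ids=ds.feature_ids,
        values=ds.values / f[:, None],
        censored_mask=ds.censored_mask,
        normalizer_per_sample=f,
    )


def normalize(ds: RawDataset, method: str = "tic", **kwargs) -> NormalizedDataset:
    """Dispatch to the configured normalization (``tic``, ``pqn`` or ``none``)."""
    if method == "tic":
        return tic_normalize(ds, **kwargs)
    if method == "pqn":
        return pqn_normalize(ds)
    if method == "none":
        return NormalizedDataset(
            batch_id=ds.batch_id, sample_ids=ds.sample_ids, feature_ids=ds.feature_ids,
            values=ds.values.copy(), censored_mask=ds.censored_mask,
            normalizer_per_sample=np.ones(ds.n_samples),
        )
    raise MirthError(f"unknown normalization {method!r}; expected one of {NORMALIZATIONS}")


def rank_feature(values: np.ndarray, censored: np.ndarray) -> np.ndarray:
    """Rank one feature column onto (0, 1) with censored entries tied for last.

    An uncensored entry d gets ``(1 + #{entries strictly below d}) / (1 + N)``,
    where every censored entry counts as strictly below every uncensored one
    and ties among uncensored values share the lowest rank.  All censored
    entries get ``0.5 * (1 + N_censored) / (1 + N)`` — halfway between zero and
    the smallest uncensored rank.
    """
    n_total = values.shape[0]
    n_cens = int(censored.sum())
    out = np.empty(n_total, dtype=float)
    out[censored] = 0.5 * (1 + n_cens) / (1 + n_total)
    unc = ~censored
    if unc.any():
        # rankdata 'min' = 1 + count of strictly smaller uncensored values
        strict_below = rankdata(values[unc], method="min") - 1
        out[unc] = (1 + n_cens + strict_below) / (1 + n_total)
    return out


def rank_transform(ds: RawDataset | NormalizedDataset) -> RankedDataset:
    """Apply the censoring-aware rank transform to every feature of a batch.

    Features with no censoring are mapped uniformly onto
    ``{1/(N+1), ..., N/(N+1)}``; the result is invariant to any strictly
    increasing per-batch distortion of the raw values.
    """
    n, p = ds.values.shape
    ranked = np.empty((n, p), dtype=float)
    n_cens = ds.censored_mask.sum(axis=0).astype(int)
    for j in range(p):
        ranked[:, j] = rank_feature(ds.values[:, j], ds.censored_mask[:, j])
    return RankedDataset(
        batch_id=ds.batch_id,
        sample_ids=ds.sample_ids,
        feature_ids=ds.feature_ids,
        values=ranked,
        censored_mask=ds.censored_mask.copy(),
        n_total=np.full(p, n, dtype=int),
        n_censored=n_cens,
    )


def preprocess(ds: RawDataset, normalization: str = "tic", **kwargs) -> RankedDataset:
    """Normalize then rank-transform one batch (the standard input pipeline)."""
    return rank_transform(normalize(ds, normalization, **kwargs))
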