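"""Reading, validation, harmonization and aggregation of per-batch metabolomics tables.

A *batch* is one metabolomics experiment: a samples x features table of raw
nonnegative ion counts. Two kinds of missingness are distinguished:

* **left-censored** entries — the feature is measured in the batch but the
  value fell below the detection threshold in that sample.  Encoded in input
  files as an empty cell or a sentinel string (default ``"NA"``) inside a
  present column.
* **unmeasured features** — a metabolite the batch never quantified.  Encoded
  by the column being absent from the file; these only materialize as missing
  entries once batches are stacked into an aggregate matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mirth")

DEFAULT_SENTINEL = "NA"


class MirthError(ValueError):
    """Base class for data-validation failures."""


class HarmonizationError(MirthError):
    """Two source features collapse onto one canonical name within a batch."""


@dataclass
class RawDataset:
    """One batch of raw ion counts.

    ``values`` is samples x features with ``NaN`` exactly where
    ``censored_mask`` is True.  The features listed in ``feature_ids`` are by
    definition the batch's measured features; unmeasured metabolites have no
    column here at all.
    """

    batch_id: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    censored_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.censored_mask = np.asarray(self.censored_mask, dtype=bool)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise MirthError(
                f"batch {self.batch_id!r}: shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample ids / {len(self.feature_ids)} feature ids"
            )
        if len(set(self.sample_ids)) != n:
            raise MirthError(f"batch {self.batch_id!r}: duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise MirthError(f"batch {self.batch_id!r}: duplicate feature ids")
        present = ~np.isnan(self.values)
        if np.any(self.values[present] < 0):
            i, j = np.argwhere(present & (self.values < 0))[0]
            raise MirthError(
                f"batch {self.batch_id!r}: negative value at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )
        if np.any(present & self.censored_mask):
            raise MirthError(f"batch {self.batch_id!r}: censored entries must have no value")
        if np.any(~present & ~self.censored_mask):
            raise MirthError(f"batch {self.batch_id!r}: absent entries must be flagged censored")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def measured_features(self) -> set[str]:
        return set(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class NormalizedDataset(RawDataset):
    """A batch after per-sample normalization; censoring flags are untouched."""

    normalizer_per_sample: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class RankedDataset:
    """A batch mapped to within-batch normalized ranks on (0, 1).

    Censored entries of a feature all share the tied sub-minimum rank
    ``0.5 * (1 + N_censored) / (1 + N_total)``; uncensored entries occupy
    ``(N_censored + 1)/(N + 1) ... N/(N + 1)`` (ties collapse to the lowest
    shared rank).
    """

    batch_id: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    censored_mask: np.ndarray
    n_total: np.ndarray
    n_censored: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.censored_mask = np.asarray(self.censored_mask, dtype=bool)
        if np.any(self.values <= 0) or np.any(self.values >= 1):
            raise MirthError(f"batch {self.batch_id!r}: ranks must lie strictly in (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def measured_features(self) -> set[str]:
        return set(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class AggregateMatrix:
    """Stacked multi-batch rank matrix over the union of harmonized features.

    ``values`` is m samples x n features with ``NaN`` at unobserved entries;
    ``observed_mask`` is False exactly where a sample's batch does not measure
    the feature.  Censored entries carry their tied rank and count as observed.
    """

    values: np.ndarray
    observed_mask: np.ndarray
    batch_of_sample: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.batch_of_sample = np.asarray(self.batch_of_sample, dtype=object)
        if self.values.shape[0] and not np.all(self.observed_mask.any(axis=0)):
            j = int(np.flatnonzero(~self.observed_mask.any(axis=0))[0])
            raise MirthError(f"feature {self.feature_ids[j]!r} observed in no batch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def batch_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.batch_of_sample:
            seen.setdefault(b)
        return list(seen)

    def rows_of_batch(self, batch_id: str) -> np.ndarray:
        return np.flatnonzero(self.batch_of_sample == batch_id)

    def missing_fraction(self) -> float:
        return float(1.0 - self.observed_mask.mean())


@dataclass(frozen=True)
class HarmonizationTable:
    """Many-to-one mapping from source metabolite names to canonical names."""

    mapping: Mapping[str, str]

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "HarmonizationTable":
        df = pd.read_csv(path, sep=sep, header=0, dtype=str)
        if df.shape[1] < 2:
            raise MirthError(f"{path}: harmonization table needs two columns")
        src, dst = df.iloc[:, 0], df.iloc[:, 1]
        if src.duplicated().any():
            dup = src[src.duplicated()].iloc[0]
            raise MirthError(f"{path}: source name {dup!r} maps to multiple canonical names")
        return cls(dict(zip(src, dst)))


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_dataset(
    path: str | Path,
    batch_id: str | None = None,
    dialect: str | None = None,
    sentinel: str = DEFAULT_SENTINEL,
) -> RawDataset:
    """Parse one delimited batch table into a :class:`RawDataset`.

    The first column holds sample IDs; the header row holds feature names.
    Empty cells and the censoring sentinel become left-censored entries; any
    other non-numeric cell is rejected with its location.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)[1:]
    dup = pd.Index(header)
    if dup.duplicated().any():
        raise MirthError(f"{path}: duplicate feature name "
                         f"{dup[dup.duplicated()][0]!r}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str,
        keep_default_na=False, na_values=[], skipinitialspace=True,
    )
    batch = batch_id if batch_id is not None else path.stem

    feature_ids = [str(c) for c in df.columns]
    sample_ids = [str(s) for s in df.index]
    if len(set(feature_ids)) != len(feature_ids):
        dup = pd.Index(feature_ids)
        raise MirthError(f"{path}: duplicate feature name {dup[dup.duplicated()][0]!r}")
    if len(set(sample_ids)) != len(sample_ids):
        dup = pd.Index(sample_ids)
        raise MirthError(f"{path}: duplicate sample id {dup[dup.duplicated()][0]!r}")

    raw = df.to_numpy(dtype=object)
    values = np.full(raw.shape, np.nan)
    censored = np.zeros(raw.shape, dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip() if isinstance(raw[i, j], str) else raw[i, j]
            if cell == "" or cell == sentinel:
                censored[i, j] = True
                continue
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise MirthError(
                    f"{path}: non-numeric cell {cell!r} at sample {sample_ids[i]!r}, "
                    f"feature {feature_ids[j]!r}"
                ) from None
            if v < 0:
                raise MirthError(
                    f"{path}: negative value {v} at sample {sample_ids[i]!r}, "
                    f"feature {feature_ids[j]!r}"
                )
            values[i, j] = v
    return RawDataset(batch, sample_ids, feature_ids, values, censored)


def harmonize(
    ds: RawDataset,
    table: HarmonizationTable,
    passthrough: bool = True,
) -> RawDataset:
    """Rename the batch's features to canonical metabolite names.

    Names missing from the table pass through unchanged when ``passthrough``
    is set, otherwise they are rejected.  Two source features mapping to one
    canonical name within the same batch is a collision error: their ion
    counts are not comparable, so they cannot be merged.
    """
    new_ids = []
    for f in ds.feature_ids:
        if f in table.mapping:
            new_ids.append(table.mapping[f])
        elif passthrough:
            new_ids.append(f)
        else:
            raise HarmonizationError(f"batch {ds.batch_id!r}: feature {f!r} not in table")
    counts = pd.Series(new_ids).value_counts()
    collisions = counts[counts > 1].index.tolist()
    if collisions:
        raise HarmonizationError(
            f"batch {ds.batch_id!r}: features collide after harmonization: {collisions}"
        )
    return replace(ds, feature_ids=new_ids)


def aggregate(datasets: Sequence[RankedDataset]) -> AggregateMatrix:
    """Stack rank-transformed batches into one matrix over the feature union.

    Rows are the concatenation of all samples, columns the union of measured
    features (first-seen order).  Duplicate sample IDs across batches are
    namespaced ``batch_id:sample_id`` rather than merged.  Observed values are
    carried over exactly.
    """
    if not datasets:
        raise MirthError("aggregate requires at least one dataset")
    feature_union: dict[str, int] = {}
    for ds in datasets:
        for f in ds.feature_ids:
            feature_union.setdefault(f, len(feature_union))
    features = list(feature_union)

    all_ids = [s for ds in datasets for s in ds.sample_ids]
    dedupe = len(set(all_ids)) != len(all_ids)
    if dedupe:
        logger.info("duplicate sample ids across batches; namespacing as batch:sample")

    m = sum(ds.n_samples for ds in datasets)
    n = len(features)
    values = np.full((m, n), np.nan)
    observed = np.zeros((m, n), dtype=bool)
    batch_of_sample = np.empty(m, dtype=object)
    sample_ids: list[str] = []
    row = 0
    for ds in datasets:
        cols = [feature_union[f] for f in ds.feature_ids]
        sl = slice(row, row + ds.n_samples)
        values[sl, cols] = ds.values
        observed[sl, cols] = True
        batch_of_sample[sl] = ds.batch_id
        sample_ids.extend(
            f"{ds.batch_id}:{s}" if dedupe else s for s in ds.sample_ids
        )
        row += ds.n_samples
    agg = AggregateMatrix(values, observed, batch_of_sample, sample_ids, features)
    logger.info(
        "aggregated %d batches into %dx%d matrix, %.1f%% missing",
        len(datasets), m, n, 100 * agg.missing_fraction(),
    )
    return agg


def write_matrix(
    X: AggregateMatrix | pd.DataFrame | np.ndarray,
    path: str | Path,
    sentinel: str = DEFAULT_SENTINEL,
    sample_ids: Sequence[str] | None = None,
    feature_ids: Sequence[str] | None = None,
) -> Path:
    """Serialize a matrix as TSV; unobserved entries become the sentinel.

    An :class:`AggregateMatrix` gains a leading ``batch`` column so that
    :func:`read_matrix` restores it losslessly.
    """
    path = Path(path)
    if isinstance(X, AggregateMatrix):
        df = pd.DataFrame(
            np.where(X.observed_mask, X.values, np.nan),
            index=pd.Index(X.sample_ids, name="sample_id"),
            columns=X.feature_ids,
        )
        df.insert(0, "batch", list(X.batch_of_sample))
    elif isinstance(X, pd.DataFrame):
        df = X.copy()
        df.index.name = df.index.name or "sample_id"
    else:
        X = np.asarray(X, dtype=float)
        idx = sample_ids if sample_ids is not None else [f"s{i}" for i in range(X.shape[0])]
        cols = feature_ids if feature_ids is not None else [f"f{j}" for j in range(X.shape[1])]
        df = pd.DataFrame(X, index=pd.Index(idx, name="sample_id"), columns=list(cols))
    df.to_csv(path, sep="\t", na_rep=sentinel, float_format="%.17g")
    return path


def read_matrix(path: str | Path, sentinel: str = DEFAULT_SENTINEL) -> AggregateMatrix:
    """Inverse of :func:`write_matrix` for aggregate matrices."""
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=[sentinel, ""])
    if "batch" not in df.columns:
        raise MirthError(f"{path}: aggregate matrix file lacks a 'batch' column")
    batches = df.pop("batch").astype(str).to_numpy(dtype=object)
    values = df.to_numpy(dtype=float)
    return AggregateMatrix(
        values=np.where(np.isnan(values), np.nan, values),
        observed_mask=~np.isnan(values),
        batch_of_sample=batches,
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
    )
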