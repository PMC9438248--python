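"""Benchmark harness: masking designs, per-feature Spearman scoring and
well-predicted classification, plus embedding-dimension pathway enrichment.

Performance is measured by masking known measurements to simulate them as
unmeasured, imputing, and correlating imputed against true ranks per masked
feature (Spearman rho, two-sided p).  Per-trial p-values are BH-adjusted; a
feature is *well-predicted* when rho > 0 and q < 0.05 in more than 90% of
trials, and *reproducibly well-predicted* when measured in at least four
batches and well-predicted in at least three-quarters of them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, spearmanr

from .datasets_io import MirthError, RawDataset
from .factorize import ImputedMatrix, impute
from .preprocess import normalize, rank_feature

logger = logging.getLogger("mirth")

MIN_SCORABLE = 3            # fewer masked samples than this -> rho undefined
WELL_PREDICTED_TRIALS = 0.90        # strict: "> 90% of trials"
REPRODUCIBLE_MIN_BATCHES = 4
REPRODUCIBLE_FRACTION = 0.75        # inclusive: ">= three-quarters"
Q_THRESHOLD = 0.05


@dataclass
class MaskPlan:
    """One trial's held-out cells for a target batch.

    ``sample_idx`` indexes the target batch's samples; ``feature_ids`` are the
    features hidden in those samples.  ``eval_feature_ids`` restricts scoring
    (the mode design evaluates only single-mode features).
    """

    design: str                      # within | across | mode
    batch_id: str
    sample_idx: np.ndarray
    feature_ids: list[str]
    eval_feature_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        self.sample_idx = np.asarray(self.sample_idx, dtype=int)


def make_mask_within(
    ds: RawDataset,
    frac_samples: float = 0.5,
    frac_features: float = 0.1,
    seed: int = 0,
) -> MaskPlan:
    """Hide a random feature subset in a random sample subset of one batch.

    This splits the batch into two pseudo-datasets, the hold-out one
    measuring fewer features.
    """
    if not (0 < frac_samples < 1) or not (0 < frac_features < 1):
        raise MirthError("mask fractions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_s = int(round(frac_samples * ds.n_samples))
    n_f = int(round(frac_features * ds.n_features))
    if n_s < 1 or n_f < 1:
        raise MirthError(
            f"batch {ds.batch_id!r}: fractions ({frac_samples}, {frac_features}) "
            "select zero samples or features"
        )
    if n_f >= ds.n_features:
        raise MirthError(f"batch {ds.batch_id!r}: masking all features leaves "
                         "nothing to train on")
    sample_idx = np.sort(rng.choice(ds.n_samples, size=n_s, replace=False))
    feats = [ds.feature_ids[j]
             for j in np.sort(rng.choice(ds.n_features, size=n_f, replace=False))]
    return MaskPlan("within", ds.batch_id, sample_idx, feats, list(feats), seed)


def make_mask_across(
    datasets: Sequence[RawDataset],
    target_batch: str,
    frac_features: float = 0.1,
    seed: int = 0,
) -> MaskPlan:
    """Hide a random set of the target batch's shared features in ALL its samples.

    Only features also measured in another batch are candidates; a feature
    unique to the target is unimputable and excluded from the pool.
    """
    target = next((d for d in datasets if d.batch_id == target_batch), None)
    if target is None:
        raise MirthError(f"no batch named {target_batch!r}")
    elsewhere: set[str] = set()
    for d in datasets:
        if d.batch_id != target_batch:
            elsewhere |= d.measured_features
    pool = [f for f in target.feature_ids if f in elsewhere]
    if not pool:
        raise MirthError(f"batch {target_batch!r} shares no feature with other batches")
    n_f = max(1, int(round(frac_features * len(pool))))
    if n_f >= target.n_features:
        raise MirthError(f"batch {target_batch!r}: masking would leave no measured feature")
    rng = np.random.default_rng(seed)
    feats = [pool[j] for j in np.sort(rng.choice(len(pool), size=n_f, replace=False))]
    return MaskPlan("across", target_batch, np.arange(target.n_samples), feats,
                    list(feats), seed)


def make_mask_mode(
    ds: RawDataset,
    mode_labels: Mapping[str, str],
    masked_mode: str = "neg",
    frac_samples: float = 0.5,
    seed: int = 0,
) -> MaskPlan:
    """Hide every feature of one ionization mode in a random half of samples.

    Evaluation is restricted to metabolites only measured in the masked mode;
    dual-mode metabolites remain assessable through their other-mode feature.
    """
    missing = [f for f in ds.feature_ids if f not in mode_labels]
    if missing:
        raise MirthError(f"batch {ds.batch_id!r}: features without mode label: "
                         f"{missing[:5]}")
    masked_feats = [f for f in ds.feature_ids if mode_labels[f] == masked_mode]
    kept = [f for f in ds.feature_ids if mode_labels[f] != masked_mode]
    if not masked_feats:
        raise MirthError(f"no features carry mode {masked_mode!r}")
    if not kept:
        raise MirthError("masking this mode removes every feature from the "
                         "hold-out samples")
    # single-mode metabolites: those whose canonical name appears with only one mode
    name_modes: dict[str, set[str]] = {}
    for f in ds.feature_ids:
        name_modes.setdefault(_base_name(f), set()).add(mode_labels[f])
    single_mode = [f for f in masked_feats if len(name_modes[_base_name(f)]) == 1]
    rng = np.random.default_rng(seed)
    n_s = max(1, int(round(frac_samples * ds.n_samples)))
    sample_idx = np.sort(rng.choice(ds.n_samples, size=n_s, replace=False))
    return MaskPlan("mode", ds.batch_id, sample_idx, masked_feats,
                    single_mode or list(masked_feats), seed)


def _base_name(feature_id: str) -> str:
    # dual-mode metabolites appear as "name [pos]" / "name [neg]" style duplicates;
    # strip a trailing bracketed mode tag if present
    for tag in (" [pos]", " [neg]", "_pos", "_neg"):
        if feature_id.endswith(tag):
            return feature_id[: -len(tag)]
    return feature_id


def apply_mask(datasets: Sequence[RawDataset], plan: MaskPlan) -> list[RawDataset]:
    """Realize a mask plan by splitting the target batch into pseudo-batches.

    The hold-out samples form a pseudo-batch that simply does not measure the
    masked features (an across-design plan covering all samples drops the
    columns outright), so downstream preprocessing re-ranks each pseudo-batch
    independently, exactly as if the data had arrived that way.
    """
    out: list[RawDataset] = []
    for ds in datasets:
        if ds.batch_id != plan.batch_id:
            out.append(ds)
            continue
        keep_cols = [j for j, f in enumerate(ds.feature_ids)
                     if f not in set(plan.feature_ids)]
        if len(plan.sample_idx) == ds.n_samples:
            out.append(RawDataset(
                ds.batch_id, ds.sample_ids, [ds.feature_ids[j] for j in keep_cols],
                ds.values[:, keep_cols], ds.censored_mask[:, keep_cols]))
            continue
        holdout = plan.sample_idx
        train = np.setdiff1d(np.arange(ds.n_samples), holdout)
        out.append(RawDataset(
            f"{ds.batch_id}#holdout",
            [ds.sample_ids[i] for i in holdout],
            [ds.feature_ids[j] for j in keep_cols],
            ds.values[np.ix_(holdout, keep_cols)],
            ds.censored_mask[np.ix_(holdout, keep_cols)]))
        out.append(RawDataset(
            f"{ds.batch_id}#train",
            [ds.sample_ids[i] for i in train],
            ds.feature_ids,
            ds.values[train], ds.censored_mask[train]))
    return out


def true_masked_ranks(
    ds: RawDataset,
    plan: MaskPlan,
    normalization: str = "tic",
) -> pd.DataFrame:
    """True censoring-aware ranks of each masked feature over the held samples.

    The truth is what the input pipeline would have produced had the feature
    been measured: the full batch is normalized first (normalization reorders
    samples within a feature), then each masked feature is ranked over the
    held-out samples.
    """
    nd = normalize(ds, normalization)
    col_of = {f: j for j, f in enumerate(nd.feature_ids)}
    rows = plan.sample_idx
    out = {}
    for f in plan.eval_feature_ids:
        j = col_of[f]
        out[f] = rank_feature(nd.values[rows, j], nd.censored_mask[rows, j])
    return pd.DataFrame(out, index=[nd.sample_ids[i] for i in rows])


def score_trial(
    truth: pd.DataFrame,
    imputed: ImputedMatrix,
    plan: MaskPlan,
) -> pd.DataFrame:
    """Spearman rho and two-sided p per masked feature over its masked samples.

    ``truth`` holds true ranks (rows = held-out sample ids).  Features with
    fewer than three masked samples, or with zero rank variance in the truth
    (e.g. fully censored), are flagged unscored.
    """
    holdout_batch = f"{plan.batch_id}#holdout"
    rows = imputed.rows_of_batch(holdout_batch)
    if rows.size == 0:
        rows = imputed.rows_of_batch(plan.batch_id)
    id_to_row = {imputed.sample_ids[i].split(":", 1)[-1]: i for i in rows}
    col_of = {f: j for j, f in enumerate(imputed.feature_ids)}
    records = []
    for f in truth.columns:
        t = truth[f].to_numpy()
        ridx = [id_to_row[s] for s in truth.index if s in id_to_row]
        pred = imputed.values[ridx, col_of[f]]
        scored = len(ridx) >= MIN_SCORABLE and np.ptp(t) > 0
        rho = p = np.nan
        if scored:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, p = spearmanr(t, pred)
            scored = np.isfinite(rho)
        records.append({"feature": f, "batch": plan.batch_id, "n_masked": len(ridx),
                        "rho": rho, "p": p, "scored": scored})
    return pd.DataFrame(records)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise MirthError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def summarize_rho(rhos: Sequence[float]) -> float:
    """Fisher-z summary: tanh of the median of atanh-transformed correlations."""
    r = np.asarray(rhos, dtype=float)
    if r.size == 0:
        raise MirthError("cannot summarize an empty list of correlations")
    if np.any(np.abs(r) >= 1):
        logger.warning("clipping |rho| >= 1 before Fisher z-transform")
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.median(np.arctanh(r))))


@dataclass
class EvaluationReport:
    """Per-trial scores and per-feature classifications for one benchmark run."""

    trials: pd.DataFrame   # trial, batch, feature, n_masked, rho, p, q, scored, significant
    design: str
    seed: int
    measured_in: dict[str, set[str]] = field(default_factory=dict)

    def per_feature(self) -> pd.DataFrame:
        """Summarize each (batch, feature): trial count, summarized rho, flags."""
        rows = []
        scored = self.trials[self.trials["scored"]]
        for (batch, feature), grp in scored.groupby(["batch", "feature"], sort=False):
            frac_sig = float(grp["significant"].mean())
            rows.append({
                "batch": batch,
                "feature": feature,
                "n_trials": len(grp),
                "summarized_rho": summarize_rho(grp["rho"].tolist()),
                "fraction_significant": frac_sig,
                "well_predicted": frac_sig > WELL_PREDICTED_TRIALS,
            })
        return pd.DataFrame(rows)

    def reproducibly_well_predicted(self) -> pd.DataFrame:
        """Features measured in >= 4 batches and well-predicted in >= 3/4 of them."""
        per = self.per_feature()
        return classify_reproducible(per, self.measured_in)


def classify_well_predicted(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag (batch, feature) pairs significant (rho>0, q<0.05) in > 90% of trials."""
    scored = trials[trials["scored"]]
    out = (scored.groupby(["batch", "feature"], sort=False)["significant"]
           .agg(["mean", "size"]).reset_index()
           .rename(columns={"mean": "fraction_significant", "size": "n_trials"}))
    out["well_predicted"] = out["fraction_significant"] > WELL_PREDICTED_TRIALS
    return out


def classify_reproducible(
    per_feature: pd.DataFrame,
    measured_in: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Apply the >= 4 batches / >= 3/4 well-predicted reproducibility rule."""
    rows = []
    for feature, grp in per_feature.groupby("feature", sort=False):
        batches = measured_in.get(feature, set(grp["batch"]))
        n_meas = len(batches)
        n_well = int(grp["well_predicted"].sum())
        rows.append({
            "feature": feature,
            "n_batches_measured": n_meas,
            "n_batches_well_predicted": n_well,
            "reproducibly_well_predicted": (
                n_meas >= REPRODUCIBLE_MIN_BATCHES
                and 4 * n_well >= 3 * n_meas  # n_well/n_meas >= 3/4, exact arithmetic
            ),
        })
    return pd.DataFrame(rows)


def run_benchmark(
    datasets: Sequence[RawDataset],
    design: str = "across",
    n_trials: int = 20,
    k: int | str = "auto",
    frac_samples: float = 0.5,
    frac_features: float = 0.1,
    normalization: str = "tic",
    seed: int = 0,
    solver: str = "lbfgs",
    target_batches: Sequence[str] | None = None,
    mode_labels: Mapping[str, str] | None = None,
    masked_mode: str = "neg",
    k_grid: Sequence[int] | None = None,
) -> EvaluationReport:
    """Repeat a masking design over trials and score every masked feature.

    Each (trial, target) unit masks by design, re-runs the full imputation
    pipeline on the masked data, scores masked features by Spearman rho, and
    BH-adjusts p-values across that unit's masked features.
    """
    if design not in ("within", "across", "mode"):
        raise MirthError(f"unknown design {design!r}")
    if design == "mode" and mode_labels is None:
        raise MirthError("mode design requires mode labels")
    by_id = {ds.batch_id: ds for ds in datasets}
    targets = list(target_batches) if target_batches else list(by_id)
    if design == "across" and len(datasets) < 2:
        raise MirthError("across design requires at least two batches")

    root = np.random.SeedSequence(seed)
    trial_seeds = root.generate_state(n_trials * len(targets) * 2) % (2**31)
    frames = []
    unit = 0
    for trial in range(n_trials):
        for target in targets:
            s = int(trial_seeds[unit])
            unit += 1
            ds = by_id[target]
            if design == "within":
                plan = make_mask_within(ds, frac_samples, frac_features, seed=s)
            elif design == "across":
                plan = make_mask_across(datasets, target, frac_features, seed=s)
            else:
                plan = make_mask_mode(ds, mode_labels, masked_mode, frac_samples, seed=s)
            masked = apply_mask(datasets, plan)
            imputed, _ = impute(masked, k=k, normalization=normalization,
                                seed=s, solver=solver, k_grid=k_grid)
            truth = true_masked_ranks(ds, plan, normalization)
            scores = score_trial(truth, imputed, plan)
            scored = scores["scored"].to_numpy()
            q = np.full(len(scores), np.nan)
            if scored.any():
                q[scored] = bh_adjust(scores.loc[scored, "p"].to_numpy())
            scores["q"] = q
            scores["significant"] = scored & (scores["rho"] > 0) & (scores["q"] < Q_THRESHOLD)
            scores["trial"] = trial
            frames.append(scores)
            logger.info("trial %d target %s: %d masked features, median rho %.3f",
                        trial, target, len(scores),
                        float(np.nanmedian(scores["rho"])) if len(scores) else np.nan)
    trials_df = pd.concat(frames, ignore_index=True)
    measured_in = {}
    for ds in datasets:
        for f in ds.feature_ids:
            measured_in.setdefault(f, set()).add(ds.batch_id)
    return EvaluationReport(trials=trials_df, design=design, seed=seed,
                            measured_in=measured_in)


def enrichment_by_dimension(
    H: np.ndarray,
    feature_ids: Sequence[str],
    annotations: Mapping[str, str],
    cutoff: float = 0.2,
) -> pd.DataFrame:
    """Fisher's exact test for pathway enrichment in each embedding dimension.

    A feature is *appreciably weighted* in a dimension when its weight exceeds
    the cutoff.  For each (dimension, pathway) pair over the annotated
    features, a 2x2 table of appreciable-weight x pathway-membership is tested
    two-sided; p-values are BH-adjusted across all tests performed.
    """
    H = np.asarray(H, dtype=float)
    annotated = [(j, f) for j, f in enumerate(feature_ids) if f in annotations]
    if not annotated:
        return pd.DataFrame(columns=["dimension", "pathway", "n_weighted",
                                     "n_pathway", "odds_ratio", "p", "q"])
    cols = np.array([j for j, _ in annotated])
    paths = np.array([annotations[f] for _, f in annotated])
    records = []
    for d in range(H.shape[0]):
        above = H[d, cols] > cutoff
        if not above.any():
            continue
        for pw in pd.unique(paths):
            in_pw = paths == pw
            a = int(np.sum(above & in_pw))
            b = int(np.sum(above & ~in_pw))
            c = int(np.sum(~above & in_pw))
            dd = int(np.sum(~above & ~in_pw))
            odds, p = fisher_exact([[a, b], [c, dd]], alternative="two-sided")
            records.append({"dimension": d, "pathway": pw, "n_weighted": a + b,
                            "n_pathway": a + c, "odds_ratio": odds, "p": p})
    df = pd.DataFrame(records)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    else:
        df = pd.DataFrame(columns=["dimension", "pathway", "n_weighted",
                                   "n_pathway", "odds_ratio", "p", "q"])
    return df
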