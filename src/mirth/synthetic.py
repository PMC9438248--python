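"""Synthetic multi-batch metabolomics data with known ground truth.

The generator emulates the statistical structure the imputation model
assumes: a shared nonnegative low-rank latent abundance matrix Y* = W* H*,
multiplicative log-normal measurement noise, per-batch strictly monotone
distortions y -> f(alpha*y + beta) (the canonical batch-effect model), a
per-batch subset of measured features, and left-censoring of each feature's
low tail at a detection-threshold quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .datasets_io import MirthError, RawDataset

BATCH_EFFECT_FAMILIES = ("identity", "log1p-scale", "power")


@dataclass(frozen=True)
class BatchEffect:
    """Strictly monotone per-batch distortion f(alpha*y + beta), alpha>0, beta>=0."""

    family: str = "identity"
    alpha: float = 1.0
    beta: float = 0.0
    param: float = 1.0      # scale for log1p-scale, exponent (0,1] for power

    def __post_init__(self) -> None:
        if self.family not in BATCH_EFFECT_FAMILIES:
            raise MirthError(f"unknown batch-effect family {self.family!r}")
        if self.alpha <= 0:
            raise MirthError("batch-effect alpha must be positive")
        if self.beta < 0:
            raise MirthError("batch-effect beta must be nonnegative to preserve "
                             "nonnegativity")
        if self.family == "power" and not (0 < self.param):
            raise MirthError("power exponent must be positive")

    def apply(self, y: np.ndarray) -> np.ndarray:
        z = self.alpha * y + self.beta
        if self.family == "identity":
            return z
        if self.family == "log1p-scale":
            return self.param * np.log1p(z)
        return np.power(z, self.param)


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe a desk-scale analogue of a multi-batch metabolomics
    compendium: a few batches of tens of samples, a shared latent rank-3
    abundance structure, mild multiplicative noise (sd 0.1 on the log scale),
    70% of the feature panel measured per batch, and no censoring unless
    requested.
    """

    n_batches: int = 3
    samples_per_batch: int = 30
    n_features: int = 50
    measured_fraction: float = 0.7
    true_rank: int = 3
    noise_sd: float = 0.1
    censor_quantile: float = 0.0
    batch_effects: Sequence[BatchEffect] | None = None
    w_shape: float = 2.0        # gamma shape of sample loadings
    h_shape: float = 1.2        # gamma shape of feature weights (right-skewed, sparse-ish)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_rank > min(self.n_batches * self.samples_per_batch, self.n_features):
            raise MirthError("true_rank exceeds min(total samples, n_features)")
        if not (0 <= self.censor_quantile <= 0.9):
            raise MirthError("censor_quantile must lie in [0, 0.9]")
        if not (0 < self.measured_fraction <= 1):
            raise MirthError("measured_fraction must lie in (0, 1]")
        if self.n_batches < 1 or self.samples_per_batch < 1 or self.n_features < 2:
            raise MirthError("need >=1 batch, >=1 sample per batch, >=2 features")


@dataclass
class GroundTruth:
    """Latent factors and per-batch truth for scoring against simulations."""

    W_star: np.ndarray
    H_star: np.ndarray
    Y_star: np.ndarray                      # noiseless latent abundances, all samples
    Y_noisy: np.ndarray                     # after multiplicative noise, before batch effects
    batch_rows: dict[str, np.ndarray]       # batch_id -> row indices into Y_star
    measured: dict[str, list[str]]          # batch_id -> measured feature names
    feature_ids: list[str] = field(default_factory=list)

    def true_values(self, batch_id: str, feature: str) -> np.ndarray:
        j = self.feature_ids.index(feature)
        return self.Y_noisy[self.batch_rows[batch_id], j]


def _default_effects(n_batches: int, rng: np.random.Generator) -> list[BatchEffect]:
    fams = ["identity", "power", "log1p-scale"]
    effects = []
    for b in range(n_batches):
        family = fams[b % len(fams)]
        effects.append(BatchEffect(
            family=family,
            alpha=float(rng.uniform(0.5, 2.0)),
            beta=float(rng.uniform(0.0, 0.5)),
            param=float(rng.uniform(0.4, 0.9)) if family == "power"
            else float(rng.uniform(0.5, 3.0)),
        ))
    return effects


def simulate(config: SimulationConfig) -> tuple[list[RawDataset], GroundTruth]:
    """Draw one multi-batch scenario; deterministic given ``config.seed``.

    Sample loadings and feature weights are gamma-distributed (nonnegative,
    right-skewed).  Each batch measures a random ``measured_fraction`` subset
    of the feature panel (every feature is guaranteed to be measured in at
    least one batch); its observed values are a monotone distortion of the
    noisy latent abundances, with each measured feature's lowest
    ``censor_quantile`` fraction of values left-censored.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_batches * config.samples_per_batch
    n = config.n_features
    k = config.true_rank
    W = rng.gamma(config.w_shape, 1.0, size=(m, k))
    H = rng.gamma(config.h_shape, 1.0, size=(k, n))
    Y_star = W @ H
    noise = (np.exp(rng.normal(0.0, config.noise_sd, size=(m, n)))
             if config.noise_sd > 0 else 1.0)
    Y_noisy = Y_star * noise

    feature_ids = [f"met{j:03d}" for j in range(n)]
    effects = (list(config.batch_effects) if config.batch_effects is not None
               else _default_effects(config.n_batches, rng))
    if len(effects) != config.n_batches:
        raise MirthError("need one batch effect per batch")

    n_meas = max(2, int(round(config.measured_fraction * n)))
    measured_idx = [np.sort(rng.choice(n, size=n_meas, replace=False))
                    for _ in range(config.n_batches)]
    covered = np.zeros(n, dtype=bool)
    for idx in measured_idx:
        covered[idx] = True
    for j in np.flatnonzero(~covered):   # orphan features go to a random batch
        b = int(rng.integers(config.n_batches))
        measured_idx[b] = np.sort(np.append(measured_idx[b], j))

    datasets: list[RawDataset] = []
    batch_rows: dict[str, np.ndarray] = {}
    measured: dict[str, list[str]] = {}
    for b in range(config.n_batches):
        batch_id = f"batch{b}"
        rows = np.arange(b * config.samples_per_batch, (b + 1) * config.samples_per_batch)
        cols = measured_idx[b]
        vals = effects[b].apply(Y_noisy[np.ix_(rows, cols)])
        censored = np.zeros_like(vals, dtype=bool)
        n_cens = int(np.floor(config.censor_quantile * rows.size))
        if n_cens > 0:
            order = np.argsort(vals, axis=0, kind="stable")
            censored[order[:n_cens], np.arange(cols.size)] = True
        values = np.where(censored, np.nan, vals)
        datasets.append(RawDataset(
            batch_id=batch_id,
            sample_ids=[f"{batch_id}_s{i:03d}" for i in range(rows.size)],
            feature_ids=[feature_ids[j] for j in cols],
            values=values,
            censored_mask=censored,
        ))
        batch_rows[batch_id] = rows
        measured[batch_id] = [feature_ids[j] for j in cols]

    truth = GroundTruth(W_star=W, H_star=H, Y_star=Y_star, Y_noisy=Y_noisy,
                        batch_rows=batch_rows, measured=measured,
                        feature_ids=feature_ids)
    return datasets, truth


FIXTURES: dict[str, SimulationConfig] = {
    # single batch, ample samples: within-batch masking scenarios
    "tiny-within": SimulationConfig(
        n_batches=1, samples_per_batch=24, n_features=20, measured_fraction=1.0,
        true_rank=2, noise_sd=0.05, censor_quantile=0.0,
        batch_effects=[BatchEffect()], seed=11),
    # three overlapping batches for across-batch transfer
    "tiny-across": SimulationConfig(
        n_batches=3, samples_per_batch=16, n_features=24, measured_fraction=0.75,
        true_rank=2, noise_sd=0.05, censor_quantile=0.05, seed=12),
    # single batch whose features carry ionization-mode labels
    "tiny-mode": SimulationConfig(
        n_batches=1, samples_per_batch=20, n_features=16, measured_fraction=1.0,
        true_rank=2, noise_sd=0.05, censor_quantile=0.0,
        batch_effects=[BatchEffect()], seed=13),
    # the latent-dimension recovery scenario used for cross-validation checks
    "rank3-recovery": SimulationConfig(
        n_batches=3, samples_per_batch=20, n_features=50, measured_fraction=0.8,
        true_rank=3, noise_sd=0.1, censor_quantile=0.0, seed=14),
}


def make_fixture(name: str, seed: int | None = None):
    """Instantiate a named, seeded test scenario.

    Returns ``(datasets, truth, config)`` and, for ``tiny-mode``,
    ``(datasets, truth, config, mode_labels)``.
    """
    if name not in FIXTURES:
        raise MirthError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    config = FIXTURES[name]
    if seed is not None:
        config = replace(config, seed=seed)
    datasets, truth = simulate(config)
    if name == "tiny-mode":
        # first 4 features are single-mode (2 pos-only, 2 neg-only); the rest
        # pair up as the pos/neg halves of dual-mode metabolites
        feats = datasets[0].feature_ids
        new_ids: list[str] = []
        labels: dict[str, str] = {}
        for i, f in enumerate(feats):
            if i < 4:
                mode = "pos" if i < 2 else "neg"
                new_ids.append(f)
                labels[f] = mode
            else:
                mode = "pos" if i % 2 == 0 else "neg"
                name_i = f"dual{(i - 4) // 2:02d}_{mode}"
                new_ids.append(name_i)
                labels[name_i] = mode
        datasets[0] = replace(datasets[0], feature_ids=new_ids)
        return datasets, truth, config, labels
    return datasets, truth, config
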