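# Methods

## Data model and missingness

A *batch* is one metabolomics experiment: `n_i` samples × `p_i` measured
features of raw nonnegative ion counts. Two missingness classes are kept
strictly apart throughout:

* **Left-censored entries** — the feature is measured in the batch but the
  value fell below the detection threshold in that sample. In input files
  these are empty cells or a sentinel string (default `NA`) inside a present
  column. They carry the information "smaller than everything reported".
* **Unmeasured metabolites** — a feature the batch never quantified, encoded
  by the column being absent from the file. These are the imputation target
  and are the only entries omitted from the factorization loss.

Feature names are harmonized against a user-supplied two-column mapping
table (many-to-one across batches is allowed; two features of one batch
collapsing onto the same canonical name is an error, since their ion counts
are not comparable). Duplicate sample IDs across batches are namespaced
`batch:sample`, never merged: batches are independent experiments.

## Normalization

Per-sample normalization controls for loading differences before ranking.

* **TIC** (default): sample *i* is divided by
  `f_i = Σ_j d_ij + 0.5 · min(D) · N_censored(i)`, the total ion count with
  each censored entry contributing half the minimum. `min(D)` is the smallest
  uncensored value in the *batch*; a `minimum="sample"` flag switches to the
  sample's own minimum (the definition is ambiguous between the two readings;
  the batch-wide minimum is the default because it is always defined when any
  value is, and never differs by more than the censoring term).
* **PQN**: reference spectrum = per-feature median over uncensored values;
  each sample is divided by the median of its entrywise quotients against the
  reference. Censored entries are excluded from both computations — their
  magnitude is unknown.
* **none**: pass-through.

Normalization never touches censoring flags. A batch with no uncensored
value anywhere has no defined minimum and is rejected.

## Censoring-aware rank transformation

Within each batch, each feature column of N entries maps onto (0, 1):

* uncensored entry `d`: `rank(d) = (1 + #{entries strictly below d}) / (1 + N)`,
  where every censored entry counts as below every uncensored one. Tied
  uncensored values share the lowest rank of their tie group (the strict-count
  formula produces this automatically; no separate tie rule is introduced).
* censored entries (c of N): all get `0.5 · (1 + c) / (1 + N)` — halfway
  between zero and the smallest attainable uncensored rank.

Consequences relied on elsewhere: an uncensored feature's sorted ranks are
exactly `{1/(N+1), …, N/(N+1)}` (uniform marginals for equal N); ranks are
bitwise invariant to any strictly increasing distortion `y → f(α·y + β)`,
which is the canonical form of a batch effect; the censored rank is strictly
positive and strictly below every uncensored rank of its feature.

## Masked nonnegative matrix factorization

Ranked batches are stacked into the aggregate matrix `X` (rows = all samples,
columns = union of features, entries in (0,1), unobserved where a batch did
not measure a feature). Censored entries sit at their tied rank and count as
observed. The factorization

```
min_{W,H ≥ 0}  Σ_{(i,j) observed} (x_ij − w_iᵀ h_j)²
```

is solved by bound-constrained L-BFGS on the concatenated `(W, H)` vector
with analytic gradients (`gW = 2 R Hᵀ`, `gH = 2 Wᵀ R`, `R` the masked
residual). An alternating masked multiplicative-update backend (`solver="mu"`)
offers the same contract. Initialization draws `W, H` i.i.d. uniform on
`(0, s)` with `s = 2·sqrt(mean(X_obs)/k)` so the initial product matches the
observed mean in expectation; everything is seeded, and optional multi-restart
keeps the lowest-loss solution. Convergence: relative loss change below
`tol = 1e-6` or `max_iter = 2000`. A solution is never accepted if its loss
exceeds the initialization's (the initial factors are returned instead, with
`converged=False`).

The dense reconstruction `WH` is **re-ranked**: per feature, within each
batch's samples, values are replaced by `i/(N+1)` ranks (ties averaged), so
imputed features are again uniform on (0, 1). Re-ranking is idempotent.
Per-batch scope matches the input transform's per-batch ranking; a
`scope="global"` flag ranks across the whole aggregate instead.

## Cross-validated selection of the embedding dimension

For each candidate `k`, the *eligible* features of every batch (those also
measured in at least one other batch; with a single batch, all features) are
randomly partitioned into `v` folds per batch (default `v=10`), independently
per batch to reduce overlap of folds across batches. Each fold is masked in
every batch where its features appear, the masked matrix is factorized,
reconstructed and re-ranked, and the mean absolute error between true and
imputed ranks over the masked cells scores the fold; fold scores are averaged
per `k` (simple mean) and the smallest `k` attaining the minimum wins.

Two numerical choices matter with few batches. A feature assigned to the same
fold in every batch where it is measured loses *all* its observations; its
feature embedding is then unconstrained by data. Such columns are tolerated
during CV fits rather than aborting the fold (with 3 batches and `v=5` almost
every fold contains one), but their masked entries are excluded from the MAE:
they are pure noise at every `k` and only blur the comparison. A fold is
skipped (with a warning) only if it would strand a *sample* with no observed
entry. With a single batch, fold features are masked in a random half of the
samples instead of everywhere.

Default grids are 1–80 (one batch) and 1–60 (several), evaluated with a
coarse stride of 5 for desk-scale runs; an explicit grid or `stride=1` gives
the full sweep.

## Evaluation harness

Three masking designs simulate unmeasured data where truth is known:

* **within**: a random fraction of features (default 10 %) is hidden in a
  random half of one batch's samples, splitting it into two pseudo-batches
  that are preprocessed independently — exactly as if the data had arrived
  that way.
* **across**: a random 10 % of a target batch's *shared* features (measured
  in ≥ 1 other batch) is dropped from the target entirely.
* **mode**: all features of one ionization mode are hidden in a random half
  of samples; scoring is restricted to metabolites only measured in the
  masked mode (dual-mode metabolites remain visible through their other-mode
  feature).

Per masked feature, Spearman's ρ (two-sided p) is computed between imputed
and true ranks over the masked samples only. The truth is computed from the
*normalized* full batch — normalization reorders samples within a feature, so
raw-value ranks would not be the ranks the pipeline reconstructs. Features
with fewer than 3 masked samples or zero truth variance (e.g. fully censored)
are flagged unscored. Within each trial, p-values are BH-adjusted across that
trial's masked features (the correction family is per trial; this is a
configuration choice). A feature is *well-predicted* when `ρ > 0` and
`q < 0.05` in strictly more than 90 % of its scored trials, and *reproducibly
well-predicted* when measured in ≥ 4 batches and well-predicted in ≥ 3/4 of
them (inclusive, by exact integer arithmetic). ρ values are summarized as
`tanh(median(atanh(ρ)))`; |ρ| ≥ 1 is clipped to 1 − 1e-12 with a warning.

Embedding interpretation: for each embedding dimension, features with weight
above a cutoff (default 0.2) are *appreciably weighted*; each
(dimension, pathway) pair over the annotated features gets a two-sided
Fisher's exact test on the 2×2 appreciable-weight × pathway-membership table,
BH-adjusted across all tests performed. Dimensions with no above-cutoff
annotated feature are skipped.

## Synthetic data generator

The generator emulates the structure the model assumes — and only that:

* latent abundances `Y* = W*H*` with `W*` (samples × k*) gamma(2, 1) and
  `H*` (k* × features) gamma(1.2, 1): nonnegative, right-skewed, sparse-ish
  feature weights; shapes are config-exposed;
* multiplicative log-normal noise `exp(N(0, noise_sd))`, default 0.1 (mild
  measurement noise on the log scale);
* per batch: a random `measured_fraction` subset of the panel (default 0.7;
  orphan features are reassigned so every feature is measured somewhere), a
  strictly monotone distortion `f(α·y + β)` with `f` cycling through identity,
  power (exponent < 1) and scaled log1p families and random `α ∈ (0.5, 2)`,
  `β ∈ (0, 0.5)`, and left-censoring of each feature's lowest
  `censor_quantile` fraction (default 0: censoring is opt-in).

Defaults (3 batches × 30 samples, 50 features, true rank 3) describe a
desk-scale analogue of a multi-batch tissue-metabolomics compendium. The
generator does **not** emulate instrument-level effects (retention-time
drift, adducts, peak-integration errors), heteroscedastic or feature-specific
noise, correlated censoring across features, or latent sub-batches. Passing
tests therefore demonstrate correctness of the algorithmic pipeline and its
qualitative behaviour (recovery improves with samples, degrades with masking
and noise) under the assumed generative model — not performance levels on any
real compendium.

Named fixtures (`tiny-within`, `tiny-across`, `tiny-mode`, `rank3-recovery`)
pin seeded scenarios used by the tests and docs; `tiny-mode` relabels paired
features as the pos/neg halves of dual-mode metabolites so the mode design's
evaluation-set logic is exercised.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` run entirely on generated data at
desk scale, chosen as the smallest sizes at which each property is
informative: rank-formula and batch-invariance checks on thousands of random
features; exact completion of rank-1/2/3 matrices up to 30 × 40 with 25 %
masked; dimension recovery on 3 × 20 samples × 50 features at true rank 3
(grid 1–8, v=5, ten generator seeds); transfer benchmarks pooled over three
generator draws × three targets with 4 trials each (masking fractions 10 %,
30 %, 50 %); a data-limited sample-size sweep (true rank 8, noise 0.2) over
10/30/100 samples per batch. The sample-size experiment deliberately uses a
richer latent rank: with rank-3 structure, 10 samples per batch already
saturate recovery and the sweep shows nothing.

## Known limitations

* The masked NMF objective is non-convex; different seeds reach different
  local optima (multi-restart is available but defaults to 1).
* Rank transformation discards magnitude information by construction;
  imputed values are ranks, not abundances.
* Heavily censored features are imputed poorly: their input ranks are a
  single tie, but their reconstructed ranks are uniform.
* With very few batches, dataset-wise CV folds often hide features
  everywhere at once; the MAE exclusion above keeps selection stable, but
  single-feature resolution of the score is lost for those features.
* PQN on heavily censored batches can fail outright when a sample shares no
  uncensored feature with the reference spectrum.
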