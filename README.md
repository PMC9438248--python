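# mirth

Imputation of entirely-unmeasured metabolite features within and across
semi-quantitative metabolomics batches.

## The problem

Mass-spectrometry metabolomics reports *relative abundances*: ion counts that
are only comparable between samples within one feature of one batch. Every
platform quantifies a different subset of the metabolome, so merging batches
leaves most of the combined sample × metabolite matrix empty, and the missing
columns cannot be filled by methods that assume a common measurement scale.
Two kinds of missingness coexist: **left-censored** entries (a measured
feature fell below the detection threshold in some samples) and **missing
metabolites** (a feature the batch never measured at all — the imputation
target).

## The method

1. **Normalization.** Each batch is normalized per sample, by default with
   total ion count (TIC): sample *i* is divided by
   `f_i = Σ_j d_ij + 0.5 · min(D) · N_censored(i)`,
   where censored entries contribute half the batch minimum. Probabilistic
   quotient normalization (PQN) or no normalization are selectable.
2. **Censoring-aware rank transformation.** Within each batch, every feature
   is mapped onto (0, 1): an uncensored entry gets
   `(1 + #{entries strictly below it}) / (1 + N)` and all censored entries of
   a feature share the tied sub-minimum rank
   `0.5 · (1 + N_censored) / (1 + N)`. Under the canonical batch-effect model
   `y = f(α·y* + β)` with monotone `f`, ranks are invariant to the batch
   effect, so ranked features are comparable across batches.
3. **Masked nonnegative matrix factorization.** Ranked batches are stacked
   into one aggregate matrix `X` (m samples × n features, union of
   harmonized feature names) and factorized as `X ≈ WH` with `W, H ≥ 0` by
   minimizing `Σ_(i,j observed) (x_ij − w_iᵀ h_j)²` — unobserved entries are
   simply dropped from the loss (bound-constrained L-BFGS with analytic
   gradients; a masked multiplicative-update backend is also provided). The
   complete reconstruction `WH` is then re-ranked per feature within each
   batch, yielding imputed ranks on (0, 1) for every unmeasured metabolite.
4. **Cross-validated rank selection.** The embedding dimension `k` is chosen
   by v-fold dataset-wise cross-validation: eligible features (measured in
   ≥ 1 other batch) are randomly partitioned into folds per batch, each fold
   is masked in every batch where it appears, and the `k` minimizing the mean
   absolute error between true and imputed ranks wins.
5. **Benchmark harness.** Masking designs (within-batch, across-batch,
   ionization-mode), per-feature Spearman ρ against held-out truth, Fisher-z
   summarization of ρ, Benjamini–Hochberg correction, *well-predicted*
   (ρ > 0 and q < 0.05 in > 90 % of trials) and *reproducibly well-predicted*
   (measured in ≥ 4 batches, well-predicted in ≥ 3/4 of them)
   classifications, and per-dimension pathway enrichment of the feature
   embeddings by Fisher's exact test.

A synthetic-data generator with known ground truth (shared low-rank
nonnegative latent abundances, per-batch monotone distortions, left-censoring
at a detection-threshold quantile, per-batch feature panels) makes the whole
pipeline testable without any external download.

## Worked example

```sh
mirth simulate --batches 3 --samples 30 --features 50 --true-rank 3 \
      --noise-sd 0.1 --censor-quantile 0.05 --seed 11 --out data
mirth cv --in data --kmin 1 --kmax 8 --stride 1 --folds 5 --seed 11 --out cv.tsv
mirth impute --in data --k 3 --seed 11 --out imputed
mirth benchmark --in data --design across --trials 5 --k 3 --seed 11 --out report.tsv
```

prints

```
wrote 3 batches to data
k_opt=3 (MAE 0.11076)
imputed 90x50 matrix at k=3 (loss 57.54)
34/37 masked features well-predicted; median summarized rho 0.912
```

Three simulated batches (30 samples each) measure overlapping 70 % subsets of
a 50-metabolite panel whose latent abundances have rank 3. Cross-validation
recovers `k_opt = 3`, the true latent dimension. `imputed/imputed.tsv` holds
the complete 90 × 50 matrix of (re-ranked) predicted ranks alongside the
sample and feature embeddings `W.tsv` / `H.tsv`. The benchmark fully masks a
random 10 % of the target batch's shared features per trial and re-imputes
them; here 34 of 37 masked features were recovered with a significant
positive rank correlation in more than 90 % of trials, with a median
summarized ρ of 0.912 against the held-out truth. Each command writes a
`manifest.json` (configuration, seeds, versions) that suffices to reproduce
the run; the same seed yields byte-identical outputs.

The same functionality is available as a library:

```python
from mirth import SimulationConfig, simulate, impute, run_benchmark

datasets, truth = simulate(SimulationConfig(seed=11))
imputed, model = impute(datasets, k="auto", seed=11)
report = run_benchmark(datasets, design="across", n_trials=20, k=3, seed=11)
```

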