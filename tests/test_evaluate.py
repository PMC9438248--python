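import numpy as np
import pandas as pd
import pytest

from mirth import (
    MirthError,
    SimulationConfig,
    apply_mask,
    bh_adjust,
    classify_reproducible,
    classify_well_predicted,
    enrichment_by_dimension,
    make_fixture,
    make_mask_across,
    make_mask_mode,
    make_mask_within,
    run_benchmark,
    simulate,
    summarize_rho,
)

from conftest import random_raw


class TestMaskPlans:
    def test_within_counts_from_fractions(self):
        rng = np.random.default_rng(0)
        ds = random_raw(rng, n=10, p=20)
        plan = make_mask_within(ds, frac_samples=0.5, frac_features=0.1, seed=1)
        assert plan.sample_idx.size == 5 and len(plan.feature_ids) == 2

    def test_within_rejects_full_feature_masking(self):
        rng = np.random.default_rng(1)
        ds = random_raw(rng, n=6, p=3)
        with pytest.raises(MirthError):
            make_mask_within(ds, frac_features=0.99, seed=0)

    def test_within_deterministic(self):
        rng = np.random.default_rng(2)
        ds = random_raw(rng, n=10, p=20)
        p1 = make_mask_within(ds, seed=7)
        p2 = make_mask_within(ds, seed=7)
        np.testing.assert_array_equal(p1.sample_idx, p2.sample_idx)
        assert p1.feature_ids == p2.feature_ids

    def test_across_masks_all_target_samples(self, three_batches):
        datasets, _ = three_batches
        plan = make_mask_across(datasets, "batch0", frac_features=0.1, seed=0)
        assert plan.sample_idx.size == datasets[0].n_samples

    def test_across_candidates_shared_only(self, three_batches):
        datasets, _ = three_batches
        target = datasets[0]
        elsewhere = set().union(*(d.measured_features for d in datasets[1:]))
        for _ in range(5):
            plan = make_mask_across(datasets, "batch0", frac_features=0.3, seed=_)
            assert set(plan.feature_ids) <= set(target.feature_ids) & elsewhere

    def test_across_leaves_other_batches_untouched(self, three_batches):
        datasets, _ = three_batches
        plan = make_mask_across(datasets, "batch0", frac_features=0.1, seed=0)
        masked = apply_mask(datasets, plan)
        for orig in datasets[1:]:
            m = next(d for d in masked if d.batch_id == orig.batch_id)
            np.testing.assert_array_equal(
                np.nan_to_num(m.values), np.nan_to_num(orig.values))

    def test_mode_masks_mode_features_in_half_samples(self):
        datasets, _, _, labels = make_fixture("tiny-mode")
        ds = datasets[0]
        plan = make_mask_mode(ds, labels, masked_mode="neg", frac_samples=0.5, seed=0)
        assert plan.sample_idx.size == ds.n_samples // 2
        assert all(labels[f] == "neg" for f in plan.feature_ids)
        # evaluation restricted to single-mode metabolites of the masked mode
        assert set(plan.eval_feature_ids) == {f for f in ds.feature_ids
                                              if labels[f] == "neg"
                                              and not f.startswith("dual")}

    def test_mode_missing_label_rejected(self):
        datasets, _, _, labels = make_fixture("tiny-mode")
        bad = dict(labels)
        bad.popitem()
        with pytest.raises(MirthError, match="without mode label"):
            make_mask_mode(datasets[0], bad, seed=0)

    def test_mode_all_one_mode_rejected(self):
        datasets, _, _, labels = make_fixture("tiny-mode")
        all_neg = {f: "neg" for f in labels}
        with pytest.raises(MirthError, match="every feature"):
            make_mask_mode(datasets[0], all_neg, masked_mode="neg", seed=0)

    def test_apply_mask_within_splits_pseudo_batches(self, three_batches):
        datasets, _ = three_batches
        plan = make_mask_within(datasets[0], seed=3)
        masked = apply_mask(datasets, plan)
        ids = {d.batch_id for d in masked}
        assert f"{datasets[0].batch_id}#holdout" in ids
        assert f"{datasets[0].batch_id}#train" in ids
        holdout = next(d for d in masked if d.batch_id.endswith("#holdout"))
        assert set(plan.feature_ids).isdisjoint(holdout.feature_ids)


class TestSpearmanScoring:
    def test_identity_and_reversal(self):
        from mirth.evaluate import MaskPlan, score_trial
        from mirth.factorize import ImputedMatrix

        truth = pd.DataFrame({"f1": [0.2, 0.4, 0.6, 0.8],
                              "f2": [0.2, 0.4, 0.6, 0.8]},
                             index=[f"s{i}" for i in range(4)])
        values = np.column_stack([[0.2, 0.4, 0.6, 0.8], [0.8, 0.6, 0.4, 0.2]])
        imputed = ImputedMatrix(values=values, observed_mask=np.ones((4, 2), bool),
                                batch_of_sample=np.array(["b"] * 4, dtype=object),
                                sample_ids=[f"s{i}" for i in range(4)],
                                feature_ids=["f1", "f2"])
        plan = MaskPlan("within", "b", np.arange(4), ["f1", "f2"], ["f1", "f2"], 0)
        out = score_trial(truth, imputed, plan).set_index("feature")
        assert out.loc["f1", "rho"] == pytest.approx(1.0)
        assert out.loc["f2", "rho"] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self):
        """Spearman rho equals Pearson correlation of rank vectors."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.random(10), rng.random(10)
            rx = np.argsort(np.argsort(x)).astype(float)
            ry = np.argsort(np.argsort(y)).astype(float)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearmanr(x, y).statistic == pytest.approx(oracle, abs=1e-12)

    def test_too_few_samples_flagged_unscored(self):
        from mirth.evaluate import MaskPlan, score_trial
        from mirth.factorize import ImputedMatrix

        truth = pd.DataFrame({"f1": [0.3, 0.6]}, index=["s0", "s1"])
        imputed = ImputedMatrix(values=np.array([[0.4], [0.5]]),
                                observed_mask=np.ones((2, 1), bool),
                                batch_of_sample=np.array(["b", "b"], dtype=object),
                                sample_ids=["s0", "s1"], feature_ids=["f1"])
        plan = MaskPlan("within", "b", np.arange(2), ["f1"], ["f1"], 0)
        out = score_trial(truth, imputed, plan)
        assert not out.loc[0, "scored"]


class TestSummarizeRho:
    def test_constant_list(self):
        assert summarize_rho([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_singleton(self):
        assert summarize_rho([-0.73]) == pytest.approx(-0.73)

    def test_symmetric_list_gives_zero(self):
        assert summarize_rho([-0.3, 0.0, 0.3]) == pytest.approx(0.0, abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(MirthError, match="empty"):
            summarize_rho([])

    def test_monotone_in_inputs(self):
        rng = np.random.default_rng(4)
        rhos = rng.uniform(-0.9, 0.9, 9).tolist()
        base = summarize_rho(rhos)
        bumped = list(rhos)
        bumped[3] = min(bumped[3] + 0.2, 0.99)
        assert summarize_rho(bumped) >= base


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(MirthError):
            bh_adjust([0.5, 1.5])

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_agrees_with_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


class TestClassification:
    def _trials(self, frac_sig, n_trials=20, feature="f", batch="b"):
        n_sig = int(round(frac_sig * n_trials))
        return pd.DataFrame({
            "trial": range(n_trials),
            "batch": batch, "feature": feature, "scored": True,
            "rho": 0.8, "p": 0.001, "q": 0.01,
            "significant": [True] * n_sig + [False] * (n_trials - n_sig),
        })

    def test_95_percent_of_trials_is_well_predicted(self):
        out = classify_well_predicted(self._trials(0.95))
        assert bool(out.loc[0, "well_predicted"])

    def test_exactly_90_percent_excluded(self):
        out = classify_well_predicted(self._trials(0.90))
        assert not bool(out.loc[0, "well_predicted"])

    def test_three_batches_not_reproducible(self):
        per = pd.DataFrame({"feature": ["f"] * 3, "batch": list("abc"),
                            "well_predicted": [True] * 3})
        out = classify_reproducible(per, {"f": {"a", "b", "c"}})
        assert not bool(out.loc[0, "reproducibly_well_predicted"])

    def test_three_of_four_batches_is_reproducible(self):
        per = pd.DataFrame({"feature": ["f"] * 4, "batch": list("abcd"),
                            "well_predicted": [True, True, True, False]})
        out = classify_reproducible(per, {"f": {"a", "b", "c", "d"}})
        assert bool(out.loc[0, "reproducibly_well_predicted"])

    def test_two_of_four_batches_not_reproducible(self):
        per = pd.DataFrame({"feature": ["f"] * 4, "batch": list("abcd"),
                            "well_predicted": [True, True, False, False]})
        out = classify_reproducible(per, {"f": {"a", "b", "c", "d"}})
        assert not bool(out.loc[0, "reproducibly_well_predicted"])


class TestEnrichment:
    def test_pure_pathway_dimension_has_smallest_p(self):
        feats = [f"f{i}" for i in range(12)]
        annotations = {f: ("lipid" if i < 4 else "amino acid")
                       for i, f in enumerate(feats)}
        H = np.full((2, 12), 0.01)
        H[0, :4] = 0.9          # dimension 0 weights exactly the lipids
        H[1, [1, 5, 8]] = 0.5   # dimension 1 mixes pathways
        out = enrichment_by_dimension(H, feats, annotations, cutoff=0.2)
        d0 = out[(out.dimension == 0) & (out.pathway == "lipid")]
        assert d0["p"].iloc[0] == out[out.dimension == 0]["p"].min()

    def test_cutoff_above_max_weight_empty(self):
        H = np.full((2, 4), 0.1)
        out = enrichment_by_dimension(H, list("abcd"), {"a": "p", "b": "p"},
                                      cutoff=0.5)
        assert len(out) == 0

    def test_extreme_table_matches_hypergeometric(self):
        """(5,0;0,5) table: two-sided Fisher p = 2/C(10,5)."""
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[5, 0], [0, 5]])
        from math import comb
        assert p == pytest.approx(2 / comb(10, 5))
        feats = [f"f{i}" for i in range(10)]
        annotations = {f: ("in" if i < 5 else "out") for i, f in enumerate(feats)}
        H = np.zeros((1, 10))
        H[0, :5] = 1.0
        out = enrichment_by_dimension(H, feats, annotations, cutoff=0.2)
        got = out[(out.pathway == "in")]["p"].iloc[0]
        assert got == pytest.approx(2 / comb(10, 5))


class TestRunBenchmark:
    def test_within_design_produces_positive_rho(self):
        cfg = SimulationConfig(n_batches=1, samples_per_batch=24, n_features=20,
                               measured_fraction=1.0, true_rank=2, noise_sd=0.05,
                               seed=11)
        datasets, _ = simulate(cfg)
        rep = run_benchmark(datasets, design="within", n_trials=3, k=2, seed=0)
        t = rep.trials[rep.trials.scored]
        assert len(t) > 0
        assert summarize_rho(t["rho"].tolist()) > 0

    def test_mode_design_runs_and_scores_single_mode_features(self):
        datasets, _, _, labels = make_fixture("tiny-mode")
        rep = run_benchmark(datasets, design="mode", n_trials=2, k=2, seed=0,
                            mode_labels=labels, masked_mode="neg")
        scored_feats = set(rep.trials["feature"])
        assert scored_feats <= {f for f in labels if labels[f] == "neg"}

    def test_scoring_uses_only_masked_cells(self, three_batches):
        """Observed cells never contribute: rho is computed over exactly the
        held-out samples of each masked feature."""
        datasets, _ = three_batches
        rep = run_benchmark(datasets, design="across", n_trials=1, k=2, seed=4,
                            target_batches=["batch0"])
        n_target = datasets[0].n_samples
        assert (rep.trials["n_masked"] == n_target).all()

    def test_deterministic_given_seed(self, three_batches):
        datasets, _ = three_batches
        r1 = run_benchmark(datasets, design="across", n_trials=2, k=2, seed=9,
                           target_batches=["batch0"])
        r2 = run_benchmark(datasets, design="across", n_trials=2, k=2, seed=9,
                           target_batches=["batch0"])
        pd.testing.assert_frame_equal(r1.trials, r2.trials)
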