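import numpy as np
import pandas as pd
import pytest

from pam50stab.datatypes import (
    SUBTYPES,
    CentroidMatrix,
    DegenerateProfileError,
    ExpressionMatrix,
    ValidationError,
)
from pam50stab.classify import (
    ReferenceSetCollection,
    _majority_call,
    _second_best,
    build_reference_sets,
    centroid_intercorrelation,
    classify_ensemble,
    classify_single,
    crosstab_nc_vs_2nd,
    default_composition,
)
from conftest import identical_refsets, make_prototype_cohort
from _oracle import brute_force_median_centering, brute_force_nc, brute_force_pearson


def toy_centroids(rows, genes=None):
    genes = genes or [f"g{i}" for i in range(len(rows[0]))]
    return CentroidMatrix(pd.DataFrame(rows, index=list(SUBTYPES), columns=genes))


class TestClassifySingle:
    def test_profile_equal_to_centroid_scores_one(self, centroids):
        luma = centroids.values.loc["LumA"]
        fpkm = pd.Series(np.exp2(luma.to_numpy() + 3.0) - 0.1, index=centroids.genes)
        centering = pd.Series(3.0, index=centroids.genes)
        corrs, call = classify_single(fpkm, centering, centroids)
        assert call == "LumA"
        assert corrs["LumA"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_five_gene_example(self):
        """Profile (1..5): rho = +1 to the ascending centroid, -1 to the
        descending one; the ascending subtype (Basal) is called."""
        cent = toy_centroids([
            [1, 2, 3, 4, 5],      # Basal: identical ranks
            [5, 4, 3, 2, 1],      # HER2E: reversed ranks
            [2, 1, 4, 3, 5],
            [1, 3, 2, 5, 4],
            [3, 1, 2, 5, 4],
        ])
        fpkm = pd.Series(np.exp2(np.array([1.0, 2, 3, 4, 5])) - 0.1,
                         index=cent.genes)
        corrs, call = classify_single(fpkm, pd.Series(0.0, index=cent.genes), cent)
        assert call == "Basal"
        assert corrs["Basal"] == pytest.approx(1.0, abs=1e-12)
        assert corrs["HER2E"] == pytest.approx(-1.0, abs=1e-12)

    def test_all_negative_correlations_still_called(self):
        """No minimum correlation cut-off: the argmax is returned even when
        every centroid correlates negatively."""
        cent = toy_centroids([
            [1, 2, 3, 4, 5],
            [2, 1, 4, 3, 5],
            [1, 3, 2, 4, 5],
            [2, 3, 1, 4, 5],
            [1, 2, 4, 3, 5],
        ])
        # descending profile anti-correlates with all ascending-ish centroids
        fpkm = pd.Series(np.exp2(np.array([5.0, 4, 3, 2, 1])) - 0.1,
                         index=cent.genes)
        corrs, call = classify_single(fpkm, pd.Series(0.0, index=cent.genes), cent)
        assert max(corrs.values()) < 0
        assert call == max(corrs, key=corrs.get)

    def test_constant_profile_degenerate(self, centroids):
        fpkm = pd.Series(1.0, index=centroids.genes)
        centering = pd.Series(0.0, index=centroids.genes)
        with pytest.raises(DegenerateProfileError):
            classify_single(fpkm, centering, centroids)

    def test_too_few_shared_genes(self, centroids):
        fpkm = pd.Series([1.0, 2.0], index=["ESR1", "ERBB2"])
        centering = pd.Series(0.0, index=["ESR1", "ERBB2"])
        with pytest.raises(ValidationError, match=">= 3"):
            classify_single(fpkm, centering, centroids)


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self):
        """Vectorised ensemble path reproduces the naive per-pair
        implementation to 1e-12 on random instances."""
        rng = np.random.default_rng(123)
        genes = [f"g{i}" for i in range(10)]
        for _ in range(10):
            fpkm = rng.gamma(2.0, 3.0, size=(10, 20))
            expr = ExpressionMatrix(pd.DataFrame(
                fpkm, index=genes, columns=[f"s{j}" for j in range(20)]))
            cent = toy_centroids(rng.normal(size=(5, 10)).tolist(), genes)
            ref_samples = list(rng.choice(expr.samples, size=8, replace=False))
            log2_ref = expr.log2()[ref_samples].to_numpy()
            centering_vec = brute_force_median_centering(log2_ref)
            refsets = ReferenceSetCollection(
                sets=[ref_samples],
                centering=pd.DataFrame({"ref001": centering_vec}, index=genes))
            cls = classify_ensemble(expr, refsets, cent)
            for sample in expr.samples:
                corrs, call, tied = brute_force_nc(
                    expr.values[sample].to_numpy(), centering_vec,
                    cent.values.to_numpy())
                # calls must agree wherever the argmax is unique; at an exact
                # correlation tie either tied subtype is a correct call
                if len(tied) == 1:
                    assert cls.table.at[sample, "pam50_nc"] == call
                else:
                    assert cls.table.at[sample, "pam50_nc"] in tied
                for st in SUBTYPES:
                    assert cls.table.at[sample, f"corr_{st}"] == pytest.approx(
                        corrs[st], abs=1e-12)


class TestEnsemble:
    def test_ensemble_of_identical_sets_equals_single(self, small_cohort, centroids):
        expr = small_cohort.expression
        refsets = identical_refsets(expr, 10)
        cls = classify_ensemble(expr, refsets, centroids)
        centering = refsets.centering["ref001"]
        for sample in expr.samples[:25]:
            corrs, call = classify_single(expr.values[sample], centering, centroids)
            assert cls.table.at[sample, "pam50_nc"] == call
            assert cls.table.at[sample, "votes_" + call] == 10
            for st in SUBTYPES:
                assert cls.table.at[sample, f"corr_{st}"] == pytest.approx(
                    corrs[st], abs=1e-12)

    def test_vote_counts_sum_and_delta_nonnegative(self, small_cohort, centroids,
                                                   small_refsets):
        cls = classify_ensemble(small_cohort.expression, small_refsets, centroids)
        votes = cls.vote_counts()
        assert (votes.sum(axis=1) == small_refsets.n_sets).all()
        assert (cls.table["delta"].dropna() >= 0).all()
        assert (cls.table["pam50_nc"] != cls.table["pam50_nc_2nd"]).all()

    def test_joint_scaling_leaves_calls_unchanged(self, small_cohort, centroids,
                                                  truth_labels):
        """Scaling every sample (cohort and references) by the same factor
        leaves all ensemble calls unchanged."""
        expr = small_cohort.expression
        comp = default_composition(truth_labels, 20)
        refsets = build_reference_sets(expr, truth_labels, comp, n_sets=10, seed=3)
        cls = classify_ensemble(expr, refsets, centroids)
        scaled = ExpressionMatrix(expr.values * 4.0)
        refsets2 = build_reference_sets(scaled, truth_labels, comp, n_sets=10, seed=3)
        cls2 = classify_ensemble(scaled, refsets2, centroids)
        assert (cls.calls() == cls2.calls()).all()

    def test_degenerate_sample_excluded_with_warning(self, centroids):
        vals = {"ok": np.exp2(centroids.values.loc["Basal"].to_numpy() + 3) - 0.1,
                "flat": np.full(50, 2.0),
                "ok2": np.exp2(centroids.values.loc["LumA"].to_numpy() + 3) - 0.1}
        expr = ExpressionMatrix(pd.DataFrame(vals, index=centroids.genes))
        # constant centering: the flat sample's centered profile is constant
        centering = pd.DataFrame({"ref001": np.zeros(50)}, index=centroids.genes)
        refsets = ReferenceSetCollection(sets=[expr.samples], centering=centering)
        with pytest.warns(UserWarning, match="flat"):
            cls = classify_ensemble(expr, refsets, centroids)
        assert cls.excluded == ["flat"]
        assert set(cls.samples) == {"ok", "ok2"}


class TestTieBreaks:
    def test_vote_tie_broken_by_mean_correlation(self):
        votes = np.array([0, 0, 50, 50, 0])
        corr = np.array([0.1, 0.2, 0.62, 0.60, 0.3])
        assert _majority_call(votes, corr, "s") == "LumA"

    def test_exact_tie_falls_back_to_subtype_order(self):
        votes = np.array([50, 0, 50, 0, 0])
        corr = np.array([0.5, 0.1, 0.5, 0.1, 0.1])
        with pytest.warns(UserWarning, match="tie"):
            assert _majority_call(votes, corr, "s") == "Basal"

    def test_second_best_and_delta_arithmetic(self):
        corr = np.array([0.1, 0.2, 0.8, 0.7, 0.3])  # LumA called
        second, delta = _second_best(corr, SUBTYPES.index("LumA"))
        assert second == "LumB"
        assert delta == pytest.approx(0.1)

    def test_exact_second_third_tie_is_ambiguous(self):
        corr = np.array([0.1, 0.3, 0.8, 0.3, 0.2])
        second, delta = _second_best(corr, SUBTYPES.index("LumA"))
        assert second == "ambiguous"
        assert np.isnan(delta)


class TestCentroidIntercorrelation:
    def test_matches_brute_force_pearson(self, centroids):
        tab = centroid_intercorrelation(centroids)
        assert np.allclose(tab.to_numpy(), tab.to_numpy().T)
        for a in SUBTYPES:
            assert tab.at[a, a] == pytest.approx(1.0, abs=1e-12)
            for b in SUBTYPES:
                expect = brute_force_pearson(centroids.values.loc[a],
                                             centroids.values.loc[b])
                assert tab.at[a, b] == pytest.approx(expect, abs=1e-12)

    def test_negated_centroid_correlates_minus_one(self):
        base = [1.0, 2.0, 4.0]
        cent = toy_centroids([base, [-x for x in base],
                              [1, 3, 2], [3, 1, 2], [2, 3, 1]])
        tab = centroid_intercorrelation(cent)
        assert tab.at["Basal", "HER2E"] == pytest.approx(-1.0, abs=1e-12)


class TestCrosstab:
    def test_three_sample_example(self, small_cohort, centroids, small_refsets):
        cls = classify_ensemble(small_cohort.expression, small_refsets, centroids)
        sub = cls.table.iloc[:0].copy()
        rows = pd.DataFrame({
            "pam50_nc": ["LumA"] * 3, "pam50_nc_2nd": ["LumB"] * 3,
        }, index=["a", "b", "c"])
        from pam50stab.classify import EnsembleClassification
        tabs = crosstab_nc_vs_2nd(
            EnsembleClassification(table=rows, n_sets=1))
        assert tabs["all"].at["LumA", "LumB"] == 3
        assert tabs["all"].to_numpy().sum() == 3

    def test_row_sums_conserve_subtype_counts(self, small_cohort, centroids,
                                              small_refsets):
        cls = classify_ensemble(small_cohort.expression, small_refsets, centroids)
        tabs = crosstab_nc_vs_2nd(cls)
        unamb = cls.table[cls.table["pam50_nc_2nd"] != "ambiguous"]
        counts = unamb["pam50_nc"].value_counts()
        for st in SUBTYPES:
            assert tabs["all"].loc[st].sum() == counts.get(st, 0)
        assert np.diag(tabs["all"].to_numpy()).sum() == 0


class TestReferenceSets:
    def test_forced_draw_with_minimal_cohort(self, centroids):
        expr, labels = make_prototype_cohort(centroids, n_per_subtype=1)
        refsets = build_reference_sets(expr, labels, {s: 1 for s in SUBTYPES},
                                       n_sets=3, seed=0)
        assert all(sorted(s) == sorted(expr.samples) for s in refsets.sets)
        expected = expr.log2().median(axis=1)
        for k in range(3):
            np.testing.assert_allclose(refsets.centering.iloc[:, k], expected)

    def test_seeded_reproducibility(self, small_cohort, truth_labels):
        comp = default_composition(truth_labels, 20)
        a = build_reference_sets(small_cohort.expression, truth_labels, comp,
                                 n_sets=5, seed=11)
        b = build_reference_sets(small_cohort.expression, truth_labels, comp,
                                 n_sets=5, seed=11)
        assert a.sets == b.sets
        pd.testing.assert_frame_equal(a.centering, b.centering)

    def test_insufficient_subtype_raises(self, small_cohort, truth_labels):
        n_basal = int((truth_labels == "Basal").sum())
        with pytest.raises(ValidationError, match="Basal"):
            build_reference_sets(small_cohort.expression, truth_labels,
                                 {"Basal": n_basal + 1}, n_sets=2, seed=0)

    def test_default_composition_is_balanced_and_feasible(self, truth_labels):
        comp = default_composition(truth_labels, 50)
        avail = truth_labels.value_counts()
        for st, count in comp.items():
            assert 1 <= count <= avail[st]
            assert count == min(10, avail[st])
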