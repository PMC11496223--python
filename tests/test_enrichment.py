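"""Enrichment statistics against brute-force combinatorial oracles."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from imgtx import (
    GeneSetCollection,
    compute_psi,
    disease_overlap_test,
    marker_enrichment,
    overrepresentation_test,
    specificity_enrichment,
)


def hypergeom_upper_tail_oracle(N, K, n, k_obs):
    """P(overlap >= k_obs) by direct summation of hypergeometric terms."""
    return sum(
        comb(K, k, exact=True) * comb(N - K, n - k, exact=True)
        for k in range(k_obs, min(K, n) + 1)
    ) / comb(N, n, exact=True)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    row1, col1, N = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(col1, x, exact=True)
            * comb(N - col1, row1 - x, exact=True)
            / comb(N, row1, exact=True)
        )

    p_obs = prob(a)
    return sum(
        p for x in range(max(0, row1 + col1 - N), min(row1, col1) + 1)
        if (p := prob(x)) <= p_obs * (1 + 1e-9)
    )


@pytest.fixture
def universe100():
    return [f"g{i:03d}" for i in range(100)]


class TestOverrepresentation:
    def test_full_overlap_matches_single_hypergeometric_term(self, universe100):
        sets = GeneSetCollection(
            sets={"s": universe100[:10]}, universe=universe100
        )
        res = overrepresentation_test(universe100[:5], sets)
        expected = comb(10, 5, exact=True) / comb(100, 5, exact=True)
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-12)
        assert res.loc[0, "overlap_count"] == 5

    def test_disjoint_set_has_p_one(self, universe100):
        sets = GeneSetCollection(sets={"s": universe100[50:60]}, universe=universe100)
        res = overrepresentation_test(universe100[:5], sets)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_set_equal_to_universe_is_uninformative(self, universe100):
        sets = GeneSetCollection(sets={"s": list(universe100)}, universe=universe100)
        res = overrepresentation_test(universe100[:5], sets)
        assert res.loc[0, "overlap_count"] == 5
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_exhaustive_subset_enumeration_small_universe(self):
        # every draw of |query| genes from a 12-gene universe, counted
        uni = [f"u{i}" for i in range(12)]
        gene_set = uni[2:7]
        rng = np.random.default_rng(0)
        for trial in range(5):
            query = list(rng.choice(uni, size=4, replace=False))
            k_obs = len(set(query) & set(gene_set))
            res = overrepresentation_test(
                query, GeneSetCollection(sets={"s": gene_set}, universe=uni)
            )
            hits = total = 0
            for draw in itertools.combinations(uni, 4):
                total += 1
                hits += len(set(draw) & set(gene_set)) >= k_obs
            assert res.loc[0, "p"] == pytest.approx(hits / total, rel=1e-12)

    def test_empty_inputs_error(self, universe100):
        sets = GeneSetCollection(sets={"s": universe100[:5]}, universe=universe100)
        with pytest.raises(ValueError, match="query"):
            overrepresentation_test(["not_in_universe"], sets)
        with pytest.raises(ValueError, match="universe"):
            overrepresentation_test(
                ["a"], GeneSetCollection(sets={"s": []}, universe=[])
            )

    def test_universe_restriction_leaves_counts_invariant(self, universe100):
        query = universe100[:8]
        gene_set = universe100[4:20]
        full = overrepresentation_test(
            query, GeneSetCollection(sets={"s": gene_set}, universe=universe100)
        )
        restricted_uni = sorted(set(query) | set(gene_set))
        small = overrepresentation_test(
            query, GeneSetCollection(sets={"s": gene_set}, universe=restricted_uni)
        )
        assert full.loc[0, "overlap_count"] == small.loc[0, "overlap_count"]
        assert full.loc[0, "p"] != small.loc[0, "p"]  # p reacts, counts do not


class TestSpecificityIndex:
    @pytest.fixture
    def fixture20x4(self):
        rng = np.random.default_rng(1)
        expr = rng.gamma(2.0, 1.0, size=(20, 4))
        expr[0] = [9.0, 0.1, 0.1, 0.1]  # strongly specific to condition A
        expr[1] = [1.0, 1.0, 1.0, 1.0]  # perfectly uniform
        return pd.DataFrame(
            expr,
            index=[f"g{i}" for i in range(20)],
            columns=["A", "B", "C", "D"],
        )

    def test_exclusive_gene_attains_minimal_psi(self, fixture20x4):
        prof = compute_psi(fixture20x4, n_perm=2000, seed=2)
        psi_A = prof.psi["A"]
        assert prof.si_rank.loc["g0", "A"] == 1.0
        assert psi_A["g0"] == psi_A.min()

    def test_uniform_gene_is_nonspecific_everywhere(self, fixture20x4):
        prof = compute_psi(fixture20x4, n_perm=2000, seed=2)
        assert (prof.psi.loc["g1"] > 0.3).all()

    def test_monte_carlo_matches_exhaustive_permutation_oracle(self, fixture20x4):
        """Sampling condition-label permutations converges to the exact
        pooled null built from all 4! relabelings."""
        prof = compute_psi(fixture20x4, n_perm=4000, seed=3)
        expr = fixture20x4.to_numpy()
        n_genes, n_cond = expr.shape
        # oracle: observed mean competition-ranks, brute force
        def mean_rank(vals, c):
            out = np.empty(n_genes)
            for g in range(n_genes):
                rs = []
                for c2 in range(n_cond):
                    if c2 == c:
                        continue
                    fc = (vals[:, c] + 1e-9) / (vals[:, c2] + 1e-9)
                    rs.append(1 + np.sum(fc > fc[g]))
                out[g] = np.mean(rs)
            return out

        for c_idx, cond in enumerate(fixture20x4.columns):
            obs = mean_rank(expr, c_idx)
            # pooled exhaustive null over all shared column relabelings
            null = []
            for pi in itertools.permutations(range(n_cond)):
                null.append(mean_rank(expr[:, pi], c_idx))
            null = np.concatenate(null)
            exact = (1 + np.array([(null <= o).sum() for o in obs])) / (1 + null.size)
            mc = prof.psi[cond].to_numpy()
            # Monte-Carlo tolerance: 3 binomial SEs on the pooled count
            se = 3 * np.sqrt(exact * (1 - exact) / (4000 * n_genes)) + 1e-3
            assert np.all(np.abs(mc - exact) <= se + 0.02)

    def test_raising_expression_never_raises_psi_there(self, fixture20x4):
        before = compute_psi(fixture20x4, n_perm=1500, seed=4).psi.loc["g5", "B"]
        boosted = fixture20x4.copy()
        boosted.loc["g5", "B"] *= 10
        after = compute_psi(boosted, n_perm=1500, seed=4).psi.loc["g5", "B"]
        assert after <= before

    def test_degenerate_threshold_makes_every_condition_flat(self, fixture20x4):
        prof = compute_psi(fixture20x4, n_perm=500, seed=5)
        res = specificity_enrichment(
            ["g0", "g3", "g7"],
            prof,
            universe=list(fixture20x4.index),
            psi_threshold=1.1,  # above the attainable maximum: all specific
        )
        assert res["p"].to_numpy() == pytest.approx(np.ones(len(res)))


class TestSpecificityEnrichment:
    def test_query_equal_to_specific_set_is_most_enriched(self):
        rng = np.random.default_rng(6)
        expr = rng.gamma(2.0, 1.0, size=(30, 3))
        expr[:6, 0] *= 20  # six genes specific to the first condition
        mat = pd.DataFrame(
            expr, index=[f"g{i}" for i in range(30)], columns=["A", "B", "C"]
        )
        prof = compute_psi(mat, n_perm=2000, seed=7)
        spec_A = [g for g in mat.index if prof.psi.loc[g, "A"] < 0.05]
        assert len(spec_A) > 0
        res = specificity_enrichment(spec_A, prof, universe=list(mat.index))
        res = res.set_index("set")
        assert res.loc["A", "p"] == res["p"].min()

    def test_null_queries_rarely_reject(self):
        rng = np.random.default_rng(8)
        expr = rng.gamma(2.0, 1.0, size=(40, 3))
        mat = pd.DataFrame(
            expr, index=[f"g{i}" for i in range(40)], columns=["A", "B", "C"]
        )
        prof = compute_psi(mat, n_perm=1000, seed=9)
        rejections = np.zeros(3)
        n_rep = 100
        for rep in range(n_rep):
            query = list(rng.choice(mat.index, size=10, replace=False))
            res = specificity_enrichment(query, prof, universe=list(mat.index))
            rejections += (res.set_index("set").loc[["A", "B", "C"], "p"] < 0.05)
        assert (rejections / n_rep <= 0.08).all()


class TestMarkerAndDiseaseTests:
    def test_contained_marker_set_is_enriched(self, universe100):
        markers = GeneSetCollection(sets={"m": universe100[:5]}, universe=universe100)
        res = marker_enrichment(universe100[:20], markers)
        assert res.loc[0, "odds_ratio"] > 1
        assert res.loc[0, "p"] < 0.05

    def test_depleted_marker_set_has_odds_ratio_below_one(self, universe100):
        markers = GeneSetCollection(sets={"m": universe100[:40]}, universe=universe100)
        res = marker_enrichment(universe100[40:90], markers)
        assert res.loc[0, "overlap_count"] == 0
        assert res.loc[0, "odds_ratio"] < 1

    def test_fisher_matches_fixed_margin_enumeration(self):
        a, b, c, d = 8, 2, 10, 80
        uni = [f"g{i}" for i in range(a + b + c + d)]
        query = uni[: a + b]
        disease = uni[:a] + uni[a + b : a + b + c]
        res = disease_overlap_test(query, disease, uni)
        assert (res.a, res.b, res.c, res.d) == (a, b, c, d)
        assert res.p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)
        assert res.odds_ratio == pytest.approx(a * d / (b * c))

    def test_proportional_table_has_unit_odds_ratio(self):
        uni = [f"g{i}" for i in range(15)]
        query = uni[:5]  # a=2, b=3
        disease = uni[:2] + uni[5:9]  # c=4, d=6
        res = disease_overlap_test(query, disease, uni)
        assert (res.a, res.b, res.c, res.d) == (2, 3, 4, 6)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_perfect_overlap_has_infinite_odds_ratio(self):
        uni = [f"g{i}" for i in range(10)]
        res = disease_overlap_test(uni[:5], uni[:5], uni)
        assert res.odds_ratio == math.inf
        assert res.p == pytest.approx(
            fisher_two_sided_oracle(5, 0, 0, 5), rel=1e-9
        )

    def test_synthetic_universe_large_table(self):
        # counts shaped like a disease-overlap analysis on a genome-scale
        # universe: 13 shared genes, 609-gene query, 173-gene disease list
        a, query_n, disease_n, N = 13, 609, 173, 24000
        uni = [f"g{i}" for i in range(N)]
        query = uni[:a] + uni[1000 : 1000 + query_n - a]
        disease = uni[:a] + uni[10000 : 10000 + disease_n - a]
        res = disease_overlap_test(query, disease, uni)
        b, c = query_n - a, disease_n - a
        d = N - a - b - c
        assert (res.a, res.b, res.c, res.d) == (a, b, c, d)
        assert res.odds_ratio == pytest.approx(a * d / (b * c))
        assert 0 < res.p < 1
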