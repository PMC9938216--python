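"""Hypergeometric enrichment, BH adjustment, interactome calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import silamnet as sn
from silamnet.enrich import (
    call_interactome,
    cross_dataset_overlap,
    disease_profile,
    hypergeom_enrich,
    restrict_to_background,
)


def hypergeom_sf_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct combinatorial enumeration (independent of scipy)."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def make_universe(N):
    return [f"g{i}" for i in range(N)]


class TestRestrict:
    def test_intersection_with_universe(self):
        coll = restrict_to_background({"s": {"A", "B", "C"}}, {"A", "B"})
        assert coll.sets["s"] == {"A", "B"}

    def test_disjoint_set_flagged_empty(self):
        coll = restrict_to_background({"s": {"X"}}, {"A"})
        assert coll.sets["s"] == set()
        assert "s" in coll.empty_after_restriction

    def test_subset_unchanged(self):
        coll = restrict_to_background({"s": {"A"}}, {"A", "B"})
        assert coll.sets["s"] == {"A"}


class TestHypergeom:
    def test_full_overlap_probability_closed_form(self):
        # drawing all 10 special genes in 10 draws from 20: p = 1/C(20,10)
        uni = make_universe(20)
        target = set(uni[:10])
        r = hypergeom_enrich(target, target, uni)
        assert r.p == pytest.approx(1.0 / math.comb(20, 10), rel=1e-12)

    def test_overlap_at_expectation_gives_fold_one(self):
        uni = make_universe(100)
        target = set(uni[:10])
        query = set(uni[:1]) | set(uni[50:59])  # k=1, n=10, K=10 -> expected 1
        r = hypergeom_enrich(query, target, uni)
        assert r.fold == pytest.approx(1.0)
        assert r.pct_enrichment == pytest.approx(0.0)

    def test_matches_enumeration_oracle_over_all_small_universes(self):
        # exhaustive check of every (N, K, n, k) configuration with N <= 12
        # (the full N <= 20 sweep runs in the acceptance suite)
        for N in range(2, 13):
            uni = make_universe(N)
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        target = set(uni[:K])
                        query = set(uni[:k]) | set(uni[K : K + n - k])
                        r = hypergeom_enrich(query, target, uni)
                        assert r.k == k
                        assert r.p == pytest.approx(
                            hypergeom_sf_oracle(k, N, K, n), rel=1e-9
                        ), (N, K, n, k)

    def test_p_monotone_decreasing_in_overlap(self):
        N, K, n = 100, 20, 30
        ps = [float(stats.hypergeom.sf(k - 1, N, K, n)) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_query_is_an_error(self):
        uni = make_universe(10)
        with pytest.raises(ValueError):
            hypergeom_enrich(set(), set(uni[:3]), uni)


class TestProfile:
    def test_bh_closed_form(self):
        # BH on p = {0.01, 0.02, 0.03} -> all 0.03
        uni = make_universe(600)
        sets = {"a": set(uni[:80]), "b": set(uni[80:220]), "c": set(uni[220:400])}
        coll = restrict_to_background(sets, uni)
        prof = disease_profile(set(uni[:50]) | set(uni[100:150]), [], coll)
        from statsmodels.stats.multitest import multipletests

        expect = multipletests(prof["p"], method="fdr_bh")[1]
        np.testing.assert_allclose(prof["p_adj"], expect)
        assert (prof["p_adj"] >= prof["p"] - 1e-15).all()

    def test_planted_set_ranks_first_across_seeds(self):
        wins = 0
        for seed in range(100):
            coll, query = sn.gen_gene_universe(sn.SynthConfig(seed=seed))
            prof = disease_profile(query, [], coll)
            prof = prof[prof["direction"] == "up"].sort_values("p")
            wins += prof.iloc[0]["set_name"] == "set_00"
        assert wins >= 95

    def test_null_profile_p_uniformish(self):
        ps = []
        for seed in range(200):
            cfg = sn.SynthConfig(seed=seed, planted_enrichment_fold=1.0,
                                 set_sizes=[400], query_size=800)
            coll, query = sn.gen_gene_universe(cfg)
            ps.append(hypergeom_enrich(query, coll.sets["set_00"], coll.universe).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_overlapping_up_down_rejected(self):
        uni = make_universe(20)
        coll = restrict_to_background({"s": set(uni[:5])}, uni)
        with pytest.raises(ValueError):
            disease_profile({"g1"}, {"g1"}, coll)

    def test_two_sided_variant_caps_at_one(self):
        uni = make_universe(100)
        r = hypergeom_enrich(set(uni[:10]), set(uni[5:15]), uni, two_sided=True)
        assert 0 < r.p <= 1.0


class TestInteractome:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["bait_1", "bait_2", "bait_3",
                                           "igg_1", "igg_2", "igg_3"])

    def test_clear_interactor_called(self):
        res = call_interactome(self._counts([[10, 12, 11, 2, 1, 2]]))
        assert res["called"].iloc[0]
        assert res["fold"].iloc[0] == pytest.approx(11.0 / (5 / 3))

    def test_equal_counts_not_called(self):
        res = call_interactome(self._counts([[3, 3, 3, 3, 3, 3]]))
        assert not res["called"].iloc[0]

    def test_absent_from_control_passes_fold_criterion(self):
        res = call_interactome(self._counts([[5, 6, 7, 0, 0, 0]]))
        assert res["called"].iloc[0]
        assert res["not_in_control"].iloc[0]

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            call_interactome(self._counts([[1.5, 2, 2, 0, 0, 0]]))

    def test_planted_interactors_recovered(self, small_cfg):
        counts, truth = sn.gen_spectral_counts(small_cfg)
        res = call_interactome(counts).join(truth.set_index("protein_id"))
        recall = res.loc[res["label"] == "interactor", "called"].mean()
        fp = res.loc[res["label"] == "background", "called"].mean()
        assert recall > 0.9
        assert fp < 0.15  # one-tailed p<0.1 admits ~10% of null proteins


class TestCrossDataset:
    def test_identical_lists_maximal_fold_perfect_r2(self):
        uni = make_universe(200)
        hits = set(uni[:40])
        eff = {g: i * 0.1 for i, g in enumerate(sorted(hits))}
        res = cross_dataset_overlap(hits, hits, uni, effects_a=eff, effects_b=eff)
        assert res.enrichment.fold == pytest.approx(200 / 40)
        assert res.r_squared == pytest.approx(1.0)

    def test_independent_effects_give_small_r2(self, rng):
        uni = make_universe(500)
        hits = set(uni[:41])
        ea = {g: rng.normal() for g in hits}
        eb = {g: rng.normal() for g in hits}
        res = cross_dataset_overlap(hits, hits, uni, effects_a=ea, effects_b=eb)
        assert res.r_squared < 0.2

    def test_tiny_overlap_skips_correlation(self):
        uni = make_universe(50)
        res = cross_dataset_overlap(set(uni[:2]), set(uni[:2]), uni,
                                    effects_a={"g0": 1.0, "g1": 2.0},
                                    effects_b={"g0": 1.0, "g1": 2.0})
        assert res.correlation_skipped

    def test_excluding_planted_locus_genes_drops_significance(self, rng):
        # mixed set: 10 locus genes with strongly correlated (cis) effects on
        # top of 30 genes with independent effects
        uni = make_universe(500)
        locus = [f"g{i}" for i in range(10)]
        rest = [f"g{i}" for i in range(10, 40)]
        hits = set(locus) | set(rest)
        ea, eb = {}, {}
        for g in locus:
            v = rng.normal(scale=3.0)
            ea[g], eb[g] = v, v + rng.normal(scale=0.1)
        for g in rest:
            ea[g], eb[g] = rng.normal(), rng.normal()
        with_locus = cross_dataset_overlap(hits, hits, uni, effects_a=ea, effects_b=eb)
        without = cross_dataset_overlap(hits, hits, uni, effects_a=ea, effects_b=eb,
                                        exclude=locus)
        assert with_locus.p_correlation < 0.001
        assert without.p_correlation > with_locus.p_correlation
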