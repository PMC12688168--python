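"""Hypergeometric enrichment, robust pathway list, resistance score + bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

from chemoresistome.data import GeneSet, GeneSetCollection
from chemoresistome.errors import ValidationError
from chemoresistome import enrichment as enr


def hypergeom_tail_oracle(k, M, n, K):
    """P(overlap >= k) by explicit combinatorial sum."""
    total = math.comb(M, K)
    return sum(math.comb(n, i) * math.comb(M - n, K - i)
               for i in range(k, min(n, K) + 1)) / total


def _collection(sets):
    coll = GeneSetCollection()
    for name, genes in sets.items():
        coll.add(GeneSet(name, "d", tuple(genes)))
    return coll


class TestHypergeomEnrich:
    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        coll = _collection({"pw": universe[40:50]})
        res = enr.hypergeom_enrich(universe[:10], universe, coll)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_combinatorial_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        hits = universe[:20]
        # pathway of 10 genes with overlap 5
        pw = universe[15:20] + universe[90:95]
        res = enr.hypergeom_enrich(hits, universe, _collection({"pw": pw}))
        assert res["overlap"].iloc[0] == 5
        assert res["p_value"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(5, 100, 20, 10), rel=1e-12)

    def test_full_containment_is_most_significant(self):
        universe = [f"g{i}" for i in range(100)]
        hits = universe[:20]
        coll = _collection({"inside": universe[:10],
                            "half": universe[15:25],
                            "outside": universe[50:60]})
        res = enr.hypergeom_enrich(hits, universe, coll).set_index("pathway")
        assert res.loc["inside", "p_value"] == pytest.approx(
            hypergeom_tail_oracle(10, 100, 20, 10), rel=1e-12)
        assert (res.loc["inside", "p_value"] < res.loc["half", "p_value"]
                < res.loc["outside", "p_value"])

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            enr.hypergeom_enrich(["x"], ["a", "b"], _collection({"pw": ["a"]}))


class TestRobustPathwayList:
    @staticmethod
    def _run(sig_names, q0=0.001):
        rows = [{"pathway": n, "p_value": q0 * (i + 1), "q_value": q0 * (i + 1),
                 "significant": True} for i, n in enumerate(sig_names)]
        return pd.DataFrame(rows, columns=["pathway", "p_value", "q_value",
                                           "significant"])

    def test_identical_runs_return_that_set(self):
        a = self._run(["x", "y", "z"])
        assert enr.robust_pathway_list(a, a.copy()) == ["x", "y", "z"]

    def test_disjoint_runs_union_top_k(self):
        a = self._run([f"a{i}" for i in range(7)])
        b = self._run([f"b{i}" for i in range(9)])
        out = enr.robust_pathway_list(a, b, k_top=5)
        assert len(out) == 10
        assert set(out) == {f"a{i}" for i in range(5)} | {f"b{i}" for i in range(5)}

    def test_shared_plus_bounded_unique(self):
        shared = [f"s{i}" for i in range(33)]
        a = self._run(shared + [f"a{i}" for i in range(7)])
        b = self._run(shared + [f"b{i}" for i in range(17)])
        out = enr.robust_pathway_list(a, b, k_top=5)
        assert set(shared) <= set(out)
        assert 33 < len(out) <= 43


class TestResistanceScore:
    def test_fraction_arithmetic(self):
        patterns = {f"g{i}": ("P3" if i < 7 else "P1") for i in range(10)}
        rs = enr.resistance_score("pt", "pw", list(patterns), patterns,
                                  list(patterns))
        assert rs.score == pytest.approx(0.7)
        assert rs.n_considered == 10 and rs.n_resistance == 7

    def test_all_reregulated_scores_zero(self):
        patterns = {f"g{i}": "P1" for i in range(5)}
        rs = enr.resistance_score("pt", "pw", list(patterns), patterns,
                                  list(patterns))
        assert rs.score == 0.0

    def test_empty_considered_set(self):
        rs = enr.resistance_score("pt", "pw", ["a", "b"], {}, ["c"])
        assert rs.n_considered == 0 and rs.score is None

    def test_planted_resistant_pathways_outscore_random(self, small_cohort,
                                                        small_fit):
        scores = enr.compute_resistance_scores(
            small_fit.assignments, small_fit.de.retained,
            small_cohort.gene_sets, n_boot=200, seed=5)
        scores = scores[scores["score"].notna()]
        resist = small_cohort.truth.planted_resistant_pathways
        above = []
        for _, sub in scores.groupby("patient"):
            rand_median = sub.loc[~sub["pathway"].isin(resist), "score"].median()
            above.extend(sub.loc[sub["pathway"].isin(resist), "score"] > rand_median)
        assert np.mean(above) >= 0.8

    def test_planted_median_exceeds_random_median(self, small_cohort, small_fit):
        scores = enr.compute_resistance_scores(
            small_fit.assignments, small_fit.de.retained,
            small_cohort.gene_sets, n_boot=50, seed=5)
        scores = scores[scores["score"].notna()]
        resist = small_cohort.truth.planted_resistant_pathways
        med_res = scores.loc[scores["pathway"].isin(resist), "score"].median()
        med_rand = scores.loc[~scores["pathway"].isin(resist), "score"].median()
        assert med_res > med_rand


class TestBootstrapPvalue:
    def test_observed_zero_gives_p_one(self):
        flags = np.array([True] * 3 + [False] * 9)
        assert enr.bootstrap_pvalue(0.0, 4, flags, n_boot=500, rng=1) == 1.0

    def test_degenerate_all_resistance_universe(self):
        flags = np.ones(10, bool)
        assert enr.bootstrap_pvalue(1.0, 4, flags, n_boot=500, rng=1) == 1.0

    def test_universe_smaller_than_pathway_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            enr.bootstrap_pvalue(0.5, 5, np.ones(3, bool))

    def test_reproducible_for_fixed_seed(self):
        flags = np.array([True] * 7 + [False] * 5)
        a = enr.bootstrap_pvalue(0.75, 4, flags, n_boot=2000, rng=42)
        b = enr.bootstrap_pvalue(0.75, 4, flags, n_boot=2000, rng=42)
        assert a == b

    def test_monotone_in_observed_score(self):
        flags = np.array([True] * 30 + [False] * 70)
        ps = [enr.bootstrap_pvalue(s, 10, flags, n_boot=5000, rng=9)
              for s in (0.0, 0.2, 0.5, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_converges_to_exact_enumeration_for_small_universe(self):
        # universes of <= 15 genes: the MC estimate approaches the exact tail
        flags = np.array([True] * 9 + [False] * 6)
        for obs, k in [(1.0, 3), (2 / 3, 3), (0.5, 4)]:
            exact = enr.exact_bootstrap_tail(obs, k, 15, 9)
            p = enr.bootstrap_pvalue(obs, k, flags, n_boot=100_000, rng=3)
            mc_sd = np.sqrt(exact * (1 - exact) / 100_000)
            assert abs(p - exact) < 4 * mc_sd + 1e-12

    def test_with_replacement_variant(self):
        flags = np.array([True] * 5 + [False] * 5)
        p = enr.bootstrap_pvalue(1.0, 3, flags, n_boot=50_000, rng=2, replace=True)
        assert p == pytest.approx(0.5 ** 3, abs=0.01)
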