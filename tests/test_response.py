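"""Response association: exact rank-sum, gene lists, ANOVA, survival."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from chemoresistome.data import PatientTable
from chemoresistome.errors import ValidationError
from chemoresistome import response as rsp
from chemoresistome.simulate import SyntheticConfig, generate_cohort


def midranks(values):
    """Hand-rolled midranks (independent of scipy.rankdata)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def permutation_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration of group labelings,
    exact rational arithmetic throughout."""
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    nx, n = len(x), len(pooled)
    w_obs = sum(ranks[:nx])
    le = ge = total = 0
    for idx in combinations(range(n), nx):
        w = sum(ranks[i] for i in idx)
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    p = 2 * min(Fraction(le, total), Fraction(ge, total))
    return float(min(p, Fraction(1)))


class TestRankSum:
    @pytest.mark.parametrize("x,y", [
        ([4, 4, 3], [1, 2, 2]),
        ([5, 4, 3, 2], [4, 3, 2, 1]),
        ([2], [3]),
        ([1, 1], [1, 1]),
        ([3, 3, 3], [3, 3]),
        ([5, 1], [2, 2, 2, 4]),
    ])
    def test_exact_p_matches_permutation_enumeration(self, x, y):
        _, p = rsp.rank_sum_test(x, y, method="exact")
        assert p == pytest.approx(permutation_oracle(x, y), abs=1e-12)

    def test_exact_on_random_tied_grades(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 9))
            nx = int(rng.integers(1, n))
            pooled = rng.integers(1, 6, size=n)
            x, y = list(pooled[:nx]), list(pooled[nx:])
            _, p = rsp.rank_sum_test(x, y, method="exact")
            assert p == pytest.approx(permutation_oracle(x, y), abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = rsp.rank_sum_test([1, 2, 3], [3, 2, 1], method="exact")
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rsp.rank_sum_test([], [1, 2])

    def test_approx_tracks_exact_for_moderate_n(self, rng):
        # heavy ties at n=18: individual instances can diverge, but the
        # tie-corrected normal approximation tracks the exact p on average
        diffs = []
        for _ in range(50):
            x = rng.integers(1, 6, size=9)
            y = rng.integers(1, 6, size=9)
            _, p_exact = rsp.rank_sum_test(x, y, method="exact")
            _, p_approx = rsp.rank_sum_test(x, y, method="approx")
            diffs.append(abs(p_exact - p_approx))
        assert np.mean(diffs) < 0.05


class TestWilcoxonResponse:
    @staticmethod
    def _assignments(pattern_by_patient, gene="g1"):
        return pd.DataFrame([{"gene": gene, "patient": p, "pattern": pt,
                              "correlation": 1.0}
                             for p, pt in pattern_by_patient.items()])

    def test_groups_built_from_cluster_patterns(self):
        a = self._assignments({"A": "P1", "B": "P1", "C": "P3", "D": "P7",
                               "E": "P5", "F": "P2"})
        mp = {"A": 4, "B": 3, "C": 1, "D": 2, "E": 5, "F": 5}
        ra = rsp.wilcoxon_response("g1", a, mp, cluster="up")
        assert sorted(ra.good_group_mp) == [3, 4]
        assert sorted(ra.poor_group_mp) == [1, 2]  # P5/P6 and P2 dropped

    def test_empty_group_returns_none(self):
        a = self._assignments({"A": "P1", "B": "P1"})
        assert rsp.wilcoxon_response("g1", a, {"A": 4, "B": 3}, "up") is None

    def test_coupled_cohort_enriches_significant_calls(self):
        # with MP coupled to the planted dysregulated fraction, bimodal genes
        # separate good and poor responders far above the 5% null rate
        def rate(coupling, seed):
            c = generate_cohort(SyntheticConfig(
                n_patients=24, n_genes=300, mp_coupling=coupling,
                n_pathways=0, resistant_pathway_ids=(), seed=seed))
            pl = c.truth.planted_pattern
            a = pl.stack().rename_axis(["gene", "patient"]).reset_index(name="pattern")
            genes = sorted(set(
                a.loc[a["pattern"].isin(["P1", "P2", "P3", "P4"]), "gene"]))
            t = rsp.response_gene_tests(genes, a, c.patients.mp_map())
            return t["significant"].mean()

        assert rate(3.0, 21) > rate(0.0, 21) + 0.10


class TestPersistentGenes:
    @staticmethod
    def _classifications(rows):
        df = pd.DataFrame(rows).set_index("gene")
        for p in ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8"):
            df[f"n_{p}"] = df.get(f"n_{p}", 0)
        return df.fillna(0)

    def test_combined_route_arithmetic(self):
        cls = self._classifications([
            {"gene": "combined", "n_classified_patients": 20, "n_P3": 8, "n_P7": 3},
            {"gene": "split", "n_classified_patients": 20, "n_P3": 9, "n_P4": 9},
            {"gene": "p4solo", "n_classified_patients": 20, "n_P4": 11},
        ])
        out = rsp.persistent_resistance_genes(cls)
        assert out == ["combined", "p4solo"]  # 55% > 50%; 45/45 fails; 55% P4

    def test_planted_persistent_gene_qualifies(self, standard_fit, standard_cohort):
        truth = standard_cohort.truth
        planted_p3 = [g for g, p in truth.primary_pattern.items() if p == "P3"]
        persist = set(standard_fit.resistance_genes.persistent_genes)
        frac = np.mean([g in persist for g in planted_p3])
        assert frac > 0.8

    def test_combined_list_is_union(self):
        gl = rsp.resistance_gene_list(["a", "b"], ["b", "c"])
        assert gl.combined == ["a", "b", "c"]


class TestRatioAnova:
    def test_identical_ratios_give_f_zero(self):
        ratios = {f"p{i}": 2.0 for i in range(9)}
        mp = {f"p{i}": 1 + i % 3 for i in range(9)}
        res = rsp.ratio_anova(ratios, mp, groups=((1,), (2,), (3,)))
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_separated_groups_give_small_p(self):
        ratios = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 9.0, "e": 9.0, "f": 9.0}
        mp = {"a": 1, "b": 1, "c": 1, "d": 4, "e": 4, "f": 4}
        res = rsp.ratio_anova(ratios, mp, groups=((1,), (4,)))
        assert res.p_value < 0.01

    def test_two_group_f_equals_t_squared(self, rng):
        x, y = rng.normal(size=8), rng.normal(1, 1, size=7)
        ratios = {f"a{i}": v for i, v in enumerate(x)}
        ratios.update({f"b{i}": v for i, v in enumerate(y)})
        mp = {k: (1 if k.startswith("a") else 4) for k in ratios}
        res = rsp.ratio_anova(ratios, mp, groups=((1,), (4,)))
        t = scipy.stats.ttest_ind(x, y)
        assert res.f_statistic == pytest.approx(t.statistic ** 2)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_infinite_ratios_excluded_by_default(self):
        ratios = {"a": 1.0, "b": 2.0, "c": np.inf, "d": 3.0, "e": 1.5}
        mp = {"a": 1, "b": 1, "c": 1, "d": 4, "e": 4}
        res = rsp.ratio_anova(ratios, mp, groups=((1,), (4,)))
        assert sum(res.group_sizes.values()) == 4

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            rsp.ratio_anova({"a": 1.0, "b": 2.0}, {"a": 1, "b": 4},
                            groups=((1,), (4,)))


class TestKaplanMeierLogrank:
    @staticmethod
    def _patients(rows):
        return PatientTable(pd.DataFrame(rows))

    def test_identical_strata_give_zero_statistic(self):
        rows = []
        for stratum, ratio in (("h", 10.0), ("l", 1.0)):
            for i, (t, e) in enumerate([(1.0, True), (2.0, False), (3.0, True)]):
                rows.append({"patient_id": f"{stratum}{i}", "mp_score": 3,
                             "rfs_years": t, "recurrence_event": e})
        pt = self._patients(rows)
        ratios = {p: (10.0 if p.startswith("h") else 1.0)
                  for p in pt.df["patient_id"]}
        res = rsp.km_logrank(pt, ratios, cutoff=5.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_rejected(self):
        rows = [{"patient_id": f"p{i}", "mp_score": 3, "rfs_years": float(i + 1),
                 "recurrence_event": False} for i in range(6)]
        pt = self._patients(rows)
        ratios = {f"p{i}": (10.0 if i < 3 else 1.0) for i in range(6)}
        with pytest.raises(ValidationError, match="events"):
            rsp.km_logrank(pt, ratios)

    def test_empty_stratum_names_cutoff(self):
        rows = [{"patient_id": f"p{i}", "mp_score": 3, "rfs_years": float(i + 1),
                 "recurrence_event": True} for i in range(4)]
        pt = self._patients(rows)
        ratios = {f"p{i}": 1.0 for i in range(4)}
        with pytest.raises(ValidationError, match="5.0"):
            rsp.km_logrank(pt, ratios, cutoff=5.0)

    def test_matches_hand_computed_logrank(self):
        # 6 patients, all events, no censoring: observed-minus-expected by hand
        times_h, times_l = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        rows = ([{"patient_id": f"h{i}", "mp_score": 3, "rfs_years": t,
                  "recurrence_event": True} for i, t in enumerate(times_h)]
                + [{"patient_id": f"l{i}", "mp_score": 3, "rfs_years": t,
                    "recurrence_event": True} for i, t in enumerate(times_l)])
        pt = self._patients(rows)
        ratios = {f"h{i}": 10.0 for i in range(3)}
        ratios.update({f"l{i}": 1.0 for i in range(3)})
        res = rsp.km_logrank(pt, ratios, cutoff=5.0)

        # hand calculation: at each event time, E_h = d * n_h / n, V per
        # two-group hypergeometric variance (d=1 throughout, no ties)
        events = sorted([(t, "h") for t in times_h] + [(t, "l") for t in times_l])
        n_h, n_l = 3, 3
        o_minus_e, var = 0.0, 0.0
        for _, grp in events:
            n = n_h + n_l
            e_h = n_h / n
            o_h = 1.0 if grp == "h" else 0.0
            o_minus_e += o_h - e_h
            var += (n_h * n_l) / (n * n) if n > 1 else 0.0
            # variance term for d=1: n_h*n_l*(n-1)/(n^2 (n-1)) = n_h n_l / n^2
            if grp == "h":
                n_h -= 1
            else:
                n_l -= 1
        chi2 = o_minus_e ** 2 / var
        assert res.statistic == pytest.approx(chi2, rel=1e-6)
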