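"""Trajectory templates, maximal-correlation assignment, gene/patient summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chemoresistome.errors import ValidationError
from chemoresistome import patterns as pat


def brute_force_assign(values, templates):
    """Independent scalar oracle: Pearson argmax via np.corrcoef."""
    v = np.asarray(values, dtype=float)
    if v.std() < 1e-12:
        return pat.UNCLASSIFIED, np.nan
    rs = [np.corrcoef(v, t.levels)[0, 1] for t in templates]
    j = int(np.argmax(rs))
    return templates[j].id, rs[j]


class TestTemplates:
    def test_exactly_eight(self):
        assert len(pat.theoretical_templates()) == 8

    def test_transition_shapes_enumeration_matches_templates(self):
        shapes = pat.enumerate_transition_shapes()
        assert len(shapes) == 8 and (0, 0) not in shapes
        # templates cover each non-flat shape exactly once
        assert sorted(t.transitions() for t in pat.theoretical_templates()) == sorted(shapes)

    def test_negation_partners(self):
        tmpl = {t.id: np.array(t.levels) for t in pat.theoretical_templates()}
        for a, b in [("P1", "P2"), ("P3", "P4"), ("P5", "P6"), ("P7", "P8")]:
            np.testing.assert_array_equal(tmpl[a], -tmpl[b])

    def test_no_two_templates_perfectly_correlated(self):
        tmpl = np.array([t.levels for t in pat.theoretical_templates()])
        z = (tmpl - tmpl.mean(1, keepdims=True)) / tmpl.std(1, keepdims=True)
        r = z @ z.T / 3.0
        off = r[~np.eye(8, dtype=bool)]
        assert np.all(off < 1 - 1e-9)

    def test_scenarios(self):
        scen = {t.id: t.scenario for t in pat.theoretical_templates()}
        assert scen["P1"] == scen["P2"] == "reregulated"
        assert scen["P3"] == scen["P4"] == "resistance"
        assert scen["P5"] == scen["P6"] == "treatment_effect"
        assert scen["P7"] == scen["P8"] == "worsening"

    def test_constant_template_override_rejected(self):
        with pytest.raises(ValidationError):
            pat.theoretical_templates({"P1": (1.0, 1.0, 1.0)})


class TestAssignment:
    @pytest.mark.parametrize("values,expected,corr", [
        ((0.0, 2.0, 0.0), "P1", 1.0),       # exact template shape, any scale
        ((0.0, -3.0, 0.0), "P2", 1.0),
        ((1.0, 3.0, 2.9), "P3", None),      # oracle-confirmed argmax
        ((0.0, 1.0, 2.0), "P7", 1.0),
    ])
    def test_examples(self, values, expected, corr):
        p, r = pat.assign_patterns(np.array(values))
        assert p == expected
        if corr is not None:
            assert r == pytest.approx(corr)
        oracle, _ = brute_force_assign(values, pat.theoretical_templates())
        assert p == oracle

    def test_zero_variance_unclassified(self):
        p, r = pat.assign_patterns(np.array([5.0, 5.0, 5.0]))
        assert p == pat.UNCLASSIFIED and np.isnan(r)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError, match="finite"):
            pat.assign_patterns(np.array([1.0, np.nan, 2.0]))

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
           st.floats(0.1, 10), st.floats(-20, 20))
    def test_scale_shift_invariance(self, values, a, b):
        v = np.array(values)
        if v.std() < 1e-6:
            return
        p0, _ = pat.assign_patterns(v)
        p1, _ = pat.assign_patterns(a * v + b)
        assert p0 == p1

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.floats(-50, 50) for _ in range(3)]))
    def test_negation_maps_to_partner_pattern(self, values):
        v = np.array(values)
        if v.std() < 1e-6:
            return
        p0, r0 = pat.assign_patterns(v)
        p1, r1 = pat.assign_patterns(-v)
        # the winning correlation is negation-invariant; skip the degenerate
        # case of a maximal correlation of ~0 (tie between a pattern and its
        # own partner, winner decided by index only)
        assert r1 == pytest.approx(r0, abs=1e-9)
        if abs(r0) < 1e-9:
            return
        assert p1 == pat.NEGATION_PARTNER[p0]

    def test_vectorized_equals_scalar_oracle(self, rng):
        tri = rng.normal(size=(2000, 3))
        vec, _ = pat.assign_patterns(tri)
        tmpl = pat.theoretical_templates()
        for row, v in zip(tri, vec):
            assert v == brute_force_assign(row, tmpl)[0]

    def test_difference_mode_matches_exact_shapes(self):
        p, _ = pat.assign_patterns(np.array([0.0, 2.0, 0.0]), mode="differences")
        assert p == "P1"


class TestGeneClassification:
    def test_main_at_fifty_percent(self):
        gc = pat.classify_gene(["P3"] * 12 + ["P1"] * 8)
        assert gc.klass == "main" and gc.main_patterns == ("P3",)

    def test_bimodal_rule(self):
        pats = ["P1"] * 8 + ["P3"] * 7 + ["P5"] * 5
        gc = pat.classify_gene(pats)
        assert gc.klass == "bimodal" and gc.main_patterns == ("P1", "P3")

    def test_bimodal_five_patient_floor(self):
        # 40% share but only 4 patients: the floor blocks bimodal status
        pats = ["P1"] * 4 + ["P3"] * 4 + ["P5", "P6"]
        gc = pat.classify_gene(pats)
        assert gc.klass == "unclassified"

    def test_strict_main_threshold(self):
        pats = ["P3"] * 10 + ["P1"] * 10
        assert pat.classify_gene(pats).klass == "main"
        assert pat.classify_gene(pats, strict_main=True).klass != "main"

    def test_unclassified_patients_excluded_from_denominator(self):
        pats = ["P3"] * 6 + [pat.UNCLASSIFIED] * 6
        gc = pat.classify_gene(pats)
        assert gc.n_classified_patients == 6
        assert gc.klass == "main"

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            pat.classify_gene([pat.UNCLASSIFIED])

    def test_classes_partition_gene_list(self, standard_fit):
        counts = standard_fit.classifications["klass"].value_counts()
        assert counts.sum() == len(standard_fit.classifications)
        assert set(counts.index) <= {"main", "bimodal", "unclassified"}


class TestPatientFractions:
    @staticmethod
    def _assignments(pattern_counts, patient="PT1"):
        rows = []
        i = 0
        for p, n in pattern_counts.items():
            for _ in range(n):
                rows.append({"gene": f"g{i}", "patient": patient, "pattern": p,
                             "correlation": 1.0})
                i += 1
        return pd.DataFrame(rows)

    def test_ratio_arithmetic(self):
        a = self._assignments({"P1": 30, "P2": 20, "P7": 5, "P8": 5, "P3": 40})
        pf = pat.pattern_fractions(a, "PT1")
        assert pf.ratio == pytest.approx(5.0)

    def test_infinite_ratio_flagged(self):
        a = self._assignments({"P1": 10})
        pf = pat.pattern_fractions(a, "PT1")
        assert np.isinf(pf.ratio) and pf.ratio_is_infinite

    def test_no_classified_genes_rejected(self):
        a = self._assignments({pat.UNCLASSIFIED: 3})
        with pytest.raises(ValidationError):
            pat.pattern_fractions(a, "PT1")

    def test_ratio_anticorrelates_with_planted_dysregulation(self, standard_fit,
                                                             standard_cohort):
        import scipy.stats
        fr = standard_fit.fractions
        truth = standard_cohort.truth
        finite = fr[np.isfinite(fr["ratio"])]
        dys = [truth.dysregulated_fraction[p] for p in finite.index]
        rho = scipy.stats.spearmanr(finite["ratio"], dys).statistic
        assert rho < 0
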