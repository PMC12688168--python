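"""Trajectory pattern classification over matched normal/pre/post triplets.

Every gene, in every patient, traces a three-point trajectory of
variance-stabilized expression: adjacent normal -> pretreatment tumor ->
posttreatment residual tumor. Enumerating the qualitative shapes of such a
trajectory — each of the two transitions goes up, down, or is unchanged,
excluding the fully flat case — yields exactly eight templates:

=======  ===============  ====================  ==========
pattern  levels (N,pre,post)  scenario           direction
=======  ===============  ====================  ==========
P1       (0,  1,  0)      reregulated            up
P2       (0, -1,  0)      reregulated            down
P3       (0,  1,  1)      resistance             up
P4       (0, -1, -1)      resistance             down
P5       (0,  0, -1)      treatment_effect       down
P6       (0,  0,  1)      treatment_effect       up
P7       (0,  1,  2)      worsening              up
P8       (0, -1, -2)      worsening              down
=======  ===============  ====================  ==========

A gene-per-patient triplet is assigned the template with the maximal Pearson
correlation; correlation is scale- and shift-invariant, so only the shape
matters. P1/P2 return to normal levels after treatment ("reregulated"),
P3/P4 stay dysregulated ("resistance state"), P5/P6 move only after
treatment, and P7/P8 keep moving away from normal ("worsening").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Triplet, triplet_value_array
from .errors import ValidationError

UNCLASSIFIED = "UNCLASSIFIED"

#: patterns whose dysregulation persists or intensifies after treatment
RESISTANCE_PATTERNS = ("P3", "P4", "P7", "P8")
#: patterns that return to normal levels after treatment
REREGULATED_PATTERNS = ("P1", "P2")

#: negation partner under sign flip of the trajectory
NEGATION_PARTNER = {"P1": "P2", "P2": "P1", "P3": "P4", "P4": "P3",
                    "P5": "P6", "P6": "P5", "P7": "P8", "P8": "P7"}

_SCENARIOS = {"P1": "reregulated", "P2": "reregulated",
              "P3": "resistance", "P4": "resistance",
              "P5": "treatment_effect", "P6": "treatment_effect",
              "P7": "worsening", "P8": "worsening"}

_DEFAULT_LEVELS = {"P1": (0.0, 1.0, 0.0), "P2": (0.0, -1.0, 0.0),
                   "P3": (0.0, 1.0, 1.0), "P4": (0.0, -1.0, -1.0),
                   "P5": (0.0, 0.0, -1.0), "P6": (0.0, 0.0, 1.0),
                   "P7": (0.0, 1.0, 2.0), "P8": (0.0, -1.0, -2.0)}


@dataclass(frozen=True)
class PatternTemplate:
    id: str
    levels: tuple[float, float, float]
    scenario: str
    direction: str

    def transitions(self) -> tuple[int, int]:
        """Sign of each transition: (normal->pre, pre->post)."""
        a, b, c = self.levels
        return (int(np.sign(b - a)), int(np.sign(c - b)))


def enumerate_transition_shapes() -> list[tuple[int, int]]:
    """All qualitative (normal->pre, pre->post) transition pairs, each of
    which is up (+1), down (-1) or unchanged (0), excluding the fully
    unchanged trajectory."""
    return [s for s in itertools.product((-1, 0, 1), repeat=2) if s != (0, 0)]


def theoretical_templates(
    levels: Mapping[str, Sequence[float]] | None = None,
) -> list[PatternTemplate]:
    """The eight theoretical trajectory templates.

    ``levels`` overrides the reference triples (the template amplitudes are a
    modeling choice — correlation argmax depends on them, so they are
    exposed); ids, scenarios and directions are fixed.
    """
    levels = dict(_DEFAULT_LEVELS) if levels is None else {**_DEFAULT_LEVELS, **{
        k: tuple(float(x) for x in v) for k, v in levels.items()}}
    out = []
    for pid in ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8"):
        lv = tuple(float(x) for x in levels[pid])
        if len(lv) != 3 or len(set(lv)) == 1:
            raise ValidationError(f"template {pid}: levels must be a non-constant triple")
        # direction = sign of the first non-zero transition
        t1, t2 = np.sign(lv[1] - lv[0]), np.sign(lv[2] - lv[1])
        direction = "up" if (t1 or t2) > 0 else "down"
        out.append(PatternTemplate(pid, lv, _SCENARIOS[pid], direction))
    return out


@dataclass
class PatternAssignment:
    gene: str
    patient: str
    pattern: str  # P1..P8 or UNCLASSIFIED
    correlation: float  # NaN when unclassified


def _zscore_rows(x: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Population z-score per row; returns (z, zero_variance_mask)."""
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = sd[:, 0] < tol
    sd = np.where(sd < tol, 1.0, sd)
    return (x - mean) / sd, flat


def assign_patterns(
    values: np.ndarray,
    templates: Sequence[PatternTemplate] | None = None,
    *,
    zero_var_tol: float = 1e-12,
    mode: str = "levels",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized maximal-correlation assignment for an (n, 3) array of
    triplet values.

    Returns ``(patterns, correlations)``: per row the winning template id (or
    UNCLASSIFIED for a zero-variance triplet, correlation NaN). Ties on the
    maximal correlation are broken by the smallest Euclidean distance between
    the z-scored triplet and template, then by lowest pattern index; for
    three-point vectors the z-distance is a monotone function of the
    correlation, so in practice the index rule decides.

    ``mode="differences"`` correlates the two transition changes
    (uncentered cosine similarity — two-point Pearson is degenerate) instead
    of the three levels.
    """
    templates = theoretical_templates() if templates is None else list(templates)
    vals = np.asarray(values, dtype=float)
    squeeze = vals.ndim == 1
    vals = np.atleast_2d(vals)
    if vals.shape[1] != 3:
        raise ValidationError(f"expected triplet values with 3 columns, got {vals.shape}")
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite triplet values")

    tmpl = np.array([t.levels for t in templates], dtype=float)
    if mode == "levels":
        zv, flat = _zscore_rows(vals, zero_var_tol)
        zt, _ = _zscore_rows(tmpl, 1e-300)
        # Pearson r of 3-vectors = normalized dot of population z-scores
        r = zv @ zt.T / 3.0
    elif mode == "differences":
        dv = np.diff(vals, axis=1)
        dt = np.diff(tmpl, axis=1)
        nv = np.linalg.norm(dv, axis=1, keepdims=True)
        flat = nv[:, 0] < zero_var_tol
        nv = np.where(nv < zero_var_tol, 1.0, nv)
        nt = np.linalg.norm(dt, axis=1, keepdims=True)
        r = (dv / nv) @ (dt / nt).T
    else:
        raise ValidationError(f"unknown assignment mode {mode!r}")

    # argmax with tie-break: z-score distance d^2 = 2n(1 - r) is monotone in
    # r, so among exact r-ties the lowest index wins — which argmax delivers.
    best = np.argmax(r, axis=1)
    patterns = np.array([templates[j].id for j in best], dtype=object)
    corr = r[np.arange(len(vals)), best]
    patterns[flat] = UNCLASSIFIED
    corr = np.where(flat, np.nan, corr)
    if squeeze:
        return patterns[0], float(corr[0])
    return patterns, corr


def assign_pattern(values: Sequence[float], templates=None, **kw) -> PatternAssignment:
    """Scalar convenience wrapper around :func:`assign_patterns`."""
    p, r = assign_patterns(np.asarray(values, dtype=float), templates, **kw)
    return PatternAssignment(gene="", patient="", pattern=str(p), correlation=r)


def assign_cohort(
    vst_values: pd.DataFrame,
    triplets: Sequence[Triplet],
    genes: Iterable[str] | None = None,
    templates: Sequence[PatternTemplate] | None = None,
    **kw,
) -> pd.DataFrame:
    """Assign every (gene, patient) triplet; long-format result table.

    Columns: gene, patient, pattern, correlation.
    """
    if genes is not None:
        vst_values = vst_values.loc[list(genes)]
    arr = triplet_value_array(vst_values, list(triplets))  # (G, P, 3)
    G, P, _ = arr.shape
    pats, corr = assign_patterns(arr.reshape(G * P, 3), templates, **kw)
    return pd.DataFrame({
        "gene": np.repeat(list(vst_values.index), P),
        "patient": np.tile([t.patient_id for t in triplets], G),
        "pattern": pats,
        "correlation": corr,
    })


# ---------------------------------------------------------------- gene-level


@dataclass
class GeneClassification:
    gene: str
    pattern_counts: dict[str, int]
    n_classified_patients: int
    klass: str  # main | bimodal | unclassified
    main_patterns: tuple[str, ...]  # (p,) for main, (p, q) for bimodal, () otherwise


def classify_gene(
    patterns: Sequence[str],
    *,
    gene: str = "",
    main_threshold: float = 0.5,
    bimodal_threshold: float = 0.3,
    min_patients: int = 5,
    strict_main: bool = False,
) -> GeneClassification:
    """Cross-patient recurrence class of one gene.

    ``main``: a single pattern in at least (strictly more than, if
    ``strict_main``) ``main_threshold`` of classified patients. ``bimodal``:
    two patterns, each in at least ``bimodal_threshold`` of classified
    patients and each observed in at least ``min_patients`` patients. The
    main rule takes precedence; otherwise the gene is unclassified.
    Denominators count patients with a non-UNCLASSIFIED assignment.
    """
    classified = [p for p in patterns if p != UNCLASSIFIED]
    if not classified:
        raise ValidationError(f"gene {gene!r}: no classified patients")
    counts = pd.Series(classified).value_counts()
    n = len(classified)
    shares = counts / n
    top = counts.index[0]
    is_main = shares.iloc[0] > main_threshold if strict_main else shares.iloc[0] >= main_threshold
    if is_main:
        return GeneClassification(gene, counts.to_dict(), n, "main", (str(top),))
    if len(counts) >= 2:
        p1, p2 = counts.index[:2]
        ok = (shares.iloc[0] >= bimodal_threshold and shares.iloc[1] >= bimodal_threshold
              and counts.iloc[0] >= min_patients and counts.iloc[1] >= min_patients)
        if ok:
            pair = tuple(sorted((str(p1), str(p2))))
            return GeneClassification(gene, counts.to_dict(), n, "bimodal", pair)
    return GeneClassification(gene, counts.to_dict(), n, "unclassified", ())


def classify_genes(assignments: pd.DataFrame, **kw) -> pd.DataFrame:
    """Apply :func:`classify_gene` to every gene in an assignment table.

    Returns a table indexed by gene with columns klass, main_patterns,
    n_classified_patients, plus one count column per pattern.
    """
    rows = []
    for gene, sub in assignments.groupby("gene", sort=True):
        pats = [p for p in sub["pattern"] if p != UNCLASSIFIED]
        if not pats:
            rows.append({"gene": gene, "klass": "unclassified", "main_patterns": "",
                         "n_classified_patients": 0})
            continue
        gc = classify_gene(pats, gene=str(gene), **kw)
        row = {"gene": gene, "klass": gc.klass,
               "main_patterns": "+".join(gc.main_patterns),
               "n_classified_patients": gc.n_classified_patients}
        row.update({f"n_{p}": c for p, c in gc.pattern_counts.items()})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene")
    for p in _DEFAULT_LEVELS:
        col = f"n_{p}"
        if col not in df.columns:
            df[col] = 0
    count_cols = [f"n_{p}" for p in _DEFAULT_LEVELS]
    df[count_cols] = df[count_cols].fillna(0).astype(int)
    return df


# ---------------------------------------------------------------- per-patient


@dataclass
class PatientPatternFractions:
    patient: str
    fractions: dict[str, float]  # P1..P8 over classified genes
    ratio: float  # (f(P1)+f(P2)) / (f(P7)+f(P8)); inf when denominator is 0
    ratio_is_infinite: bool = field(default=False)


def pattern_fractions(assignments: pd.DataFrame, patient: str) -> PatientPatternFractions:
    """Fraction of the patient's classified genes in each pattern, and the
    reregulated-to-dysregulated ratio (P1+P2)/(P7+P8).

    The denominator is the patient's classified (non-UNCLASSIFIED) DE genes.
    A zero P7+P8 fraction yields an infinite ratio, flagged explicitly.
    """
    sub = assignments.loc[(assignments["patient"] == patient)
                          & (assignments["pattern"] != UNCLASSIFIED), "pattern"]
    if len(sub) == 0:
        raise ValidationError(f"patient {patient!r}: no classified genes")
    counts = sub.value_counts()
    n = len(sub)
    fractions = {p: float(counts.get(p, 0)) / n for p in _DEFAULT_LEVELS}
    num = fractions["P1"] + fractions["P2"]
    den = fractions["P7"] + fractions["P8"]
    if den == 0:
        return PatientPatternFractions(patient, fractions, float("inf"), True)
    return PatientPatternFractions(patient, fractions, num / den, False)


def cohort_pattern_fractions(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-patient pattern fractions and ratio, one row per patient."""
    rows = []
    for patient in sorted(assignments["patient"].unique()):
        pf = pattern_fractions(assignments, patient)
        row = {"patient": patient, **pf.fractions,
               "ratio": pf.ratio, "ratio_is_infinite": pf.ratio_is_infinite}
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient")
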