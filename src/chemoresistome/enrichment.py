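"""Pathway over-representation and the per-patient resistance score.

Enrichment of response-associated genes is an upper-tail hypergeometric test
per pathway, run separately for each direction cluster (up: P1/P3/P7, down:
P2/P4/P8) over a configurable universe (default: all DE genes intersected
with the collection's gene space), with BH q-values within a run.

The resistance score of a patient in a pathway is the fraction of
"resistance genes" (patterns P3/P4/P7/P8) among the pathway's considered
genes — DE genes with an assigned pattern in that patient. Its null is the
score of a random gene set of the same considered size drawn from the
patient's considered-gene universe; the bootstrap p-value is the fraction of
random scores greater than or equal to the observed one (no pseudocount, so
p can be 0 at resolution 1/n_boot). Drawing a set uniformly without
replacement makes the number of resistance genes hypergeometric, so the null
is sampled directly from that count distribution — distributionally
identical to materializing the sets, and far cheaper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .data import GeneSetCollection
from .errors import ValidationError
from .normalize import benjamini_hochberg
from .patterns import RESISTANCE_PATTERNS, UNCLASSIFIED

log = logging.getLogger(__name__)

#: pattern families defining the enrichment clusters
CLUSTER_FAMILIES = {"P1_P3_P7": ("P1", "P3", "P7"), "P2_P4_P8": ("P2", "P4", "P8")}


# ---------------------------------------------------------------- enrichment

def hypergeom_enrich(
    hit_genes: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    cluster_label: str = "",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per pathway.

    Pathway membership is intersected with the universe; the p-value is
    P(overlap >= observed) for a random hit list of the same size, BH
    q-values across the pathways of this run.
    """
    hits = set(hit_genes)
    uni = set(universe)
    if not hits <= uni:
        raise ValidationError(f"{len(hits - uni)} hit genes outside the universe")
    M, n_hits = len(uni), len(hits)
    rows = []
    for name, members in collection.intersect_universe(uni).items():
        K = len(members)
        k = len(set(members) & hits)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, n_hits, K))
        rows.append({"pathway": name, "source": collection[name].description,
                     "pattern_cluster": cluster_label, "overlap": k,
                     "pathway_size": K, "universe_size": M,
                     "n_hits": n_hits, "p_value": p})
    df = pd.DataFrame(rows, columns=["pathway", "source", "pattern_cluster",
                                     "overlap", "pathway_size", "universe_size",
                                     "n_hits", "p_value"])
    if len(df):
        df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
        df["significant"] = df["q_value"] < q_threshold
    else:
        df["q_value"] = []
        df["significant"] = []
    return df.sort_values(["q_value", "p_value", "pathway"]).reset_index(drop=True)


def robust_pathway_list(
    enrich_all: pd.DataFrame,
    enrich_subset: pd.DataFrame,
    k_top: int = 5,
) -> list[str]:
    """Pathways robust to subtype composition.

    Intersection of the significant pathways from the full-cohort run and the
    subtype-restricted run, plus the ``k_top`` most significant (by q, ties
    by p) significant pathways unique to each run; duplicates collapsed.
    """
    def sig(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["significant"]] if len(df) else df

    sa, sb = sig(enrich_all), sig(enrich_subset)
    set_a, set_b = set(sa["pathway"]), set(sb["pathway"])
    shared = set_a & set_b
    out = set(shared)
    for df, other in ((sa, set_b), (sb, set_a)):
        uniq = df[~df["pathway"].isin(other)]
        uniq = uniq.sort_values(["q_value", "p_value", "pathway"]).head(k_top)
        out |= set(uniq["pathway"])
    return sorted(out)


# ---------------------------------------------------------------- scores

@dataclass
class ResistanceScore:
    patient: str
    pathway: str
    n_considered: int
    n_resistance: int
    score: float | None  # None when no gene is considered
    p_boot: float | None = None
    n_boot: int | None = None


def resistance_score(
    patient: str,
    pathway: str,
    pathway_genes: Iterable[str],
    patient_patterns: Mapping[str, str],
    de_genes: Iterable[str],
) -> ResistanceScore:
    """Fraction of resistance-pattern genes among the pathway's considered
    genes for one patient.

    Considered genes = pathway members that are differentially expressed and
    carry an assigned (non-UNCLASSIFIED) pattern in this patient. An empty
    considered set yields an undefined score (``n_considered = 0``, no
    p-value attached downstream).
    """
    de = set(de_genes)
    considered = [g for g in pathway_genes
                  if g in de and patient_patterns.get(g, UNCLASSIFIED) != UNCLASSIFIED]
    if not considered:
        return ResistanceScore(patient, pathway, 0, 0, None)
    n_res = sum(patient_patterns[g] in RESISTANCE_PATTERNS for g in considered)
    return ResistanceScore(patient, pathway, len(considered), n_res,
                           n_res / len(considered))


def bootstrap_pvalue(
    observed_score: float,
    pathway_size: int,
    universe_is_resistance: Sequence[bool],
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
    replace: bool = False,
) -> float:
    """Bootstrap p-value of an observed resistance score.

    Random gene sets of ``pathway_size`` are drawn from the patient's
    considered-gene universe (``universe_is_resistance`` flags each universe
    gene); p = #(random score >= observed) / n_boot. Without replacement
    (default) the resistance count of a random set is hypergeometric; with
    replacement it is binomial — the null is sampled from that count
    distribution. Reproducible for a fixed seed/generator.
    """
    flags = np.asarray(universe_is_resistance, dtype=bool)
    U, R = len(flags), int(flags.sum())
    if pathway_size > U:
        raise ValidationError(f"pathway considered size {pathway_size} exceeds "
                              f"patient universe {U}")
    if pathway_size <= 0:
        raise ValidationError("pathway considered size must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if replace:
        draws = rng.binomial(pathway_size, R / U if U else 0.0, size=n_boot)
    else:
        draws = rng.hypergeometric(R, U - R, pathway_size, size=n_boot)
    random_scores = draws / pathway_size
    return float(np.mean(random_scores >= observed_score - 1e-12))


def exact_bootstrap_tail(observed_score: float, pathway_size: int,
                         universe_size: int, n_resistance_universe: int) -> float:
    """Exact P(random score >= observed) under without-replacement draws
    (hypergeometric tail); the limit of :func:`bootstrap_pvalue` as n_boot
    grows."""
    k_min = int(np.ceil(observed_score * pathway_size - 1e-12))
    return float(scipy.stats.hypergeom.sf(
        k_min - 1, universe_size, n_resistance_universe, pathway_size))


def compute_resistance_scores(
    assignments: pd.DataFrame,
    de_genes: Iterable[str],
    collection: GeneSetCollection,
    pathways: Sequence[str] | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    replace: bool = False,
) -> pd.DataFrame:
    """Resistance scores with bootstrap p-values for every (patient, pathway).

    Long-format table: patient, pathway, n_considered, n_resistance, score,
    p_boot, n_boot. Iteration order (sorted patients, then the requested
    pathway order) is fixed, so a fixed seed reproduces every p-value.
    """
    de = sorted(set(de_genes))
    names = list(pathways) if pathways is not None else collection.names()
    rng = np.random.default_rng(seed)
    rows = []
    for patient in sorted(assignments["patient"].unique()):
        sub = assignments[(assignments["patient"] == patient)
                          & (assignments["pattern"] != UNCLASSIFIED)]
        patterns = dict(zip(sub["gene"], sub["pattern"]))
        universe = [g for g in de if g in patterns]
        flags = np.array([patterns[g] in RESISTANCE_PATTERNS for g in universe])
        for name in names:
            rs = resistance_score(patient, name, collection[name].genes, patterns, de)
            if rs.n_considered == 0:
                rows.append(rs.__dict__)
                continue
            rs.p_boot = bootstrap_pvalue(rs.score, rs.n_considered, flags,
                                         n_boot=n_boot, rng=rng, replace=replace)
            rs.n_boot = n_boot
            rows.append(rs.__dict__)
    return pd.DataFrame(rows)
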