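"""Linking trajectory patterns to clinical response.

Two routes define resistance-associated genes: (1) persistent genes, whose
dysregulated pattern (P3, P3+P7, P4, or P4+P8) recurs in more than half of
patients; (2) bimodal genes, where the same gene is reregulated in some
patients and dysregulated in others — for those, the Miller–Payne grades of
the "good response" patients (pattern P1 or P2) are compared with the grades
of the "poor response" patients (P3/P7 or P4/P8) by a two-sided Wilcoxon
rank-sum test, run separately per direction cluster (P1 vs P3/P7 and P2 vs
P4/P8). MP grades are small-sample ordinal data with heavy ties, so the test
uses exact permutation enumeration (midranks) up to a combined n of 20 and a
tie-corrected normal approximation beyond.

Cohort-level statistics: one-way ANOVA of the reregulated-to-dysregulated
ratio (P1+P2)/(P7+P8) across MP groups, and Kaplan–Meier / log-rank on
recurrence-free survival stratified by that ratio at a cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .data import PatientTable
from .errors import ValidationError
from .normalize import benjamini_hochberg
from .patterns import UNCLASSIFIED

log = logging.getLogger(__name__)

#: good-response vs poor-response pattern groups per direction cluster
CLUSTERS = {"up": ("P1", ("P3", "P7")), "down": ("P2", ("P4", "P8"))}

EXACT_N_MAX = 20


# ---------------------------------------------------------------- rank-sum

def rank_sum_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Wilcoxon rank-sum W: sum of the midranks of ``x`` in the pooled sample."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = scipy.stats.rankdata(pooled)
    return float(ranks[: len(x)].sum())


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  method: str = "auto") -> tuple[float, float]:
    """Two-sided rank-sum p-value; returns (W, p).

    ``method="exact"`` enumerates all C(n, nx) group labelings of the pooled
    midranks (valid under ties); ``"approx"`` uses the tie-corrected normal
    approximation; ``"auto"`` picks exact when the combined n <= 20. The
    two-sided exact p is ``min(1, 2*min(P(W<=w), P(W>=w)))``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank_sum_test: both groups must be non-empty")
    n = len(x) + len(y)
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "approx"
    w = rank_sum_statistic(x, y)
    if method == "exact":
        pooled = np.concatenate([x, y])
        ranks = scipy.stats.rankdata(pooled)
        combos = np.fromiter(
            (i for c in combinations(range(n), len(x)) for i in c), dtype=np.intp
        ).reshape(-1, len(x))
        ws = ranks[combos].sum(axis=1)
        eps = 1e-9
        p_le = np.mean(ws <= w + eps)
        p_ge = np.mean(ws >= w - eps)
        return w, float(min(1.0, 2.0 * min(p_le, p_ge)))
    if method == "approx":
        nx, ny = len(x), len(y)
        mean = nx * (n + 1) / 2.0
        pooled = np.concatenate([x, y])
        _, t = np.unique(pooled, return_counts=True)
        tie_term = ((t ** 3 - t).sum()) / (n * (n - 1)) if n > 1 else 0.0
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return w, 1.0
        # continuity correction toward the mean, as is standard practice
        z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
        return w, float(min(1.0, 2.0 * scipy.stats.norm.sf(abs(z))))
    raise ValidationError(f"unknown rank-sum method {method!r}")


# ---------------------------------------------------------------- gene tests

@dataclass
class ResponseAssociation:
    gene: str
    cluster: str  # up (P1 vs P3/P7) | down (P2 vs P4/P8)
    good_group_mp: list[int]
    poor_group_mp: list[int]
    statistic: float
    p_value: float


def wilcoxon_response(
    gene: str,
    assignments: pd.DataFrame,
    patient_mp: Mapping[str, int],
    cluster: str,
    method: str = "auto",
) -> ResponseAssociation | None:
    """Compare MP grades of good- vs poor-response patients for one gene.

    Patients whose pattern for this gene is outside the cluster (including
    the treatment-effect patterns P5/P6 and UNCLASSIFIED) are dropped from
    the test. Returns None (with a logged reason) when either group is empty.
    """
    if cluster not in CLUSTERS:
        raise ValidationError(f"unknown cluster {cluster!r}")
    good_pat, poor_pats = CLUSTERS[cluster]
    sub = assignments[assignments["gene"] == gene]
    good = [patient_mp[p] for p, pat in zip(sub["patient"], sub["pattern"])
            if pat == good_pat and p in patient_mp]
    poor = [patient_mp[p] for p, pat in zip(sub["patient"], sub["pattern"])
            if pat in poor_pats and p in patient_mp]
    if not good or not poor:
        log.debug("wilcoxon_response: gene %s cluster %s skipped (empty group)", gene, cluster)
        return None
    w, p = rank_sum_test(good, poor, method=method)
    return ResponseAssociation(gene, cluster, good, poor, w, p)


def response_gene_tests(
    genes: Sequence[str],
    assignments: pd.DataFrame,
    patient_mp: Mapping[str, int],
    alpha: float = 0.05,
    method: str = "auto",
) -> pd.DataFrame:
    """Run both direction clusters for each gene; long-format result table.

    Raw p-values are used for the significance call at ``alpha`` (BH-adjusted
    values are emitted alongside for transparency, not used for selection).
    """
    rows = []
    sub_all = assignments[assignments["gene"].isin(set(genes))]
    by_gene = dict(tuple(sub_all.groupby("gene")))
    for gene in genes:
        sub = by_gene.get(gene)
        if sub is None:
            continue
        for cluster in CLUSTERS:
            ra = wilcoxon_response(gene, sub, patient_mp, cluster, method=method)
            if ra is None:
                continue
            rows.append({
                "gene": gene, "cluster": cluster,
                "n_good": len(ra.good_group_mp), "n_poor": len(ra.poor_group_mp),
                "statistic": ra.statistic, "p_value": ra.p_value,
            })
    df = pd.DataFrame(rows, columns=["gene", "cluster", "n_good", "n_poor",
                                     "statistic", "p_value"])
    if len(df):
        df["adjusted_p"] = benjamini_hochberg(df["p_value"].to_numpy())
        df["significant"] = df["p_value"] < alpha
    else:
        df["adjusted_p"] = []
        df["significant"] = []
    return df


# ---------------------------------------------------------------- gene lists

def persistent_resistance_genes(classifications: pd.DataFrame,
                                threshold: float = 0.5) -> list[str]:
    """Genes whose dysregulated pattern persists across most patients.

    A gene qualifies when the classified-patient share of P3 alone, P3+P7
    combined, P4 alone, or P4+P8 combined strictly exceeds ``threshold``.
    Expects the table produced by :func:`chemoresistome.patterns.classify_genes`.
    """
    n = classifications["n_classified_patients"].to_numpy(dtype=float)
    out = []
    with np.errstate(invalid="ignore", divide="ignore"):
        s3 = classifications["n_P3"].to_numpy() / n
        s4 = classifications["n_P4"].to_numpy() / n
        s7 = classifications["n_P7"].to_numpy() / n
        s8 = classifications["n_P8"].to_numpy() / n
    qual = (s3 > threshold) | (s3 + s7 > threshold) | (s4 > threshold) | (s4 + s8 > threshold)
    qual &= n > 0
    return [g for g, q in zip(classifications.index, qual) if q]


@dataclass
class ResistanceGeneList:
    persistent_genes: list[str]
    bimodal_significant_genes: list[str]
    combined: list[str]


def resistance_gene_list(persistent: Sequence[str],
                         bimodal_significant: Sequence[str]) -> ResistanceGeneList:
    combined = sorted(set(persistent) | set(bimodal_significant))
    return ResistanceGeneList(sorted(set(persistent)),
                              sorted(set(bimodal_significant)), combined)


# ---------------------------------------------------------------- ratio stats

@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    group_sizes: dict[str, int]


def ratio_anova(
    ratios: Mapping[str, float],
    patient_mp: Mapping[str, int],
    groups: Sequence[Sequence[int]] = ((1,), (2,), (3, 4, 5)),
    infinite: str = "exclude",
) -> AnovaResult:
    """One-way ANOVA of the (P1+P2)/(P7+P8) ratio across MP-grade groups.

    ``groups`` partitions MP grades; the default three groups follow the
    low/mid/high grouping of the ratio-vs-response comparison. Infinite
    ratios (zero dysregulated fraction) are excluded by default
    (``infinite="cap"`` instead caps them at twice the largest finite ratio).
    """
    buckets: dict[str, list[float]] = {}
    finite_vals = [v for v in ratios.values() if np.isfinite(v)]
    cap = 2.0 * max(finite_vals) if finite_vals else 1.0
    for pid, r in ratios.items():
        if pid not in patient_mp:
            continue
        if not np.isfinite(r):
            if infinite == "exclude":
                log.info("ratio_anova: excluding patient %s (infinite ratio)", pid)
                continue
            r = cap
        mp = patient_mp[pid]
        for gi, grades in enumerate(groups):
            if mp in grades:
                label = "-".join(map(str, grades))
                buckets.setdefault(label, []).append(float(r))
                break
    sizes = {k: len(v) for k, v in buckets.items()}
    if len(buckets) < 2 or any(len(v) < 2 for v in buckets.values()):
        raise ValidationError(f"degenerate MP grouping for ANOVA: sizes {sizes}")
    arrays = [np.asarray(v) for v in buckets.values()]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all ratios identical: no variance anywhere
        return AnovaResult(0.0, 1.0, sizes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = scipy.stats.f_oneway(*arrays)
    if not np.isfinite(f):  # zero within-group variance, nonzero between
        f, p = float("inf"), 0.0
    return AnovaResult(float(f), float(p), sizes)


@dataclass
class KMResult:
    statistic: float
    p_value: float
    strata_sizes: dict[str, int]
    curves: dict[str, pd.DataFrame]  # stratum -> KM survival table


def km_logrank(patients: PatientTable, ratios: Mapping[str, float],
               cutoff: float = 5.0) -> KMResult:
    """Kaplan–Meier + two-group log-rank for ratio > cutoff vs <= cutoff.

    Infinite ratios fall in the high stratum. Requires recurrence-free
    survival columns and at least one event overall.
    """
    df = patients.df
    for col in ("rfs_years", "recurrence_event"):
        if col not in df.columns or df[col].isna().all():
            raise ValidationError(f"km_logrank requires column {col!r}")
    pid = df["patient_id"].astype(str)
    keep = pid.isin(ratios.keys()) & df["rfs_years"].notna() & df["recurrence_event"].notna()
    sub = df[keep]
    r = np.array([ratios[p] for p in sub["patient_id"].astype(str)])
    high = r > cutoff
    times = sub["rfs_years"].to_numpy(dtype=float)
    events = sub["recurrence_event"].astype(bool).to_numpy()
    if high.all() or (~high).all():
        raise ValidationError(f"km_logrank: a stratum is empty at cutoff {cutoff}")
    if not events.any():
        raise ValidationError("km_logrank: no recurrence events; log-rank undefined")
    res = logrank_test(times[high], times[~high], events[high], events[~high])
    curves = {}
    for label, mask in ((f"ratio>{cutoff}", high), (f"ratio<={cutoff}", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=label)
        curves[label] = kmf.survival_function_
    return KMResult(float(res.test_statistic), float(res.p_value),
                    {f"ratio>{cutoff}": int(high.sum()), f"ratio<={cutoff}": int((~high).sum())},
                    curves)
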