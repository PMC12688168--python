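"""Size-factor normalization, variance stabilization, and the DE gene filter.

The normalization is the median-of-ratios estimator (each sample's factor is
the median, over genes with all-positive counts, of its count divided by the
gene's geometric mean across samples). The variance-stabilizing transform is
a shifted log on the normalized scale, ``log2(count/factor + pseudocount)``
— a documented stand-in for a dispersion-trend VST that keeps the
pipeline dependency-free while preserving the log2-like scale the pattern
templates assume.

Differential expression is tested per contrast (post vs normal, pre vs
normal, post vs pre) by pairing within patient on the transformed values —
pairing absorbs the patient effect the way a patient covariate would in a
count-model fit. P-values are Benjamini–Hochberg adjusted per contrast, and a
gene is retained when, in ANY contrast, the absolute fold change exceeds 2
(strict), the adjusted p-value is at most 0.05, and the gene reaches a raw
count of at least 100 in at least one sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .data import CountMatrix, Triplet, triplet_value_array
from .errors import ValidationError

log = logging.getLogger(__name__)

CONTRASTS = {
    "post_vs_normal": (2, 0),
    "pre_vs_normal": (1, 0),
    "post_vs_pre": (2, 1),
}


@dataclass
class VstMatrix:
    """Variance-stabilized expression on a log2-like scale."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample scale factors.

    Falls back to total-count ratios (normalized to geometric mean 1) with a
    logged warning when no gene has all-positive counts.
    """
    c = counts.counts
    allpos = (c > 0).all(axis=1)
    if allpos.sum() == 0:
        log.warning("size_factors: no gene with all-positive counts; "
                    "falling back to total-count ratios")
        totals = c.sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise ValidationError("cannot estimate size factors: a sample has zero total count")
        return totals / np.exp(np.mean(np.log(totals)))
    sub = c[allpos].astype(float)
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    return np.exp(np.median(ratios, axis=0))


def vst_transform(counts: CountMatrix, factors: np.ndarray | None = None,
                  pseudocount: float = 1.0) -> VstMatrix:
    """Shifted-log transform of size-factor-normalized counts.

    ``value = log2(count / factor + pseudocount)``; monotone in counts within
    a sample, and a zero count maps to ``log2(pseudocount)`` (0 by default).
    """
    if factors is None:
        factors = size_factors(counts)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (len(counts.samples),) or (factors <= 0).any():
        raise ValidationError("factors must be positive, one per sample")
    values = np.log2(counts.counts / factors[None, :] + pseudocount)
    return VstMatrix(list(counts.genes), list(counts.samples), values)


@dataclass
class DEFilterResult:
    retained: list[str]
    table: pd.DataFrame  # gene, contrast, log2_fold_change, p_value, adjusted_p, max_count, retained_in_contrast


def de_filter(
    vst: VstMatrix,
    counts: CountMatrix,
    triplets: Sequence[Triplet],
    *,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    min_count: int = 100,
    paired_test: str = "ttest",
) -> DEFilterResult:
    """The differential-expression gene filter defining the pattern universe.

    Per contrast, a paired test across patients on the within-triplet VST
    differences (one-sample t-test on the differences by default;
    ``paired_test="wilcoxon"`` switches to the signed-rank test), BH
    adjustment per contrast. The fold change is derived from the mean VST
    difference (``2**|mean diff|``) and the threshold is strict (> 2 means
    exactly 2.0 fails). The count gate uses the raw counts over all samples.
    """
    triplets = list(triplets)
    if len(triplets) < 2:
        raise ValidationError("de_filter needs at least 2 complete triplets")
    if paired_test not in ("ttest", "wilcoxon"):
        raise ValidationError(f"unknown paired test {paired_test!r}")
    vdf = vst.to_frame()
    arr = triplet_value_array(vdf, triplets)  # (G, P, 3)
    max_count = counts.to_frame().loc[vst.genes].to_numpy().max(axis=1)

    frames = []
    retained_any = np.zeros(len(vst.genes), dtype=bool)
    for contrast, (ia, ib) in CONTRASTS.items():
        diffs = arr[:, :, ia] - arr[:, :, ib]  # (G, P)
        lfc = diffs.mean(axis=1)
        if paired_test == "ttest":
            with np.errstate(divide="ignore", invalid="ignore"):
                _, p = scipy.stats.ttest_1samp(diffs, 0.0, axis=1)
        else:
            p = np.array([
                scipy.stats.wilcoxon(d).pvalue if np.any(d != 0) else 1.0
                for d in diffs
            ])
        p = np.where(np.isfinite(p), p, 1.0)  # zero-variance differences: no evidence
        q = multipletests(p, method="fdr_bh")[1]
        keep = (np.power(2.0, np.abs(lfc)) > fc_threshold) & (q <= alpha) & (max_count >= min_count)
        retained_any |= keep
        frames.append(pd.DataFrame({
            "gene": vst.genes, "contrast": contrast, "log2_fold_change": lfc,
            "p_value": p, "adjusted_p": q, "max_count": max_count,
            "retained_in_contrast": keep,
        }))
    table = pd.concat(frames, ignore_index=True)
    retained = [g for g, k in zip(vst.genes, retained_any) if k]
    log.info("de_filter: retained %d / %d genes", len(retained), len(vst.genes))
    return DEFilterResult(retained, table)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (thin wrapper kept for a stable public surface)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
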