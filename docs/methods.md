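# Methods

This note documents the models and procedures the package implements, the
defaults that matter, the design choices made where the design was open,
and what the synthetic-data tests do and do not demonstrate.

## Data model

A cohort is a gene × sample matrix of raw RNA-seq counts plus a sample
table (sample → patient, timepoint ∈ {normal, pre, post}, optional tumor
cellularity) and a patient table (Miller–Payne grade 1–5, optional RCB
class, subtype, regimen, recurrence-free survival). Only patients with a
complete matched triplet enter the pattern analysis; incomplete patients
are reported, not dropped silently, so the enrollment-to-analysis funnel is
always reconstructible from the logs and the triplet side report. Gene
identifiers are opaque strings; no identifier mapping is attempted, because
mapping is dataset-specific. Gene-set genes absent from the expression
matrix are intersected out at use time.

## Normalization and the DE filter

Size factors are the median-of-ratios estimator: for each sample, the
median over all-positive genes of its count divided by the gene's geometric
mean across samples. When no gene is positive everywhere the estimator
falls back to total-count ratios with a logged warning.

The variance-stabilizing transform is a shifted log on the normalized
scale, `log2(count/factor + 1)`. This is a deliberate, documented stand-in
for a dispersion-trend VST: it preserves the log2-like scale the pattern
templates assume, is monotone per sample, and keeps zeros finite. It does
not reproduce a fitted mean–dispersion trend; on negative-binomial data it
nevertheless flattens the SD-vs-mean relationship by two orders of
magnitude relative to raw counts (checked in the test suite).

Differential expression per contrast (post vs normal, pre vs normal, post
vs pre) is a paired test across patients on the within-triplet VST
differences — a one-sample t-test on the differences by default, with a
Wilcoxon signed-rank option. Pairing within patient absorbs the patient
effect the way a patient covariate would in a count-model fit; this keeps
the stage dependency-free and transparent. No fold-change shrinkage,
outlier trimming, or independent filtering is applied. P-values are
BH-adjusted per contrast. A gene is retained when, in any contrast, the
fold change derived from the mean VST difference satisfies `2**|Δ| > 2`
(strictly), the adjusted p is ≤ 0.05, and the gene reaches a raw count of
≥ 100 in at least one sample. The fold-change threshold is strict and the
p threshold inclusive by design; both are exposed (`--fc-threshold`,
`--alpha`, `--min-count`).

## Trajectory templates and assignment

The eight templates enumerate the qualitative shapes of a three-point
trajectory: each of the two transitions is up, down, or unchanged, and the
fully unchanged trajectory is excluded (3 × 3 − 1 = 8). The default level
triples are unit steps — P1 (0,1,0), P2 (0,−1,0), P3 (0,1,1), P4 (0,−1,−1),
P5 (0,0,−1), P6 (0,0,1), P7 (0,1,2), P8 (0,−1,−2) — encoding the verbal
shape descriptions with equal step sizes. The amplitudes are exposed in
configuration because the correlation argmax depends on them; the taxonomy
(ids, scenarios, directions) is fixed.

Assignment maximizes the Pearson correlation of the VST triplet with each
template. Pearson correlation of 3-vectors is scale- and shift-invariant,
so only shape matters; negating a trajectory maps each pattern to its
negation partner (P1↔P2, P3↔P4, P5↔P6, P7↔P8). A triplet with standard
deviation below 1e-12 is UNCLASSIFIED. Ties on the maximal correlation are
broken by the smaller Euclidean distance between z-scored triplet and
template, then by lowest pattern index; for 3-vectors the z-distance is
`d² = 2n(1−r)`, a monotone function of r, so among exact correlation ties
the index rule is what decides — the tie-break is nevertheless implemented
as stated so the contract is explicit. An alternative "differences" mode
correlates the two transition changes instead of the three levels; because
two-point Pearson is degenerate (always ±1), this mode uses the uncentered
cosine of the change vector. The level-based mode is the default and is the
one used everywhere downstream.

Gene-level recurrence: a gene is *main* if a single pattern covers at least
50% of its classified patients (a strict-inequality flag exists because
"at least half" and "more than half" are both defensible readings of the
recurrence idea; ≥ is the default), *bimodal* if two patterns each cover
≥ 30% of classified patients and each occur in ≥ 5 patients. Main takes
precedence; denominators count non-UNCLASSIFIED patients only.

Per-patient fractions use the patient's classified DE genes as the
denominator (UNCLASSIFIED excluded — the choice is logged). The response
ratio is (f(P1)+f(P2)) / (f(P7)+f(P8)); a zero denominator yields an
explicit +inf with a flag. Infinite ratios are excluded from the ANOVA by
default (the statistic is undefined on the real line; a capping option
exists) but participate in Kaplan–Meier stratification, where they simply
fall in the high stratum.

## Response association

Persistent resistance genes: patient share of P3, P3+P7, P4, or P4+P8
strictly above 50%. Bimodal genes are tested by a two-sided Wilcoxon
rank-sum comparison of MP grades between the good-response group (pattern
P1, or P2 in the down cluster) and the poor-response group (P3/P7, or
P4/P8), run separately per direction cluster; patients whose pattern for
the gene is P5/P6 or UNCLASSIFIED are outside both groups and are dropped
from that gene's test. MP grades are heavily tied small-sample ordinals, so
the test enumerates all label assignments of the pooled midranks exactly up
to a combined n of 20 (the exact null is valid under ties) and uses the
tie-corrected normal approximation with continuity correction beyond. The
two-sided exact p is `min(1, 2·min(P(W≤w), P(W≥w)))`. Significance is
called on the raw p at 0.05 — BH-adjusted values are emitted alongside for
transparency but deliberately not used for selection, keeping the gene
list's operating characteristics simple and auditable. A subtype-restricted
rerun (default HR+) is built in, and the intersection behavior feeds the
robust pathway list below.

MP grouping for the ratio ANOVA defaults to {1}, {2}, {3–5} (low, mid,
high response) and is configurable; the grouping is logged because any
3-way split of a 5-grade ordinal is a modeling choice. The ANOVA handles
the degenerate cases explicitly: zero total variance → F = 0, p = 1; zero
within-group variance with nonzero separation → F = ∞, p = 0. With two
groups it reduces exactly to the squared two-sample t-test.

## Enrichment, robust pathway list, resistance score

Over-representation is the upper-tail hypergeometric test per pathway,
with BH q-values within each run; runs are per direction cluster
(P1/P3/P7 and P2/P4/P8). The default hit list is the Wilcoxon-significant
bimodal genes of the cluster; `enrichment_hits="combined"` additionally
includes persistent genes whose main pattern belongs to the cluster. The
universe is the DE genes intersected with the collection's gene space
(configurable — the natural alternative, all measured genes, is exposed by
passing a different universe). The robust list intersects the significant
pathways of the full-cohort and subtype-restricted runs and adds the top
five most significant pathways unique to each run (by q, ties by p).
A final curation step for significance and functional redundancy is a
judgement call and is deliberately not automated; a user-supplied curated
subset and a pathway → functional-module mapping file are accepted by the
reporting layer instead.

The resistance score of patient i in pathway P is
`score = n_resistance / n_considered`, where considered genes are pathway
members that are DE and pattern-assigned in that patient, and resistance
genes are those with P3/P4/P7/P8. Its null: random gene sets of the same
considered size drawn from the patient's considered-gene universe, with
`p = #(random score ≥ observed) / n_boot` at n_boot = 10 000, no
pseudocount (p = 0 is possible and is rendered as "< 1/n_boot"). Drawing a
set uniformly without replacement makes its resistance count exactly
hypergeometric, so the implementation samples the count distribution
directly (binomial for the with-replacement option) — distributionally
identical to materializing index sets and orders of magnitude faster. The
p-value is conservative and lattice-valued at small considered sizes
(achievable values are multiples of the count pmf); calibration is
therefore demonstrated where the lattice is fine (several hundred
considered genes, the size of large GO/Reactome sets), and small-pathway
p-values should be read as conservative.

## Pathway deregulation score

Per pathway: genes standardized by the normal samples' mean and SD (overall
SD as fallback for genes constant in normals), samples reduced by PCA to
the components explaining ≥ 90% of variance (capped at 5; both invented
defaults, exposed), and a principal curve fitted through all samples by
Hastie–Stuetzle iteration — initialize at the first principal component,
then alternate lowess smoothing of each coordinate against arc length
(span 0.6) with reprojection onto the polyline, until the mean squared
projection distance changes by < 1e-6 or 100 iterations. Each sample's
summary is its arc-length coordinate λ.

The PDS is the arc-length distance beyond the normals' typical position:
`pds_raw = max(0, |λ − median λ(normals)| − median_normals |λ − median λ(normals)|)`,
normalized per pathway by its maximum. Subtracting the normals' median
distance before flooring at zero is what makes "the median PDS of normal
samples is 0" hold exactly rather than approximately; without it, the
median absolute deviation of the normals would leak into every score. Arc
length along the curve (not Euclidean distance to the normal projections)
is used as the deviation coordinate. This is a simplified principal-curve
deregulation score: it omits the gene-filtering and curve-stability
heuristics of the full published algorithm, and is labeled as simplified in
its outputs.

## Synthetic cohorts

The generator emulates the study design: n patients (default 24), three
samples each, negative-binomial counts with `var = μ + φμ²` (φ = 0.05
default; φ = 0 gives Poisson) around pattern-defined log2 means. Each gene
has a baseline log2 mean drawn uniformly from (7, 11) — high enough that
the count gate of the DE filter does not interact with the planted signal —
and its planted template shifts the per-timepoint mean by `effect_size`
(default 2) log2 units per template level. Per-sample library factors are
log-uniform on (0.5, 2), exercising the normalization stage nontrivially.

Half of the genes are planted FLAT (no change) so the DE filter has true
negatives; FLAT is not one of the eight templates. Pattern proportions are
configurable and sum to 1. Patient heterogeneity: each patient has a
resistance propensity drawn from (0.15, 0.75), the probability that a
reregulated-primary gene (P1/P2) appears as its persistent partner (P3/P4)
in that patient — this is what creates bimodal genes whose group split
correlates with response. The MP grade is produced by ranking a latent
score `−mp_coupling · z(dysregulated fraction) + noise` into grades
(truncated to 1–4 by default, matching the observed range of such cohorts);
`mp_coupling = 0` decouples response from expression entirely, which is the
null configuration used for calibration tests. Recurrence-free survival is
exponential with an MP-dependent scale and administrative censoring.
Pathways are uniform random gene sets except the designated resistant
pathways, which draw 80% of members (default) from persistent-resistance
primary genes. Identical configurations (including seed) are bit-identical.

What the generator does *not* emulate: stromal/immune admixture, tumor
cellularity effects on expression, single-cell structure, gene–gene
correlation beyond the planted patterns, and realistic effect-size
distributions (the effect sizes of real pattern genes are unknown;
defaults are configuration, not a claim of realism). Passing
tests therefore demonstrate the correctness and calibration of the
machinery under the stated noise model, not performance on real tumors.

## Numerical choices and degenerate inputs

- Zero-variance triplets → UNCLASSIFIED; zero-variance paired differences
  → p = 1 (no evidence, not an error).
- Pseudocount 1 on the normalized scale keeps zeros finite.
- Bootstrap p resolution is 1/n_boot; p = 0 is legitimate output.
- Rank-sum exact/approx switch at combined n = 20; the exact path costs
  C(20,10) ≈ 1.8e5 enumerated labelings at worst.
- Principal-curve fitting collapses duplicate polyline vertices and stops
  early if the curve degenerates to a point; all-identical point clouds are
  rejected.
- Problem sizes in the tests and the acceptance script (24 patients × 2000
  genes; 300-gene cohorts across 20 seeds for null calibration; 1000 draws
  × 10 000 resamples for bootstrap calibration) are chosen as the smallest
  sizes at which the measured properties are stable.

## Known limitations

- The VST stand-in and the paired-test DE filter are transparent
  approximations of a count-model pipeline; absolute DE gene counts on real
  data will differ from a dispersion-modeled fit, though the downstream
  pattern machinery only needs a reasonable gene universe on a log2 scale.
- Bootstrap p-values at small considered sizes are conservative (see
  above).
- The log-rank stage requires both ratio strata to be populated; cohorts
  whose ratios all fall on one side of the cutoff get a logged warning and
  no survival statistic rather than a fabricated one.
- Balloon/circular-map rendering is a reporting convenience; all figures
  are derived views of emitted tables, never the primary output.
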