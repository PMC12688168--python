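# chemoresistome

Longitudinal analysis of adaptive chemoresistance from matched
tumor–normal transcriptome triplets.

When breast-cancer patients receive neoadjuvant chemotherapy (systemic
treatment before surgery), each patient can contribute three matched RNA-seq
samples: adjacent normal epithelium, a pretreatment tumor biopsy, and the
posttreatment residual tumor. For every gene in every patient this yields a
three-point expression trajectory whose *shape* — rather than its absolute
level — carries information about how the tumor responded: did a
dysregulated gene return to normal levels after treatment, or did its
dysregulation persist or even intensify in the residual tumor?

This package implements that trajectory analysis as a tested, reusable
pipeline for people working on treatment-resistance transcriptomics:

- **Pattern classification.** Enumerating the qualitative three-point
  trajectories (each transition up, down, or unchanged; the fully flat case
  excluded) gives exactly eight templates P1–P8. Each gene-per-patient
  triplet of variance-stabilized expression values *v* = (normal, pre, post)
  is assigned the template *T* maximizing the Pearson correlation
  r(*v*, *T*) — a scale- and shift-invariant match of shape. P1/P2 are
  *reregulated* (return to normal), P3/P4 a persistent *resistance state*,
  P5/P6 *treatment effects*, P7/P8 *worsening*.
- **Gene-level recurrence.** Across patients a gene is *main-pattern* (one
  pattern in ≥ 50% of classified patients) or *bimodal* (two patterns, each
  in ≥ 30% of patients and ≥ 5 patients).
- **Response association.** Persistent genes (P3, P3+P7, P4, or P4+P8 in
  > 50% of patients) form one resistance-gene route; for bimodal genes the
  Miller–Payne (MP) response grades of patients with reregulated vs
  dysregulated patterns are compared by a Wilcoxon rank-sum test (exact
  permutation enumeration under ties up to n = 20). The per-patient ratio
  (f(P1)+f(P2)) / (f(P7)+f(P8)) is tested against MP groups by one-way
  ANOVA and against recurrence-free survival by Kaplan–Meier/log-rank.
- **Pathway resistance scores.** For each patient and pathway, the
  resistance score is the fraction of resistance-pattern (P3/P4/P7/P8)
  genes among the pathway's differentially expressed, pattern-assigned
  genes; its p-value comes from a bootstrap null of 10 000 random same-size
  gene sets drawn from the patient's gene universe.
- **Pathway deregulation score (PDS).** Per pathway, all samples are
  embedded by normal-referenced standardization + PCA, a Hastie–Stuetzle
  principal curve is threaded through the cloud, and each sample is scored
  by its arc-length distance beyond the normal samples' position,
  normalized to [0, 1].
- **Synthetic cohorts with ground truth.** A negative-binomial cohort
  generator plants known trajectories, couples MP grades to the planted
  dysregulated fraction, and seeds resistance-enriched pathways, so every
  stage is testable end to end without any data download.

## Worked example

```python
from chemoresistome import SyntheticConfig, generate_cohort, ChemoresistomeModel

cohort = generate_cohort(SyntheticConfig(seed=7))   # 24 patients x 2000 genes
model = ChemoresistomeModel.from_cohort(cohort, seed=7)
results = model.fit()
print(results.summary())
```

```
Chemoresistome analysis results
===============================================
Complete triplets:                24
Patients without triplet:          0
Genes tested:                   2000
DE genes retained (|FC|>2, q<=0.05, count>=100):    987
  main-pattern genes:            960
  bimodal genes:                  27
  unclassified genes:              0
Persistent resistance genes:     589
Bimodal response genes (p<0.05):    8
Combined resistance genes:       590
Ratio ANOVA across MP groups: F = 18.012, p = 2.784e-05
Enriched pathways (q<0.05):        0
Resistance scores computed:      960 (patients x pathways)
```

Reading the output: of the 2000 simulated genes, 987 pass the
differential-expression filter (absolute fold change > 2, BH-adjusted
p ≤ 0.05, raw count ≥ 100 somewhere). Most DE genes recur with one main
pattern across the 24 patients; 27 are bimodal, and 8 of those separate
good from poor responders at p < 0.05. The reregulated-to-dysregulated
ratio is strongly associated with the MP grade (ANOVA p ≈ 2.8e-05) because
the generator couples response to the planted dysregulated fraction.
Per-patient, per-pathway scores then quantify where resistance concentrates:

```
patient pathway  n_considered  n_resistance    score  p_boot  n_boot
   PT01   PW001            30            27 0.900000  0.0001   10000
   PT01   PW002             8             8 1.000000  0.0144   10000
   PT01   PW003            35            32 0.914286  0.0000   10000
```

`PW001`–`PW004` were planted as resistance-enriched pathways; their scores
sit far above the random-pathway background (p_boot near 0; a p of 0.0000
means "< 1/10000").

The same pipeline runs from the shell on TSV/MTX + GMT inputs:

```bash
chemoresistome simulate --outdir cohort --seed 7
chemoresistome run-all --outdir run --seed 7
```

which writes every stage table, the figures (pattern-fraction stacks,
balloon plot, per-patient circular chemoresistome maps, PDS heatmap), and a
manifest with content hashes.

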