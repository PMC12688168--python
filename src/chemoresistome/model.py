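"""Cohort-level model facade.

``ChemoresistomeModel`` holds the cohort data (counts, sample and patient
tables, optional gene sets) plus all stage parameters; ``fit()`` runs
normalization, the DE filter, trajectory-pattern assignment, gene and
patient summaries, response association, enrichment, and (optionally) the
bootstrap resistance scores, returning a ``ChemoresistomeResults`` whose
``summary()`` renders the headline statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import normalize as nrm
from . import patterns as pat
from . import response as rsp
from .data import (CountMatrix, GeneSetCollection, PatientTable, SampleTable,
                   TripletIndex, build_triplets)
from .errors import ValidationError
from .pds import compute_pds_collection

log = logging.getLogger(__name__)


class ChemoresistomeModel:
    """Longitudinal chemoresistome analysis of one matched-triplet cohort.

    Parameters mirror the stage defaults: DE filter (fold change > 2,
    BH-adjusted p <= 0.05, max raw count >= 100), gene classification
    (main >= 50%, bimodal >= 30% and >= 5 patients), gene-level response
    test at raw p < 0.05, enrichment q < 0.05 with a subtype-restricted
    rerun, bootstrap of 10 000 resamples, survival ratio cutoff 5.
    """

    def __init__(
        self,
        counts: CountMatrix,
        samples: SampleTable,
        patients: PatientTable,
        gene_sets: GeneSetCollection | None = None,
        *,
        fc_threshold: float = 2.0,
        alpha: float = 0.05,
        min_count: int = 100,
        paired_test: str = "ttest",
        main_threshold: float = 0.5,
        bimodal_threshold: float = 0.3,
        min_bimodal_patients: int = 5,
        strict_main_threshold: bool = False,
        template_levels: dict | None = None,
        assignment_mode: str = "levels",
        mp_groups: Sequence[Sequence[int]] = ((1,), (2,), (3, 4, 5)),
        km_cutoff: float = 5.0,
        subtype_filter: str | None = "HR+",
        enrichment_q: float = 0.05,
        enrichment_hits: str = "bimodal",
        k_top: int = 5,
        n_boot: int = 10_000,
        seed: int = 0,
    ):
        self.counts = counts
        self.samples = samples
        self.patients = patients
        self.gene_sets = gene_sets
        self.fc_threshold = fc_threshold
        self.alpha = alpha
        self.min_count = min_count
        self.paired_test = paired_test
        self.main_threshold = main_threshold
        self.bimodal_threshold = bimodal_threshold
        self.min_bimodal_patients = min_bimodal_patients
        self.strict_main_threshold = strict_main_threshold
        self.templates = pat.theoretical_templates(template_levels)
        self.assignment_mode = assignment_mode
        self.mp_groups = tuple(tuple(g) for g in mp_groups)
        self.km_cutoff = km_cutoff
        self.subtype_filter = subtype_filter
        self.enrichment_q = enrichment_q
        if enrichment_hits not in ("bimodal", "combined"):
            raise ValidationError(f"unknown enrichment_hits mode {enrichment_hits!r}")
        self.enrichment_hits = enrichment_hits
        self.k_top = k_top
        self.n_boot = n_boot
        self.seed = seed

    @classmethod
    def from_cohort(cls, cohort, **kw) -> "ChemoresistomeModel":
        """Build from a :func:`chemoresistome.simulate.generate_cohort` tuple."""
        return cls(cohort.counts, cohort.samples, cohort.patients,
                   cohort.gene_sets, **kw)

    # ------------------------------------------------------------------ fit

    def fit(self, compute_scores: bool = True) -> "ChemoresistomeResults":
        triplet_index = build_triplets(self.counts, self.samples)
        triplets = triplet_index.triplets
        if len(triplets) < 2:
            raise ValidationError(f"only {len(triplets)} complete triplets; need >= 2")
        log.info("fit: %d complete triplets, %d incomplete patients",
                 len(triplets), len(triplet_index.incomplete))

        factors = nrm.size_factors(self.counts)
        vst = nrm.vst_transform(self.counts, factors)
        de = nrm.de_filter(vst, self.counts, triplets,
                           fc_threshold=self.fc_threshold, alpha=self.alpha,
                           min_count=self.min_count, paired_test=self.paired_test)

        assignments = pat.assign_cohort(vst.to_frame(), triplets, genes=de.retained,
                                        templates=self.templates,
                                        mode=self.assignment_mode)
        classifications = (
            pat.classify_genes(assignments,
                               main_threshold=self.main_threshold,
                               bimodal_threshold=self.bimodal_threshold,
                               min_patients=self.min_bimodal_patients,
                               strict_main=self.strict_main_threshold)
            if len(assignments) else pd.DataFrame()
        )
        fractions = (pat.cohort_pattern_fractions(
            assignments[assignments["pattern"] != pat.UNCLASSIFIED])
            if len(assignments) else pd.DataFrame())

        mp = self.patients.mp_map()
        bimodal_genes = (list(classifications.index[classifications["klass"] == "bimodal"])
                         if len(classifications) else [])
        gene_tests = rsp.response_gene_tests(bimodal_genes, assignments, mp,
                                             alpha=self.alpha)
        persistent = (rsp.persistent_resistance_genes(classifications)
                      if len(classifications) else [])
        bimodal_sig = (sorted(set(gene_tests.loc[gene_tests["significant"], "gene"]))
                       if len(gene_tests) else [])
        gene_list = rsp.resistance_gene_list(persistent, bimodal_sig)

        # subtype-restricted rerun of the gene tests
        gene_tests_subtype = pd.DataFrame()
        subtype_patients: list[str] = []
        if self.subtype_filter is not None:
            smap = self.patients.subtype_map()
            subtype_patients = [p for p, s in smap.items() if s == self.subtype_filter]
            if subtype_patients:
                sub_assign = assignments[assignments["patient"].isin(subtype_patients)]
                sub_mp = {p: mp[p] for p in subtype_patients if p in mp}
                gene_tests_subtype = rsp.response_gene_tests(
                    bimodal_genes, sub_assign, sub_mp, alpha=self.alpha)

        ratios = (dict(zip(fractions.index, fractions["ratio"]))
                  if len(fractions) else {})
        anova = None
        try:
            anova = rsp.ratio_anova(ratios, mp, groups=self.mp_groups)
        except ValidationError as e:
            log.warning("ratio ANOVA unavailable: %s", e)
        km = None
        try:
            km = rsp.km_logrank(self.patients, ratios, cutoff=self.km_cutoff)
        except ValidationError as e:
            log.warning("KM/log-rank unavailable: %s", e)

        enrich_all = enrich_subset = pd.DataFrame()
        robust: list[str] = []
        scores = pd.DataFrame()
        if self.gene_sets is not None and len(self.gene_sets):
            universe = sorted(set(de.retained)
                              & {g for gs in self.gene_sets for g in gs.genes})
            enrich_all = self._enrich(gene_tests, classifications, universe)
            if len(gene_tests_subtype):
                enrich_subset = self._enrich(gene_tests_subtype, classifications, universe)
                robust = enr.robust_pathway_list(enrich_all, enrich_subset,
                                                 k_top=self.k_top)
            else:
                robust = sorted(enrich_all.loc[enrich_all["significant"], "pathway"]) \
                    if len(enrich_all) else []
            if compute_scores:
                score_pathways = robust or self.gene_sets.names()
                scores = enr.compute_resistance_scores(
                    assignments, de.retained, self.gene_sets,
                    pathways=score_pathways, n_boot=self.n_boot, seed=self.seed)

        return ChemoresistomeResults(
            model=self, triplet_index=triplet_index, size_factors=factors,
            vst=vst, de=de, assignments=assignments,
            classifications=classifications, fractions=fractions,
            gene_tests=gene_tests, gene_tests_subtype=gene_tests_subtype,
            resistance_genes=gene_list, anova=anova, km=km,
            enrichment_all=enrich_all, enrichment_subtype=enrich_subset,
            robust_pathways=robust, resistance_scores=scores,
        )

    def _enrich(self, gene_tests: pd.DataFrame, classifications: pd.DataFrame,
                universe: list[str]) -> pd.DataFrame:
        frames = []
        for label, family in enr.CLUSTER_FAMILIES.items():
            cluster = "up" if "P1" in family else "down"
            if len(gene_tests):
                hits = set(gene_tests.loc[(gene_tests["significant"])
                                          & (gene_tests["cluster"] == cluster), "gene"])
            else:
                hits = set()
            if self.enrichment_hits == "combined" and len(classifications):
                dys = {"P3", "P7"} if cluster == "up" else {"P4", "P8"}
                main = classifications[classifications["klass"] == "main"]
                persist = set(rsp.persistent_resistance_genes(classifications))
                hits |= {g for g, mp_ in zip(main.index, main["main_patterns"])
                         if g in persist and set(mp_.split("+")) <= dys}
            hits &= set(universe)
            if not hits or not universe:
                continue
            frames.append(enr.hypergeom_enrich(hits, universe, self.gene_sets,
                                               cluster_label=label,
                                               q_threshold=self.enrichment_q))
        if not frames:
            return pd.DataFrame(columns=["pathway", "source", "pattern_cluster",
                                         "overlap", "pathway_size", "universe_size",
                                         "n_hits", "p_value", "q_value", "significant"])
        return pd.concat(frames, ignore_index=True)

    # ------------------------------------------------------------------ PDS

    def pathway_deregulation(self, collection: GeneSetCollection | None = None,
                             **kw) -> pd.DataFrame:
        """PDS matrix (pathways x samples) relative to the normal samples."""
        coll = collection or self.gene_sets
        if coll is None:
            raise ValidationError("no gene-set collection for PDS")
        vst = nrm.vst_transform(self.counts)
        normals = [str(r["sample_id"]) for _, r in self.samples.df.iterrows()
                   if r["timepoint"] == "normal"]
        return compute_pds_collection(vst.to_frame(), coll, normals, **kw)


@dataclass
class ChemoresistomeResults:
    """Everything :meth:`ChemoresistomeModel.fit` computes."""

    model: ChemoresistomeModel
    triplet_index: TripletIndex
    size_factors: np.ndarray
    vst: nrm.VstMatrix
    de: nrm.DEFilterResult
    assignments: pd.DataFrame
    classifications: pd.DataFrame
    fractions: pd.DataFrame
    gene_tests: pd.DataFrame
    gene_tests_subtype: pd.DataFrame
    resistance_genes: rsp.ResistanceGeneList
    anova: rsp.AnovaResult | None
    km: rsp.KMResult | None
    enrichment_all: pd.DataFrame
    enrichment_subtype: pd.DataFrame
    robust_pathways: list[str] = field(default_factory=list)
    resistance_scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def ratios(self) -> dict[str, float]:
        if not len(self.fractions):
            return {}
        return dict(zip(self.fractions.index, self.fractions["ratio"]))

    def summary(self) -> str:
        m = self.model
        lines = [
            "Chemoresistome analysis results",
            "=" * 47,
            f"Complete triplets:            {len(self.triplet_index.triplets):>6}",
            f"Patients without triplet:     {len(self.triplet_index.incomplete):>6}",
            f"Genes tested:                 {len(self.vst.genes):>6}",
            f"DE genes retained (|FC|>{m.fc_threshold:g}, q<={m.alpha:g}, "
            f"count>={m.min_count}): {len(self.de.retained):>6}",
        ]
        if len(self.classifications):
            counts = self.classifications["klass"].value_counts()
            lines += [
                f"  main-pattern genes:         {counts.get('main', 0):>6}",
                f"  bimodal genes:              {counts.get('bimodal', 0):>6}",
                f"  unclassified genes:         {counts.get('unclassified', 0):>6}",
            ]
        rg = self.resistance_genes
        lines += [
            f"Persistent resistance genes:  {len(rg.persistent_genes):>6}",
            f"Bimodal response genes (p<{m.alpha:g}): {len(rg.bimodal_significant_genes):>4}",
            f"Combined resistance genes:    {len(rg.combined):>6}",
        ]
        if self.anova is not None:
            lines.append(f"Ratio ANOVA across MP groups: F = {self.anova.f_statistic:.3f}, "
                         f"p = {self.anova.p_value:.4g}")
        if self.km is not None:
            lines.append(f"Log-rank (ratio cutoff {m.km_cutoff:g}):  chi2 = "
                         f"{self.km.statistic:.3f}, p = {self.km.p_value:.4g}")
        if len(self.enrichment_all):
            nsig = int(self.enrichment_all["significant"].sum())
            lines.append(f"Enriched pathways (q<{m.enrichment_q:g}):   {nsig:>6}")
        if self.robust_pathways:
            lines.append(f"Robust pathway list:          {len(self.robust_pathways):>6}")
        if len(self.resistance_scores):
            defined = self.resistance_scores["score"].notna()
            lines.append(f"Resistance scores computed:   {int(defined.sum()):>6} "
                         f"(patients x pathways)")
        return "\n".join(lines)
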