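"""Synthetic neoadjuvant-cohort generator with known ground truth.

Emulates the study design the analysis expects: 20–30 breast-cancer patients
receiving neoadjuvant chemotherapy, each contributing a matched triplet
(adjacent normal epithelium, pretreatment biopsy, posttreatment residual
tumor). Counts are negative binomial around pattern-defined log2 means:
every gene carries a baseline log2 expression, and its planted trajectory
template (or FLAT for no change) shifts the per-timepoint mean by
``effect_size`` log2 units per template level; per-sample library-size
factors rescale the means.

Patient-to-patient heterogeneity is created by giving each patient a
"resistance propensity": genes whose primary pattern is reregulated (P1/P2)
flip, with that probability, to their persistent counterpart (P3/P4) in that
patient — producing the bimodal gene behavior the response-association stage
looks for. Genes planted with P3/P4/P7/P8 as their primary pattern keep it
in every patient (persistent resistance genes). The Miller–Payne grade is
coupled to the patient's planted dysregulated fraction: with positive
``mp_coupling``, patients with more resistance-pattern genes get lower
grades (worse pathological response).

Everything is driven by a single integer seed; identical configs produce
bit-identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats

from .data import (CountMatrix, GeneSet, GeneSetCollection, PatientTable,
                   SampleTable, TIMEPOINTS)
from .errors import ConfigurationError
from .patterns import RESISTANCE_PATTERNS, _DEFAULT_LEVELS

log = logging.getLogger(__name__)

FLAT = "FLAT"

_DEFAULT_PROPORTIONS = {
    FLAT: 0.50,
    "P1": 0.09, "P2": 0.09,
    "P3": 0.07, "P4": 0.07,
    "P5": 0.04, "P6": 0.04,
    "P7": 0.05, "P8": 0.05,
}

_LEVELS = {**{k: np.array(v) for k, v in _DEFAULT_LEVELS.items()},
           FLAT: np.zeros(3)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``effect_size`` is the log2-scale step per template transition;
    ``nb_dispersion`` is the NB dispersion phi in var = mu + phi*mu^2;
    ``mp_coupling`` scales how strongly a patient's planted dysregulated
    fraction depresses their MP grade (0 decouples them);
    ``bimodal_flip_range`` bounds the per-patient probability that a
    reregulated-primary gene appears in its persistent form.
    """

    n_patients: int = 24
    n_genes: int = 2000
    pattern_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    effect_size: float = 2.0
    baseline_log_mean_range: tuple[float, float] = (7.0, 11.0)
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] = (0.5, 2.0)
    mp_coupling: float = 3.0
    mp_range: tuple[int, int] = (1, 4)
    bimodal_flip_range: tuple[float, float] = (0.15, 0.75)
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (10, 40)
    resistant_pathway_ids: tuple[str, ...] = ("PW001", "PW002", "PW003", "PW004")
    resistance_enrichment: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_genes < 1 or self.n_pathways < 0:
            raise ConfigurationError("non-positive cohort dimensions")
        total = sum(self.pattern_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"pattern_proportions sum to {total}, not 1")
        unknown = set(self.pattern_proportions) - set(_LEVELS)
        if unknown:
            raise ConfigurationError(f"unknown pattern ids in proportions: {sorted(unknown)}")
        if any(v < 0 for v in self.pattern_proportions.values()):
            raise ConfigurationError("pattern proportions must be non-negative")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        for name in ("baseline_log_mean_range", "library_size_range",
                     "pathway_size_range", "bimodal_flip_range", "mp_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be ordered low <= high")
        if not (1 <= self.mp_range[0] <= self.mp_range[1] <= 5):
            raise ConfigurationError("mp_range must lie within the 1..5 MP scale")
        if not 0 <= self.resistance_enrichment <= 1:
            raise ConfigurationError("resistance_enrichment must be in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted, for confusion-matrix style evaluation downstream."""

    planted_pattern: pd.DataFrame  # genes x patients, entries P1..P8 / FLAT
    planted_mp: dict[str, int]
    planted_resistant_pathways: set[str]
    primary_pattern: dict[str, str]  # gene -> its cohort-level pattern
    library_sizes: dict[str, float]
    baseline_log2: dict[str, float]
    dysregulated_fraction: dict[str, float]  # per patient, over non-FLAT genes

    def pattern_of(self, gene: str, patient: str) -> str:
        return str(self.planted_pattern.at[gene, patient])

    def to_jsonable(self) -> dict:
        return {
            "planted_pattern": {g: self.planted_pattern.loc[g].to_dict()
                                for g in self.planted_pattern.index},
            "planted_mp": self.planted_mp,
            "planted_resistant_pathways": sorted(self.planted_resistant_pathways),
            "primary_pattern": self.primary_pattern,
            "library_sizes": self.library_sizes,
            "baseline_log2": self.baseline_log2,
            "dysregulated_fraction": self.dysregulated_fraction,
        }


class Cohort(NamedTuple):
    counts: CountMatrix
    samples: SampleTable
    patients: PatientTable
    gene_sets: GeneSetCollection
    truth: GroundTruth


def sample_nb_counts(mean: np.ndarray, dispersion: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion*mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _grade_by_rank(latent: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Map a latent response score to integer grades lo..hi by rank quantile
    (higher latent -> higher grade), keeping group sizes balanced."""
    n = len(latent)
    n_grades = hi - lo + 1
    order = scipy.stats.rankdata(latent, method="ordinal") - 1  # 0..n-1
    return lo + (order * n_grades // n).astype(int)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate counts, metadata, gene sets, and ground truth for one cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    width = max(2, len(str(config.n_patients)))
    patients = [f"PT{str(i + 1).zfill(width)}" for i in range(config.n_patients)]
    gwidth = max(4, len(str(config.n_genes)))
    genes = [f"G{str(i + 1).zfill(gwidth)}" for i in range(config.n_genes)]
    sample_ids = [f"{p}_{tp}" for p in patients for tp in TIMEPOINTS]

    # --- planted patterns -------------------------------------------------
    props = config.pattern_proportions
    keys = sorted(props)
    primary = rng.choice(keys, size=config.n_genes, p=[props[k] for k in keys])
    flip_prob = rng.uniform(*config.bimodal_flip_range, size=config.n_patients)

    planted = np.tile(primary[:, None], (1, config.n_patients)).astype(object)
    for j, pid in enumerate(patients):
        flips = rng.random(config.n_genes) < flip_prob[j]
        planted[(primary == "P1") & flips, j] = "P3"
        planted[(primary == "P2") & flips, j] = "P4"
    planted_df = pd.DataFrame(planted, index=genes, columns=patients)

    # --- expression means and counts -------------------------------------
    baseline = rng.uniform(*config.baseline_log_mean_range, size=config.n_genes)
    lo, hi = config.library_size_range
    lib = np.power(2.0, rng.uniform(np.log2(lo), np.log2(hi), size=3 * config.n_patients))

    # planted may contain patterns absent from the proportion keys (P3/P4
    # flips), so the level lookup covers every template id plus FLAT
    code = np.empty((config.n_genes, config.n_patients), dtype=int)
    all_ids = sorted(_LEVELS)
    id_index = {k: i for i, k in enumerate(all_ids)}
    level_lut = np.stack([_LEVELS[k] for k in all_ids])
    for j in range(config.n_patients):
        code[:, j] = [id_index[p] for p in planted[:, j]]
    levels = level_lut[code]  # (G, Npat, 3)
    log2_mu = baseline[:, None, None] + config.effect_size * levels
    mu = np.power(2.0, log2_mu).reshape(config.n_genes, 3 * config.n_patients)
    mu = mu * lib[None, :]
    counts = sample_nb_counts(mu, config.nb_dispersion, rng)
    cm = CountMatrix(genes, sample_ids, counts)

    # --- clinical metadata -------------------------------------------------
    non_flat = primary != FLAT
    dys = np.zeros(config.n_patients)
    if non_flat.sum():
        is_res = np.isin(planted[non_flat], RESISTANCE_PATTERNS)
        dys = is_res.mean(axis=0)
    dys_z = (dys - dys.mean()) / dys.std() if dys.std() > 0 else np.zeros_like(dys)
    latent = -config.mp_coupling * dys_z + rng.standard_normal(config.n_patients)
    mp = _grade_by_rank(latent, *config.mp_range)

    rcb = np.where(mp >= 4, "RCB-I", np.where(mp >= 3, "RCB-II", "RCB-III"))
    subtype = np.array(["HR+"] * config.n_patients, dtype=object)
    n_tnbc = min(3, config.n_patients // 8) or (1 if config.n_patients >= 8 else 0)
    n_tp = 1 if config.n_patients >= 10 else 0
    picks = rng.permutation(config.n_patients)
    subtype[picks[:n_tnbc]] = "TNBC"
    if n_tp:
        subtype[picks[n_tnbc:n_tnbc + n_tp]] = "TP"

    # recurrence-free survival: better responders recur later, admin censor
    event_time = rng.exponential(scale=1.5 * np.power(1.8, mp))
    censor_time = rng.uniform(3.0, 8.0, size=config.n_patients)
    rfs = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    patients_df = pd.DataFrame({
        "patient_id": patients, "mp_score": mp, "rcb_class": rcb,
        "subtype": subtype, "regimen": "ddAC-T",
        "rfs_years": np.round(rfs, 3), "recurrence_event": event,
    })
    cellularity = rng.uniform(0.3, 0.9, size=3 * config.n_patients)
    samples_df = pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": np.repeat(patients, 3),
        "timepoint": np.tile(TIMEPOINTS, config.n_patients),
        "cellularity": [np.nan if tp == "normal" else round(c, 3)
                        for tp, c in zip(np.tile(TIMEPOINTS, config.n_patients), cellularity)],
    })

    truth = GroundTruth(
        planted_pattern=planted_df,
        planted_mp=dict(zip(patients, map(int, mp))),
        planted_resistant_pathways=set(config.resistant_pathway_ids) if config.n_pathways else set(),
        primary_pattern=dict(zip(genes, primary)),
        library_sizes=dict(zip(sample_ids, map(float, lib))),
        baseline_log2=dict(zip(genes, map(float, baseline))),
        dysregulated_fraction=dict(zip(patients, map(float, dys))),
    )
    gene_sets = generate_pathway_collection(config, truth, rng=rng)
    truth.planted_resistant_pathways &= set(gene_sets.names())
    return Cohort(cm, SampleTable(samples_df), PatientTable(patients_df), gene_sets, truth)


def generate_pathway_collection(
    config: SyntheticConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """Gene-set collection over the cohort's gene universe.

    Pathways named in ``resistant_pathway_ids`` draw
    ``resistance_enrichment`` of their members from genes whose primary
    planted pattern is persistent-resistance (P3/P4/P7/P8 in a majority of
    patients); all other pathways are uniform random gene sets.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 1])
    universe = np.array(list(truth.primary_pattern))
    res_pool = np.array([g for g, p in truth.primary_pattern.items()
                         if p in RESISTANCE_PATTERNS])
    width = max(3, len(str(config.n_pathways)))
    names = [f"PW{str(i + 1).zfill(width)}" for i in range(config.n_pathways)]
    unknown = set(config.resistant_pathway_ids) - set(names)
    if unknown and config.n_pathways:
        raise ConfigurationError(
            f"resistant_pathway_ids not among generated pathway names: {sorted(unknown)}")
    lo, hi = config.pathway_size_range
    if hi > len(universe):
        raise ConfigurationError("pathway size exceeds gene universe")
    coll = GeneSetCollection()
    for name in names:
        k = int(rng.integers(lo, hi + 1))
        if name in config.resistant_pathway_ids and len(res_pool):
            k_res = min(int(round(config.resistance_enrichment * k)), len(res_pool))
            res_part = rng.choice(res_pool, size=k_res, replace=False)
            rest_pool = np.setdiff1d(universe, res_part)
            rest = rng.choice(rest_pool, size=k - k_res, replace=False)
            members = np.concatenate([res_part, rest])
            desc = "synthetic resistance-enriched pathway"
        else:
            members = rng.choice(universe, size=k, replace=False)
            desc = "synthetic random pathway"
        coll.add(GeneSet(name, desc, tuple(sorted(members))))
    return coll


def default_config(**overrides) -> SyntheticConfig:
    """The package's reference study conditions, optionally overridden."""
    return replace(SyntheticConfig(), **overrides)
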