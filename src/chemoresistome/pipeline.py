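"""End-to-end pipeline orchestration, run manifest, and report rendering.

``run_pipeline`` executes simulate-or-load -> normalize -> de-filter ->
classify -> associate -> score -> pds -> report into a run directory,
logging per-stage row counts (so enrollment-to-analysis funnels are
reconstructible) and writing a JSON manifest with parameters, seed, and a
content hash of every output file. Reruns with the same config reproduce
identical tables.

``render_reports`` draws the summary figures — per-patient pattern-fraction
stacked bars, the pathway-by-patient balloon plot of resistance scores,
per-patient circular chemoresistome maps, and the PDS heatmap — each backed
by a 1:1 companion data table; figures are derived views only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .errors import ValidationError
from .model import ChemoresistomeModel
from .simulate import SyntheticConfig, generate_cohort
from . import __version__

log = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "de-filter", "classify", "associate",
          "score", "pds", "report")

#: p-value color bands for rendered resistance maps
P_BANDS = ((0.01, "#b2182b"), (0.05, "#ef8a62"), (0.10, "#fddbc7"), (np.inf, "#d9d9d9"))


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    When ``counts_path`` is unset a synthetic cohort is generated from
    ``synthetic`` (stage parameters keep their defaults unless overridden).
    """

    outdir: str = "chemoresistome_run"
    counts_path: str | None = None
    counts_format: str | None = None
    samples_path: str | None = None
    patients_path: str | None = None
    gmt_path: str | None = None
    module_map_path: str | None = None  # pathway -> functional module, TSV
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    model_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure aborts with the stage name and cause; outputs of the
    completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": [], "files": {}, "counts": {}}
    stage = "simulate"
    try:
        # --- stage 1: simulate or load ------------------------------------
        if config.counts_path is None:
            syn = dict(config.synthetic)
            syn.setdefault("seed", config.seed)
            cohort = generate_cohort(SyntheticConfig(**syn))
            counts, samples, patients, gene_sets = (cohort.counts, cohort.samples,
                                                    cohort.patients, cohort.gene_sets)
            cio.write_counts(counts, outdir / "counts.tsv")
            cio.write_sample_table(samples, outdir / "samples.tsv")
            cio.write_patient_table(patients, outdir / "patients.tsv")
            cio.write_gmt(gene_sets, outdir / "pathways.gmt")
            cio.write_json(cohort.truth.to_jsonable(), outdir / "ground_truth.json")
        else:
            counts = cio.read_counts(config.counts_path, config.counts_format)
            samples = cio.read_sample_table(config.samples_path)
            patients = cio.read_patient_table(config.patients_path)
            gene_sets = cio.read_gmt(config.gmt_path) if config.gmt_path else None
        manifest["stages"].append(stage)
        manifest["counts"][stage] = {"genes": counts.shape[0], "samples": counts.shape[1]}

        params = dict(config.model_params)
        params.setdefault("seed", config.seed)
        model = ChemoresistomeModel(counts, samples, patients, gene_sets, **params)
        res = model.fit()

        # --- stages 2-3: normalize + de-filter ----------------------------
        stage = "normalize"
        pd.DataFrame({"sample": res.vst.samples,
                      "size_factor": res.size_factors}).to_csv(
            outdir / "size_factors.tsv", sep="\t", index=False)
        res.vst.to_frame().to_csv(outdir / "vst.tsv", sep="\t", index_label="gene")
        manifest["stages"].append(stage)
        stage = "de-filter"
        res.de.table.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        Path(outdir / "de_genes.txt").write_text("\n".join(res.de.retained) + "\n")
        manifest["stages"].append(stage)
        manifest["counts"][stage] = {"tested": len(res.vst.genes),
                                     "retained": len(res.de.retained)}

        # --- stage 4: classify --------------------------------------------
        stage = "classify"
        res.assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        res.classifications.to_csv(outdir / "gene_classifications.tsv", sep="\t")
        res.fractions.to_csv(outdir / "patient_fractions.tsv", sep="\t")
        manifest["stages"].append(stage)
        manifest["counts"][stage] = {
            "triplets": len(res.triplet_index.triplets),
            "incomplete_patients": len(res.triplet_index.incomplete),
            "assignments": len(res.assignments)}

        # --- stage 5: associate -------------------------------------------
        stage = "associate"
        res.gene_tests.to_csv(outdir / "gene_response_tests.tsv", sep="\t", index=False)
        if len(res.gene_tests_subtype):
            res.gene_tests_subtype.to_csv(outdir / "gene_response_tests_subtype.tsv",
                                          sep="\t", index=False)
        rg = res.resistance_genes
        cio.write_json({"persistent": rg.persistent_genes,
                        "bimodal": rg.bimodal_significant_genes,
                        "combined": rg.combined}, outdir / "resistance_genes.json")
        Path(outdir / "resistance_genes.txt").write_text("\n".join(rg.combined) + "\n")
        stats = {}
        if res.anova is not None:
            stats["anova"] = {"F": res.anova.f_statistic, "p": res.anova.p_value,
                              "group_sizes": res.anova.group_sizes}
        if res.km is not None:
            stats["logrank"] = {"statistic": res.km.statistic, "p": res.km.p_value,
                                "strata_sizes": res.km.strata_sizes}
        cio.write_json(stats, outdir / "response_stats.json")
        manifest["stages"].append(stage)
        manifest["counts"][stage] = {"persistent": len(rg.persistent_genes),
                                     "bimodal_significant": len(rg.bimodal_significant_genes),
                                     "combined": len(rg.combined)}

        # --- stage 6: score -----------------------------------------------
        stage = "score"
        if len(res.enrichment_all):
            res.enrichment_all.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        if len(res.enrichment_subtype):
            res.enrichment_subtype.to_csv(outdir / "enrichment_subtype.tsv",
                                          sep="\t", index=False)
        Path(outdir / "robust_pathways.txt").write_text(
            "\n".join(res.robust_pathways) + "\n")
        if len(res.resistance_scores):
            res.resistance_scores.to_csv(outdir / "resistance_scores.tsv",
                                         sep="\t", index=False)
        manifest["stages"].append(stage)
        manifest["counts"][stage] = {"robust_pathways": len(res.robust_pathways),
                                     "scores": int(len(res.resistance_scores))}

        # --- stage 7: pds -------------------------------------------------
        stage = "pds"
        if gene_sets is not None and len(gene_sets):
            pds = model.pathway_deregulation()
            pds.to_csv(outdir / "pds.tsv", sep="\t", index_label="pathway")
            manifest["counts"][stage] = {"pathways": len(pds)}
        manifest["stages"].append(stage)

        # --- stage 8: report ----------------------------------------------
        stage = "report"
        render_reports(outdir, module_map_path=config.module_map_path)
        manifest["stages"].append(stage)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest["parameters"] = {"model": params, "synthetic": config.synthetic}
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    cio.write_json(manifest, outdir / "manifest.json")
    return outdir


# ---------------------------------------------------------------- rendering

def _p_color(p: float) -> str:
    for bound, color in P_BANDS:
        if p < bound:
            return color
    return P_BANDS[-1][1]


def render_reports(results_dir, module_map_path=None) -> list[Path]:
    """Render figures (PNG) + companion tables from a run directory."""
    d = Path(results_dir)
    made: list[Path] = []

    # pattern-fraction stacked bars per patient
    fr_path = d / "patient_fractions.tsv"
    if fr_path.exists():
        fr = pd.read_csv(fr_path, sep="\t", index_col=0)
        cols = [c for c in fr.columns if c.startswith("P")]
        order = fr[["P7", "P8"]].sum(axis=1).sort_values().index
        tab = fr.loc[order, cols]
        tab.to_csv(d / "fig_pattern_fractions.tsv", sep="\t")
        ax = tab.plot(kind="bar", stacked=True, figsize=(9, 4), width=0.85,
                      colormap="tab10")
        ax.set_ylabel("fraction of classified genes")
        ax.set_xlabel("patient (ordered by P7+P8 fraction)")
        plt.tight_layout()
        plt.savefig(d / "fig_pattern_fractions.png", dpi=120)
        plt.close()
        made += [d / "fig_pattern_fractions.tsv", d / "fig_pattern_fractions.png"]

    # balloon plot + circular chemoresistome maps
    sc_path = d / "resistance_scores.tsv"
    if sc_path.exists():
        sc = pd.read_csv(sc_path, sep="\t")
        sc = sc[sc["score"].notna()].copy()
        modules = {}
        if module_map_path and Path(module_map_path).exists():
            mm = pd.read_csv(module_map_path, sep="\t")
            modules = dict(zip(mm.iloc[:, 0].astype(str), mm.iloc[:, 1].astype(str)))
        elif module_map_path:
            log.warning("module map %s not found; grouping 'unassigned'", module_map_path)
        sc["module"] = [modules.get(p, "unassigned") for p in sc["pathway"]]
        balloon = sc.sort_values(["module", "pathway", "patient"])
        balloon.to_csv(d / "fig_balloon.tsv", sep="\t", index=False)
        pathways = sorted(sc["pathway"].unique())
        patients = sorted(sc["patient"].unique())
        if pathways and patients:
            fig, ax = plt.subplots(
                figsize=(max(6, 0.35 * len(patients)), max(4, 0.3 * len(pathways))))
            yi = {p: i for i, p in enumerate(pathways)}
            xi = {p: i for i, p in enumerate(patients)}
            ax.scatter([xi[p] for p in sc["patient"]], [yi[p] for p in sc["pathway"]],
                       s=20 + 380 * sc["score"].to_numpy(),
                       c=[_p_color(p) for p in sc["p_boot"].fillna(1.0)],
                       edgecolor="k", linewidth=0.3)
            ax.set_xticks(range(len(patients)), patients, rotation=90, fontsize=7)
            ax.set_yticks(range(len(pathways)), pathways, fontsize=7)
            ax.set_title("resistance score (size) and bootstrap p (color)")
            plt.tight_layout()
            plt.savefig(d / "fig_balloon.png", dpi=120)
            plt.close()
            made += [d / "fig_balloon.tsv", d / "fig_balloon.png"]

        # circular per-patient maps (first few patients keep the output small)
        for patient in patients[:6]:
            sub = sc[sc["patient"] == patient].sort_values("pathway")
            sub.to_csv(d / f"fig_chemoresistome_{patient}.tsv", sep="\t", index=False)
            theta = np.linspace(0, 2 * np.pi, len(sub), endpoint=False)
            fig = plt.figure(figsize=(5, 5))
            ax = fig.add_subplot(projection="polar")
            ax.bar(theta, sub["score"], width=2 * np.pi / max(len(sub), 1) * 0.9,
                   color=[_p_color(p) for p in sub["p_boot"].fillna(1.0)],
                   edgecolor="k", linewidth=0.3)
            ax.set_ylim(0, 1)
            ax.set_xticks(theta)
            ax.set_xticklabels(sub["pathway"], fontsize=6)
            ax.set_title(f"chemoresistome map: {patient}")
            plt.tight_layout()
            plt.savefig(d / f"fig_chemoresistome_{patient}.png", dpi=120)
            plt.close()
            made += [d / f"fig_chemoresistome_{patient}.tsv",
                     d / f"fig_chemoresistome_{patient}.png"]

    # PDS heatmap
    pds_path = d / "pds.tsv"
    if pds_path.exists():
        pds = pd.read_csv(pds_path, sep="\t", index_col=0)
        pds.to_csv(d / "fig_pds_heatmap.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(max(6, 0.25 * pds.shape[1]),
                                        max(3, 0.25 * pds.shape[0])))
        im = ax.imshow(pds.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=0, vmax=1)
        ax.set_xticks(range(pds.shape[1]), pds.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(pds.shape[0]), pds.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="PDS")
        plt.tight_layout()
        plt.savefig(d / "fig_pds_heatmap.png", dpi=120)
        plt.close()
        made += [d / "fig_pds_heatmap.tsv", d / "fig_pds_heatmap.png"]
    return made
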