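"""End-to-end orchestration: simulate/load -> filter -> classify -> gene
stats -> pathways -> signatures, with a serialized config and deterministic,
re-runnable outputs.

Each stage writes plain TSV/JSON files into the output directory; identical
config + seed yields byte-identical outputs (log lines carry no timestamps
for that reason).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gene_stats, pathway_analysis, signatures, synthetic_cohort
from .impact_filter import FilterPolicy, filter_triplet
from .synthetic_cohort import SimConfig, simulate_cohort, synthetic_pathway_catalog
from .triplet_classify import (
    classify_origin,
    shared_somatic_vaf_ratio,
    vaf_summary,
    venn_counts,
)
from .variant_io import read_gene_sets, read_signature_catalog

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "filter", "classify", "genestats", "pathways", "signatures")

log = logging.getLogger("triovar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully determines a run together with the code version."""

    outdir: str
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    vcf_dir: str | None = None  # load mode instead of simulate mode
    gene_sets: str | None = None  # GMT path; synthetic catalog when absent
    signature_catalog: str | None = None  # TSV path; cohort catalog when absent
    filter_policy: dict = field(default_factory=dict)
    stages: tuple = ALL_STAGES
    gsea_n_perm: int = 1000
    gsea_weight_p: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["stages"] = list(d["stages"])
        # outdir is incidental to the run's identity; normalize so reruns in
        # different directories stay byte-identical
        d["outdir"] = "."
        return json.dumps(d, indent=2, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the JSON-serializable summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    (outdir / "run_config.json").write_text(config.to_json() + "\n")
    stages = tuple(config.stages)
    summary: dict = {"stages": list(stages), "seed": config.seed}

    # ---- acquire cohort -------------------------------------------------
    catalog = None
    cohort = None
    if config.vcf_dir:
        try:
            patients = synthetic_cohort.read_cohort(config.vcf_dir)
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        log.info("loaded %d patient triplets from %s", len(patients), config.vcf_dir)
    else:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        try:
            sim = SimConfig.from_dict(sim_kwargs)
            cohort = simulate_cohort(sim)
        except (TypeError, ValueError) as exc:
            raise PipelineError("simulate", str(exc)) from exc
        patients = cohort.patients
        if "simulate" in stages:
            synthetic_cohort.write_cohort(cohort, outdir / "cohort")
        catalog = cohort.catalog
        log.info("simulated cohort: %d patients, %d genes", sim.n_patients, sim.n_genes)
    summary["n_patients"] = len(patients)
    summary["variant_counts_raw"] = {
        t: float(np.mean([len(p.sample(t)) for p in patients]))
        for t in ("blood", "normal", "tumor")
    }

    if config.signature_catalog:
        catalog = read_signature_catalog(config.signature_catalog)

    # ---- filter ---------------------------------------------------------
    policy = FilterPolicy(**config.filter_policy) if config.filter_policy else FilterPolicy()
    if "filter" in stages:
        filtered = []
        report_frames = []
        for triplet in patients:
            ftrip, reports = filter_triplet(triplet, policy)
            filtered.append(ftrip)
            for tissue, rep in reports.items():
                df = rep.to_frame()
                df.insert(0, "tissue", tissue)
                df.insert(0, "patient_id", triplet.patient_id)
                report_frames.append(df)
        _write_tsv(pd.concat(report_frames, ignore_index=True),
                   outdir / "filter_report.tsv", index=False)
        analysis_patients = filtered
        summary["variant_counts_filtered"] = {
            t: float(np.mean([len(p.sample(t)) for p in analysis_patients]))
            for t in ("blood", "normal", "tumor")
        }
        log.info("filtered cohort with policy gq_min=%s", policy.gq_min)
    else:
        analysis_patients = patients

    # ---- classify -------------------------------------------------------
    need_classes = {"classify", "genestats", "pathways", "signatures"} & set(stages)
    classified = {}
    classified_gene = {}
    if need_classes:
        try:
            for triplet in analysis_patients:
                classified[triplet.patient_id] = classify_origin(triplet, "variant")
                classified_gene[triplet.patient_id] = classify_origin(triplet, "gene")
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc
    if "classify" in stages:
        origin_all = pd.concat(
            [t.assign(patient_id=pid) for pid, t in classified.items()]
        )
        _write_tsv(origin_all, outdir / "origin_table.tsv")
        venns = {pid: venn_counts(classified_gene[pid]) for pid in classified_gene}
        (outdir / "venn_counts.json").write_text(
            json.dumps(venns, indent=2, sort_keys=True) + "\n"
        )
        rows = []
        for pid, table in classified.items():
            for cls in ("shared_somatic", "tumor_private", "normal_private",
                        "germline_all"):
                for tissue in ("blood", "normal", "tumor"):
                    s = vaf_summary(table, cls, tissue)
                    if s.n:
                        rows.append({"patient_id": pid, "origin_class": cls,
                                     "tissue": tissue, "n": s.n, "min": s.min,
                                     "max": s.max, "median": s.median, "iqr": s.iqr})
        _write_tsv(pd.DataFrame(rows), outdir / "vaf_summaries.tsv", index=False)
        pooled = pd.concat(classified.values())
        ratio = shared_somatic_vaf_ratio(pooled)
        summary["shared_somatic_vaf_ratio"] = {
            "mean": ratio.mean, "min": ratio.min, "max": ratio.max,
            "n": int(len(ratio.ratios)),
        }
        pooled_summary = vaf_summary(pooled, "shared_somatic", "normal")
        if pooled_summary.n:
            summary["normal_shared_somatic_vaf"] = {
                "n": pooled_summary.n, "median": pooled_summary.median,
                "iqr": pooled_summary.iqr, "min": pooled_summary.min,
                "max": pooled_summary.max,
            }
        log.info("classified %d patients", len(classified))

    # ---- gene stats -----------------------------------------------------
    somatic = ("shared_somatic", "tumor_private", "normal_private")
    if "genestats" in stages:
        try:
            mats = {
                "blood": gene_stats.build_gene_matrix(classified, "blood"),
                "normal": gene_stats.build_gene_matrix(
                    classified, "normal", somatic),
                "tumor": gene_stats.build_gene_matrix(
                    classified, "tumor", somatic),
            }
            for tissue, mat in mats.items():
                _write_tsv(mat, outdir / f"gene_matrix_{tissue}.tsv")
            for a, b in (("blood", "normal"), ("blood", "tumor"),
                         ("normal", "tumor")):
                res = gene_stats.fisher_gene_test(mats[a], mats[b])
                _write_tsv(res, outdir / f"diffmut_{a}_vs_{b}.tsv")
                summary[f"n_significant_{a}_vs_{b}"] = int((res["q"] < 0.05).sum())
            if mats["tumor"].shape[1]:
                _write_tsv(gene_stats.top_frequent_genes(mats["tumor"], 10),
                           outdir / "top_genes_tumor.tsv", index=False)
            ages = [p.age for p in analysis_patients]
            if all(a is not None for a in ages) and cohort is not None:
                lengths = cohort.genes.set_index("gene")["length_bp"]
                burdens = []
                for p in analysis_patients:
                    n_som = int(
                        classified[p.patient_id]["origin_class"].isin(somatic).sum()
                    )
                    burdens.append(
                        gene_stats.mutation_burden(n_som, float(lengths.sum()))
                    )
                corr = gene_stats.burden_age_correlation(burdens, ages)
                summary["burden_age_pearson"] = {
                    "r": corr.r, "p": corr.p, "n": corr.n, "defined": corr.defined,
                }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("genestats", str(exc)) from exc
        log.info("gene statistics written")

    # ---- pathways -------------------------------------------------------
    if "pathways" in stages:
        try:
            if config.gene_sets:
                pw_catalog = read_gene_sets(config.gene_sets)
            else:
                gene_universe = sorted(
                    set().union(*(set(t["gene"]) for t in classified.values()))
                )
                pw_catalog = synthetic_pathway_catalog(
                    gene_universe, seed=config.seed)
            alt = pathway_analysis.pathway_alteration_matrix(
                classified, pw_catalog, somatic)
            _write_tsv(alt, outdir / "pathway_alterations.tsv")
            for definition in ("A", "B"):
                contrib = pathway_analysis.germline_somatic_contribution(
                    classified, pw_catalog, definition)
                _write_tsv(contrib, outdir / f"contribution_{definition}.tsv")
            mats = {
                "blood": gene_stats.build_gene_matrix(classified, "blood"),
                "normal": gene_stats.build_gene_matrix(classified, "normal"),
                "tumor": gene_stats.build_gene_matrix(classified, "tumor"),
            }
            for a, b in (("blood", "normal"), ("blood", "tumor"),
                         ("normal", "tumor")):
                ranked = pathway_analysis.rank_genes_log_or(mats[a], mats[b])
                gsea = pathway_analysis.gsea_preranked(
                    ranked, pw_catalog, weight_p=config.gsea_weight_p,
                    n_perm=config.gsea_n_perm, seed=config.seed)
                _write_tsv(gsea, outdir / f"gsea_{a}_vs_{b}.tsv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("pathways", str(exc)) from exc
        log.info("pathway analysis written")

    # ---- signatures -----------------------------------------------------
    if "signatures" in stages:
        try:
            if cohort is None:
                raise PipelineError(
                    "signatures",
                    "signature analysis needs a reference sequence; "
                    "run in simulate mode or extend the config",
                )
            reference = {"1": cohort.reference}
            all_samples = [p.sample(t) for p in analysis_patients
                           for t in ("blood", "normal", "tumor")]
            sbs, skipped = signatures.build_sbs_matrix(all_samples, reference)
            _write_tsv(sbs, outdir / "sbs_matrix.tsv")
            if catalog is None:
                raise PipelineError("signatures", "no signature catalog available")
            exposures = signatures.refit_signatures(sbs, catalog)
            _write_tsv(exposures.fractions, outdir / "exposures.tsv")
            groups = {
                t: [f"{p.patient_id}_{t}" for p in analysis_patients]
                for t in ("blood", "normal", "tumor")
            }
            contrib = signatures.signature_percent_contribution(exposures, groups)
            _write_tsv(contrib, outdir / "signature_contribution.tsv", index=False)
            summary["signature_percent"] = {
                row.group + ":" + row.signature: round(row.percent, 2)
                for row in contrib.itertuples()
            }
            frac_n = exposures.fractions.loc[groups["normal"]].to_numpy()
            frac_t = exposures.fractions.loc[groups["tumor"]].to_numpy()
            wil = signatures.wilcoxon_signed_rank(frac_n.ravel(), frac_t.ravel())
            summary["wilcoxon_normal_vs_tumor"] = {
                "statistic": wil.statistic, "p": wil.p, "n": wil.n,
                "testable": wil.testable,
            }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("signatures", str(exc)) from exc
        log.info("signature analysis written")

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
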