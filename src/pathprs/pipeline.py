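"""End-to-end orchestration: simulate/ingest -> QC -> annotate -> score -> associate.

Every stage persists its outputs under the run directory, and a run report
records the parameters, seed and per-stage row counts so a run is fully
auditable.  With identical config and seed, every output file is
byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .association import GridSpec, run_association_grid
from .io_formats import (
    PhenotypeTable,
    RegionSpec,
    read_gene_sets,
    read_genotypes,
    read_phenotype_table,
    read_summary_stats,
    write_association_table,
)
from .pathway_annotation import (
    build_pathway_snp_sets,
    map_snps_to_genes,
    pathway_snp_count_table,
)
from .prs_core import (
    APOE_MODES,
    ClumpSpec,
    build_score_matrix,
    harmonize_weights,
    write_score_table,
)
from .qc import QcThresholds, compute_pcs, filter_samples, filter_variants, remove_roi_outliers
from .synthetic_data import SimConfig, roi_families, write_simulation

logger = logging.getLogger("pathprs")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class InputPaths:
    genotypes: str
    sumstats: str
    genes_bed: str
    pathways_gmt: str
    phenotypes: str
    genotype_format: str = "vcf"
    roi_columns: tuple[str, ...] = ()
    covariate_columns: tuple[str, ...] = ()
    roi_families: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Everything one run needs; built in code or loaded from YAML."""

    out_dir: str
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: InputPaths | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    clump: ClumpSpec = field(default_factory=ClumpSpec)
    apoe_region: RegionSpec | None = None
    gene_window_kb: float = 0.0
    apoe_modes: tuple[str, ...] = APOE_MODES
    clump_scope: str = "pathway"
    standardize_scores: bool = True
    fdr_scope: str = "family"
    n_pcs: int = 0  # extra PCs appended as covariates when none are present

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {
            "out_dir": raw["out_dir"],
            "seed": int(raw.get("seed", 0)),
        }
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", kwargs["seed"])
            kwargs["simulate"] = _sim_config_from_dict(sim)
        if "inputs" in raw:
            inp = dict(raw["inputs"])
            if "roi_families" in inp:
                inp["roi_families"] = {
                    k: tuple(v) for k, v in inp["roi_families"].items()
                }
            for key in ("roi_columns", "covariate_columns"):
                if key in inp:
                    inp[key] = tuple(inp[key])
            kwargs["inputs"] = InputPaths(**inp)
        if "qc" in raw:
            kwargs["qc"] = QcThresholds(**raw["qc"])
        if "clump" in raw:
            c = dict(raw["clump"])
            if "p_thresholds" in c:
                c["p_thresholds"] = tuple(float(x) for x in c["p_thresholds"])
            kwargs["clump"] = ClumpSpec(**c)
        if "apoe_region" in raw:
            kwargs["apoe_region"] = RegionSpec(**raw["apoe_region"])
        for key in (
            "gene_window_kb",
            "clump_scope",
            "standardize_scores",
            "fdr_scope",
            "n_pcs",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "apoe_modes" in raw:
            kwargs["apoe_modes"] = tuple(raw["apoe_modes"])
        return cls(**kwargs)


def _sim_config_from_dict(raw: dict) -> SimConfig:
    from .synthetic_data import PathwaySimSpec, RoiSimSpec

    raw = dict(raw)
    if "pathways" in raw:
        raw["pathways"] = tuple(
            PathwaySimSpec(
                pathway_id=p["pathway_id"],
                description=p.get("description", p["pathway_id"]),
                gene_indices=tuple(p["gene_indices"]),
                effect_mean=float(p.get("effect_mean", 0.05)),
                effect_sd=float(p.get("effect_sd", 0.015)),
            )
            for p in raw["pathways"]
        )
    if "rois" in raw:
        raw["rois"] = tuple(RoiSimSpec(**r) for r in raw["rois"])
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    return SimConfig(**raw)


def _config_echo(cfg: PipelineConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (str, int, float, bool)) or obj is None:
            return obj
        return str(obj)

    return clean(cfg)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the run report (also written as JSON).

    Stage order: simulate/ingest, QC (samples, variants, ROI outliers,
    optional PCs), pathway annotation, harmonize + score, association.
    Any stage error aborts with the stage name; partial outputs persist.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    report: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "parameters": _config_echo(cfg),
        "stages": {},
    }

    # --- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if cfg.simulate is not None:
            sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
            paths = write_simulation(sim_cfg, out / "inputs")
            genotype_format = "vcf"
            roi_fams = roi_families(sim_cfg)
            roi_cols = [r.name for r in sim_cfg.rois]
            cov_cols = ["age", "sex", "icv", "site", "array"] + [
                f"PC{i + 1}" for i in range(sim_cfg.n_pcs)
            ]
            if cfg.apoe_region is None:
                from .synthetic_data import simulate_annotation

                _, _, region = simulate_annotation(sim_cfg)
                cfg = dataclasses.replace(cfg, apoe_region=region)
        else:
            inp = cfg.inputs
            paths = {
                "genotypes": inp.genotypes,
                "sumstats": inp.sumstats,
                "genes_bed": inp.genes_bed,
                "pathways_gmt": inp.pathways_gmt,
                "phenotypes": inp.phenotypes,
            }
            genotype_format = inp.genotype_format
            roi_fams = dict(inp.roi_families)
            roi_cols = list(inp.roi_columns)
            cov_cols = list(inp.covariate_columns)
        if cfg.apoe_region is None:
            raise ValueError("apoe_region must be set for non-simulated inputs")
        G = read_genotypes(paths["genotypes"], fmt=genotype_format)
        stats_records, stats_report = read_summary_stats(paths["sumstats"])
        genes, pathways, unresolved = read_gene_sets(
            paths["pathways_gmt"], paths["genes_bed"]
        )
        ph = read_phenotype_table(paths["phenotypes"], roi_cols, cov_cols)
        report["stages"][stage] = {
            "n_samples": G.n_samples,
            "n_variants": G.n_variants,
            "n_sumstats": len(stats_records),
            "n_sumstats_rejected": stats_report.n_rejected,
            "n_genes": len(genes),
            "n_pathways": len(pathways),
            "unresolved_genes": {k: sorted(v) for k, v in unresolved.items()},
        }
        logger.info("stage=%s samples=%d variants=%d", stage, G.n_samples, G.n_variants)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: qc ---------------------------------------------------------
    stage = "qc"
    try:
        G, sample_report = filter_samples(G, cfg.qc)
        G, variant_report = filter_variants(G, cfg.qc)
        if G.n_variants == 0:
            raise ValueError("no variants survive QC")
        ph, roi_report = remove_roi_outliers(ph, cfg.qc)
        if cfg.n_pcs > 0 and not any(c.startswith("PC") for c in ph.covariate_columns):
            pcs = compute_pcs(G, cfg.n_pcs)
            ph = PhenotypeTable(
                data=ph.data.join(pcs, how="left"),
                roi_columns=ph.roi_columns,
                covariate_columns=[*ph.covariate_columns, *pcs.columns],
            )
        qc_counts = {
            "samples_removed": sample_report.n_removed,
            "variants_removed_call_rate": len(variant_report.removed_call_rate),
            "variants_removed_maf": len(variant_report.removed_maf),
            "variants_removed_hwe": len(variant_report.removed_hwe),
            "roi_values_removed": roi_report.n_removed,
            "n_samples_after": G.n_samples,
            "n_variants_after": G.n_variants,
        }
        report["stages"][stage] = qc_counts
        _write_qc_report(qc_counts, out / "qc_report.tsv")
        logger.info("stage=%s %s", stage, qc_counts)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: annotate ---------------------------------------------------
    stage = "annotate"
    try:
        snp_map = map_snps_to_genes(G.variants, genes, window_kb=cfg.gene_window_kb)
        sumstat_ids = {r.variant_id for r in stats_records}
        snp_sets = build_pathway_snp_sets(
            pathways, snp_map, sumstat_ids, cfg.apoe_region, G.variants
        )
        counts = pathway_snp_count_table(snp_sets)
        counts.to_csv(out / "pathway_snp_counts.tsv", sep="\t", index=False)
        report["stages"][stage] = {
            "n_pathways": len(snp_sets),
            "snp_counts": dict(zip(counts["pathway_id"], counts["n_snps"].astype(int))),
        }
        logger.info("stage=%s pathways=%d", stage, len(snp_sets))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: score ------------------------------------------------------
    stage = "score"
    try:
        weights, harm_report = harmonize_weights(stats_records, G)
        table = build_score_matrix(
            G,
            weights,
            snp_sets,
            cfg.clump,
            cfg.apoe_region,
            modes=cfg.apoe_modes,
            clump_scope=cfg.clump_scope,
        )
        write_score_table(table, out / "scores.tsv", out / "score_n_snps.tsv")
        report["stages"][stage] = {
            "n_weights_ok": harm_report.n_ok,
            "n_unmatched": harm_report.n_unmatched,
            "n_ambiguous_dropped": harm_report.n_ambiguous,
            "n_mismatch_dropped": harm_report.n_mismatch,
            "n_score_columns": table.scores.shape[1],
        }
        logger.info("stage=%s columns=%d", stage, table.scores.shape[1])
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: associate --------------------------------------------------
    stage = "associate"
    try:
        grid = GridSpec(roi_families=roi_fams, fdr_scope=cfg.fdr_scope)
        assoc = run_association_grid(
            table, ph, grid, standardize_scores=cfg.standardize_scores
        )
        write_association_table(assoc, out / "associations.tsv")
        report["stages"][stage] = {
            "n_cells": len(assoc),
            "n_estimable": int(assoc["estimable"].sum()),
            "n_nominal": int((assoc["p"] < 0.05).sum()),
            "n_fdr_significant": int((assoc["q"] < 0.05).sum()),
        }
        logger.info("stage=%s cells=%d", stage, len(assoc))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _write_qc_report(counts: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")


def _setup_logging(log_path) -> None:
    # no timestamps: log files must be byte-identical across reruns
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
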