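"""Synthetic discovery + target cohorts with planted pathway effects.

Individual-level genotype/imaging cohorts of the kind this pipeline targets
are access-restricted, so every stage is exercised on simulated data with
the statistical structure the analysis assumes:

* LD-structured diploid genotypes — haplotypes per block are drawn from a
  latent exchangeable-correlation Gaussian thresholded at each variant's
  MAF quantile; dosage is the sum of two independent haplotypes; blocks
  are independent;
* a discovery GWAS — an independent cohort from the same genotype law with
  a quantitative liability that is linear in planted per-pathway SNP
  effects; per-SNP marginal OLS yields betas and P-values;
* overlapping pathway gene sets tiling the simulated chromosome, with one
  "immune-response analogue" pathway that excludes the APOE-like region;
* ROI phenotypes linear in the linked pathway's true dosage burden plus
  covariates (age, sex, ICV, site, array, ancestry PCs) plus Gaussian
  noise, with configurable effect direction per ROI (emulating
  opposite-direction findings in younger vs older cohorts).

Everything is reproducible from the config seed: each artifact is a pure
function of (config, seed), including the bytes of the emitted files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import qc
from .io_formats import (
    GeneRecord,
    GenotypeMatrix,
    PathwayDefinition,
    PhenotypeTable,
    RegionSpec,
    SummaryStatRecord,
    write_bed_genes,
    write_gmt,
    write_phenotype_table,
    write_summary_stats,
    write_vcf,
)

_ALLELE_PAIRS = [  # non-palindromic ref/alt pairs only
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]


class SimConfigError(ValueError):
    """The simulation config is internally inconsistent."""


@dataclass(frozen=True)
class PathwaySimSpec:
    """One simulated pathway: its genes and planted per-SNP effect law."""

    pathway_id: str
    description: str
    gene_indices: tuple[int, ...]
    effect_mean: float = 0.05
    effect_sd: float = 0.015


@dataclass(frozen=True)
class RoiSimSpec:
    """One simulated ROI: family, linked pathway, effect direction and size.

    ``effect_size`` is the standardized effect: the coefficient of the
    z-scored true pathway burden in the ROI's generating equation (noise SD
    is ``noise_sd``, 1 by default, so it is approximately the standardized
    regression slope).
    """

    name: str
    family: str  # cortical | subcortical
    linked_pathway: str | None = None
    sign: int = -1
    effect_size: float = 0.15
    base: float = 10.0


def default_pathways() -> tuple[PathwaySimSpec, ...]:
    """Three overlapping pathways; the immune analogue avoids the APOE gene."""
    return (
        PathwaySimSpec("PW_LIPID", "protein-lipid complex analogue", (0, 1, 2, 3, 4, 19)),
        PathwaySimSpec("PW_TAU", "tau protein binding analogue", (4, 5, 6, 7, 19)),
        PathwaySimSpec("PW_IMMUNE", "immune response analogue", (10, 11, 12, 13, 14)),
    )


def default_rois() -> tuple[RoiSimSpec, ...]:
    return (
        RoiSimSpec("middletemporal_thickness", "cortical", "PW_LIPID", sign=-1, base=2.5),
        RoiSimSpec("posteriorcingulate_thickness", "cortical", "PW_IMMUNE", sign=-1, base=2.5),
        RoiSimSpec("superiorparietal_thickness", "cortical", None, base=2.5),
        RoiSimSpec("entorhinal_thickness", "cortical", None, base=2.5),
        RoiSimSpec("hippocampus_older_volume", "subcortical", "PW_TAU", sign=-1, base=50.0),
        RoiSimSpec("hippocampus_younger_volume", "subcortical", "PW_TAU", sign=+1, base=50.0),
        RoiSimSpec("caudate_volume", "subcortical", None, base=50.0),
        RoiSimSpec("amygdala_volume", "subcortical", None, base=50.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic study.

    Defaults describe a desk-scale study: a 2 000-sample target cohort and
    an 8 000-sample discovery cohort over 500 SNPs in 25 LD blocks of 20,
    20 genes tiling the chromosome, three overlapping pathways with planted
    effects, and an APOE-like large-effect locus in the last gene.
    """

    seed: int = 0
    n_target: int = 2000
    n_discovery: int = 8000
    n_snps: int = 500
    block_size: int = 20
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    n_genes: int = 20
    pathways: tuple[PathwaySimSpec, ...] = field(default_factory=default_pathways)
    rois: tuple[RoiSimSpec, ...] = field(default_factory=default_rois)
    apoe_gene_index: int | None = 19
    apoe_effect: float = 0.3
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.1, "sex": 0.1, "icv": 0.3}
    )
    noise_sd: float = 1.0
    discovery_noise_sd: float = 1.0
    n_pcs: int = 5
    chrom: str = "1"
    bp_start: int = 10_001
    bp_spacing: int = 5_000

    def __post_init__(self) -> None:
        if self.n_snps % self.block_size:
            raise SimConfigError("block_size must divide n_snps")
        if self.n_snps % self.n_genes:
            raise SimConfigError("n_genes must divide n_snps (gene tiling)")
        if not (0.0 <= self.within_block_r < 1.0):
            raise SimConfigError("within_block_r must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimConfigError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0 or self.discovery_noise_sd <= 0:
            raise SimConfigError("noise SDs must be > 0")
        for pw in self.pathways:
            bad = [g for g in pw.gene_indices if not (0 <= g < self.n_genes)]
            if bad:
                raise SimConfigError(
                    f"pathway {pw.pathway_id} references nonexistent gene indices {bad}"
                )
        ids = [pw.pathway_id for pw in self.pathways]
        if len(set(ids)) != len(ids):
            raise SimConfigError("duplicate pathway_id in config")
        by_id = {pw.pathway_id: pw for pw in self.pathways}
        for roi in self.rois:
            if roi.linked_pathway is None:
                continue
            if roi.linked_pathway not in by_id:
                raise SimConfigError(
                    f"ROI {roi.name} linked to unknown pathway {roi.linked_pathway}"
                )
            if not by_id[roi.linked_pathway].gene_indices:
                raise SimConfigError(
                    f"ROI {roi.name} linked to empty pathway {roi.linked_pathway}"
                )

    @property
    def snps_per_gene(self) -> int:
        return self.n_snps // self.n_genes


# ---------------------------------------------------------------------------
# the generative law shared by target and discovery cohorts
# ---------------------------------------------------------------------------


@dataclass
class _SimLaw:
    mafs: np.ndarray  # (n_snps,)
    thresholds: np.ndarray  # latent-Gaussian quantiles of the MAFs
    positions: np.ndarray
    variant_ids: list[str]
    alleles: list[tuple[str, str]]  # (ref, alt)
    effects_by_pathway: dict[str, np.ndarray]  # standardized per-SNP effects
    apoe_effect_vec: np.ndarray
    total_effects: np.ndarray


def _rng_for(cfg: SimConfig, slot: int) -> np.random.Generator:
    kids = np.random.SeedSequence(cfg.seed).spawn(4)
    return np.random.default_rng(kids[slot])


def gene_snp_indices(cfg: SimConfig, gene_index: int) -> np.ndarray:
    spg = cfg.snps_per_gene
    return np.arange(gene_index * spg, (gene_index + 1) * spg)


def derive_law(cfg: SimConfig) -> _SimLaw:
    """Draw the study-level quantities (MAFs, alleles, planted effects)."""
    rng = _rng_for(cfg, 0)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_snps)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), cfg.n_snps)
    alleles = [_ALLELE_PAIRS[i] for i in pair_idx]
    positions = cfg.bp_start + np.arange(cfg.n_snps) * cfg.bp_spacing
    variant_ids = [f"rs{i + 1:05d}" for i in range(cfg.n_snps)]
    effects_by_pathway = {}
    for pw in cfg.pathways:
        idx = np.concatenate([gene_snp_indices(cfg, g) for g in pw.gene_indices])
        vec = np.zeros(cfg.n_snps)
        vec[idx] = rng.normal(pw.effect_mean, pw.effect_sd, idx.size)
        effects_by_pathway[pw.pathway_id] = vec
    apoe_vec = np.zeros(cfg.n_snps)
    if cfg.apoe_gene_index is not None and cfg.apoe_effect:
        idx = gene_snp_indices(cfg, cfg.apoe_gene_index)
        apoe_vec[idx[len(idx) // 2]] = cfg.apoe_effect
    total = apoe_vec + sum(effects_by_pathway.values()) if effects_by_pathway else apoe_vec
    return _SimLaw(
        mafs=mafs,
        thresholds=stats.norm.ppf(mafs),
        positions=positions,
        variant_ids=variant_ids,
        alleles=alleles,
        effects_by_pathway=effects_by_pathway,
        apoe_effect_vec=apoe_vec,
        total_effects=total,
    )


def _sample_dosages(
    cfg: SimConfig, law: _SimLaw, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Diploid dosages for n individuals under the block-LD law (no missing)."""
    nb = cfg.n_snps // cfg.block_size
    r = cfg.within_block_r
    block_of = np.repeat(np.arange(nb), cfg.block_size)
    # float32 + in-place ops: halves the memory traffic of the big draws
    sq_r = np.float32(np.sqrt(r))
    sq_1r = np.float32(np.sqrt(1.0 - r))
    thresh = law.thresholds.astype(np.float32)
    dosage = np.zeros((n, cfg.n_snps), dtype=np.float32)
    hap_u = []
    for _ in range(2):
        u = rng.standard_normal((n, nb), dtype=np.float32)
        z = rng.standard_normal((n, cfg.n_snps), dtype=np.float32)
        z *= sq_1r
        z += sq_r * u[:, block_of]
        dosage += z < thresh
        hap_u.append(u)
    # resample monomorphic columns (fresh idiosyncratic noise, same block factor)
    for _ in range(10):
        mono = np.ptp(dosage, axis=0) == 0
        if not mono.any():
            break
        cols = np.nonzero(mono)[0]
        dosage[:, cols] = 0.0
        for u in hap_u:
            z = rng.standard_normal((n, cols.size), dtype=np.float32)
            z *= sq_1r
            z += sq_r * u[:, block_of[cols]]
            dosage[:, cols] += z < thresh[cols]
    else:
        raise SimConfigError("could not draw polymorphic genotypes; MAF too extreme")
    return dosage


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Target-cohort genotype matrix; reproducible from the config seed."""
    law = derive_law(cfg)
    rng = _rng_for(cfg, 1)
    dosage = _sample_dosages(cfg, law, cfg.n_target, rng).astype(np.float64)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan
    variants = pd.DataFrame(
        {
            "variant_id": law.variant_ids,
            "chrom": cfg.chrom,
            "bp": law.positions,
            "ref": [a[0] for a in law.alleles],
            "alt": [a[1] for a in law.alleles],
        }
    )
    sample_ids = [f"T{i + 1:05d}" for i in range(cfg.n_target)]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosage=dosage)


def simulate_annotation(
    cfg: SimConfig,
) -> tuple[list[GeneRecord], list[PathwayDefinition], RegionSpec | None]:
    """Genes tiling the chromosome, pathway GMT sets, and the APOE-like region."""
    genes = []
    for g in range(cfg.n_genes):
        idx = gene_snp_indices(cfg, g)
        law_positions = cfg.bp_start + idx * cfg.bp_spacing
        genes.append(
            GeneRecord(
                gene_id=f"GENE{g:03d}",
                chrom=cfg.chrom,
                start_bp=int(law_positions[0]),
                end_bp=int(law_positions[-1]),
            )
        )
    pathways = [
        PathwayDefinition(
            pathway_id=pw.pathway_id,
            description=pw.description,
            gene_ids=frozenset(f"GENE{g:03d}" for g in pw.gene_indices),
        )
        for pw in cfg.pathways
    ]
    region = None
    if cfg.apoe_gene_index is not None:
        g = genes[cfg.apoe_gene_index]
        region = RegionSpec(chrom=g.chrom, start_bp=g.start_bp, end_bp=g.end_bp)
    return genes, pathways, region


def simulate_discovery_sumstats(cfg: SimConfig) -> list[SummaryStatRecord]:
    """Marginal per-SNP OLS of a quantitative liability in a fresh cohort.

    Liability = sum over SNPs of planted standardized effect x z-scored
    dosage + Gaussian noise.  Betas are reported per alt-allele copy on the
    raw dosage scale with two-sided t-test P-values.
    """
    law = derive_law(cfg)
    rng = _rng_for(cfg, 2)
    G = _sample_dosages(cfg, law, cfg.n_discovery, rng)  # float32, no missing
    n = cfg.n_discovery
    mean = G.mean(axis=0, dtype=np.float64)
    var = np.einsum("ij,ij->j", G, G, optimize=True).astype(np.float64) / n - mean**2
    sd = np.sqrt(var)
    # liability on standardized dosages without materializing the Z matrix
    w = law.total_effects / sd
    y = G @ w.astype(np.float32) - float(mean @ w)
    y = y.astype(np.float64) + rng.standard_normal(n) * cfg.discovery_noise_sd
    yc = y - y.mean()
    sxx = var * n
    sxy = (G.T @ yc.astype(np.float32)).astype(np.float64)
    beta = sxy / sxx
    syy = float((yc**2).sum())
    sigma2 = np.maximum(syy - beta * sxy, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df=n - 2), np.finfo(float).tiny, 1.0)
    maf = np.minimum(mean / 2.0, 1.0 - mean / 2.0)
    return [
        SummaryStatRecord(
            variant_id=law.variant_ids[j],
            chrom=cfg.chrom,
            bp=int(law.positions[j]),
            a1=law.alleles[j][1],  # effect allele = alt
            a2=law.alleles[j][0],
            beta=float(beta[j]),
            p=float(p[j]),
            maf=float(maf[j]),
        )
        for j in range(cfg.n_snps)
    ]


def simulate_target_phenotypes(G: GenotypeMatrix, cfg: SimConfig) -> PhenotypeTable:
    """ROI measures + covariates for the target cohort.

    Each linked ROI is ``base + sign * effect_size * z(burden) +
    covariate effects + N(0, noise_sd)`` where the burden is the linked
    pathway's planted-effect-weighted dosage sum; unlinked ROIs are pure
    covariates + noise.  Ancestry PCs are computed from ``G`` itself (the
    same circularity the real pipeline has), so they enter both the
    generating equation's covariate set and the downstream adjustment.
    """
    if G.n_samples != cfg.n_target:
        raise SimConfigError("genotype matrix does not match config n_target")
    law = derive_law(cfg)
    rng = _rng_for(cfg, 3)
    n = G.n_samples
    age = rng.normal(55.0, 8.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    icv = rng.normal(1.5e6, 1.5e5, n)
    site = np.array(["site1", "site2", "site3"])[rng.integers(0, 3, n)]
    array = np.array(["arrayA", "arrayB"])[rng.integers(0, 2, n)]
    pcs = qc.compute_pcs(G, cfg.n_pcs) if cfg.n_pcs > 0 else None

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    cov_term = np.zeros(n)
    numeric = {"age": age, "sex": sex, "icv": icv}
    for name, eff in cfg.covariate_effects.items():
        if name not in numeric:
            raise SimConfigError(f"covariate_effects references unknown {name!r}")
        cov_term += eff * z(numeric[name])

    dose = G.dosage.copy()
    col_mean = np.nanmean(dose, axis=0)
    nanmask = np.isnan(dose)
    dose[nanmask] = np.take(col_mean, np.nonzero(nanmask)[1])

    data = {"age": age, "sex": sex, "icv": icv, "site": site, "array": array}
    if pcs is not None:
        for c in pcs.columns:
            data[c] = pcs[c].to_numpy()
    roi_cols = []
    for roi in cfg.rois:
        genetic = np.zeros(n)
        if roi.linked_pathway is not None:
            effects = law.effects_by_pathway[roi.linked_pathway]
            if not np.any(effects != 0):
                burden = np.zeros(n)
            else:
                burden = dose @ effects
            pw = next(p for p in cfg.pathways if p.pathway_id == roi.linked_pathway)
            idx = np.concatenate([gene_snp_indices(cfg, g) for g in pw.gene_indices])
            if idx.size == 0:
                raise SimConfigError(f"ROI {roi.name} linked to empty pathway")
            genetic = roi.sign * roi.effect_size * z(burden)
        noise = rng.standard_normal(n) * cfg.noise_sd
        data[roi.name] = roi.base + genetic + cov_term + noise
        roi_cols.append(roi.name)
    df = pd.DataFrame(data, index=pd.Index(G.sample_ids, name="sample_id"))
    covariates = ["age", "sex", "icv", "site", "array"] + (
        list(pcs.columns) if pcs is not None else []
    )
    return PhenotypeTable(data=df, roi_columns=roi_cols, covariate_columns=covariates)


def roi_families(cfg: SimConfig) -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for roi in cfg.rois:
        fams.setdefault(roi.family, []).append(roi.name)
    return {k: tuple(v) for k, v in fams.items()}


def truth_dict(cfg: SimConfig) -> dict:
    """Planted effects and links, for recovery tests (written as truth.json)."""
    law = derive_law(cfg)
    nonzero = {
        pid: {
            law.variant_ids[j]: float(vec[j]) for j in np.nonzero(vec)[0]
        }
        for pid, vec in law.effects_by_pathway.items()
    }
    apoe = {
        law.variant_ids[j]: float(law.apoe_effect_vec[j])
        for j in np.nonzero(law.apoe_effect_vec)[0]
    }
    return {
        "seed": cfg.seed,
        "pathway_effects": nonzero,
        "apoe_effect": apoe,
        "roi_links": {
            r.name: {
                "family": r.family,
                "pathway": r.linked_pathway,
                "sign": r.sign,
                "effect_size": r.effect_size,
            }
            for r in cfg.rois
        },
    }


def write_simulation(cfg: SimConfig, out_dir) -> dict[str, str]:
    """Emit the full synthetic study as files; returns the path map.

    Files: ``genotypes.vcf``, ``sumstats.tsv``, ``genes.bed``,
    ``pathways.gmt``, ``phenotypes.tsv``, ``truth.json``.  Byte-identical
    across runs with the same config.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    G = simulate_genotypes(cfg)
    stats_records = simulate_discovery_sumstats(cfg)
    genes, pathways, region = simulate_annotation(cfg)
    ph = simulate_target_phenotypes(G, cfg)
    paths = {
        "genotypes": str(out / "genotypes.vcf"),
        "sumstats": str(out / "sumstats.tsv"),
        "genes_bed": str(out / "genes.bed"),
        "pathways_gmt": str(out / "pathways.gmt"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_vcf(G, paths["genotypes"])
    write_summary_stats(stats_records, paths["sumstats"])
    write_bed_genes(genes, paths["genes_bed"])
    write_gmt(pathways, paths["pathways_gmt"])
    write_phenotype_table(ph, paths["phenotypes"])
    truth = truth_dict(cfg)
    if region is not None:
        truth["apoe_region"] = {
            "chrom": region.chrom,
            "start_bp": region.start_bp,
            "end_bp": region.end_bp,
        }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# canned study conditions
# ---------------------------------------------------------------------------


def null_config(seed: int) -> SimConfig:
    """No planted effects anywhere: calibration / type-I error conditions."""
    pathways = tuple(
        replace(pw, effect_mean=0.0, effect_sd=0.0) for pw in default_pathways()
    )
    rois = tuple(replace(r, effect_size=0.0) for r in default_rois())
    return SimConfig(
        seed=seed,
        n_target=1000,
        n_snps=500,
        pathways=pathways,
        rois=rois,
        apoe_effect=0.0,
    )


def planted_config(seed: int, effect_size: float = 0.15, sign: int = -1) -> SimConfig:
    """One planted (pathway, ROI) pair among null ROIs: power conditions."""
    rois = (
        RoiSimSpec("hippocampus_volume", "subcortical", "PW_TAU", sign=sign,
                   effect_size=effect_size, base=50.0),
        RoiSimSpec("caudate_volume", "subcortical", None, base=50.0),
        RoiSimSpec("amygdala_volume", "subcortical", None, base=50.0),
        RoiSimSpec("accumbens_volume", "subcortical", None, base=50.0),
        RoiSimSpec("putamen_volume", "subcortical", None, base=50.0),
        RoiSimSpec("thalamus_volume", "subcortical", None, base=50.0),
    )
    return SimConfig(seed=seed, n_target=2000, rois=rois)


def sign_flip_config(seed: int, effect_size: float = 0.15) -> SimConfig:
    """Same pathway driving two ROIs with opposite directions."""
    rois = (
        RoiSimSpec("hippocampus_older_volume", "subcortical", "PW_TAU", sign=-1,
                   effect_size=effect_size, base=50.0),
        RoiSimSpec("hippocampus_younger_volume", "subcortical", "PW_TAU", sign=+1,
                   effect_size=effect_size, base=50.0),
        RoiSimSpec("caudate_volume", "subcortical", None, base=50.0),
        RoiSimSpec("amygdala_volume", "subcortical", None, base=50.0),
    )
    return SimConfig(seed=seed, n_target=2000, rois=rois)


def dense_weak_config(seed: int) -> SimConfig:
    """Many weak causal SNPs genome-wide: threshold-profile conditions.

    Per-SNP standardized effects are small and heterogeneous so discovery
    P-values spread across the whole threshold ladder; the single ROI
    tracks the total genome-wide burden.
    """
    pathways = (
        PathwaySimSpec(
            "PW_ALL", "all genes", tuple(range(20)), effect_mean=0.006, effect_sd=0.004
        ),
    )
    rois = (
        RoiSimSpec("hippocampus_volume", "subcortical", "PW_ALL", sign=-1,
                   effect_size=0.2, base=50.0),
    )
    return SimConfig(
        seed=seed,
        n_target=2000,
        n_discovery=4000,
        pathways=pathways,
        rois=rois,
        apoe_effect=0.0,
    )
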