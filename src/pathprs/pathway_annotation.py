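"""Resolve pathway gene sets to SNP sets matched to the discovery sample.

A variant belongs to a gene when its position falls inside the gene body
extended by an optional flanking window; a pathway's SNP set is the union
of its genes' SNPs intersected with the variants present in the discovery
summary statistics.  Pathways may overlap — shared genes contribute their
SNPs to every pathway containing them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneRecord, PathwayDefinition, RegionSpec


@dataclass
class PathwaySnpSet:
    """A pathway resolved to the SNPs its genes contain."""

    pathway_id: str
    description: str
    gene_ids: frozenset[str]
    snp_ids: frozenset[str]
    n_genes_resolved: int
    includes_apoe_region: bool


def map_snps_to_genes(
    variants: pd.DataFrame, genes: list[GeneRecord], window_kb: float = 0.0
) -> dict[str, set[str]]:
    """Map each variant to the genes whose (windowed) body contains it.

    ``variants`` needs columns ``variant_id, chrom, bp``.  A variant maps to
    a gene iff ``bp`` lies in ``[start - window, end + window]`` on the same
    chromosome; a variant may map to several genes.  Unmapped variants are
    absent from the returned dict.
    """
    if window_kb < 0:
        raise ValueError("window_kb must be >= 0")
    window = int(round(window_kb * 1000))
    mapping: dict[str, set[str]] = {}
    chroms = variants["chrom"].to_numpy()
    bps = variants["bp"].to_numpy()
    vids = variants["variant_id"].to_numpy()
    for gene in genes:
        hit = (
            (chroms == gene.chrom)
            & (bps >= gene.start_bp - window)
            & (bps <= gene.end_bp + window)
        )
        for vid in vids[hit]:
            mapping.setdefault(vid, set()).add(gene.gene_id)
    return mapping


def build_pathway_snp_sets(
    pathways: list[PathwayDefinition],
    snp_gene_map: dict[str, set[str]],
    sumstat_ids: set[str],
    apoe_region: RegionSpec | None,
    variants: pd.DataFrame,
) -> list[PathwaySnpSet]:
    """Resolve each pathway to its SNP set, matched to the discovery sample.

    The SNP set is the union over the pathway's genes of positionally
    mapped SNPs, intersected with ``sumstat_ids``.
    ``includes_apoe_region`` is true iff any SNP of the set lies inside
    ``apoe_region``.  Pathways resolving to zero SNPs are retained with a
    warning (their score columns are undefined downstream).
    """
    gene_to_snps: dict[str, set[str]] = {}
    for vid, gene_ids in snp_gene_map.items():
        if vid not in sumstat_ids:
            continue
        for gid in gene_ids:
            gene_to_snps.setdefault(gid, set()).add(vid)
    coords = variants.set_index("variant_id")[["chrom", "bp"]]
    out = []
    for pw in pathways:
        snps: set[str] = set()
        n_resolved = 0
        for gid in pw.gene_ids:
            gene_snps = gene_to_snps.get(gid)
            if gene_snps:
                n_resolved += 1
                snps |= gene_snps
        if not snps:
            warnings.warn(f"pathway {pw.pathway_id!r} resolved to 0 SNPs")
        in_apoe = False
        if apoe_region is not None and snps:
            sub = coords.loc[sorted(snps)]
            in_apoe = bool(
                np.any(
                    (sub["chrom"].to_numpy() == apoe_region.chrom)
                    & (sub["bp"].to_numpy() >= apoe_region.start_bp)
                    & (sub["bp"].to_numpy() <= apoe_region.end_bp)
                )
            )
        out.append(
            PathwaySnpSet(
                pathway_id=pw.pathway_id,
                description=pw.description,
                gene_ids=pw.gene_ids,
                snp_ids=frozenset(snps),
                n_genes_resolved=n_resolved,
                includes_apoe_region=in_apoe,
            )
        )
    return out


def pathway_snp_count_table(snp_sets: list[PathwaySnpSet]) -> pd.DataFrame:
    """Per-pathway counts: genes resolved, SNPs, APOE-region membership."""
    return pd.DataFrame(
        {
            "pathway_id": [s.pathway_id for s in snp_sets],
            "description": [s.description for s in snp_sets],
            "n_genes": [s.n_genes_resolved for s in snp_sets],
            "n_snps": [len(s.snp_ids) for s in snp_sets],
            "includes_apoe": ["Y" if s.includes_apoe_region else "N" for s in snp_sets],
        }
    )
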