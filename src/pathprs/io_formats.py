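"""Readers and writers for every on-disk format the pipeline touches.

Conventions used throughout the package:

* coordinates are 1-based and intervals are closed on both ends (BED's
  half-open 0-based starts are converted on read);
* the summary-statistic effect column is named ``BETA`` and is interpreted
  as the per-A1-allele effect on the discovery trait (odds ratios must be
  log-transformed upstream);
* the dosage-TSV dialect stores samples as rows and variants as columns,
  with a header row of variant IDs and ``NA`` for missing calls.

Readers validate strictly and never drop rows silently: every rejected row
is recorded with its row number in a :class:`ReadReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")


def _REPR_FLOAT(x) -> str:
    """Shortest round-trip decimal representation for table writers."""
    return repr(float(x))

SUMSTAT_REQUIRED_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "P")

#: fixed column set (and order) of the association output table
ASSOCIATION_COLUMNS = (
    "roi",
    "score_label",
    "threshold",
    "apoe_mode",
    "n",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "p",
    "q",
    "delta_r2_prs",
    "delta_r2_apoe",
    "beats_apoe",
)


class FormatError(ValueError):
    """A file violates its format contract (missing columns, duplicates...)."""


@dataclass
class ReadReport:
    """Accounting of accepted vs rejected rows for one read operation."""

    n_input: int = 0
    n_accepted: int = 0
    row_errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.row_errors)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStatRecord:
    """One discovery-GWAS variant: alleles, effect size and P-value.

    ``a1`` is the effect allele; ``beta`` is the per-A1-allele effect on the
    discovery trait (log-odds scale for a case-control discovery sample).
    """

    variant_id: str
    chrom: str
    bp: int
    a1: str
    a2: str
    beta: float
    p: float
    maf: float | None = None

    def validate(self) -> None:
        if self.bp < 1:
            raise ValueError(f"bp must be >= 1, got {self.bp}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if self.a1 == self.a2:
            raise ValueError(f"effect and other allele identical: {self.a1}")
        for allele in (self.a1, self.a2):
            if allele not in VALID_ALLELES:
                raise ValueError(f"allele {allele!r} is not a SNP allele")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class GeneRecord:
    """Gene body on 1-based closed coordinates."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start_bp} > end {self.end_bp}"
            )


@dataclass(frozen=True)
class PathwayDefinition:
    """A named gene set (e.g. one GO term)."""

    pathway_id: str
    description: str
    gene_ids: frozenset[str]


@dataclass(frozen=True)
class RegionSpec:
    """A genomic interval, closed on both ends (e.g. the APOE region)."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start_bp > end_bp")

    def contains(self, chrom: str, bp: int) -> bool:
        return chrom == self.chrom and self.start_bp <= bp <= self.end_bp


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant coordinates/alleles.

    ``dosage`` holds alt-allele counts (or dosages) in ``[0, 2]`` with
    ``NaN`` for missing calls; rows are samples, columns are variants.
    ``variants`` is a DataFrame with columns
    ``variant_id, chrom, bp, ref, alt`` sorted by ``(chrom, bp)``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage shape does not match sample/variant counts")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample IDs")
        vids = self.variants["variant_id"]
        if vids.duplicated().any():
            dups = vids[vids.duplicated()].tolist()
            raise FormatError(f"duplicate variant IDs: {dups[:5]}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosage, initial=0.0) < 0 or np.nanmax(
                self.dosage, initial=0.0
            ) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def is_sorted(self) -> bool:
        keys = list(zip(self.variants["chrom"], self.variants["bp"]))
        return all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))

    def sort_variants(self) -> "GenotypeMatrix":
        order = self.variants.sort_values(
            ["chrom", "bp"], kind="mergesort"
        ).index.to_numpy()
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[order].reset_index(drop=True),
            dosage=self.dosage[:, order],
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            variants=self.variants.copy(),
            dosage=self.dosage[keep, :],
        )

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep],
        )

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.dosage, axis=0) / 2.0

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return int(idx[0])


@dataclass
class PhenotypeTable:
    """ROI measures plus covariates, one row per sample.

    ``data`` is indexed by sample ID; ``roi_columns`` and
    ``covariate_columns`` name the respective column groups.
    """

    data: pd.DataFrame
    roi_columns: list[str]
    covariate_columns: list[str]

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample_id in phenotype table")
        missing = [
            c
            for c in [*self.roi_columns, *self.covariate_columns]
            if c not in self.data.columns
        ]
        if missing:
            raise FormatError(f"phenotype table missing declared columns: {missing}")

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(
            self.data.copy(), list(self.roi_columns), list(self.covariate_columns)
        )


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def read_summary_stats(path) -> tuple[list[SummaryStatRecord], ReadReport]:
    """Read tab-delimited GWAS summary statistics.

    Required columns: ``SNP CHR BP A1 A2 BETA P`` (``MAF`` optional).
    Rows failing validation are rejected and recorded in the report with
    their (1-based, data-row) numbers; accepted + rejected = input rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in SUMSTAT_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"summary statistics missing required column {col!r}")
    has_maf = "MAF" in df.columns
    records: list[SummaryStatRecord] = []
    report = ReadReport(n_input=len(df))
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec = SummaryStatRecord(
                variant_id=str(row.SNP),
                chrom=str(row.CHR),
                bp=int(row.BP),
                a1=str(row.A1).upper(),
                a2=str(row.A2).upper(),
                beta=float(row.BETA),
                p=float(row.P),
                maf=float(row.MAF) if has_maf and str(row.MAF) != "NA" else None,
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            report.row_errors.append((i, str(exc)))
            continue
        records.append(rec)
    report.n_accepted = len(records)
    return records, report


def write_summary_stats(records, path) -> None:
    rows = []
    any_maf = any(r.maf is not None for r in records)
    for r in records:
        row = {
            "SNP": r.variant_id,
            "CHR": r.chrom,
            "BP": r.bp,
            "A1": r.a1,
            "A2": r.a2,
            "BETA": repr(float(r.beta)),
            "P": repr(float(r.p)),
        }
        if any_maf:
            row["MAF"] = "NA" if r.maf is None else repr(float(r.maf))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path, fmt: str = "vcf", variants_path=None) -> GenotypeMatrix:
    """Read target genotypes from VCF (GT or DS) or dosage-TSV.

    Multi-allelic, non-SNP and mixed-ploidy VCF records are rejected with a
    warning and kept out of the matrix.  Variants are returned sorted by
    ``(chrom, bp)``; unsorted input triggers a notice.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path, variants_path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    try:
        vcf.get_header_type("DS")
        has_ds = True
    except KeyError:
        has_ds = False
    rows = []
    dosages = []
    for v in vcf:
        if len(v.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record at {v.CHROM}:{v.POS}")
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            warnings.warn(f"skipping non-SNP record at {v.CHROM}:{v.POS}")
            continue
        ds = v.format("DS") if has_ds else None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            gts = v.genotypes
            if any(len(g) != 3 for g in gts):
                warnings.warn(f"skipping mixed-ploidy record at {v.CHROM}:{v.POS}")
                continue
            col = np.array(
                [
                    np.nan if (g[0] < 0 or g[1] < 0) else float(g[0] > 0) + float(g[1] > 0)
                    for g in gts
                ]
            )
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{ref}:{alt}"
        rows.append((vid, str(v.CHROM), int(v.POS), ref, alt))
        dosages.append(col)
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "bp", "ref", "alt"]
    )
    dosage = (
        np.column_stack(dosages) if dosages else np.empty((len(sample_ids), 0))
    )
    G = GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosage=dosage)
    if not G.is_sorted():
        warnings.warn("VCF records not sorted by (chrom, bp); sorting")
        G = G.sort_variants()
    return G


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write hard genotypes as a minimal VCF 4.2 (GT field, ``./.`` missing).

    Dosages are rounded to the nearest integer genotype.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(G.variants["chrom"]):
            sub = G.variants[G.variants["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['bp'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, var in G.variants.iterrows():
            col = G.dosage[:, j]
            gts = [
                "./." if np.isnan(d) else gt_strings[int(round(d))] for d in col
            ]
            fh.write(
                f"{var['chrom']}\t{var['bp']}\t{var['variant_id']}\t{var['ref']}\t"
                f"{var['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_dosage_tsv(path, variants_path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip")
    sample_ids = [str(s) for s in df.index]
    variant_ids = [str(c) for c in df.columns]
    if variants_path is not None:
        variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
        variants = variants.set_index("variant_id").loc[variant_ids].reset_index()
    else:
        variants = _variants_from_ids(variant_ids)
    G = GenotypeMatrix(
        sample_ids=sample_ids, variants=variants, dosage=df.to_numpy(dtype=float)
    )
    if not G.is_sorted():
        warnings.warn("dosage-TSV variants not sorted by (chrom, bp); sorting")
        G = G.sort_variants()
    return G


def _variants_from_ids(variant_ids) -> pd.DataFrame:
    """Recover coordinates from ``chrom:bp:ref:alt`` IDs, else placeholders."""
    rows = []
    for i, vid in enumerate(variant_ids):
        parts = vid.split(":")
        if len(parts) == 4 and parts[1].isdigit():
            rows.append((vid, parts[0], int(parts[1]), parts[2], parts[3]))
        else:
            rows.append((vid, "0", i + 1, "N", "N"))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "bp", "ref", "alt"])


def write_dosage_tsv(G: GenotypeMatrix, path, variants_path=None) -> None:
    df = pd.DataFrame(
        G.dosage, index=pd.Index(G.sample_ids, name="sample_id"),
        columns=G.variants["variant_id"],
    )
    df.to_csv(path, sep="\t", na_rep="NA", float_format=_REPR_FLOAT)
    if variants_path is not None:
        G.variants.to_csv(variants_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_bed_genes(path) -> list[GeneRecord]:
    """Read gene bodies from BED (0-based half-open; converted to 1-based closed)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"BED line needs >= 4 fields: {line!r}")
            chrom, start, end, name = parts[:4]
            genes.append(
                GeneRecord(
                    gene_id=name, chrom=chrom, start_bp=int(start) + 1, end_bp=int(end)
                )
            )
    return genes


def write_bed_genes(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start_bp - 1}\t{g.end_bp}\t{g.gene_id}\n")


def read_gmt(path) -> list[PathwayDefinition]:
    """Read GMT gene sets: set-ID <TAB> description <TAB> member genes..."""
    pathways = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"GMT line needs >= 2 fields: {line!r}")
            pid, desc, genes = parts[0], parts[1], parts[2:]
            if pid in seen:
                raise FormatError(f"duplicate gene-set ID {pid!r}")
            seen.add(pid)
            if not genes:
                warnings.warn(f"gene set {pid!r} is empty; retained")
            pathways.append(
                PathwayDefinition(
                    pathway_id=pid, description=desc, gene_ids=frozenset(genes)
                )
            )
    return pathways


def write_gmt(pathways, path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            genes = "\t".join(sorted(p.gene_ids))
            fh.write(f"{p.pathway_id}\t{p.description}" + ("\t" + genes if genes else "") + "\n")


def read_gene_sets(
    gmt_path, bed_path
) -> tuple[list[GeneRecord], list[PathwayDefinition], dict[str, set[str]]]:
    """Read pathways (GMT) and resolve members against gene coordinates (BED).

    Genes named in the GMT but absent from the BED are reported in the
    returned ``unresolved`` map; each pathway keeps its remaining genes.
    """
    genes = read_bed_genes(bed_path)
    known = {g.gene_id for g in genes}
    raw = read_gmt(gmt_path)
    resolved = []
    unresolved: dict[str, set[str]] = {}
    for p in raw:
        missing = set(p.gene_ids) - known
        if missing:
            unresolved[p.pathway_id] = missing
        resolved.append(
            PathwayDefinition(
                pathway_id=p.pathway_id,
                description=p.description,
                gene_ids=frozenset(p.gene_ids & known),
            )
        )
    return genes, resolved, unresolved


# ---------------------------------------------------------------------------
# phenotype and association tables
# ---------------------------------------------------------------------------


def read_phenotype_table(path, roi_columns, covariate_columns) -> PhenotypeTable:
    """Read a TSV of ROI measures + covariates keyed by ``sample_id``.

    Declared ROI/covariate columns must be present (error names the missing
    column); non-numeric ROI cells become missing with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise FormatError("phenotype table missing 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicated sample_id in phenotype table")
    df = df.set_index("sample_id")
    for col in [*roi_columns, *covariate_columns]:
        if col not in df.columns:
            raise FormatError(f"phenotype table missing declared column {col!r}")
    for col in roi_columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} non-numeric value(s) in ROI {col!r} set to missing"
            )
        df[col] = coerced
    return PhenotypeTable(
        data=df, roi_columns=list(roi_columns), covariate_columns=list(covariate_columns)
    )


def write_phenotype_table(ph: PhenotypeTable, path) -> None:
    out = ph.data[[*ph.roi_columns, *ph.covariate_columns]].copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format=_REPR_FLOAT)


def write_association_table(df: pd.DataFrame, path) -> None:
    """Write association results with the fixed column set and order."""
    missing = [c for c in ASSOCIATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"association table missing columns: {missing}")
    df.loc[:, list(ASSOCIATION_COLUMNS)].to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format=_REPR_FLOAT
    )


def read_association_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    if tuple(df.columns) != ASSOCIATION_COLUMNS:
        raise FormatError(
            f"association table columns {tuple(df.columns)} != {ASSOCIATION_COLUMNS}"
        )
    return df
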