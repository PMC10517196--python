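"""Polygenic score computation: harmonization, selection, clumping, scoring.

The score of sample *i* is the weighted sum ``sum_j beta_j * dosage_ij``
over the index SNPs that survive selection.  Selection follows the
clumping-and-thresholding recipe: restrict to a pathway SNP set (for
pathway scores), mask the APOE region (include / exclude / only), keep
SNPs with discovery ``p <= pT``, then greedily LD-clump (ascending P,
removing neighbours with ``r^2 > r2_max`` within ``window_kb``).

LD is measured on the target cohort itself as the squared Pearson
correlation of dosage columns (pairwise-complete over non-missing calls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import _REPR_FLOAT, GenotypeMatrix, RegionSpec, SummaryStatRecord
from .pathway_annotation import PathwaySnpSet

GENOME_WIDE = "genome_wide"

APOE_MODES = ("with_apoe", "no_apoe", "apoe_only")

_PALINDROMIC = (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True)
class ClumpSpec:
    """Clumping + thresholding parameters.

    Defaults: ``r2_max`` 0.2, ``window_kb`` 500, eight P-value thresholds
    from 0.5 down to 1e-6 with 0.001 as the primary threshold.
    """

    r2_max: float = 0.2
    window_kb: float = 500.0
    p_thresholds: tuple[float, ...] = (0.5, 0.3, 0.1, 0.01, 0.001, 1e-4, 1e-5, 1e-6)
    primary_threshold: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_max < 1.0):
            raise ValueError("r2_max must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be > 0")
        if list(self.p_thresholds) != sorted(self.p_thresholds, reverse=True):
            raise ValueError("p_thresholds must be sorted decreasing")

    def all_thresholds(self) -> tuple[float, ...]:
        ts = set(self.p_thresholds) | {self.primary_threshold}
        return tuple(sorted(ts, reverse=True))


@dataclass(frozen=True)
class HarmonizedWeight:
    """A summary-stat weight oriented to the target's alt allele."""

    variant_index: int
    variant_id: str
    chrom: str
    bp: int
    p: float
    status: str  # ok | ambiguous_dropped | mismatch_dropped
    orientation: str | None = None  # same | flipped
    beta_alt: float | None = None


@dataclass
class HarmonizeReport:
    n_stats: int = 0
    n_ok: int = 0
    n_unmatched: int = 0
    n_ambiguous: int = 0
    n_mismatch: int = 0


def harmonize_weights(
    stats: list[SummaryStatRecord], G: GenotypeMatrix
) -> tuple[list[HarmonizedWeight], HarmonizeReport]:
    """Orient discovery effect sizes to the target's alt allele.

    Variants are matched by ``(chrom, bp)``.  ``A1/A2 = alt/ref`` keeps the
    sign (orientation ``same``); ``A1/A2 = ref/alt`` negates it
    (``flipped``).  Strand-ambiguous allele pairs (A/T, C/G) are dropped as
    ``ambiguous_dropped``; any other pair is ``mismatch_dropped``.  Several
    records at one target position are treated as a conflict and all
    dropped.
    """
    pos_to_idx: dict[tuple[str, int], int] = {
        (c, int(b)): j
        for j, (c, b) in enumerate(zip(G.variants["chrom"], G.variants["bp"]))
    }
    by_idx: dict[int, list[SummaryStatRecord]] = {}
    report = HarmonizeReport(n_stats=len(stats))
    for rec in stats:
        idx = pos_to_idx.get((rec.chrom, rec.bp))
        if idx is None:
            report.n_unmatched += 1
            continue
        by_idx.setdefault(idx, []).append(rec)
    out: list[HarmonizedWeight] = []
    for idx, recs in sorted(by_idx.items()):
        var = G.variants.iloc[idx]
        if len(recs) > 1:
            warnings.warn(
                f"{len(recs)} summary-stat records at {var['chrom']}:{var['bp']}; "
                "all dropped as conflicting"
            )
            for rec in recs:
                report.n_mismatch += 1
                out.append(_dropped(rec, idx, "mismatch_dropped"))
            continue
        rec = recs[0]
        if frozenset((rec.a1, rec.a2)) in _PALINDROMIC:
            report.n_ambiguous += 1
            out.append(_dropped(rec, idx, "ambiguous_dropped"))
            continue
        if rec.a1 == var["alt"] and rec.a2 == var["ref"]:
            orientation, beta_alt = "same", rec.beta
        elif rec.a1 == var["ref"] and rec.a2 == var["alt"]:
            orientation, beta_alt = "flipped", -rec.beta
        else:
            report.n_mismatch += 1
            out.append(_dropped(rec, idx, "mismatch_dropped"))
            continue
        report.n_ok += 1
        out.append(
            HarmonizedWeight(
                variant_index=idx,
                variant_id=rec.variant_id,
                chrom=rec.chrom,
                bp=rec.bp,
                p=rec.p,
                status="ok",
                orientation=orientation,
                beta_alt=beta_alt,
            )
        )
    return out, report


def _dropped(rec: SummaryStatRecord, idx: int, status: str) -> HarmonizedWeight:
    return HarmonizedWeight(
        variant_index=idx,
        variant_id=rec.variant_id,
        chrom=rec.chrom,
        bp=rec.bp,
        p=rec.p,
        status=status,
    )


def ok_weights(weights: list[HarmonizedWeight]) -> list[HarmonizedWeight]:
    return [w for w in weights if w.status == "ok"]


def threshold_by_p(weights: list[HarmonizedWeight], pT: float) -> list[HarmonizedWeight]:
    """Keep weights with ``p <= pT`` (boundary inclusive)."""
    kept = [w for w in ok_weights(weights) if w.p <= pT]
    if not kept:
        warnings.warn(f"no SNPs pass P-value threshold {pT}")
    return kept


def exclude_region(
    weights: list[HarmonizedWeight], region: RegionSpec, mode: str = "exclude"
) -> list[HarmonizedWeight]:
    """Drop (``exclude``) or keep only (``only``) SNPs inside a closed region."""
    if mode not in ("exclude", "only"):
        raise ValueError(f"mode must be 'exclude' or 'only', got {mode!r}")
    inside = [w for w in weights if region.contains(w.chrom, w.bp)]
    outside = [w for w in weights if not region.contains(w.chrom, w.bp)]
    return inside if mode == "only" else outside


def restrict_to_pathway(
    weights: list[HarmonizedWeight], ps: PathwaySnpSet
) -> list[HarmonizedWeight]:
    """Intersect the weight list with a pathway's SNP set."""
    kept = [w for w in weights if w.variant_id in ps.snp_ids]
    if not kept:
        warnings.warn(f"no weights overlap pathway {ps.pathway_id!r}")
    return kept


def pairwise_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of ``x`` against each column of ``Y``.

    Pairwise-complete over non-missing entries; pairs with fewer than two
    complete observations or zero variance get ``r^2 = 0``.
    """
    x = np.asarray(x, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    valid = ~np.isnan(x)[:, None] & ~np.isnan(Y)
    xv = np.where(valid, x[:, None], 0.0)
    yv = np.where(valid, Y, 0.0)
    n = valid.sum(axis=0)
    sx, sy = xv.sum(axis=0), yv.sum(axis=0)
    sxx, syy, sxy = (xv * xv).sum(axis=0), (yv * yv).sum(axis=0), (xv * yv).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / np.maximum(n, 1)
        vx = sxx - sx**2 / np.maximum(n, 1)
        vy = syy - sy**2 / np.maximum(n, 1)
        denom = vx * vy
        r2 = np.where((n >= 2) & (denom > 0), cov**2 / np.maximum(denom, 1e-300), 0.0)
    return r2


def ld_clump(
    weights: list[HarmonizedWeight], G: GenotypeMatrix, spec: ClumpSpec
) -> list[HarmonizedWeight]:
    """Greedy LD clumping of ok-status weights.

    Repeatedly take the unclumped SNP with the smallest P-value as the
    index (ties broken by smaller bp, then variant ID), and remove every
    unclumped SNP on the same chromosome within ``window_kb`` whose
    ``r^2`` with the index exceeds ``r2_max``.  Returns the index SNPs in
    selection order.  A zero-variance variant has ``r^2 = 0`` with
    everything and cannot clump anything.
    """
    ws = sorted(
        ok_weights(weights), key=lambda w: (w.p, w.bp, w.variant_id)
    )
    if not ws:
        return []
    chroms = np.array([w.chrom for w in ws])
    bps = np.array([w.bp for w in ws], dtype=float)
    cols = np.array([w.variant_index for w in ws])
    window_bp = spec.window_kb * 1000.0
    alive = np.ones(len(ws), dtype=bool)
    selected: list[HarmonizedWeight] = []
    for i in range(len(ws)):
        if not alive[i]:
            continue
        alive[i] = False
        w = ws[i]
        selected.append(w)
        cand = alive & (chroms == w.chrom) & (np.abs(bps - w.bp) <= window_bp)
        idxs = np.nonzero(cand)[0]
        if idxs.size:
            r2 = pairwise_r2(G.dosage[:, w.variant_index], G.dosage[:, cols[idxs]])
            alive[idxs[r2 > spec.r2_max]] = False
    return selected


def compute_prs(
    G: GenotypeMatrix,
    weights: list[HarmonizedWeight],
    missing_policy: str = "mean_impute",
) -> tuple[np.ndarray, int]:
    """Per-sample weighted-sum score over the given (clumped) weights.

    Under ``mean_impute`` (default, mirroring PLINK ``--score``), a missing
    dosage is replaced by twice the alt-allele frequency observed in the
    target; under ``omit`` the term is skipped.  Returns
    ``(scores, n_snps_used)``; an empty weight list yields an all-missing
    column with ``n_snps_used = 0``.
    """
    if missing_policy not in ("mean_impute", "omit"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if not weights:
        return np.full(G.n_samples, np.nan), 0
    cols = np.array([w.variant_index for w in weights])
    betas = np.array([w.beta_alt for w in weights], dtype=float)
    D = G.dosage[:, cols]
    if missing_policy == "mean_impute":
        fill = np.nanmean(D, axis=0)  # = 2 * alt-allele frequency
        D = np.where(np.isnan(D), fill, D)
        scores = D @ betas
    else:
        scores = np.nansum(D * betas, axis=1)
    return scores, len(weights)


@dataclass
class ScoreTable:
    """Per-sample scores keyed by (score label, P threshold, APOE mode)."""

    scores: pd.DataFrame  # index sample_id; MultiIndex columns (label, threshold, mode)
    n_snps_used: dict[tuple[str, float, str], int] = field(default_factory=dict)

    def column(self, label: str, threshold: float, mode: str) -> pd.Series:
        return self.scores[(label, threshold, mode)]

    def labels(self) -> list[str]:
        return list(dict.fromkeys(self.scores.columns.get_level_values(0)))


def build_score_matrix(
    G: GenotypeMatrix,
    weights: list[HarmonizedWeight],
    pathway_sets: list[PathwaySnpSet],
    spec: ClumpSpec,
    apoe_region: RegionSpec,
    modes: tuple[str, ...] = APOE_MODES,
    thresholds: tuple[float, ...] | None = None,
    clump_scope: str = "pathway",
    missing_policy: str = "mean_impute",
) -> ScoreTable:
    """Compute the full score grid: labels x thresholds x APOE modes.

    Labels are the genome-wide score plus one per pathway.  For each column
    the order of operations is: restrict to the pathway (pathway labels
    only), apply the APOE mask, threshold by P, LD-clump, score.  With
    ``clump_scope='genomewide'`` clumping instead happens once on the full
    SNP set per (mode, threshold) and pathway columns inherit the surviving
    index SNPs.  An empty column is recorded as all-missing with
    ``n_snps_used = 0`` rather than aborting the grid.
    """
    if clump_scope not in ("pathway", "genomewide"):
        raise ValueError(f"unknown clump_scope {clump_scope!r}")
    for mode in modes:
        if mode not in APOE_MODES:
            raise ValueError(f"unknown APOE mode {mode!r}")
    thresholds = spec.all_thresholds() if thresholds is None else tuple(thresholds)
    base = ok_weights(weights)
    labels: list[tuple[str, PathwaySnpSet | None]] = [(GENOME_WIDE, None)]
    labels += [(ps.pathway_id, ps) for ps in pathway_sets]

    gw_clumped: dict[tuple[str, float], list[HarmonizedWeight]] = {}
    if clump_scope == "genomewide":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for mode in modes:
                masked = _apply_apoe(base, apoe_region, mode)
                for thr in thresholds:
                    sel = [w for w in masked if w.p <= thr]
                    gw_clumped[(mode, thr)] = ld_clump(sel, G, spec)

    data: dict[tuple[str, float, str], np.ndarray] = {}
    n_used: dict[tuple[str, float, str], int] = {}
    for label, ps in labels:
        restricted = base if ps is None else [
            w for w in base if w.variant_id in ps.snp_ids
        ]
        for mode in modes:
            masked = _apply_apoe(restricted, apoe_region, mode)
            for thr in thresholds:
                if clump_scope == "genomewide":
                    clumped = gw_clumped[(mode, thr)]
                    if ps is not None:
                        clumped = [w for w in clumped if w.variant_id in ps.snp_ids]
                else:
                    sel = [w for w in masked if w.p <= thr]
                    clumped = ld_clump(sel, G, spec)
                scores, n = compute_prs(G, clumped, missing_policy)
                key = (label, float(thr), mode)
                data[key] = scores
                n_used[key] = n
    columns = pd.MultiIndex.from_tuples(
        list(data.keys()), names=["score_label", "threshold", "apoe_mode"]
    )
    frame = pd.DataFrame(
        np.column_stack(list(data.values())),
        index=pd.Index(G.sample_ids, name="sample_id"),
        columns=columns,
    )
    return ScoreTable(scores=frame, n_snps_used=n_used)


def _apply_apoe(
    weights: list[HarmonizedWeight], region: RegionSpec, mode: str
) -> list[HarmonizedWeight]:
    if mode == "with_apoe":
        return list(weights)
    return exclude_region(weights, region, "only" if mode == "apoe_only" else "exclude")


def write_score_table(table: ScoreTable, path, n_snps_path=None) -> None:
    """Write scores as TSV with flat ``label|threshold|mode`` column keys."""
    flat = table.scores.copy()
    flat.columns = [
        f"{lbl}|{thr!r}|{mode}" for lbl, thr, mode in table.scores.columns
    ]
    flat.to_csv(path, sep="\t", na_rep="NA", float_format=_REPR_FLOAT)
    if n_snps_path is not None:
        rows = [
            {"score_label": lbl, "threshold": repr(thr), "apoe_mode": mode, "n_snps_used": n}
            for (lbl, thr, mode), n in table.n_snps_used.items()
        ]
        pd.DataFrame(rows).to_csv(n_snps_path, sep="\t", index=False)


def read_score_table(path, n_snps_path=None) -> ScoreTable:
    flat = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip")
    flat.index = flat.index.astype(str)
    keys = []
    for col in flat.columns:
        lbl, thr, mode = col.split("|")
        keys.append((lbl, float(thr), mode))
    flat.columns = pd.MultiIndex.from_tuples(
        keys, names=["score_label", "threshold", "apoe_mode"]
    )
    n_used: dict[tuple[str, float, str], int] = {}
    if n_snps_path is not None:
        meta = pd.read_csv(n_snps_path, sep="\t")
        for row in meta.itertuples(index=False):
            n_used[(row.score_label, float(row.threshold), row.apoe_mode)] = int(
                row.n_snps_used
            )
    return ScoreTable(scores=flat, n_snps_used=n_used)


def flip_variant(G: GenotypeMatrix, variant_id: str) -> GenotypeMatrix:
    """Swap ref/alt of one variant (dosage d -> 2 - d); testing utility."""
    j = G.index_of(variant_id)
    variants = G.variants.copy()
    ref, alt = variants.at[j, "ref"], variants.at[j, "alt"]
    variants.at[j, "ref"], variants.at[j, "alt"] = alt, ref
    dosage = G.dosage.copy()
    dosage[:, j] = 2.0 - dosage[:, j]
    return GenotypeMatrix(
        sample_ids=list(G.sample_ids), variants=variants, dosage=dosage
    )
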