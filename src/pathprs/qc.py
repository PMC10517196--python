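"""Genotype and phenotype quality control.

Variant filters (minor allele frequency, SNP call rate, Hardy-Weinberg
equilibrium), sample completeness filtering, per-ROI outlier removal, and
ancestry principal components.  Thresholds default to standard array-QC
practice for population cohorts: MAF >= 1%, SNP call rate >= 98%, HWE
chi-square P >= 1e-4, sample completeness >= 97%, ROI outliers beyond
2.5 SD of the per-ROI mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, PhenotypeTable


@dataclass(frozen=True)
class QcThresholds:
    """QC cut-offs; a value is *retained* when it meets the threshold."""

    maf_min: float = 0.01
    variant_call_min: float = 0.98
    sample_call_min: float = 0.97
    hwe_p_min: float = 1e-4
    roi_outlier_sd: float = 2.5

    def __post_init__(self) -> None:
        for name in ("maf_min", "variant_call_min", "sample_call_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.roi_outlier_sd <= 0:
            raise ValueError("roi_outlier_sd must be > 0")


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float
    monomorphic: bool


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> HweResult:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the observed allele frequency
    (p^2, 2pq, q^2).  A monomorphic site (one allele absent) is defined to
    have ``p = 1`` and is flagged.

    >>> hwe_test(25, 50, 25).p
    1.0
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be > 0")
    p_a = (2 * n_AA + n_Aa) / (2 * n)
    if p_a in (0.0, 1.0):
        return HweResult(chi2=0.0, p=1.0, monomorphic=True)
    expected = n * np.array([p_a**2, 2 * p_a * (1 - p_a), (1 - p_a) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return HweResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)), monomorphic=False)


@dataclass
class SampleFilterReport:
    n_input: int
    removed: dict[str, float] = field(default_factory=dict)  # id -> completeness

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_samples(
    G: GenotypeMatrix, t: QcThresholds
) -> tuple[GenotypeMatrix, SampleFilterReport]:
    """Drop samples whose genotyping completeness falls below the threshold."""
    report = SampleFilterReport(n_input=G.n_samples)
    if G.n_variants == 0:
        return G, report
    completeness = 1.0 - np.isnan(G.dosage).mean(axis=1)
    keep = completeness >= t.sample_call_min
    for sid, c, k in zip(G.sample_ids, completeness, keep):
        if not k:
            report.removed[sid] = float(c)
    if not keep.any():
        raise ValueError("sample completeness filter removed every sample")
    return G.subset_samples(keep), report


@dataclass
class VariantFilterReport:
    n_input: int
    removed_call_rate: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    removed_hwe: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return (
            len(self.removed_call_rate) + len(self.removed_maf) + len(self.removed_hwe)
        )


def filter_variants(
    G: GenotypeMatrix, t: QcThresholds
) -> tuple[GenotypeMatrix, VariantFilterReport]:
    """Apply the three variant filters as independent predicates.

    All predicates are evaluated on the unfiltered matrix, so the retained
    set does not depend on filter order; a variant failing several filters
    is attributed to the first in the order (call rate, MAF, HWE).  HWE is
    computed on hard genotype counts: dosages are rounded to the nearest
    integer for counting only.
    """
    report = VariantFilterReport(n_input=G.n_variants)
    if G.n_variants == 0:
        return G, report
    missing = np.isnan(G.dosage)
    call_rate = 1.0 - missing.mean(axis=0)
    freq = G.alt_freq()
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = np.empty(G.n_variants)
    for j in range(G.n_variants):
        col = G.dosage[:, j]
        hard = np.rint(col[~np.isnan(col)]).astype(int)
        if hard.size == 0:
            hwe_p[j] = 1.0
            continue
        hwe_p[j] = hwe_test(
            int((hard == 0).sum()), int((hard == 1).sum()), int((hard == 2).sum())
        ).p
    fail_call = call_rate < t.variant_call_min
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf >= t.maf_min)  # all-missing column (NaN maf) fails
    fail_hwe = hwe_p < t.hwe_p_min
    keep = ~(fail_call | fail_maf | fail_hwe)
    vids = G.variants["variant_id"].to_numpy()
    report.removed_call_rate = list(vids[fail_call])
    report.removed_maf = list(vids[~fail_call & fail_maf])
    report.removed_hwe = list(vids[~fail_call & ~fail_maf & fail_hwe])
    out = G.subset_variants(keep)
    if out.n_variants == 0:
        import warnings

        warnings.warn("variant QC removed every variant")
    return out, report


@dataclass
class RoiOutlierReport:
    removed: dict[str, list[str]] = field(default_factory=dict)  # roi -> sample ids
    zero_variance: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())


def remove_roi_outliers(
    ph: PhenotypeTable, t: QcThresholds
) -> tuple[PhenotypeTable, RoiOutlierReport]:
    """Set per-ROI values beyond ``roi_outlier_sd`` SD of the mean to missing.

    Single pass: mean and SD (ddof=1) are computed once from all non-missing
    values of the ROI; removal of one ROI value leaves the sample's other
    ROIs untouched.
    """
    out = ph.copy()
    report = RoiOutlierReport()
    for roi in ph.roi_columns:
        values = out.data[roi]
        obs = values.dropna()
        if len(obs) < 3:
            raise ValueError(f"ROI {roi!r} has fewer than 3 non-missing values")
        sd = obs.std(ddof=1)
        if sd == 0:
            report.zero_variance.append(roi)
            continue
        mean = obs.mean()
        outlier = (values - mean).abs() > t.roi_outlier_sd * sd
        if outlier.any():
            report.removed[roi] = list(values.index[outlier.fillna(False)])
            out.data.loc[outlier.fillna(False), roi] = np.nan
    return out, report


def compute_pcs(G: GenotypeMatrix, k: int) -> pd.DataFrame:
    """Ancestry principal components from standardized dosages.

    Missing dosages are mean-imputed per variant; each variant is then
    centred and scaled to unit variance (zero-variance variants are
    dropped).  Component signs are fixed by making the largest-magnitude
    variant loading positive, so the result is fully deterministic.
    Returns a DataFrame (samples x PC1..PCk) ordered by decreasing
    explained variance; ``k`` beyond the matrix rank is truncated with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = G.dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    X = X - X.mean(axis=0)  # idempotent; guards against float drift
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if k > rank:
        import warnings

        warnings.warn(f"requested {k} PCs but rank is {rank}; truncating")
        k = max(rank, 1)
    scores = U[:, :k] * S[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            scores[:, i] = -scores[:, i]
    return pd.DataFrame(
        scores,
        index=pd.Index(G.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
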