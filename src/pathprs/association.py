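"""Covariate-adjusted score x ROI regression grid with BH-FDR correction.

Each cell regresses one ROI measure on one polygenic score plus the
covariates (ordinary least squares, complete cases).  The reported effect
is the score term's coefficient with its t-based 95% CI; incremental
variance explained (delta R^2) is the gain in R^2 over the covariates-only
model on the same rows.  P-values are Benjamini-Hochberg corrected within
blocks of (ROI family x APOE mode x P threshold), mirroring a
"scores x family ROIs" testing grid, and each cell's delta R^2 is compared
against the variance explained by the APOE-region-only score alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import ASSOCIATION_COLUMNS, PhenotypeTable
from .prs_core import GENOME_WIDE, ScoreTable


@dataclass(frozen=True)
class GridSpec:
    """ROI families and FDR grouping for the association grid.

    ``fdr_scope='family'`` (default) corrects within each
    (family, APOE mode, threshold) block; ``'joint'`` pools the families
    of one (mode, threshold) into a single block.
    """

    roi_families: dict[str, tuple[str, ...]]
    fdr_scope: str = "family"

    def __post_init__(self) -> None:
        if self.fdr_scope not in ("family", "joint"):
            raise ValueError(f"unknown fdr_scope {self.fdr_scope!r}")
        seen: set[str] = set()
        for fam, rois in self.roi_families.items():
            overlap = seen & set(rois)
            if overlap:
                raise ValueError(f"ROI families overlap: {sorted(overlap)}")
            seen |= set(rois)


@dataclass
class FitResult:
    """OLS result for the score term of one (ROI, score) cell."""

    n: int
    beta: float = np.nan
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    r2_full: float = np.nan
    r2_cov: float = np.nan
    delta_r2: float = np.nan
    estimable: bool = True
    perfect_fit: bool = False
    reason: str = ""


def _design(X) -> np.ndarray | None:
    if X is None:
        return None
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X if X.shape[1] else None


def fit_association(y, s, X=None) -> FitResult:
    """OLS of ``y`` on ``[intercept, s, X]``; inference for the score term.

    Complete cases only.  The 95% CI uses the t quantile at the residual
    degrees of freedom.  A constant score or a rank-deficient design is
    flagged unestimable rather than silently pseudo-inverted; an exact fit
    is flagged (``se = 0``).
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    X = _design(X)
    mask = ~np.isnan(y) & ~np.isnan(s)
    if X is not None:
        mask &= ~np.isnan(X).any(axis=1)
    y, s = y[mask], s[mask]
    X = X[mask] if X is not None else None
    n = int(mask.sum())
    cols = [np.ones(n), s] + ([X[:, j] for j in range(X.shape[1])] if X is not None else [])
    design = np.column_stack(cols) if n else np.empty((0, 2))
    k = design.shape[1]
    if n < k + 2:
        return FitResult(n=n, estimable=False, reason="too few complete cases")
    if np.ptp(s) == 0:
        return FitResult(n=n, estimable=False, reason="constant score")
    if np.linalg.matrix_rank(design) < k:
        return FitResult(n=n, estimable=False, reason="rank-deficient design")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    tss = float(((y - y.mean()) ** 2).sum())
    perfect = bool(res.ssr <= 1e-12 * max(tss, 1.0))
    if X is not None:
        res_cov = sm.OLS(y, np.column_stack([np.ones(n), X])).fit()
        r2_cov = float(res_cov.rsquared) if tss > 0 else 0.0
    else:
        r2_cov = 0.0
    r2_full = float(res.rsquared) if tss > 0 else 0.0
    delta = r2_full - r2_cov
    return FitResult(
        n=n,
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p=float(res.pvalues[1]),
        r2_full=r2_full,
        r2_cov=r2_cov,
        delta_r2=delta,
        perfect_fit=perfect,
    )


def delta_r2(y, s, X=None) -> tuple[float, float, float]:
    """Incremental R^2 of the score over the covariates-only model.

    Both models are fitted on the same complete-case rows;
    ``delta = R2(y ~ X + s) - R2(y ~ X) >= 0`` up to float tolerance.
    Unlike coefficient inference, R^2 is well-defined even when the score
    is collinear with the covariates (the increment is then zero), so this
    uses least squares directly rather than requiring an estimable score
    term.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    X = _design(X)
    mask = ~np.isnan(y) & ~np.isnan(s)
    if X is not None:
        mask &= ~np.isnan(X).any(axis=1)
    y, s = y[mask], s[mask]
    X = X[mask] if X is not None else None
    n = int(mask.sum())
    if n < 3:
        raise ValueError("delta_r2 needs at least 3 complete cases")

    tss = float(((y - y.mean()) ** 2).sum())

    def r2(design: np.ndarray) -> float:
        if tss <= 0:
            return 0.0
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        ssr = float(((y - design @ beta) ** 2).sum())
        return 1.0 - ssr / tss

    cov_design = np.column_stack([np.ones(n)] + ([X] if X is not None else []))
    full_design = np.column_stack([cov_design, s])
    r2_cov = r2(cov_design)
    r2_full = r2(full_design)
    return r2_full, r2_cov, r2_full - r2_cov


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (q-values).

    ``q_(i) = min_{j >= i}(p_(j) * m / j)`` capped at 1, mapped back to the
    input order.

    >>> bh_fdr([0.01, 0.02, 0.03, 0.04]).tolist()
    [0.04, 0.04, 0.04, 0.04]
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_association_grid(
    scores: ScoreTable,
    ph: PhenotypeTable,
    grid: GridSpec,
    standardize_scores: bool = True,
) -> pd.DataFrame:
    """Fit every (score column, ROI) cell and FDR-correct within blocks.

    Samples are aligned by ID.  With ``standardize_scores`` (default) each
    score is z-scored over the cell's complete cases, so betas are per-SD
    of score; P-values and R^2 are invariant to this choice.
    ``beats_apoe`` compares each cell's delta R^2 against the variance
    explained by the genome-wide APOE-only score at the same threshold.
    Unestimable cells carry NaNs and are excluded from their FDR block.
    Results are sorted by (family, roi, score_label).
    """
    common = [sid for sid in scores.scores.index if sid in ph.data.index]
    if not common:
        raise ValueError("no overlapping sample IDs between scores and phenotypes")
    sc = scores.scores.loc[common]
    data = ph.data.loc[common]
    X = _covariate_design(data, ph.covariate_columns)
    declared = {r for rois in grid.roi_families.values() for r in rois}
    missing = declared - set(ph.roi_columns)
    if missing:
        raise ValueError(f"grid names unknown ROIs: {sorted(missing)}")

    apoe_delta: dict[tuple[str, float], float] = {}

    def apoe_only_delta(roi: str, thr: float) -> float:
        key = (roi, thr)
        if key not in apoe_delta:
            col = (GENOME_WIDE, thr, "apoe_only")
            if col in sc.columns:
                fit = fit_association(data[roi].to_numpy(), sc[col].to_numpy(), X)
                apoe_delta[key] = fit.delta_r2 if fit.estimable else np.nan
            else:
                apoe_delta[key] = np.nan
        return apoe_delta[key]

    rows = []
    for family, rois in grid.roi_families.items():
        for label, thr, mode in sc.columns:
            s_col = sc[(label, thr, mode)].to_numpy()
            for roi in rois:
                y = data[roi].to_numpy()
                s_used = s_col
                if standardize_scores:
                    mask = ~np.isnan(s_col) & ~np.isnan(y)
                    sd = np.nanstd(s_col[mask]) if mask.any() else 0.0
                    if sd > 0:
                        s_used = (s_col - np.nanmean(s_col[mask])) / sd
                fit = fit_association(y, s_used, X)
                d_apoe = apoe_only_delta(roi, thr)
                rows.append(
                    {
                        "family": family,
                        "roi": roi,
                        "score_label": label,
                        "threshold": thr,
                        "apoe_mode": mode,
                        "n": fit.n,
                        "beta": fit.beta,
                        "se": fit.se,
                        "ci_low": fit.ci_low,
                        "ci_high": fit.ci_high,
                        "p": fit.p,
                        "q": np.nan,
                        "delta_r2_prs": fit.delta_r2,
                        "delta_r2_apoe": d_apoe,
                        "beats_apoe": (
                            bool(fit.delta_r2 > d_apoe)
                            if fit.estimable and not np.isnan(d_apoe)
                            else pd.NA
                        ),
                        "estimable": fit.estimable,
                    }
                )
    out = pd.DataFrame(rows)
    block_keys = (
        ["family", "apoe_mode", "threshold"]
        if grid.fdr_scope == "family"
        else ["apoe_mode", "threshold"]
    )
    for _, idx in out.groupby(block_keys).groups.items():
        sub = out.loc[idx]
        est = sub.index[sub["estimable"] & sub["p"].notna() & (sub["p"] > 0)]
        if len(est):
            out.loc[est, "q"] = bh_fdr(out.loc[est, "p"].to_numpy())
    out = out.sort_values(["family", "roi", "score_label", "threshold", "apoe_mode"])
    return out.reset_index(drop=True)[["family", *ASSOCIATION_COLUMNS, "estimable"]]


def _covariate_design(data: pd.DataFrame, covariate_columns) -> np.ndarray | None:
    """Numeric covariates as-is; categoricals expanded to dummy columns."""
    if not covariate_columns:
        return None
    parts = []
    for col in covariate_columns:
        series = data[col]
        if pd.api.types.is_numeric_dtype(series):
            parts.append(series.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(series.astype(str), drop_first=True)
            if dummies.shape[1]:
                parts.append(dummies.to_numpy(dtype=float))
    if not parts:
        return None
    return np.column_stack(parts)
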