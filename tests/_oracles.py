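"""Independent reference implementations used as test oracles.

These are deliberately naive (plain loops, textbook formulas) and share no
code with the package, so agreement is evidence of correctness rather than
of shared bugs.
"""

from __future__ import annotations

import numpy as np


def greedy_clump_reference(snps, corr):
    """Brute-force greedy clumping.

    ``snps``: list of dicts with keys ``id, chrom, bp, p, col``;
    ``corr[i][j]``: r^2 between snps i and j.  Window is 500 kb unless a
    snp dict carries ``window_bp``.  Tie-break: smaller p, then smaller bp,
    then id.  Returns selected ids in order.
    """
    remaining = list(range(len(snps)))
    selected = []
    while remaining:
        best = min(
            remaining,
            key=lambda i: (snps[i]["p"], snps[i]["bp"], snps[i]["id"]),
        )
        selected.append(snps[best]["id"])
        remaining.remove(best)
        window = snps[best].get("window_bp", 500_000)
        for i in list(remaining):
            if (
                snps[i]["chrom"] == snps[best]["chrom"]
                and abs(snps[i]["bp"] - snps[best]["bp"]) <= window
                and corr[best][i] > 0.2
            ):
                remaining.remove(i)
    return selected


def r2_matrix(dosage):
    """Pairwise dosage r^2 by direct per-pair Pearson (no missing values)."""
    m = dosage.shape[1]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                out[i, j] = 1.0
                continue
            x, y = dosage[:, i], dosage[:, j]
            if x.std() == 0 or y.std() == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = np.corrcoef(x, y)[0, 1] ** 2
    return out


def bh_reference(p):
    """Step-up BH by literal definition: q_i = min_{j: p_j >= p_i} p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos in range(m):
        i = order[rank_pos]
        candidates = [
            p[order[k]] * m / (k + 1) for k in range(rank_pos, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q


def ols_reference(y, design):
    """Normal-equations OLS: beta, se, t-based p for every coefficient."""
    from scipy import stats

    design = np.asarray(design, float)
    y = np.asarray(y, float)
    n, k = design.shape
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    df = n - k
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def hwe_chi2_reference(n_AA, n_Aa, n_aa):
    """Textbook HWE chi-square from expected p^2 / 2pq / q^2 counts."""
    from scipy import stats

    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 0.0, 1.0
    exp = [n * p * p, 2 * n * p * q, n * q * q]
    obs = [n_AA, n_Aa, n_aa]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    return chi2, float(stats.chi2.sf(chi2, 1))
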