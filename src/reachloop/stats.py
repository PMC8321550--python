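"""Shared statistical helpers: FDR control and test wrappers with
explicit handling of the degenerate inputs that arise in spike-count
comparisons (all-tied pairs, zero-margin contingency tables).

q < fdr_alpha under Benjamini–Hochberg is the significance criterion
everywhere in the pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    NaN entries (untestable units/sessions) are passed through as NaN
    and do not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def signed_rank_p(x, y=None) -> float:
    """Two-sided Wilcoxon signed-rank p on pairs (or on differences).

    All-zero differences (no information) give p = 1. Exact null
    distribution for small samples without ties, normal approximation
    with continuity correction otherwise (scipy's ``method='auto'``).
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0 or np.all(d == 0):
        return 1.0
    method = "exact" if np.count_nonzero(d) <= 25 else "approx"
    return float(sps.wilcoxon(d, zero_method="wilcox", correction=True,
                              alternative="two-sided", method=method).pvalue)


def rank_sum_p(x, y, method: str | None = None) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p.

    Exact null distribution for modest untied samples, tie-corrected
    normal approximation otherwise (or when ``method`` forces it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return np.nan
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    if method is None:
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (no_ties and x.size * y.size <= 10000) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def chi2_test(table) -> tuple[float, float, int, bool]:
    """Pearson chi-square without continuity correction.

    Returns (chi2, p, dof, degenerate). Zero-margin tables are
    degenerate: chi2 = 0, p = 1, flagged. A low-count warning flag is
    handled by callers where the contract requires it.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 0.0, 1.0, 0, True
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p), int(dof), False


def f_variance_test(x, y) -> tuple[float, float]:
    """Two-sample two-sided F-test of equal variances: F = var(x)/var(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        return np.nan, np.nan
    f = vx / vy
    dist = sps.f(x.size - 1, y.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (NaN when either input is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(sps.spearmanr(x, y).statistic)


def spearman_normal_p(rho: float, n: int) -> float:
    """Permutation-null p for Spearman's rho via the large-sample
    normal approximation rho * sqrt(n - 1) ~ N(0, 1)."""
    if not np.isfinite(rho):
        return np.nan
    z = abs(rho) * np.sqrt(max(n - 1, 0))
    return float(2.0 * sps.norm.sf(z))
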