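"""Group-level statistics for paired normocapnia/hypercapnia cohorts.

Nonparametric throughout: paired Wilcoxon signed-rank tests for state
differences, Friedman ANOVA with Bonferroni-adjusted Wilcoxon post-hocs for
band differences (alpha_post-hoc < 0.017), the Pitman-Morgan test for
equality of variances of paired estimates, Spearman rank correlation, and
median [IQR] summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_paired",
    "friedman_with_posthoc",
    "pitman_morgan",
    "spearman",
    "summarize_median_iqr",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    degenerate: bool = False
    note: str = ""


def wilcoxon_paired(a, b, exact_max_n: int = 25) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used up to ``exact_max_n`` informative pairs, the
    continuity-corrected normal approximation above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(0.0, 1.0, degenerate=True, note="all differences zero")
    if nz.size < 6:
        return TestResult(np.nan, np.nan, degenerate=True, note=f"only {nz.size} informative pairs")
    method = "exact" if nz.size <= exact_max_n else "approx"
    res = sps.wilcoxon(nz, method=method, correction=(method == "approx"))
    return TestResult(float(res.statistic), float(res.pvalue), note=f"n={nz.size}, {method}")


def friedman_with_posthoc(groups: dict[str, np.ndarray], alpha_posthoc: float = 0.017):
    """Friedman ANOVA across matched groups plus pairwise Wilcoxon post-hocs.

    Returns (chi2, p, posthoc) where posthoc maps each pair of group names to
    a dict with the Wilcoxon result and the decision at ``alpha_posthoc``
    (Bonferroni level 0.05/3 for three bands).
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len({len(x) for x in arrays}) != 1:
        raise ValueError("groups must be matched (equal sizes)")
    chi2, p = sps.friedmanchisquare(*arrays)
    posthoc = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = wilcoxon_paired(arrays[i], arrays[j])
            posthoc[(names[i], names[j])] = {
                "result": res,
                "significant": (not res.degenerate) and res.p_value < alpha_posthoc,
            }
    return float(chi2), float(p), posthoc


def pitman_morgan(a, b) -> TestResult:
    """Pitman-Morgan test of equal variances for paired samples.

    Equality of Var(a) and Var(b) is equivalent to zero correlation between
    the pair sums and differences; the test is the t-test of that
    correlation with n-2 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D samples")
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    s, d = a + b, a - b
    if s.std() == 0 or d.std() == 0:
        return TestResult(0.0, 1.0, degenerate=True, note="zero variance in sums or differences")
    r = np.corrcoef(s, d)[0, 1]
    if abs(r) >= 1.0:
        return TestResult(np.inf * np.sign(r), 0.0, note="perfect correlation")
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * sps.t.sf(abs(t), n - 2)
    return TestResult(float(t), float(p))


def spearman(a, b) -> TestResult:
    """Spearman rank correlation with tie handling; two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return TestResult(np.nan, np.nan, degenerate=True, note="constant input")
    rho, p = sps.spearmanr(a, b)
    return TestResult(float(rho), float(p))


def summarize_median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear-interpolation
    quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q3 - q1)
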