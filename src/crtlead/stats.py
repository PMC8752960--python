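"""Nonparametric statistics for pacing-response comparisons.

Paired responses (reduction vs 0) use the one-sided Wilcoxon signed-rank
test (H0: distribution symmetric about mu = 0, Ha: mu > 0); unpaired
comparisons between pacing strategies use the Mann-Whitney U test.  Exact
null distributions are used for small samples, tie-corrected normal
approximations otherwise, and Bonferroni correction guards families of
pairwise comparisons.  Significance is declared at p < 0.01; effect sizes
are always reported alongside p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ALPHA",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "bonferroni",
]

ALPHA = 0.01


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    n: tuple
    significant: bool
    effect_size: float  # median of the tested quantity (location estimate)

    def adjusted(self, m: int) -> "TestResult":
        p = min(1.0, m * self.p_value)
        return TestResult(
            self.statistic, p, self.alternative, self.n, p < ALPHA, self.effect_size
        )


def wilcoxon_signed_rank(
    values, mu: float = 0.0, alternative: str = "greater", zero_method: str = "wilcox"
) -> TestResult:
    """One-sample Wilcoxon signed-rank test of symmetry about ``mu``.

    Zero differences are dropped by default (Wilcoxon convention;
    ``zero_method="pratt"`` keeps them in the ranking).  The exact null
    distribution is used for n <= 25 without ties, otherwise the
    tie-corrected normal approximation.
    """
    d = np.asarray(values, dtype=float) - mu
    if d.size == 0:
        raise ValueError("empty sample")
    nz = d[d != 0] if zero_method == "wilcox" else d
    if nz.size == 0:
        raise ValueError("all values equal mu: no nonzero differences to rank")
    has_ties = len(np.unique(np.abs(nz[nz != 0]))) < np.count_nonzero(nz)
    method = "exact" if (np.count_nonzero(nz) <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        d, alternative=alternative, zero_method=zero_method, method=method
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n=(int(np.count_nonzero(nz)),),
        significant=res.pvalue < ALPHA,
        effect_size=float(np.median(np.asarray(values, dtype=float))),
    )


def mann_whitney(x, y, alternative: str = "greater") -> TestResult:
    """Mann-Whitney U test (unpaired rank-sum), Ha: x shifted above y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n=(int(x.size), int(y.size)),
        significant=res.pvalue < ALPHA,
        effect_size=float(np.median(x) - np.median(y)),
    )


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)
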