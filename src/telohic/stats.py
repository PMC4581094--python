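"""The two statistical tests used for the population comparisons:
Mann-Whitney U (focus intensity distributions) and the pooled
two-proportion z test (hypercluster fractions).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import mannwhitneyu as _scipy_mwu
from scipy.stats import norm, rankdata

__all__ = ["mann_whitney_u", "two_proportion_z"]

#: combined sample size at or below which the exact null distribution is used
EXACT_LIMIT = 12


def mann_whitney_u(
    sample_a, sample_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of sample_a, p-value).

    U is computed from midrank sums (ties get midranks). The p-value is
    exact by enumeration of the null distribution when the combined sample
    size is at most 12 and there are no ties, and otherwise uses the
    normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = ranks[: a.size].sum()
    U = float(r_a - a.size * (a.size + 1) / 2.0)

    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_LIMIT and no_ties) else "asymptotic"
    res = _scipy_mwu(a, b, alternative=alternative, method=method)
    return U, float(res.pvalue)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z test; returns (z, two-sided p).

    z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2)) with p the pooled
    proportion; p-value from the standard normal. Degenerate pooled
    proportions (0 or 1) give z = 0 when the group proportions are equal.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    denom = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if denom == 0:
        z = 0.0
    else:
        z = (p1 - p2) / denom
    p = 2.0 * float(norm.sf(abs(z)))
    return z, min(p, 1.0)
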