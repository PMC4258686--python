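"""Two-sample and paired rank tests with an exact small-sample path.

Both tests route through SciPy but pin the method choice so that small,
tie-free inputs use exact null enumeration (making hand-enumerated oracle
p-values reproducible bit-for-bit) and larger or tied inputs use the
tie-corrected normal approximation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

EXACT_MAX_N = 10


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def rank_sum_p(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both groups have <= 10 observations and the
    pooled values are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.  A pooled sample with a single
    distinct value carries no rank information and returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) == 1:
        return 1.0
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def signed_rank_p(diffs, alternative: str = "two-sided") -> tuple[float, int]:
    """Wilcoxon signed-rank p-value on paired differences.

    Zero differences are dropped (the Wilcoxon convention) before ranking;
    returns ``(p, n_used)``.  All-zero differences carry no information and
    yield p = 1 with n_used = 0.  Exact enumeration over sign patterns when
    the non-zero differences are <= 10 with tie-free magnitudes.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0, 0
    if len(d) <= EXACT_MAX_N and not _has_ties(np.abs(d)):
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative=alternative, method=method)
    return float(res.pvalue), len(d)
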