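"""Shared rank-test machinery.

The two-group comparisons throughout the pipeline are two-sided
Mann-Whitney U tests.  Small comparisons (n_a * n_b <= 400) use the exact
null distribution: scipy's exact method when the pooled sample is
tie-free, or full enumeration of rank splits when ties are present and
the enumeration space is small.  Larger comparisons use the tie-corrected
normal approximation without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

EXACT_PRODUCT_LIMIT = 400
_ENUM_LIMIT = 200_000  # max C(n, n_a) for exact-with-ties enumeration


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann-Whitney comparison of two value sets."""
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    u: float
    p: float
    method: str  # "EXACT" | "NORMAL_APPROX"

    def as_dict(self) -> dict:
        return dict(n_a=self.n_a, n_b=self.n_b, mean_a=self.mean_a,
                    mean_b=self.mean_b, sd_a=self.sd_a, sd_b=self.sd_b,
                    u=self.u, p=self.p, method=self.method)


def _enumerate_exact_p(pooled_ranks: np.ndarray, n_a: int,
                       u_obs: float) -> float:
    """Exact two-sided p over all C(n, n_a) assignments of ranks to group A.

    Handles ties (average ranks); p = min(1, 2*min(P(U<=u), P(U>=u))).
    """
    offset = n_a * (n_a + 1) / 2.0
    us = np.array([sum(c) - offset
                   for c in combinations(pooled_ranks, n_a)])
    n_tot = len(us)
    lo = np.sum(us <= u_obs + 1e-9) / n_tot
    hi = np.sum(us >= u_obs - 1e-9) / n_tot
    return min(1.0, 2.0 * min(lo, hi))


def mann_whitney(a, b) -> GroupComparison:
    """Two-sided Mann-Whitney U test with summary statistics.

    NaNs are dropped; an empty group is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann-Whitney comparison requires two non-empty groups")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    has_ties = len(np.unique(pooled)) < pooled.size
    if n_a * n_b <= EXACT_PRODUCT_LIMIT:
        if not has_ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact")
            p, method = float(res.pvalue), "EXACT"
        elif comb(n_a + n_b, n_a) <= _ENUM_LIMIT:
            p, method = _enumerate_exact_p(ranks, n_a, u_a), "EXACT"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=False)
            p, method = float(res.pvalue), "NORMAL_APPROX"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        p, method = float(res.pvalue), "NORMAL_APPROX"

    return GroupComparison(
        n_a=n_a, n_b=n_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)) if n_a > 1 else float("nan"),
        sd_b=float(b.std(ddof=1)) if n_b > 1 else float("nan"),
        u=u_a, p=p, method=method,
    )
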