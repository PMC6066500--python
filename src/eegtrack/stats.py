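"""Nonparametric statistics: Spearman rank correlation and the Wilcoxon
signed-rank test, with exact small-sample p-values.

Both tests are implemented here (rather than delegated) because the exact
null enumeration at the study's sample sizes is part of the contract: the
Spearman p-value is computed by full permutation enumeration for n <= 9 and
by the t approximation with n-2 degrees of freedom otherwise; the Wilcoxon
p-value by enumeration of all 2^n sign assignments (via a rank-sum
distribution convolution) for n <= 20 and by the tie-corrected normal
approximation otherwise.  Ties receive mid-ranks; zero differences are
dropped.  scipy's implementations serve as cross-checks in the test suite,
never as the implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

__all__ = ["SpearmanResult", "WilcoxonResult", "spearman", "wilcoxon_signed_rank"]

SPEARMAN_EXACT_MAX_N = 9
WILCOXON_EXACT_MAX_N = 20


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p: float
    n: int
    method: str  # "exact-permutation" | "t-approximation"

    def __iter__(self):
        return iter((self.r, self.p))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p: float
    n: int            # pairs remaining after dropping zero differences
    n_dropped: int
    method: str       # "exact-enumeration" | "normal-approximation"

    def __iter__(self):
        return iter((self.statistic, self.p))


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("undefined correlation: constant input")
    return float(rx @ ry) / denom


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    r is the Pearson correlation of mid-ranks.  For n <= 9 the p-value is
    the exact two-sided permutation probability P(|r_perm| >= |r_obs|)
    under random pairing; for larger n the t approximation
    ``t = r sqrt((n-2)/(1-r^2))`` with n-2 df is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a reported p-value")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx, ry = rankdata(x), rankdata(y)
    r = _rank_corr(rx, ry)
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
        r_all = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(r_all) >= abs(r) - 1e-12))
        method = "exact-permutation"
    else:
        if abs(r) >= 1.0:
            p = 2.0 / math.factorial(n)  # smallest attainable, degenerate |r|=1
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(t_dist.sf(abs(t), n - 2))
        method = "t-approximation"
    return SpearmanResult(r=r, p=min(p, 1.0), n=n, method=method)


def _wilcoxon_exact_tail(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for W+ given doubled ranks (integers) and doubled stat.

    Builds the null distribution of 2*W+ over all sign assignments by
    convolution; the distribution is symmetric about its mean, so the
    two-sided p is P(|W+ - mu| >= |w - mu|).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for rk in ranks2:
        rk = int(rk)
        shifted = np.zeros_like(counts)
        shifted[rk:] = counts[: total + 1 - rk]
        counts = counts + shifted
    counts /= counts.sum()
    mu = total / 2.0
    dev = abs(w2 - mu)
    support = np.arange(total + 1)
    return float(counts[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(pre, post) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of post vs pre, two-sided.

    Zero differences are dropped (the classic reduction); tied absolute
    differences receive mid-ranks.  Exact enumeration of the 2^n sign
    assignments for n <= 20, tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D sequences")
    d = post - pre
    nz = d != 0
    n_dropped = int((~nz).sum())
    d = d[nz]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    if n < 5:
        raise ValueError(f"only {n} nonzero differences; need >= 5")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        ranks2 = np.round(2 * ranks).astype(int)  # mid-ranks are half-integers
        p = _wilcoxon_exact_tail(ranks2, 2 * w_plus)
        method = "exact-enumeration"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        dev = max(abs(w_plus - mu) - 0.5, 0.0)  # continuity correction
        z = dev / math.sqrt(var)
        p = 2.0 * float(norm.sf(z))
        method = "normal-approximation"
    return WilcoxonResult(
        statistic=w_plus, p=min(p, 1.0), n=n, n_dropped=n_dropped, method=method
    )
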