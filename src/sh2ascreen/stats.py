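"""Mann-Whitney U rank test and small shared statistical helpers.

The exact method computes the null distribution of U by dynamic programming
over rank subsets, which is identical to full enumeration of all
C(n1+n2, n1) group assignments when the pooled data are tie-free.  The
approximate method is the normal approximation with mid-ranks, tie-corrected
variance, and a continuity correction (matching R's ``wilcox.test`` with
``correct=TRUE``).
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

from .errors import ValidationError

ALTERNATIVES = ("two_sided", "x_less", "x_greater")

#: "auto" selects the exact method when the number of group assignments is
#: enumerable below this bound and the pooled data are tie-free.
EXACT_ASSIGNMENT_LIMIT = 100_000


def _exact_u_counts(n1: int, n2: int) -> list[int]:
    """counts[u] = number of size-n1 rank subsets of {1..n1+n2} with U = u."""
    n = n1 + n2
    offset = n1 * (n1 + 1) // 2
    max_s = n1 * n + 1  # rank sums are < this
    ways = [[0] * max_s for _ in range(n1 + 1)]
    ways[0][0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            wk, wk1 = ways[k], ways[k - 1]
            for s in range(max_s - 1, rank - 1, -1):
                if wk1[s - rank]:
                    wk[s] += wk1[s - rank]
    return [ways[n1][u + offset] for u in range(n1 * n2 + 1)]


def _exact_p(u: float, n1: int, n2: int, alternative: str) -> float:
    counts = _exact_u_counts(n1, n2)
    total = comb(n1 + n2, n1)
    ui = int(round(u))
    ge = sum(counts[ui:])
    le = sum(counts[: ui + 1])
    if alternative == "x_greater":
        return ge / total
    if alternative == "x_less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


def _tie_term(sorted_row: np.ndarray) -> float:
    _, counts = np.unique(sorted_row, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def mwu_matrix(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "two_sided",
    continuity: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Mann-Whitney normal approximation for many simultaneous tests.

    ``a`` and ``b`` are (tests x n1) and (tests x n2).  Returns per-row
    ``(U, p)`` where U is the statistic of the ``a`` group.  Rows whose
    pooled values are completely tied get p = 1 (no evidence).
    """
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    pooled = np.concatenate([a, b], axis=1)
    ranks = rankdata(pooled, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0

    var = np.full(pooled.shape[0], n1 * n2 * (n + 1) / 12.0)
    srt = np.sort(pooled, axis=1)
    tied_rows = np.nonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))[0]
    for i in tied_rows:
        var[i] = n1 * n2 / 12.0 * ((n + 1) - _tie_term(srt[i]) / (n * (n - 1)))

    mu = n1 * n2 / 2.0
    num = u - mu
    sigma = np.sqrt(np.maximum(var, 0.0))
    p = np.ones_like(u)
    ok = sigma > 0
    cc = 0.5 if continuity else 0.0
    if alternative == "x_greater":
        z = (num[ok] - cc) / sigma[ok]
        p[ok] = ndtr(-z)
    elif alternative == "x_less":
        z = (num[ok] + cc) / sigma[ok]
        p[ok] = ndtr(z)
    else:
        z = np.maximum((np.abs(num[ok]) - cc) / sigma[ok], 0.0)
        p[ok] = np.minimum(1.0, 2.0 * ndtr(-z))
    np.clip(p, np.finfo(float).tiny, 1.0, out=p)
    return u, p


def mann_whitney_u(
    x,
    y,
    alternative: str = "two_sided",
    method: str = "auto",
    continuity: bool = True,
) -> tuple[float, float]:
    """Mann-Whitney U test of ``x`` against ``y``.

    Parameters
    ----------
    alternative : one of ``two_sided``, ``x_less``, ``x_greater``.
    method : ``exact`` (DP over rank subsets; requires tie-free data),
        ``normal_approx_tie_corrected``, or ``auto`` which picks the exact
        method whenever the assignment space is enumerable and tie-free.

    Returns ``(U, p)`` with U the statistic of ``x`` and p in (0, 1].
    Completely tied data yield p = 1 by convention.
    """
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if method == "auto":
        if not has_ties and comb(n1 + n2, n1) <= EXACT_ASSIGNMENT_LIMIT:
            method = "exact"
        else:
            method = "normal_approx_tie_corrected"
    if method == "exact":
        if has_ties:
            raise ValidationError("exact method requires tie-free data")
        ranks = rankdata(pooled)
        u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
        return u, _exact_p(u, n1, n2, alternative)
    if method == "normal_approx_tie_corrected":
        u, p = mwu_matrix(x[None, :], y[None, :], alternative, continuity)
        return float(u[0]), float(p[0])
    raise ValidationError(f"unknown method {method!r}")


def percentile_rank(values, query: float) -> float:
    """Mid-rank percentile of ``query`` within ``values``, in [0, 100].

    A value equal to the median of an odd-sized set scores 50.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot rank within an empty set")
    less = float(np.sum(values < query))
    equal = float(np.sum(values == query))
    return 100.0 * (less + 0.5 * equal) / values.size


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
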