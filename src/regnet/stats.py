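"""Shared statistical primitives.

A single hypergeometric upper-tail routine backs both the master-regulator
overlap test and the promoter motif enrichment test, so the two report
identical P values on identical 2x2 tables.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["hypergeom_upper_tail", "fisher_exact_enrichment", "welch_t"]


def hypergeom_upper_tail(k: int, universe: int, n_a: int, n_b: int) -> float:
    """P(X >= k) for the overlap X of two fixed-size subsets of a universe.

    X follows Hypergeometric(M=universe, K=n_a, n=n_b); this one-sided tail
    equals the one-sided Fisher exact P for enrichment in the corresponding
    2x2 table.
    """
    if not (0 <= n_a <= universe and 0 <= n_b <= universe):
        raise ValueError("set sizes must lie within the universe")
    if k < 0:
        raise ValueError("overlap count must be nonnegative")
    return float(stats.hypergeom.sf(k - 1, universe, n_a, n_b))


def fisher_exact_enrichment(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact P for the table [[a, b], [c, d]].

    ``a`` = focal-class successes; the upper tail asks whether the focal
    class has at least the observed number of successes given the margins.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table counts must be nonnegative")
    return hypergeom_upper_tail(a, a + b + c + d, a + b, a + c)


def welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-statistic for mean(y) - mean(x).

    ``x`` and ``y`` are genes x samples arrays. Degenerate rows with zero
    pooled standard error yield t = 0 when the means agree and are clipped
    to a large finite magnitude otherwise (signatures must stay finite).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 samples")
    diff = y.mean(axis=1) - x.mean(axis=1)
    se2 = x.var(axis=1, ddof=1) / nx + y.var(axis=1, ddof=1) / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where(se2 == 0, np.where(diff == 0, 0.0, np.sign(diff) * 1e12), t)
    return t
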