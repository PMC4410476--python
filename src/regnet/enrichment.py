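"""GSEA-style running-sum enrichment of a gene set in a ranked signature.

The enrichment score (ES) is the signed extreme deviation of the weighted
Kolmogorov–Smirnov running sum: walking the ranking, set members add
|score|^w normalised by the members' total weight, non-members subtract
1/(N - n). Two implementations are provided: a straightforward O(N)
reference (:func:`gsea_enrichment`, which also extracts the leading edge)
and a batch form (:func:`es_batch`) that evaluates the running-sum extreme
only at member positions, used for the permutation nulls where thousands
of random member sets are scored against the same ranking.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .containers import GeneSignature

__all__ = ["gsea_enrichment", "es_batch", "random_position_sets"]


def _signed_extreme(maxima: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """Pick the deviation of larger magnitude; ties resolve positive."""
    return np.where(maxima >= -minima, maxima, minima)


def gsea_enrichment(
    signature: GeneSignature,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, list[str]]:
    """Enrichment score and leading edge of ``gene_set`` in the signature.

    Returns
    -------
    (es, leading_edge)
        ``es`` is the signed extreme of the running sum, in [-1, 1];
        the leading edge contains the members at or before the positive
        extreme (or at/after the negative extreme when the ES is negative)
        — the genes that drive the enrichment.
    """
    gene_set = set(gene_set)
    ranking = signature.ranking()
    member = np.asarray(ranking.isin(gene_set))
    n = int(member.sum())
    if n == 0:
        raise ValueError("gene set does not intersect the signature's genes")
    N = len(ranking)
    w = signature.ranked_weights(weight_exponent)
    wm = np.where(member, w, 0.0)
    total = wm.sum()
    inc = wm / total if total > 0 else member / n
    dec = np.where(member, 0.0, 1.0 / (N - n)) if N > n else np.zeros(N)
    running = np.cumsum(inc - dec)
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    es = float(_signed_extreme(running[imax : imax + 1], running[imin : imin + 1])[0])
    if es >= 0:
        leading = [g for g, m in zip(ranking[: imax + 1], member[: imax + 1]) if m]
    else:
        leading = [g for g, m in zip(ranking[imin:], member[imin:]) if m]
    return es, leading


def es_batch(weights: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Enrichment scores for many member-position sets on one ranking.

    Parameters
    ----------
    weights
        |score|^w for each rank position, in ranking order (length N).
    positions
        (B, n) integer array of member rank positions, each row sorted
        ascending.

    Notes
    -----
    The running sum is piecewise: it only rises at member positions and
    declines linearly between them, so its extrema are attained either at
    a member position (maximum candidates), just before one, or at the
    final position where the sum returns to zero (minimum candidates).
    """
    positions = np.asarray(positions)
    if positions.ndim != 2:
        raise ValueError("positions must be a (B, n) array")
    B, n = positions.shape
    N = len(weights)
    wp = weights[positions]
    total = wp.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        inc = np.where(total > 0, wp / total, 1.0 / n)
    cum = np.cumsum(inc, axis=1)
    if N > n:
        miss = (positions - np.arange(n)) / (N - n)
    else:
        miss = np.zeros_like(cum)
    at_member = cum - miss
    before_member = at_member - inc
    maxima = at_member.max(axis=1)
    minima = np.minimum(before_member.min(axis=1), 0.0)
    return _signed_extreme(maxima, minima)


def random_position_sets(
    n_positions: int, set_size: int, n_sets: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_sets, set_size) sorted uniform position sets without replacement.

    Permuting the gene labels of a signature places a fixed gene set at
    uniformly random rank positions, so these sets realise the
    label-shuffling null.
    """
    keys = rng.random((n_sets, n_positions))
    pos = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    pos.sort(axis=1)
    return pos
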