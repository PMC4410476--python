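"""Master-regulator inference by regulon enrichment.

A group contrast is summarised as a gene signature of Welch t-statistics,
ranked by |t|. Each regulator whose (trimmed) regulon is large enough is
scored by the GSEA enrichment of its targets in that ranking; the null
distribution comes from shuffling the signature's gene labels, which
places the regulon at uniformly random rank positions. The normalised
enrichment score NES = (ES - null mean) / null sd is mapped to a one-sided
P value on the standard-normal scale (NES 2.33 <-> P 0.01); the empirical
permutation tail P is reported alongside. Regulators with P below a cutoff
(default 0.01) are the master-regulator candidates, and candidate sets
from different strata (e.g. brain regions) are compared with a one-sided
Fisher exact / hypergeometric overlap test.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import (
    Edge,
    EnrichmentResult,
    ExpressionMatrix,
    GeneSignature,
    Interactome,
)
from .enrichment import es_batch, gsea_enrichment, random_position_sets
from .stats import hypergeom_upper_tail, welch_t

__all__ = [
    "compute_signature",
    "trim_regulon",
    "marina",
    "call_candidates",
    "mr_overlap_test",
]

logger = logging.getLogger(__name__)

#: "more than 25 targets" eligibility rule
DEFAULT_MIN_REGULON = 26
#: regulons larger than this are trimmed to their top-MI interactions
DEFAULT_MAX_TARGETS = 100


def compute_signature(
    expr: ExpressionMatrix, group_a: str, group_b: str
) -> GeneSignature:
    """Per-gene Welch t-statistics for the contrast ``group_b - group_a``.

    The signature ranks genes by |t| descending (ties by gene id), the
    convention for master-regulator analysis of a two-group contrast.
    """
    for g in (group_a, group_b):
        if g not in set(expr.annotations["group"]):
            available = sorted(set(expr.annotations["group"]))
            raise ValueError(f"group {g!r} not found; available groups: {available}")
    a_ids = expr.samples_in_group(group_a)
    b_ids = expr.samples_in_group(group_b)
    t = welch_t(
        expr.values[a_ids].to_numpy(dtype=float),
        expr.values[b_ids].to_numpy(dtype=float),
    )
    scores = pd.Series(t, index=expr.genes, name="t")
    return GeneSignature(scores, contrast=f"{group_b} vs {group_a}", rank_by="abs")


def trim_regulon(edges: Sequence[Edge], max_targets: int = DEFAULT_MAX_TARGETS) -> list[Edge]:
    """Keep the ``max_targets`` highest-MI edges of a regulon.

    Trimming de-biases the enrichment analysis, which otherwise favours
    regulators with very large regulons. Ties are broken by higher
    bootstrap support, then by target id.
    """
    if len(edges) <= max_targets:
        return list(edges)
    ranked = sorted(edges, key=lambda e: (-e.mi, -e.support, e.target))
    return ranked[:max_targets]


def _eligible_regulons(
    interactome: Interactome,
    universe: set[str],
    min_regulon: int,
    max_targets: int,
) -> dict[str, list[Edge]]:
    """Intersect regulons with the measured universe, trim, filter by size."""
    out: dict[str, list[Edge]] = {}
    for reg, edges in interactome.regulons.items():
        in_universe = [e for e in edges if e.target in universe]
        trimmed = trim_regulon(in_universe, max_targets)
        if len(trimmed) >= min_regulon:
            out[reg] = trimmed
    return out


def marina(
    interactome: Interactome,
    signature: GeneSignature,
    n_permutations: int = 10000,
    min_regulon: int = DEFAULT_MIN_REGULON,
    weight_exponent: float = 1.0,
    max_targets: int = DEFAULT_MAX_TARGETS,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Score every eligible regulator's regulon against the signature.

    Regulons are intersected with the signature's gene universe and
    trimmed to ``max_targets`` before the eligibility check
    (``min_regulon``, i.e. "more than 25 targets" by default). The null is
    gene-label shuffling of the signature, realised as uniformly random
    member-position sets shared per regulon size. Results are sorted by
    NES descending.
    """
    universe = set(signature.genes)
    regulons = _eligible_regulons(interactome, universe, min_regulon, max_targets)
    if not regulons:
        logger.warning("no regulator passed the eligibility rule; empty result")
        return []
    rng = np.random.default_rng(seed)
    N = len(signature.genes)
    w = signature.ranked_weights(weight_exponent)
    sizes = sorted({len(v) for v in regulons.values()})
    null_es = {
        size: es_batch(w, random_position_sets(N, size, n_permutations, rng))
        for size in sizes
    }
    results = []
    for reg, edges in regulons.items():
        targets = {e.target for e in edges}
        es, leading = gsea_enrichment(signature, targets, weight_exponent)
        null = null_es[len(edges)]
        mu, sd = float(null.mean()), float(null.std(ddof=0))
        if sd == 0:
            nes, p = 0.0, 1.0
        else:
            nes = (es - mu) / sd
            p = float(norm.sf(nes))
        p_emp = (1.0 + np.count_nonzero(null >= es)) / (n_permutations + 1.0)
        results.append(
            EnrichmentResult(reg, es, nes, p, float(p_emp), leading, len(edges))
        )
    results.sort(key=lambda r: (-r.nes, r.regulator))
    return results


def call_candidates(
    results: Sequence[EnrichmentResult], alpha: float = 0.01, use: str = "normal"
) -> list[EnrichmentResult]:
    """Master-regulator candidates: results with P strictly below ``alpha``.

    ``use`` selects the P value: ``"normal"`` (NES mapped through the
    standard-normal tail, the default convention) or ``"empirical"``
    (permutation tail).
    """
    if use not in ("normal", "empirical"):
        raise ValueError("use must be 'normal' or 'empirical'")
    key = (lambda r: r.p) if use == "normal" else (lambda r: r.p_empirical)
    return [r for r in results if key(r) < alpha]


def mr_overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Overlap count and one-sided Fisher/hypergeometric P for two MR sets."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = hypergeom_upper_tail(k, len(universe), len(set_a), len(set_b))
    return k, p
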