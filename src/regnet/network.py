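"""Interactome reverse engineering: pairwise MI, thresholding, DPI, bootstrap.

The inference follows the classic information-theoretic recipe for
expression-based network reconstruction: estimate the mutual information
between every regulator and every candidate target, keep pairs whose MI
clears a permutation-calibrated significance threshold, prune likely
indirect interactions with the Data Processing Inequality (for any chain
A - B - C routed through a regulator B, I(A;C) cannot exceed the weaker of
I(A;B) and I(B;C), so the weakest edge of such a triangle is removed), and
optionally stabilise the edge list by bootstrap consensus over resampled
sample sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binomtest

from .containers import Edge, ExpressionMatrix, Interactome
from . import mi as mi_mod

__all__ = ["NetworkParams", "apply_dpi", "infer_interactome"]

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    """Knobs of the interactome inference.

    ``p_threshold`` (default 1e-8) sets the permutation-null significance
    of the MI cutoff; ``mi_threshold`` overrides it with a fixed cutoff
    when given; ``bonferroni=True`` instead derives the per-pair P value
    as 0.05 / (number of candidate pairs). ``dpi_tolerance`` relaxes the
    triangle pruning (0 = strict). With ``n_bootstrap > 0`` the network is
    re-inferred on bootstrap resamples of the samples and edges are kept
    when their support count beats a chance model (one-sided binomial
    test, Bonferroni-corrected at ``consensus_alpha`` over the edges that
    appeared at least once).
    """

    p_threshold: float = 1e-8
    mi_threshold: float | None = None
    bonferroni: bool = False
    dpi_tolerance: float = 0.0
    n_bootstrap: int = 100
    consensus_alpha: float = 0.05
    estimator: str = "adaptive_partitioning"
    n_null_pairs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if not 0 <= self.dpi_tolerance <= 1:
            raise ValueError("dpi_tolerance must lie in [0, 1]")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be nonnegative")
        if not 0 < self.consensus_alpha < 1:
            raise ValueError("consensus_alpha must lie in (0, 1)")


def apply_dpi(
    edges: Mapping[tuple[str, str], float],
    regulators: Iterable[str],
    tolerance: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Prune indirect edges by the Data Processing Inequality.

    ``edges`` maps unordered node pairs (stored as sorted 2-tuples) to MI
    weights. For every triangle whose indirect path runs through a
    regulator B, the direct edge A-C is removed when
    ``mi(A,C) < (1 - tolerance) * min(mi(A,B), mi(B,C))``. All removal
    decisions are evaluated against the original weights and applied
    simultaneously, so the result does not depend on traversal order.
    """
    if not 0 <= tolerance <= 1:
        raise ValueError("tolerance must lie in [0, 1]")
    regulators = set(regulators)
    normalised: dict[tuple[str, str], float] = {}
    for (a, b), w in edges.items():
        key = (a, b) if a <= b else (b, a)
        if key in normalised and normalised[key] != w:
            raise ValueError(f"conflicting weights for edge {key}")
        normalised[key] = w
    edges = normalised
    adjacency: dict[str, dict[str, float]] = {}
    for (a, b), w in edges.items():
        if w < 0:
            raise ValueError("edge weights must be nonnegative MI values")
        adjacency.setdefault(a, {})[b] = w
        adjacency.setdefault(b, {})[a] = w
    to_remove: set[tuple[str, str]] = set()
    for b in regulators:
        neigh = sorted(adjacency.get(b, {}))
        for i, a in enumerate(neigh):
            for c in neigh[i + 1 :]:
                key = (a, c) if a <= c else (c, a)
                if key not in edges:
                    continue
                if edges[key] < (1.0 - tolerance) * min(adjacency[b][a], adjacency[b][c]):
                    to_remove.add(key)
    return {k: w for k, w in edges.items() if k not in to_remove}


def _candidate_pairs(regulators: Sequence[str], genes: Sequence[str]) -> list[tuple[str, str]]:
    reg_set = set(regulators)
    pairs: list[tuple[str, str]] = []
    for r in regulators:
        for g in genes:
            if g == r:
                continue
            if g in reg_set:
                key = (r, g) if r <= g else (g, r)
                if key != (r, g):
                    continue  # symmetric regulator pair counted once
            pairs.append((r, g))
    return pairs


def _edges_one_run(
    data: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]],
    regulators: Sequence[str],
    threshold: float,
    params: NetworkParams,
) -> dict[tuple[str, str], float]:
    edges: dict[tuple[str, str], float] = {}
    for r, g in pairs:
        est = mi_mod.mutual_information(data[r], data[g], params.estimator)
        if est.value >= threshold and not est.constant_input:
            key = (r, g) if r <= g else (g, r)
            edges[key] = est.value
    return apply_dpi(edges, regulators, params.dpi_tolerance)


def _to_interactome(
    edges: Mapping[tuple[str, str], float],
    regulators: Sequence[str],
    support: Mapping[tuple[str, str], int] | None,
    params_record: dict,
) -> Interactome:
    reg_set = set(regulators)
    regulons: dict[str, list[Edge]] = {r: [] for r in regulators}
    for (a, b), w in sorted(edges.items()):
        s = support.get((a, b), 0) if support else 0
        if a in reg_set:
            regulons[a].append(Edge(b, w, s))
        if b in reg_set:
            regulons[b].append(Edge(a, w, s))
    return Interactome(regulons, params_record)


def infer_interactome(
    expr: ExpressionMatrix,
    regulators: Sequence[str],
    params: NetworkParams | None = None,
) -> Interactome:
    """Infer the regulator -> target interactome from an expression matrix.

    Regulator identifiers absent from the matrix are skipped (and listed
    in the result's ``params["skipped_regulators"]``). With
    ``params.n_bootstrap == 0`` the network is a single MI + threshold +
    DPI pass; otherwise the pass is repeated on bootstrap resamples of the
    samples and the consensus edges are returned with their support
    counts, each weighted by its mean MI over the supporting runs.
    """
    params = params or NetworkParams()
    if len(list(regulators)) == 0:
        raise ValueError("regulator list is empty")
    n_samples = expr.n_samples
    if n_samples < 8:
        raise ValueError("need at least 8 samples to infer a network")
    present = [r for r in regulators if r in expr.genes]
    skipped = [r for r in regulators if r not in expr.genes]
    if skipped:
        logger.warning("skipping %d regulators absent from the matrix", len(skipped))
    if not present:
        raise ValueError("no regulator is present in the expression matrix")

    genes = list(expr.genes)
    pairs = _candidate_pairs(present, genes)
    n_pairs = len(pairs)

    if params.mi_threshold is not None:
        threshold = float(params.mi_threshold)
    else:
        p = 0.05 / n_pairs if params.bonferroni else params.p_threshold
        threshold = mi_mod.mi_threshold(
            n_samples,
            p,
            n_null_pairs=params.n_null_pairs,
            estimator=params.estimator,
            seed=params.seed,
        )
    record = asdict(params)
    record.update(
        applied_mi_threshold=threshold,
        skipped_regulators=skipped,
        n_candidate_pairs=n_pairs,
    )

    arr = expr.values.to_numpy(dtype=float)
    row = {g: i for i, g in enumerate(genes)}

    if params.n_bootstrap == 0:
        data = {g: arr[row[g]] for g in genes}
        edges = _edges_one_run(data, pairs, present, threshold, params)
        return _to_interactome(edges, present, None, record)

    rng = np.random.default_rng(params.seed)
    support: dict[tuple[str, str], int] = {}
    mi_sums: dict[tuple[str, str], float] = {}
    for _ in range(params.n_bootstrap):
        cols = rng.integers(0, n_samples, size=n_samples)
        boot = arr[:, cols]
        data = {g: boot[row[g]] for g in genes}
        edges = _edges_one_run(data, pairs, present, threshold, params)
        for key, w in edges.items():
            support[key] = support.get(key, 0) + 1
            mi_sums[key] = mi_sums.get(key, 0.0) + w
    if not support:
        return _to_interactome({}, present, None, record)
    total_occurrences = sum(support.values())
    p_chance = total_occurrences / (n_pairs * params.n_bootstrap)
    n_candidates = len(support)
    alpha = params.consensus_alpha / n_candidates
    consensus: dict[tuple[str, str], float] = {}
    kept_support: dict[tuple[str, str], int] = {}
    for key, count in support.items():
        p_val = binomtest(count, params.n_bootstrap, p_chance, alternative="greater").pvalue
        # maximal support is always consensus, even when the chance model is
        # saturated (every candidate edge present in every run)
        if count == params.n_bootstrap or p_val < alpha:
            consensus[key] = mi_sums[key] / count
            kept_support[key] = count
    record.update(consensus_chance_rate=p_chance, n_observed_edges=n_candidates)
    return _to_interactome(consensus, present, kept_support, record)
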