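"""Regulator–regulator activity coupling with random-regulon nulls.

Two regulators whose inferred activity profiles co-vary across samples are
candidates for a functional relationship (co-factors, or a signalling
molecule feeding a transcription factor). Coupling is measured as the
Pearson correlation of the two activity rows; its significance is judged
against correlations obtained when the two regulons are replaced by
random gene sets of the same sizes, which preserves everything about the
activity machinery except the regulon membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ActivityMatrix, ExpressionMatrix, Interactome
from .activity import nes_rows_for_gene_sets
from .marina import DEFAULT_MAX_TARGETS, DEFAULT_MIN_REGULON, _eligible_regulons

__all__ = ["CorrelationResult", "activity_correlation", "correlation_significance"]


@dataclass
class CorrelationResult:
    """Observed activity correlation of a regulator pair and its null."""

    pair: tuple[str, str]
    r: float
    p: float
    n_random: int
    null_mean: float
    null_sd: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant activity row")
    return float(np.corrcoef(x, y)[0, 1])


def activity_correlation(activity: ActivityMatrix, a: str, b: str) -> float:
    """Pearson correlation of two regulators' activity rows across samples."""
    for reg in (a, b):
        if reg not in activity.regulators:
            raise ValueError(f"regulator {reg!r} not in the activity matrix")
    return _pearson(activity.row(a), activity.row(b))


def correlation_significance(
    interactome: Interactome,
    expr: ExpressionMatrix,
    pair: tuple[str, str],
    n_random: int = 199,
    n_permutations: int = 200,
    min_regulon: int = DEFAULT_MIN_REGULON,
    weight_exponent: float = 1.0,
    max_targets: int = DEFAULT_MAX_TARGETS,
    seed: int = 0,
) -> CorrelationResult:
    """Test a pair's activity correlation against random-regulon nulls.

    For each of ``n_random`` draws, two mutually disjoint gene sets
    matching the pair's (trimmed) regulon sizes are sampled from the
    measured gene universe (excluding the regulators' own genes), their
    activity rows are inferred with the same single-sample machinery, and
    their correlation recorded. The two-sided, add-one-smoothed empirical
    P is (1 + #{|r_null| >= |r_obs|}) / (n_random + 1).
    """
    if n_random < 19:
        raise ValueError("n_random must be at least 19 for any P resolution")
    a, b = pair
    universe = set(expr.genes)
    regulons = _eligible_regulons(interactome, universe, min_regulon, max_targets)
    for reg in (a, b):
        if reg not in regulons:
            raise ValueError(
                f"regulator {reg!r} is not eligible (needs > {min_regulon - 1} measured targets)"
            )
    set_a = {e.target for e in regulons[a]}
    set_b = {e.target for e in regulons[b]}

    obs = nes_rows_for_gene_sets(
        expr,
        {a: set_a, b: set_b},
        n_permutations,
        weight_exponent,
        seed=seed,
    )
    r_obs = _pearson(obs.loc[a].to_numpy(), obs.loc[b].to_numpy())

    rng = np.random.default_rng(seed)
    pool = np.array(sorted(universe - {a, b}))
    na, nb = len(set_a), len(set_b)
    if na + nb > len(pool):
        raise ValueError("gene universe too small for disjoint random regulons")
    random_sets: dict[str, set] = {}
    for i in range(n_random):
        draw = rng.choice(len(pool), size=na + nb, replace=False)
        random_sets[f"null{i}_a"] = set(pool[draw[:na]])
        random_sets[f"null{i}_b"] = set(pool[draw[na:]])
    null_rows = nes_rows_for_gene_sets(
        expr,
        random_sets,
        n_permutations,
        weight_exponent,
        seed=seed + 1,
    )
    null_r = np.array(
        [
            _pearson(
                null_rows.loc[f"null{i}_a"].to_numpy(),
                null_rows.loc[f"null{i}_b"].to_numpy(),
            )
            for i in range(n_random)
        ]
    )
    p = (1.0 + np.count_nonzero(np.abs(null_r) >= abs(r_obs))) / (n_random + 1.0)
    return CorrelationResult(
        (a, b), r_obs, float(p), n_random, float(null_r.mean()), float(null_r.std(ddof=0))
    )
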