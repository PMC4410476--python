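"""Single-sample regulator activity inference (per-sample regulon NES).

Each sample's signature is its deviation from the dataset mean expression
profile; a regulator's activity in that sample is the normalised
enrichment score of its regulon in that per-sample signature. Unlike the
group-contrast analysis, the per-sample signature keeps the *sign* of the
deviation and genes are ranked by signed score, so the resulting NES is
directional: positive when the regulon's targets are coherently above the
dataset mean (regulator activated in that sample) and negative when below.

The permutation null (random member-position sets) is drawn once per
regulon size and shared across samples; each sample still gets its own
null ES distribution because its signature weights differ.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ActivityMatrix, ExpressionMatrix, GeneSignature, Interactome
from .enrichment import es_batch, random_position_sets
from .marina import DEFAULT_MAX_TARGETS, DEFAULT_MIN_REGULON, _eligible_regulons

__all__ = ["single_sample_signatures", "activity_matrix", "nes_rows_for_gene_sets"]


def single_sample_signatures(
    expr: ExpressionMatrix, scale: str = "mean_difference"
) -> dict[str, GeneSignature]:
    """One signed deviation signature per sample.

    ``scale="mean_difference"`` (default) scores each gene as its value in
    the sample minus its mean across all samples; ``scale="z"``
    additionally divides by the gene's across-sample standard deviation.
    The signatures sum to zero per gene across samples by construction.
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if scale not in ("mean_difference", "z"):
        raise ValueError("scale must be 'mean_difference' or 'z'")
    centred = expr.values.sub(expr.values.mean(axis=1), axis=0)
    if scale == "z":
        sd = expr.values.std(axis=1, ddof=1).replace(0.0, 1.0)
        centred = centred.div(sd, axis=0)
    return {
        s: GeneSignature(centred[s], contrast=f"{s} vs dataset mean", rank_by="signed")
        for s in expr.samples
    }


def nes_rows_for_gene_sets(
    expr: ExpressionMatrix,
    gene_sets: Mapping[str, set],
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    scale: str = "mean_difference",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample NES rows for arbitrary gene sets (sets x samples).

    This is the engine behind :func:`activity_matrix` and behind the
    random-regulon nulls of the activity-correlation test: random
    member-position sets are drawn once per distinct set size and reused
    for every sample and every query set of that size.
    """
    for name, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        missing = set(genes) - set(expr.genes)
        if missing:
            raise ValueError(f"gene set {name!r} has genes outside the matrix")
    signatures = single_sample_signatures(expr, scale)
    N = len(expr.genes)
    rng = np.random.default_rng(seed)
    sizes = sorted({len(g) for g in gene_sets.values()})
    null_pos = {
        size: random_position_sets(N, size, n_permutations, rng) for size in sizes
    }
    names_by_size: dict[int, list[str]] = {}
    for name, genes in gene_sets.items():
        names_by_size.setdefault(len(genes), []).append(name)

    out = pd.DataFrame(
        np.zeros((len(gene_sets), expr.n_samples)),
        index=pd.Index(list(gene_sets), name="set"),
        columns=expr.samples,
    )
    for sample, sig in signatures.items():
        ranking = sig.ranking()
        w = sig.ranked_weights(weight_exponent)
        rank_of = pd.Series(np.arange(N), index=ranking)
        for size in sizes:
            null = es_batch(w, null_pos[size])
            mu, sd = float(null.mean()), float(null.std(ddof=0))
            names = names_by_size[size]
            obs_pos = np.vstack(
                [np.sort(rank_of[list(gene_sets[name])].to_numpy()) for name in names]
            )
            es = es_batch(w, obs_pos)
            nes = np.zeros_like(es) if sd == 0 else (es - mu) / sd
            out.loc[names, sample] = nes
    return out


def activity_matrix(
    interactome: Interactome,
    expr: ExpressionMatrix,
    n_permutations: int = 1000,
    min_regulon: int = DEFAULT_MIN_REGULON,
    weight_exponent: float = 1.0,
    max_targets: int = DEFAULT_MAX_TARGETS,
    scale: str = "mean_difference",
    seed: int = 0,
) -> ActivityMatrix:
    """Infer the regulators x samples activity matrix.

    Regulons are intersected with the measured genes and trimmed exactly
    as in the contrast analysis; regulators below ``min_regulon`` are
    absent from the result.
    """
    universe = set(expr.genes)
    regulons = _eligible_regulons(interactome, universe, min_regulon, max_targets)
    if not regulons:
        raise ValueError("no regulator passed the eligibility rule")
    gene_sets = {reg: {e.target for e in edges} for reg, edges in regulons.items()}
    values = nes_rows_for_gene_sets(
        expr, gene_sets, n_permutations, weight_exponent, scale, seed
    )
    provenance = {
        "n_permutations": n_permutations,
        "min_regulon": min_regulon,
        "weight_exponent": weight_exponent,
        "max_targets": max_targets,
        "scale": scale,
        "seed": seed,
    }
    return ActivityMatrix(values, provenance)
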