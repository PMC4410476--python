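"""Synthetic expression, probe and promoter data with planted ground truth.

The generator emulates the structure of a multi-region, multi-group animal
expression study (several brain regions x ordered exposure groups x a few
subjects per cell) driven by a planted regulatory network: each regulator
has a latent per-sample *activity*, its targets covary with that activity,
and the regulator's own measured expression is only partially coupled to
its activity. That dissociation — activity is what the targets see, not
what the regulator's own transcript shows — is the methodological premise
of regulon-based activity inference, so the generator keeps the two as
distinct variables linked by a configurable decoupling factor.

Every downstream stage of the pipeline (probe cleaning, network inference,
master-regulator calling, single-sample activity, activity correlation,
motif enrichment) can therefore be tested against planted truth without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "TargetEffect",
    "PlantedNetwork",
    "StudyDesign",
    "PlantedTruth",
    "generate_network",
    "simulate_expression",
    "simulate_null_expression",
    "simulate_probes",
    "generate_promoters",
    "gr_like_pfm",
    "desk_network",
    "desk_design",
    "flat_design",
]

DEFAULT_GROUPS = ("naive", "non_dependent", "dependent")


class TargetEffect(NamedTuple):
    sign: int
    weight: float


@dataclass
class PlantedNetwork:
    """Ground-truth regulator -> target map with signed effect weights."""

    regulators: list[str]
    regulon_map: dict[str, dict[str, TargetEffect]]
    background_genes: list[str]

    def __post_init__(self) -> None:
        for reg, targets in self.regulon_map.items():
            if reg in targets:
                raise ValueError(f"regulator {reg!r} targets itself")
            for t, eff in targets.items():
                if not np.isfinite(eff.weight) or eff.weight == 0:
                    raise ValueError(f"effect weight for {reg}->{t} must be finite and nonzero")

    @property
    def target_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for targets in self.regulon_map.values():
            for t in targets:
                seen.setdefault(t)
        return list(seen)

    @property
    def gene_universe(self) -> list[str]:
        return self.regulators + self.target_genes + self.background_genes

    def edges(self) -> list[tuple[str, str, int, float]]:
        return [
            (reg, t, eff.sign, eff.weight)
            for reg, targets in self.regulon_map.items()
            for t, eff in targets.items()
        ]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(reg, t) for reg, targets in self.regulon_map.items() for t in targets}

    def edges_to_tsv(self, path) -> None:
        pd.DataFrame(
            self.edges(), columns=["regulator", "target", "sign", "weight"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class StudyDesign:
    """Sample layout: regions x ordered groups x replicates, plus planted shifts.

    ``activity_shift[regulator][(region, group)]`` moves that regulator's
    latent activity by the given amount in every sample of that design cell.
    """

    regions: Sequence[str] = ("regionA", "regionB")
    groups: Sequence[str] = DEFAULT_GROUPS
    replicates_per_cell: int = 8
    activity_shift: Mapping[str, Mapping[tuple[str, str], float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 2:
            raise ValueError("replicates_per_cell must be >= 2")
        if not self.regions or not self.groups:
            raise ValueError("design must have at least one region and one group")

    def validate_against(self, network: PlantedNetwork) -> None:
        unknown = set(self.activity_shift) - set(network.regulators)
        if unknown:
            raise ValueError(f"activity_shift names unknown regulators: {sorted(unknown)}")

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for region in self.regions:
            for group in self.groups:
                for rep in range(1, self.replicates_per_cell + 1):
                    rows.append(
                        {
                            "sample_id": f"{region}.{group}.s{rep:02d}",
                            "region": region,
                            "group": group,
                            "subject": f"subj{rep:02d}",
                        }
                    )
        return pd.DataFrame(rows).set_index("sample_id")

    @property
    def n_samples(self) -> int:
        return len(self.regions) * len(self.groups) * self.replicates_per_cell


@dataclass
class PlantedTruth:
    """Everything the generator knows: network, latent activities, annotations."""

    network: PlantedNetwork
    latent_activity: pd.DataFrame  # regulators x samples
    sample_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.latent_activity.shape[1] != len(self.sample_annotations):
            raise ValueError("latent activity columns must match sample count")


def generate_network(
    n_regulators: int,
    targets_per_regulator: int,
    target_overlap_fraction: float = 0.0,
    n_background_genes: int = 0,
    sign_mix: float = 0.0,
    seed: int = 0,
) -> PlantedNetwork:
    """Generate a planted network of disjoint-or-overlapping regulons.

    Each regulator receives exactly ``targets_per_regulator`` targets. A
    slot is, with probability ``target_overlap_fraction``, filled from a
    small shared pool (so that the expected fraction of each regulon shared
    with other regulons equals that parameter); otherwise a fresh private
    gene is created. A fraction ``sign_mix`` of effects are repressive
    (sign -1); all effect weights are 1.

    Raises
    ------
    ValueError
        If overlap is requested with fewer than two regulators (sharing is
        then impossible), or parameters are out of range.
    """
    if n_regulators < 1 or targets_per_regulator < 1:
        raise ValueError("n_regulators and targets_per_regulator must be positive")
    if not 0 <= target_overlap_fraction < 1:
        raise ValueError("target_overlap_fraction must lie in [0, 1)")
    if not 0 <= sign_mix <= 1:
        raise ValueError("sign_mix must lie in [0, 1]")
    if target_overlap_fraction > 0 and n_regulators < 2:
        raise ValueError(
            "infeasible sizing: target overlap requires at least 2 regulators"
        )
    rng = np.random.default_rng(seed)
    regulators = [f"R{i:03d}" for i in range(1, n_regulators + 1)]
    # Shared pool sized at twice the expected shared slots per regulon: small
    # enough that pool genes are re-drawn by several regulons, large enough
    # that per-slot Bernoulli(overlap) draws almost never exhaust it.
    pool_size = max(1, int(np.ceil(2 * target_overlap_fraction * targets_per_regulator)))
    shared_pool = [f"S{i:04d}" for i in range(1, pool_size + 1)]
    regulon_map: dict[str, dict[str, TargetEffect]] = {}
    fresh_counter = 0
    for reg in regulators:
        targets: dict[str, TargetEffect] = {}
        shared_draw = rng.random(targets_per_regulator) < target_overlap_fraction
        available_pool = list(shared_pool)
        rng.shuffle(available_pool)
        for slot in range(targets_per_regulator):
            if shared_draw[slot] and available_pool:
                gene = available_pool.pop()
            else:
                fresh_counter += 1
                gene = f"G{fresh_counter:05d}"
            sign = -1 if rng.random() < sign_mix else 1
            targets[gene] = TargetEffect(sign, 1.0)
        regulon_map[reg] = targets
    background = [f"B{i:04d}" for i in range(1, n_background_genes + 1)]
    return PlantedNetwork(regulators, regulon_map, background)


def simulate_expression(
    network: PlantedNetwork,
    design: StudyDesign,
    noise_sd: float = 1.0,
    activity_sd: float = 1.0,
    decoupling: float = 0.5,
    correlated_pairs: Sequence[tuple[str, str, float]] = (),
    target_transform: str | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate expression profiles driven by planted regulator activities.

    Per sample, a regulator's latent activity is a baseline draw
    (sd ``activity_sd``) plus the design's activity shift for the sample's
    (region, group) cell. Each target is the signed, weighted sum of its
    regulators' activities plus independent noise (sd ``noise_sd``); a
    regulator's own expression is its activity plus noise attenuated by the
    ``decoupling`` factor (0 = expression equals activity); background
    genes are pure noise.

    Parameters
    ----------
    correlated_pairs
        Optional (regulator_a, regulator_b, rho) triples; the baseline
        activity of ``b`` is made to correlate with ``a``'s at level rho.
    target_transform
        ``None`` (linear-Gaussian targets) or ``"cube"``, which applies
        the strictly monotone map x -> x**3 to each target value — useful
        for checking that rank-based dependence measures are unaffected.
    """
    if noise_sd <= 0 or activity_sd <= 0:
        raise ValueError("noise_sd and activity_sd must be positive")
    if target_transform not in (None, "cube"):
        raise ValueError("target_transform must be None or 'cube'")
    design.validate_against(network)
    rng = np.random.default_rng(seed)
    annotations = design.sample_table()
    samples = annotations.index
    n_samples = len(samples)
    regulators = network.regulators
    r_index = {r: i for i, r in enumerate(regulators)}

    z = rng.standard_normal((len(regulators), n_samples))
    for a, b, rho in correlated_pairs:
        if not -1 <= rho <= 1:
            raise ValueError("correlation rho must lie in [-1, 1]")
        ia, ib = r_index[a], r_index[b]
        z[ib] = rho * z[ia] + np.sqrt(1.0 - rho**2) * z[ib]
    activity = activity_sd * z
    for reg, shifts in design.activity_shift.items():
        i = r_index[reg]
        for (region, group), shift in shifts.items():
            mask = (annotations["region"] == region) & (annotations["group"] == group)
            activity[i, mask.to_numpy()] += shift

    genes = network.gene_universe
    values = np.empty((len(genes), n_samples))
    g_index = {g: i for i, g in enumerate(genes)}
    # regulators: activity + attenuated independent noise
    for reg in regulators:
        noise = rng.standard_normal(n_samples) * noise_sd * decoupling
        values[g_index[reg]] = activity[r_index[reg]] + noise
    # targets: signed weighted sum of regulating activities + noise
    target_rows: dict[str, np.ndarray] = {}
    for reg, targets in network.regulon_map.items():
        for t, eff in targets.items():
            contrib = eff.sign * eff.weight * activity[r_index[reg]]
            target_rows[t] = target_rows.get(t, 0.0) + contrib
    for t in network.target_genes:
        row = target_rows[t] + rng.standard_normal(n_samples) * noise_sd
        if target_transform == "cube":
            row = row**3
        values[g_index[t]] = row
    for g in network.background_genes:
        values[g_index[g]] = rng.standard_normal(n_samples) * noise_sd

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        annotations,
    )
    truth = PlantedTruth(
        network,
        pd.DataFrame(activity, index=pd.Index(regulators, name="regulator"), columns=samples),
        annotations,
    )
    return expr, truth


def simulate_null_expression(
    network: PlantedNetwork,
    design: StudyDesign,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Fully exchangeable null data: every gene is independent noise.

    The gene universe and sample layout match ``network`` and ``design``,
    but no gene is coupled to any regulator — the condition under which
    gene-label permutation nulls are exactly calibrated. Contrast with
    :func:`simulate_expression` with all shifts zero, where regulon
    targets still co-vary through their regulator's baseline activity;
    that co-expression makes label-shuffling P values anticonservative
    even though the group contrast is null (a known property of
    gene-permutation enrichment nulls, documented in the methods note).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    annotations = design.sample_table()
    genes = network.gene_universe
    values = rng.standard_normal((len(genes), len(annotations))) * noise_sd
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=annotations.index),
        annotations,
    )


def simulate_probes(
    expr: ExpressionMatrix,
    probes_per_gene: int = 4,
    bad_probe_fraction: float = 0.25,
    probe_noise_sd: float = 0.1,
    seed: int = 0,
):
    """Explode a gene matrix into probes, a fraction of which are junk.

    Good probes are the gene value plus small independent noise
    (sd ``probe_noise_sd``); bad probes (each probe independently bad with
    probability ``bad_probe_fraction``) are pure standard-normal noise with
    no relation to the gene. Returns the probe matrix and a truth table
    (probe_id, gene, is_bad).
    """
    from .probes import ProbeMatrix  # local import to avoid a cycle

    if probes_per_gene < 2:
        raise ValueError("probes_per_gene must be >= 2 for correlation clustering")
    if not 0 <= bad_probe_fraction <= 1:
        raise ValueError("bad_probe_fraction must lie in [0, 1]")
    if probe_noise_sd <= 0:
        raise ValueError("probe_noise_sd must be positive")
    rng = np.random.default_rng(seed)
    n_samples = expr.n_samples
    rows, probe_ids, genes, is_bad = [], [], [], []
    for gene in expr.genes:
        base = expr.values.loc[gene].to_numpy(dtype=float)
        for j in range(1, probes_per_gene + 1):
            bad = bool(rng.random() < bad_probe_fraction)
            if bad:
                row = rng.standard_normal(n_samples)
            else:
                row = base + rng.standard_normal(n_samples) * probe_noise_sd
            rows.append(row)
            probe_ids.append(f"{gene}_p{j}")
            genes.append(gene)
            is_bad.append(bad)
    values = pd.DataFrame(
        np.asarray(rows), index=pd.Index(probe_ids, name="probe_id"), columns=expr.samples
    )
    probe_to_gene = pd.Series(genes, index=values.index, name="gene")
    truth = pd.DataFrame(
        {"gene": genes, "is_bad": is_bad}, index=values.index
    ).reset_index()
    return ProbeMatrix(values, probe_to_gene, expr.annotations), truth


def generate_promoters(
    n_target: int,
    n_control: int,
    pssm,
    length: int = 1000,
    planted_fraction_target: float = 0.3,
    planted_fraction_control: float = 0.02,
    gc_content: float = 0.5,
    seed: int = 0,
):
    """Generate labelled promoter sets with motif instances planted.

    Background bases are i.i.d. with the requested GC content. In a
    Bernoulli(``planted_fraction_*``) subset of each class one motif
    instance, sampled per-position from the PSSM's frequencies, is embedded
    at a uniform random position on a uniform random strand.

    Returns
    -------
    (PromoterSet, PromoterSet, pandas.DataFrame)
        Target set, control set and a label table
        (name, promoter_class, planted).
    """
    from .motif import PromoterSet, reverse_complement

    if not 0 <= planted_fraction_target <= 1 or not 0 <= planted_fraction_control <= 1:
        raise ValueError("planted fractions must lie in [0, 1]")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must lie in (0, 1)")
    if pssm.length > length:
        raise ValueError("motif longer than promoter")
    rng = np.random.default_rng(seed)
    base_probs = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    alphabet = np.array(list("ACGT"))

    def make_class(prefix: str, n: int, fraction: float, label: str):
        seqs: dict[str, str] = {}
        records = []
        for i in range(1, n + 1):
            name = f"{prefix}{i:04d}"
            seq = "".join(alphabet[rng.choice(4, size=length, p=base_probs)])
            planted = bool(rng.random() < fraction)
            if planted:
                site = pssm.sample_site(rng)
                if rng.random() < 0.5:
                    site = reverse_complement(site)
                pos = int(rng.integers(0, length - pssm.length + 1))
                seq = seq[:pos] + site + seq[pos + pssm.length :]
            seqs[name] = seq
            records.append({"name": name, "promoter_class": label, "planted": planted})
        return PromoterSet(seqs, label), records

    targets, rec_t = make_class("t", n_target, planted_fraction_target, "target")
    controls, rec_c = make_class("c", n_control, planted_fraction_control, "control")
    labels = pd.DataFrame(rec_t + rec_c)
    return targets, controls, labels


def gr_like_pfm():
    """A synthetic nuclear-receptor-style binding motif for fixtures.

    A 14 bp half-palindromic matrix (two strong half-sites around a weak
    spacer) with heterogeneous per-position counts, loosely shaped like a
    glucocorticoid-receptor response element. It is *not* a database
    matrix: the counts are invented so that window-score distributions
    are realistic (mixed information content, no score-lattice ties).
    """
    from .motif import PSSM

    counts = np.array(
        # A   G   A   A   C   A   n   n   T   G   T   T   C   T
        [
            [54, 2, 51, 49, 1, 40, 19, 14, 2, 1, 3, 2, 3, 3],  # A
            [2, 1, 4, 5, 55, 8, 14, 17, 1, 2, 2, 3, 51, 4],    # C
            [2, 55, 2, 3, 1, 6, 15, 18, 3, 53, 2, 1, 2, 2],    # G
            [2, 2, 3, 3, 3, 6, 12, 11, 54, 4, 53, 54, 4, 51],  # T
        ],
        dtype=float,
    )
    return PSSM(counts)


# ---------------------------------------------------------------------------
# Desk-scale presets: minutes-scale end-to-end runs with one shifted regulator.

def desk_network(seed: int = 0) -> PlantedNetwork:
    """10 regulators x 30 targets + 200 background genes, all-activating."""
    return generate_network(
        n_regulators=10,
        targets_per_regulator=30,
        target_overlap_fraction=0.0,
        n_background_genes=200,
        sign_mix=0.0,
        seed=seed,
    )


def desk_design(
    shifted_regulator: str = "R001",
    shift: float = 2.0,
    regions: Sequence[str] = ("regionA", "regionB"),
    groups: Sequence[str] = DEFAULT_GROUPS,
    replicates_per_cell: int = 8,
) -> StudyDesign:
    """2 regions x 3 groups x 8 replicates with one regulator shifted.

    The shifted regulator's latent activity is raised by ``shift`` in every
    region of the last (most-exposed) group, the analogue of a regulator
    recruited by the dependent phenotype.
    """
    shifts = {shifted_regulator: {(r, groups[-1]): shift for r in regions}}
    return StudyDesign(regions, groups, replicates_per_cell, shifts)


def flat_design(n_samples: int = 200, groups: Sequence[str] = ("naive", "dependent")) -> StudyDesign:
    """A shift-free two-group design with ``n_samples`` total samples."""
    n_cells = 2 * len(groups)
    if n_samples % n_cells:
        raise ValueError(f"n_samples must be divisible by {n_cells}")
    return StudyDesign(
        regions=("regionA", "regionB"),
        groups=groups,
        replicates_per_cell=n_samples // n_cells,
        activity_shift={},
    )
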