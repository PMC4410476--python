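"""Probe-to-gene collapsing by correlation clustering.

Microarray platforms measure each transcript with several probes, some of
which are mis-mapped or otherwise uninformative. This stage clusters each
gene's probes by their correlation across samples, keeps the largest
internally consistent cluster, and collapses it to one gene-level value —
a simplified stand-in for probe-cleaning tools that additionally re-map
probes against a transcript database (re-mapping is out of scope here; the
probe -> gene map is an input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from .containers import ExpressionMatrix

__all__ = ["ProbeMatrix", "clean_probes"]


@dataclass
class ProbeMatrix:
    """Probes x samples values plus a probe -> gene map.

    Probes absent from the map (NaN gene) are treated as unmapped.
    Optional sample annotations are carried through to the collapsed
    gene-level matrix.
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("probe ids must be unique")
        for g in self.probe_to_gene.dropna():
            if not isinstance(g, str) or not g:
                raise ValueError("mapped gene identifiers must be nonempty strings")

    def to_tsv(self, values_path, map_path) -> None:
        self.values.rename_axis("probe_id").to_csv(values_path, sep="\t")
        self.probe_to_gene.rename_axis("probe_id").rename("gene").to_csv(map_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, map_path, annotations_path=None) -> "ProbeMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
        pmap = pd.read_csv(map_path, sep="\t", index_col=0, comment="#")["gene"]
        ann = None
        if annotations_path is not None:
            ann = pd.read_csv(annotations_path, sep="\t", index_col=0, comment="#")
        return cls(values, pmap, ann)


def _correlation(rows: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        rows = np.apply_along_axis(rankdata, 1, rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(rows)
    return np.nan_to_num(corr, nan=-2.0)  # constant probes correlate with nothing


def _mean_pairwise(corr: np.ndarray, members: np.ndarray) -> float:
    if len(members) < 2:
        return 1.0
    pairs = [corr[i, j] for i, j in combinations(members, 2)]
    return float(np.mean(pairs))


def clean_probes(
    probes: ProbeMatrix,
    min_probe_correlation: float = 0.5,
    min_probes_per_gene: int = 2,
    method: str = "pearson",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse a probe matrix to gene level by correlation clustering.

    Per gene, probes are linked when their pairwise correlation is at
    least ``min_probe_correlation``; the single-linkage components of this
    threshold graph are the candidate clusters. The largest component
    whose mean within-cluster correlation also meets the threshold is
    retained (ties: higher mean correlation, then lexicographically
    smallest probe id); the gene's value is the mean of the retained
    probes. Genes whose retained cluster has fewer than
    ``min_probes_per_gene`` probes are dropped.

    Returns
    -------
    (ExpressionMatrix, pandas.DataFrame)
        The collapsed matrix and a per-probe fate report with columns
        probe_id, gene, retained, reason.
    """
    if not -1 < min_probe_correlation <= 1:
        raise ValueError("min_probe_correlation must lie in (-1, 1]")
    if min_probes_per_gene < 1:
        raise ValueError("min_probes_per_gene must be positive")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if probes.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for probe correlations")

    report_rows: list[dict] = []
    gene_values: dict[str, np.ndarray] = {}

    mapped = probes.probe_to_gene.dropna()
    for probe in probes.values.index:
        if probe not in mapped.index:
            report_rows.append(
                {"probe_id": probe, "gene": "", "retained": False, "reason": "unmapped"}
            )

    for gene, members in sorted(mapped.groupby(mapped).groups.items()):
        probe_ids = sorted(members)
        rows = probes.values.loc[probe_ids].to_numpy(dtype=float)
        corr = _correlation(rows, method)
        adj = csr_matrix(corr >= min_probe_correlation)
        n_comp, labels = connected_components(adj, directed=False)
        clusters = []
        for c in range(n_comp):
            idx = np.flatnonzero(labels == c)
            mean_corr = _mean_pairwise(corr, idx)
            if mean_corr >= min_probe_correlation:
                clusters.append((len(idx), mean_corr, [probe_ids[i] for i in idx], idx))
        if clusters:
            clusters.sort(key=lambda c: (-c[0], -c[1], c[2]))
            size, _, kept_ids, kept_idx = clusters[0]
        else:
            size, kept_ids, kept_idx = 0, [], np.array([], dtype=int)

        if size >= min_probes_per_gene:
            gene_values[gene] = rows[kept_idx].mean(axis=0)
            kept = set(kept_ids)
            for p in probe_ids:
                reason = "retained" if p in kept else "outside_selected_cluster"
                report_rows.append(
                    {"probe_id": p, "gene": gene, "retained": p in kept, "reason": reason}
                )
        else:
            reason = "gene_below_min_probes" if size else "no_consistent_cluster"
            for p in probe_ids:
                report_rows.append(
                    {"probe_id": p, "gene": gene, "retained": False, "reason": reason}
                )

    report = pd.DataFrame(report_rows, columns=["probe_id", "gene", "retained", "reason"])
    if not gene_values:
        warnings.warn("all probes dropped; returning an empty gene matrix")
    values = pd.DataFrame(
        gene_values.values(),
        index=pd.Index(gene_values.keys(), name="gene"),
        columns=probes.values.columns,
    )
    annotations = probes.annotations
    if annotations is None:
        annotations = pd.DataFrame(
            {"region": "NA", "group": "NA", "subject": "NA"},
            index=probes.values.columns,
        )
    return ExpressionMatrix(values, annotations), report
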