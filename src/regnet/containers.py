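"""Core in-memory containers shared across the pipeline stages.

The containers wrap :class:`pandas.DataFrame`/:class:`pandas.Series` objects
(the field's lingua franca for gene-by-sample data) and add the light
validation and the plain-text I/O dialects used throughout the package:
tab-delimited matrices with an identifier column, TSV edge lists, and TSV
activity tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "Edge",
    "Interactome",
    "EnrichmentResult",
    "ActivityMatrix",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample annotations.

    Parameters
    ----------
    values
        Real-valued matrix, rows indexed by gene identifier, columns by
        sample identifier.
    annotations
        One row per sample (index = sample id) with at least the columns
        ``region``, ``group`` and ``subject``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.annotations.index):
            # allow same set, different order
            if set(self.values.columns) != set(self.annotations.index):
                raise ValueError(
                    "sample ids of expression values and annotations differ"
                )
            self.annotations = self.annotations.loc[self.values.columns]
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.annotations.loc[ids])

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.annotations["group"] == group
        return list(self.annotations.index[mask])

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, values_path: str | Path, annotations_path: str | Path) -> None:
        self.values.rename_axis("gene").to_csv(values_path, sep="\t")
        self.annotations.rename_axis("sample_id").to_csv(annotations_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, values_path: str | Path, annotations_path: str | Path
    ) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
        ann = pd.read_csv(annotations_path, sep="\t", index_col=0, comment="#")
        ann.index = ann.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values, ann)


@dataclass
class GeneSignature:
    """Per-gene differential scores defining a ranking of the gene universe.

    ``rank_by="abs"`` ranks genes by descending ``|score|`` (the convention
    for two-group t-statistic signatures); ``rank_by="signed"`` ranks by
    descending signed score (used for single-sample deviation signatures,
    where the direction of the deviation carries the activity sign).
    Ties are broken by gene identifier.
    """

    scores: pd.Series
    contrast: str = ""
    rank_by: str = "abs"

    def __post_init__(self) -> None:
        if self.rank_by not in ("abs", "signed"):
            raise ValueError("rank_by must be 'abs' or 'signed'")
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in signature")
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("signature scores must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    def ranking(self) -> pd.Index:
        """Genes ordered by the ranking rule (descending, ties by gene id)."""
        s = self.scores.sort_index(kind="stable")
        key = s.abs() if self.rank_by == "abs" else s
        return key.sort_values(ascending=False, kind="stable").index

    def ranked_weights(self, weight_exponent: float = 1.0) -> np.ndarray:
        """|score|^w along the ranking order."""
        ranked = self.scores.loc[self.ranking()].to_numpy(dtype=float)
        return np.abs(ranked) ** float(weight_exponent)


@dataclass(frozen=True)
class Edge:
    """One inferred regulator->target interaction."""

    target: str
    mi: float
    support: int = 0


@dataclass
class Interactome:
    """Regulator -> regulon mapping with MI weights and bootstrap support."""

    regulons: dict[str, list[Edge]]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reg, edges in self.regulons.items():
            for e in edges:
                if e.target == reg:
                    raise ValueError(f"self-edge on regulator {reg!r}")
                if e.mi < 0:
                    raise ValueError("negative MI weight")

    @property
    def regulators(self) -> list[str]:
        return list(self.regulons)

    def regulon_targets(self, regulator: str) -> set[str]:
        return {e.target for e in self.regulons[regulator]}

    def gene_universe(self) -> set[str]:
        genes: set[str] = set(self.regulons)
        for edges in self.regulons.values():
            genes.update(e.target for e in edges)
        return genes

    def n_edges(self) -> int:
        return sum(len(v) for v in self.regulons.values())

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (reg, e.target, e.mi, e.support)
            for reg, edges in self.regulons.items()
            for e in edges
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "mi", "support"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, params: dict | None = None) -> "Interactome":
        regulons: dict[str, list[Edge]] = {}
        for row in df.itertuples(index=False):
            regulons.setdefault(str(row.regulator), []).append(
                Edge(str(row.target), float(row.mi), int(row.support))
            )
        return cls(regulons, params or {})

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            Path(sidecar).write_text(json.dumps(self.params, indent=1, default=str))

    def to_adjacency(self, path: str | Path) -> None:
        """Two-column (regulator, target) text format for interoperability."""
        with open(path, "w") as fh:
            for reg in self.regulons:
                for e in self.regulons[reg]:
                    fh.write(f"{reg}\t{e.target}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path | None = None) -> "Interactome":
        df = pd.read_csv(path, sep="\t", comment="#")
        params = {}
        if sidecar is not None and Path(sidecar).exists():
            params = json.loads(Path(sidecar).read_text())
        return cls.from_frame(df, params)


@dataclass
class EnrichmentResult:
    """Regulon enrichment of one regulator in one signature."""

    regulator: str
    es: float
    nes: float
    p: float
    p_empirical: float
    leading_edge: list[str]
    regulon_size_used: int

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["leading_edge"] = ";".join(self.leading_edge)
        return d


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [r.as_dict() for r in results]
    cols = [
        "regulator",
        "es",
        "nes",
        "p",
        "p_empirical",
        "regulon_size_used",
        "leading_edge",
    ]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


@dataclass
class ActivityMatrix:
    """Regulators x samples matrix of single-sample activity scores (NES)."""

    values: pd.DataFrame
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("activity matrix entries must be finite")

    @property
    def regulators(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def row(self, regulator: str) -> np.ndarray:
        return self.values.loc[regulator].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("regulator").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ActivityMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0, comment="#"))
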