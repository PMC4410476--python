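"""Promoter binding-site scanning and enrichment testing.

A transcription-factor binding motif, given as a position frequency
matrix (JASPAR PFM flat text), is turned into a log-likelihood-ratio
scoring matrix with a pseudocount and a background base composition. Each
promoter (by convention a 1,000 bp window, 500 bp either side of the
transcription start site) is scanned on both strands and summarised by
its maximum window score. A promoter "has an occurrence" when that score
clears a cutoff — by default the 95th percentile of the control set's
maxima — and enrichment of occurrences among the inferred-target
promoters relative to control promoters is tested with a one-sided Fisher
exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import fisher_exact_enrichment

__all__ = [
    "PSSM",
    "PromoterSet",
    "reverse_complement",
    "score_sequence",
    "enrichment_test",
    "read_fasta_promoters",
    "write_fasta_promoters",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE["N"] = 4
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PSSM:
    """Position-specific scoring matrix built from base counts.

    ``counts`` is a (4, L) array of base counts (rows A, C, G, T). A
    pseudocount (default 0.5 per base) regularises the per-position
    frequencies; the background is uniform unless supplied.
    """

    counts: np.ndarray
    pseudocount: float = 0.5
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("counts must be a (4, L) array with L >= 4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a length-4 probability vector")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        padded = self.counts + self.pseudocount
        return padded / padded.sum(axis=0, keepdims=True)

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        bg = self.background if background is None else np.asarray(background, dtype=float)
        return np.log(self.frequencies / bg[:, None])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.frequencies.argmax(axis=0))

    def sample_site(self, rng: np.random.Generator) -> str:
        freqs = self.frequencies
        return "".join(
            _BASES[rng.choice(4, p=freqs[:, j])] for j in range(self.length)
        )

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_jaspar(cls, path: str | Path, pseudocount: float = 0.5) -> "PSSM":
        """Read a JASPAR PFM flat file (4 labelled or bare count rows)."""
        from Bio import motifs

        text = Path(path).read_text()
        fmt = "jaspar" if text.lstrip().startswith(">") else "pfm-four-rows"
        from io import StringIO

        motif = motifs.read(StringIO(text), fmt)
        counts = np.array([motif.counts[b] for b in _BASES], dtype=float)
        return cls(counts, pseudocount)

    def to_jaspar(self, path: str | Path, name: str = "motif") -> None:
        lines = [f">{name}"]
        for i, b in enumerate(_BASES):
            row = " ".join(f"{int(round(c)):6d}" for c in self.counts[i])
            lines.append(f"{b} [{row} ]")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PromoterSet:
    """Named promoter sequences sharing one class label (target | control)."""

    sequences: dict[str, str]
    label: str = ""

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for promoter {name!r}")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"promoter {name!r} has characters outside ACGTN")

    def __len__(self) -> int:
        return len(self.sequences)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int64, count=len(seq))


def _window_scores(codes: np.ndarray, score_matrix: np.ndarray) -> np.ndarray:
    """Score every length-L window of an encoded sequence; N windows -> -inf."""
    L = score_matrix.shape[1]
    n_win = len(codes) - L + 1
    padded = np.vstack([score_matrix, np.zeros(L)])  # row 4 = N placeholder
    scores = np.zeros(n_win)
    for j in range(L):
        scores += padded[codes[j : j + n_win], j]
    has_n = np.convolve((codes == 4).astype(float), np.ones(L), mode="valid") > 0
    scores[has_n] = -np.inf
    return scores


def score_sequence(
    pssm: PSSM, sequence: str, background: np.ndarray | None = None
) -> tuple[float, int, str]:
    """Best log-likelihood-ratio motif match in a sequence, both strands.

    Returns ``(score, position, strand)`` where ``position`` is the
    0-based start of the best window on the forward strand and ``strand``
    is ``"+"`` or ``"-"``. Windows containing N are skipped. Ties resolve
    to the smaller position, then to the forward strand.
    """
    L = pssm.length
    if len(sequence) < L:
        raise ValueError("sequence shorter than the motif")
    codes = _encode(sequence.upper())
    S = pssm.log_odds(background)
    fwd = _window_scores(codes, S)
    # reverse-strand score at forward position i = score of the reverse
    # complement of the window, i.e. the base-complemented, position-reversed
    # matrix applied to the forward encoding
    rev = _window_scores(codes, S[::-1, ::-1])
    if not np.isfinite(fwd).any() and not np.isfinite(rev).any():
        raise ValueError("no window free of N")
    stacked = np.column_stack([fwd, rev]).ravel()  # position-major, '+' first
    best = int(np.argmax(stacked))
    return float(stacked[best]), best // 2, "+" if best % 2 == 0 else "-"


def _pooled_background(promoters: PromoterSet) -> np.ndarray:
    counts = np.zeros(4)
    for seq in promoters.sequences.values():
        codes = _encode(seq.upper())
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


@dataclass
class MotifEnrichmentResult:
    """2x2 occurrence table, its Fisher P, and the per-promoter maxima."""

    table: tuple[int, int, int, int]  # (target_hit, target_miss, control_hit, control_miss)
    p: float
    threshold: float
    target_scores: pd.Series
    control_scores: pd.Series


def enrichment_test(
    targets: PromoterSet,
    controls: PromoterSet,
    pssm: PSSM,
    score_threshold: float | None = None,
    control_quantile: float = 0.95,
    background: np.ndarray | None = None,
) -> MotifEnrichmentResult:
    """Fisher test of motif occurrences in target vs control promoters.

    The occurrence cutoff is ``score_threshold`` when given, else the
    ``control_quantile`` (default 95th percentile) of the control set's
    maximum scores. The background base composition defaults to the
    pooled control sequences.
    """
    if len(targets) == 0 or len(controls) == 0:
        raise ValueError("both promoter sets must be nonempty")
    bg = _pooled_background(controls) if background is None else np.asarray(background)
    t_scores = pd.Series(
        {n: score_sequence(pssm, s, bg)[0] for n, s in targets.sequences.items()},
        name="max_score",
    )
    c_scores = pd.Series(
        {n: score_sequence(pssm, s, bg)[0] for n, s in controls.sequences.items()},
        name="max_score",
    )
    threshold = (
        float(np.quantile(c_scores, control_quantile))
        if score_threshold is None
        else float(score_threshold)
    )
    t_hit = int((t_scores >= threshold).sum())
    c_hit = int((c_scores >= threshold).sum())
    table = (t_hit, len(targets) - t_hit, c_hit, len(controls) - c_hit)
    total_hit = t_hit + c_hit
    if total_hit == 0 or total_hit == len(targets) + len(controls):
        warnings.warn("degenerate occurrence table (all or none); P is uninformative")
    p = fisher_exact_enrichment(*table)
    return MotifEnrichmentResult(table, p, threshold, t_scores, c_scores)


# -- FASTA I/O (headers carry class and planting labels) --------------------

def write_fasta_promoters(
    path: str | Path,
    promoters: PromoterSet,
    planted: dict[str, bool] | None = None,
) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for name, seq in promoters.sequences.items():
        desc = f"class={promoters.label}"
        if planted is not None:
            desc += f" planted={int(planted.get(name, False))}"
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    seqio_write(records, str(path), "fasta")


def read_fasta_promoters(path: str | Path, label: str = "") -> PromoterSet:
    from Bio.SeqIO import parse as seqio_parse

    seqs: dict[str, str] = {}
    inferred = label
    for rec in seqio_parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        if not inferred and "class=" in rec.description:
            inferred = rec.description.split("class=")[1].split()[0]
    return PromoterSet(seqs, inferred)
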