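"""End-to-end pipeline orchestration with a flat-text config file.

The pipeline mirrors the study workflow: (optional) probe cleaning, one
pooled interactome from all samples, per-region group-contrast signatures,
master-regulator calling per region and contrast, cross-region MR-set
overlap tests, per-sample activity inference, and optional activity
correlation and promoter motif enrichment. One global seed fans out to
per-stage seeds by fixed offsets, and every artifact carries the config
hash and seed in a comment header, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import activity_matrix
from .containers import ExpressionMatrix, Interactome, results_to_frame
from .correlation import correlation_significance
from .marina import call_candidates, compute_signature, marina, mr_overlap_test
from .motif import PSSM, enrichment_test, read_fasta_promoters
from .network import NetworkParams, infer_interactome
from .probes import ProbeMatrix, clean_probes

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_STAGE_SEED_OFFSETS = {
    "network": 1,
    "marina": 2,
    "activity": 3,
    "correlation": 4,
}

_BOOL_KEYS = {"bonferroni", "per_region", "run_activity_correlation"}
_INT_KEYS = {
    "seed",
    "n_bootstrap",
    "n_null_pairs",
    "n_permutations",
    "activity_permutations",
    "min_regulon",
    "max_targets",
    "n_random",
}
_FLOAT_KEYS = {
    "p_threshold",
    "mi_threshold",
    "dpi_tolerance",
    "consensus_alpha",
    "alpha",
    "weight_exponent",
    "min_probe_correlation",
}


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration (flat ``key = value`` text file).

    Required keys: ``expression`` and ``annotations`` (or ``probes`` +
    ``probe_map``), ``regulators``, ``contrasts`` (comma-separated
    ``groupA:groupB`` pairs), ``outdir``. Everything else has defaults.
    """

    expression: str | None = None
    annotations: str | None = None
    probes: str | None = None
    probe_map: str | None = None
    regulators: str = ""
    contrasts: str = ""
    outdir: str = "run"
    seed: int = 0
    per_region: bool = False
    # probe cleaning
    min_probe_correlation: float = 0.5
    min_probes_per_gene: int = 2
    # network
    p_threshold: float = 1e-8
    mi_threshold: float | None = None
    bonferroni: bool = False
    dpi_tolerance: float = 0.0
    n_bootstrap: int = 0
    consensus_alpha: float = 0.05
    estimator: str = "adaptive_partitioning"
    n_null_pairs: int = 1000
    # enrichment
    n_permutations: int = 10000
    activity_permutations: int = 1000
    alpha: float = 0.01
    weight_exponent: float = 1.0
    min_regulon: int = 26
    max_targets: int = 100
    # optional stages
    run_activity_correlation: bool = False
    n_random: int = 199
    promoters_target: str | None = None
    promoters_control: str | None = None
    pssm: str | None = None
    raw_text: str = field(default="", repr=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        kwargs: dict = {"raw_text": text}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno} is not 'key = value': {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r} (line {lineno})")
            if key in _BOOL_KEYS:
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            elif key in _FLOAT_KEYS:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        text = self.raw_text or json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "raw_text"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_SEED_OFFSETS[stage]) % 2**31

    def contrast_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for item in self.contrasts.split(","):
            item = item.strip()
            if not item:
                continue
            a, _, b = item.partition(":")
            if not a or not b:
                raise ValueError(f"contrast {item!r} must be 'groupA:groupB'")
            pairs.append((a.strip(), b.strip()))
        if not pairs:
            raise ValueError("config must list at least one contrast")
        return pairs

    def validate_paths(self) -> None:
        if self.probes:
            needed = [self.probes, self.probe_map, self.annotations]
        else:
            needed = [self.expression, self.annotations]
        needed.append(self.regulators)
        for extra in (self.promoters_target, self.promoters_control, self.pssm):
            if extra:
                needed.append(extra)
        missing = [p for p in needed if not p or not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing files: {missing}")


def _done(log: dict, stage: str, t0: float) -> None:
    # wall time goes to the logger only, keeping run_log.json bit-identical
    # across reruns with the same seed
    logger.info("stage %s finished in %.2fs", stage, time.time() - t0)
    log["stages"][stage] = "ok"


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the run directory.

    Stage failures abort with the failing stage named; artifacts written
    before the failure are retained for inspection.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={config.config_hash()} seed={config.seed}\n"
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    stage = "load"
    try:
        t0 = time.time()
        if config.probes:
            stage = "clean"
            pm = ProbeMatrix.from_tsv(config.probes, config.probe_map, config.annotations)
            expr, report = clean_probes(
                pm, config.min_probe_correlation, config.min_probes_per_gene
            )
            _write_tsv(report, outdir / "probe_report.tsv", header)
            _write_tsv(
                expr.values.rename_axis("gene"), outdir / "expression_clean.tsv",
                header, index=True,
            )
        else:
            expr = ExpressionMatrix.from_tsv(config.expression, config.annotations)
        regulators = [
            line.strip()
            for line in Path(config.regulators).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        _done(log, stage, t0)

        stage = "infer-network"
        t0 = time.time()
        params = NetworkParams(
            p_threshold=config.p_threshold,
            mi_threshold=config.mi_threshold,
            bonferroni=config.bonferroni,
            dpi_tolerance=config.dpi_tolerance,
            n_bootstrap=config.n_bootstrap,
            consensus_alpha=config.consensus_alpha,
            estimator=config.estimator,
            n_null_pairs=config.n_null_pairs,
            seed=config.stage_seed("network"),
        )
        regions = sorted(set(expr.annotations["region"]))
        networks: dict[str, Interactome]
        if config.per_region:
            networks = {
                region: infer_interactome(
                    expr.subset_samples(
                        expr.annotations.index[expr.annotations["region"] == region]
                    ),
                    regulators,
                    params,
                )
                for region in regions
            }
        else:
            networks = {"pooled": infer_interactome(expr, regulators, params)}
        for name, inter in networks.items():
            with open(outdir / f"interactome_{name}.tsv", "w") as fh:
                fh.write(header)
                inter.to_frame().to_csv(fh, sep="\t", index=False)
            (outdir / f"interactome_{name}.params.json").write_text(
                json.dumps(inter.params, indent=1, default=str)
            )
        _done(log, stage, t0)

        stage = "marina"
        t0 = time.time()
        candidate_sets: dict[tuple[str, str], set] = {}
        universe_by_contrast: dict[str, set] = {}
        for region in regions:
            region_ids = expr.annotations.index[expr.annotations["region"] == region]
            region_expr = expr.subset_samples(region_ids)
            inter = networks[region if config.per_region else "pooled"]
            for group_a, group_b in config.contrast_pairs():
                sig = compute_signature(region_expr, group_a, group_b)
                results = marina(
                    inter,
                    sig,
                    n_permutations=config.n_permutations,
                    min_regulon=config.min_regulon,
                    weight_exponent=config.weight_exponent,
                    max_targets=config.max_targets,
                    seed=config.stage_seed("marina"),
                )
                tag = f"{region}_{group_a}_vs_{group_b}"
                _write_tsv(results_to_frame(results), outdir / f"marina_{tag}.tsv", header)
                candidates = call_candidates(results, config.alpha)
                _write_tsv(
                    results_to_frame(candidates), outdir / f"candidates_{tag}.tsv", header
                )
                contrast_tag = f"{group_a}_vs_{group_b}"
                candidate_sets[(region, contrast_tag)] = {
                    r.regulator for r in candidates
                }
                universe_by_contrast.setdefault(contrast_tag, set()).update(
                    r.regulator for r in results
                )
        _done(log, stage, t0)

        stage = "mr-overlap"
        t0 = time.time()
        overlap_rows = []
        for contrast_tag, universe in universe_by_contrast.items():
            keys = [k for k in candidate_sets if k[1] == contrast_tag]
            for (ra, _), (rb, _) in combinations(keys, 2):
                k, p = mr_overlap_test(
                    candidate_sets[(ra, contrast_tag)],
                    candidate_sets[(rb, contrast_tag)],
                    universe,
                )
                overlap_rows.append(
                    {
                        "contrast": contrast_tag,
                        "region_a": ra,
                        "region_b": rb,
                        "overlap": k,
                        "p": p,
                    }
                )
        if overlap_rows:
            _write_tsv(pd.DataFrame(overlap_rows), outdir / "mr_overlap.tsv", header)
        _done(log, stage, t0)

        stage = "activity"
        t0 = time.time()
        pooled = networks[regions[0] if config.per_region else "pooled"]
        act = activity_matrix(
            pooled,
            expr,
            n_permutations=config.activity_permutations,
            min_regulon=config.min_regulon,
            weight_exponent=config.weight_exponent,
            max_targets=config.max_targets,
            seed=config.stage_seed("activity"),
        )
        with open(outdir / "activity.tsv", "w") as fh:
            fh.write(header)
            for col in ("region", "group", "subject"):
                fh.write("# " + col + "\t" + "\t".join(expr.annotations[col]) + "\n")
            act.values.rename_axis("regulator").to_csv(fh, sep="\t")
        _done(log, stage, t0)

        if config.run_activity_correlation:
            stage = "activity-corr"
            t0 = time.time()
            rows = []
            for a, b in combinations(sorted(act.regulators), 2):
                cr = correlation_significance(
                    pooled,
                    expr,
                    (a, b),
                    n_random=config.n_random,
                    min_regulon=config.min_regulon,
                    seed=config.stage_seed("correlation"),
                )
                rows.append(
                    {"a": a, "b": b, "r": cr.r, "p": cr.p, "n_random": cr.n_random}
                )
            _write_tsv(pd.DataFrame(rows), outdir / "activity_correlation.tsv", header)
            _done(log, stage, t0)

        if config.promoters_target and config.promoters_control and config.pssm:
            stage = "motif-enrich"
            t0 = time.time()
            targets = read_fasta_promoters(config.promoters_target, "target")
            controls = read_fasta_promoters(config.promoters_control, "control")
            pssm = PSSM.from_jaspar(config.pssm)
            res = enrichment_test(targets, controls, pssm)
            (outdir / "motif_enrichment.json").write_text(
                json.dumps(
                    {
                        "config_hash": config.config_hash(),
                        "seed": config.seed,
                        "table": res.table,
                        "p": res.p,
                        "threshold": res.threshold,
                    },
                    indent=1,
                )
            )
            scores = pd.concat(
                [
                    res.target_scores.rename_axis("promoter").reset_index().assign(cls="target"),
                    res.control_scores.rename_axis("promoter").reset_index().assign(cls="control"),
                ]
            )
            _write_tsv(scores, outdir / "motif_scores.tsv", header)
            _done(log, stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    return outdir
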