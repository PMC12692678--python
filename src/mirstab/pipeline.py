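"""End-to-end orchestration: inputs -> profiles -> labels -> genes -> ranking.

``run_pipeline`` executes every stage in order, writes all tabular artifacts
into an output directory, and records a manifest (config hash, seed, per-stage
row counts) so that identical configuration and inputs provably yield
identical results. Inputs come either from the four files on disk or from the
synthetic generator when the configuration carries a ``synthetic`` section.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from mirstab import io
from mirstab.complementarity import ScoringScheme, normalize_rna, rank_by_diff, summarize_global_diff
from mirstab.expression import aggregate_profiles
from mirstab.genes import build_gene_profiles, filter_gene_profiles
from mirstab.integrate import (
    assign_quadrants,
    mean_logfc,
    reselect_mirnas,
    select_critical_genes,
)
from mirstab.synthetic import SyntheticConfig, generate_dataset
from mirstab.thresholds import DEFAULT_CURVES, SeparationCurve, classify, partition_counts, validate_nestedness

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Full pipeline configuration with the analysis constants as defaults.

    Analysis defaults: ``min_regulators=20`` (genes with fewer targeting
    miRNAs are excluded), ``n_critical_genes=200``, ``min_genes=10``
    (re-selection cutoff), ``top_k=10`` ranked plant candidates.
    """

    experiments: Optional[str] = None
    interactions: Optional[str] = None
    gene_logfc: Optional[str] = None
    plant_fasta: Optional[str] = None
    human_fasta: Optional[str] = None
    human_under: Optional[str] = None  # optional id lists; default: reselected sets
    human_over: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    curves: dict[str, SeparationCurve] = field(
        default_factory=lambda: dict(DEFAULT_CURVES)
    )
    level: str = "III"
    zero_policy: str = "exclude"
    gene_div_basis: str = "critical"
    min_regulators: int = 20
    n_critical_genes: int = 200
    min_genes: int = 10
    score_rule: str = "rank_sum"
    top_k: int = 10
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    seed: int = 0

    def __post_init__(self) -> None:
        validate_nestedness([self.curves[lvl] for lvl in ("I", "II", "III")])
        if self.level not in self.curves:
            raise ValueError(f"unknown threshold level {self.level!r}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        inputs = raw.pop("inputs", {}) or {}
        for key in ("experiments", "interactions", "gene_logfc", "plant_fasta",
                    "human_fasta", "human_under", "human_over"):
            if key in inputs:
                kwargs[key] = inputs[key]
        if "seed" in raw:
            kwargs["seed"] = int(raw.pop("seed"))
        synth = raw.pop("synthetic", None)
        if synth is not None:
            synth = dict(synth)
            if "bias_mixture" in synth:
                synth["bias_mixture"] = tuple(map(tuple, synth["bias_mixture"]))
            if "seq_length_range" in synth:
                synth["seq_length_range"] = tuple(synth["seq_length_range"])
            synth.setdefault("seed", kwargs.get("seed", 0))
            kwargs["synthetic"] = SyntheticConfig(**synth)
        thresholds = raw.pop("thresholds", {}) or {}
        if thresholds:
            level = thresholds.pop("level", "III")
            curves = dict(DEFAULT_CURVES)
            for lvl, params in thresholds.items():
                curves[lvl] = SeparationCurve(level=lvl, **params)
            kwargs["curves"] = curves
            kwargs["level"] = level
        analysis = raw.pop("analysis", {}) or {}
        for key in ("zero_policy", "gene_div_basis", "min_regulators",
                    "n_critical_genes", "min_genes", "score_rule", "top_k"):
            if key in analysis:
                kwargs[key] = analysis[key]
        scoring = raw.pop("scoring", None)
        if scoring:
            kwargs["scheme"] = ScoringScheme(**scoring)
        if raw:
            raise ValueError(f"unknown configuration section(s): {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj

        blob = json.dumps(encode(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.synthetic is not None:
        dataset = generate_dataset(config.synthetic)
        dataset.write(outdir / "inputs")
        return (
            dataset.experiments,
            dataset.interactions,
            dataset.gene_logfc,
            dataset.plant_sequences,
            dataset.human_sequences,
        )
    missing = [k for k in ("experiments", "interactions", "gene_logfc",
                           "plant_fasta", "human_fasta") if getattr(config, k) is None]
    if missing:
        raise PipelineError(
            f"stage 'inputs' failed: no synthetic section and missing input path(s) {missing}"
        )
    return (
        io.read_experiments(config.experiments),
        io.read_interactions(config.interactions),
        io.read_gene_logfc(config.gene_logfc),
        {k: normalize_rna(v) for k, v in io.read_fasta(config.plant_fasta).items()},
        {k: normalize_rna(v) for k, v in io.read_fasta(config.human_fasta).items()},
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Any]:
    """Run every stage, write artifacts into ``outdir``, return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    experiments, interactions, gene_logfc, plant, human = _stage("inputs")(
        _load_inputs, config, outdir
    )

    profiles = _stage("expression_stats")(
        aggregate_profiles, experiments, zero_policy=config.zero_policy
    )
    io.write_tsv(profiles, outdir / "profiles.tsv")

    curve = config.curves[config.level]
    labels = _stage("critical_threshold")(classify, profiles, curve)
    io.write_tsv(labels, outdir / "labels.tsv")
    parts = partition_counts(labels)

    gene_profiles = _stage("gene_regulation")(
        build_gene_profiles, interactions, labels, gene_div_basis=config.gene_div_basis
    )
    kept = filter_gene_profiles(gene_profiles, config.min_regulators)
    io.write_tsv(gene_profiles, outdir / "gene_profiles.tsv")

    means = _stage("integration")(mean_logfc, gene_logfc)
    summaries = _stage("integration")(assign_quadrants, kept, means)
    io.write_tsv(summaries, outdir / "summaries.tsv")
    critical_genes = _stage("integration")(
        select_critical_genes, summaries, n=config.n_critical_genes,
        score_rule=config.score_rule,
    )
    io.write_id_list(critical_genes, outdir / "critical_genes.txt")
    selection = _stage("integration")(
        reselect_mirnas, interactions, critical_genes, labels, min_genes=config.min_genes
    )
    io.write_id_list(sorted(selection.reselected_under), outdir / "reselected_under.txt")
    io.write_id_list(sorted(selection.reselected_over), outdir / "reselected_over.txt")

    if config.human_under and config.human_over:
        under_ids = io.read_id_list(config.human_under)
        over_ids = io.read_id_list(config.human_over)
    else:
        under_ids = sorted(selection.reselected_under)
        over_ids = sorted(selection.reselected_over)
    missing = [m for m in (*under_ids, *over_ids) if m not in human]
    if missing:
        logger.warning("%d selected miRNA(s) missing from human FASTA, e.g. %s",
                       len(missing), missing[:3])
    under_seqs = {m: human[m] for m in under_ids if m in human}
    over_seqs = {m: human[m] for m in over_ids if m in human}

    mean_abs_diff = None
    if under_seqs and over_seqs and plant:
        results = _stage("complementarity")(
            rank_by_diff, plant, under_seqs, over_seqs, config.scheme, None
        )
        mean_abs_diff = summarize_global_diff(results)
        top = results.head(config.top_k)
        ranking = pd.DataFrame(
            {
                "mirna": top["plant_id"],
                "coefficient_similarity_up": top["avg_comp_over"],
                "coefficient_similarity_down": top["avg_comp_under"],
                "diff": top["diff"],
            }
        )
    else:
        logger.warning("complementarity stage skipped: empty plant or human set")
        ranking = pd.DataFrame(
            columns=["mirna", "coefficient_similarity_up", "coefficient_similarity_down", "diff"]
        )
    io.write_tsv(ranking, outdir / "ranking.tsv")

    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": {
            "experiments": int(len(experiments)),
            "mirna_profiles": int(len(profiles)),
            "critical_under": parts.n_critical_under,
            "critical_over": parts.n_critical_over,
            "neutral": parts.n_neutral,
            "interactions": int(len(interactions)),
            "genes_profiled": int(len(gene_profiles)),
            "genes_kept": int(len(kept)),
            "critical_genes": len(critical_genes),
            "reselected_under": len(selection.reselected_under),
            "reselected_over": len(selection.reselected_over),
            "plant_sequences": len(plant),
            "ranking_rows": int(len(ranking)),
        },
        "mean_abs_diff": mean_abs_diff,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
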