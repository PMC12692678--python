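"""Synthetic generators for the four pipeline inputs.

The generators emulate the structure of the real resources the analysis was
designed for — a large miRNA differential-expression compendium (thousands of
miRNAs, heavy-tailed experiment counts per miRNA, per-miRNA directional bias),
a validated miRNA->gene interaction table with power-law gene in-degrees, a
per-gene per-cancer logFC table optionally coupled to the regulators' planted
direction, and plant/human mature miRNA FASTA files with planted
high-similarity pairs — while returning the planted ground truth so every
downstream stage has a recoverable test surface.

Determinism: every generator is a pure function of its configuration. A single
integer seed fans out through ``numpy.random.SeedSequence.spawn`` into one
independent substream per generator, so adding or rerunning one generator
never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RNA_ALPHABET = ("A", "C", "G", "U")
EXPERIMENT_TYPES = ("microarray", "rna_seq", "qpcr")

# substream indices; fixed so each generator is independently reproducible
_STREAM_EXPERIMENTS = 0
_STREAM_INTERACTIONS = 1
_STREAM_GENE_LOGFC = 2
_STREAM_SEQUENCES = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Parameters
    ----------
    n_mirnas, n_experiments
        Number of distinct miRNAs and total expression records across all of
        them. Experiment counts per miRNA are heavy-tailed (many miRNAs carry
        only a handful of records) with a guaranteed minimum of one.
    bias_mixture
        Mixture of ``(weight, down_probability)`` components. Each miRNA draws
        its probability of being counted as underexpressed in any one
        experiment from this mixture. The default plants roughly 70% of
        miRNAs as stably directional (half down-biased, half up-biased) and
        the rest unbiased, with near-equal down/up totals.
    experiments_per_mirna_dispersion
        Heavy-tail control for per-miRNA experiment counts. Counts are
        ``1 + multinomial`` with Pareto-like weights ``u**-d``; ``d = 0``
        gives near-uniform counts, ``d = 1`` a very heavy tail.
    n_genes, degree_exponent
        Gene count and the exponent of the truncated discrete power law for
        gene in-degree (number of regulator miRNAs), support ``[1, n_mirnas]``.
    mirna_popularity_exponent
        Skew of miRNA popularity when genes sample their regulators; ``0``
        samples uniformly, larger values give the heavy-tailed miRNA
        out-degrees seen in curated interaction catalogues (a few hub miRNAs
        with hundreds of targets, many with a handful).
    n_cancers
        Number of cancer-type labels for experiments and gene logFC values.
    coupling_strength
        In ``[0, 1]``; weight of the planted regulator-direction signal in
        gene mean logFC. A gene whose regulators are predominantly
        down-biased gets (at full coupling) a positive mean logFC — the
        de-repression pattern the integration stage is designed to detect.
    effect_scale, gene_noise_sd, cancer_noise_sd
        Magnitude of the coupled signal, standard deviation of the gene-level
        noise term, and of the independent per-cancer noise.
    n_plant_seqs, n_human_seqs, seq_length_range
        Sequence counts and the (inclusive) mature-sequence length interval,
        constrained to [18, 26] nt.
    n_planted_similar_pairs, max_planted_substitutions
        Number of plant sequences generated as near-copies of human
        sequences, each with 0..max_planted_substitutions point substitutions
        at distinct positions.
    """

    n_mirnas: int = 400
    n_experiments: int = 20_000
    bias_mixture: tuple[tuple[float, float], ...] = ((0.35, 0.9), (0.35, 0.1), (0.30, 0.5))
    experiments_per_mirna_dispersion: float = 1.0
    n_genes: int = 800
    degree_exponent: float = 1.1
    mirna_popularity_exponent: float = 1.5
    n_cancers: int = 12
    coupling_strength: float = 0.8
    effect_scale: float = 2.0
    gene_noise_sd: float = 1.0
    cancer_noise_sd: float = 0.5
    n_plant_seqs: int = 200
    n_human_seqs: int = 400
    seq_length_range: tuple[int, int] = (20, 24)
    n_planted_similar_pairs: int = 10
    max_planted_substitutions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_experiments", "n_genes", "n_cancers",
                     "n_plant_seqs", "n_human_seqs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_experiments < self.n_mirnas:
            raise ValueError(
                f"n_experiments ({self.n_experiments}) must be >= n_mirnas "
                f"({self.n_mirnas}) so every miRNA gets at least one record"
            )
        object.__setattr__(self, "bias_mixture", tuple(map(tuple, self.bias_mixture)))
        weights = [w for w, _ in self.bias_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"bias_mixture weights must sum to 1, got {sum(weights)}")
        for w, p in self.bias_mixture:
            if not (0.0 <= w <= 1.0 and 0.0 <= p <= 1.0):
                raise ValueError(f"bias_mixture entries must lie in [0,1], got ({w}, {p})")
        if self.experiments_per_mirna_dispersion < 0:
            raise ValueError("experiments_per_mirna_dispersion must be >= 0")
        if self.degree_exponent <= 0:
            raise ValueError("degree_exponent must be positive")
        if self.mirna_popularity_exponent < 0:
            raise ValueError("mirna_popularity_exponent must be >= 0")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        lo, hi = self.seq_length_range
        if not (18 <= lo <= hi <= 26):
            raise ValueError(
                f"seq_length_range must be a non-empty interval within [18, 26], got {self.seq_length_range}"
            )
        if self.n_planted_similar_pairs > min(self.n_plant_seqs, self.n_human_seqs):
            raise ValueError(
                "n_planted_similar_pairs cannot exceed min(n_plant_seqs, n_human_seqs)"
            )
        if self.n_planted_similar_pairs < 0 or self.max_planted_substitutions < 0:
            raise ValueError("planted-pair settings must be non-negative")

    def replace(self, **changes) -> "SyntheticConfig":
        return dataclasses.replace(self, **changes)


def _substream(config: SyntheticConfig, index: int) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(4)
    return np.random.default_rng(children[index])


def mirna_names(n: int) -> list[str]:
    return [f"hsa-miR-{i:04d}" for i in range(1, n + 1)]


def gene_names(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def cancer_names(n: int) -> list[str]:
    return [f"cancer_{i:02d}" for i in range(1, n + 1)]


def _experiment_counts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed per-miRNA experiment counts, min 1, summing exactly to n_experiments."""
    d = config.experiments_per_mirna_dispersion
    u = rng.random(config.n_mirnas)
    weights = np.power(u, -d) if d > 0 else np.ones(config.n_mirnas)
    extra = rng.multinomial(config.n_experiments - config.n_mirnas, weights / weights.sum())
    return 1 + extra


def generate_experiments(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the expression-record table and its per-miRNA truth table.

    Returns
    -------
    experiments
        One row per record: mirna_id, cancer_type, experiment_type, logfc.
        The logFC sign encodes direction (negative = underexpressed); its
        magnitude is lognormal(0, 1).
    truth
        One row per miRNA: mirna_id, down_probability (the planted Bernoulli
        bias), n_experiments, and true_direction in {down, up, neutral}
        (down iff down_probability > 0.5, neutral iff exactly 0.5).
    """
    rng = _substream(config, _STREAM_EXPERIMENTS)
    ids = np.asarray(mirna_names(config.n_mirnas))
    counts = _experiment_counts(config, rng)

    weights = np.array([w for w, _ in config.bias_mixture])
    probs = np.array([p for _, p in config.bias_mixture])
    component = rng.choice(len(weights), size=config.n_mirnas, p=weights)
    p_down = probs[component]

    total = int(counts.sum())
    rec_mirna = np.repeat(ids, counts)
    rec_p = np.repeat(p_down, counts)
    is_down = rng.random(total) < rec_p
    magnitude = rng.lognormal(mean=0.0, sigma=1.0, size=total)
    logfc = np.where(is_down, -magnitude, magnitude)
    cancers = rng.choice(cancer_names(config.n_cancers), size=total)
    exp_types = rng.choice(EXPERIMENT_TYPES, size=total)

    experiments = pd.DataFrame(
        {
            "mirna_id": rec_mirna,
            "cancer_type": cancers,
            "experiment_type": exp_types,
            "logfc": logfc,
        }
    )
    direction = np.where(p_down > 0.5, "down", np.where(p_down < 0.5, "up", "neutral"))
    truth = pd.DataFrame(
        {
            "mirna_id": ids,
            "down_probability": p_down,
            "n_experiments": counts,
            "true_direction": direction,
        }
    )
    return experiments, truth


def _truncated_power_law_degrees(
    n: int, exponent: float, k_max: int, rng: np.random.Generator
) -> np.ndarray:
    support = np.arange(1, k_max + 1)
    pmf = support.astype(float) ** -exponent
    pmf /= pmf.sum()
    return rng.choice(support, size=n, p=pmf)


def generate_interactions(
    config: SyntheticConfig, mirna_ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Generate the validated-interaction table (mirna_id, gene_id).

    Gene in-degrees follow a discrete power law with exponent
    ``degree_exponent`` truncated to [1, n_mirnas]; regulators per gene are
    sampled without replacement and weighted by a Pareto-like miRNA
    popularity (heavy-tailed out-degrees), so the table holds no duplicate
    pairs and every gene has at least one regulator.
    """
    if mirna_ids is None:
        mirna_ids = mirna_names(config.n_mirnas)
    mirna_ids = list(mirna_ids)
    if not mirna_ids:
        raise ValueError("mirna_ids must be non-empty")
    rng = _substream(config, _STREAM_INTERACTIONS)
    degrees = _truncated_power_law_degrees(
        config.n_genes, config.degree_exponent, len(mirna_ids), rng
    )
    e = config.mirna_popularity_exponent
    popularity = np.power(rng.random(len(mirna_ids)), -e) if e > 0 else np.ones(len(mirna_ids))
    popularity /= popularity.sum()
    genes = gene_names(config.n_genes)
    arr = np.asarray(mirna_ids)
    rows_m: list[np.ndarray] = []
    rows_g: list[np.ndarray] = []
    for gene, deg in zip(genes, degrees):
        chosen = rng.choice(arr, size=int(deg), replace=False, p=popularity)
        rows_m.append(chosen)
        rows_g.append(np.full(int(deg), gene, dtype=object))
    return pd.DataFrame(
        {"mirna_id": np.concatenate(rows_m), "gene_id": np.concatenate(rows_g)}
    )


def true_gene_div(interactions: pd.DataFrame, truth: pd.DataFrame) -> pd.Series:
    """Membership ratio of each gene's regulators' planted biases.

    ``(n_down - n_up) / (n_down + n_up)`` over the gene's regulators' true
    directions, 0 when the gene has no directional regulator.
    """
    known = set(truth["mirna_id"])
    unknown = set(interactions["mirna_id"]) - known
    if unknown:
        raise ValueError(f"interactions reference unknown miRNA ids: {sorted(unknown)[:5]}")
    merged = interactions.drop_duplicates().merge(truth, on="mirna_id")
    down = merged["true_direction"].eq("down").groupby(merged["gene_id"]).sum()
    up = merged["true_direction"].eq("up").groupby(merged["gene_id"]).sum()
    denom = (down + up).astype(float)
    div = (down - up) / denom.where(denom > 0, np.nan)
    return div.fillna(0.0).rename("div_true")


def generate_gene_logfc(
    config: SyntheticConfig, interactions: pd.DataFrame, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-gene per-cancer logFC, optionally coupled to regulators.

    With coupling strength ``c``, a gene's latent mean is
    ``c * div_true * effect_scale + (1 - c) * eps`` with
    ``eps ~ N(0, gene_noise_sd)``; each cancer-type value adds independent
    ``N(0, cancer_noise_sd)`` noise. Returns the long-format table and a
    gene-level truth table (gene_id, div_true, mean_logfc_true).
    """
    rng = _substream(config, _STREAM_GENE_LOGFC)
    div = true_gene_div(interactions, truth)
    genes = div.index.to_numpy()
    c = config.coupling_strength
    eps = rng.normal(0.0, config.gene_noise_sd, size=len(genes))
    mean = c * div.to_numpy() * config.effect_scale + (1.0 - c) * eps
    cancers = cancer_names(config.n_cancers)
    noise = rng.normal(0.0, config.cancer_noise_sd, size=(len(genes), len(cancers)))
    values = mean[:, None] + noise
    table = pd.DataFrame(
        {
            "gene_id": np.repeat(genes, len(cancers)),
            "cancer_type": np.tile(cancers, len(genes)),
            "logfc": values.ravel(),
        }
    )
    gene_truth = pd.DataFrame(
        {"gene_id": genes, "div_true": div.to_numpy(), "mean_logfc_true": mean}
    )
    return table, gene_truth


def _random_rna(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(RNA_ALPHABET, size=length))


def _substitute(seq: str, k: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=k, replace=False)
    for pos in positions:
        alternatives = [c for c in RNA_ALPHABET if c != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def generate_sequences(
    config: SyntheticConfig,
    human_ids: Optional[Sequence[str]] = None,
    template_ids: Optional[Sequence[str]] = None,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Generate plant and human mature miRNA sequences with planted pairs.

    The last ``n_planted_similar_pairs`` plant sequences are copies of human
    sequences with 0..max_planted_substitutions point substitutions at
    distinct positions. Templates are drawn from ``template_ids`` when given
    (e.g. the planted-down human miRNAs), else from all human sequences.

    Returns ``(plant, human, planted)`` where the first two are ordered
    {id: sequence} mappings and ``planted`` has columns plant_id, human_id,
    n_substitutions.
    """
    rng = _substream(config, _STREAM_SEQUENCES)
    lo, hi = config.seq_length_range
    if human_ids is None:
        human_ids = [f"hsa-miR-{i:04d}" for i in range(1, config.n_human_seqs + 1)]
    human_ids = list(human_ids)
    if len(human_ids) != config.n_human_seqs:
        raise ValueError(
            f"human_ids length ({len(human_ids)}) != n_human_seqs ({config.n_human_seqs})"
        )
    if len(set(human_ids)) != len(human_ids):
        raise ValueError("human_ids must be unique")
    human = {name: _random_rna(rng, lo, hi) for name in human_ids}

    pool = list(template_ids) if template_ids is not None else human_ids
    unknown = set(pool) - set(human_ids)
    if unknown:
        raise ValueError(f"template_ids not among human ids: {sorted(unknown)[:5]}")
    if config.n_planted_similar_pairs > 0 and not pool:
        raise ValueError("template pool is empty but planted pairs were requested")

    n_background = config.n_plant_seqs - config.n_planted_similar_pairs
    plant = {
        f"pln-miR-{i:04d}": _random_rna(rng, lo, hi) for i in range(1, n_background + 1)
    }
    planted_rows = []
    for j in range(config.n_planted_similar_pairs):
        plant_id = f"pln-miR-{n_background + j + 1:04d}"
        template = pool[int(rng.integers(len(pool)))]
        k = int(rng.integers(0, config.max_planted_substitutions + 1))
        plant[plant_id] = _substitute(human[template], k, rng)
        planted_rows.append((plant_id, template, k))
    planted = pd.DataFrame(
        planted_rows, columns=["plant_id", "human_id", "n_substitutions"]
    )
    return plant, human, planted


@dataclass
class SyntheticDataset:
    """All four pipeline inputs plus the planted ground truth."""

    config: SyntheticConfig
    experiments: pd.DataFrame
    mirna_truth: pd.DataFrame
    interactions: pd.DataFrame
    gene_logfc: pd.DataFrame
    gene_truth: pd.DataFrame
    plant_sequences: dict[str, str] = field(repr=False, default_factory=dict)
    human_sequences: dict[str, str] = field(repr=False, default_factory=dict)
    planted_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir) -> None:
        from pathlib import Path

        from mirstab import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_tsv(self.experiments, outdir / "experiments.tsv")
        io.write_tsv(self.interactions, outdir / "interactions.tsv")
        io.write_tsv(self.gene_logfc, outdir / "gene_logfc.tsv")
        io.write_fasta(self.plant_sequences, outdir / "plant.fasta")
        io.write_fasta(self.human_sequences, outdir / "human.fasta")
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        io.write_tsv(self.mirna_truth, truth_dir / "mirna_truth.tsv")
        io.write_tsv(self.gene_truth, truth_dir / "gene_truth.tsv")
        io.write_tsv(self.planted_pairs, truth_dir / "planted_pairs.tsv")


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset with consistent identifiers.

    Human sequence ids are the miRNA ids of the expression compendium, and
    planted plant sequences copy down-biased human miRNAs, so the planted
    sequence structure lines up with the under-set the pipeline recovers.
    """
    experiments, truth = generate_experiments(config)
    interactions = generate_interactions(config, truth["mirna_id"])
    gene_logfc, gene_truth = generate_gene_logfc(config, interactions, truth)
    if config.n_human_seqs != config.n_mirnas:
        raise ValueError(
            "generate_dataset requires n_human_seqs == n_mirnas so that human "
            "sequences map onto the expression compendium"
        )
    down_ids = truth.loc[truth["true_direction"] == "down", "mirna_id"].tolist()
    plant, human, planted = generate_sequences(
        config,
        human_ids=truth["mirna_id"].tolist(),
        template_ids=down_ids or None,
    )
    return SyntheticDataset(
        config=config,
        experiments=experiments,
        mirna_truth=truth,
        interactions=interactions,
        gene_logfc=gene_logfc,
        gene_truth=gene_truth,
        plant_sequences=plant,
        human_sequences=human,
        planted_pairs=planted,
    )
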