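"""Integration of gene regulatory profiles with per-cancer gene expression.

Combines each gene's regulator-derived membership ratio (gene_div) with its
mean logFC across cancer types, assigns sign quadrants, scores genes by the
combined magnitude of the two axes, selects the top-N critical genes, and
re-selects the critical miRNAs that target at least k of them.

Sign convention: a positive gene_div means the gene's critical regulators are
predominantly underexpressed in cancer; under miRNA-mediated repression the
de-repressed gene is then expected to rise (positive mean logFC). Quadrants
where both signs agree (Q1: +/+, Q3: -/-) are the concordant, presumably
miRNA-driven genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

SCORE_RULES = ("rank_sum", "product", "z_sum")

SUMMARY_COLUMNS = ["gene_id", "mean_logfc", "gene_div", "quadrant", "concordant"]


def mean_logfc(gene_logfc: pd.DataFrame) -> pd.Series:
    """Unweighted per-gene arithmetic mean of logFC across cancer types.

    Genes with no finite value are dropped with a warning.
    """
    values = gene_logfc.dropna(subset=["logfc"])
    dropped = set(gene_logfc["gene_id"]) - set(values["gene_id"])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} gene(s) with no logFC values, "
            f"e.g. {sorted(dropped)[:3]}",
            stacklevel=2,
        )
    return values.groupby("gene_id", sort=True)["logfc"].mean().rename("mean_logfc")


def _quadrant(ml: float, gd: float) -> int:
    # zeros are compatible with either sign; ambiguity resolved to the
    # lowest-numbered candidate quadrant
    patterns = {1: (1, 1), 2: (-1, 1), 3: (-1, -1), 4: (1, -1)}
    for q, (sm, sg) in patterns.items():
        if (ml == 0 or np.sign(ml) == sm) and (gd == 0 or np.sign(gd) == sg):
            return q
    raise AssertionError("unreachable: sign patterns cover the plane")


def assign_quadrants(gene_profiles: pd.DataFrame, means: pd.Series) -> pd.DataFrame:
    """Join gene_div with mean logFC and assign quadrant / concordance.

    Quadrants over (mean_logfc, gene_div): Q1 (+,+), Q2 (-,+), Q3 (-,-),
    Q4 (+,-). A zero on either axis is non-concordant and falls in the
    lowest-numbered compatible quadrant. Only genes present in both inputs
    are returned.
    """
    merged = gene_profiles.merge(
        means.rename("mean_logfc").reset_index(), on="gene_id", how="inner"
    )
    ml = merged["mean_logfc"].to_numpy(dtype=float)
    gd = merged["gene_div"].to_numpy(dtype=float)
    quadrant = np.fromiter((_quadrant(a, b) for a, b in zip(ml, gd)), dtype=int, count=len(ml))
    concordant = ((ml > 0) & (gd > 0)) | ((ml < 0) & (gd < 0))
    out = merged[["gene_id"]].copy()
    out["mean_logfc"] = ml
    out["gene_div"] = gd
    out["quadrant"] = quadrant
    out["concordant"] = concordant
    return out


def _scores(summaries: pd.DataFrame, score_rule: str) -> np.ndarray:
    aml = np.abs(summaries["mean_logfc"].to_numpy(dtype=float))
    agd = np.abs(summaries["gene_div"].to_numpy(dtype=float))
    if score_rule == "rank_sum":
        return rankdata(aml) / len(aml) + rankdata(agd) / len(agd)
    if score_rule == "product":
        return aml * agd
    if score_rule == "z_sum":
        def z(x):
            sd = x.std()
            return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        return z(aml) + z(agd)
    raise ValueError(f"score_rule must be one of {SCORE_RULES}, got {score_rule!r}")


def select_critical_genes(
    summaries: pd.DataFrame, n: int = 200, score_rule: str = "rank_sum"
) -> list[str]:
    """Top-``n`` genes by combined magnitude of mean_logfc and gene_div.

    The default rule sums the rank-normalised |mean_logfc| and |gene_div|
    (avoiding the unit mismatch between a logFC and a ratio); "product" and
    "z_sum" are alternatives. Ties break by gene id, so the selection is
    invariant to input order.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n > len(summaries):
        raise ValueError(f"n ({n}) exceeds number of genes ({len(summaries)})")
    scores = _scores(summaries, score_rule)
    order = sorted(
        range(len(summaries)),
        key=lambda i: (-scores[i], summaries["gene_id"].iat[i]),
    )
    return [summaries["gene_id"].iat[i] for i in order[:n]]


@dataclass(frozen=True)
class CriticalSelection:
    """Top critical genes and the re-selected miRNA sets targeting them."""

    critical_genes: tuple[str, ...]
    reselected_under: frozenset[str]
    reselected_over: frozenset[str]


def reselect_mirnas(
    interactions: pd.DataFrame,
    critical_genes: list[str] | tuple[str, ...],
    labels: pd.DataFrame,
    min_genes: int = 10,
) -> CriticalSelection:
    """Critical miRNAs targeting at least ``min_genes`` distinct critical genes.

    Under- and over-labelled miRNAs are collected separately (the sets are
    disjoint since each miRNA carries one label); neutral miRNAs are never
    selected. The boundary is inclusive.
    """
    pairs = interactions[["mirna_id", "gene_id"]].drop_duplicates()
    unknown = set(pairs["mirna_id"]) - set(labels["mirna_id"])
    if unknown:
        raise KeyError(
            f"interactions reference miRNA id(s) absent from labels, e.g. {sorted(unknown)[:5]}"
        )
    critical_set = set(critical_genes)
    hits = pairs[pairs["gene_id"].isin(critical_set)]
    counts = hits.groupby("mirna_id")["gene_id"].nunique()
    qualified = set(counts[counts >= min_genes].index)
    label_of = dict(zip(labels["mirna_id"], labels["label"]))
    under = frozenset(m for m in qualified if label_of[m] == "critical_under")
    over = frozenset(m for m in qualified if label_of[m] == "critical_over")
    logger.info(
        "reselected %d under / %d over miRNAs targeting >= %d of %d critical genes",
        len(under), len(over), min_genes, len(critical_set),
    )
    return CriticalSelection(tuple(critical_genes), under, over)
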