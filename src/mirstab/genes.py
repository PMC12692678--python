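"""Per-gene regulatory profiles from interactions and miRNA labels.

For each gene the number of targeting critical-underexpressed and
critical-overexpressed miRNAs is counted over its distinct regulators
(duplicate interaction rows — multiple evidence lines for one pair —
collapse to one regulator), together with a gene-level membership ratio
mirroring the miRNA statistic:

    gene_div = (n_under - n_over) / (n_under + n_over)

over the critical regulators only (0 when a gene has none), with a config
switch to divide by all regulators instead. Genes targeted by fewer
regulators than a cutoff (default 20) are dropped before integration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mirstab.thresholds import LABELS

GENE_PROFILE_COLUMNS = [
    "gene_id",
    "n_under_regulators",
    "n_over_regulators",
    "n_total_regulators",
    "gene_div",
]


def build_gene_profiles(
    interactions: pd.DataFrame,
    labels: pd.DataFrame,
    gene_div_basis: str = "critical",
) -> pd.DataFrame:
    """One regulatory profile per gene appearing in the interaction table.

    ``labels`` must cover every miRNA referenced by ``interactions``
    (neutral labels allowed). ``gene_div_basis`` selects the gene_div
    denominator: "critical" (under+over, the div analogue) or "all"
    (all distinct regulators). Output sorted by gene_id.
    """
    if gene_div_basis not in ("critical", "all"):
        raise ValueError(f"gene_div_basis must be 'critical' or 'all', got {gene_div_basis!r}")
    bad_labels = set(labels["label"]) - set(LABELS)
    if bad_labels:
        raise ValueError(f"unknown labels: {sorted(bad_labels)}")
    pairs = interactions[["mirna_id", "gene_id"]].drop_duplicates()
    unknown = set(pairs["mirna_id"]) - set(labels["mirna_id"])
    if unknown:
        raise KeyError(
            f"interactions reference {len(unknown)} miRNA id(s) absent from labels, "
            f"e.g. {sorted(unknown)[:5]}"
        )
    merged = pairs.merge(labels[["mirna_id", "label"]], on="mirna_id")
    grouped = merged.groupby("gene_id", sort=True)["label"]
    under = grouped.apply(lambda s: int((s == "critical_under").sum()))
    over = grouped.apply(lambda s: int((s == "critical_over").sum()))
    total = grouped.size()
    critical = (under + over).astype(float)
    denom = critical if gene_div_basis == "critical" else total.astype(float)
    gene_div = ((under - over) / denom.where(denom > 0, np.nan)).fillna(0.0)
    return pd.DataFrame(
        {
            "gene_id": under.index,
            "n_under_regulators": under.to_numpy(),
            "n_over_regulators": over.to_numpy(),
            "n_total_regulators": total.to_numpy(),
            "gene_div": gene_div.to_numpy(),
        }
    ).reset_index(drop=True)


def filter_gene_profiles(profiles: pd.DataFrame, min_regulators: int = 20) -> pd.DataFrame:
    """Keep genes with at least ``min_regulators`` distinct regulators.

    The boundary is inclusive (a gene with exactly ``min_regulators``
    survives); input order is preserved.
    """
    if min_regulators < 1:
        raise ValueError(f"min_regulators must be >= 1, got {min_regulators}")
    return profiles[profiles["n_total_regulators"] >= min_regulators].reset_index(drop=True)
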