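"""Per-miRNA membership-ratio statistics and boxplot summaries.

Each miRNA is summarised over its expression records by the number of
underexpression (logFC < 0) and overexpression (logFC > 0) cases and the
membership ratio

    div = (n_down - n_up) / (n_down + n_up),

which lies in [-1, 1]: +1 means the miRNA was counted as underexpressed in
every experiment, -1 always overexpressed. The cumulative logFC over counted
records is carried alongside.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

ZERO_POLICIES = ("exclude", "half")

PROFILE_COLUMNS = ["mirna_id", "n_up", "n_down", "n_total", "div", "cum_logfc"]
SUMMARY_COLUMNS = ["mirna_id", "median", "q1", "q3", "whisker_low", "whisker_high"]


def classify_direction(logfc: float, zero_policy: str = "exclude") -> str:
    """Direction of a single record from the sign of its logFC.

    Returns "down" (underexpressed) for negative logFC, "up" for positive.
    A logFC of exactly zero is "excluded" under the default policy and
    "split" under the "half" policy (it contributes half a case to each
    direction during aggregation).
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}, got {zero_policy!r}")
    if not math.isfinite(logfc):
        raise ValueError(f"logfc must be finite, got {logfc}")
    if logfc < 0:
        return "down"
    if logfc > 0:
        return "up"
    return "excluded" if zero_policy == "exclude" else "split"


def _apply_filters(
    records: pd.DataFrame,
    cancer_types: Optional[Iterable[str]],
    experiment_types: Optional[Iterable[str]],
) -> pd.DataFrame:
    if cancer_types is not None:
        records = records[records["cancer_type"].isin(set(cancer_types))]
    if experiment_types is not None:
        records = records[records["experiment_type"].isin(set(experiment_types))]
    return records


def aggregate_profiles(
    records: pd.DataFrame,
    cancer_types: Optional[Iterable[str]] = None,
    experiment_types: Optional[Iterable[str]] = None,
    zero_policy: str = "exclude",
) -> pd.DataFrame:
    """Aggregate expression records into one membership-ratio profile per miRNA.

    Optional ``cancer_types`` / ``experiment_types`` restrict the records
    before aggregation. miRNAs with no counted record (e.g. all-zero logFC
    under the exclude policy) are dropped; an empty input yields an empty
    profile table. Output is sorted by mirna_id.
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}, got {zero_policy!r}")
    if records.empty:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    values = records["logfc"].astype(float)
    if not np.isfinite(values).all():
        bad = records.loc[~np.isfinite(values), "mirna_id"].iloc[0]
        raise ValueError(f"non-finite logfc for miRNA {bad!r}")
    records = _apply_filters(records.assign(logfc=values), cancer_types, experiment_types)
    if records.empty:
        return pd.DataFrame(columns=PROFILE_COLUMNS)

    logfc = records["logfc"].to_numpy(dtype=float)
    down_w = (logfc < 0).astype(float)
    up_w = (logfc > 0).astype(float)
    if zero_policy == "half":
        zero = logfc == 0
        down_w = down_w + 0.5 * zero
        up_w = up_w + 0.5 * zero
    counted = (down_w + up_w) > 0
    contrib = pd.DataFrame(
        {
            "mirna_id": records["mirna_id"].to_numpy(),
            "n_down": down_w,
            "n_up": up_w,
            "cum_logfc": np.where(counted, logfc, 0.0),
        }
    )[counted]
    if contrib.empty:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    agg = contrib.groupby("mirna_id", sort=True).sum().reset_index()
    agg["n_total"] = agg["n_up"] + agg["n_down"]
    agg["div"] = (agg["n_down"] - agg["n_up"]) / agg["n_total"]
    if zero_policy == "exclude":
        agg[["n_up", "n_down", "n_total"]] = agg[["n_up", "n_down", "n_total"]].astype(int)
    return agg[PROFILE_COLUMNS]


def _boxplot_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    # linear-interpolation quantiles; Tukey whiskers clamped to the data range
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    whisker_low = values[values >= lo_fence].min()
    whisker_high = values[values <= hi_fence].max()
    return float(med), float(q1), float(q3), float(whisker_low), float(whisker_high)


def summarize_expression(records: pd.DataFrame, mirna_ids: Sequence[str]) -> pd.DataFrame:
    """Tukey boxplot statistics of per-experiment logFC for the requested miRNAs.

    Quartiles use linear interpolation; whiskers sit at the most extreme data
    points within 1.5 * IQR of the quartiles. Raises ``KeyError`` naming any
    requested id with no records.
    """
    grouped = dict(tuple(records.groupby("mirna_id")["logfc"]))
    rows = []
    for mirna in mirna_ids:
        if mirna not in grouped:
            raise KeyError(f"no expression records for miRNA {mirna!r}")
        med, q1, q3, wl, wh = _boxplot_stats(grouped[mirna].to_numpy(dtype=float))
        rows.append((mirna, med, q1, q3, wl, wh))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
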