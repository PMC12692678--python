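"""Nonlinear critical-threshold curves and miRNA classification.

A miRNA with membership ratio ``div`` over ``n`` experiments is called
critical when it lies beyond a decaying separation curve in the
(experiment count, |div|) plane: with few experiments only a near-unanimous
direction counts, while a large experiment count makes a modest but stable
imbalance significant. The curve family is ``threshold(n) = min(1, a / n**b)``
with a minimum experiment count; three nested default levels (I strictest,
III most permissive) mirror the usual triage into candidate tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

LABELS = ("critical_under", "critical_over", "neutral")


@dataclass(frozen=True)
class SeparationCurve:
    """Parametric separation curve ``threshold(n) = min(1, a / n**b)``.

    ``a`` scales the curve, ``b`` its decay, and ``n_min`` is the minimum
    number of experiments for a miRNA to be classifiable at all.
    """

    level: str
    a: float
    b: float
    n_min: int = 1

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"curve {self.level}: a and b must be positive")
        if self.n_min < 1:
            raise ValueError(f"curve {self.level}: n_min must be >= 1")

    def threshold(self, n_total):
        """Threshold value in (0, 1] at experiment count ``n_total`` (array ok)."""
        n = np.asarray(n_total, dtype=float)
        if np.any(n < 1):
            raise ValueError("n_total must be >= 1")
        out = np.minimum(1.0, self.a / n**self.b)
        return float(out) if np.isscalar(n_total) else out


DEFAULT_CURVES: dict[str, SeparationCurve] = {
    "I": SeparationCurve("I", a=8.0, b=0.5, n_min=10),
    "II": SeparationCurve("II", a=4.0, b=0.5, n_min=5),
    "III": SeparationCurve("III", a=2.0, b=0.5, n_min=3),
}


def validate_nestedness(curves: Sequence[SeparationCurve]) -> None:
    """Require each curve to dominate the next (I above II above III).

    Dominance — a pointwise greater-or-equal threshold and a
    greater-or-equal n_min — guarantees the critical sets are nested:
    everything critical at a strict level is critical at every more
    permissive one.
    """
    grid = np.arange(1, 10_001, dtype=float)
    for stricter, looser in zip(curves, curves[1:]):
        if stricter.n_min < looser.n_min or np.any(
            stricter.threshold(grid) < looser.threshold(grid) - 1e-12
        ):
            raise ValueError(
                f"curves not nested: level {stricter.level} must dominate level {looser.level}"
            )


LABEL_COLUMNS = ["mirna_id", "label", "div", "n_total", "threshold_at_n"]


def classify(profiles: pd.DataFrame, curve: SeparationCurve) -> pd.DataFrame:
    """Label each profile critical_under / critical_over / neutral.

    critical_under iff ``n_total >= n_min`` and ``div >= threshold(n_total)``
    (positive div = predominantly counted as underexpressed); critical_over
    symmetric at ``-threshold``; ties on the curve count as critical.
    """
    if profiles.empty:
        return pd.DataFrame(columns=LABEL_COLUMNS)
    n = profiles["n_total"].to_numpy(dtype=float)
    div = profiles["div"].to_numpy(dtype=float)
    thr = curve.threshold(n)
    eligible = n >= curve.n_min
    label = np.where(
        eligible & (div >= thr),
        "critical_under",
        np.where(eligible & (div <= -thr), "critical_over", "neutral"),
    )
    return pd.DataFrame(
        {
            "mirna_id": profiles["mirna_id"].to_numpy(),
            "label": label,
            "div": div,
            "n_total": profiles["n_total"].to_numpy(),
            "threshold_at_n": thr,
        }
    )


class PartitionCounts(NamedTuple):
    n_critical_under: int
    n_critical_over: int
    n_neutral: int


def partition_counts(labels: pd.DataFrame | Iterable[str]) -> PartitionCounts:
    """Count miRNAs per label; the three counts sum to the number of miRNAs."""
    series = labels["label"] if isinstance(labels, pd.DataFrame) else pd.Series(list(labels))
    counts = series.value_counts()
    return PartitionCounts(
        int(counts.get("critical_under", 0)),
        int(counts.get("critical_over", 0)),
        int(counts.get("neutral", 0)),
    )
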