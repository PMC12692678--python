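"""Cross-kingdom plant-vs-human miRNA sequence similarity ranking.

Each plant mature miRNA is globally aligned (Needleman-Wunsch via
``Bio.Align.PairwiseAligner``) against every member of two human miRNA sets
— the underexpressed and the overexpressed critical miRNAs — with a simple
match/mismatch/gap scheme; the alignment score is normalised to [0, 1] so
that identical sequences score 1. Per plant miRNA the two set averages

    AvgComp(p, H) = sum_i Comp(p, h_i) / N

and their difference ``diff = AvgComp_under - AvgComp_over`` are computed,
and plant miRNAs are ranked by |diff|: a large positive diff marks a plant
sequence resembling the miRNAs depleted in cancer, the candidates of
interest for plant miRNA panels.

"Complementarity" here is sequence similarity under substitution semantics.
An optional reverse-complement mode scores the plant sequence's reverse
complement instead, for true base-pairing semantics; it is off by default.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

NORMALIZATIONS = ("max_len", "mean_len", "alignment_len")

RANKING_COLUMNS = [
    "plant_id",
    "avg_comp_under",
    "avg_comp_over",
    "n_under",
    "n_over",
    "diff",
]


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside {A, C, G, U} after T->U mapping."""


def normalize_rna(seq: str) -> str:
    """Uppercase, map T->U, and reject ambiguity codes or gaps."""
    if not seq:
        raise InvalidSequenceError("empty sequence")
    out = seq.upper().replace("T", "U")
    bad = set(out) - RNA_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"invalid character(s) {sorted(bad)} in sequence {seq[:30]!r}"
        )
    return out


@dataclass(frozen=True)
class RnaSequence:
    """A mature miRNA sequence, normalised to uppercase RNA."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if not 15 <= len(self.seq) <= 30:
            raise ValueError(
                f"{self.id}: mature miRNA length must be 15-30 nt, got {len(self.seq)}"
            )


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring and normalisation for the similarity coefficient.

    Defaults (match 1, mismatch 0, gap -0.5, normalisation by the longer
    sequence length) give a similarity in [0, 1] equal to 1 for identical
    sequences. ``reverse_complement=True`` scores the plant sequence's
    reverse complement instead of the sequence itself.
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -0.5
    normalization: str = "max_len"
    reverse_complement: bool = False

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap > 0:
            raise ValueError("gap score must be <= 0")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATIONS}, got {self.normalization!r}"
            )


@functools.lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _as_seq(x: str | RnaSequence) -> str:
    return x.seq if isinstance(x, RnaSequence) else normalize_rna(x)


def similarity_score(
    p: str | RnaSequence, h: str | RnaSequence, scheme: ScoringScheme = ScoringScheme()
) -> float:
    """Normalised global-alignment similarity of two RNA sequences in [0, 1].

    The maximal Needleman-Wunsch score under the scheme is divided by
    ``match * L`` where ``L`` is the normalisation length (longer sequence by
    default); negative scores (possible for very unequal lengths) clamp to 0.
    Symmetric in its arguments for the length-based normalisations.
    """
    a, b = _as_seq(p), _as_seq(h)
    if scheme.reverse_complement:
        a = a.translate(_COMPLEMENT)[::-1]
    aligner = _aligner(scheme.match, scheme.mismatch, scheme.gap)
    raw = aligner.score(a, b)
    if scheme.normalization == "max_len":
        length = max(len(a), len(b))
    elif scheme.normalization == "mean_len":
        length = (len(a) + len(b)) / 2
    else:  # alignment_len: columns of one optimal alignment
        length = next(iter(aligner.align(a, b))).length
    return float(np.clip(raw / (scheme.match * length), 0.0, 1.0))


def average_complementarity(
    p: str | RnaSequence,
    human_set: Sequence[str | RnaSequence] | Mapping[str, str],
    scheme: ScoringScheme = ScoringScheme(),
) -> float:
    """Mean similarity of one plant sequence against a set of human sequences."""
    seqs = list(human_set.values()) if isinstance(human_set, Mapping) else list(human_set)
    if not seqs:
        raise ValueError("human set must be non-empty")
    return float(np.mean([similarity_score(p, h, scheme) for h in seqs]))


def rank_by_diff(
    plant_set: Mapping[str, str],
    under_set: Mapping[str, str],
    over_set: Mapping[str, str],
    scheme: ScoringScheme = ScoringScheme(),
    top_k: int | None = 10,
) -> pd.DataFrame:
    """Rank plant miRNAs by |AvgComp_under - AvgComp_over|, descending.

    One row per plant miRNA with the two set averages, the set sizes and
    their difference; sorted by |diff| (ties by plant id) and truncated to
    ``top_k`` rows (``None`` keeps all).
    """
    if not plant_set or not under_set or not over_set:
        raise ValueError("plant, under and over sets must all be non-empty")
    rows = []
    for plant_id, seq in plant_set.items():
        avg_under = average_complementarity(seq, under_set, scheme)
        avg_over = average_complementarity(seq, over_set, scheme)
        rows.append(
            (plant_id, avg_under, avg_over, len(under_set), len(over_set),
             avg_under - avg_over)
        )
    results = pd.DataFrame(rows, columns=RANKING_COLUMNS)
    results = results.sort_values(
        by=["diff", "plant_id"],
        key=lambda col: -col.abs() if col.name == "diff" else col,
        ascending=True,
        kind="mergesort",
    ).reset_index(drop=True)
    return results if top_k is None else results.head(top_k).reset_index(drop=True)


def summarize_global_diff(results: pd.DataFrame) -> float:
    """Mean |diff| across a ranking table (the global under-vs-over asymmetry)."""
    if results.empty:
        raise ValueError("results must be non-empty")
    return float(results["diff"].abs().mean())
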