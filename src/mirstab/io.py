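"""Tab-separated and FASTA input/output used by every pipeline stage.

All tabular artifacts are UTF-8, tab-delimited, with a mandatory header row.
FASTA handling goes through Biopython; RNA normalization (uppercase, T->U,
ambiguity-code rejection) is applied on ingest by the complementarity module.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

EXPERIMENT_COLUMNS = ["mirna_id", "cancer_type", "experiment_type", "logfc"]
INTERACTION_COLUMNS = ["mirna_id", "gene_id"]
GENE_LOGFC_COLUMNS = ["gene_id", "cancer_type", "logfc"]


class InputFormatError(ValueError):
    """A tabular input file does not have the expected columns."""


def _read_tsv(path: os.PathLike | str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in required if c not in ("logfc",)})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_experiments(path: os.PathLike | str) -> pd.DataFrame:
    return _read_tsv(path, EXPERIMENT_COLUMNS)


def read_interactions(path: os.PathLike | str) -> pd.DataFrame:
    return _read_tsv(path, INTERACTION_COLUMNS)


def read_gene_logfc(path: os.PathLike | str) -> pd.DataFrame:
    return _read_tsv(path, GENE_LOGFC_COLUMNS)


def write_tsv(df: pd.DataFrame, path: os.PathLike | str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_id_list(path: os.PathLike | str) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip()
            if tok and not tok.startswith("#"):
                out.append(tok)
    return out


def write_id_list(ids: Iterable[str], path: os.PathLike | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tok in ids:
            fh.write(f"{tok}\n")


def read_fasta(path: os.PathLike | str) -> dict[str, str]:
    """Read FASTA into an insertion-ordered {id: sequence} mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InputFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(sequences: Mapping[str, str], path: os.PathLike | str) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")
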