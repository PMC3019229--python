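"""Sequence, label-table and prediction-table input/output.

FASTA records may use the DNA or RNA alphabet and either case; sequences are
normalised internally to upper-case RNA (T -> U).  Record ids are taken from
the FASTA header up to the first whitespace.  All user-facing coordinates
are 1-based inclusive with respect to the first base of the 3' UTR.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MicroRNA",
    "Transcript",
    "LabelRecord",
    "DOWN_REGULATED",
    "UNAFFECTED",
    "read_sequences",
    "read_label_table",
    "write_label_table",
    "write_fasta",
    "write_predictions",
]

DOWN_REGULATED = "down_regulated"
UNAFFECTED = "unaffected"
LABELS = (DOWN_REGULATED, UNAFFECTED)

MIN_MIRNA_LENGTH = 16


@dataclass(frozen=True)
class MicroRNA:
    """A mature miRNA, 5'->3', ACGU alphabet."""

    id: str
    sequence: str

    def __post_init__(self):
        _validate_sequence(self.id, self.sequence)
        if len(self.sequence) < MIN_MIRNA_LENGTH:
            raise ValueError(
                f"miRNA {self.id!r} is {len(self.sequence)} nt; "
                f"at least {MIN_MIRNA_LENGTH} required"
            )


@dataclass(frozen=True)
class Transcript:
    """A transcript represented by its 3' UTR, 5'->3', starting immediately
    after the stop codon."""

    id: str
    utr: str

    def __post_init__(self):
        _validate_sequence(self.id, self.utr)
        if len(self.utr) < 1:
            raise ValueError(f"transcript {self.id!r} has an empty UTR")

    @property
    def length(self) -> int:
        return len(self.utr)


@dataclass(frozen=True)
class LabelRecord:
    transcript_id: str
    mirna_id: str
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(
                f"unknown label {self.label!r} for pair "
                f"({self.transcript_id}, {self.mirna_id}); expected one of {LABELS}"
            )


def _validate_sequence(record_id: str, seq: str) -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in "ACGU":
            raise ValueError(
                f"record {record_id!r}: invalid character {ch!r} at position {pos}"
            )


def normalize_sequence(seq: str) -> str:
    """Upper-case and map the DNA alphabet to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def read_sequences(path, kind: str) -> list:
    """Read a FASTA file as a list of :class:`MicroRNA` (``kind="mirna"``) or
    :class:`Transcript` (``kind="utr"``), order preserved."""
    if kind not in ("mirna", "utr"):
        raise ValueError(f"kind must be 'mirna' or 'utr', got {kind!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        if kind == "mirna":
            records.append(MicroRNA(id=rec.id, sequence=seq))
        else:
            records.append(Transcript(id=rec.id, utr=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[Union[MicroRNA, Transcript]], path) -> None:
    """Write miRNAs or transcripts to FASTA (RNA alphabet, one line per seq)."""
    seqs = []
    for r in records:
        seq = r.sequence if isinstance(r, MicroRNA) else r.utr
        seqs.append(SeqRecord(Seq(seq), id=r.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seqs)


LABEL_COLUMNS = ["transcript_id", "mirna_id", "label"]


def read_label_table(path) -> List[LabelRecord]:
    """Read the tab-delimited (transcript, miRNA) -> label table.

    Requires a header with columns transcript_id, mirna_id, label; labels are
    ``down_regulated`` or ``unaffected``.  Duplicate pairs are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"label table {path} lacks required columns: {missing}")
    dup = df.duplicated(subset=["transcript_id", "mirna_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["transcript_id", "mirna_id"]].drop_duplicates()
        listing = ", ".join(f"({t}, {m})" for t, m in pairs.itertuples(index=False))
        raise ValueError(f"duplicate (transcript, miRNA) pairs in label table: {listing}")
    return [
        LabelRecord(row.transcript_id, row.mirna_id, row.label)
        for row in df.itertuples(index=False)
    ]


def write_label_table(records: Iterable[LabelRecord], path) -> None:
    df = pd.DataFrame(
        [(r.transcript_id, r.mirna_id, r.label) for r in records],
        columns=LABEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


SITE_TABLE_COLUMNS = [
    "transcript_id",
    "mirna_id",
    "seed_type",
    "seed_start",
    "seed_end",
    "discriminant",
]
GENE_TABLE_COLUMNS = ["transcript_id", "mirna_id", "n_sites", "gene_score"]


def write_predictions(sites, genes, out_prefix) -> tuple:
    """Write the site- and gene-level prediction tables.

    ``sites``/``genes`` are DataFrames (or row iterables) with the columns of
    ``SITE_TABLE_COLUMNS``/``GENE_TABLE_COLUMNS``.  Both tables are written
    tab-delimited with a header, rows sorted by descending score; empty
    inputs yield header-only files.  Returns the two output paths.
    """
    site_df = pd.DataFrame(sites, columns=SITE_TABLE_COLUMNS)[SITE_TABLE_COLUMNS]
    gene_df = pd.DataFrame(genes, columns=GENE_TABLE_COLUMNS)[GENE_TABLE_COLUMNS]
    if len(site_df):
        site_df = site_df.sort_values(
            ["discriminant", "transcript_id", "mirna_id", "seed_start"],
            ascending=[False, True, True, True],
            kind="mergesort",
        )
    if len(gene_df):
        gene_df = gene_df.sort_values(
            ["gene_score", "transcript_id", "mirna_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
    out_prefix = str(out_prefix)
    site_path = out_prefix + ".sites.tsv"
    gene_path = out_prefix + ".genes.tsv"
    site_df.to_csv(site_path, sep="\t", index=False)
    gene_df.to_csv(gene_path, sep="\t", index=False)
    return site_path, gene_path
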