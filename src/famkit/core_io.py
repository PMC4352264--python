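"""Readers, writers and record types for the formats the pipeline touches.

All coordinates are 0-based half-open internally; human-readable reports
(TSV writers, CLI output) use 1-based inclusive positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
DNA_ALPHABET = set("ACGTN")

__all__ = [
    "ProteinRecord",
    "GeneLocus",
    "ExpressionMatrix",
    "read_fasta",
    "write_fasta",
    "pick_longest_isoform",
    "read_locus_table",
    "write_locus_table",
    "read_expression_matrix",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A sequence record; also used for nucleotide records (promoters, CDS)."""

    id: str
    sequence: str
    description: str = ""
    gene_group: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position on a chromosome.

    ``chromosome`` is a label such as ``Chr5a`` ("Chr" + number + optional
    subgenome letter) or ``unknown``.  ``ordinal`` is the 1-based rank of the
    gene along its chromosome; ``start``/``end`` are 0-based half-open.
    """

    gene_id: str
    chromosome: str
    ordinal: int
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"locus {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise ValueError(f"locus {self.gene_id}: negative start")
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"locus {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class ExpressionMatrix:
    """Non-negative signal per (gene, sample)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match gene/sample id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if np.any(self.values < 0):
            raise ValueError("negative expression values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene_id)]
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None


def _validate_sequence(rec_id: str, seq: str, alphabet: set[str], strict: bool,
                       wildcard: str) -> str:
    bad = sorted(set(seq) - alphabet)
    if not bad:
        return seq
    if strict:
        raise ValueError(f"record {rec_id!r}: illegal characters {bad}")
    warnings.warn(f"record {rec_id!r}: characters {bad} replaced by {wildcard}")
    table = str.maketrans({c: wildcard for c in bad})
    return seq.translate(table)


def read_fasta(path: str | Path, alphabet: Literal["protein", "dna"] = "protein",
               strict: bool = True) -> list[ProteinRecord]:
    """Read a FASTA file into validated records.

    Sequences are upper-cased with whitespace stripped.  Duplicate ids and
    empty sequences are errors; characters outside the alphabet raise in
    strict mode and are replaced by the wildcard (X or N) otherwise.
    """
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
    wildcard = "X" if alphabet == "protein" else "N"
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).upper().split())
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        seq = _validate_sequence(rec.id, seq, allowed, strict, wildcard)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with deterministic wrapping and LF line endings."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def pick_longest_isoform(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep one record per gene_group: the longest isoform.

    Length ties are broken by the lexicographically smallest id so the
    selection is deterministic.  Every record must carry a gene_group.
    """
    groups: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.gene_group is None:
            raise ValueError(f"record {rec.id!r} has no gene_group")
        cur = groups.get(rec.gene_group)
        if cur is None:
            groups[rec.gene_group] = rec
            order.append(rec.gene_group)
        elif (len(rec.sequence), _neg_id(rec.id)) > (len(cur.sequence), _neg_id(cur.id)):
            groups[rec.gene_group] = rec
    return [groups[g] for g in order]


class _neg_id(str):
    """Reverses string comparison so max() prefers the smaller id on ties."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


LOCUS_COLUMNS = ["gene_id", "chromosome", "ordinal", "start", "end", "strand"]


def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """Read a TSV gene-locus table (gene_id, chromosome, ordinal, start, end, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str, "strand": str})
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"locus table missing columns: {sorted(missing)}")
    loci = [
        GeneLocus(
            gene_id=row.gene_id,
            chromosome=row.chromosome,
            ordinal=int(row.ordinal),
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
        )
        for row in df.itertuples()
    ]
    seen: dict[tuple[str, int], str] = {}
    for loc in loci:
        if loc.chromosome == "unknown":
            continue
        key = (loc.chromosome, loc.ordinal)
        if key in seen:
            raise ValueError(
                f"duplicate (chromosome, ordinal) {key}: {seen[key]} and {loc.gene_id}"
            )
        seen[key] = loc.gene_id
    return loci


def write_locus_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    rows = [
        (l.gene_id, l.chromosome, l.ordinal, l.start, l.end, l.strand) for l in loci
    ]
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False,
                                                     lineterminator="\n")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column gene ids, header row sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    return ExpressionMatrix.from_frame(df)
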