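"""Strand-aware IUPAC consensus scanning of promoter sequences.

Promoters are assumed to be the −2000..−1 region 5'→3' on the gene's coding
strand.  Each consensus in the library is matched at every offset on the
sense strand, and its reverse complement likewise (reported as antisense
with sense-strand coordinates).  All overlapping matches are reported, the
semantics of classical plant cis-element databases (PLACE).  The default
library carries the stress-related elements commonly profiled in promoter
surveys of ABA- and cold-responsive genes: ABRE (ABA-responsive element),
DRE (dehydration-responsive element), CBFHV and LTRE (low-temperature
elements).  The exact consensus strings are configuration, not contract:
override them with your database's entries via a two-column TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MotifDefinition",
    "ElementHit",
    "DEFAULT_LIBRARY",
    "scan_promoter",
    "element_summary",
    "read_motif_library",
    "reverse_complement",
]

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        bad = sorted(set(self.consensus.upper()) - set(IUPAC))
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid IUPAC codes {bad}")


@dataclass(frozen=True)
class ElementHit:
    promoter_id: str
    motif: str
    strand: str   # "sense" | "antisense"
    start: int    # 0-based offset on the sense strand
    match: str    # the sense-strand substring


DEFAULT_LIBRARY: list[MotifDefinition] = [
    MotifDefinition("ABRE", "ACGTGKC"),
    MotifDefinition("DRE", "RCCGAC"),
    MotifDefinition("CBFHV", "RYCGAC"),
    MotifDefinition("LTRE", "CCGAC"),
]


def _matches(seq: str, consensus: str) -> bool:
    # a sequence N matches only the consensus code N (no wildcard credit)
    for s, c in zip(seq, consensus):
        if s == "N":
            if c != "N":
                return False
        elif s not in IUPAC[c]:
            return False
    return True


def scan_promoter(promoter_id: str, sequence: str,
                  library: Sequence[MotifDefinition] = DEFAULT_LIBRARY) -> list[ElementHit]:
    """All (possibly overlapping) consensus matches on both strands.

    Antisense hits are matches of a consensus's reverse complement on the
    sense strand; their coordinates and matched substring refer to the sense
    strand.
    """
    seq = sequence.upper()
    hits: list[ElementHit] = []
    for motif in library:
        for strand, cons in (("sense", motif.consensus.upper()),
                             ("antisense", reverse_complement(motif.consensus.upper()))):
            w = len(cons)
            for start in range(len(seq) - w + 1):
                if _matches(seq[start:start + w], cons):
                    hits.append(ElementHit(promoter_id, motif.name, strand, start,
                                           seq[start:start + w]))
    hits.sort(key=lambda h: (h.start, h.motif, h.strand))
    return hits


def element_summary(hits: Iterable[ElementHit],
                    promoter_ids: Sequence[str] | None = None,
                    motif_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-promoter, per-motif hit counts with a 'multiple' flag per cell.

    Returns a DataFrame indexed by promoter with one count column per motif
    plus ``<motif>_multiple`` booleans (count >= 2).  Pass the full id lists
    to include zero rows/columns for promoters or motifs without hits.
    """
    rows = [(h.promoter_id, h.motif) for h in hits]
    df = pd.DataFrame(rows, columns=["promoter", "motif"])
    counts = df.groupby(["promoter", "motif"]).size().unstack(fill_value=0)
    if promoter_ids is not None:
        counts = counts.reindex(list(promoter_ids), fill_value=0)
    if motif_names is not None:
        counts = counts.reindex(columns=list(motif_names), fill_value=0)
    counts = counts.astype(int)
    for motif in list(counts.columns):
        counts[f"{motif}_multiple"] = counts[motif] >= 2
    counts.index.name = "promoter"
    return counts


def read_motif_library(path: str | Path) -> list[MotifDefinition]:
    """Read a TSV motif library with columns (name, iupac)."""
    df = pd.read_csv(path, sep="\t")
    if not {"name", "iupac"} <= set(df.columns):
        raise ValueError("motif library needs columns: name, iupac")
    return [MotifDefinition(str(r.name_), str(r.iupac))
            for r in df.rename(columns={"name": "name_"}).itertuples()]
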