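"""CCCH zinc-finger motif detection, tallies, position profiles, protein stats.

The CCCH (C3H) motif is C-X(i)-C-X(j)-C-X(k)-H: three cysteines and one
histidine with variable spacers.  The scanner looks for the degenerate
pattern with i in [i_min, i_max] (default 4..17), j in [j_min, j_max]
(default 4..6) and k fixed (default 3); the classical definition caps i at
15 and allows k of 3-4, both reachable through ScanParams.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .core_io import ProteinRecord

__all__ = [
    "ScanParams",
    "MotifHit",
    "MotifTally",
    "PositionProfile",
    "scan_ccch",
    "tally_motifs",
    "position_profile",
    "protein_stats",
    "molecular_weight",
    "isoelectric_point",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ScanParams:
    i_min: int = 4
    i_max: int = 17
    j_min: int = 4
    j_max: int = 6
    k: int = 3
    overlap_policy: Literal["nonoverlapping_shortest_first", "all_matches"] = (
        "nonoverlapping_shortest_first"
    )

    def __post_init__(self) -> None:
        if not (0 < self.i_min <= self.i_max):
            raise ValueError("need 0 < i_min <= i_max")
        if not (0 < self.j_min <= self.j_max):
            raise ValueError("need 0 < j_min <= j_max")
        if self.k < 1:
            raise ValueError("need k >= 1")


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    start: int  # 0-based
    end: int    # half-open
    i: int
    j: int
    k: int

    @property
    def pattern_label(self) -> str:
        return f"C-X{self.i}-C-X{self.j}-C-X{self.k}-H"

    def __post_init__(self) -> None:
        if self.end - self.start != self.i + self.j + self.k + 4:
            raise ValueError("span length inconsistent with spacers")


@dataclass
class MotifTally:
    family: str
    pattern_counts: dict[str, int]
    per_protein_counts: dict[str, int]

    @property
    def n_proteins(self) -> int:
        return len(self.per_protein_counts)

    @property
    def n_motifs(self) -> int:
        return sum(self.pattern_counts.values())

    def motifs_per_protein_histogram(self) -> dict[int, int]:
        """Histogram of per-protein motif counts (proteins with >=1 hit)."""
        return dict(sorted(Counter(
            c for c in self.per_protein_counts.values() if c > 0
        ).items()))


def _match_at(seq: str, start: int, i: int, j: int, k: int) -> bool:
    """True when the four C/C/C/H anchors sit at the offsets implied by (i, j, k)."""
    end = start + i + j + k + 4
    if end > len(seq):
        return False
    return (
        seq[start] == "C"
        and seq[start + 1 + i] == "C"
        and seq[start + 2 + i + j] == "C"
        and seq[end - 1] == "H"
    )


def scan_ccch(record: ProteinRecord, params: ScanParams = ScanParams()) -> list[MotifHit]:
    """Locate CCCH motifs in one protein.

    Under ``all_matches`` every (start, i, j) combination whose anchors hold
    is reported.  Under ``nonoverlapping_shortest_first`` the sequence is
    scanned left to right; at the first matching start the smallest i, then
    smallest j, wins and scanning resumes after the matched histidine.
    """
    seq = record.sequence
    k = params.k
    hits: list[MotifHit] = []
    if params.overlap_policy == "all_matches":
        for start in range(len(seq)):
            if seq[start] != "C":
                continue
            for i in range(params.i_min, params.i_max + 1):
                for j in range(params.j_min, params.j_max + 1):
                    if _match_at(seq, start, i, j, k):
                        hits.append(MotifHit(record.id, start, start + i + j + k + 4, i, j, k))
        return hits
    pos = 0
    while pos < len(seq):
        if seq[pos] != "C":
            pos += 1
            continue
        found = None
        for i in range(params.i_min, params.i_max + 1):
            for j in range(params.j_min, params.j_max + 1):
                if _match_at(seq, pos, i, j, k):
                    found = (i, j)
                    break
            if found:
                break
        if found is None:
            pos += 1
            continue
        i, j = found
        end = pos + i + j + k + 4
        hits.append(MotifHit(record.id, pos, end, i, j, k))
        pos = end
    return hits


def tally_motifs(hits_by_protein: Mapping[str, Sequence[MotifHit]],
                 family: str = "CCCH") -> MotifTally:
    """Family-level tallies: per-pattern counts and per-protein motif counts."""
    pattern_counts: Counter[str] = Counter()
    per_protein: dict[str, int] = {}
    for pid, hits in hits_by_protein.items():
        per_protein[pid] = len(hits)
        for h in hits:
            pattern_counts[h.pattern_label] += 1
    return MotifTally(family, dict(sorted(pattern_counts.items())), per_protein)


@dataclass
class PositionProfile:
    """Per-column residue frequencies of aligned motif instances.

    Information content is log2(20) minus the column's Shannon entropy, in
    bits, with no small-sample correction.
    """

    width: int
    frequencies: np.ndarray  # (width, 20)
    alphabet: str = AMINO_ACIDS

    @property
    def information_content(self) -> np.ndarray:
        freqs = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
        entropy = -terms.sum(axis=1)
        return np.log2(len(self.alphabet)) - entropy


def position_profile(hits: Sequence[MotifHit],
                     sequences: Mapping[str, str]) -> PositionProfile:
    """Column frequency profile for one motif pattern's instances.

    All hits must share the same (i, j, k) so the instances align without
    gaps; mixed patterns are an error.
    """
    if not hits:
        raise ValueError("no hits to profile")
    signatures = {(h.i, h.j, h.k) for h in hits}
    if len(signatures) > 1:
        raise ValueError(f"mixed motif patterns in profile input: {sorted(signatures)}")
    width = hits[0].end - hits[0].start
    counts = np.zeros((width, len(AMINO_ACIDS)))
    index = {aa: n for n, aa in enumerate(AMINO_ACIDS)}
    for h in hits:
        instance = sequences[h.protein_id][h.start:h.end]
        for col, aa in enumerate(instance):
            if aa in index:  # X carries no information
                counts[col, index[aa]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return PositionProfile(width=width, frequencies=counts / totals)


# Average residue masses (Da), ExPASy-style; water added once per chain.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER = 18.0153
_MEAN_RESIDUE_MASS = sum(_RESIDUE_MASS.values()) / len(_RESIDUE_MASS)

# EMBOSS pKa values for the ionizable groups.
_PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da; X counts as the mean residue mass."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(_RESIDUE_MASS.get(aa, _MEAN_RESIDUE_MASS) for aa in sequence) + _WATER


def _net_charge(sequence: str, ph: float) -> float:
    counts = Counter(sequence)
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE["Cterm"] - ph))
    for aa, pka in _PKA_POSITIVE.items():
        if aa in counts:
            charge += counts[aa] / (1.0 + 10 ** (ph - pka))
    for aa, pka in _PKA_NEGATIVE.items():
        if aa in counts:
            charge -= counts[aa] / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection of the Henderson-Hasselbalch curve.

    X residues carry no charge terms.  The charge curve is strictly
    decreasing in pH so bisection on [0, 14] converges unconditionally.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2
        q = _net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def protein_stats(record: ProteinRecord) -> tuple[float, float]:
    """(molecular weight in kDa, isoelectric point) of one protein."""
    return molecular_weight(record.sequence) / 1000.0, isoelectric_point(record.sequence)
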