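"""Duplicate-pair classification, Nei-Gojobori Ka/Ks, selection mode, dating.

Ka/Ks follows Nei & Gojobori (1986): synonymous/nonsynonymous site fractions
per codon, pathway-averaged difference counts between codon pairs, and a
Jukes-Cantor multiple-hit correction d = -(3/4)·ln(1 - (4/3)·p) on each
proportion.  Pathways passing through stop codons are excluded and the
remaining pathway weights renormalized (configurable to count stop steps as
nonsynonymous instead).

Divergence time uses the grass synonymous molecular clock
T = Ks / (2·λ) × 10⁻⁶ Mya with λ = 6.5×10⁻⁹ substitutions per synonymous
site per year by default.

A reference table of published switchgrass CCCH (PvC3H) duplicate pairs —
chromosomes, Ks, Ka, selection calls and divergence dates for 19 pairs — is
packaged for parity checks (``load_reference_pairs``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from itertools import permutations
from typing import Literal, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .core_io import GeneLocus

__all__ = [
    "DuplicatePair",
    "CodonPair",
    "KaKsResult",
    "EvolutionParams",
    "classify_duplication",
    "ng86_sites",
    "kaks",
    "classify_selection",
    "divergence_time",
    "load_reference_pairs",
    "round_half_up",
]

_CHROM_RE = re.compile(r"^Chr(\d+)([a-z]?)$", re.IGNORECASE)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding, matching how printed tables round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvolutionParams:
    lambda_rate: float = 6.5e-9  # synonymous substitutions / site / year (grasses)
    code_table: int = 1          # NCBI translation table id
    stop_policy: Literal["exclude", "nonsynonymous"] = "exclude"

    def __post_init__(self) -> None:
        if self.lambda_rate <= 0:
            raise ValueError("lambda_rate must be positive")


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    locus_a: GeneLocus
    locus_b: GeneLocus
    dup_type: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a duplicate pair needs two distinct genes")


@dataclass(frozen=True)
class CodonPair:
    """Two in-frame aligned coding sequences of equal length."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("coding sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("length not divisible by 3")

    def codons(self) -> list[tuple[str, str]]:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        return [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    ratio: float | None     # None when Ks == 0
    selection: str
    T_mya: float | None     # None when Ks == 0 (non-informative)
    codons_compared: int
    codons_skipped: int = 0


def _parse_chromosome(label: str) -> tuple[int, str] | None:
    """(number, subgenome letter) or None for 'unknown'."""
    if label == "unknown":
        return None
    m = _CHROM_RE.match(label)
    if not m:
        raise ValueError(f"malformed chromosome label {label!r}")
    return int(m.group(1)), m.group(2).lower()


def classify_duplication(locus_a: GeneLocus, locus_b: GeneLocus,
                         max_intervening: int = 4) -> str:
    """Type a duplicate pair from its two loci.

    Tandem: same chromosome with at most ``max_intervening`` gene loci
    in-between (the "fewer than five intervening genes" convention at the
    default).  Homeologous: same chromosome number, different subgenome
    letter (e.g. Chr5a vs Chr5b).  Anything else with known chromosomes is
    plain paralogous; an unknown chromosome on either side gives 'unknown'.
    """
    ca = _parse_chromosome(locus_a.chromosome)
    cb = _parse_chromosome(locus_b.chromosome)
    if ca is None or cb is None:
        return "unknown"
    if locus_a.chromosome == locus_b.chromosome:
        intervening = abs(locus_a.ordinal - locus_b.ordinal) - 1
        return "tandem" if intervening <= max_intervening else "paralogous"
    if ca[0] == cb[0] and ca[1] and cb[1] and ca[1] != cb[1]:
        return "homeologous"
    return "paralogous"


def _code(table_id: int):
    table = unambiguous_dna_by_id[table_id]
    return table.forward_table, set(table.stop_codons)


_BASES = "ACGT"


def ng86_sites(codon: str, code_table: int = 1,
               stop_policy: str = "exclude") -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes the fraction of its three single-nucleotide
    changes that are synonymous.  Under the default stop policy, changes to
    stop codons are dropped from a position's denominator; under
    'nonsynonymous' they count as nonsynonymous changes.
    """
    codon = codon.upper()
    fwd, stops = _code(code_table)
    if codon in stops:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if codon not in fwd:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = fwd[codon]
    s = 0.0
    for pos in range(3):
        syn = counted = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut in stops:
                if stop_policy == "exclude":
                    continue
                counted += 1
                continue
            counted += 1
            if fwd[mut] == aa:
                syn += 1
        if counted:
            s += syn / counted
    return s, 3.0 - s


def _pathway_counts(ca: str, cb: str, fwd: dict, stops: set,
                    stop_policy: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one codon pair."""
    diff = [p for p in range(3) if ca[p] != cb[p]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        return (1.0, 0.0) if fwd[ca] == fwd[cb] else (0.0, 1.0)

    def steps(order: tuple[int, ...]):
        cur = ca
        path = []
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1:]
            path.append((cur, nxt))
            cur = nxt
        return path

    valid: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in permutations(diff):
        sd = nd = 0.0
        through_stop = False
        for cur, nxt in steps(order):
            mid_is_stop = nxt in stops and nxt != cb
            if mid_is_stop:
                through_stop = True
            a1 = fwd.get(cur, "*")
            a2 = fwd.get(nxt, "*")
            if a1 == a2 and a1 != "*":
                sd += 1
            else:
                nd += 1
        if through_stop and stop_policy == "exclude":
            fallback.append((sd, nd))
        else:
            valid.append((sd, nd))
    # if every pathway crosses a stop, fall back to counting those steps
    pool = valid if valid else fallback
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def kaks(pair: CodonPair, params: EvolutionParams = EvolutionParams()) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction for one codon pair.

    Codon pairs containing gaps, ambiguity codes or stop codons are skipped
    pairwise.  S and N are averaged over the two sequences.  Saturation
    (ps or pn >= 3/4) makes the Jukes-Cantor log undefined and raises.
    """
    fwd, stops = _code(params.code_table)
    S_a = N_a = S_b = N_b = 0.0
    Sd = Nd = 0.0
    compared = skipped = 0
    for ca, cb in pair.codons():
        if (set(ca) | set(cb)) - set(_BASES) or ca in stops or cb in stops:
            skipped += 1
            continue
        compared += 1
        sa, na = ng86_sites(ca, params.code_table, params.stop_policy)
        sb, nb = ng86_sites(cb, params.code_table, params.stop_policy)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        sd, nd = _pathway_counts(ca, cb, fwd, stops, params.stop_policy)
        Sd += sd
        Nd += nd
    if compared == 0:
        raise ValueError("no comparable codons")
    S = (S_a + S_b) / 2
    N = (N_a + N_b) / 2
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(ps, "ps")
    Ka = _jukes_cantor(pn, "pn")
    ratio = (Ka / Ks) if Ks > 0 else None
    selection = classify_selection(Ka, Ks)
    T = divergence_time(Ks, params) if Ks > 0 else None
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ks=Ks, Ka=Ka,
                      ratio=ratio, selection=selection, T_mya=T,
                      codons_compared=compared, codons_skipped=skipped)


def _jukes_cantor(p: float, label: str) -> float:
    if p >= 0.75:
        raise ValueError(f"saturation: JC correction undefined ({label} = {p:.3f} >= 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def classify_selection(ka: float, ks: float) -> str:
    """Selection mode from the Ka/Ks ratio.

    Ratio above 1 is diversifying (positive) selection, below 1 purifying;
    exactly 1 is neutral.  Ks = 0 with Ka > 0 — nonsynonymous change with no
    synonymous change — is called diversifying (ratio undefined); Ks = Ka = 0
    is neutral.
    """
    if ka < 0 or ks < 0:
        raise ValueError("Ka and Ks must be non-negative")
    if ks == 0:
        return "diversifying" if ka > 0 else "neutral"
    ratio = ka / ks
    if ratio > 1:
        return "diversifying"
    if ratio < 1:
        return "purifying"
    return "neutral"


def divergence_time(ks: float, params: EvolutionParams = EvolutionParams(),
                    ndigits: int | None = 1) -> float:
    """Divergence time in Mya from the synonymous clock, T = Ks/(2λ)·10⁻⁶.

    Reported to one decimal by default; pass ``ndigits=None`` for the raw
    value.
    """
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    t = ks / (2.0 * params.lambda_rate) * 1e-6
    return t if ndigits is None else round_half_up(t, ndigits)


def load_reference_pairs() -> pd.DataFrame:
    """Published switchgrass PvC3H duplicate-pair table (19 pairs).

    Columns: gene_a, gene_b, chrom_a, chrom_b, ks, ka, ratio, selection,
    dup_type, t_mya.  'NA' marks ratio/date undefined for Ks = 0 pairs.
    """
    with resources.files("famkit.data").joinpath("switchgrass_c3h_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])
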