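import math

import numpy as np
import pytest

from famkit.core_io import ProteinRecord
from famkit.motif_scan import (
    MotifHit,
    ScanParams,
    isoelectric_point,
    molecular_weight,
    position_profile,
    protein_stats,
    scan_ccch,
    tally_motifs,
    _net_charge,
)

ALL = ScanParams(overlap_policy="all_matches")


def brute_force_hits(seq, params=ScanParams()):
    """Independent enumeration of every (start, i, j) anchor combination."""
    out = []
    k = params.k
    for start in range(len(seq)):
        for i in range(params.i_min, params.i_max + 1):
            for j in range(params.j_min, params.j_max + 1):
                end = start + i + j + k + 4
                if end > len(seq):
                    continue
                if (seq[start] == "C" and seq[start + 1 + i] == "C"
                        and seq[start + 2 + i + j] == "C" and seq[end - 1] == "H"):
                    out.append((start, end, i, j))
    return out


def test_single_exact_template():
    seq = "C" + "A" * 8 + "C" + "A" * 5 + "C" + "AAA" + "H"
    hits = scan_ccch(ProteinRecord("t", seq))
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end) == (0, 20)
    assert h.pattern_label == "C-X8-C-X5-C-X3-H"


def test_no_anchors_no_hits():
    assert scan_ccch(ProteinRecord("t", "MKHHHAAA")) == []


@pytest.mark.parametrize("seed", range(4))
def test_all_matches_equals_bruteforce_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(50):
        seq = "".join(rng.choice(alphabet, size=400))
        got = {(h.start, h.end, h.i, h.j)
               for h in scan_ccch(ProteinRecord("r", seq), ALL)}
        assert got == set(brute_force_hits(seq))


def test_nonoverlap_is_subset_and_disjoint():
    rng = np.random.default_rng(99)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(50):
        seq = "".join(rng.choice(alphabet, size=300))
        rec = ProteinRecord("r", seq)
        nonov = scan_ccch(rec)
        allm = {(h.start, h.end) for h in scan_ccch(rec, ALL)}
        spans = [(h.start, h.end) for h in nonov]
        assert set(spans) <= allm
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # pairwise disjoint, left to right


def test_nonoverlap_prefers_smallest_i_then_j():
    # C at 0; anchors valid for both i=4 (C at 5) and i=6 (C at 7)
    seq = "C" + "AAAA" + "C" + "A" + "C" + "AAAA" + "C" + "AAA" + "H" + "AAAA" + "C" + "AAA" + "H"
    hits = scan_ccch(ProteinRecord("t", seq))
    assert hits[0].i == 4


def test_hit_invariants_validated():
    with pytest.raises(ValueError):
        MotifHit("p", 0, 10, i=4, j=4, k=3)  # span != i+j+k+4


def test_tally_counts():
    h = lambda pid, s, i, j: MotifHit(pid, s, s + i + j + 7, i, j, 3)
    grouped = {
        "p1": [h("p1", 0, 8, 5)],
        "p2": [h("p2", 0, 8, 5), h("p2", 40, 7, 5)],
        "p3": [h("p3", 0, 8, 5), h("p3", 40, 7, 5), h("p3", 80, 4, 4)],
    }
    tally = tally_motifs(grouped)
    assert tally.n_proteins == 3
    assert tally.n_motifs == 6
    assert tally.motifs_per_protein_histogram() == {1: 1, 2: 1, 3: 1}
    assert sum(tally.pattern_counts.values()) == 6
    assert tally.pattern_counts["C-X8-C-X5-C-X3-H"] == 3


def test_tally_empty():
    tally = tally_motifs({})
    assert tally.n_proteins == 0 and tally.n_motifs == 0
    assert tally.motifs_per_protein_histogram() == {}


def test_tally_planted_single_motif_bin(family_scale_hits):
    tally = tally_motifs(family_scale_hits)
    assert tally.n_proteins == 103
    assert tally.n_motifs == 202
    assert tally.motifs_per_protein_histogram()[1] == 53


class TestPositionProfile:
    def _hits(self, seqs):
        return [MotifHit(pid, 0, len(s), 8, 5, 3) for pid, s in seqs.items()]

    def test_conserved_column_has_max_ic(self):
        seqs = {f"p{n}": "C" + "ADEFGILM"[n % 8] * 8 + "C" + "AAAAA" + "CAAAH"
                for n in range(10)}
        prof = position_profile(self._hits(seqs), seqs)
        assert prof.frequencies[0, prof.alphabet.index("C")] == 1.0
        assert prof.information_content[0] == pytest.approx(math.log2(20))

    def test_uniform_column_zero_ic(self):
        # 20 instances, column 1 cycles through all 20 residues
        seqs = {f"p{n}": "C" + "ACDEFGHIKLMNPQRSTVWY"[n] * 8 + "C" + "AAAAA" + "CAAAH"
                for n in range(20)}
        prof = position_profile(self._hits(seqs), seqs)
        assert prof.information_content[1] == pytest.approx(0.0, abs=1e-12)
        assert prof.frequencies[1].sum() == pytest.approx(1.0)

    def test_known_proportions_recovered(self):
        # 50 instances, column 1 is D in 30 and E in 20
        seqs = {f"p{n}": "C" + ("D" if n < 30 else "E") * 8 + "C" + "AAAAA" + "CAAAH"
                for n in range(50)}
        prof = position_profile(self._hits(seqs), seqs)
        assert prof.frequencies[1, prof.alphabet.index("D")] == pytest.approx(0.6)
        assert prof.frequencies[1, prof.alphabet.index("E")] == pytest.approx(0.4)

    def test_mixed_patterns_rejected(self):
        seqs = {"a": "C" + "A" * 8 + "C" + "AAAAA" + "CAAAH",
                "b": "C" + "A" * 7 + "C" + "AAAAA" + "CAAAH"}
        hits = [MotifHit("a", 0, 20, 8, 5, 3), MotifHit("b", 0, 19, 7, 5, 3)]
        with pytest.raises(ValueError, match="mixed"):
            position_profile(hits, seqs)


class TestProteinStats:
    def test_single_glycine_mass(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)

    def test_pi_is_zero_charge_point(self):
        for seq in ("MKCDEHRY", "AAAA", "DDKK"):
            pi = isoelectric_point(seq)
            assert abs(_net_charge(seq, pi)) < 1e-4

    def test_acidic_below_basic(self):
        assert isoelectric_point("DDDD") < isoelectric_point("KKKK")

    def test_stats_tuple(self):
        mw_kda, pi = protein_stats(ProteinRecord("p", "GG"))
        assert mw_kda == pytest.approx((2 * 57.0519 + 18.0153) / 1000)
        assert 0 < pi < 14

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            molecular_weight("")
        with pytest.raises(ValueError):
            isoelectric_point("")
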