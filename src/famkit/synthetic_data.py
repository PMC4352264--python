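"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments (identical seed →
byte-identical output) and returns a machine-readable truth table alongside
the data, so every stage can be tested against planted ground truth without
any external download.

Backgrounds are deliberately clean by default: proteome backgrounds exclude
C and H so planted CCCH motifs are the only anchor residues (scanner recall
and precision exactly 1), and promoter backgrounds exclude C so planted
cis-elements are the only matches of any C-containing consensus.  Pass
``background="realistic"`` for uniform-alphabet stress tests where those
guarantees lapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneLocus, ProteinRecord
from .molecular_evolution import CodonPair, ng86_sites
from .phylogeny import DistanceMatrix, PhyloTree, TreeNode
from .promoter_elements import DEFAULT_LIBRARY, IUPAC, MotifDefinition, reverse_complement

__all__ = [
    "gen_proteome",
    "paper_scale_motif_plan",
    "gen_codon_pair",
    "gen_locus_table",
    "gen_promoters",
    "gen_expression_pairs",
    "gen_expression_blocks",
    "gen_qpcr",
    "gen_clade_alignment",
    "gen_random_tree",
    "tree_path_distances",
    "gen_supported_tree",
]

_CH_FREE = "ADEFGIKLMNPQRSTVWY"   # 18 residues, no Cys / His
_FULL_AA = "ACDEFGHIKLMNPQRSTVWY"

# common CCCH spacer signatures (i, j) with k = 3, roughly the field's
# frequency ordering: C-X8-C-X5 and C-X7-C-X5 dominate real families
_DEFAULT_PATTERNS = [(8, 5), (7, 5), (5, 4), (9, 5), (7, 6), (4, 5), (10, 5)]


def paper_scale_motif_plan() -> list[int]:
    """A family-scale motifs-per-protein plan: 103 proteins, 202 motifs,
    53 of the proteins carrying a single motif and the rest one to six."""
    plan = [1] * 53 + [2] * 20 + [3] * 17 + [4] * 9 + [5] * 2 + [6] * 2
    assert len(plan) == 103 and sum(plan) == 202
    return plan


def gen_proteome(
    motifs_per_protein: Sequence[int],
    seed: int = 0,
    patterns: Sequence[tuple[int, int]] = tuple(_DEFAULT_PATTERNS),
    k: int = 3,
    min_gap: int = 10,
    base_length: int = 400,
    background: str = "ch_free",
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Proteome with planted CCCH motifs.

    ``motifs_per_protein[p]`` motifs are planted in protein p, with spacer
    signatures drawn from ``patterns``; spacers and background come from the
    C/H-free alphabet unless ``background='realistic'``.  Returns records
    plus a truth table (protein_id, start, end, i, j, k, pattern).

    ``min_gap`` must stay above 12 - i_min + k - 3 (9 at the defaults): a
    shorter gap lets a degenerate match with a large first spacer bridge
    from one planted motif's anchors into the next one's.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(_CH_FREE if background == "ch_free" else _FULL_AA))
    spacer_alpha = np.array(list(_CH_FREE))  # spacers never hold extra anchors
    records: list[ProteinRecord] = []
    truth: list[tuple] = []
    for p, n_motifs in enumerate(motifs_per_protein):
        pid = f"P{p + 1:04d}"
        pieces: list[str] = []
        pos = 0
        lead = int(rng.integers(min_gap, min_gap + 20))
        pieces.append("".join(rng.choice(alphabet, size=lead)))
        pos += lead
        for _ in range(n_motifs):
            i, j = patterns[int(rng.integers(0, len(patterns)))]
            spacers = [
                "".join(rng.choice(spacer_alpha, size=n)) for n in (i, j, k)
            ]
            motif = "C" + spacers[0] + "C" + spacers[1] + "C" + spacers[2] + "H"
            pieces.append(motif)
            truth.append((pid, pos, pos + len(motif), i, j, k, f"C-X{i}-C-X{j}-C-X{k}-H"))
            pos += len(motif)
            gap = int(rng.integers(min_gap, min_gap + 30))
            pieces.append("".join(rng.choice(alphabet, size=gap)))
            pos += gap
        if pos < base_length:
            pieces.append("".join(rng.choice(alphabet, size=base_length - pos)))
        records.append(ProteinRecord(id=pid, sequence="".join(pieces)))
    truth_df = pd.DataFrame(
        truth, columns=["protein_id", "start", "end", "i", "j", "k", "pattern"]
    )
    return records, truth_df


_SENSE_CODONS: list[str] | None = None


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        fwd = unambiguous_dna_by_id[1].forward_table
        _SENSE_CODONS = sorted(fwd)
    return _SENSE_CODONS


def _inverse_jc(d: float) -> float:
    """Raw proportion whose Jukes-Cantor correction equals d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _substitution_options(seq: list[str], synonymous: bool,
                          allowed: set[int] | None = None) -> list[tuple[int, str]]:
    """(codon index, mutated codon) choices of the requested class, stop-free."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    fwd, stops = table.forward_table, set(table.stop_codons)
    options = []
    for idx, codon in enumerate(seq):
        if allowed is not None and idx not in allowed:
            continue
        aa = fwd[codon]
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1:]
                if mut in stops:
                    continue
                if (fwd[mut] == aa) == synonymous:
                    options.append((idx, mut))
    return options


def gen_codon_pair(
    n_codons: int, omega: float, target_ks: float, seed: int = 0
) -> tuple[CodonPair, dict]:
    """A codon-sequence pair evolved to a requested Ks and Ka/Ks.

    The ancestor is a random stop-free codon sequence; its copy receives
    round(p_s·S) synonymous and round(p_n·N) nonsynonymous single-nucleotide
    substitutions, where p_s and p_n are the raw proportions whose
    Jukes-Cantor corrections equal the targets (Ks and ω·Ks).  Substitutions
    never create stop codons.  The truth dict carries the realized counts.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    p_s = _inverse_jc(target_ks)
    p_n = _inverse_jc(omega * target_ks)
    # the inverse-JC proportion asymptotes at 3/4; refuse requests within 5
    # raw percentage points of the singularity (Ks or Ka beyond ~2.0), where
    # neither generation nor estimation is meaningful
    if p_s >= 0.70 or p_n >= 0.70:
        raise ValueError("requested divergence is beyond Jukes-Cantor saturation")
    rng = np.random.default_rng(seed)
    codons = list(rng.choice(_sense_codons(), size=n_codons))
    S = sum(ng86_sites(c)[0] for c in codons)
    N = 3 * n_codons - S
    n_syn = int(round(p_s * S))
    n_non = int(round(p_n * N))
    derived = list(codons)
    realized_syn = realized_non = 0
    hits = np.zeros(n_codons, dtype=int)
    for synonymous, count in ((True, n_syn), (False, n_non)):
        for _ in range(count):
            # spread substitutions over least-hit codons first: multiple hits
            # in one codon force pathway averaging in the estimator, which
            # would decouple realized from countable substitutions
            options: list[tuple[int, str]] = []
            for level in sorted(set(hits)):
                allowed = {x for x in range(n_codons) if hits[x] == level}
                options = _substitution_options(derived, synonymous, allowed)
                if options:
                    break
            if not options:
                break
            idx, mut = options[int(rng.integers(0, len(options)))]
            derived[idx] = mut
            hits[idx] += 1
            if synonymous:
                realized_syn += 1
            else:
                realized_non += 1
    pair = CodonPair("".join(codons), "".join(derived))
    truth = {
        "n_codons": n_codons,
        "omega": omega,
        "target_ks": target_ks,
        "S": S,
        "N": N,
        "syn_substitutions": realized_syn,
        "nonsyn_substitutions": realized_non,
    }
    return pair, truth


def gen_locus_table(
    n_tandem: int = 3,
    n_homeologous: int = 15,
    n_paralogous: int = 1,
    chrom_numbers: Sequence[int] = tuple(range(1, 10)),
    genes_per_chromosome: int = 30,
    seed: int = 0,
    tandem_intervening: int | None = None,
) -> tuple[list[GeneLocus], pd.DataFrame]:
    """Gene loci on an a/b-subgenome chromosome set with planted duplicate pairs.

    Chromosomes ChrNa/ChrNb are filled with ``genes_per_chromosome`` loci
    each; planted pairs of each type pick ordinal slots so that tandem pairs
    have at most 4 intervening genes (or exactly ``tandem_intervening``),
    homeologous pairs sit on ChrNa vs ChrNb, and paralogous pairs on
    different chromosome numbers.  Truth table: gene_a, gene_b, dup_type.
    """
    rng = np.random.default_rng(seed)
    chroms = [f"Chr{n}{s}" for n in chrom_numbers for s in "ab"]
    assignment: dict[tuple[str, int], str] = {}
    counter = [0]

    def new_gene(chrom: str, ordinal: int) -> str:
        counter[0] += 1
        gid = f"G{counter[0]:04d}"
        assignment[(chrom, ordinal)] = gid
        return gid

    def free_ordinal(chrom: str, avoid_span: int = 0) -> int:
        for _ in range(1000):
            o = int(rng.integers(1, genes_per_chromosome + 1 - avoid_span))
            if all((chrom, o + x) not in assignment for x in range(avoid_span + 1)):
                return o
        raise RuntimeError("could not place a planted pair; increase genes_per_chromosome")

    truth: list[tuple[str, str, str]] = []
    for _ in range(n_tandem):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        gap = int(rng.integers(0, 5)) if tandem_intervening is None else tandem_intervening
        o = free_ordinal(chrom, avoid_span=gap + 1)
        a, b = new_gene(chrom, o), new_gene(chrom, o + gap + 1)
        truth.append((a, b, "tandem" if gap <= 4 else "paralogous"))
    for _ in range(n_homeologous):
        n = chrom_numbers[int(rng.integers(0, len(chrom_numbers)))]
        a = new_gene(f"Chr{n}a", free_ordinal(f"Chr{n}a"))
        b = new_gene(f"Chr{n}b", free_ordinal(f"Chr{n}b"))
        truth.append((a, b, "homeologous"))
    for _ in range(n_paralogous):
        n1, n2 = rng.choice(np.asarray(chrom_numbers), size=2, replace=False)
        ca = f"Chr{n1}{'ab'[int(rng.integers(0, 2))]}"
        cb = f"Chr{n2}{'ab'[int(rng.integers(0, 2))]}"
        a = new_gene(ca, free_ordinal(ca))
        b = new_gene(cb, free_ordinal(cb))
        truth.append((a, b, "paralogous"))
    for chrom in chroms:  # background fill
        for o in range(1, genes_per_chromosome + 1):
            if (chrom, o) not in assignment:
                new_gene(chrom, o)
    loci = [
        GeneLocus(gene_id=gid, chromosome=chrom, ordinal=o,
                  start=o * 1000, end=o * 1000 + 500,
                  strand="+" if rng.integers(0, 2) else "-")
        for (chrom, o), gid in sorted(assignment.items())
    ]
    truth_df = pd.DataFrame(truth, columns=["gene_a", "gene_b", "dup_type"])
    return loci, truth_df


def _realize_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC[c])[int(rng.integers(0, len(IUPAC[c])))] for c in consensus)


def gen_promoters(
    planting: Mapping[str, Mapping[str, int]],
    library: Sequence[MotifDefinition] = DEFAULT_LIBRARY,
    length: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Promoters with planted cis-elements on random strands.

    ``planting`` maps promoter id -> {motif name: count}.  The background is
    C-free (A/G/T only) so any consensus containing a C — true of the whole
    default library and its reverse complements — can only match a planted
    instance; exact-count recovery additionally requires that the planted
    motifs' consensi do not match one another (ABRE vs DRE are clean, DRE vs
    its sub-pattern LTRE are not).  Truth table: promoter, motif, count.
    """
    rng = np.random.default_rng(seed)
    by_name = {m.name: m for m in library}
    bg = np.array(list("AGT"))
    promoters: dict[str, str] = {}
    truth: list[tuple[str, str, int]] = []
    for pid, wanted in planting.items():
        seq = rng.choice(bg, size=length)
        slots_used: list[tuple[int, int]] = []
        for motif_name, count in wanted.items():
            motif = by_name[motif_name]
            for _ in range(count):
                instance = _realize_iupac(motif.consensus.upper(), rng)
                if rng.integers(0, 2):
                    instance = reverse_complement(instance)
                w = len(instance)
                for _attempt in range(1000):
                    start = int(rng.integers(0, length - w + 1))
                    if all(start + w <= s or start >= e for s, e in slots_used):
                        break
                else:  # pragma: no cover
                    raise RuntimeError("could not place cis-element; promoter too crowded")
                seq[start:start + w] = list(instance)
                slots_used.append((start, start + w))
            truth.append((pid, motif_name, count))
        promoters[pid] = "".join(seq)
    truth_df = pd.DataFrame(truth, columns=["promoter", "motif", "count"])
    return promoters, truth_df


def gen_expression_pairs(
    n_pairs: int, correlation: float, n_samples: int = 21, seed: int = 0,
    baseline_log2: float = 8.0, spread_log2: float = 2.0,
) -> tuple[ExpressionMatrix, list[tuple[str, str]]]:
    """Expression matrix of gene pairs with a target profile correlation.

    Each pair's two log2 profiles are jointly Gaussian with the requested
    Pearson correlation; signals are 2^(baseline + spread·z), well above the
    pseudocount so the log2 transform is effectively linear.
    """
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    rows: list[np.ndarray] = []
    pairs: list[tuple[str, str]] = []
    for p in range(n_pairs):
        x = rng.standard_normal(n_samples)
        z = rng.standard_normal(n_samples)
        y = correlation * x + math.sqrt(max(0.0, 1 - correlation ** 2)) * z
        a, b = f"pair{p + 1}_a", f"pair{p + 1}_b"
        genes += [a, b]
        rows.append(2.0 ** (baseline_log2 + spread_log2 * x))
        rows.append(2.0 ** (baseline_log2 + spread_log2 * y))
        pairs.append((a, b))
    samples = [f"S{s + 1:02d}" for s in range(n_samples)]
    return ExpressionMatrix(genes, samples, np.vstack(rows)), pairs


def gen_expression_blocks(
    n_blocks: int = 3, genes_per_block: int = 4, n_samples: int = 12,
    seed: int = 0, block_sd: float = 3.0, noise_sd: float = 0.3,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Matrix with blocks of co-expressed genes, for clustering checks."""
    rng = np.random.default_rng(seed)
    genes, rows, truth = [], [], []
    for blk in range(n_blocks):
        profile = block_sd * rng.standard_normal(n_samples)
        for g in range(genes_per_block):
            gid = f"B{blk + 1}G{g + 1}"
            genes.append(gid)
            truth.append((gid, blk))
            rows.append(2.0 ** (8.0 + profile + noise_sd * rng.standard_normal(n_samples)))
    samples = [f"S{s + 1:02d}" for s in range(n_samples)]
    truth_df = pd.DataFrame(truth, columns=["gene", "block"])
    return ExpressionMatrix(genes, samples, np.vstack(rows)), truth_df


def gen_qpcr(
    fold_plan: Mapping[tuple[str, str, float], float],
    references: Sequence[str] = ("PvFTSH4", "Actin2"),
    n_replicates: int = 3,
    sigma_ct: float = 0.05,
    seed: int = 0,
    control_timepoint: float = 0.0,
    target_base_ct: float = 28.0,
    reference_base_ct: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table realizing planted fold changes with replicate noise.

    ``fold_plan`` maps (gene, treatment, timepoint) -> fold vs the 0 h
    control of that treatment.  Reference genes stay flat (up to noise) and
    a control timepoint row is emitted for every planted condition.  Truth
    table: gene, treatment, timepoint_h, fold.
    """
    rng = np.random.default_rng(seed)
    conditions: set[tuple[str, float]] = set()
    targets: set[str] = set()
    for gene, treatment, tp in fold_plan:
        targets.add(gene)
        conditions.add((treatment, tp))
        conditions.add((treatment, control_timepoint))
    rows = []
    for treatment, tp in sorted(conditions):
        for rep in range(1, n_replicates + 1):
            for ref in references:
                rows.append((ref, treatment, tp, f"r{rep}",
                             reference_base_ct + sigma_ct * rng.standard_normal()))
            for gene in sorted(targets):
                fold = 1.0 if tp == control_timepoint else fold_plan.get(
                    (gene, treatment, tp), 1.0)
                ct = target_base_ct - math.log2(fold) + sigma_ct * rng.standard_normal()
                rows.append((gene, treatment, tp, f"r{rep}", ct))
    df = pd.DataFrame(rows, columns=["gene", "treatment", "timepoint_h", "replicate", "ct"])
    truth = pd.DataFrame(
        [(g, tr, tp, f) for (g, tr, tp), f in fold_plan.items()],
        columns=["gene", "treatment", "timepoint_h", "fold"],
    )
    return df, truth


def gen_clade_alignment(
    group_sizes: Sequence[int], n_sites: int = 200, seed: int = 0,
    within_divergence: float = 0.05, between_divergence: float = 0.5,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Protein alignment whose taxa fall into clean groups.

    Each group descends from its own random ancestral sequence (groups
    differ at ~``between_divergence`` of sites); members diverge from the
    group ancestor at ~``within_divergence``.  Truth: taxon, group.
    """
    rng = np.random.default_rng(seed)
    alpha = np.array(list(_FULL_AA))
    root = rng.choice(alpha, size=n_sites)
    aln: dict[str, str] = {}
    truth = []
    for g, size in enumerate(group_sizes):
        anc = root.copy()
        mask = rng.random(n_sites) < between_divergence
        anc[mask] = rng.choice(alpha, size=int(mask.sum()))
        for m in range(size):
            taxon = f"g{g + 1}t{m + 1}"
            seq = anc.copy()
            mask = rng.random(n_sites) < within_divergence
            seq[mask] = rng.choice(alpha, size=int(mask.sum()))
            aln[taxon] = "".join(seq)
            truth.append((taxon, g))
    return aln, pd.DataFrame(truth, columns=["taxon", "group"])


def gen_random_tree(n_leaves: int, seed: int = 0, min_branch: float = 0.1,
                    max_branch: float = 1.0) -> PhyloTree:
    """Random unrooted binary tree with positive branch lengths.

    Built by sequential leaf attachment to random edges; leaf names are
    T1..Tn.  Used as the additivity oracle for neighbor joining.
    """
    if n_leaves < 4:
        raise ValueError("need >= 4 leaves")
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    leaves = [TreeNode(name=f"T{x + 1}", length=blen()) for x in range(n_leaves)]
    root = TreeNode(children=[leaves[0], leaves[1], leaves[2]])
    edges: list[tuple[TreeNode, TreeNode]] = [(root, c) for c in root.children]
    for leaf in leaves[3:]:
        parent, child = edges[int(rng.integers(0, len(edges)))]
        mid = TreeNode(children=[child, leaf], length=blen())
        # split the edge: keep the child's branch length on the lower half
        parent.children[parent.children.index(child)] = mid
        edges.remove((parent, child))
        edges += [(parent, mid), (mid, child), (mid, leaf)]
    return PhyloTree(root=root, taxa=[f"T{x + 1}" for x in range(n_leaves)])


def tree_path_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (additive) distances of a tree."""
    dists: dict[str, dict[str, float]] = {}

    def collect(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            return {node.name: 0.0}
        below: list[dict[str, float]] = []
        for child in node.children:
            sub = {t: d + child.length for t, d in collect(child).items()}
            below.append(sub)
        for x in range(len(below)):
            for y in range(x + 1, len(below)):
                for ta, da in below[x].items():
                    for tb, db in below[y].items():
                        dists.setdefault(ta, {})[tb] = da + db
                        dists.setdefault(tb, {})[ta] = da + db
        merged: dict[str, float] = {}
        for sub in below:
            merged.update(sub)
        return merged

    collect(tree.root)
    taxa = tree.taxa
    n = len(taxa)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                d[a, b] = dists[taxa[a]][taxa[b]]
    return DistanceMatrix(list(taxa), d)


def gen_supported_tree(
    groups: Sequence[Sequence[str]], singletons: Sequence[str],
    clade_support: float = 99.0, other_support: float = 30.0,
) -> PhyloTree:
    """A tree whose only well-supported edges are the given groups.

    Each group becomes a pectinate subtree whose top edge carries
    ``clade_support``; every other internal edge gets ``other_support``.
    Used to exercise clade extraction on family-scale layouts without
    building bootstrap trees of that size.
    """

    def caterpillar(names: Sequence[str]) -> TreeNode:
        node = TreeNode(name=names[0], length=0.1)
        for name in names[1:]:
            node = TreeNode(children=[node, TreeNode(name=name, length=0.1)],
                            length=0.1, support=other_support)
        return node

    children: list[TreeNode] = []
    for group in groups:
        if len(group) == 1:
            children.append(TreeNode(name=group[0], length=0.1))
            continue
        top = caterpillar(list(group))
        top.support = clade_support
        children.append(top)
    for name in singletons:
        children.append(TreeNode(name=name, length=0.1))
    root = TreeNode(children=children)
    taxa = [n for g in groups for n in g] + list(singletons)
    return PhyloTree(root=root, taxa=taxa)
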