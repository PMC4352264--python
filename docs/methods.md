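# Methods

This note documents the models and procedures famkit implements, the
defaults and why they were chosen, what the synthetic generators emulate,
and the numerical conventions. It states no empirical result that the test
suite does not itself compute.

## Motif scanning

The CCCH zinc finger is detected as the degenerate anchor pattern
C-X(i)-C-X(j)-C-X(k)-H over the raw protein sequence. Defaults are
i ∈ [4, 17], j ∈ [4, 6], k = 3 — the wide first-spacer range used in
genome-wide C3H surveys; the classical family definition caps i at 15 and
allows k ∈ {3, 4}, and both variants are reachable through `ScanParams`.

Two overlap policies are provided, because a count of "motifs per protein"
is only well defined once one is chosen:

- `nonoverlapping_shortest_first` (default): scan left to right; at the
  first start position admitting any match take the smallest i, then the
  smallest j, and resume scanning after the matched histidine. This mirrors
  non-overlapping regex semantics and is fully deterministic.
- `all_matches`: report every (start, i, j) combination whose four anchors
  hold. This is the mode checked against the brute-force enumeration oracle
  in the tests.

Position profiles are plain column frequency matrices over the 20-residue
alphabet; information content is log2(20) − H(column) in bits with no
small-sample correction, so a fully conserved column scores ≈ 4.32 bits and
a uniform column 0. X residues are ignored (they carry no information).

Protein statistics: molecular weight is the sum of average residue masses
plus one water; X contributes the mean residue mass. The isoelectric point
is found by bisecting the Henderson–Hasselbalch net-charge curve over the
N/C termini and D, E, C, Y, H, K, R side chains to |charge| < 1e−4, using
the EMBOSS pKa set. Published pI calculators use slightly different pKa
tables; any consistent table satisfies the defining zero-charge property the
tests assert, so exact parity with a specific web tool is not claimed.

## Phylogeny

Distances are amino-acid p-distances: the proportion of differing sites
among comparable sites, with either pairwise deletion (default) or complete
deletion of gapped columns. Tree building is the classical Saitou–Nei
neighbor-joining agglomeration; ties in the Q criterion are broken by
smallest (row, column) index so results are bitwise reproducible. Negative
branch lengths are retained by default (`clamp_negative` zeroes them for
presentation); NJ on an additive matrix reproduces the generating tree
exactly, which the tests exploit as an oracle.

Bootstrap support resamples alignment columns with replacement (seeded),
rebuilds the tree per replicate, and scores each reference internal edge by
the percentage of replicates containing its bipartition. The reference
topology never depends on the bootstrap seed.

Clade extraction takes every internal edge with support strictly above the
threshold (default 50), uses the smaller side of its split as a candidate
clade, and reports the inclusion-maximal candidates; taxa covered by no
clade are singletons. "Strictly above" matters: a support of exactly 50
does not found a clade.

## Molecular evolution

Duplicate typing works from chromosome labels of the form ChrN[a|b] plus
each gene's ordinal rank along its chromosome. Tandem: same chromosome and
at most 4 intervening gene loci (strictly fewer than five). Homeologous:
same chromosome number, different subgenome letter — the signature of
allopolyploid duplication. Everything else with known chromosomes is plain
paralogous; an unknown chromosome yields "unknown".

Ka/Ks is Nei–Gojobori (1986). Per sense codon, each position contributes
the fraction of its three single-nucleotide changes that are synonymous;
changes to stop codons are excluded from the denominator by default
(configurable to count as nonsynonymous). S and N are averaged over the two
sequences. Codon pairs differing at one position are classified directly;
at two or three positions the syn/nonsyn difference counts are averaged
over all substitution orderings, excluding pathways through stop codons and
renormalizing (if every pathway crosses a stop, the stop steps are counted
nonsynonymous rather than dropping the codon). Raw proportions ps = Sd/S
and pn = Nd/N receive the Jukes–Cantor correction d = −(3/4)·ln(1−(4/3)p),
which is undefined at p ≥ 3/4 — such saturated comparisons raise an error
rather than returning a number.

Selection is called from the ratio: > 1 diversifying, < 1 purifying, = 1
neutral. Ks = 0 with Ka > 0 is reported as diversifying with an undefined
ratio (nonsynonymous divergence with no synonymous divergence); Ka = Ks = 0
is neutral. Divergence time is T = Ks/(2λ)×10⁻⁶ Mya with λ = 6.5×10⁻⁹
synonymous substitutions/site/year (the grass clock) — reported to one
decimal with half-up rounding, and as NA (raw value available) when Ks = 0,
where the clock carries no information. The published 19-pair switchgrass
reference table uses exactly these conventions; its Ka/Ks column was
evidently computed from unrounded operands, so ratio parity is asserted
only at the table's printed precision.

The original analyses behind such tables typically ran DNAsp, which
defaults to the same NG86 + Jukes–Cantor scheme; exact numeric parity with
any specific program is not claimed.

## Promoter elements

Promoters are taken as the −2000..−1 window 5'→3' on the coding strand.
Each IUPAC consensus is matched at every offset on the sense strand, and
its reverse complement likewise (reported as antisense with sense-strand
coordinates); all overlapping matches are kept, matching classical plant
cis-element database semantics. A sequence N matches only the consensus
code N, so unknown bases never create hits. The default library (ABRE
ACGTGKC, DRE RCCGAC, CBFHV RYCGAC, LTRE CCGAC) is a documented assumption,
not a contract — cis-element databases carry many variants per element and
the library is overridable via a two-column TSV. Note the default entries
are mutually nested (every LTRE is inside a DRE realization), so counts of
different elements over the same promoter are not disjoint.

## Expression atlas

"Value normalization" for heatmap display is row-centered log2:
x → log2(x+1) − mean, so each cell is a log2 fold change against the gene's
own mean and constant genes map to zero rows. A per-gene z-score variant is
provided. Clustering is scipy's agglomerative linkage (euclidean, average
by default) on the transformed matrix; scipy's index-ordered tie-breaking
makes trees deterministic, and the tests check the merge heights against a
from-scratch agglomerative re-computation.

Expression similarity within a duplicate pair is the Pearson correlation of
the two transformed profiles, with "similar" meaning r ≥ 0.8 by default.
The threshold is a design choice: published atlas comparisons call pairs
similar by eye, so the qualitative contrast (purifying-selected pairs more
often similar than diversifying-selected ones) is reproduced on synthetic
data rather than asserted as a numeric parity.

## qPCR

ΔCt normalizes the target against the arithmetic mean Ct of the reference
genes (the geometric mean of their expression); ΔΔCt compares the treated
group's mean ΔCt with the 0 h control of the same treatment; fold change is
E^(−ΔΔCt) with amplification efficiency E = 2 (configurable). The fold is
invariant to plate-wide Ct shifts. Induction uses a symmetric cut-off:
fold ≥ 2 or ≤ 0.5. Significance per timepoint is Welch's t on log2
replicate folds (an exact permutation variant exists, which returns p = 1
on identical replicate sets); a Tukey HSD over the joint timepoint layout
uses the studentized range on the pooled within-group variance. The 0 h
control within each treatment is assumed to be the comparison baseline.

## Synthetic data

Every generator is a pure function of its arguments (same seed →
byte-identical output) and emits a truth table consumed by the tests.

- **Proteomes**: backgrounds and spacers exclude C and H, so planted motifs
  own all anchor residues and scanner recall/precision are exactly 1. The
  minimum inter-motif gap is 10: a shorter gap lets a degenerate match with
  a large first spacer bridge from one motif's anchors into the next one's
  (the bridging condition is gap ≤ 12 − i_min at k = 3). The family-scale
  plan plants 202 motifs across 103 proteins with 53 single-motif proteins.
  A realistic-composition mode drops the clean-background guarantee for
  stress testing.
- **Codon pairs**: the copy receives round(p·sites) synonymous and
  nonsynonymous substitutions, where p inverts the Jukes–Cantor correction
  of the requested Ks (and ω·Ks), never creating stops. Substitutions are
  placed on least-hit codons first, because multiple hits in one codon force
  pathway averaging in the estimator and decouple realized from countable
  substitutions. Requests with inverse-JC proportions ≥ 0.70 (Ks ≳ 2) are
  refused as effectively saturated — the inverse proportion asymptotes at
  3/4, so a hard "at saturation" request cannot exist.
- **Loci**: ChrNa/ChrNb chromosome sets with planted tandem (0–4
  intervening loci, or a fixed spacing for boundary tests), homeologous and
  paralogous pairs among background genes.
- **Promoters**: C-free (A/G/T) backgrounds, so any consensus containing a
  C — all default entries and their reverse complements — can only match a
  planted instance. Exact-count recovery additionally requires the planted
  motifs not to match one another; tests plant ABRE and DRE, which are
  mutually clean. Instances are realized from the IUPAC consensus and
  inserted on a random strand at non-overlapping positions.
- **Expression**: gene pairs with jointly Gaussian log2 profiles at a target
  Pearson correlation, and block-structured matrices for clustering; signals
  sit well above the pseudocount (baseline 2⁸) so the transform is
  effectively linear. Microarray noise (probe effects, cross-hybridization)
  is not modeled.
- **qPCR**: Ct tables realizing planted folds with Gaussian Ct noise
  (default σ = 0.05 cycles, three biological replicates), flat reference
  genes, and a 0 h control per treatment.

A green test on these fixtures establishes that the algorithms recover
planted structure under the generators' stated assumptions; it does not
establish performance on real proteomes (where anchor residues occur in the
background), real promoters (where elements occur by chance), or real
microarray data.

## Degenerate inputs and numerical conventions

Coordinates are 0-based half-open internally, 1-based inclusive in reports.
Report rounding is half-up (Decimal), matching how printed tables round:
Ks/Ka/ratio to 3 decimals, divergence time to 1. Empty sequences, duplicate
FASTA ids, duplicate (chromosome, ordinal) slots, start ≥ end intervals,
non-finite or negative expression values, and Ct ≤ 0 are rejected at the
I/O boundary. A pair of aligned sequences with no comparable sites is an
error naming the pair. Pearson correlation of a constant profile is
reported as 0 (undefined covariance). Isoform selection keeps the longest
sequence per gene group, breaking length ties by the lexicographically
smallest id.
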