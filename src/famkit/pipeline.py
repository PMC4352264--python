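"""End-to-end family analysis: scan → tree → duplication/Ka-Ks → promoters →
expression atlas → qPCR, with per-stage TSV outputs and a JSON summary.

Stages run only when their inputs are configured; a missing optional input
logs a notice and the stage is skipped.  Identical config and seed give a
byte-identical report bundle.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import core_io, expression_atlas, molecular_evolution as me, motif_scan, phylogeny, promoter_elements, qpcr_quant

log = logging.getLogger("famkit")

__all__ = ["PipelineConfig", "run_family_analysis"]


@dataclass
class PipelineConfig:
    out_dir: str
    proteome_fasta: str | None = None
    alignment_fasta: str | None = None
    cds_pairs_fasta: str | None = None
    pairs_tsv: str | None = None          # gene_a, gene_b[, cds_a, cds_b]
    locus_tsv: str | None = None
    promoter_fasta: str | None = None
    motif_library_tsv: str | None = None
    expression_tsv: str | None = None
    ct_tsv: str | None = None
    qpcr_targets: list[str] = field(default_factory=list)
    qpcr_references: list[str] = field(default_factory=lambda: ["PvFTSH4", "Actin2"])
    # parameters; defaults are the published analysis' stated values
    i_min: int = 4
    i_max: int = 17
    j_min: int = 4
    j_max: int = 6
    overlap_policy: str = "nonoverlapping_shortest_first"
    bootstrap_replicates: int = 1000
    support_threshold: float = 50.0
    lambda_rate: float = 6.5e-9
    max_intervening: int = 4
    fold_cutoff: float = 2.0
    similarity_threshold: float = 0.8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def hits_frame(hits: list[motif_scan.MotifHit]) -> pd.DataFrame:
    """Motif hits as a report table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [(h.protein_id, h.start + 1, h.end, h.pattern_label) for h in hits],
        columns=["protein_id", "start", "end", "pattern"],
    )


def kaks_frame(rows: list[dict[str, Any]]) -> pd.DataFrame:
    """Ka/Ks results as a report table with the published rounding (Ks, Ka,
    ratio to 3 decimals; divergence time to one)."""
    out = []
    for r in rows:
        res: me.KaKsResult = r["result"]
        out.append({
            "gene_a": r["gene_a"],
            "gene_b": r["gene_b"],
            "chrom_a": r.get("chrom_a", "unknown"),
            "chrom_b": r.get("chrom_b", "unknown"),
            "ks": me.round_half_up(res.Ks, 3),
            "ka": me.round_half_up(res.Ka, 3),
            "ratio": "NA" if res.ratio is None else me.round_half_up(res.ratio, 3),
            "selection": res.selection,
            "dup_type": r.get("dup_type", "unknown"),
            "t_mya": "NA" if res.T_mya is None else res.T_mya,
        })
    return pd.DataFrame(out)


def run_family_analysis(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage; returns the summary dict (also written as
    summary.json in the output directory alongside per-stage TSVs)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed, "stages": []}
    t0 = time.time()

    records = None
    if config.proteome_fasta:
        records = core_io.read_fasta(config.proteome_fasta, alphabet="protein")
        params = motif_scan.ScanParams(
            i_min=config.i_min, i_max=config.i_max,
            j_min=config.j_min, j_max=config.j_max,
            overlap_policy=config.overlap_policy,
        )
        hits_by_protein = {r.id: motif_scan.scan_ccch(r, params) for r in records}
        tally = motif_scan.tally_motifs(hits_by_protein)
        all_hits = [h for hs in hits_by_protein.values() for h in hs]
        _write_tsv(hits_frame(all_hits), out / "motif_hits.tsv")
        summary["motif_scan"] = {
            "n_proteins": tally.n_proteins,
            "n_motifs": tally.n_motifs,
            "pattern_counts": tally.pattern_counts,
            "motifs_per_protein": {
                str(k): v for k, v in tally.motifs_per_protein_histogram().items()
            },
        }
        summary["stages"].append("motif_scan")
    else:
        log.info("no proteome FASTA configured; skipping motif scan")

    if config.alignment_fasta:
        aln_records = core_io.read_fasta(config.alignment_fasta, alphabet="protein",
                                         strict=False)
        alignment = {r.id: r.sequence for r in aln_records}
        tree = phylogeny.bootstrap_support(
            alignment,
            phylogeny.TreeParams(
                bootstrap_replicates=config.bootstrap_replicates,
                support_threshold=config.support_threshold,
                rng_seed=config.seed,
            ),
        )
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        clades, singletons = phylogeny.extract_clades(tree, config.support_threshold)
        clade_rows = [
            {"clade_id": f"clade{n + 1}", "support": c.support,
             "members": ",".join(sorted(c.members))}
            for n, c in enumerate(clades)
        ]
        _write_tsv(pd.DataFrame(clade_rows, columns=["clade_id", "support", "members"]),
                   out / "clades.tsv")
        summary["phylogeny"] = {
            "n_taxa": len(alignment),
            "total_branch_length": round(tree.total_branch_length(), 4),
            "n_clades": len(clades),
            "n_clade_members": sum(len(c.members) for c in clades),
            "n_singletons": len(singletons),
        }
        summary["stages"].append("phylogeny")
    else:
        log.info("no alignment configured; skipping phylogeny")

    if config.cds_pairs_fasta and config.pairs_tsv:
        loci = {}
        if config.locus_tsv:
            loci = {l.gene_id: l for l in core_io.read_locus_table(config.locus_tsv)}
        cds = {r.id: r for r in core_io.read_fasta(config.cds_pairs_fasta, alphabet="dna")}
        pairs = pd.read_csv(config.pairs_tsv, sep="\t")
        evo = me.EvolutionParams(lambda_rate=config.lambda_rate)
        rows = []
        for row in pairs.itertuples():
            cds_a = getattr(row, "cds_a", row.gene_a)
            cds_b = getattr(row, "cds_b", row.gene_b)
            result = me.kaks(me.CodonPair(cds[cds_a].sequence, cds[cds_b].sequence), evo)
            entry: dict[str, Any] = {"gene_a": row.gene_a, "gene_b": row.gene_b,
                                     "result": result}
            if row.gene_a in loci and row.gene_b in loci:
                la, lb = loci[row.gene_a], loci[row.gene_b]
                entry.update(chrom_a=la.chromosome, chrom_b=lb.chromosome,
                             dup_type=me.classify_duplication(la, lb,
                                                              config.max_intervening))
            rows.append(entry)
        table = kaks_frame(rows)
        _write_tsv(table, out / "kaks.tsv")
        selection_counts = table["selection"].value_counts().to_dict()
        summary["molecular_evolution"] = {
            "n_pairs": len(table),
            "selection_counts": selection_counts,
            "dup_type_counts": table["dup_type"].value_counts().to_dict(),
        }
        summary["stages"].append("molecular_evolution")
    else:
        log.info("no CDS pair inputs configured; skipping Ka/Ks")

    if config.promoter_fasta:
        library = (promoter_elements.read_motif_library(config.motif_library_tsv)
                   if config.motif_library_tsv else promoter_elements.DEFAULT_LIBRARY)
        proms = core_io.read_fasta(config.promoter_fasta, alphabet="dna")
        all_hits = []
        for rec in proms:
            all_hits.extend(promoter_elements.scan_promoter(rec.id, rec.sequence, library))
        hit_rows = pd.DataFrame(
            [(h.promoter_id, h.motif, h.strand, h.start + 1, h.match) for h in all_hits],
            columns=["promoter", "motif", "strand", "start", "match"],
        )
        _write_tsv(hit_rows, out / "promoter_hits.tsv")
        counts = promoter_elements.element_summary(
            all_hits, promoter_ids=[r.id for r in proms],
            motif_names=[m.name for m in library],
        )
        counts.reset_index().to_csv(out / "promoter_summary.tsv", sep="\t", index=False,
                                    lineterminator="\n")
        summary["promoters"] = {"n_promoters": len(proms), "n_hits": len(all_hits)}
        summary["stages"].append("promoters")
    else:
        log.info("no promoter FASTA configured; skipping cis-element scan")

    if config.expression_tsv:
        matrix = core_io.read_expression_matrix(config.expression_tsv)
        transformed = expression_atlas.normalize_log2(matrix)
        transformed.to_csv(out / "expression_log2.tsv", sep="\t", lineterminator="\n")
        gene_axis = expression_atlas.hcluster(transformed, axis="genes")
        sample_axis = expression_atlas.hcluster(transformed, axis="samples")
        summary["expression_atlas"] = {
            "n_genes": len(matrix.gene_ids),
            "n_samples": len(matrix.sample_ids),
            "gene_leaf_order": gene_axis.leaf_order,
            "sample_leaf_order": sample_axis.leaf_order,
        }
        if config.pairs_tsv:
            pairs = pd.read_csv(config.pairs_tsv, sep="\t")
            pair_list = [(r.gene_a, r.gene_b) for r in pairs.itertuples()
                         if r.gene_a in transformed.index and r.gene_b in transformed.index]
            if pair_list:
                sims, _ = expression_atlas.pair_expression_similarity(
                    transformed, pair_list, threshold=config.similarity_threshold)
                _write_tsv(pd.DataFrame(
                    [(s.gene_a, s.gene_b, round(s.correlation, 4), s.similar)
                     for s in sims],
                    columns=["gene_a", "gene_b", "correlation", "similar"]),
                    out / "pair_similarity.tsv")
                summary["expression_atlas"]["n_pairs_compared"] = len(sims)
        summary["stages"].append("expression_atlas")
    else:
        log.info("no expression matrix configured; skipping atlas")

    if config.ct_tsv and config.qpcr_targets:
        ct = qpcr_quant.read_ct_table(config.ct_tsv)
        rows = []
        for target in config.qpcr_targets:
            for res in qpcr_quant.ddct_fold(ct, target, config.qpcr_references,
                                            cutoff=config.fold_cutoff):
                rows.append((res.gene, res.treatment, res.timepoint_h,
                             round(res.fold, 3), res.induced,
                             "NA" if res.p_value is None else round(res.p_value, 4),
                             res.significant))
        _write_tsv(pd.DataFrame(rows, columns=["gene", "treatment", "timepoint_h",
                                               "fold", "induced", "p", "significant"]),
                   out / "qpcr_folds.tsv")
        summary["qpcr"] = {
            "n_results": len(rows),
            "n_induced": sum(1 for r in rows if r[4]),
        }
        summary["stages"].append("qpcr")
    else:
        log.info("no Ct table configured; skipping qPCR")

    log.info("pipeline finished in %.2f s", time.time() - t0)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
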