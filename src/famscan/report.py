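"""End-to-end survey orchestration and summary statistics.

``run_pipeline`` wires the stages in dependency order — domain scan,
subgroup assignment, duplication analysis, chromosome/QTL mapping,
expression scoring — skipping any stage whose inputs are absent, and
returns a ``SurveySummary`` whose internal arithmetic (totals, percentages)
is re-checked at emit time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from . import duplication as dup
from .domains import GROUP_I, UNCLASSIFIED, WrkyGene, enumerate_variants, scan_gene
from .expression import (
    classify_response,
    profiles_from_cq,
    read_cq_csv,
    read_evidence_csv,
    summarize_evidence,
)
from .genome_qtl import (
    chromosome_distribution,
    mean_gene_spacing_mb,
    parse_qtl_table,
    qtl_overlap,
)
from .loci import Locus, read_bed, read_gff3, subgenome_of
from .phylo import ReferenceDomainSet, assign_subgroups, distance_matrix, nj_tree


def fmt_percent(numerator: float, denominator: float) -> str:
    """Percentage formatted to two decimals, round half up (e.g. '4.88%')."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(numerator) / Decimal(denominator) * 100
    return f"{value.quantize(Decimal('0.01'), rounding=ROUND_HALF_UP)}%"


@dataclass
class PipelineInputs:
    proteome: str | Path
    loci: Optional[str | Path] = None  # GFF3 (.gff3/.gff) or BED (.bed)
    chrom_lengths: Optional[str | Path] = None  # JSON {chromosome: bp}
    qtl: Optional[str | Path] = None
    evidence: Optional[str | Path] = None
    cq: Optional[str | Path] = None
    refs: Optional[str | Path] = None
    duplicate_threshold: float = 85.0
    max_mismatch: int = 2
    linker_window: int = 50
    support_threshold: float = 0.7
    tandem_max_distance_bp: int = 100_000
    min_block_pairs: int = 3
    segmental_max_gap_bp: int = 2_000_000
    qtl_contained: bool = False


@dataclass
class SurveySummary:
    total_proteins: int = 0
    total_wrky_genes: int = 0
    total_domains: int = 0
    two_domain_genes: int = 0
    unclassified_genes: int = 0
    group_counts: Dict[str, int] = field(default_factory=dict)
    subgroup_counts: Dict[str, int] = field(default_factory=dict)
    variant_summary: Dict[str, Dict] = field(default_factory=dict)
    variant_domain_count: int = 0
    distribution: Optional[List[Dict]] = None
    unanchored: Optional[int] = None
    density_min: Optional[float] = None
    density_max: Optional[float] = None
    mean_spacing_mb: Optional[float] = None
    duplication: Optional[Dict] = None
    qtl: Optional[Dict] = None
    expression: Optional[Dict] = None
    qpcr: Optional[Dict] = None

    max_domains_per_gene: int = 0

    def validate(self) -> None:
        """Internal consistency checks asserted at emit time."""
        assert sum(self.group_counts.values()) == self.total_wrky_genes
        if self.max_domains_per_gene <= 2:
            # every extra domain beyond one per gene is a second domain
            assert self.two_domain_genes == self.total_domains - self.total_wrky_genes
        if self.distribution is not None and self.unanchored is not None:
            anchored = sum(row["genes"] for row in self.distribution)
            assert anchored + self.unanchored == self.total_wrky_genes
            for row in self.distribution:
                assert row["density_per_mb"] == row["genes"] / (row["length_bp"] / 1e6)
        if self.duplication:
            d = self.duplication
            if d.get("tandem_gene_percent") is not None and self.total_wrky_genes:
                expected = fmt_percent(d["tandem_gene_count"], self.total_wrky_genes)
                assert d["tandem_gene_percent"] == expected

    def to_dict(self) -> Dict:
        return {
            "totals": {
                "proteins": self.total_proteins,
                "wrky_genes": self.total_wrky_genes,
                "domains": self.total_domains,
                "two_domain_genes": self.two_domain_genes,
                "unclassified": self.unclassified_genes,
            },
            "group_counts": self.group_counts,
            "subgroup_counts": self.subgroup_counts,
            "variants": {
                "by_heptapeptide": self.variant_summary,
                "variant_domains": self.variant_domain_count,
            },
            "distribution": self.distribution,
            "unanchored": self.unanchored,
            "density_min": self.density_min,
            "density_max": self.density_max,
            "mean_spacing_mb": self.mean_spacing_mb,
            "duplication": self.duplication,
            "qtl": self.qtl,
            "expression": self.expression,
            "qpcr": self.qpcr,
        }

    def to_text(self) -> str:
        lines = [
            "WRKY family survey summary",
            "==========================",
            f"proteins scanned       : {self.total_proteins}",
            f"WRKY genes             : {self.total_wrky_genes}",
            f"WRKY domains           : {self.total_domains}",
            f"two-domain genes       : {self.two_domain_genes}",
            f"group counts           : {self.group_counts}",
            f"subgroup counts        : {self.subgroup_counts}",
            f"variant domains        : {self.variant_domain_count}",
        ]
        if self.distribution is not None:
            lines.append(f"unanchored genes       : {self.unanchored}")
            lines.append(
                f"density range (per Mb) : {self.density_min:.3f}-{self.density_max:.3f}"
            )
            if self.mean_spacing_mb is not None:
                lines.append(f"mean gene spacing (Mb) : {self.mean_spacing_mb:.3f}")
        if self.duplication is not None:
            d = self.duplication
            lines.append(
                "duplication            : "
                f"{d['duplicate_pairs']} pairs, {d['tandem_pairs']} tandem "
                f"({d['tandem_gene_percent']} of genes), "
                f"{d['ortholog_pairs']} ortholog pairs, "
                f"{d['segmental_blocks']} segmental blocks"
            )
        if self.qtl is not None:
            lines.append(
                f"QTL overlap            : {self.qtl['genes_in_qtl']} genes in "
                f"{self.qtl['n_qtls']} QTLs; multi-stress: {self.qtl['multi_stress_genes']}"
            )
        if self.expression is not None:
            e = self.expression
            lines.append(
                "in-silico expression   : "
                f"{e['microarray_genes']} microarray genes + {e['est_genes']} EST genes "
                f"= {e['per_kind_sum']} (sum) / {e['union_genes']} (union)"
            )
        if self.qpcr is not None:
            lines.append(
                f"qPCR multi-stress genes: {self.qpcr['multi_stress_genes']}"
            )
        return "\n".join(lines) + "\n"


def read_proteome(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_loci(path: str | Path) -> Dict[str, Locus]:
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return read_bed(path)
    return read_gff3(path)


def run_pipeline(inputs: PipelineInputs, outdir: Optional[str | Path] = None) -> SurveySummary:
    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)

    proteome = read_proteome(inputs.proteome)
    loci = load_loci(inputs.loci) if inputs.loci else {}

    genes: List[WrkyGene] = [
        scan_gene(
            gene_id,
            seq,
            locus=loci.get(gene_id),
            max_mismatch=inputs.max_mismatch,
            linker_window=inputs.linker_window,
        )
        for gene_id, seq in sorted(proteome.items())
    ]
    wrky = [g for g in genes if g.domains]

    if inputs.refs:
        refs = ReferenceDomainSet.from_fasta(inputs.refs)
        assign_subgroups(wrky, refs, support_threshold=inputs.support_threshold)

    summary = SurveySummary(
        total_proteins=len(genes),
        total_wrky_genes=len(wrky),
        total_domains=sum(len(g.domains) for g in wrky),
        two_domain_genes=sum(1 for g in wrky if len(g.domains) == 2),
        max_domains_per_gene=max((len(g.domains) for g in wrky), default=0),
        unclassified_genes=sum(1 for g in genes if g.group == UNCLASSIFIED),
        group_counts={
            grp: sum(1 for g in wrky if g.group == grp)
            for grp in sorted({g.group for g in wrky})
        },
        subgroup_counts={
            sub: sum(1 for g in wrky if g.subgroup == sub)
            for sub in sorted({g.subgroup for g in wrky if g.subgroup})
        },
    )
    variant_summary = enumerate_variants(wrky)
    summary.variant_summary = variant_summary
    summary.variant_domain_count = sum(v["count"] for v in variant_summary.values())

    if outdir_path is not None:
        _write_domain_tables(wrky, genes, outdir_path)
        if len(wrky) >= 3:
            dm = distance_matrix({g.gene_id: g.domains[0].sequence for g in wrky})
            (outdir_path / "tree.nwk").write_text(nj_tree(dm).newick + "\n")

    # duplication needs sequences + loci
    if loci:
        wrky_seqs = {g.gene_id: g.sequence for g in wrky if g.gene_id in loci}
        wrky_loci = {g: loci[g] for g in wrky_seqs}
        duplicates = dup.find_duplicates(
            wrky_seqs, threshold=inputs.duplicate_threshold, loci=wrky_loci
        )
        tandem = dup.find_tandem(
            duplicates, wrky_loci, max_distance_bp=inputs.tandem_max_distance_bp
        )
        subs = {subgenome_of(l.chromosome) for l in wrky_loci.values()}
        orthologs = (
            dup.find_orthologs(wrky_seqs, wrky_loci, threshold=inputs.duplicate_threshold)
            if {"A", "C"} <= subs
            else []
        )
        blocks = dup.find_segmental(
            duplicates,
            wrky_loci,
            min_block_pairs=inputs.min_block_pairs,
            max_gap_bp=inputs.segmental_max_gap_bp,
            tandem_pairs=tandem,
        )
        tandem_genes = sorted({g for p in tandem for g in p.key})
        per_sub_counts = {
            s: sum(1 for l in wrky_loci.values() if subgenome_of(l.chromosome) == s)
            for s in sorted(subs)
        }
        tandem_per_sub = {
            s: sum(
                1
                for g in tandem_genes
                if subgenome_of(wrky_loci[g].chromosome) == s
            )
            for s in sorted(subs)
        }
        summary.duplication = {
            "duplicate_pairs": len(duplicates),
            "tandem_pairs": len(tandem),
            "tandem_gene_count": len(tandem_genes),
            "tandem_gene_percent": (
                fmt_percent(len(tandem_genes), len(wrky)) if wrky else None
            ),
            "genes_per_subgenome": per_sub_counts,
            "tandem_genes_per_subgenome": tandem_per_sub,
            "tandem_percent_per_subgenome": {
                s: fmt_percent(tandem_per_sub[s], per_sub_counts[s])
                for s in per_sub_counts
                if per_sub_counts[s]
            },
            "ortholog_pairs": len(orthologs),
            "segmental_blocks": len(blocks),
            "segmental_block_sizes": [b.size for b in blocks],
        }
        if outdir_path is not None:
            _write_pair_tables(duplicates, tandem, orthologs, blocks, outdir_path)
    else:
        tandem = []

    if inputs.chrom_lengths and loci:
        chrom_lengths = json.loads(Path(inputs.chrom_lengths).read_text())
        wrky_loci_all = {g.gene_id: loci[g.gene_id] for g in wrky if g.gene_id in loci}
        summaries, unanchored = chromosome_distribution(wrky_loci_all, chrom_lengths)
        summary.distribution = [
            {
                "chromosome": s.chromosome,
                "genes": s.gene_count,
                "length_bp": s.length_bp,
                "density_per_mb": s.density_per_mb,
            }
            for s in summaries
        ]
        summary.unanchored = unanchored
        densities = [s.density_per_mb for s in summaries if s.gene_count > 0]
        if densities:
            summary.density_min = min(densities)
            summary.density_max = max(densities)
        summary.mean_spacing_mb = mean_gene_spacing_mb(summaries)

    if inputs.qtl and loci:
        qtls = parse_qtl_table(inputs.qtl)
        wrky_loci_all = {g.gene_id: loci[g.gene_id] for g in wrky if g.gene_id in loci}
        overlap = qtl_overlap(
            wrky_loci_all,
            qtls,
            tandem_pairs=[p.key for p in tandem],
            contained=inputs.qtl_contained,
        )
        summary.qtl = {
            "n_qtls": len(qtls),
            "genes_in_qtl": len(overlap.genes_in_any_qtl),
            "genes_per_qtl": overlap.genes_per_qtl,
            "multi_stress_genes": overlap.multi_stress_genes,
            "tandem_pairs_in_qtl": overlap.tandem_pairs_in_qtl,
        }
        if outdir_path is not None:
            pd.DataFrame(
                [
                    {"qtl": name, "genes": ";".join(gene_list)}
                    for name, gene_list in overlap.genes_per_qtl.items()
                ]
            ).to_csv(outdir_path / "qtl_genes.csv", index=False)

    if inputs.evidence:
        ev = summarize_evidence(read_evidence_csv(inputs.evidence))
        summary.expression = {
            "microarray_genes": ev.microarray_gene_count,
            "est_genes": ev.est_gene_count,
            "est_records": ev.est_record_count,
            "est_libraries": ev.est_library_count,
            "per_kind_sum": ev.per_kind_sum,
            "union_genes": ev.union_count,
        }

    if inputs.cq:
        profiles = profiles_from_cq(read_cq_csv(inputs.cq))
        responses = classify_response(profiles)
        summary.qpcr = {
            "genes": sorted({p.gene for p in profiles}),
            "responsive_genes": sorted(
                g for g, r in responses.items() if r["responsive_conditions"]
            ),
            "highly_responsive_genes": sorted(
                g for g, r in responses.items() if r["highly_responsive_conditions"]
            ),
            "multi_stress_genes": sorted(
                g for g, r in responses.items() if r["multi_stress"]
            ),
        }
        if outdir_path is not None:
            pd.DataFrame(
                [
                    {
                        "gene": p.gene,
                        "condition": p.condition,
                        "timepoint_h": t,
                        "fold": f,
                        "sd": s,
                        "class": c,
                    }
                    for p in profiles
                    for t, f, s, c in zip(p.timepoints_h, p.folds, p.sds, p.classes)
                ]
            ).to_csv(outdir_path / "fold_changes.csv", index=False)

    summary.validate()
    if outdir_path is not None:
        (outdir_path / "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        (outdir_path / "summary.txt").write_text(summary.to_text())
    return summary


def _write_domain_tables(
    wrky: Sequence[WrkyGene], genes: Sequence[WrkyGene], outdir: Path
) -> None:
    pd.DataFrame(
        [
            {
                "gene": g.gene_id,
                "domain_index": i + 1,
                "heptapeptide": d.heptapeptide.sequence,
                "mismatches": d.heptapeptide.mismatches,
                "finger_type": d.finger.finger_type,
                "span_start": d.span[0],
                "span_end": d.span[1],
                "sequence": d.sequence,
            }
            for g in wrky
            for i, d in enumerate(g.domains)
        ]
    ).to_csv(outdir / "domains.csv", index=False)
    pd.DataFrame(
        [
            {
                "gene": g.gene_id,
                "group": g.group,
                "subgroup": g.subgroup or "",
                "n_domains": len(g.domains),
            }
            for g in genes
        ]
    ).to_csv(outdir / "classification.csv", index=False)


def _write_pair_tables(duplicates, tandem, orthologs, blocks, outdir: Path) -> None:
    def pairs_df(pairs):
        return pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "identity": p.identity,
                    "kind": p.kind,
                    "chromosome_a": p.chromosome_a,
                    "chromosome_b": p.chromosome_b,
                    "distance_bp": p.distance_bp,
                    "intervening_wrky": p.intervening_wrky,
                }
                for p in pairs
            ]
        )

    pairs_df(list(duplicates) + list(tandem) + list(orthologs)).to_csv(
        outdir / "pairs.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "chromosome_a": b.chromosome_pair[0],
                "chromosome_b": b.chromosome_pair[1],
                "n_pairs": b.size,
                "pairs": ";".join(f"{p.gene_a}|{p.gene_b}" for p in b.pairs),
            }
            for b in blocks
        ]
    ).to_csv(outdir / "blocks.csv", index=False)
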