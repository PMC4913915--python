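"""Chromosome distribution statistics and stress-QTL interval overlap.

QTL intervals are physical spans (1-based inclusive) tagged with a stress
label; a gene resides in a QTL when their spans share at least one base on
the same chromosome (a strict mode requires full containment).  Strand is
ignored — QTL intervals are strandless.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .loci import Locus


@dataclass(frozen=True)
class QtlInterval:
    name: str
    chromosome: str
    start: int
    end: int
    stress: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("QTL chromosome must be non-empty")
        if self.start > self.end or self.start < 1:
            raise ValueError(f"QTL {self.name}: invalid span {self.start}-{self.end}")


@dataclass
class ChromosomeSummary:
    chromosome: str
    gene_count: int
    length_bp: int
    density_per_mb: float


@dataclass
class QtlOverlapResult:
    genes_per_qtl: Dict[str, List[str]]  # QTL name -> sorted gene ids
    qtls_per_gene: Dict[str, List[str]]  # gene id -> QTL names
    multi_stress_genes: List[str]  # genes in >=2 QTLs with different stresses
    tandem_pairs_in_qtl: List[Tuple[str, str, str]]  # (gene_a, gene_b, qtl name)

    @property
    def genes_in_any_qtl(self) -> List[str]:
        return sorted(self.qtls_per_gene)


def qtl_keys(qtls: Sequence[QtlInterval]) -> List[str]:
    """Stable per-interval keys: the QTL name, suffixed when names repeat
    across rows (the same name can label intervals on different maps)."""
    seen: Dict[str, int] = {}
    keys = []
    for q in qtls:
        seen[q.name] = seen.get(q.name, 0) + 1
        keys.append(q.name if seen[q.name] == 1 else f"{q.name}#{seen[q.name]}")
    return keys


# span strings may use hyphen, en-dash, em-dash or tilde as separators
_SPAN_RE = re.compile(r"^\s*(\d+)\s*[-–—~]\s*(\d+)\s*$")


def parse_span(text: str) -> Tuple[int, int]:
    m = _SPAN_RE.match(str(text))
    if not m:
        raise ValueError(f"malformed span {text!r}")
    return int(m.group(1)), int(m.group(2))


def parse_qtl_table(path: str | Path) -> List[QtlInterval]:
    """Read a QTL table CSV: chromosome, qtl_name, position ("start-end"),
    stress, source.  Overlapping or duplicated intervals are kept as-is."""
    df = pd.read_csv(path, dtype=str)
    if df.empty and len(df.columns) == 0:
        return []
    required = {"chromosome", "qtl_name", "position", "stress"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    intervals: List[QtlInterval] = []
    for idx, row in df.iterrows():
        try:
            start, end = parse_span(row["position"])
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from exc
        intervals.append(
            QtlInterval(
                name=str(row["qtl_name"]),
                chromosome=str(row["chromosome"]),
                start=start,
                end=end,
                stress=str(row["stress"]),
                source=str(row.get("source", "")) if "source" in df.columns else "",
            )
        )
    return intervals


def write_qtl_table(intervals: Sequence[QtlInterval], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chromosome": [q.chromosome for q in intervals],
            "qtl_name": [q.name for q in intervals],
            "position": [f"{q.start}-{q.end}" for q in intervals],
            "stress": [q.stress for q in intervals],
            "source": [q.source for q in intervals],
        }
    ).to_csv(path, index=False)


def chromosome_distribution(
    loci: Dict[str, Locus], chrom_lengths: Dict[str, int]
) -> Tuple[List[ChromosomeSummary], int]:
    """Per-chromosome gene counts and densities, plus the unanchored count.

    Genes on chromosomes absent from ``chrom_lengths`` (scaffolds) count as
    unanchored.  Density is genes per Mb: count / (length / 1e6).
    """
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom}: non-positive length")
    counts: Dict[str, int] = {c: 0 for c in chrom_lengths}
    unanchored = 0
    for loc in loci.values():
        if loc.chromosome in counts:
            counts[loc.chromosome] += 1
        else:
            unanchored += 1
    summaries = [
        ChromosomeSummary(
            chromosome=chrom,
            gene_count=counts[chrom],
            length_bp=chrom_lengths[chrom],
            density_per_mb=counts[chrom] / (chrom_lengths[chrom] / 1e6),
        )
        for chrom in sorted(chrom_lengths)
    ]
    return summaries, unanchored


def mean_gene_spacing_mb(summaries: Sequence[ChromosomeSummary]) -> Optional[float]:
    """Mb of anchored chromosome per anchored gene (None when no genes)."""
    total_genes = sum(s.gene_count for s in summaries)
    if total_genes == 0:
        return None
    return sum(s.length_bp for s in summaries) / 1e6 / total_genes


def qtl_overlap(
    loci: Dict[str, Locus],
    qtls: Sequence[QtlInterval],
    tandem_pairs: Sequence[Tuple[str, str]] = (),
    contained: bool = False,
) -> QtlOverlapResult:
    """Intersect gene loci with QTL intervals.

    Overlap means >=1 shared base (inclusive coordinates on both sides);
    with ``contained=True`` the gene must lie fully inside the interval.
    Also reports genes hit by QTLs of two or more distinct stress labels,
    and tandem pairs whose two members fall inside one QTL.
    """
    keys = qtl_keys(qtls)
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, q in enumerate(qtls):
        # half-open tree coordinates; payload keeps the interval itself
        trees[q.chromosome].addi(q.start, q.end + 1, (i, q))

    genes_per_qtl: Dict[str, set] = {key: set() for key in keys}
    qtls_per_gene: Dict[str, List[Tuple[int, QtlInterval]]] = defaultdict(list)
    for gene_id in sorted(loci):
        loc = loci[gene_id]
        for hit in trees[loc.chromosome].overlap(loc.start, loc.end + 1):
            i, q = hit.data
            if contained and not (loc.start >= q.start and loc.end <= q.end):
                continue
            genes_per_qtl[keys[i]].add(gene_id)
            qtls_per_gene[gene_id].append((i, q))

    multi_stress = sorted(
        gene
        for gene, hits in qtls_per_gene.items()
        if len({q.stress for _, q in hits}) >= 2
    )
    tandem_in_qtl: List[Tuple[str, str, str]] = []
    for a, b in tandem_pairs:
        if a not in loci or b not in loci:
            continue
        for i, q in enumerate(qtls):
            la, lb = loci[a], loci[b]
            if (
                la.chromosome == q.chromosome
                and lb.chromosome == q.chromosome
                and min(la.start, lb.start) >= q.start
                and max(la.end, lb.end) <= q.end
            ):
                tandem_in_qtl.append((a, b, keys[i]))
    return QtlOverlapResult(
        genes_per_qtl={name: sorted(genes) for name, genes in genes_per_qtl.items()},
        qtls_per_gene={
            gene: [keys[i] for i, _ in sorted(hits, key=lambda h: h[0])]
            for gene, hits in qtls_per_gene.items()
        },
        multi_stress_genes=multi_stress,
        tandem_pairs_in_qtl=tandem_in_qtl,
    )
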