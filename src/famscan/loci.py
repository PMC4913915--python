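"""Gene locus records and flat coordinate I/O.

Coordinates are 1-based inclusive throughout the package (GFF3 convention);
BED conversion (0-based half-open) happens only at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable


@dataclass(frozen=True)
class Locus:
    """Genomic span of one gene, 1-based inclusive."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid locus span {self.start}-{self.end} on {self.chromosome}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def write_gff3(loci: Dict[str, Locus], path: str | Path, source: str = "famscan") -> None:
    lines = ["##gff-version 3"]
    for gene_id, loc in sorted(loci.items(), key=lambda kv: (kv[1].chromosome, kv[1].start)):
        lines.append(
            "\t".join(
                [
                    loc.chromosome,
                    source,
                    "gene",
                    str(loc.start),
                    str(loc.end),
                    ".",
                    loc.strand,
                    ".",
                    f"ID={gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> Dict[str, Locus]:
    """Read gene loci from a flat GFF3 file (gene features with ID attributes)."""
    loci: Dict[str, Locus] = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}: line {n}: expected 9 GFF3 columns, got {len(fields)}")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields
        if ftype != "gene":
            continue
        gene_id = None
        for item in attrs.split(";"):
            if item.startswith("ID="):
                gene_id = item[3:]
        if gene_id is None:
            raise ValueError(f"{path}: line {n}: gene feature without ID attribute")
        loci[gene_id] = Locus(chrom, int(start), int(end), strand if strand in "+-." else ".")
    return loci


def write_bed(loci: Dict[str, Locus], path: str | Path) -> None:
    """Write loci as BED (0-based half-open, converted at this boundary)."""
    lines = []
    for gene_id, loc in sorted(loci.items(), key=lambda kv: (kv[1].chromosome, kv[1].start)):
        lines.append(
            f"{loc.chromosome}\t{loc.start - 1}\t{loc.end}\t{gene_id}\t0\t{loc.strand}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> Dict[str, Locus]:
    loci: Dict[str, Locus] = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}: line {n}: BED needs at least 4 columns")
        chrom, start, end, name = fields[:4]
        strand = fields[5] if len(fields) >= 6 else "."
        loci[name] = Locus(chrom, int(start) + 1, int(end), strand)
    return loci


def subgenome_of(chromosome: str, mapping: Dict[str, str] | None = None) -> str:
    """Sub-genome label for a chromosome name.

    Default rule: the leading letter (A/C for *Brassica napus*). A mapping
    dict overrides for other naming schemes.
    """
    if mapping is not None and chromosome in mapping:
        return mapping[chromosome]
    if not chromosome or not chromosome[0].isalpha():
        raise ValueError(f"cannot derive sub-genome from chromosome name {chromosome!r}")
    return chromosome[0].upper()


def loci_sorted(loci: Dict[str, Locus]) -> Iterable[tuple[str, Locus]]:
    return sorted(loci.items(), key=lambda kv: (kv[1].chromosome, kv[1].start, kv[0]))
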