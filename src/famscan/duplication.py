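"""Gene-duplication analysis: duplicates, tandem arrays, orthologs, blocks.

Two family members are duplicates when their global-alignment identity
exceeds a threshold (85% by default, computed on protein sequences).  On
top of the duplicate pairs:

* tandem pairs sit on one chromosome with no other family member between
  them and a bounded genomic gap;
* A/C sub-genome orthologs are reciprocal best hits across sub-genomes;
* segmental blocks are maximal chains of collinear duplicate pairs between
  a chromosome pair, built by a greedy sorted-anchor sweep (block sizes in
  a gene-family survey are tiny, so chaining DP buys nothing).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .align import global_align
from .loci import Locus, subgenome_of

KIND_DUPLICATE = "duplicate"
KIND_TANDEM = "tandem"
KIND_ORTHOLOG = "ortholog"
KIND_SEGMENTAL = "segmental-member"


@dataclass(frozen=True)
class DuplicationPair:
    gene_a: str
    gene_b: str
    identity: float
    kind: str = KIND_DUPLICATE
    chromosome_a: Optional[str] = None
    chromosome_b: Optional[str] = None
    distance_bp: Optional[int] = None
    intervening_wrky: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("pair members must be ordered gene_a < gene_b")

    @property
    def key(self) -> Tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class SegmentalBlock:
    block_id: int
    pairs: List[DuplicationPair]
    chromosome_pair: Tuple[str, str]
    span_a: Tuple[int, int]
    span_b: Tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.pairs)


def ordered_pair(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a < b else (b, a)


def find_duplicates(
    sequences: Dict[str, str],
    threshold: float = 85.0,
    loci: Optional[Dict[str, Locus]] = None,
    **align_kwargs,
) -> List[DuplicationPair]:
    """All unordered pairs with alignment identity strictly above threshold."""
    ids = sorted(sequences)
    if len(ids) < 2:
        return []
    pairs: List[DuplicationPair] = []
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            identity = global_align(sequences[ga], sequences[gb], **align_kwargs).identity
            if identity > threshold:
                pairs.append(
                    DuplicationPair(
                        gene_a=ga,
                        gene_b=gb,
                        identity=identity,
                        chromosome_a=loci[ga].chromosome if loci and ga in loci else None,
                        chromosome_b=loci[gb].chromosome if loci and gb in loci else None,
                    )
                )
    return pairs


def find_tandem(
    pairs: Sequence[DuplicationPair],
    loci: Dict[str, Locus],
    max_distance_bp: int = 100_000,
    max_intervening_wrky: int = 0,
) -> List[DuplicationPair]:
    """Duplicate pairs that form tandem arrays.

    A pair is tandem iff both genes share a chromosome, at most
    ``max_intervening_wrky`` other family members lie between them (zero by
    default: true neighbors), and the inter-gene gap is at most
    ``max_distance_bp``.
    """
    by_chrom: Dict[str, List[Tuple[int, str]]] = defaultdict(list)
    for gene_id, loc in loci.items():
        by_chrom[loc.chromosome].append((loc.start, gene_id))
    for starts in by_chrom.values():
        starts.sort()

    tandem: List[DuplicationPair] = []
    for pair in pairs:
        for gene in pair.key:
            if gene not in loci:
                raise KeyError(f"no locus for gene {gene}")
        la, lb = loci[pair.gene_a], loci[pair.gene_b]
        if la.chromosome != lb.chromosome:
            continue
        left, right = (la, lb) if la.start <= lb.start else (lb, la)
        gap = max(0, right.start - left.end - 1)
        if gap > max_distance_bp:
            continue
        intervening = sum(
            1
            for start, gid in by_chrom[la.chromosome]
            if left.end < start < right.start and gid not in pair.key
        )
        if intervening > max_intervening_wrky:
            continue
        tandem.append(
            replace(
                pair,
                kind=KIND_TANDEM,
                chromosome_a=la.chromosome,
                chromosome_b=lb.chromosome,
                distance_bp=gap,
                intervening_wrky=intervening,
            )
        )
    return tandem


def find_orthologs(
    sequences: Dict[str, str],
    loci: Dict[str, Locus],
    threshold: float = 85.0,
    subgenomes: Tuple[str, str] = ("A", "C"),
    subgenome_map: Optional[Dict[str, str]] = None,
    **align_kwargs,
) -> List[DuplicationPair]:
    """Reciprocal-best-hit ortholog pairs across two sub-genomes.

    The sub-genome of each gene comes from its chromosome name (leading
    letter, or an explicit mapping).  Hits below the identity threshold are
    ignored; best-hit ties resolve by gene-id order, so the result is
    deterministic.
    """
    genes_by_sub: Dict[str, List[str]] = {s: [] for s in subgenomes}
    for gene_id in sorted(sequences):
        if gene_id not in loci:
            raise KeyError(f"no locus for gene {gene_id}")
        sub = subgenome_of(loci[gene_id].chromosome, subgenome_map)
        if sub in genes_by_sub:
            genes_by_sub[sub].append(gene_id)
    sub_a, sub_b = subgenomes
    a_genes, b_genes = genes_by_sub[sub_a], genes_by_sub[sub_b]
    if not a_genes or not b_genes:
        return []

    identity: Dict[Tuple[str, str], float] = {}
    for ga in a_genes:
        for gb in b_genes:
            identity[(ga, gb)] = global_align(
                sequences[ga], sequences[gb], **align_kwargs
            ).identity

    def best_hit(gene: str, candidates: List[str], lookup) -> Optional[str]:
        best: Optional[Tuple[float, str]] = None
        for cand in candidates:
            ident = lookup(gene, cand)
            if ident <= threshold:
                continue
            if best is None or ident > best[0]:
                best = (ident, cand)
        return best[1] if best else None

    pairs: List[DuplicationPair] = []
    for ga in a_genes:
        gb = best_hit(ga, b_genes, lambda x, y: identity[(x, y)])
        if gb is None:
            continue
        back = best_hit(gb, a_genes, lambda x, y: identity[(y, x)])
        if back != ga:
            continue
        first, second = ordered_pair(ga, gb)
        pairs.append(
            DuplicationPair(
                gene_a=first,
                gene_b=second,
                identity=identity[(ga, gb)],
                kind=KIND_ORTHOLOG,
                chromosome_a=loci[first].chromosome,
                chromosome_b=loci[second].chromosome,
            )
        )
    return pairs


def find_segmental(
    pairs: Sequence[DuplicationPair],
    loci: Dict[str, Locus],
    min_block_pairs: int = 3,
    max_gap_bp: int = 2_000_000,
    tandem_pairs: Sequence[DuplicationPair] = (),
) -> List[SegmentalBlock]:
    """Chain collinear duplicate pairs into segmental blocks.

    Pairs are bucketed by chromosome pair and sorted by position on the
    first chromosome; a greedy sweep extends a chain while the inter-anchor
    gap on both chromosomes stays within ``max_gap_bp`` and the second-
    chromosome positions stay strictly monotonic (increasing, or decreasing
    for inverted blocks — the direction is set by the first extension).
    Chains shorter than ``min_block_pairs`` are discarded; tandem pairs
    never participate.
    """
    tandem_keys = {p.key for p in tandem_pairs}
    anchors: Dict[Tuple[str, str], List[Tuple[int, int, DuplicationPair]]] = defaultdict(list)
    for pair in pairs:
        if pair.key in tandem_keys:
            continue
        la = loci.get(pair.gene_a)
        lb = loci.get(pair.gene_b)
        if la is None or lb is None:
            continue
        chrom_pair = tuple(sorted((la.chromosome, lb.chromosome)))
        if (la.chromosome, lb.chromosome) != chrom_pair:
            la, lb = lb, la
        anchors[chrom_pair].append((la.start, lb.start, pair))

    blocks: List[SegmentalBlock] = []
    block_id = 0
    for chrom_pair in sorted(anchors):
        chain: List[Tuple[int, int, DuplicationPair]] = []
        direction = 0  # 0 unset, +1 increasing, -1 decreasing on second chrom

        def flush() -> None:
            nonlocal block_id, chain, direction
            if len(chain) >= min_block_pairs:
                block_id += 1
                xs = [c[0] for c in chain]
                ys = [c[1] for c in chain]
                blocks.append(
                    SegmentalBlock(
                        block_id=block_id,
                        pairs=[replace(c[2], kind=KIND_SEGMENTAL) for c in chain],
                        chromosome_pair=chrom_pair,
                        span_a=(min(xs), max(xs)),
                        span_b=(min(ys), max(ys)),
                    )
                )
            chain = []
            direction = 0

        for anchor in sorted(anchors[chrom_pair]):
            if not chain:
                chain.append(anchor)
                continue
            px, py, _ = chain[-1]
            x, y, _ = anchor
            step = 0 if y == py else (1 if y > py else -1)
            ok = (
                x - px <= max_gap_bp
                and abs(y - py) <= max_gap_bp
                and step != 0
                and (direction == 0 or step == direction)
            )
            if ok:
                if direction == 0:
                    direction = step
                chain.append(anchor)
            else:
                flush()
                chain.append(anchor)
        flush()
    return blocks
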