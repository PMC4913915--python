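"""WRKY domain calling by motif grammar.

A WRKY domain is the ~60-residue DNA-binding region consisting of the
WRKYGQK heptapeptide (or an accepted variant) followed, after a short
linker, by a zinc finger of either the C2H2 type (C-X4-5-C-X22-23-H-X1-H)
or the C2-HC type (C-X7-C-X23-H-X1-C).

The scanner here is a deterministic grammar matcher: a heptapeptide hit
requires the W/Y/G anchor residues at positions 1/4/5 and at most
``max_mismatch`` substitutions overall relative to WRKYGQK; a finger hit is
the literal spacing grammar above.  Genes are classified by domain count
and finger type: two or more domains -> group I, one C2H2 domain ->
group II, one C2-HC domain -> group III, none -> unclassified.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .loci import Locus

CANONICAL_HEPTAPEPTIDE = "WRKYGQK"

#: Anchor offsets within the heptapeptide that must match exactly (W, Y, G).
HEPTAPEPTIDE_ANCHORS = ((0, "W"), (3, "Y"), (4, "G"))

#: Variant heptapeptides known from surveyed Brassica napus domains.
KNOWN_VARIANTS = (
    "WRKYGKK",
    "WRKYGRK",
    "WKKYGQK",
    "WKKYGQR",
    "WKNYGQK",
    "WMKYGQK",
    "WRKYGHK",
)

# Zinc-finger spacing grammar: (anchor residues, allowed spacer lengths
# between consecutive anchors).  Spacer alternatives are tried in listed
# order; the first matching start position wins, C2H2 before C2HC on ties.
C2H2_SPACINGS = tuple((x1, x2, 1) for x1 in (4, 5) for x2 in (22, 23))
C2HC_SPACINGS = ((7, 23, 1),)

GROUP_I = "I"
GROUP_II = "II"
GROUP_III = "III"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class HeptapeptideHit:
    position: int  # 1-based index of the W residue
    sequence: str
    mismatches: int

    @property
    def is_variant(self) -> bool:
        return self.mismatches > 0

    @property
    def end(self) -> int:
        return self.position + 6


@dataclass(frozen=True)
class ZincFingerHit:
    finger_type: str  # "C2H2" or "C2HC"
    span: Tuple[int, int]  # 1-based inclusive
    anchor_positions: Tuple[int, int, int, int]


@dataclass(frozen=True)
class WrkyDomain:
    heptapeptide: HeptapeptideHit
    finger: ZincFingerHit
    span: Tuple[int, int]
    sequence: str  # residues from heptapeptide start to finger end


@dataclass
class WrkyGene:
    gene_id: str
    protein_id: str
    sequence: str
    locus: Optional[Locus] = None
    domains: List[WrkyDomain] = field(default_factory=list)
    group: str = UNCLASSIFIED
    subgroup: Optional[str] = None


def scan_heptapeptides(protein: str, max_mismatch: int = 2) -> List[HeptapeptideHit]:
    """All 7-mers with intact W/Y/G anchors and <= max_mismatch substitutions.

    ``X`` is tolerated in the input but never matches any heptapeptide
    residue.  Overlapping hits are all reported, left to right.
    """
    protein = protein.upper()
    hits: List[HeptapeptideHit] = []
    for i in range(len(protein) - 6):
        window = protein[i : i + 7]
        if any(window[off] != res for off, res in HEPTAPEPTIDE_ANCHORS):
            continue
        mismatches = sum(
            1 for a, b in zip(window, CANONICAL_HEPTAPEPTIDE) if a != b or a == "X"
        )
        if mismatches <= max_mismatch:
            hits.append(HeptapeptideHit(position=i + 1, sequence=window, mismatches=mismatches))
    return hits


def _match_finger_at(protein: str, i: int) -> Optional[ZincFingerHit]:
    """Try both finger grammars at 0-based position i; C2H2 wins ties."""
    for finger_type, anchors, spacings in (
        ("C2H2", "CCHH", C2H2_SPACINGS),
        ("C2HC", "CCHC", C2HC_SPACINGS),
    ):
        for x1, x2, x3 in spacings:
            positions = (i, i + 1 + x1, i + 2 + x1 + x2, i + 3 + x1 + x2 + x3)
            if positions[-1] >= len(protein):
                continue
            if all(protein[p] == a for p, a in zip(positions, anchors)):
                return ZincFingerHit(
                    finger_type=finger_type,
                    span=(i + 1, positions[-1] + 1),
                    anchor_positions=tuple(p + 1 for p in positions),
                )
    return None


def scan_zinc_finger(
    protein: str, search_start: int = 1, search_limit: Optional[int] = None
) -> Optional[ZincFingerHit]:
    """First zinc-finger grammar match starting at or after ``search_start``.

    ``search_start`` is a 1-based residue index; ``search_limit`` (1-based,
    inclusive) bounds the latest allowed start position, which is how the
    caller enforces the linker window.
    """
    protein = protein.upper()
    if search_start < 1:
        raise ValueError("search_start must be >= 1")
    last = len(protein) if search_limit is None else min(search_limit, len(protein))
    for i in range(search_start - 1, last):
        hit = _match_finger_at(protein, i)
        if hit is not None:
            return hit
    return None


def call_domains(
    protein: str,
    max_mismatch: int = 2,
    linker_window: int = 50,
    max_span: int = 80,
) -> List[WrkyDomain]:
    """Pair heptapeptide hits with downstream zinc fingers, greedily left to right.

    Each heptapeptide is paired with the nearest finger starting within
    ``linker_window`` residues after its end; a finger already consumed by
    an earlier heptapeptide is not reused.  Domains longer than ``max_span``
    residues (heptapeptide start to finger end) are rejected.
    """
    protein = protein.upper()
    domains: List[WrkyDomain] = []
    next_free = 1  # first residue not yet claimed by a previous finger
    for hepta in scan_heptapeptides(protein, max_mismatch=max_mismatch):
        search_from = max(hepta.end + 1, next_free)
        finger = scan_zinc_finger(
            protein, search_start=search_from, search_limit=hepta.end + linker_window
        )
        if finger is None:
            continue
        span = (hepta.position, finger.span[1])
        if span[1] - span[0] + 1 > max_span:
            continue
        domains.append(
            WrkyDomain(
                heptapeptide=hepta,
                finger=finger,
                span=span,
                sequence=protein[span[0] - 1 : span[1]],
            )
        )
        next_free = finger.span[1] + 1
    return domains


def classify_gene(domains: Sequence[WrkyDomain]) -> str:
    """Group label from domain count and finger type.

    >=2 domains -> I; one C2H2 domain -> II; one C2-HC domain -> III;
    no domains -> unclassified.  Genes with more than two domains are kept
    in group I (the conservative generalization of the two-domain rule).
    """
    if len(domains) >= 2:
        return GROUP_I
    if len(domains) == 1:
        return GROUP_II if domains[0].finger.finger_type == "C2H2" else GROUP_III
    return UNCLASSIFIED


def scan_gene(
    gene_id: str,
    protein: str,
    locus: Optional[Locus] = None,
    protein_id: Optional[str] = None,
    **call_kwargs,
) -> WrkyGene:
    domains = call_domains(protein, **call_kwargs)
    return WrkyGene(
        gene_id=gene_id,
        protein_id=protein_id or gene_id,
        sequence=protein.upper(),
        locus=locus,
        domains=domains,
        group=classify_gene(domains),
    )


def enumerate_variants(genes: Sequence[WrkyGene]) -> Dict[str, Dict]:
    """Tabulate variant heptapeptides over domains (not genes).

    Returns ``{heptapeptide: {"count": n, "groups": {group: n}}}`` for every
    non-canonical heptapeptide observed in a called domain.
    """
    summary: Dict[str, Dict] = {}
    for gene in genes:
        for domain in gene.domains:
            if not domain.heptapeptide.is_variant:
                continue
            entry = summary.setdefault(
                domain.heptapeptide.sequence, {"count": 0, "groups": defaultdict(int)}
            )
            entry["count"] += 1
            entry["groups"][gene.group] += 1
    for entry in summary.values():
        entry["groups"] = dict(entry["groups"])
    return summary
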