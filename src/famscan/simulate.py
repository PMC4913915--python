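"""Seeded synthetic two-sub-genome proteome with planted ground truth.

The generator emulates the substrate of an allopolyploid gene-family
survey: WRKY genes of every group built from fixed per-group domain
templates, an ortholog complement on the C sub-genome produced by copying
A-sub-genome genes at a configured divergence, tandem clusters, collinear
segmental blocks, decoy proteins carrying at most one grammar element, QTL
intervals, expression-evidence records, and qPCR Cq tables whose noiseless
2^-ddCt recovery equals the planted fold change.

Every grammar-critical residue (heptapeptide, zinc-finger anchors) is
protected from mutation unless a variant is planted explicitly, so the
domain scanner's ground truth is exact by construction.  All randomness
flows from numpy Generators seeded from the config seed; identical
seed + config gives byte-identical output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .config import GROUP_LABELS, SimulationConfig
from .domains import CANONICAL_HEPTAPEPTIDE, KNOWN_VARIANTS
from .genome_qtl import QtlInterval
from .loci import Locus, write_bed, write_gff3

#: residues safe for spacers and flanks: no W (heptapeptide anchor) and no
#: C/H (zinc-finger anchors), so filler can never complete a grammar element.
SAFE_ALPHABET = "ADEFGIKLMNPQRSTVY"

_VARIANT_WEIGHTS = np.array([0.6] + [0.4 / 6] * 6)  # Q->K substitution dominates


class InfeasiblePackingError(ValueError):
    """Total gene footprint exceeds a chromosome's length."""


def _template_rng(label: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(f"famscan-template-{label}".encode()))


def _safe_string(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(SAFE_ALPHABET), size=length))


def finger_template(finger_type: str, rng: np.random.Generator) -> Tuple[str, List[int]]:
    """Zinc-finger sequence (minimal grammar spacings) and its 0-based
    anchor offsets."""
    if finger_type == "C2H2":
        x1, x2, x3, last = 4, 22, 1, "H"
    elif finger_type == "C2HC":
        x1, x2, x3, last = 7, 23, 1, "C"
    else:
        raise ValueError(finger_type)
    seq = "C" + _safe_string(rng, x1) + "C" + _safe_string(rng, x2) + "H" + _safe_string(rng, x3) + last
    anchors = [0, 1 + x1, 2 + x1 + x2, 3 + x1 + x2 + x3]
    return seq, anchors


def domain_template(label: str) -> Tuple[str, List[int]]:
    """Canonical domain sequence for a group/subgroup label and the 0-based
    offsets of its grammar-critical residues (heptapeptide + anchors).

    Spacers are label-specific (drawn from a label-keyed fixed stream), so
    templates of different subgroups are mutually distant while every
    instance of one label starts identical.
    """
    if label not in GROUP_LABELS:
        raise ValueError(f"unknown group label {label!r}")
    rng = _template_rng(label)
    finger_type = "C2HC" if label == "III" else "C2H2"
    linker = _safe_string(rng, 10)
    finger, finger_anchors = finger_template(finger_type, rng)
    seq = CANONICAL_HEPTAPEPTIDE + linker + finger
    protected = list(range(7)) + [7 + len(linker) + a for a in finger_anchors]
    return seq, protected


@dataclass
class _GenePlan:
    role: str  # primary | ortholog | tandem | segmental | decoy
    group: Optional[str]  # group/subgroup label, None for decoys
    chromosome: str
    residues: List[str]
    protected: List[int]  # absolute 0-based positions that mutations skip
    domain_hepta_offsets: List[int]  # absolute 0-based offset of each domain's W
    decoy_kind: Optional[str] = None
    cluster: Optional[int] = None
    block: Optional[int] = None
    source: Optional["_GenePlan"] = None
    gene_id: str = ""
    locus: Optional[Locus] = None

    @property
    def protein(self) -> str:
        return "".join(self.residues)

    @property
    def is_wrky(self) -> bool:
        return self.role != "decoy"

    @property
    def heptapeptides(self) -> List[str]:
        return ["".join(self.residues[o : o + 7]) for o in self.domain_hepta_offsets]


@dataclass
class GroundTruthManifest:
    """Planted truth for one generated bundle."""

    genes: Dict[str, Dict] = field(default_factory=dict)
    tandem_pairs: List[Tuple[str, str, float]] = field(default_factory=list)
    ortholog_pairs: List[Tuple[str, str, float]] = field(default_factory=list)
    segmental_blocks: List[Dict] = field(default_factory=list)
    qpcr_spec: Dict = field(default_factory=dict)

    @property
    def wrky_gene_ids(self) -> List[str]:
        return sorted(g for g, info in self.genes.items() if info["role"] != "decoy")

    @property
    def planted_domain_count(self) -> int:
        return sum(
            len(info["heptapeptides"])
            for info in self.genes.values()
            if info["role"] != "decoy"
        )

    @property
    def variant_domain_count(self) -> int:
        return sum(
            1
            for info in self.genes.values()
            if info["role"] != "decoy"
            for h in info["heptapeptides"]
            if h != CANONICAL_HEPTAPEPTIDE
        )

    @property
    def group_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for info in self.genes.values():
            if info["role"] == "decoy":
                continue
            counts[info["group"]] = counts.get(info["group"], 0) + 1
        return counts

    def chromosome_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for info in self.genes.values():
            if info["role"] == "decoy":
                continue
            chrom = info["locus"]["chromosome"]
            counts[chrom] = counts.get(chrom, 0) + 1
        return counts

    def to_dict(self) -> Dict:
        return {
            "genes": self.genes,
            "tandem_pairs": [list(p) for p in self.tandem_pairs],
            "ortholog_pairs": [list(p) for p in self.ortholog_pairs],
            "segmental_blocks": self.segmental_blocks,
            "qpcr_spec": {
                gene: {
                    cond: {str(tp): fc for tp, fc in series.items()}
                    for cond, series in conditions.items()
                }
                for gene, conditions in self.qpcr_spec.items()
            },
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )


def _group_base_label(label: str) -> str:
    return "II" if label.startswith("II") and label != "III" else label


def _is_subgroup(label: Optional[str]) -> bool:
    return label is not None and label.startswith("II") and label != "III"


def _build_wrky_plan(label: str, chromosome: str, rng: np.random.Generator, role: str) -> _GenePlan:
    dom, dom_protected = domain_template(label)
    if label == "I":
        parts = [
            _safe_string(rng, 20), dom, _safe_string(rng, 20), dom, _safe_string(rng, 40),
        ]
        offsets = [20, 20 + len(dom) + 20]
    else:
        parts = [_safe_string(rng, 20), dom, _safe_string(rng, 50)]
        offsets = [20]
    residues = list("".join(parts))
    protected = [o + p for o in offsets for p in dom_protected]
    return _GenePlan(
        role=role,
        group=label,
        chromosome=chromosome,
        residues=residues,
        protected=protected,
        domain_hepta_offsets=offsets,
    )


def _copy_plan(source: _GenePlan, chromosome: str, role: str) -> _GenePlan:
    return _GenePlan(
        role=role,
        group=source.group,
        chromosome=chromosome,
        residues=list(source.residues),
        protected=list(source.protected),
        domain_hepta_offsets=list(source.domain_hepta_offsets),
        cluster=source.cluster,
        block=source.block,
        source=source,
    )


def _mutate(plan: _GenePlan, n_substitutions: int, rng: np.random.Generator) -> None:
    mutable = sorted(set(range(len(plan.residues))) - set(plan.protected))
    if n_substitutions > len(mutable):
        raise ValueError("requested more substitutions than mutable positions")
    positions = rng.choice(len(mutable), size=n_substitutions, replace=False)
    for idx in sorted(positions):
        pos = mutable[idx]
        current = plan.residues[pos]
        choices = [c for c in SAFE_ALPHABET if c != current]
        plan.residues[pos] = choices[int(rng.integers(len(choices)))]


def _hamming_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("hamming identity needs equal lengths")
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / len(a)


def _build_decoy(kind: str, chromosome: str, rng: np.random.Generator) -> _GenePlan:
    if kind == "heptapeptide_only":
        seq = _safe_string(rng, 20) + CANONICAL_HEPTAPEPTIDE + _safe_string(rng, 40)
    elif kind == "finger_only":
        finger, _ = finger_template("C2H2", rng)
        seq = _safe_string(rng, 20) + finger + _safe_string(rng, 40)
    elif kind == "random":
        seq = _safe_string(rng, 80)
    else:
        raise ValueError(kind)
    return _GenePlan(
        role="decoy",
        group=None,
        chromosome=chromosome,
        residues=list(seq),
        protected=[],
        domain_hepta_offsets=[],
        decoy_kind=kind,
    )


def generate_proteome(
    config: SimulationConfig,
) -> Tuple[List[Tuple[str, str]], Dict[str, Locus], GroundTruthManifest]:
    """Build the synthetic proteome, gene loci and ground-truth manifest.

    Returns ``(records, loci, manifest)`` where records are
    ``(gene_id, protein_sequence)`` in genomic order.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_chromosomes_per_subgenome
    a_chroms = [f"A{i:02d}" for i in range(1, n + 1)]
    c_chroms = [f"C{i:02d}" for i in range(1, n + 1)]

    plans: List[_GenePlan] = []
    # primary A-sub-genome genes, round-robin over A chromosomes
    primary: List[_GenePlan] = []
    idx = 0
    for label in GROUP_LABELS:
        for _ in range(config.group_counts.get(label, 0)):
            chrom = a_chroms[idx % len(a_chroms)]
            primary.append(_build_wrky_plan(label, chrom, rng, role="primary"))
            idx += 1
    plans.extend(primary)

    # C-sub-genome ortholog complement
    n_orth = round(config.ortholog_fraction * len(primary))
    orth_sources = (
        sorted(rng.choice(len(primary), size=n_orth, replace=False)) if n_orth else []
    )
    ortholog_pairs_plans: List[Tuple[_GenePlan, _GenePlan]] = []
    for src_idx in orth_sources:
        src = primary[src_idx]
        copy = _copy_plan(src, "C" + src.chromosome[1:], role="ortholog")
        n_sub = round(config.ortholog_divergence * len(copy.residues))
        _mutate(copy, n_sub, rng)
        plans.append(copy)
        ortholog_pairs_plans.append((src, copy))

    # tandem clusters (group III, like the tandem-prone branch of the family)
    cluster_pairs_plans: List[Tuple[_GenePlan, _GenePlan]] = []
    for cluster_id, (size, identity_target) in enumerate(config.tandem_cluster_spec):
        chrom = a_chroms[cluster_id % len(a_chroms)]
        head = _build_wrky_plan("III", chrom, rng, role="tandem")
        head.cluster = cluster_id
        members = [head]
        for _ in range(size - 1):
            copy = _copy_plan(members[-1], chrom, role="tandem")
            n_sub = round((1.0 - identity_target / 100.0) * len(copy.residues))
            _mutate(copy, n_sub, rng)
            members.append(copy)
        plans.extend(members)
        cluster_pairs_plans.extend(zip(members, members[1:]))

    # collinear segmental blocks
    block_labels = ("IIb", "IIc", "IId", "I", "IIe")
    block_pairs_plans: List[Tuple[int, Tuple[str, str], List[Tuple[_GenePlan, _GenePlan]]]] = []
    for block_id, (n_genes, (chrom_a, chrom_b)) in enumerate(config.segmental_block_spec):
        for chrom in (chrom_a, chrom_b):
            if chrom not in a_chroms + c_chroms:
                raise ValueError(f"segmental block chromosome {chrom} not in genome")
        members: List[Tuple[_GenePlan, _GenePlan]] = []
        for k in range(n_genes):
            src = _build_wrky_plan(block_labels[k % len(block_labels)], chrom_a, rng, role="segmental")
            src.block = block_id
            copy = _copy_plan(src, chrom_b, role="segmental")
            n_sub = round(config.segmental_divergence * len(copy.residues))
            _mutate(copy, n_sub, rng)
            plans.extend([src, copy])
            members.append((src, copy))
        block_pairs_plans.append((block_id, (chrom_a, chrom_b), members))

    # decoys, spread over all chromosomes
    decoy_idx = 0
    all_chroms = a_chroms + c_chroms
    for kind in ("heptapeptide_only", "finger_only", "random"):
        for _ in range(config.decoy_counts.get(kind, 0)):
            chrom = all_chroms[decoy_idx % len(all_chroms)]
            plans.append(_build_decoy(kind, chrom, rng))
            decoy_idx += 1

    # plant variant heptapeptides over all WRKY domains
    wrky_domains = [
        (plan, off) for plan in plans if plan.is_wrky for off in plan.domain_hepta_offsets
    ]
    n_variants = round(config.variant_fraction * len(wrky_domains))
    if n_variants:
        chosen = rng.choice(len(wrky_domains), size=n_variants, replace=False)
        for i in sorted(chosen):
            plan, off = wrky_domains[i]
            variant = KNOWN_VARIANTS[
                int(rng.choice(len(KNOWN_VARIANTS), p=_VARIANT_WEIGHTS))
            ]
            plan.residues[off : off + 7] = list(variant)

    # optional spacer noise on every gene independently (grammar residues stay fixed)
    if config.spacer_mutation_rate > 0:
        for plan in plans:
            if not plan.is_wrky:
                continue
            mutable = sorted(set(range(len(plan.residues))) - set(plan.protected))
            for pos in mutable:
                if rng.random() < config.spacer_mutation_rate:
                    current = plan.residues[pos]
                    choices = [c for c in SAFE_ALPHABET if c != current]
                    plan.residues[pos] = choices[int(rng.integers(len(choices)))]

    # place genes chromosome by chromosome, preserving build order so that
    # cluster and block members stay consecutive
    by_chrom: Dict[str, List[_GenePlan]] = {c: [] for c in all_chroms}
    for plan in plans:
        if plan.chromosome not in by_chrom:
            raise ValueError(f"unknown chromosome {plan.chromosome}")
        by_chrom[plan.chromosome].append(plan)

    lo, hi = config.intergenic_spacing
    t_lo, t_hi = config.tandem_spacing
    s_lo, s_hi = config.segmental_spacing
    for chrom in all_chroms:
        prev_end = 0
        prev_plan: Optional[_GenePlan] = None
        for plan in by_chrom[chrom]:
            if prev_plan is None:
                gap = int(rng.integers(300_000, 800_000))
            elif plan.cluster is not None and plan.cluster == prev_plan.cluster:
                gap = int(rng.integers(t_lo, t_hi))
            elif plan.block is not None and plan.block == prev_plan.block:
                gap = int(rng.integers(s_lo, s_hi))
            else:
                gap = int(rng.integers(lo, hi))
            start = prev_end + gap + 1
            end = start + 3 * len(plan.residues) - 1
            if end > config.chromosome_length:
                raise InfeasiblePackingError(
                    f"gene footprint exceeds chromosome {chrom} "
                    f"(needed {end} bp of {config.chromosome_length})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            plan.locus = Locus(chrom, start, end, strand)
            prev_end = end
            prev_plan = plan

    # assign identifiers in genomic order
    ordered = sorted(plans, key=lambda p: (p.locus.chromosome, p.locus.start))
    for i, plan in enumerate(ordered, start=1):
        plan.gene_id = f"SynG{i:04d}"

    manifest = GroundTruthManifest(qpcr_spec=config.qpcr_spec)
    for plan in ordered:
        manifest.genes[plan.gene_id] = {
            "role": plan.role,
            "decoy_kind": plan.decoy_kind,
            "group": (_group_base_label(plan.group) if plan.group else None),
            "subgroup": (plan.group if _is_subgroup(plan.group) else None),
            "heptapeptides": plan.heptapeptides,
            "finger_types": (
                ["C2HC" if plan.group == "III" else "C2H2"] * len(plan.domain_hepta_offsets)
            ),
            "locus": {
                "chromosome": plan.locus.chromosome,
                "start": plan.locus.start,
                "end": plan.locus.end,
                "strand": plan.locus.strand,
            },
        }
    for a, b in cluster_pairs_plans:
        x, y = sorted((a.gene_id, b.gene_id))
        manifest.tandem_pairs.append((x, y, _hamming_identity(a.protein, b.protein)))
    for a, b in ortholog_pairs_plans:
        x, y = sorted((a.gene_id, b.gene_id))
        manifest.ortholog_pairs.append((x, y, _hamming_identity(a.protein, b.protein)))
    for block_id, chroms, members in block_pairs_plans:
        pairs = []
        for a, b in members:
            x, y = sorted((a.gene_id, b.gene_id))
            pairs.append([x, y, _hamming_identity(a.protein, b.protein)])
            # cross-sub-genome block pairs are also reciprocal best hits
            if chroms[0][0] != chroms[1][0]:
                manifest.ortholog_pairs.append((x, y, _hamming_identity(a.protein, b.protein)))
        manifest.segmental_blocks.append(
            {"block_id": block_id, "chromosomes": list(chroms), "pairs": pairs}
        )
    manifest.tandem_pairs.sort()
    manifest.ortholog_pairs.sort()

    records = [(plan.gene_id, plan.protein) for plan in ordered]
    loci = {plan.gene_id: plan.locus for plan in ordered}
    return records, loci, manifest


def generate_qtl_table(config: SimulationConfig) -> List[QtlInterval]:
    """QTL intervals from the config spec (1-based inclusive, unmerged)."""
    valid = set(config.chromosomes)
    intervals = []
    for i, (chrom, (start, end), stress) in enumerate(config.qtl_spec, start=1):
        if chrom not in valid:
            raise ValueError(f"QTL spec {i}: unknown chromosome {chrom}")
        if not (1 <= start <= end <= config.chromosome_length):
            raise ValueError(
                f"QTL spec {i}: span {start}-{end} outside chromosome bounds"
            )
        intervals.append(
            QtlInterval(
                name=f"QTL{i:02d}", chromosome=chrom, start=start, end=end,
                stress=stress, source="synthetic",
            )
        )
    return intervals


def generate_cq_table(config: SimulationConfig) -> pd.DataFrame:
    """Tidy Cq table realizing the planted log2 fold changes.

    Reference Cq sits at 20, control target Cq at 25; the treated target Cq
    is shifted down by the planted log2 fold change so that noiseless
    2^-ddCt recovery is exact.  Gaussian noise (config SD, Cq units) is
    added independently per technical replicate.
    """
    rng = np.random.default_rng([config.seed, 2])
    rows = []
    base_ref, base_target = 20.0, 25.0
    for gene in sorted(config.qpcr_spec):
        for condition in sorted(config.qpcr_spec[gene]):
            series = config.qpcr_spec[gene][condition]
            timepoints = [0.0] + sorted(series)
            for tp in timepoints:
                log2fc = 0.0 if tp == 0.0 else series[tp]
                for bio in range(1, config.n_biological_replicates + 1):
                    for tech in range(1, config.n_technical_replicates + 1):
                        noise_t = rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd else 0.0
                        noise_r = rng.normal(0.0, config.qpcr_noise_sd) if config.qpcr_noise_sd else 0.0
                        rows.append(
                            {
                                "gene": gene,
                                "condition": condition,
                                "timepoint_h": tp,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "target_cq": base_target - log2fc + noise_t,
                                "reference_cq": base_ref + noise_r,
                            }
                        )
    return pd.DataFrame(rows)


def generate_evidence_table(config: SimulationConfig) -> pd.DataFrame:
    """In-silico expression evidence derived from the planted qPCR truth.

    Genes with any planted up-response get a microarray record; genes with
    a cold or drought response additionally get EST-library records."""
    rows = []
    for gene in sorted(config.qpcr_spec):
        conditions = config.qpcr_spec[gene]
        peak = {cond: max(series.values(), default=0.0) for cond, series in conditions.items()}
        if max(peak.values(), default=0.0) >= 1.0:
            rows.append(
                {
                    "record_id": f"MA_{gene}",
                    "genes": gene,
                    "source_id": "GSM900001-GSM900030",
                    "condition": "Sclerotinia sclerotiorum",
                }
            )
        for cond, library in (("cold", "dbEST 90001"), ("drought", "dbEST 90002")):
            if peak.get(cond, 0.0) >= 1.0:
                rows.append(
                    {
                        "record_id": f"EST_{gene}_{cond}",
                        "genes": gene,
                        "source_id": library,
                        "condition": f"{cond} stress",
                    }
                )
    return pd.DataFrame(rows, columns=["record_id", "genes", "source_id", "condition"])


def write_bundle(config: SimulationConfig, outdir: str | Path) -> GroundTruthManifest:
    """Generate and write the full synthetic bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, loci, manifest = generate_proteome(config)

    fasta_lines = []
    for gene_id, protein in records:
        fasta_lines.append(f">{gene_id}")
        for i in range(0, len(protein), 60):
            fasta_lines.append(protein[i : i + 60])
    (outdir / "proteome.fasta").write_text("\n".join(fasta_lines) + "\n")

    write_gff3(loci, outdir / "loci.gff3")
    write_bed(loci, outdir / "loci.bed")

    from .genome_qtl import write_qtl_table

    write_qtl_table(generate_qtl_table(config), outdir / "qtl.csv")
    generate_cq_table(config).to_csv(outdir / "cq.csv", index=False)
    generate_evidence_table(config).to_csv(outdir / "evidence.csv", index=False)
    manifest.save_json(outdir / "manifest.json")
    manifest.save_yaml(outdir / "manifest.yaml")
    chrom_lengths = {c: config.chromosome_length for c in config.chromosomes}
    (outdir / "chromosomes.json").write_text(
        json.dumps(chrom_lengths, indent=2, sort_keys=True) + "\n"
    )
    return manifest
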