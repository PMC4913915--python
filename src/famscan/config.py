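"""Simulation configuration for the synthetic genome generator."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import yaml

GROUP_LABELS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")

#: gene -> condition -> timepoint (h) -> planted log2 fold change
QpcrSpec = Dict[str, Dict[str, Dict[float, float]]]

DEFAULT_CONDITIONS = ("cold", "salinity", "drought")
DEFAULT_TIMEPOINTS = (3.0, 6.0, 9.0, 12.0, 24.0)


def default_qpcr_spec() -> QpcrSpec:
    """Planted qPCR truth: six genes, three of them highly up-regulated
    (peak fold >= 20) under all three stresses, one up under cold only,
    one down under salinity, one flat."""
    high = {3.0: 1.5, 6.0: 3.0, 9.0: 4.6, 12.0: 3.5, 24.0: 2.0}
    up = {3.0: 1.0, 6.0: 2.0, 9.0: 2.5, 12.0: 1.5, 24.0: 0.5}
    down = {3.0: -1.2, 6.0: -2.0, 9.0: -1.5, 12.0: -1.0, 24.0: -0.5}
    flat = {t: 0.0 for t in DEFAULT_TIMEPOINTS}
    spec: QpcrSpec = {}
    for gene in ("qG01", "qG02", "qG03"):
        spec[gene] = {cond: dict(high) for cond in DEFAULT_CONDITIONS}
    spec["qG04"] = {"cold": dict(up), "salinity": dict(flat), "drought": dict(flat)}
    spec["qG05"] = {"cold": dict(flat), "salinity": dict(down), "drought": dict(flat)}
    spec["qG06"] = {cond: dict(flat) for cond in DEFAULT_CONDITIONS}
    return spec


def default_qtl_spec() -> List[Tuple[str, Tuple[int, int], str]]:
    return [
        ("A01", (1, 15_000_000), "Sclerotinia sclerotiorum"),
        ("A01", (8_000_000, 22_000_000), "cold"),
        ("A02", (5_000_000, 20_000_000), "salinity"),
        ("C01", (1, 12_000_000), "drought"),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-sub-genome family survey.

    Defaults are desk-scale: 3 chromosomes of 40 Mb per sub-genome, 25
    primary family genes with realistic ~2.7 Mb mean intergenic spacing,
    an 80% ortholog complement at 5% divergence, two tandem clusters and
    one within-sub-genome segmental block.
    """

    seed: int = 0
    n_chromosomes_per_subgenome: int = 3
    chromosome_length: int = 40_000_000
    group_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "I": 6, "IIa": 2, "IIb": 3, "IIc": 4, "IId": 3, "IIe": 3, "III": 4,
        }
    )
    variant_fraction: float = 0.15
    tandem_cluster_spec: List[Tuple[int, float]] = field(
        default_factory=lambda: [(2, 95.0), (2, 92.0)]
    )
    ortholog_fraction: float = 0.8
    ortholog_divergence: float = 0.05
    segmental_block_spec: List[Tuple[int, Tuple[str, str]]] = field(
        default_factory=lambda: [(3, ("A02", "A03"))]
    )
    segmental_divergence: float = 0.04
    decoy_counts: Dict[str, int] = field(
        default_factory=lambda: {"heptapeptide_only": 2, "finger_only": 2, "random": 2}
    )
    qtl_spec: List[Tuple[str, Tuple[int, int], str]] = field(default_factory=default_qtl_spec)
    qpcr_spec: QpcrSpec = field(default_factory=default_qpcr_spec)
    qpcr_noise_sd: float = 0.15
    n_biological_replicates: int = 3
    n_technical_replicates: int = 3
    spacer_mutation_rate: float = 0.0
    # placement knobs (bp): regular spacing sits above the default segmental
    # chaining gap so only planted blocks chain; tandem spacing sits well
    # below the tandem distance rule.
    intergenic_spacing: Tuple[int, int] = (2_200_000, 3_200_000)
    tandem_spacing: Tuple[int, int] = (5_000, 30_000)
    segmental_spacing: Tuple[int, int] = (200_000, 600_000)

    def __post_init__(self) -> None:
        if self.n_chromosomes_per_subgenome < 1:
            raise ValueError("need at least one chromosome per sub-genome")
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        for label, count in self.group_counts.items():
            if label not in GROUP_LABELS:
                raise ValueError(f"unknown group label {label!r}")
            if count < 0:
                raise ValueError(f"negative count for group {label}")
        for frac_name in ("variant_fraction", "ortholog_fraction"):
            frac = getattr(self, frac_name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1]")
        for rate_name in ("ortholog_divergence", "segmental_divergence", "spacer_mutation_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1]")
        for size, ident in self.tandem_cluster_spec:
            if size < 2:
                raise ValueError("tandem clusters need >= 2 members")
            if not 0.0 < ident <= 100.0:
                raise ValueError("tandem identity target must be in (0, 100]")
        for n_genes, chroms in self.segmental_block_spec:
            if n_genes < 1:
                raise ValueError("segmental blocks need >= 1 gene")
            if len(chroms) != 2 or chroms[0] == chroms[1]:
                raise ValueError("segmental block needs two distinct chromosomes")
        for kind, count in self.decoy_counts.items():
            if kind not in ("heptapeptide_only", "finger_only", "random"):
                raise ValueError(f"unknown decoy kind {kind!r}")
            if count < 0:
                raise ValueError(f"negative decoy count for {kind}")
        if self.qpcr_noise_sd < 0:
            raise ValueError("qPCR noise SD must be non-negative")
        if self.n_biological_replicates < 1 or self.n_technical_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        for gene, conditions in self.qpcr_spec.items():
            for cond, series in conditions.items():
                for tp, log2fc in series.items():
                    if not math.isfinite(log2fc):
                        raise ValueError(
                            f"qpcr_spec[{gene}][{cond}][{tp}]: log2 fold must be finite"
                        )

    @property
    def chromosomes(self) -> List[str]:
        n = self.n_chromosomes_per_subgenome
        return [f"A{i:02d}" for i in range(1, n + 1)] + [
            f"C{i:02d}" for i in range(1, n + 1)
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "tandem_cluster_spec" in raw:
            raw["tandem_cluster_spec"] = [tuple(item) for item in raw["tandem_cluster_spec"]]
        if "segmental_block_spec" in raw:
            raw["segmental_block_spec"] = [
                (int(n), tuple(chroms)) for n, chroms in raw["segmental_block_spec"]
            ]
        if "qtl_spec" in raw:
            raw["qtl_spec"] = [
                (chrom, (int(span[0]), int(span[1])), stress)
                for chrom, span, stress in raw["qtl_spec"]
            ]
        if "qpcr_spec" in raw:
            raw["qpcr_spec"] = {
                gene: {
                    cond: {float(tp): float(fc) for tp, fc in series.items()}
                    for cond, series in conditions.items()
                }
                for gene, conditions in raw["qpcr_spec"].items()
            }
        for tup_field in ("intergenic_spacing", "tandem_spacing", "segmental_spacing"):
            if tup_field in raw:
                raw[tup_field] = tuple(raw[tup_field])
        return cls(**raw)
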