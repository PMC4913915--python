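"""Subgroup assignment by domain distance, and neighbor-joining trees.

Group II WRKY genes split into subgroups IIa-IIe by phylogenetic clade.
Here the assignment is nearest-reference: each gene's domain is compared
against a labeled reference domain set by pairwise global alignment, and
the gene takes the subgroup of the closest reference (p-distance
= 1 - identity/100).  Genes whose nearest reference is farther than a
support threshold stay unclassified, mirroring family members that drop
out of a phylogeny for lack of support.

Neighbor joining is delegated to scikit-bio; negative branch-length
estimates (a known NJ artifact) are clamped to zero and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import skbio
from skbio.tree import TreeNode, nj

from .align import global_align
from .domains import GROUP_II, WrkyGene

SUBGROUP_LABELS = ("IIa", "IIb", "IIc", "IId", "IIe")


@dataclass
class ReferenceDomainSet:
    """Labeled reference WRKY domain sequences (one or more per subgroup)."""

    entries: List[Tuple[str, str, str]]  # (reference_id, label, sequence)

    def __post_init__(self) -> None:
        for ref_id, label, seq in self.entries:
            if not seq or seq != seq.upper():
                raise ValueError(f"reference {ref_id}: sequence must be non-empty uppercase")
        missing = [s for s in SUBGROUP_LABELS if s not in {e[1] for e in self.entries}]
        if missing:
            raise ValueError(f"reference set missing subgroup(s): {', '.join(missing)}")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDomainSet":
        """Read references from FASTA with ``>id|label`` headers."""
        from Bio import SeqIO

        entries = []
        for record in SeqIO.parse(str(path), "fasta"):
            if "|" not in record.id:
                raise ValueError(f"reference header {record.id!r} lacks '|label' suffix")
            ref_id, label = record.id.rsplit("|", 1)
            entries.append((ref_id, label, str(record.seq).upper()))
        return cls(entries)

    def labels(self) -> List[str]:
        return sorted({e[1] for e in self.entries})


@dataclass
class DistanceMatrix:
    labels: List[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match label count")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.data < 0) or np.any(self.data > 1):
            raise ValueError("p-distances must lie in [0, 1]")

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.data[i, j])


@dataclass
class PhyloTree:
    tree: TreeNode
    n_negative_clamped: int = 0

    @property
    def newick(self) -> str:
        return str(self.tree).strip()

    def leaf_names(self) -> List[str]:
        return sorted(t.name for t in self.tree.tips())

    def path_length(self, a: str, b: str) -> float:
        return float(self.tree.find(a).distance(self.tree.find(b)))

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(tree=TreeNode.read([newick]))


def distance_matrix(sequences: Dict[str, str] | Sequence[Tuple[str, str]], **align_kwargs) -> DistanceMatrix:
    """All-pairs p-distance matrix from global-alignment identities."""
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    labels = [k for k, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("sequence labels must be unique")
    n = len(items)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = global_align(items[i][1], items[j][1], **align_kwargs).p_distance
            data[i, j] = data[j, i] = d
    return DistanceMatrix(labels, data)


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if len(matrix.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = skbio.DistanceMatrix(matrix.data, ids=matrix.labels)
    tree = nj(dm, neg_as_zero=False)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    return PhyloTree(tree=tree, n_negative_clamped=clamped)


def assign_subgroups(
    genes: Sequence[WrkyGene],
    refs: ReferenceDomainSet,
    support_threshold: float = 0.7,
    **align_kwargs,
) -> List[WrkyGene]:
    """Label each group-II gene with the subgroup of its nearest reference.

    A gene whose minimum p-distance to every reference exceeds
    ``support_threshold`` is left unclassified (subgroup None).  Genes in
    groups I and III are never given a II subgroup.  Ties between equally
    close references resolve by reference id order.
    """
    ordered_refs = sorted(e for e in refs.entries if e[1] in SUBGROUP_LABELS)
    for gene in genes:
        if gene.group != GROUP_II or not gene.domains:
            gene.subgroup = None
            continue
        query = gene.domains[0].sequence
        best: Optional[Tuple[float, str, str]] = None
        for ref_id, label, seq in ordered_refs:
            d = global_align(query, seq, **align_kwargs).p_distance
            if best is None or d < best[0]:
                best = (d, ref_id, label)
        assert best is not None
        gene.subgroup = best[2] if best[0] <= support_threshold else None
    return list(genes)
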