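"""Global alignment, distance matrices, NJ trees and subgroup assignment."""

import random

import numpy as np
import pytest
from Bio import Align

from famscan.align import global_align
from famscan.phylo import (
    DistanceMatrix,
    PhyloTree,
    ReferenceDomainSet,
    assign_subgroups,
    distance_matrix,
    nj_tree,
)
from famscan.domains import scan_gene
from famscan.simulate import domain_template

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestGlobalAlign:
    def test_identical_sequences_full_identity(self):
        assert global_align("WRKYGQK", "WRKYGQK").identity == 100.0

    def test_single_substitution(self):
        aln = global_align("WRKYGQK", "WRKYGKK")
        assert aln.identity == pytest.approx(100 * 6 / 7)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            global_align("", "WRKY")

    def test_score_matches_biopython_oracle(self):
        """Optimal scores agree with an independent aligner on seeded pairs."""
        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=1,
            mismatch_score=-1,
            open_gap_score=-2,
            extend_gap_score=-2,
        )
        rng = random.Random(42)
        for _ in range(100):
            a = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 30)))
            b = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 30)))
            assert global_align(a, b).score == aligner.score(a, b)

    def test_reported_alignment_realizes_reported_score(self):
        rng = random.Random(7)
        for _ in range(50):
            a = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 30)))
            b = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 30)))
            aln = global_align(a, b)
            score = sum(
                -2 if "-" in (x, y) else (1 if x == y else -1)
                for x, y in zip(aln.aligned_a, aln.aligned_b)
            )
            assert score == aln.score
            assert 0.0 <= aln.identity <= 100.0

    def test_score_symmetric_in_arguments(self):
        rng = random.Random(3)
        for _ in range(30):
            a = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 25)))
            b = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 25)))
            assert global_align(a, b).score == global_align(b, a).score


class TestDistanceMatrix:
    def test_identical_pair_distance_zero(self):
        dm = distance_matrix({"a": "WRKYGQK", "b": "WRKYGQK"})
        assert dm[("a", "b")] == 0.0

    def test_one_substitution_distance(self):
        dm = distance_matrix({"a": "WRKYGQK", "b": "WRKYGKK"})
        assert dm[("a", "b")] == pytest.approx(1 / 7)

    def test_entries_match_pairwise_alignments(self):
        seqs = {"x": "WRKYGQKAAA", "y": "WRKYGKKAAC", "z": "MRRYGQKAAA"}
        dm = distance_matrix(seqs)
        for a in seqs:
            for b in seqs:
                if a < b:
                    assert dm[(a, b)] == pytest.approx(
                        global_align(seqs[a], seqs[b]).p_distance
                    )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.2, 0.0]]))


class TestNeighborJoining:
    def test_three_leaf_branch_lengths(self):
        """Three-point formulas: v_a = (d_ab + d_ac - d_bc) / 2."""
        dm = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        )
        tree = nj_tree(dm)
        newick = tree.newick
        assert "a:0.1" in newick.replace("0.10000000000000003", "0.1")
        assert tree.path_length("a", "b") == pytest.approx(0.2)
        assert tree.path_length("a", "c") == pytest.approx(0.4)
        assert tree.path_length("b", "c") == pytest.approx(0.4)

    def test_additive_metric_recovered_as_path_lengths(self):
        # distances realized by tree ((a:0.1,b:0.2):0.1,(c:0.3,d:0.4))
        labels = ["a", "b", "c", "d"]
        d = {
            ("a", "b"): 0.3,
            ("a", "c"): 0.5,
            ("a", "d"): 0.6,
            ("b", "c"): 0.6,
            ("b", "d"): 0.7,
            ("c", "d"): 0.7,
        }
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            mat[i, j] = mat[j, i] = v
        tree = nj_tree(DistanceMatrix(labels, mat))
        for (x, y), v in d.items():
            assert tree.path_length(x, y) == pytest.approx(v, abs=1e-9)

    def test_uniform_metric_total_length(self):
        # all pairwise distances equal u: any binary topology on 4 leaves has
        # total length 4*(u/2) + internal 0 = 2u
        u = 0.6
        mat = np.full((4, 4), u)
        np.fill_diagonal(mat, 0.0)
        tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], mat))
        total = sum(n.length or 0.0 for n in tree.tree.traverse() if n.length)
        assert total == pytest.approx(2 * u)

    def test_leaf_set_preserved_and_newick_roundtrip(self):
        rng = np.random.default_rng(0)
        n = 6
        pts = rng.random((n, 3))
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                mat[i, j] = min(1.0, np.abs(pts[i] - pts[j]).sum())
        labels = [f"t{i}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(labels, mat))
        assert tree.leaf_names() == sorted(labels)
        reparsed = PhyloTree.from_newick(tree.newick)
        assert reparsed.leaf_names() == sorted(labels)
        for a in labels[:3]:
            for b in labels[3:]:
                assert reparsed.path_length(a, b) == pytest.approx(
                    tree.path_length(a, b), abs=1e-9
                )

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]])))


def _gene_from_label(gid, label):
    seq, _ = domain_template(label)
    return scan_gene(gid, "M" * 5 + seq + "L" * 5)


@pytest.fixture(scope="module")
def refs():
    return ReferenceDomainSet(
        [(f"ref_{lbl}", lbl, domain_template(lbl)[0]) for lbl in
         ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")]
    )


class TestSubgroupAssignment:

    def test_identical_domain_takes_reference_subgroup(self, refs):
        gene = _gene_from_label("g1", "IIc")
        assign_subgroups([gene], refs)
        assert gene.subgroup == "IIc"

    def test_distant_gene_left_unclassified(self, refs):
        gene = _gene_from_label("g1", "IIc")
        assign_subgroups([gene], refs, support_threshold=0.0 + 1e-12)
        assert gene.subgroup == "IIc"  # distance 0 passes any threshold
        far = ReferenceDomainSet(
            [(f"r{lbl}", lbl, "WRKYGQK" + "A" * 40) for lbl in
             ("IIa", "IIb", "IIc", "IId", "IIe")]
        )
        gene2 = _gene_from_label("g2", "IIc")
        assign_subgroups([gene2], far, support_threshold=0.1)
        assert gene2.subgroup is None

    def test_group_one_and_three_never_subgrouped(self, refs):
        g1 = _gene_from_label("a", "I")
        g1.domains = g1.domains * 2  # force group I via two domains
        g1.group = "I"
        g3 = _gene_from_label("b", "III")
        assign_subgroups([g1, g3], refs)
        assert g1.subgroup is None
        assert g3.subgroup is None

    def test_missing_subgroup_in_refs_rejected(self):
        with pytest.raises(ValueError, match="IIe"):
            ReferenceDomainSet(
                [(f"r{lbl}", lbl, "WRKY") for lbl in ("IIa", "IIb", "IIc", "IId")]
            )

    def test_planted_subgroups_recovered_at_ten_percent_divergence(self, refs):
        from famscan import SimulationConfig, generate_proteome

        cfg = SimulationConfig(
            seed=11,
            spacer_mutation_rate=0.10,
            tandem_cluster_spec=[],
            segmental_block_spec=[],
            decoy_counts={"heptapeptide_only": 0, "finger_only": 0, "random": 0},
        )
        records, _, manifest = generate_proteome(cfg)
        genes = [scan_gene(gid, seq) for gid, seq in records]
        assign_subgroups(genes, refs)
        checked = 0
        for gene in genes:
            planted = manifest.genes[gene.gene_id]["subgroup"]
            if planted is not None:
                assert gene.subgroup == planted, gene.gene_id
                checked += 1
        assert checked > 0
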