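"""Duplicate, tandem, ortholog and segmental detection."""

import random

import pytest

from famscan import SimulationConfig, generate_proteome
from famscan.align import global_align
from famscan.domains import scan_gene
from famscan.duplication import (
    find_duplicates,
    find_orthologs,
    find_segmental,
    find_tandem,
)
from famscan.loci import Locus

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_duplicates(seqs, threshold=85.0):
    ids = sorted(seqs)
    out = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if global_align(seqs[a], seqs[b]).identity > threshold:
                out.add((a, b))
    return out


class TestFindDuplicates:
    def test_identical_pair(self):
        pairs = find_duplicates({"g1": "MKKLV" * 10, "g2": "MKKLV" * 10})
        assert len(pairs) == 1
        assert pairs[0].identity == 100.0
        assert pairs[0].key == ("g1", "g2")

    def test_distant_pair_excluded(self):
        a = "MKKLVPQRST" * 5
        b = "".join(random.Random(1).choice(AA20) for _ in range(50))
        assert find_duplicates({"g1": a, "g2": b}) == []

    def test_matches_all_pairs_oracle(self):
        rng = random.Random(5)
        base = "".join(rng.choice(AA20) for _ in range(60))
        seqs = {}
        for i in range(20):
            s = list(base)
            for _ in range(rng.randint(0, 20)):
                s[rng.randrange(len(s))] = rng.choice(AA20)
            seqs[f"g{i:02d}"] = "".join(s)
        got = {p.key for p in find_duplicates(seqs)}
        assert got == brute_force_duplicates(seqs)

    def test_threshold_monotonicity(self):
        rng = random.Random(6)
        base = "".join(rng.choice(AA20) for _ in range(60))
        seqs = {}
        for i in range(10):
            s = list(base)
            for _ in range(rng.randint(0, 15)):
                s[rng.randrange(len(s))] = rng.choice(AA20)
            seqs[f"g{i}"] = "".join(s)
        lo = {p.key for p in find_duplicates(seqs, threshold=80)}
        hi = {p.key for p in find_duplicates(seqs, threshold=90)}
        assert hi <= lo


class TestFindTandem:
    SEQ = "MKKLV" * 12

    def _pairs(self):
        return find_duplicates({"g1": self.SEQ, "g2": self.SEQ})

    def test_adjacent_duplicates_are_tandem(self):
        loci = {
            "g1": Locus("A01", 1000, 1180),
            "g2": Locus("A01", 6000, 6180),
        }
        tandem = find_tandem(self._pairs(), loci)
        assert len(tandem) == 1
        assert tandem[0].kind == "tandem"
        assert tandem[0].distance_bp == 6000 - 1180 - 1

    def test_different_chromosomes_not_tandem(self):
        loci = {"g1": Locus("A01", 1000, 1180), "g2": Locus("C01", 1000, 1180)}
        assert find_tandem(self._pairs(), loci) == []

    def test_intervening_family_member_blocks_tandem(self):
        loci = {
            "g1": Locus("A01", 1000, 1180),
            "g2": Locus("A01", 9000, 9180),
            "g3": Locus("A01", 5000, 5180),  # another family member between
        }
        assert find_tandem(self._pairs(), loci) == []

    def test_gap_above_limit_not_tandem(self):
        loci = {"g1": Locus("A01", 1000, 1180), "g2": Locus("A01", 500_000, 500_180)}
        assert find_tandem(self._pairs(), loci, max_distance_bp=100_000) == []

    def test_missing_locus_raises_with_gene_name(self):
        with pytest.raises(KeyError, match="g2"):
            find_tandem(self._pairs(), {"g1": Locus("A01", 1, 180)})

    def test_planted_tandem_set_recovered(self, synthetic):
        records, loci, manifest = synthetic
        wrky = {gid: seq for gid, seq in records if scan_gene(gid, seq).domains}
        wrky_loci = {gid: loci[gid] for gid in wrky}
        pairs = find_duplicates(wrky, loci=wrky_loci)
        tandem = find_tandem(pairs, wrky_loci)
        assert sorted(p.key for p in tandem) == [(a, b) for a, b, _ in manifest.tandem_pairs]


class TestFindOrthologs:
    def test_identical_cross_subgenome_pair(self):
        seqs = {"a1": "MKKLV" * 10, "c1": "MKKLV" * 10}
        loci = {"a1": Locus("A01", 1, 150), "c1": Locus("C01", 1, 150)}
        pairs = find_orthologs(seqs, loci)
        assert [p.key for p in pairs] == [("a1", "c1")]
        assert pairs[0].kind == "ortholog"

    def test_non_reciprocal_best_hit_excluded(self):
        base = "MKKLVPQRSTWCDEF" * 4
        better = base
        worse = base[:-6] + "AAAAAA"  # further from c1 than a1 is
        seqs = {"a1": better, "a2": worse, "c1": base}
        loci = {
            "a1": Locus("A01", 1, 180),
            "a2": Locus("A02", 1, 180),
            "c1": Locus("C01", 1, 180),
        }
        pairs = find_orthologs(seqs, loci)
        # c1's best A hit is a1, so a2 gets no pair
        assert [p.key for p in pairs] == [("a1", "c1")]

    def test_unparseable_chromosome_raises(self):
        seqs = {"g1": "MKKLV" * 10, "g2": "MKKLV" * 10}
        loci = {"g1": Locus("1", 1, 150), "g2": Locus("C01", 1, 150)}
        with pytest.raises(ValueError):
            find_orthologs(seqs, loci)

    def test_planted_orthologs_recovered(self, synthetic):
        records, loci, manifest = synthetic
        wrky = {gid: seq for gid, seq in records if scan_gene(gid, seq).domains}
        wrky_loci = {gid: loci[gid] for gid in wrky}
        pairs = find_orthologs(wrky, wrky_loci)
        assert sorted(p.key for p in pairs) == [
            (a, b) for a, b, _ in manifest.ortholog_pairs
        ]


def _mk_pair(a, b, identity=95.0):
    from famscan.duplication import DuplicationPair

    x, y = sorted((a, b))
    return DuplicationPair(gene_a=x, gene_b=y, identity=identity)


class TestFindSegmental:
    def test_three_collinear_pairs_form_block(self):
        loci = {}
        pairs = []
        for k in range(3):
            loci[f"a{k}"] = Locus("A03", 1_000_000 * (k + 1), 1_000_000 * (k + 1) + 500)
            loci[f"c{k}"] = Locus("C03", 1_000_000 * (k + 1), 1_000_000 * (k + 1) + 500)
            pairs.append(_mk_pair(f"a{k}", f"c{k}"))
        blocks = find_segmental(pairs, loci)
        assert len(blocks) == 1
        assert blocks[0].size == 3
        assert blocks[0].chromosome_pair == ("A03", "C03")

    def test_two_pairs_below_minimum_discarded(self):
        loci = {}
        pairs = []
        for k in range(2):
            loci[f"a{k}"] = Locus("A03", 1_000_000 * (k + 1), 1_000_000 * (k + 1) + 500)
            loci[f"c{k}"] = Locus("C03", 1_000_000 * (k + 1), 1_000_000 * (k + 1) + 500)
            pairs.append(_mk_pair(f"a{k}", f"c{k}"))
        assert find_segmental(pairs, loci) == []

    def test_large_gap_breaks_chain(self):
        loci = {}
        pairs = []
        positions = [1_000_000, 2_000_000, 9_000_000, 10_000_000]
        for k, pos in enumerate(positions):
            loci[f"a{k}"] = Locus("A03", pos, pos + 500)
            loci[f"c{k}"] = Locus("C03", pos, pos + 500)
            pairs.append(_mk_pair(f"a{k}", f"c{k}"))
        # both fragments have only 2 anchors -> no block at min 3
        assert find_segmental(pairs, loci) == []

    def test_inverted_block_detected(self):
        loci = {}
        pairs = []
        for k in range(3):
            loci[f"a{k}"] = Locus("A03", 1_000_000 * (k + 1), 1_000_000 * (k + 1) + 500)
            loci[f"c{k}"] = Locus("C03", 1_000_000 * (3 - k), 1_000_000 * (3 - k) + 500)
            pairs.append(_mk_pair(f"a{k}", f"c{k}"))
        blocks = find_segmental(pairs, loci)
        assert len(blocks) == 1 and blocks[0].size == 3

    def test_tandem_pairs_excluded_from_chaining(self):
        loci = {}
        pairs = []
        for k in range(3):
            loci[f"a{k}"] = Locus("A03", 1_000_000 * (k + 1), 1_000_000 * (k + 1) + 500)
            loci[f"c{k}"] = Locus("C03", 1_000_000 * (k + 1), 1_000_000 * (k + 1) + 500)
            pairs.append(_mk_pair(f"a{k}", f"c{k}"))
        assert find_segmental(pairs, loci, tandem_pairs=pairs) == []

    def test_planted_block_recovered_exactly(self, synthetic):
        records, loci, manifest = synthetic
        wrky = {gid: seq for gid, seq in records if scan_gene(gid, seq).domains}
        wrky_loci = {gid: loci[gid] for gid in wrky}
        pairs = find_duplicates(wrky, loci=wrky_loci)
        tandem = find_tandem(pairs, wrky_loci)
        blocks = find_segmental(pairs, wrky_loci, tandem_pairs=tandem)
        assert len(blocks) == len(manifest.segmental_blocks)
        got = sorted(p.key for p in blocks[0].pairs)
        planted = sorted((a, b) for a, b, _ in manifest.segmental_blocks[0]["pairs"])
        assert got == planted


class TestSetRelations:
    def test_tandem_subset_of_duplicates_and_disjoint_from_orthologs(self, synthetic):
        records, loci, manifest = synthetic
        wrky = {gid: seq for gid, seq in records if scan_gene(gid, seq).domains}
        wrky_loci = {gid: loci[gid] for gid in wrky}
        duplicates = {p.key for p in find_duplicates(wrky, loci=wrky_loci)}
        tandem = {p.key for p in find_tandem(find_duplicates(wrky, loci=wrky_loci), wrky_loci)}
        orthologs = {p.key for p in find_orthologs(wrky, wrky_loci)}
        assert tandem <= duplicates
        assert not (tandem & orthologs)
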