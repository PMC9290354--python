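"""Similarity search, homology groups, distances and neighbor joining."""

import itertools

import numpy as np
import pytest

from mirsexbias.align import Scoring
from mirsexbias.homology import (
    DistanceMatrix,
    HomologyGroup,
    SimilarityHit,
    TreeNode,
    build_groups,
    distance_matrix,
    find_hits,
    neighbor_joining,
    uncorrected_distance,
)
from mirsexbias.io_tables import write_newick


def hit(q, s):
    return SimilarityHit(q, s, 50, 1e-10, 60, 0.95, (1, 60), (1, 60))


class TestFindHits:
    def test_planted_orthologs_recovered(self, small_study):
        """Ortholog pairs diverged at 5% per lineage come back as hits at the
        pairing threshold in ~all cases (the seed can miss only when no
        10-mer survives, which is rare)."""
        hits = find_hits(small_study["seqs1"], small_study["seqs2"])
        edges = {(h.query, h.subject) for h in hits}
        truth = small_study["truth"].orthologs
        found = sum(
            (r.id1, r.id2) in edges for r in truth.itertuples()
        )
        assert found / len(truth) >= 0.98

    def test_symmetry_of_edge_set(self, small_study):
        f = find_hits(small_study["seqs1"], small_study["seqs2"])
        r = find_hits(small_study["seqs2"], small_study["seqs1"])
        assert {(h.query, h.subject) for h in f} == {
            (h.subject, h.query) for h in r
        }

    def test_genome_scan_length_filter_excludes_59(self):
        # a perfect 59-nt overlap fails the >=60 genome-scan length rule
        core = "ACGTTGCAAC" * 6  # 60 nt
        q = {"q": core[:59]}
        s = {"s": core + "TTTTTTTTTT"}
        with_filter = find_hits(q, s, min_aln_len=60, evalue_max=10.0)
        without = find_hits(q, s, evalue_max=10.0)
        assert with_filter == [] and len(without) == 1

    def test_unpaired_loci_rarely_hit(self, small_study):
        """Novel (unpaired) loci are random sequence: at the pairing
        threshold at most a few percent may pair by chance."""
        hits = find_hits(small_study["seqs1"], small_study["seqs2"])
        hit_subjects = {h.subject for h in hits}
        truth = small_study["truth"]
        novel = set(
            truth.loci.query("species == 'dpse' and age_class == 'novel'")["id"]
        )
        assert len(novel & hit_subjects) / max(len(novel), 1) <= 0.05


class TestBuildGroups:
    def test_no_hits_everything_unpaired(self):
        groups = build_groups([], ["a1", "a2"], ["b1"])
        assert all(g.cls == "unpaired" for g in groups)
        assert len(groups) == 3

    def test_chain_is_transitive_one_to_many(self):
        groups = build_groups(
            [hit("a1", "b1"), hit("a2", "b1")], ["a1", "a2"], ["b1"]
        )
        grouped = [g for g in groups if g.cls != "unpaired"]
        assert grouped == [
            HomologyGroup(("a1", "a2"), ("b1",), "one_to_many")
        ]

    def test_mir92_like_family_resolution(self):
        """Two copies in species 1, three in species 2, all cross-similar ->
        one many-to-many group; severing one species-2 copy's cross-edges
        leaves it unpaired (the dps-mir-92c situation)."""
        ids1 = ["dme-92a", "dme-92b"]
        ids2 = ["dps-92a", "dps-92b", "dps-92c"]
        all_edges = [hit(a, b) for a in ids1 for b in ids2]
        groups = build_groups(all_edges, ids1, ids2)
        assert [g.cls for g in groups] == ["many_to_many"]
        pruned = [h for h in all_edges if h.subject != "dps-92c"]
        groups = build_groups(pruned, ids1, ids2)
        assert {g.cls for g in groups} == {"many_to_many", "unpaired"}
        unpaired = [g for g in groups if g.cls == "unpaired"][0]
        assert unpaired.members2 == ("dps-92c",)

    def test_override_edge_restores_pairing(self):
        groups = build_groups(
            [], ["dme-311"], ["dps-92c"], overrides=[("dme-311", "dps-92c")]
        )
        assert groups == [
            HomologyGroup(("dme-311",), ("dps-92c",), "one_to_one")
        ]

    def test_components_match_transitive_closure_oracle(self, rng):
        """Against brute-force transitive closure on random bipartite
        graphs."""
        for _ in range(40):
            n1, n2 = rng.integers(2, 12, 2)
            ids1 = [f"a{i}" for i in range(n1)]
            ids2 = [f"b{i}" for i in range(n2)]
            edges = [
                (a, b)
                for a in ids1
                for b in ids2
                if rng.random() < 0.15
            ]
            groups = build_groups([hit(a, b) for a, b in edges], ids1, ids2)
            # oracle: repeated merging until fixpoint
            comps = [{x} for x in ids1 + ids2]
            for a, b in edges:
                ca = next(c for c in comps if a in c)
                cb = next(c for c in comps if b in c)
                if ca is not cb:
                    comps.remove(ca)
                    comps.remove(cb)
                    comps.append(ca | cb)
            expect = {frozenset(c) for c in comps}
            got = {frozenset(g.members1 + g.members2) for g in groups}
            assert got == expect

    def test_groups_partition_all_loci(self, small_study):
        hits = find_hits(small_study["seqs1"], small_study["seqs2"])
        ids1 = [l.id for l in small_study["ann1"]]
        ids2 = [l.id for l in small_study["ann2"]]
        groups = build_groups(hits, ids1, ids2)
        members = list(
            itertools.chain.from_iterable(g.members1 + g.members2 for g in groups)
        )
        assert sorted(members) == sorted(ids1 + ids2)
        for g in groups:
            assert g.cls == HomologyGroup.classify(len(g.members1), len(g.members2))


class TestUncorrectedDistance:
    def test_identical_zero(self):
        assert uncorrected_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_hand_counted_three_in_sixty(self):
        s1 = "ACGTTGCAAC" * 6
        s2 = list(s1)
        for pos in (5, 20, 40):
            s2[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s2[pos]]
        assert uncorrected_distance(s1, "".join(s2)) == pytest.approx(0.05)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            uncorrected_distance("", "ACGT")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ("a", "b", "c"), np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        )
        assert write_newick(neighbor_joining(dm)) == "(a:0,b:2,c:3);"

    def test_zero_matrix_star_all_zero_lengths(self):
        dm = DistanceMatrix(tuple("abcd"), np.zeros((4, 4)))
        tree = neighbor_joining(dm)

        def lengths(n):
            out = [n.length] if n.length else []
            for c in n.children:
                out += lengths(c)
            return out

        assert lengths(tree) == []

    def test_additive_five_taxon_exact_recovery(self):
        # ((A:2,B:3):1,(C:4,D:5):2,E:6) path metric
        labels = tuple("ABCDE")
        paths = {
            ("A", "B"): 5, ("A", "C"): 9, ("A", "D"): 10, ("A", "E"): 9,
            ("B", "C"): 10, ("B", "D"): 11, ("B", "E"): 10,
            ("C", "D"): 9, ("C", "E"): 12, ("D", "E"): 13,
        }
        d = np.zeros((5, 5))
        for (x, y), v in paths.items():
            i, j = labels.index(x), labels.index(y)
            d[i, j] = d[j, i] = v
        nwk = write_newick(neighbor_joining(DistanceMatrix(labels, d)))
        assert nwk == "((A:2,B:3):1,(C:4,D:5):2,E:6);"

    def test_matches_skbio_topology_on_random_additive_matrices(self, rng):
        import io

        from skbio import DistanceMatrix as SkDM, TreeNode as SkTree
        from skbio.tree import nj as skbio_nj

        for _ in range(10):
            n = 6
            labels = [f"t{i}" for i in range(n)]
            # random additive matrix: random binary tree with random lengths
            clusters = [(l, 0.0) for l in labels]
            d = {l: {} for l in labels}
            leaf_sets = [({l}, 0.0) for l in labels]
            depth = {l: 0.0 for l in labels}
            dist = np.zeros((n, n))
            active = [[i] for i in range(n)]
            height = np.zeros(n)
            while len(active) > 1:
                i, j = sorted(rng.choice(len(active), 2, replace=False))
                li = float(rng.uniform(0.5, 2))
                lj = float(rng.uniform(0.5, 2))
                for x in active[i]:
                    for y in active[j]:
                        dist[x, y] = dist[y, x] = (
                            height[x] + li + height[y] + lj
                        )
                for x in active[i]:
                    height[x] += li
                for y in active[j]:
                    height[y] += lj
                active[i] += active[j]
                del active[j]
            dm = DistanceMatrix(tuple(labels), dist)
            mine = SkTree.read(io.StringIO(write_newick(neighbor_joining(dm))))
            theirs = skbio_nj(SkDM(dist, labels))
            assert mine.compare_rfd(theirs) == 0.0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], float))

    def test_single_pair(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 3.0], [3.0, 0]]))
        assert write_newick(neighbor_joining(dm)) == "(a:1.5,b:1.5);"
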