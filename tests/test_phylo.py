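"""Distance matrices, Neighbor-Joining correctness, Newick, bipartitions."""

import random

import numpy as np
import pytest

from cysdom.align import Msa
from cysdom.phylo import (
    DistanceMatrix,
    ascii_tree,
    distance_matrix,
    has_bipartition,
    neighbor_joining,
    parse_newick,
    to_newick,
)

from conftest import random_additive_case


def _dm(labels, rows):
    return DistanceMatrix(labels=tuple(labels), d=np.asarray(rows, dtype=float))


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            _dm(("a", "b"), [[0, 1], [2, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            _dm(("a", "b"), [[1, 1], [1, 0]])
        with pytest.raises(ValueError, match="negative"):
            _dm(("a", "b"), [[0, -1], [-1, 0]])

    def test_identical_msa_rows_zero_matrix(self):
        msa = Msa(labels=("a", "b", "c"), rows=("ACDW" * 10,) * 3)
        D = distance_matrix(msa)
        assert np.all(D.d == 0)

    def test_matrix_symmetric_zero_diagonal(self):
        msa = Msa(
            labels=("a", "b", "c"),
            rows=("ACDEFGHIKL" * 5, "ACDEFGHIKM" * 5, "ACDEWGHIKL" * 5),
        )
        D = distance_matrix(msa)
        assert np.allclose(D.d, D.d.T) and np.all(np.diag(D.d) == 0)

    def test_phylip_output_shape(self):
        D = _dm(("a", "b", "c"), [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        lines = D.to_phylip().strip().splitlines()
        assert lines[0] == "3"
        assert lines[1].split("\t")[0] == "a"
        assert len(lines) == 4


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # a+b=2, a+c=3, b+c=4 -> a=0.5, b=1.5, c=2.5
        D = _dm(("A", "B", "C"), [[0, 2, 3], [2, 0, 4], [3, 4, 0]])
        tree = neighbor_joining(D)
        assert to_newick(tree) == "(A:0.500000,B:1.500000,C:2.500000);"

    def test_three_taxon_distances_reproduced_exactly(self, rng):
        for _ in range(20):
            x, y, z = (rng.uniform(0.1, 5) for _ in range(3))
            # triangle-inequality-satisfying random matrix
            D = _dm(("A", "B", "C"), [[0, x + y, x + z], [x + y, 0, y + z], [x + z, y + z, 0]])
            out = neighbor_joining(D).leaf_distances()
            assert np.allclose(out.d, D.d, atol=1e-12)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        D = _dm(
            ("A", "B", "C", "D"),
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        )
        tree = neighbor_joining(D)
        assert has_bipartition(tree, {"A", "B"})
        assert not has_bipartition(tree, {"A", "C"})
        assert np.allclose(tree.leaf_distances().d, D.d, atol=1e-12)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(_dm(("a", "b"), [[0, 1], [1, 0]]))

    def test_random_additive_matrices_recovered(self, rng):
        """NJ is exact on additive inputs: topology and branch lengths."""
        for _ in range(100):
            labels, D, true_splits = random_additive_case(rng, rng.randint(4, 8))
            tree = neighbor_joining(DistanceMatrix(labels=tuple(labels), d=D))
            all_taxa = frozenset(labels)
            canon = lambda splits: {min(s, all_taxa - s, key=sorted) for s in splits}
            assert canon(tree.bipartitions()) == canon(true_splits)
            out = tree.leaf_distances()
            order = [out.labels.index(l) for l in labels]
            assert np.abs(out.d[np.ix_(order, order)] - D).max() < 1e-9

    def test_cross_check_against_dendropy(self, rng):
        """Same splits as an independent NJ implementation."""
        dendropy = pytest.importorskip("dendropy")
        labels, D, _ = random_additive_case(rng, 6)
        # perturb slightly so the matrix is not exactly additive
        noise = np.array([[rng.uniform(-0.01, 0.01) for _ in labels] for _ in labels])
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        Dn = np.abs(D + noise)
        Dn = (Dn + Dn.T) / 2
        np.fill_diagonal(Dn, 0)
        tree = neighbor_joining(DistanceMatrix(labels=tuple(labels), d=Dn))

        csv = "," + ",".join(labels) + "\n"
        for i, l in enumerate(labels):
            csv += l + "," + ",".join(str(v) for v in Dn[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        dendro_splits = set()
        all_taxa = frozenset(labels)
        for edge in dtree.preorder_edge_iter():
            if edge.bipartition:
                side = frozenset(
                    t.label for t in dtree.taxon_namespace
                    if edge.bipartition.leafset_bitmask
                    & dtree.taxon_namespace.taxon_bitmask(t)
                )
                if 1 < len(side) < len(labels) - 1:
                    dendro_splits.add(min(side, all_taxa - side, key=sorted))
        mine = {
            min(s, all_taxa - s, key=sorted) for s in tree.bipartitions()
        }
        assert mine == dendro_splits


class TestNewick:
    def test_three_taxon_format(self):
        D = _dm(("A", "B", "C"), [[0, 2, 3], [2, 0, 4], [3, 4, 0]])
        assert to_newick(neighbor_joining(D)) == "(A:0.500000,B:1.500000,C:2.500000);"

    def test_round_trip_preserves_topology_and_lengths(self, rng):
        labels, D, _ = random_additive_case(rng, 7)
        tree = neighbor_joining(DistanceMatrix(labels=tuple(labels), d=D))
        back = parse_newick(to_newick(tree))
        assert back.bipartitions() == tree.bipartitions()
        assert np.allclose(
            back.leaf_distances().d, tree.leaf_distances().d, atol=1e-5
        )

    def test_labels_with_metacharacters_quoted(self):
        from cysdom.phylo import PhyloTree, TreeNode

        tree = PhyloTree(
            root=TreeNode(
                children=[
                    (TreeNode(label="a b"), 1.0),
                    (TreeNode(label="c(d)"), 1.0),
                    (TreeNode(label="plain"), 1.0),
                ]
            )
        )
        nwk = to_newick(tree)
        assert "'a b'" in nwk and "'c(d)'" in nwk and "plain" in nwk
        assert parse_newick(nwk).leaf_labels == {"a b", "c(d)", "plain"}

    def test_missing_semicolon_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("(A:1,B:2)")


class TestBipartitions:
    def test_simple_splits(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert has_bipartition(tree, {"A", "B"})
        assert has_bipartition(tree, {"C", "D"})
        assert not has_bipartition(tree, {"A", "C"})

    def test_invalid_taxa_sets_rejected(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            has_bipartition(tree, {"A"})
        with pytest.raises(ValueError):
            has_bipartition(tree, {"A", "B", "Z"})

    def test_matches_exhaustive_split_enumeration(self, rng):
        """has_bipartition agrees with testing every subset directly."""
        import itertools

        for _ in range(10):
            labels, D, true_splits = random_additive_case(rng, 6)
            tree = neighbor_joining(DistanceMatrix(labels=tuple(labels), d=D))
            for r in (2, 3):
                for combo in itertools.combinations(labels, r):
                    expected = (
                        frozenset(combo) in true_splits
                        or frozenset(set(labels) - set(combo)) in true_splits
                    )
                    assert has_bipartition(tree, set(combo)) == expected

    def test_ascii_rendering_mentions_all_leaves(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        text = ascii_tree(tree)
        for leaf in "ABCD":
            assert leaf in text
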