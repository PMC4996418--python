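"""Trimming, distances, neighbor joining, bootstrap, MDS and the trace."""

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from twistmotif.evolution import (
    DistanceError,
    DistanceMatrix,
    TreeError,
    TrimmingError,
    bootstrap_support,
    classical_mds,
    evolutionary_trace,
    msa_distance,
    nj_tree,
    tree_bipartitions,
    tree_distances,
    trim_alignment,
)
from twistmotif.seq_io import Msa, read_newick


def msa(*rows):
    return Msa(tuple((f"r{i}", row) for i, row in enumerate(rows)))


def random_additive_tree(rng, n_leaves):
    """Random topology with branch lengths in [0.1, 2]; returns TreeNode."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    for child in root.children:
        if child.length is None:
            child.length = float(rng.uniform(0.1, 2.0))
    return root


class TestTrim:
    def test_gap_free_alignment_unchanged(self):
        m = msa("ACDE", "ACDE", "ACDF")
        trimmed, removed = trim_alignment(m)
        assert trimmed.rows == m.rows
        assert removed == []

    def test_half_gapped_column_removed_at_default_threshold(self):
        rows = ["AC"] * 5 + ["A-"] * 5
        m = Msa(tuple((f"r{i}", r) for i, r in enumerate(rows)))
        trimmed, removed = trim_alignment(m, 0.4)
        assert removed == [2]
        assert trimmed.n_cols == 1

    def test_threshold_one_keeps_partially_gapped_columns(self):
        m = msa("AC-", "A--", "ACD")
        # column 3 has gap fraction 2/3; only columns over 1.0 would go
        trimmed, removed = trim_alignment(m, 1.0)
        assert removed == []
        assert trimmed.n_cols == 3

    def test_explicit_ranges_removed_regardless(self):
        m = msa("ACDEF", "ACDEF")
        trimmed, removed = trim_alignment(m, 0.4, drop_ranges=[(2, 3)])
        assert removed == [2, 3]
        assert trimmed.row("r0") == "AEF"

    def test_removing_everything_is_an_error(self):
        m = msa("AC", "AC")
        with pytest.raises(TrimmingError):
            trim_alignment(m, 0.4, drop_ranges=[(1, 2)])


class TestDistances:
    def test_identical_rows_distance_zero_both_methods(self):
        m = msa("ACDE", "ACDE")
        for method in ("p-distance", "matrix-normalized"):
            d = msa_distance(m, method)
            assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_p_distance_counts_mismatches(self):
        d = msa_distance(msa("ACDE", "ACDA"))
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_gapped_columns_masked_pairwise(self):
        d = msa_distance(msa("AC-E", "ACD-"))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_no_shared_columns_is_an_error(self):
        with pytest.raises(DistanceError, match="r0.*r1"):
            msa_distance(msa("A--B".replace("B", "C"), "-CC-"))

    def test_matrix_normalized_in_unit_range(self, family):
        d = msa_distance(family.true_msa, "matrix-normalized")
        assert (d.values >= 0).all()
        assert (d.values <= 1).all()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            labels=("A", "B", "C"),
            values=np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float),
            method="p-distance",
        )
        tree = nj_tree(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_four_taxon_additive_matrix_recovered(self):
        # hand-computed path lengths of ((A:1,B:2):1,(C:3,D:4):1)
        labels = ("A", "B", "C", "D")
        vals = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        d = DistanceMatrix(labels=labels, values=vals, method="p-distance")
        tree = nj_tree(d)
        assert frozenset({"C", "D"}) in tree_bipartitions(tree)
        recovered = tree_distances(tree)
        assert np.allclose(recovered.values, vals, atol=1e-9)

    def test_zero_distance_pair_become_siblings(self):
        vals = np.array(
            [[0, 0, 5, 6], [0, 0, 5, 6], [5, 5, 0, 3], [6, 6, 3, 0]], dtype=float
        )
        d = DistanceMatrix(labels=("A", "B", "C", "D"), values=vals, method="p-distance")
        tree = nj_tree(d)
        assert frozenset({"C", "D"}) in tree_bipartitions(tree)

    def test_too_few_labels_rejected(self):
        d = DistanceMatrix(
            labels=("A", "B"), values=np.array([[0, 1], [1, 0]], dtype=float),
            method="p-distance",
        )
        with pytest.raises(TreeError):
            nj_tree(d)

    def test_additive_recovery_random_trees(self):
        """NJ reproduces random additive matrices exactly (small sample;
        the broader sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            true = random_additive_tree(rng, int(rng.integers(5, 13)))
            dm = tree_distances(true)
            rec = tree_distances(nj_tree(dm))
            assert rec.labels == dm.labels
            assert np.allclose(rec.values, dm.values, atol=1e-9)
            assert tree_bipartitions(nj_tree(dm)) == tree_bipartitions(true)

    def test_agrees_with_independent_nj_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            true = random_additive_tree(rng, 7)
            dm = tree_distances(true)
            mine = nj_tree(dm)
            other = skbio_nj(SkbioDM(dm.values, ids=list(dm.labels)))
            assert tree_bipartitions(mine) == tree_bipartitions(other)


class TestBootstrap:
    def test_perfectly_supported_split_gets_100(self):
        rows = ["A" * 50, "A" * 50, "C" * 50, "C" * 50]
        # every column separates {r0,r1} from {r2,r3}
        m = Msa(tuple((f"r{i}", r) for i, r in enumerate(rows)))
        tree = bootstrap_support(m, replicates=20, seed=0)
        supports = [n.support for n in tree.non_tips() if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_all_or_nothing(self, family):
        tree = bootstrap_support(family.true_msa, replicates=1, seed=5)
        supports = [n.support for n in tree.non_tips() if hasattr(n, "support")]
        assert set(supports) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self, family):
        t1 = bootstrap_support(family.true_msa, replicates=10, seed=9)
        t2 = bootstrap_support(family.true_msa, replicates=10, seed=9)
        s1 = sorted(n.support for n in t1.non_tips() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips() if hasattr(n, "support"))
        assert s1 == s2


class TestClassicalMds:
    def test_two_points(self):
        d = DistanceMatrix(
            labels=("A", "B"), values=np.array([[0, 2], [2, 0]], dtype=float),
            method="p-distance",
        )
        emb = classical_mds(d, k=3)
        assert emb.coordinates[:, 0] == pytest.approx([1.0, -1.0])
        assert emb.eigenvalues[0] == pytest.approx(2.0)

    def test_3_4_5_triangle_reproduced(self):
        # law-of-cosines oracle: the 3-4-5 right triangle is realizable
        vals = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        d = DistanceMatrix(labels=("A", "B", "C"), values=vals, method="p-distance")
        emb = classical_mds(d, k=3)
        diff = np.linalg.norm(
            emb.coordinates[:, None, :] - emb.coordinates[None, :, :], axis=-1
        )
        assert np.allclose(diff, vals, atol=1e-9)

    def test_all_zero_distances_embed_at_origin(self):
        d = DistanceMatrix(
            labels=("A", "B", "C"), values=np.zeros((3, 3)), method="p-distance"
        )
        emb = classical_mds(d)
        assert np.allclose(emb.coordinates, 0)

    def test_coordinates_centered_and_explained_sums_to_one(self, family):
        d = msa_distance(family.true_msa)
        emb = classical_mds(d, k=3)
        assert np.allclose(emb.coordinates.mean(axis=0), 0, atol=1e-9)
        assert emb.explained.sum() <= 1.0 + 1e-12
        assert (np.diff(emb.eigenvalues) <= 1e-12).all()

    def test_axis_sign_convention_is_deterministic(self, family):
        d = msa_distance(family.true_msa)
        e1 = classical_mds(d, k=3)
        e2 = classical_mds(d, k=3)
        assert np.allclose(e1.coordinates, e2.coordinates)
        for axis in range(e1.k):
            col = e1.coordinates[:, axis]
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            assert col[nz[0]] > 0


class TestEvolutionaryTrace:
    def test_planted_two_clade_column(self):
        rows = ["ANA"] * 3 + ["ATA"] * 3
        m = Msa(tuple((f"r{i}", r) for i, r in enumerate(rows)))
        tree = read_newick(
            "((r0:1,(r1:1,r2:1):1):1,(r3:1,(r4:1,r5:1):1):1);"
        )
        result = evolutionary_trace(m, tree, levels=3)
        assert result.level(2).column_classes[1] == "class-specific"

    def test_identical_rows_conserved_at_every_level(self):
        rows = ["MKVL"] * 4
        m = Msa(tuple((f"r{i}", r) for i, r in enumerate(rows)))
        tree = read_newick("((r0:1,r1:1):1,(r2:1,r3:1):1);")
        result = evolutionary_trace(m, tree, levels=4)
        for lv in result.levels:
            assert set(lv.column_classes) == {"conserved"}

    def test_level_one_has_single_group_and_no_class_specific(self, family):
        result = evolutionary_trace(family.true_msa, family.true_tree, levels=2)
        assert len(result.level(1).groups) == 1
        assert "class-specific" not in result.level(1).column_classes

    def test_conserved_at_level_one_stays_conserved(self, family):
        result = evolutionary_trace(family.true_msa, family.true_tree, levels=4)
        lvl1 = result.level(1).column_classes
        for lv in result.levels[1:]:
            for c, cls in enumerate(lvl1):
                if cls == "conserved":
                    assert lv.column_classes[c] == "conserved"

    def test_leaf_row_mismatch_rejected(self, family):
        tree = read_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError):
            evolutionary_trace(family.true_msa, tree)
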