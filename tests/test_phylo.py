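import numpy as np
import pytest

from asterfam.phylo import (
    DistanceMatrix,
    ReferencePanel,
    TrimConfig,
    assign_labels,
    neighbor_joining,
    pairwise_distance,
    trim_alignment,
)


class TestTrimAlignment:
    def test_all_gap_column_removed(self):
        aln = {"a": "A-A", "b": "C-C"}
        assert trim_alignment(aln) == {"a": "AA", "b": "CC"}

    def test_threshold_boundary_is_inclusive(self):
        # 10 rows: 1 non-gap (0.1) drops, 2 non-gaps (0.2) stays
        one = {f"s{i}": ("A" if i == 0 else "-") for i in range(10)}
        two = {f"s{i}": ("A" if i < 2 else "-") for i in range(10)}
        assert all(v == "" for v in trim_alignment(one).values())
        assert all(len(v) == 1 for v in trim_alignment(two).values())

    def test_idempotent(self):
        aln = {"a": "AC-GT-", "b": "A--GTT", "c": "ACCG--"}
        once = trim_alignment(aln, TrimConfig(0.5))
        assert trim_alignment(once, TrimConfig(0.5)) == once

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            trim_alignment({"a": "ACGT", "b": "ACG"})


class TestPairwiseDistance:
    def test_identical_rows(self):
        dm = pairwise_distance({"a": "AAAA", "b": "AAAA"})
        assert dm.d[0, 1] == 0

    def test_quarter_divergence(self):
        dm = pairwise_distance({"a": "AAAA", "b": "AAAT"})
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gapped_columns_excluded(self):
        dm = pairwise_distance({"a": "AA--", "b": "AATT"})
        assert dm.d[0, 1] == 0

    def test_no_comparable_columns_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="no comparable"):
            dm = pairwise_distance({"a": "AA--", "b": "--TT"})
        assert dm.d[0, 1] == 1.0


def _tree_paths(tree):
    dm = tree.tip_tip_distances()
    return {frozenset((a, b)): dm[a, b] for a in dm.ids for b in dm.ids if a < b}


class TestNeighborJoining:
    def test_four_taxon_additive_tree_recovered(self):
        # distances from the unrooted tree ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        paths = _tree_paths(tree)
        for (i, a) in enumerate(labels):
            for (j, b) in enumerate(labels):
                if i < j:
                    assert paths[frozenset((a, b))] == pytest.approx(d[i, j], abs=1e-9)
        # AB form a cherry: their path excludes C and D's long branches
        assert paths[frozenset(("A", "B"))] == 3

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        paths = _tree_paths(tree)
        assert paths[frozenset(("a", "b"))] == pytest.approx(4, abs=1e-9)
        assert paths[frozenset(("a", "c"))] == pytest.approx(6, abs=1e-9)
        assert paths[frozenset(("b", "c"))] == pytest.approx(8, abs=1e-9)

    def test_ultrametric_matrix_reproduced(self):
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(list("abcd"), d))
        paths = _tree_paths(tree)
        labels = list("abcd")
        for i in range(4):
            for j in range(i + 1, 4):
                assert paths[frozenset((labels[i], labels[j]))] == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_agrees_with_skbio_on_random_matrices(self):
        """Independent cross-check against scikit-bio's NJ on clean matrices."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj

        rng = np.random.default_rng(5)
        for _ in range(5):
            n = 6
            # additive matrices from random tip "heights" avoid ties/negatives
            coords = rng.uniform(0, 10, size=(n, 3))
            d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, 0)
            labels = [f"t{i}" for i in range(n)]
            ours = _tree_paths(neighbor_joining(DistanceMatrix(labels, d)))
            theirs_tree = nj(SkbioDM(d, labels))
            theirs = {
                frozenset((a, b)): theirs_tree.tip_tip_distances()[a, b]
                for a in labels
                for b in labels
                if a < b
            }
            for key in ours:
                assert ours[key] == pytest.approx(theirs[key], abs=1e-6)


class TestAssignLabels:
    def _tree(self, aln):
        return neighbor_joining(pairwise_distance(aln))

    def test_sibling_reference_wins(self):
        aln = {
            "AT_RAF": "AAAAAAAAAA",
            "x": "AAAAAAAAAT",
            "AT_MEKK": "TTTTTTTTTT",
            "AT_ZIK": "GGGGGGGGGG",
        }
        panel = ReferencePanel(
            {"AT_RAF": ("RAF", 8), "AT_MEKK": ("MEKK", 1), "AT_ZIK": ("ZIK", 6)}
        )
        labels = assign_labels(self._tree(aln), panel)
        assert labels["x"] == ("RAF", 8)

    def test_reference_leaf_keeps_its_own_labels(self):
        aln = {
            "AT_RAF": "AAAAAAAAAA",
            "AT_MEKK": "TTTTTTTTTT",
            "AT_ZIK": "GGGGGGGGGG",
            "y": "TTTTTTTTTA",
        }
        panel = ReferencePanel(
            {"AT_RAF": ("RAF", None), "AT_MEKK": ("MEKK", None), "AT_ZIK": ("ZIK", None)}
        )
        labels = assign_labels(self._tree(aln), panel)
        assert labels["AT_MEKK"] == ("MEKK", None)
        assert labels["y"] == ("MEKK", None)

    def test_patristic_tie_resolves_to_smallest_reference_id(self):
        # x sits exactly between the two references on a symmetric tree
        from io import StringIO

        from skbio import TreeNode

        tree = TreeNode.read(StringIO("((AT1:1,AT2:1):0,x:0,AT3:5);"))
        panel = ReferencePanel(
            {"AT1": ("MEKK", None), "AT2": ("ZIK", None), "AT3": ("RAF", None)}
        )
        labels = assign_labels(tree, panel)
        assert labels["x"] == ("MEKK", None)

    def test_missing_subfamily_rejected(self):
        aln = {"AT_RAF": "AAAA", "x": "AAAT", "AT_MEKK": "TTTT"}
        panel = ReferencePanel({"AT_RAF": ("RAF", None), "AT_MEKK": ("MEKK", None)})
        with pytest.raises(ValueError, match="ZIK"):
            assign_labels(self._tree(aln), panel)

    def test_invalid_cluster_range_rejected(self):
        with pytest.raises(ValueError):
            ReferencePanel({"r": ("MEKK", 9)})


def test_subfamily_recovery_on_planted_signatures(small_pipeline):
    """Label propagation recovers >=95% of planted subfamilies when the
    between-subfamily divergence dominates the within-subfamily noise."""
    _cfg, results, truth = small_pipeline
    truth_sub = {g: truth.ogg_subfamily[o] for g, o in truth.ogg_membership.items()}
    assigned = results["subfamily_of"]
    assert assigned
    hits = sum(1 for g, (s, _c) in assigned.items() if truth_sub.get(g) == s)
    assert hits / len(assigned) >= 0.95
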