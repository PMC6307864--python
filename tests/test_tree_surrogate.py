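"""Distances, neighbor joining, rooting and clade-label propagation."""

import io
import itertools
import math

import numpy as np
import pytest

from glur.errors import ConfigurationError, IncomparablePairError, SaturationError
from glur.io_formats import MultipleAlignment, SequenceRecord
from glur.synthetic_data import make_protostome_benchmark
from glur.tree_surrogate import (
    DistanceMatrix,
    Node,
    PhyloTree,
    assign_classes,
    corrected_distances,
    kimura_protein_correction,
    neighbor_joining,
    newick_string,
    p_distance,
    path_length,
    root_on_outgroup,
)


# -- helpers ----------------------------------------------------------------

def random_binary_tree(labels, rng):
    """Random unrooted binary tree with positive branch lengths."""
    nodes = [Node(lbl, float(rng.uniform(0.1, 2.0))) for lbl in labels[:3]]
    root = Node()
    for nd in nodes:
        root.add(nd)
    edges = list(nodes)
    for lbl in labels[3:]:
        edge = edges[int(rng.integers(len(edges)))]
        parent = edge.parent
        mid = Node(length=float(rng.uniform(0.1, 2.0)))
        parent.children[parent.children.index(edge)] = mid
        mid.parent = parent
        half = edge.length / 2
        edge.length = half
        mid.length = half
        leaf = Node(lbl, float(rng.uniform(0.1, 2.0)))
        mid.add(edge)
        mid.add(leaf)
        edges.extend([edge, mid, leaf])
    return PhyloTree(root)


def additive_matrix(tree, labels):
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = path_length(tree, labels[i], labels[j])
    return DistanceMatrix(list(labels), D)


def splits(tree):
    """Non-trivial bipartitions of the unrooted topology."""
    all_leaves = frozenset(tree.leaf_names())
    out = set()
    stack = list(tree.root.children)
    while stack:
        nd = stack.pop()
        stack.extend(nd.children)
        side = frozenset(nd.leaf_names())
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(min(side, all_leaves - side, key=sorted))
    return out


# -- p-distance -------------------------------------------------------------

class TestPDistance:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment([SequenceRecord("a", "ACDEF"), SequenceRecord("b", "ACDEF")])
        assert p_distance(aln).get("a", "b") == 0.0

    def test_one_in_four_mismatch(self):
        aln = MultipleAlignment([SequenceRecord("a", "AAAA"), SequenceRecord("b", "AAAT")])
        assert p_distance(aln).get("a", "b") == 0.25

    def test_pairwise_deletion_ignores_gapped_columns(self):
        aln = MultipleAlignment([SequenceRecord("a", "A-CD"), SequenceRecord("b", "AAC-")])
        assert p_distance(aln).get("a", "b") == 0.0  # only columns 0 and 2 compared

    def test_no_shared_columns_raises(self):
        aln = MultipleAlignment([SequenceRecord("a", "AA--"), SequenceRecord("b", "--CC")])
        with pytest.raises(IncomparablePairError):
            p_distance(aln)

    def test_matches_direct_recount_on_random_alignment(self):
        rng = np.random.default_rng(11)
        letters = list("ACDEF-")
        rows = ["".join(rng.choice(letters, size=40)) for _ in range(5)]
        aln = MultipleAlignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])
        dm = p_distance(aln)
        for i, j in itertools.combinations(range(5), 2):
            shared = [(x, y) for x, y in zip(rows[i], rows[j]) if x != "-" and y != "-"]
            expected = sum(x != y for x, y in shared) / len(shared)
            assert dm.values[i, j] == pytest.approx(expected)


class TestKimuraCorrection:
    def test_zero_maps_to_zero(self):
        assert kimura_protein_correction(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert kimura_protein_correction(0.5) == pytest.approx(-math.log(0.45))

    def test_correction_inflates_distances(self):
        for p in np.linspace(0.01, 0.84, 50):
            assert kimura_protein_correction(p) >= p

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            kimura_protein_correction(0.85)

    def test_pipeline_caps_saturated_pairs(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.86], [0.86, 0.0]]))
        out = corrected_distances(dm, saturation_cap=5.0)
        assert out.get("a", "b") == 5.0


# -- neighbor joining -------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        la = path_length(tree, "a", "b") + path_length(tree, "a", "c") - path_length(tree, "b", "c")
        assert la / 2 == pytest.approx(2.0)  # (5+9-10)/2
        assert path_length(tree, "a", "b") == pytest.approx(5.0)
        assert path_length(tree, "b", "c") == pytest.approx(10.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ConfigurationError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_four_taxon_topologies_all_recovered(self):
        # the three unrooted quartets, as additive matrices from known trees
        for pair in (("a", "b"), ("a", "c"), ("a", "d")):
            rng = np.random.default_rng(7)
            tree = random_binary_tree(["x1", "x2", "x3", "x4"], rng)
            rename = dict(zip(["x1", "x2", "x3", "x4"],
                              [pair[0], pair[1]] + [l for l in "abcd" if l not in pair]))
            for leaf in tree.leaves():
                leaf.name = rename[leaf.name]
            labels = ["a", "b", "c", "d"]
            dm = additive_matrix(tree, labels)
            out = neighbor_joining(dm)
            assert splits(out) == splits(tree)

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_additive_matrices_recover_generating_topology(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(10):
            true = random_binary_tree(labels, rng)
            dm = additive_matrix(true, labels)
            out = neighbor_joining(dm)
            assert splits(out) == splits(true)
            # path lengths reproduce the additive input
            for i, j in itertools.combinations(labels, 2):
                assert path_length(out, i, j) == pytest.approx(dm.get(i, j))

    def test_agrees_with_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        rng = np.random.default_rng(17)
        labels = [f"t{i}" for i in range(7)]
        true = random_binary_tree(labels, rng)
        dm = additive_matrix(true, labels)
        mine = neighbor_joining(dm)
        other = nj(SkDM(dm.values, ids=labels))
        other_splits = set()
        for node in other.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(labels) - 1:
                other_splits.add(min(side, frozenset(labels) - side, key=sorted))
        assert splits(mine) == other_splits

    def test_newick_round_trip_through_independent_parser(self):
        from skbio import TreeNode

        rng = np.random.default_rng(23)
        labels = [f"leaf{i}" for i in range(10)]
        for _ in range(5):
            tree = random_binary_tree(labels, rng)
            parsed = TreeNode.read(io.StringIO(newick_string(tree)))
            dists = parsed.tip_tip_distances()
            for i, j in itertools.combinations(labels, 2):
                assert path_length(tree, i, j) == pytest.approx(
                    dists[i, j], abs=1e-9
                )


# -- rooting and assignment -------------------------------------------------

def quartet_tree():
    """((A1,A2),(K1,q)) plus outgroup; built by hand."""
    root = Node()
    a = Node(length=1.0)
    a.add(Node("A1", 0.5))
    a.add(Node("A2", 0.5))
    k = Node(length=1.0)
    k.add(Node("K1", 0.5))
    k.add(Node("q", 0.5))
    inner = Node(length=2.0)
    inner.add(a)
    inner.add(k)
    root.add(inner)
    root.add(Node("OUT", 4.0))
    root.add(Node("OUT2", 4.0))
    return PhyloTree(root)


class TestRootingAndAssignment:
    def test_rooting_preserves_leaf_path_lengths(self):
        rng = np.random.default_rng(31)
        labels = [f"t{i}" for i in range(8)]
        tree = random_binary_tree(labels, rng)
        before = {p: path_length(tree, *p) for p in itertools.combinations(labels, 2)}
        rooted = root_on_outgroup(tree, {"t0"})
        for pair, d in before.items():
            assert path_length(rooted, *pair) == pytest.approx(d)
        assert len(rooted.root.children) == 2

    def test_missing_outgroup_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            root_on_outgroup(quartet_tree(), {"nope"})

    def test_query_in_single_class_clade_gets_that_class(self):
        tree = quartet_tree()
        ca = assign_classes(tree, {"A1": "AMPA", "A2": "AMPA", "K1": "Kainate"},
                            {"OUT", "OUT2"})
        assert ca.assignments["q"] == "Kainate"
        assert ca.support["q"] == ["K1"]

    def test_mixed_reference_clade_is_unassigned(self):
        root = Node()
        mixed = Node(length=1.0)
        mixed.add(Node("A1", 0.5))
        mixed.add(Node("K1", 0.5))
        pair = Node(length=1.0)
        pair.add(Node("q", 0.2))
        pair.add(mixed)
        root.add(pair)
        root.add(Node("OUT", 3.0))
        root.add(Node("X", 1.0))
        ca = assign_classes(PhyloTree(root), {"A1": "AMPA", "K1": "Kainate"}, {"OUT"})
        assert ca.assignments["q"] == "unassigned"

    def test_monophyly_flags(self):
        tree = quartet_tree()
        ca = assign_classes(tree, {"A1": "AMPA", "A2": "AMPA", "K1": "Kainate"},
                            {"OUT", "OUT2"})
        assert ca.monophyletic == {"AMPA": True, "Kainate": True}

    def test_assignment_invariant_under_leaf_order_permutation(self):
        bench = make_protostome_benchmark(
            seed=2, counts={"Lophotrochozoa": {"AMPA": 4, "Kainate": 2},
                            "Ecdysozoa": {"AMPA": 2, "Kainate": 4}})
        records = bench["records"]
        base = None
        for order in (records, records[::-1]):
            aln = MultipleAlignment(list(order))
            tree = neighbor_joining(corrected_distances(p_distance(aln)))
            ca = assign_classes(tree, bench["reference_classes"], bench["outgroup"])
            if base is None:
                base = ca.assignments
            else:
                assert ca.assignments == base

    def test_two_class_synthetic_family_assignment_accuracy(self):
        """Planted two-class families are assigned ≥95% correctly."""
        bench = make_protostome_benchmark(
            seed=4, counts={"Lophotrochozoa": {"AMPA": 10, "Kainate": 4},
                            "Ecdysozoa": {"AMPA": 3, "Kainate": 10}})
        aln = MultipleAlignment(bench["records"])
        tree = neighbor_joining(corrected_distances(p_distance(aln)))
        ca = assign_classes(tree, bench["reference_classes"], bench["outgroup"])
        correct = sum(ca.assignments[q] == cls for q, cls in bench["truth"].items())
        assert correct / len(bench["truth"]) >= 0.95
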