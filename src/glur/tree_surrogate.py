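"""Desk-scale tree surrogate for clade-level class assignment.

Class membership claims at the level of deep, well-separated splits (e.g.
AMPA vs Kainate) do not need full Bayesian or maximum-likelihood inference:
a Kimura-corrected p-distance matrix, a neighbor-joining tree rooted on the
designated outgroup, and propagation of class labels from reference leaves
to query leaves reproduce them. Neighbor joining is exact on additive
distance matrices, which is what the tests exploit. Alignment export for
external ML/Bayesian tools is provided through
:func:`glur.io_formats.write_phylip`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, IncomparablePairError, LabelError, SaturationError
from .io_formats import MultipleAlignment

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ConfigurationError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ConfigurationError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ConfigurationError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ConfigurationError("distances must be finite and non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


class Node:
    """Tree node: leaves carry a name, every non-root node a branch length."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out = []
        stack = [self]
        while stack:
            nd = stack.pop()
            if nd.is_leaf():
                out.append(nd)
            else:
                stack.extend(reversed(nd.children))
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]


@dataclass
class PhyloTree:
    root: Node

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def find(self, name: str) -> Node:
        for lf in self.leaves():
            if lf.name == name:
                return lf
        raise KeyError(name)


def _fmt_len(x: float) -> str:
    s = f"{x:.10g}"
    if "." not in s and "e" not in s and "inf" not in s:
        s += ".0"
    return s


def _newick(node: Node, top: bool) -> str:
    if node.is_leaf():
        body = node.name
    else:
        body = "(" + ",".join(_newick(c, False) for c in node.children) + ")" + node.name
    if top:
        return body
    return f"{body}:{_fmt_len(node.length)}"


def newick_string(tree: PhyloTree) -> str:
    """Render the tree as a Newick string with branch lengths."""
    names = tree.leaf_names()
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise LabelError(f"duplicate leaf label(s): {', '.join(dup)}")
    return _newick(tree.root, True) + ";"


# ---------------------------------------------------------------------------
# Distances


def p_distance(alignment: MultipleAlignment) -> DistanceMatrix:
    """Pairwise-deletion p-distance: mismatches over shared ungapped columns."""
    seqs = np.array([list(rec.sequence) for rec in alignment.records])
    gaps = seqs == "-"
    n = len(alignment.records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gaps[i] & ~gaps[j]
            m = int(both.sum())
            if m == 0:
                raise IncomparablePairError(
                    alignment.records[i].id, alignment.records[j].id
                )
            mism = int((seqs[i][both] != seqs[j][both]).sum())
            D[i, j] = D[j, i] = mism / m
    return DistanceMatrix([rec.id for rec in alignment.records], D)


def kimura_protein_correction(p: float) -> float:
    """Kimura's distance correction for proteins: ``d = -ln(1 - p - 0.2 p²)``.

    Valid for p < 0.85; beyond that the argument goes non-positive
    (saturation) and a :class:`SaturationError` is raised.
    """
    if not 0 <= p < 0.85:
        raise SaturationError(p)
    return -math.log(1.0 - p - 0.2 * p * p)


def corrected_distances(dm: DistanceMatrix, saturation_cap: float = 5.0) -> DistanceMatrix:
    """Apply the Kimura correction entrywise, capping saturated pairs.

    Pairs with p ≥ 0.85 receive ``saturation_cap`` with a logged warning
    instead of aborting the run.
    """
    n = len(dm.labels)
    out = np.zeros_like(dm.values)
    for i in range(n):
        for j in range(i + 1, n):
            p = dm.values[i, j]
            try:
                d = kimura_protein_correction(p)
            except SaturationError:
                logger.warning(
                    "saturated p-distance %.3f between %s and %s; capped at %.2f",
                    p, dm.labels[i], dm.labels[j], saturation_cap,
                )
                d = saturation_cap
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(dm.labels), out)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Q-criterion minimisation with ties broken by the lowest (i, j) index pair
    in the current agglomeration order; negative branch lengths are clamped
    to zero with a logged warning. The returned tree is unrooted,
    represented with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ConfigurationError("neighbor joining requires at least 3 taxa")
    D = dm.values.astype(float).copy()
    nodes = [Node(name=lbl) for lbl in dm.labels]
    active = list(range(n))

    def clamp(x: float, a: str) -> float:
        if x < 0:
            logger.warning("clamped negative branch length %.4g on %s", x, a or "<internal>")
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        u = Node()
        ni, nj = nodes[i], nodes[j]
        ni.length = clamp(li, ni.name)
        nj.length = clamp(lj, nj.name)
        u.add(ni)
        u.add(nj)
        # distances from the new node
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : -1] = new_row[:-1]
        D[: -1, -1] = new_row[:-1]
        nodes.append(u)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final three-way join
    i, j, k = active
    root = Node()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in zip((i, j, k), (li, lj, lk)):
        nodes[idx].length = clamp(ln, nodes[idx].name)
        root.add(nodes[idx])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Rooting and clade assignment


def _reroot_on_edge(tree: PhyloTree, node: Node, fraction: float = 0.5) -> PhyloTree:
    """Place a new root on the branch above ``node``, splitting its length."""
    if node.parent is None:
        return tree
    old_parent = node.parent
    old_len = node.length
    new_root = Node()
    new_root.add(node)
    prev = new_root
    prev_len = old_len * (1 - fraction)
    node.length = old_len * fraction
    came_from = node
    cur = old_parent
    # walk the old parent chain, re-hanging each node under the new root side
    while cur is not None:
        nxt = cur.parent
        nxt_len = cur.length
        cur.children = [c for c in cur.children if c is not came_from]
        cur.length = prev_len
        cur.parent = None
        prev.add(cur)
        came_from, prev, prev_len, cur = cur, cur, nxt_len, nxt
    # splice out a degree-2 former root
    stack = [new_root]
    while stack:
        nd = stack.pop()
        for ch in list(nd.children):
            if not ch.is_leaf() and len(ch.children) == 1:
                only = ch.children[0]
                only.length += ch.length
                nd.children[nd.children.index(ch)] = only
                only.parent = nd
                stack.append(nd)
                break
        else:
            stack.extend(nd.children)
    node.parent = new_root
    return PhyloTree(new_root)


def _clone(node: Node) -> Node:
    copy = Node(node.name, node.length)
    for ch in node.children:
        copy.add(_clone(ch))
    return copy


def root_on_outgroup(tree: PhyloTree, outgroup: set[str]) -> PhyloTree:
    """Root the tree on the branch above the outgroup's common ancestor.

    The input tree is left untouched; a rooted copy is returned.
    """
    tree = PhyloTree(_clone(tree.root))
    names = set(tree.leaf_names())
    missing = sorted(set(outgroup) - names)
    if missing or not outgroup:
        raise ConfigurationError(f"outgroup leaves missing from tree: {missing}")
    ingroup = sorted(names - set(outgroup))
    if not ingroup:
        raise ConfigurationError("outgroup covers the whole tree")
    # orient the tree from an ingroup leaf so the outgroup is a proper subtree
    tree = _reroot_on_edge(tree, tree.find(ingroup[0]))
    mrca = _mrca(tree, outgroup)
    if set(mrca.leaf_names()) != set(outgroup):
        logger.warning("outgroup is not monophyletic; rooting on its common-ancestor edge")
    if mrca.parent is None:  # outgroup spans the root: root above the ingroup instead
        mrca = _mrca(tree, set(ingroup))
    return _reroot_on_edge(tree, mrca)


def _mrca(tree: PhyloTree, names: set[str]) -> Node:
    paths = []
    for nm in names:
        node = tree.find(nm)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        paths.append(list(reversed(path)))
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        first = paths[0][depth]
        if all(p[depth] is first for p in paths):
            mrca = first
        else:
            break
    return mrca


@dataclass
class CladeAssignment:
    """Query → class labels propagated from reference leaves."""

    assignments: dict[str, str]
    support: dict[str, list[str]] = field(default_factory=dict)
    monophyletic: dict[str, bool] = field(default_factory=dict)


def assign_classes(
    tree: PhyloTree,
    reference_labels: dict[str, str],
    outgroup: set[str],
) -> CladeAssignment:
    """Propagate class labels from labelled reference leaves to query leaves.

    After outgroup rooting, each unlabelled leaf takes the class of the
    smallest rooted clade that contains it together with at least one
    reference leaf — provided all reference leaves in that clade agree;
    a mixed clade yields ``"unassigned"``. Outgroup leaves confer no class.
    """
    rooted = root_on_outgroup(tree, outgroup)
    is_ref = {
        lf.name for lf in rooted.leaves()
        if lf.name in reference_labels and lf.name not in outgroup
    }
    if not is_ref:
        raise ConfigurationError("no reference leaves present outside the outgroup")
    assignments: dict[str, str] = {}
    support: dict[str, list[str]] = {}
    for leaf in rooted.leaves():
        if leaf.name in reference_labels or leaf.name in outgroup:
            continue
        node = leaf.parent
        label = "unassigned"
        refs: list[str] = []
        while node is not None:
            clade_refs = [nm for nm in node.leaf_names() if nm in is_ref]
            if clade_refs:
                classes = {reference_labels[nm] for nm in clade_refs}
                if len(classes) == 1:
                    label = classes.pop()
                    refs = sorted(clade_refs)
                break
            node = node.parent
        assignments[leaf.name] = label
        support[leaf.name] = refs
    mono: dict[str, bool] = {}
    for cls in sorted(set(reference_labels.values())):
        members = {nm for nm in is_ref if reference_labels[nm] == cls}
        if not members:
            continue
        clade = set(_mrca(rooted, members).leaf_names())
        mono[cls] = all(
            reference_labels.get(nm) == cls for nm in clade if nm in is_ref
        )
    return CladeAssignment(assignments, support, mono)


def path_length(tree: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    na, nb = tree.find(a), tree.find(b)
    anc_a = {}
    d = 0.0
    node = na
    while node is not None:
        anc_a[id(node)] = d
        d += node.length
        node = node.parent
    d = 0.0
    node = nb
    while node is not None:
        if id(node) in anc_a:
            return d + anc_a[id(node)]
        d += node.length
        node = node.parent
    raise LabelError(f"{a!r} and {b!r} are not in the same tree")
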