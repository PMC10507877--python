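"""Low-level tree plumbing on top of dendropy.

Everything here is topology bookkeeping: Newick round-trips, split sets,
postorder index arrays for the vectorised algorithms, unrooted topology
enumeration by stepwise addition, and NNI neighbourhoods.  The scientific
algorithms (parsimony, likelihood, reconstruction) live in their own modules
and consume the index arrays produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy
import numpy as np

from .errors import CapabilityError, ContractError, InputError

__all__ = [
    "parse_newick",
    "to_newick",
    "leaf_labels",
    "split_set",
    "rf_distance_splits",
    "IndexedTree",
    "index_tree",
    "enumerate_topology_shapes",
    "shape_to_newick",
    "count_unrooted_topologies",
    "nni_neighbors",
]


def parse_newick(text: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick string into a dendropy Tree.

    Internal-node labels (used for bootstrap supports and progenitor names)
    are kept as plain node labels, not taxa.
    """
    tree = dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True)
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def split_set(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions of the (implicitly unrooted) tree.

    Each split is canonicalised as the frozenset of leaf labels on the side
    *not* containing the lexicographically smallest leaf, so rooted and
    unrooted renderings of the same topology compare equal.
    """
    labels = set(leaf_labels(tree))
    if len(labels) != len(leaf_labels(tree)):
        raise ContractError("duplicate leaf labels in tree")
    anchor = min(labels)
    n = len(labels)
    splits: set[frozenset[str]] = set()
    below: dict[dendropy.Node, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {node.taxon.label}
        else:
            s: set[str] = set()
            for ch in node.child_nodes():
                s |= below[ch]
            below[node] = s
            side = s if anchor not in s else labels - s
            if 2 <= len(side) <= n - 2:
                splits.add(frozenset(side))
    return frozenset(splits)


def has_split(tree: dendropy.Tree, side) -> bool:
    """Whether the bipartition separating ``side`` from the rest is an edge
    of the tree (either orientation)."""
    side = frozenset(side)
    labels = frozenset(leaf_labels(tree))
    return side in split_set(tree) or (labels - side) in split_set(tree)


def rf_distance_splits(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance via the package's own split sets."""
    l1, l2 = set(leaf_labels(t1)), set(leaf_labels(t2))
    if l1 != l2:
        raise InputError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}")
    s1, s2 = split_set(t1), split_set(t2)
    return len(s1 ^ s2)


# ---------------------------------------------------------------------------
# Indexed (array) representation for vectorised traversals
# ---------------------------------------------------------------------------

@dataclass
class IndexedTree:
    """Postorder array view of a tree (root is the last node).

    ``children[i]`` lists child indices of node ``i``; leaves carry their
    taxon label in ``labels`` and their column index into a caller-supplied
    leaf ordering in ``leaf_col``.  ``edge_length[i]`` is the length of the
    edge above node ``i`` (``nan`` for the root).
    """

    nodes: list[dendropy.Node]
    children: list[list[int]]
    parent: np.ndarray
    labels: list[str | None]
    leaf_col: np.ndarray          # -1 for internal nodes
    edge_length: np.ndarray
    leaf_order: list[str]
    node_index: dict[int, int] = field(repr=False, default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_binary(self, allow_root_trifurcation: bool = True) -> bool:
        for i, ch in enumerate(self.children):
            if not ch:
                continue
            if len(ch) == 2:
                continue
            if len(ch) == 3 and allow_root_trifurcation and i == self.root:
                continue
            return False
        return True


def index_tree(tree: dendropy.Tree, leaf_order: Sequence[str] | None = None,
               require_binary: bool = False) -> IndexedTree:
    nodes = list(tree.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    labels: list[str | None] = []
    children: list[list[int]] = []
    parent = np.full(len(nodes), -1, dtype=np.int64)
    edge_length = np.full(len(nodes), np.nan)
    seen_leaves: list[str] = []
    for i, n in enumerate(nodes):
        labels.append(n.taxon.label if n.is_leaf() else n.label)
        children.append([idx[id(c)] for c in n.child_nodes()])
        for c in n.child_nodes():
            parent[idx[id(c)]] = i
        if n.edge.length is not None:
            edge_length[i] = n.edge.length
        if n.is_leaf():
            seen_leaves.append(n.taxon.label)
    if leaf_order is None:
        leaf_order = seen_leaves
    pos = {lab: j for j, lab in enumerate(leaf_order)}
    leaf_col = np.full(len(nodes), -1, dtype=np.int64)
    for i, n in enumerate(nodes):
        if n.is_leaf():
            lab = n.taxon.label
            if lab not in pos:
                raise ContractError(f"tree leaf {lab!r} not in leaf order")
            leaf_col[i] = pos[lab]
    it = IndexedTree(nodes, children, parent, labels, leaf_col, edge_length,
                     list(leaf_order), idx)
    if require_binary and not it.is_binary():
        raise CapabilityError(
            "this operation supports binary trees only (a single "
            "trifurcation at the root of an unrooted tree is allowed)")
    return it


# ---------------------------------------------------------------------------
# Exhaustive enumeration of unrooted binary topologies
# ---------------------------------------------------------------------------
#
# An unrooted binary tree on labels (l0, l1, ..., l_{n-1}) is represented as
# a nested tuple over l1..l_{n-1}; l0 hangs off the root edge.  Stepwise
# addition inserts the next label on every edge (every subtree position,
# including the whole tree), which visits each labelled topology exactly
# once and yields (2n-5)!! shapes in total.

Shape = object  # str leaf or 2-tuple


def _insert_everywhere(shape, label) -> Iterator[object]:
    yield (shape, label)
    if isinstance(shape, tuple):
        left, right = shape
        for nl in _insert_everywhere(left, label):
            yield (nl, right)
        for nr in _insert_everywhere(right, label):
            yield (left, nr)


def enumerate_topology_shapes(labels: Sequence[str]) -> Iterator[object]:
    """Yield every unrooted binary topology on ``labels`` as a nested tuple
    over ``labels[1:]`` (``labels[0]`` is the implicit third root branch)."""
    labels = list(labels)
    if len(labels) < 3:
        raise InputError("need at least 3 labels to enumerate topologies")
    if len(set(labels)) != len(labels):
        raise ContractError("labels must be unique")

    def rec(k: int) -> Iterator[object]:
        if k == 3:
            yield (labels[1], labels[2])
            return
        for smaller in rec(k - 1):
            yield from _insert_everywhere(smaller, labels[k - 1])

    return rec(len(labels))


def _shape_newick(shape) -> str:
    if isinstance(shape, tuple):
        return "(" + _shape_newick(shape[0]) + "," + _shape_newick(shape[1]) + ")"
    return shape


def shape_to_newick(shape, first_label: str) -> str:
    """Render an enumeration shape as an unrooted Newick string with a
    trifurcating pseudo-root."""
    if isinstance(shape, tuple):
        l, r = shape
        return f"({first_label},{_shape_newick(l)},{_shape_newick(r)});"
    return f"({first_label},{shape});"


def count_unrooted_topologies(n: int) -> int:
    """(2n-5)!! unrooted binary topologies on n labelled leaves."""
    if n < 3:
        raise InputError("defined for n >= 3")
    out = 1
    for k in range(4, n + 1):
        out *= 2 * k - 5
    return out


# ---------------------------------------------------------------------------
# NNI neighbourhood (on an adjacency representation of the unrooted tree)
# ---------------------------------------------------------------------------

def _tree_to_adjacency(tree: dendropy.Tree):
    """Unrooted adjacency map {node_id: set(neighbor_ids)} plus leaf labels.

    A degree-2 root of a rooted tree is suppressed so the result is a proper
    unrooted tree.
    """
    t = tree.clone(depth=1)
    t.deroot()
    nodes = list(t.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
    leaf_label: dict[int, str] = {}
    for n in nodes:
        i = idx[id(n)]
        if n.is_leaf():
            leaf_label[i] = n.taxon.label
        for c in n.child_nodes():
            j = idx[id(c)]
            adj[i].add(j)
            adj[j].add(i)
    return adj, leaf_label


def _adjacency_to_newick(adj: dict[int, set[int]],
                         leaf_label: dict[int, str]) -> str:
    start = next(i for i in adj if i not in leaf_label and len(adj[i]) >= 3)

    def sub(node: int, came_from: int) -> str:
        if node in leaf_label:
            return leaf_label[node]
        parts = [sub(nb, node) for nb in sorted(adj[node]) if nb != came_from]
        return "(" + ",".join(parts) + ")"

    parts = [sub(nb, start) for nb in sorted(adj[start])]
    return "(" + ",".join(parts) + ");"


def nni_neighbors(tree: dendropy.Tree) -> list[dendropy.Tree]:
    """All nearest-neighbour-interchange rearrangements of an unrooted
    binary tree (two per internal edge)."""
    adj, leaf_label = _tree_to_adjacency(tree)
    out = []
    seen = set()
    internal_edges = [
        (u, v) for u in adj for v in adj[u]
        if u < v and u not in leaf_label and v not in leaf_label
    ]
    for u, v in internal_edges:
        u_sub = [x for x in adj[u] if x != v]
        v_sub = [x for x in adj[v] if x != u]
        if len(u_sub) != 2 or len(v_sub) != 2:
            raise CapabilityError("NNI requires a binary unrooted tree")
        b = u_sub[1]
        for c in v_sub:
            new = {k: set(s) for k, s in adj.items()}
            new[u].discard(b); new[b].discard(u)
            new[v].discard(c); new[c].discard(v)
            new[u].add(c); new[c].add(u)
            new[v].add(b); new[b].add(v)
            nwk = _adjacency_to_newick(new, leaf_label)
            t = parse_newick(nwk, rooted=False)
            key = split_set(t)
            if key not in seen and key != split_set(tree):
                seen.add(key)
                out.append(t)
    return out
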