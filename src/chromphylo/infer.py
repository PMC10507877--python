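"""Distance-based tree inference and branch support.

The distance between two cell types is the raw count of sites at which
their 0/1 profiles differ -- no proportion, no multiple-hit correction --
and neighbor-joining is run directly on those counts.  Branch support comes
from the nonparametric bootstrap: sites are resampled with replacement, the
chosen method is re-run, and each internal branch of the point-estimate
tree is annotated with the percentage of replicate trees containing its
split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from ._tree import leaf_labels, parse_newick, split_set
from .data import AccessibilityMatrix
from .errors import ConfigurationError, ContractError, InputError

__all__ = [
    "DistanceMatrix", "pairwise_difference_matrix", "nj_tree",
    "root_with_outgroup", "bootstrap_support",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric, hollow, non-negative pairwise distances over named taxa."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.taxa = list(self.taxa)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ContractError(f"distance matrix shape {self.values.shape} != ({n},{n})")
        if len(set(self.taxa)) != n:
            raise ContractError("taxa must be unique")
        if not np.allclose(self.values, self.values.T):
            raise ContractError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ContractError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ContractError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])

    def subset(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.values[np.ix_(idx, idx)])


def pairwise_difference_matrix(matrix: AccessibilityMatrix) -> DistanceMatrix:
    """Count of sites at which each pair of cells differ (raw counts)."""
    if matrix.n_cells < 2 or matrix.n_sites == 0:
        raise InputError("need at least 2 cells and 1 site")
    X = matrix.values.astype(np.int64)
    # d(i,j) = sum |x_i - x_j| for binary columns
    gram = X.T @ X
    ones = X.sum(axis=0)
    d = ones[:, None] + ones[None, :] - 2 * gram
    return DistanceMatrix(matrix.cell_names, d.astype(float))


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining; negative branch-length estimates are
    clamped to zero and the number of clamps is logged and recorded on the
    returned tree (``tree.n_clamped_branches``)."""
    if len(d.taxa) < 3:
        raise InputError("neighbor-joining needs at least 3 taxa")
    skdm = _SkbioDM(d.values, ids=d.taxa)
    newick = str(_skbio_nj(skdm, neg_as_zero=False))
    tree = parse_newick(newick, rooted=False)
    clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            clamped += 1
    if clamped:
        logger.info("nj_tree: clamped %d negative branch length(s) to 0", clamped)
    tree.n_clamped_branches = clamped
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the outgroup's pendant branch, split at its midpoint; the
    ingroup topology is untouched.  Returns a new tree."""
    t = tree.clone(depth=1)
    node = t.find_node_with_taxon_label(outgroup)
    if node is None or not node.is_leaf():
        raise ConfigurationError(f"outgroup {outgroup!r} is not a leaf of the tree")
    edge = node.edge
    half = None if edge.length is None else edge.length / 2.0
    t.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    t.is_rooted = True
    return t


def bootstrap_support(matrix: AccessibilityMatrix, method: str | Callable,
                      B: int = 1000, seed: int = 0,
                      **method_kwargs) -> dendropy.Tree:
    """Bootstrap branch supports for the point-estimate tree.

    ``method`` is "nj", "mp", "ml" or any callable mapping an
    AccessibilityMatrix to a tree.  Supports (percent of replicates
    containing each internal split of the point tree) are written to the
    internal-node labels; the replicate count is stored as
    ``tree.bootstrap_replicates``.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ContractError("bootstrap needs at least one replicate")
    builder = _tree_builder(method, **method_kwargs)
    point = builder(matrix)
    target = {s: 0 for s in split_set(point)}
    rng = np.random.default_rng(seed)
    n = matrix.n_sites
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        rep = AccessibilityMatrix(
            [_renumber(matrix.sites[i], k) for k, i in enumerate(idx)],
            matrix.cells, matrix.values[idx])
        for s in split_set(builder(rep)):
            if s in target:
                target[s] += 1
    _annotate_supports(point, {s: 100.0 * c / B for s, c in target.items()})
    point.bootstrap_replicates = B
    return point


def _renumber(site, k):
    from .data import GenomicInterval
    return GenomicInterval(site.chrom, site.start, site.end,
                           f"{site.site_id}#bs{k}")


def _tree_builder(method, **kw) -> Callable[[AccessibilityMatrix], dendropy.Tree]:
    if callable(method):
        return method
    if method == "nj":
        return lambda m: nj_tree(pairwise_difference_matrix(m))
    if method == "mp":
        from .parsimony import mp_exhaustive

        def mp_builder(m):
            _, trees = mp_exhaustive(m, **kw)
            return trees[0]  # deterministic enumeration order; ties surfaced elsewhere
        return mp_builder
    if method == "ml":
        from .likelihood import ml_search
        return lambda m: ml_search(m, **kw)
    raise ConfigurationError(f"unknown tree method {method!r}")


def _annotate_supports(tree: dendropy.Tree, supports: dict) -> None:
    labels = set(leaf_labels(tree))
    anchor = min(labels)
    n = len(labels)
    below: dict[dendropy.Node, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {node.taxon.label}
            continue
        s: set[str] = set()
        for ch in node.child_nodes():
            s |= below[ch]
        below[node] = s
        side = s if anchor not in s else labels - s
        key = frozenset(side)
        if key in supports and 2 <= len(side) <= n - 2:
            node.label = f"{supports[key]:g}"
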