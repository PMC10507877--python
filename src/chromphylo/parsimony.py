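"""Maximum parsimony for undirected binary characters.

Open->closed and closed->open changes cost the same, so the Fitch algorithm
gives the minimum number of state changes per site.  State sets are encoded
as 2-bit masks (1 = {0}, 2 = {1}, 3 = {0,1}) and all sites are processed at
once as numpy arrays, so scoring a topology is a handful of vector ops.

The exhaustive search enumerates every unrooted binary topology by stepwise
addition ((2n-5)!! of them) and returns *all* co-optimal topologies; ties
are surfaced rather than broken silently.  Above the exhaustive cap, a
nearest-neighbour-interchange hill climb from the neighbor-joining tree is
available as ``mp_search``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import dendropy
import numpy as np

from ._tree import (count_unrooted_topologies, enumerate_topology_shapes,
                    index_tree, nni_neighbors, parse_newick, shape_to_newick)
from .data import AccessibilityMatrix
from .errors import CapabilityError, ConfigurationError, InputError

__all__ = [
    "fitch_length", "fitch_site_scores", "enumerate_topologies",
    "mp_exhaustive", "mp_search", "EXHAUSTIVE_CAP",
]

logger = logging.getLogger(__name__)

#: Largest taxon count for which exhaustive enumeration is attempted
#: ((2n-5)!! = 2,027,025 topologies at n = 10).
EXHAUSTIVE_CAP = 10


def fitch_site_scores(tree: dendropy.Tree, matrix: AccessibilityMatrix) -> np.ndarray:
    """Fitch minimum change count for every site on ``tree``."""
    from ._tree import leaf_labels
    missing = set(leaf_labels(tree)).symmetric_difference(matrix.cell_names)
    if missing:
        raise ConfigurationError(
            f"tree leaves and matrix cells disagree on {sorted(missing)}")
    it = index_tree(tree, leaf_order=matrix.cell_names)
    masks = np.empty((it.n_nodes, matrix.n_sites), dtype=np.uint8)
    score = np.zeros(matrix.n_sites, dtype=np.int64)
    for i in range(it.n_nodes):
        ch = it.children[i]
        if not ch:
            masks[i] = matrix.values[:, it.leaf_col[i]] + 1
            continue
        if len(ch) not in (2, 3) or (len(ch) == 3 and i != it.root):
            raise CapabilityError("Fitch scoring supports binary trees only")
        m = masks[ch[0]]
        for c in ch[1:]:
            inter = m & masks[c]
            union = m | masks[c]
            empty = inter == 0
            score += empty
            m = np.where(empty, union, inter)
        masks[i] = m
    return score


def fitch_length(tree: dendropy.Tree, matrix: AccessibilityMatrix) -> int:
    """Total parsimony score: sum over sites of the Fitch minimum number of
    state changes on the tree."""
    return int(fitch_site_scores(tree, matrix).sum())


def enumerate_topologies(labels: Sequence[str],
                         cap: int = EXHAUSTIVE_CAP):
    """Yield every unrooted binary topology on ``labels`` exactly once as a
    dendropy tree; (2n-5)!! in total."""
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise InputError("topology enumeration needs at least 3 labels")
    if n > cap:
        raise CapabilityError(
            f"{n} taxa would enumerate {count_unrooted_topologies(n):,} "
            f"topologies (cap {cap}); use the heuristic search instead")
    for shape in enumerate_topology_shapes(labels):
        yield parse_newick(shape_to_newick(shape, labels[0]), rooted=False)


def _shape_fitch_total(shape, first_mask: np.ndarray,
                       masks: dict[str, np.ndarray],
                       weights: np.ndarray) -> int:
    """Fitch score of an enumeration shape, summed over (weighted) site
    patterns, without materialising a tree object."""
    score_box = np.zeros(first_mask.shape[0], dtype=np.int64)

    def down(node) -> np.ndarray:
        if isinstance(node, tuple):
            a, b = down(node[0]), down(node[1])
            inter = a & b
            empty = inter == 0
            score_box[...] += empty
            return np.where(empty, a | b, inter)
        return masks[node]

    m = down(shape)
    inter = m & first_mask
    empty = inter == 0
    score_box[...] += empty
    return int(score_box @ weights)


def mp_exhaustive(matrix: AccessibilityMatrix,
                  cap: int = EXHAUSTIVE_CAP) -> tuple[int, list[dendropy.Tree]]:
    """Exhaustive maximum-parsimony search.

    Returns the minimum total Fitch score and *all* topologies attaining it.
    """
    labels = matrix.cell_names
    if len(labels) < 3:
        raise InputError("parsimony search needs at least 3 taxa")
    if len(labels) > cap:
        raise CapabilityError(
            f"{len(labels)} taxa exceed the exhaustive cap ({cap}); "
            "use mp_search (NNI hill climbing) instead")
    # collapse identical site patterns: the Fitch score is additive over
    # sites, so unique patterns weighted by multiplicity suffice
    uniq, counts = np.unique(matrix.values, axis=0, return_counts=True)
    masks = {name: (uniq[:, j].astype(np.uint8) + 1)
             for j, name in enumerate(labels)}
    weights = counts.astype(np.int64)
    first = masks[labels[0]]
    best: int | None = None
    best_shapes: list = []
    for shape in enumerate_topology_shapes(labels):
        s = _shape_fitch_total(shape, first, masks, weights)
        if best is None or s < best:
            best, best_shapes = s, [shape]
        elif s == best:
            best_shapes.append(shape)
    trees = [parse_newick(shape_to_newick(sh, labels[0]), rooted=False)
             for sh in best_shapes]
    return int(best), trees


def mp_search(matrix: AccessibilityMatrix,
              start: dendropy.Tree | None = None) -> tuple[int, dendropy.Tree]:
    """NNI hill climb on the Fitch score, for taxon counts beyond the
    exhaustive cap; starts from the neighbor-joining tree by default."""
    from .infer import nj_tree, pairwise_difference_matrix
    if start is None:
        start = nj_tree(pairwise_difference_matrix(matrix))
    current, cur_score = start, fitch_length(start, matrix)
    logger.warning("mp_search: heuristic NNI search; optimality not guaranteed")
    improved = True
    while improved:
        improved = False
        for cand in nni_neighbors(current):
            s = fitch_length(cand, matrix)
            if s < cur_score:
                current, cur_score = cand, s
                improved = True
                break
    return cur_score, current
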