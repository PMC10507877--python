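"""Ancestral open/closed-state reconstruction on a fixed, outgroup-rooted
topology.

Two estimators are provided, mirroring standard practice:

* Maximum parsimony with the ACCTRAN and DELTRAN resolutions.  Subtree
  change costs are computed by a vectorised Sankoff pass; the preorder
  resolution then either prefers a change on the earliest possible edge
  (ACCTRAN, accelerating changes toward the root) or defers it (DELTRAN),
  while always realising the Fitch minimum number of changes.  When the
  root's state set is ambiguous it is resolved toward the outgroup's
  observed state -- the outgroup is there precisely to polarise changes.

* Marginal maximum likelihood under a fitted two-state model: for each
  internal node and site, the posterior probability of the open state given
  all leaves, combining below- and above-likelihoods and mixing over rate
  categories (including the invariant class) by their per-site posterior
  weights.  Calls are the argmax state, with an exact-tie default for
  "ambiguous" and an optional minimum-posterior threshold mode.

The reconstruction design matches the study setup: branch lengths and model
parameters are fitted from the differentiated cells plus the LSK outgroup
only, and the held-out progenitor profiles validate the node predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
import dendropy
import numpy as np
import pandas as pd

from ._tree import IndexedTree, index_tree, leaf_labels
from .data import AccessibilityMatrix, subset_cells
from .errors import CapabilityError, ConfigurationError, ContractError
from .hematopoiesis import constraint_tree
from .likelihood import (ModelFitResult, SubstitutionModel, _compress,
                         _transition_matrices, ml_fit)

__all__ = [
    "constraint_tree", "fitch_state_sets", "acctran", "deltran",
    "ml_marginals", "call_states", "AncestralEstimate", "reconstruct",
    "AMBIGUOUS",
]

#: Integer code for an ambiguous call in the call tables.
AMBIGUOUS = -1

_BIG = np.int64(1) << 40


def _require_rooted_binary(tree: dendropy.Tree) -> None:
    if not tree.is_rooted:
        raise ContractError("ancestral reconstruction needs a rooted tree")
    for node in tree.preorder_node_iter():
        ch = node.child_nodes()
        if ch and len(ch) != 2:
            raise CapabilityError(
                "ancestral reconstruction supports binary rooted trees only")


def _node_names(it: IndexedTree) -> list[str]:
    names = []
    for i in range(it.n_nodes):
        if it.leaf_col[i] >= 0:
            names.append(it.labels[i])
        elif it.labels[i]:
            names.append(it.labels[i])
        elif i == it.root:
            names.append("root")
        else:
            names.append(f"node{i}")
    return names


def fitch_state_sets(tree: dendropy.Tree, matrix: AccessibilityMatrix):
    """Fitch downpass and uppass (final/MPR) state sets for every node.

    Returns ``(downpass, final, score)``: two DataFrames of state-set
    strings ("0", "1" or "01") indexed by site with one column per node,
    plus the per-site Fitch score.
    """
    _require_rooted_binary(tree)
    order = [l for l in leaf_labels(tree)]
    it = index_tree(tree, leaf_order=order)
    X = matrix.columns(order)
    n_sites = matrix.n_sites
    down = np.empty((it.n_nodes, n_sites), dtype=np.uint8)
    final = np.empty_like(down)
    score = np.zeros(n_sites, dtype=np.int64)
    for i in range(it.n_nodes):
        ch = it.children[i]
        if not ch:
            down[i] = X[:, it.leaf_col[i]] + 1
            continue
        a, b = down[ch[0]], down[ch[1]]
        inter = a & b
        empty = inter == 0
        score += empty
        down[i] = np.where(empty, a | b, inter)
    final[it.root] = down[it.root]
    for i in reversed(range(it.n_nodes)):        # preorder (parents first)
        for c in it.children[i]:
            if not it.children[c]:
                final[c] = down[c]
                continue
            fp, sc = final[i], down[c]
            l, r = down[it.children[c][0]], down[it.children[c][1]]
            subset = (fp & sc) == fp
            was_union = (l & r) == 0
            final[c] = np.where(subset, fp,
                                np.where(was_union, sc | fp, sc | (fp & (l | r))))
    names = _node_names(it)
    text = {1: "0", 2: "1", 3: "01"}
    ids = matrix.site_ids

    def frame(arr):
        return pd.DataFrame({names[i]: [text[v] for v in arr[i]]
                             for i in range(it.n_nodes)}, index=ids)

    return frame(down), frame(final), score


def _sankoff_costs(it: IndexedTree, X: np.ndarray) -> np.ndarray:
    """cost[i, site, s] = minimum changes in the subtree of i given state s."""
    cost = np.zeros((it.n_nodes, X.shape[0], 2), dtype=np.int64)
    for i in range(it.n_nodes):
        ch = it.children[i]
        if not ch:
            obs = X[:, it.leaf_col[i]]
            cost[i, :, 0] = np.where(obs == 0, 0, _BIG)
            cost[i, :, 1] = np.where(obs == 1, 0, _BIG)
            continue
        for c in ch:
            same = cost[c]
            other = cost[c][:, ::-1] + 1
            cost[i] += np.minimum(same, other)
    return cost


def _mp_resolve(tree: dendropy.Tree, matrix: AccessibilityMatrix,
                outgroup: str, accelerate: bool) -> pd.DataFrame:
    _require_rooted_binary(tree)
    order = leaf_labels(tree)
    if outgroup not in order:
        raise ConfigurationError(f"outgroup {outgroup!r} is not a leaf of the tree")
    it = index_tree(tree, leaf_order=order)
    X = matrix.columns(order)
    cost = _sankoff_costs(it, X)
    names = _node_names(it)
    state = np.empty((it.n_nodes, matrix.n_sites), dtype=np.int8)
    og = X[:, order.index(outgroup)]
    root_cost = cost[it.root]
    # root: minimum cost state, ties resolved toward the outgroup's state
    state[it.root] = np.where(root_cost[:, 1] < root_cost[:, 0], 1,
                              np.where(root_cost[:, 0] < root_cost[:, 1], 0, og))
    for i in reversed(range(it.n_nodes)):
        for c in it.children[i]:
            fp = state[i]
            rows = np.arange(matrix.n_sites)
            same = cost[c][rows, fp]
            diff = cost[c][rows, 1 - fp] + 1
            if accelerate:
                change = diff <= same
            else:
                change = diff < same
            state[c] = np.where(change, 1 - fp, fp)
    internal = [i for i in range(it.n_nodes) if it.children[i]]
    return pd.DataFrame({names[i]: state[i] for i in internal},
                        index=matrix.site_ids)


def acctran(tree: dendropy.Tree, matrix: AccessibilityMatrix,
            outgroup: str = "LSK") -> pd.DataFrame:
    """Accelerated-transformation parsimony reconstruction: among the
    minimum-change labelings, changes are placed as close to the root as
    possible (at every preorder branch a change is taken whenever one is
    optional).  Returns internal-node states per site."""
    return _mp_resolve(tree, matrix, outgroup, accelerate=True)


def deltran(tree: dendropy.Tree, matrix: AccessibilityMatrix,
            outgroup: str = "LSK") -> pd.DataFrame:
    """Delayed-transformation parsimony reconstruction: changes are deferred
    toward the tips wherever the minimum-change criterion allows."""
    return _mp_resolve(tree, matrix, outgroup, accelerate=False)


def ml_marginals(tree: dendropy.Tree, model: SubstitutionModel,
                 matrix: AccessibilityMatrix) -> pd.DataFrame:
    """Marginal posterior probability of the open state at every internal
    node for every site, given all leaves.

    ``tree`` must carry fitted branch lengths.  Rate-category mixing uses
    the per-site posterior category weights, with the invariant class
    contributing only to constant patterns (where it pins the node to the
    constant state).
    """
    _require_rooted_binary(tree)
    order = leaf_labels(tree)
    it = index_tree(tree, leaf_order=order)
    brlens = np.nan_to_num(it.edge_length, nan=0.0)
    if np.any(brlens < 0):
        raise ContractError("negative branch length")
    for i in range(it.n_nodes):
        if i != it.root and np.isnan(it.edge_length[i]):
            raise ContractError("tree lacks fitted branch lengths")
    pat = _compress(matrix, order)
    rates, w = model.category_rates_weights()
    K, n_pat = rates.size, pat.states.shape[0]
    pi = model.pi

    # below[i][k, p, s]  = P(data below i | state s at i)
    # msg[c][k, p, s_par] = sum_s P_c(s_par -> s) below[c][s]
    below = np.ones((it.n_nodes, K, n_pat, 2))
    msg = np.zeros_like(below)
    for i in range(it.n_nodes):
        ch = it.children[i]
        if not ch:
            below[i] = 0.0
            below[i, :, np.arange(n_pat), pat.states[:, it.leaf_col[i]]] = 1.0
        else:
            for c in ch:
                below[i] *= msg[c]
        if i != it.root:
            P = _transition_matrices(pi, rates, brlens[i])
            msg[i] = np.einsum("kij,kpj->kpi", P, below[i])

    above = np.empty_like(below)
    above[it.root] = pi[None, None, :]
    for i in reversed(range(it.n_nodes)):
        ch = it.children[i]
        for c in ch:
            sib = np.ones((K, n_pat, 2))
            for b in ch:
                if b is not c:
                    sib *= msg[b]
            P = _transition_matrices(pi, rates, brlens[c])
            above[c] = np.einsum("kij,kpi->kpj", P, above[i] * sib)

    # per-category site likelihoods and total (including invariant class)
    cat_site = np.einsum("kps,s->kp", below[it.root], pi)      # (K, n_pat)
    var_mix = (1.0 - model.p_inv) * np.einsum("k,kp->kp", w, cat_site)
    c0, c1 = pat.constant
    inv0 = model.p_inv * model.pi0 * c0
    inv1 = model.p_inv * model.pi1 * c1
    total = var_mix.sum(axis=0) + inv0 + inv1

    names = _node_names(it)
    internal = [i for i in range(it.n_nodes) if it.children[i]]
    out = {}
    for i in internal:
        joint_open = above[i][..., 1] * below[i][..., 1]       # (K, n_pat)
        num = np.einsum("k,kp->p", w, joint_open) * (1.0 - model.p_inv) + inv1
        out[names[i]] = (num / total)[pat.site_to_pattern]
    return pd.DataFrame(out, index=matrix.site_ids)


def call_states(marginals: pd.DataFrame, tie_tolerance: float = 1e-9,
                threshold: float | None = None) -> pd.DataFrame:
    """Discrete calls from marginal open-probabilities.

    Default: call the argmax state, "ambiguous" (coded ``AMBIGUOUS`` = -1)
    only when P(open) is within ``tie_tolerance`` of 1/2.  If ``threshold``
    is given, any node/site whose winning posterior is below it is also
    ambiguous (sensitivity-analysis mode).
    """
    p = marginals.to_numpy(dtype=float)
    call = (p > 0.5).astype(np.int8)
    amb = np.abs(p - 0.5) <= tie_tolerance
    if threshold is not None:
        amb |= np.maximum(p, 1.0 - p) < threshold
    call[amb] = AMBIGUOUS
    return pd.DataFrame(call, index=marginals.index, columns=marginals.columns)


@dataclass
class AncestralEstimate:
    """Bundle of reconstructions on one fixed topology."""

    tree: dendropy.Tree
    acctran: pd.DataFrame
    deltran: pd.DataFrame
    marginals: pd.DataFrame
    ml_calls: pd.DataFrame
    fit: ModelFitResult

    def calls(self, method: str) -> pd.DataFrame:
        if method == "acctran":
            return self.acctran
        if method == "deltran":
            return self.deltran
        if method == "ml":
            return self.ml_calls
        raise ConfigurationError(f"unknown reconstruction method {method!r}")

    def ambiguous_counts(self) -> pd.Series:
        """Number of ambiguous ML calls per internal node (the sites removed
        from sensitivity/specificity for the ML method)."""
        return (self.ml_calls == AMBIGUOUS).sum(axis=0)


def reconstruct(matrix: AccessibilityMatrix, tree: dendropy.Tree | None = None,
                model_tag: str = "BIN+I+R4", outgroup: str = "LSK",
                tie_tolerance: float = 1e-9, threshold: float | None = None,
                **fit_kw) -> AncestralEstimate:
    """Run all three reconstructions on the fixed (default: constraint)
    topology.

    Branch lengths and model parameters are fitted from the tree's leaf
    columns only; any other columns in ``matrix`` (observed progenitors)
    are ignored here and held out for validation.
    """
    if tree is None:
        tree = constraint_tree()
    leaves = leaf_labels(tree)
    missing = [l for l in leaves if l not in matrix.cell_names]
    if missing:
        raise ConfigurationError(f"matrix lacks tree leaves {missing}")
    leaf_matrix = subset_cells(matrix, leaves)
    fit = ml_fit(tree, leaf_matrix, model_tag, **fit_kw)
    marg = ml_marginals(fit.tree, fit.model, leaf_matrix)
    return AncestralEstimate(
        tree=fit.tree,
        acctran=acctran(tree, leaf_matrix, outgroup),
        deltran=deltran(tree, leaf_matrix, outgroup),
        marginals=marg,
        ml_calls=call_states(marg, tie_tolerance, threshold),
        fit=fit,
    )
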