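"""Two-state likelihood models for binary accessibility characters.

The substitution process is the reversible two-state chain with stationary
frequencies (pi0, pi1) and rate matrix

    Q = mu * [[-pi1, pi1], [pi0, -pi0]],   mu = 1 / (2 pi0 pi1),

scaled so one unit of branch length is one expected state change per site
at relative rate 1.  Transition probabilities are closed form:
P_ij(t) = pi_j + (delta_ij - pi_j) exp(-mu t).

Among-site rate heterogeneity is a finite mixture: an optional invariant
class (+I, rate 0, weight p_inv), a 4-category discrete-gamma class (+G,
category means of Gamma(alpha, alpha)), or n free rate categories with free
weights (+Rn).  Rates are normalised so the expected rate over *all*
classes, including the invariant one, is 1: (1 - p_inv) * sum_k w_k r_k = 1.
That keeps branch lengths comparable across models, and AIC values
internally comparable, even though they need not be bit-identical to any
external tool's parameterisation.

Model fitting is coordinate ascent: a bounded line search per branch, then
scalar searches for pi1, p_inv and alpha (or a bounded quasi-Newton step
for the free rates/weights), each accepted only if it improves the
log-likelihood, so lnL is non-decreasing across sweeps.  Free-parameter
counts for AIC: frequencies 1; +I adds 1; +G adds 1; +Rn adds 2n-2; branch
lengths 2*n_taxa - 3 for every model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import gamma as _gamma_dist

from ._tree import IndexedTree, index_tree, leaf_labels, nni_neighbors
from .data import AccessibilityMatrix
from .errors import (CapabilityError, ConfigurationError, ContractError,
                     InputError)
from .parsimony import enumerate_topologies

__all__ = [
    "MODEL_TAGS", "SubstitutionModel", "ModelFitResult", "site_log_likelihood",
    "log_likelihood", "ml_fit", "select_model_aic", "ml_search",
    "BRANCH_LENGTH_BOUNDS",
]

MODEL_TAGS = ("BIN", "BIN+I", "BIN+I+G", "BIN+I+R4", "BIN+I+R8", "BIN+I+R12")

#: Branch-length search interval (expected changes per site).
BRANCH_LENGTH_BOUNDS = (1e-8, 100.0)


def _discrete_gamma_means(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability categories of Gamma(alpha, alpha)."""
    edges = _gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    upper = _gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    return np.maximum(k * np.diff(upper), 1e-12)


@dataclass
class SubstitutionModel:
    """Parameters of the two-state model plus its rate mixture."""

    pi1: float = 0.5
    p_inv: float = 0.0
    rate_model: str = "single"          # "single" | "gamma" | "free"
    alpha: float = 1.0                  # gamma shape
    n_gamma_cat: int = 4
    rates: np.ndarray | None = None     # free rates (raw; normalised on use)
    weights: np.ndarray | None = None   # free weights (raw; normalised on use)
    tag: str = "BIN"

    def __post_init__(self):
        if not 0.0 < self.pi1 < 1.0:
            raise ContractError("pi1 must lie strictly between 0 and 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ContractError("p_inv must lie in [0, 1)")
        if self.rate_model not in ("single", "gamma", "free"):
            raise ContractError(f"unknown rate model {self.rate_model!r}")
        if self.rate_model == "free":
            r = np.asarray(self.rates, dtype=float)
            w = np.asarray(self.weights, dtype=float)
            if r.shape != w.shape or r.ndim != 1 or r.size < 2:
                raise ContractError("free model needs matching rates/weights (>= 2)")
            if (r < 0).any() or (w <= 0).any():
                raise ContractError("free rates must be >= 0 and weights > 0")
            self.rates, self.weights = r, w

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    @property
    def pi(self) -> np.ndarray:
        return np.array([self.pi0, self.pi1])

    def category_rates_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Variable-class rates and weights, normalised so that
        (1 - p_inv) * sum(w * r) = 1 (invariant class excluded here)."""
        if self.rate_model == "single":
            r, w = np.array([1.0]), np.array([1.0])
        elif self.rate_model == "gamma":
            r = _discrete_gamma_means(self.alpha, self.n_gamma_cat)
            w = np.full(self.n_gamma_cat, 1.0 / self.n_gamma_cat)
        else:
            w = self.weights / self.weights.sum()
            r = self.rates
        mean = float((w * r).sum())
        if mean <= 0:
            raise ContractError("rate mixture has zero mean rate")
        r = r / mean / (1.0 - self.p_inv)
        return r, w

    def n_free_params(self, n_taxa: int) -> int:
        k = 1 + (2 * n_taxa - 3)        # frequencies + branch lengths
        if "+I" in self.tag:
            k += 1
        if self.rate_model == "gamma":
            k += 1
        elif self.rate_model == "free":
            k += 2 * len(self.rates) - 2
        return k

    @classmethod
    def from_tag(cls, tag: str, **kw) -> "SubstitutionModel":
        if tag not in MODEL_TAGS:
            raise ConfigurationError(f"unknown model tag {tag!r}; have {MODEL_TAGS}")
        if tag in ("BIN", "BIN+I"):
            return cls(rate_model="single", tag=tag, **kw)
        if tag == "BIN+I+G":
            return cls(rate_model="gamma", tag=tag, **kw)
        n = int(tag.rsplit("R", 1)[1])
        init = _discrete_gamma_means(1.0, n)
        return cls(rate_model="free", rates=init,
                   weights=np.full(n, 1.0 / n), tag=tag, **kw)


# ---------------------------------------------------------------------------
# Pattern compression and the pruning recursion
# ---------------------------------------------------------------------------

@dataclass
class _Patterns:
    states: np.ndarray        # (n_pat, n_leaves) uint8
    counts: np.ndarray        # (n_pat,)
    leaf_order: list[str]
    site_to_pattern: np.ndarray

    @property
    def constant(self) -> np.ndarray:
        c0 = (self.states == 0).all(axis=1)
        c1 = (self.states == 1).all(axis=1)
        return c0, c1


def _compress(matrix: AccessibilityMatrix, leaf_order: Sequence[str]) -> _Patterns:
    X = matrix.columns(leaf_order)
    uniq, inv, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    return _Patterns(uniq.astype(np.uint8), counts.astype(float),
                     list(leaf_order), inv)


def _transition_matrices(pi: np.ndarray, rates: np.ndarray,
                         t: float) -> np.ndarray:
    """P(t) for every rate category; shape (K, 2, 2)."""
    mu = 1.0 / (2.0 * pi[0] * pi[1])
    decay = np.exp(-mu * rates * t)          # (K,)
    P = np.empty((rates.size, 2, 2))
    P[:] = pi[None, None, :]
    P[:, 0, 0] += decay * pi[1]
    P[:, 0, 1] -= decay * pi[1]
    P[:, 1, 1] += decay * pi[0]
    P[:, 1, 0] -= decay * pi[0]
    return P


def _below_partials(it: IndexedTree, pat: _Patterns, brlens: np.ndarray,
                    pi: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Conditional likelihoods of the data below each node, already
    propagated across the node's own branch for children; shape
    (n_nodes, K, n_pat, 2) of P(below | node state)."""
    K, n_pat = rates.size, pat.states.shape[0]
    L = np.ones((it.n_nodes, K, n_pat, 2))
    for i in range(it.n_nodes):
        ch = it.children[i]
        if not ch:
            col = pat.states[:, it.leaf_col[i]]
            L[i] = 0.0
            L[i, :, np.arange(n_pat), col] = 1.0
            continue
        for c in ch:
            P = _transition_matrices(pi, rates, brlens[c])
            # message from child c: sum_j P[parent_state, j] * L[c][..., j]
            L[i] *= np.einsum("kij,kpj->kpi", P, L[c])
    return L


def _pattern_likelihoods(it: IndexedTree, pat: _Patterns, model: SubstitutionModel,
                         brlens: np.ndarray) -> np.ndarray:
    rates, w = model.category_rates_weights()
    L = _below_partials(it, pat, brlens, model.pi, rates)
    root_var = np.einsum("kps,s->kp", L[it.root], model.pi)
    site = (1.0 - model.p_inv) * np.einsum("k,kp->p", w, root_var)
    if model.p_inv > 0:
        c0, c1 = pat.constant
        site = site + model.p_inv * (c0 * model.pi0 + c1 * model.pi1)
    return site


def _unrooted_view(tree: dendropy.Tree) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.deroot()
    return t


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ContractError("tree has missing branch lengths")
        if edge.length < 0:
            raise ContractError(f"negative branch length {edge.length}")


def log_likelihood(tree: dendropy.Tree, model: SubstitutionModel,
                   matrix: AccessibilityMatrix) -> float:
    """Total log-likelihood of the matrix on ``tree`` (which must carry
    non-negative branch lengths for all leaves in the matrix)."""
    _check_branch_lengths(tree)
    order = leaf_labels(tree)
    pat = _compress(matrix, order)
    it = index_tree(tree, leaf_order=order)
    brlens = np.nan_to_num(it.edge_length, nan=0.0)
    site = _pattern_likelihoods(it, pat, model, brlens)
    if np.any(site <= 0):
        return -np.inf
    return float((pat.counts * np.log(site)).sum())


def site_log_likelihood(tree: dendropy.Tree, model: SubstitutionModel,
                        pattern: Mapping[str, int] | Sequence[int]) -> float:
    """Natural log of one site pattern's likelihood.

    ``pattern`` maps leaf labels to 0/1 states (or is a sequence aligned
    with the tree's leaf order).
    """
    order = leaf_labels(tree)
    if isinstance(pattern, Mapping):
        states = [pattern[l] for l in order]
    else:
        states = list(pattern)
        if len(states) != len(order):
            raise ContractError("pattern length does not match leaf count")
    from .data import CellType, GenomicInterval
    m = AccessibilityMatrix(
        [GenomicInterval("p", 0, 1, "p:0-1")],
        [CellType(l) for l in order],
        np.asarray(states, dtype=np.uint8)[None, :])
    return log_likelihood(tree, model, m)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFitResult:
    """A fitted model on a fixed topology."""

    model: SubstitutionModel
    tree: dendropy.Tree
    lnL: float
    k: int
    converged: bool = True
    n_sweeps: int = 0

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.lnL


def _initial_brlens(it: IndexedTree, pat: _Patterns) -> np.ndarray:
    # crude but scale-aware start: total per-site diversity spread over edges
    p1 = (pat.counts @ pat.states) / pat.counts.sum()
    het = float(np.mean(2 * p1 * (1 - p1)))
    t0 = max(het / max(it.n_nodes - 1, 1), 1e-3)
    out = np.full(it.n_nodes, t0)
    return out


def ml_fit(topology: dendropy.Tree, matrix: AccessibilityMatrix,
           model_tag: str = "BIN", *, empirical_freqs: bool = False,
           max_sweeps: int = 100, tol: float = 1e-6) -> ModelFitResult:
    """Maximum-likelihood fit of branch lengths and model parameters on a
    fixed topology by coordinate ascent.

    The topology is fitted in its unrooted form (2n-3 branch parameters,
    identical for every model so AIC values are comparable); if the input
    was rooted through a leaf (an outgroup), the fitted tree is returned
    rooted the same way with the root placed mid-branch.
    """
    if matrix.n_sites == 0:
        raise InputError("cannot fit on an empty matrix")
    root_leaf = None
    if topology.is_rooted and len(topology.seed_node.child_nodes()) == 2:
        for ch in topology.seed_node.child_nodes():
            if ch.is_leaf():
                root_leaf = ch.taxon.label
    tree = _unrooted_view(topology)
    order = leaf_labels(tree)
    pat = _compress(matrix, order)
    it = index_tree(tree, leaf_order=order, require_binary=True)
    n_taxa = len(order)

    model = SubstitutionModel.from_tag(model_tag)
    emp = float((pat.counts @ pat.states).sum() / (pat.counts.sum() * n_taxa))
    model = replace(model, pi1=min(max(emp, 1e-3), 1 - 1e-3))
    if "+I" in model.tag:
        c0, c1 = pat.constant
        const_frac = float(pat.counts[c0 | c1].sum() / pat.counts.sum())
        model = replace(model, p_inv=min(0.5 * const_frac, 0.5))

    brlens = _initial_brlens(it, pat)
    edges = [i for i in range(it.n_nodes) if i != it.root]
    lo, hi = BRANCH_LENGTH_BOUNDS

    def lnl(m: SubstitutionModel, b: np.ndarray) -> float:
        site = _pattern_likelihoods(it, pat, m, b)
        if np.any(site <= 0) or not np.all(np.isfinite(site)):
            return -np.inf
        return float((pat.counts * np.log(site)).sum())

    # the likelihood saturates for long branches, so a plain bounded search
    # can stall on the flat tail; scan a geometric grid first, then refine
    # around the best grid point
    grid = np.geomspace(lo, hi, 21)

    def line_search(neg, x0):
        xs = np.append(grid, x0)
        vals = [neg(x) for x in xs]
        k = int(np.argmin(vals))
        left = xs[k - 1] if 0 < k < len(grid) else lo
        right = xs[k + 1] if k < len(grid) - 1 else hi
        res = minimize_scalar(lambda u: neg(np.exp(u)),
                              bounds=(np.log(left), np.log(right)),
                              method="bounded", options={"xatol": 1e-9})
        if res.fun <= vals[k]:
            return float(np.exp(res.x)), -float(res.fun)
        return float(xs[k]), -float(vals[k])

    cur = lnl(model, brlens)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        before = cur
        # branch lengths: one edge at a time
        for e in edges:
            def neg(t, e=e):
                b = brlens.copy()
                b[e] = t
                return -lnl(model, b)
            x, val = line_search(neg, brlens[e])
            if val > cur:
                brlens[e] = x
                cur = val
        # stationary frequency
        if not empirical_freqs:
            def neg_pi(x):
                return -lnl(replace(model, pi1=float(x)), brlens)
            res = minimize_scalar(neg_pi, bounds=(1e-4, 1 - 1e-4),
                                  method="bounded", options={"xatol": 1e-8})
            if -res.fun > cur:
                model = replace(model, pi1=float(res.x))
                cur = -res.fun
        # invariant proportion
        if "+I" in model.tag:
            def neg_pinv(x):
                return -lnl(replace(model, p_inv=float(x)), brlens)
            res = minimize_scalar(neg_pinv, bounds=(0.0, 1 - 1e-6),
                                  method="bounded", options={"xatol": 1e-9})
            if -res.fun > cur:
                model = replace(model, p_inv=float(res.x))
                cur = -res.fun
        # rate heterogeneity parameters
        if model.rate_model == "gamma":
            def neg_alpha(x):
                return -lnl(replace(model, alpha=float(np.exp(x))), brlens)
            res = minimize_scalar(neg_alpha, bounds=(np.log(0.05), np.log(100.0)),
                                  method="bounded", options={"xatol": 1e-7})
            if -res.fun > cur:
                model = replace(model, alpha=float(np.exp(res.x)))
                cur = -res.fun
        elif model.rate_model == "free":
            n = model.rates.size
            x0 = np.concatenate([np.log(np.maximum(model.rates, 1e-8)),
                                 np.log(model.weights / model.weights.sum())])

            def neg_free(x):
                m = replace(model, rates=np.exp(x[:n]),
                            weights=np.exp(x[n:] - x[n:].max()))
                return -lnl(m, brlens)
            res = minimize(neg_free, x0, method="L-BFGS-B",
                           bounds=[(-12, 8)] * n + [(-20, 0)] * n,
                           options={"maxiter": 60})
            if -res.fun > cur:
                x = res.x
                model = replace(model, rates=np.exp(x[:n]),
                                weights=np.exp(x[n:] - x[n:].max()))
                cur = -res.fun
        if cur - before < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ml_fit({model_tag}): coordinate ascent did not converge in "
            f"{max_sweeps} sweeps; returning best-so-far", RuntimeWarning)

    for i, e in enumerate(edges):
        it.nodes[e].edge.length = float(brlens[e])
    fitted = tree
    if root_leaf is not None:
        from .infer import root_with_outgroup
        fitted = root_with_outgroup(tree, root_leaf)
    return ModelFitResult(model, fitted, cur, model.n_free_params(n_taxa),
                          converged, sweeps)


def select_model_aic(topology: dendropy.Tree, matrix: AccessibilityMatrix,
                     tags: Sequence[str] = MODEL_TAGS,
                     **fit_kw) -> tuple[ModelFitResult, pd.DataFrame]:
    """Fit every candidate model on the fixed topology and return the
    minimum-AIC fit together with the full comparison table."""
    fits = {tag: ml_fit(topology, matrix, tag, **fit_kw) for tag in tags}
    table = pd.DataFrame(
        [{"model": tag, "lnL": f.lnL, "k": f.k, "AIC": f.aic,
          "converged": f.converged} for tag, f in fits.items()]
    ).sort_values("AIC", kind="stable").reset_index(drop=True)
    best = fits[table.loc[0, "model"]]
    return best, table


def ml_search(matrix: AccessibilityMatrix, model_tag: str = "BIN", *,
              mode: str = "nni", start: dendropy.Tree | None = None,
              exhaustive_cap: int = 8, **fit_kw) -> dendropy.Tree:
    """Search topology space for the maximum-likelihood tree.

    ``mode="nni"`` hill-climbs from the neighbor-joining start tree,
    refitting after each accepted move (lnL never decreases);
    ``mode="exhaustive"`` fits every topology (small taxon counts only).
    The returned tree carries fitted branch lengths and the fit as
    ``tree.ml_result``.
    """
    from .infer import nj_tree, pairwise_difference_matrix
    labels = matrix.cell_names
    if len(labels) < 4:
        raise InputError("ML tree search needs at least 4 taxa")
    if mode == "exhaustive":
        if len(labels) > exhaustive_cap:
            raise CapabilityError(
                f"exhaustive ML search capped at {exhaustive_cap} taxa")
        best = None
        for topo in enumerate_topologies(labels, cap=exhaustive_cap):
            fit = ml_fit(topo, matrix, model_tag, **fit_kw)
            if best is None or fit.lnL > best.lnL:
                best = fit
    elif mode == "nni":
        current = start if start is not None else nj_tree(pairwise_difference_matrix(matrix))
        best = ml_fit(current, matrix, model_tag, **fit_kw)
        improved = True
        while improved:
            improved = False
            for cand in nni_neighbors(best.tree):
                fit = ml_fit(cand, matrix, model_tag, **fit_kw)
                if fit.lnL > best.lnL + 1e-9:
                    best = fit
                    improved = True
                    break
    else:
        raise ConfigurationError(f"unknown search mode {mode!r}")
    tree = best.tree
    tree.ml_result = best
    return tree
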