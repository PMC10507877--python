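"""scikit-learn-style estimator classes over the functional core.

Tree inference is fit-shaped (a matrix of binary characters in, a fitted
tree out), ancestral reconstruction is fit/predict-shaped, and site
classification is transform-shaped, so each is exposed as an estimator
compatible with sklearn's ``get_params``/``set_params``/``clone`` protocol
(fitted attributes carry a trailing underscore).  The module-level
functions in :mod:`chromphylo.infer`, :mod:`chromphylo.parsimony`,
:mod:`chromphylo.likelihood`, :mod:`chromphylo.ancestral` and
:mod:`chromphylo.classify` are the primitives these delegate to.

``X`` is an :class:`~chromphylo.data.AccessibilityMatrix` or a plain
(n_sites, n_cells) binary array accompanied by the ``cells`` parameter.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import ancestral as _anc
from . import classify as _cls
from . import hematopoiesis as hp
from . import infer as _infer
from . import likelihood as _lik
from . import parsimony as _pars
from ._tree import to_newick
from .data import AccessibilityMatrix, CellType, GenomicInterval, subset_cells
from .errors import ConfigurationError

__all__ = [
    "NeighborJoiningTree", "ParsimonyTree", "MaximumLikelihoodTree",
    "AncestralReconstructor", "SiteClassifier",
]


def _as_matrix(X, cells: Sequence[str] | None) -> AccessibilityMatrix:
    if isinstance(X, AccessibilityMatrix):
        return X if cells is None else subset_cells(X, cells)
    X = np.asarray(X)
    if cells is None:
        raise ConfigurationError(
            "plain arrays need the `cells` parameter naming the columns")
    sites = [GenomicInterval("site", i, i + 1, f"site:{i}-{i + 1}")
             for i in range(X.shape[0])]
    return AccessibilityMatrix(sites, [CellType(c) for c in cells], X)


class _TreeEstimator(BaseEstimator):
    """Shared plumbing for estimators whose fit result is a tree."""

    def _finalize(self, tree):
        self.tree_ = tree
        if self.outgroup is not None:
            self.tree_ = _infer.root_with_outgroup(tree, self.outgroup)
        self.newick_ = to_newick(self.tree_)
        return self


class NeighborJoiningTree(_TreeEstimator):
    """Neighbor-joining on raw pairwise character-difference counts.

    Parameters
    ----------
    cells : optional column names when ``X`` is a plain array.
    outgroup : if given, the fitted tree is rooted on that leaf's branch.

    Attributes
    ----------
    distance_matrix_ : the pairwise difference counts used.
    tree_, newick_ : the fitted (possibly rooted) tree.
    """

    def __init__(self, cells: Sequence[str] | None = None,
                 outgroup: str | None = None):
        self.cells = cells
        self.outgroup = outgroup

    def fit(self, X, y=None):
        m = _as_matrix(X, self.cells)
        self.distance_matrix_ = _infer.pairwise_difference_matrix(m)
        return self._finalize(_infer.nj_tree(self.distance_matrix_))


class ParsimonyTree(_TreeEstimator):
    """Exhaustive maximum parsimony with undirected binary characters.

    All co-optimal topologies are kept in ``trees_``; ``tree_`` is the
    first in deterministic enumeration order.
    """

    def __init__(self, cells: Sequence[str] | None = None,
                 outgroup: str | None = None,
                 exhaustive_cap: int = _pars.EXHAUSTIVE_CAP):
        self.cells = cells
        self.outgroup = outgroup
        self.exhaustive_cap = exhaustive_cap

    def fit(self, X, y=None):
        m = _as_matrix(X, self.cells)
        self.best_score_, self.trees_ = _pars.mp_exhaustive(
            m, cap=self.exhaustive_cap)
        return self._finalize(self.trees_[0])


class MaximumLikelihoodTree(_TreeEstimator):
    """Maximum-likelihood tree under the two-state model.

    ``model="auto"`` selects among the six candidate models by AIC on the
    starting (neighbor-joining) topology before the topology search.
    """

    def __init__(self, model: str = "BIN+I+R4", search: str = "nni",
                 cells: Sequence[str] | None = None,
                 outgroup: str | None = None):
        self.model = model
        self.search = search
        self.cells = cells
        self.outgroup = outgroup

    def fit(self, X, y=None):
        m = _as_matrix(X, self.cells)
        tag = self.model
        if tag == "auto":
            start = _infer.nj_tree(_infer.pairwise_difference_matrix(m))
            best, self.aic_table_ = _lik.select_model_aic(start, m)
            tag = best.model.tag
        self.model_tag_ = tag
        tree = _lik.ml_search(m, tag, mode=self.search)
        self.fit_result_ = tree.ml_result
        self.lnL_ = self.fit_result_.lnL
        return self._finalize(tree)


class AncestralReconstructor(BaseEstimator):
    """Ancestral open/closed states on a fixed outgroup-rooted topology.

    ``fit`` fits the substitution model and branch lengths from the tree's
    leaf columns; ``predict`` returns the per-node calls of the requested
    method ("acctran", "deltran" or "ml").
    """

    def __init__(self, tree_newick: str | None = None,
                 model: str = "BIN+I+R4", outgroup: str = hp.STEM,
                 tie_tolerance: float = 1e-9,
                 threshold: float | None = None):
        self.tree_newick = tree_newick
        self.model = model
        self.outgroup = outgroup
        self.tie_tolerance = tie_tolerance
        self.threshold = threshold

    def fit(self, X, y=None, cells: Sequence[str] | None = None):
        from ._tree import parse_newick
        m = _as_matrix(X, cells)
        tree = None if self.tree_newick is None \
            else parse_newick(self.tree_newick, rooted=True)
        self.estimate_ = _anc.reconstruct(
            m, tree=tree, model_tag=self.model, outgroup=self.outgroup,
            tie_tolerance=self.tie_tolerance, threshold=self.threshold)
        self.tree_ = self.estimate_.tree
        self.marginals_ = self.estimate_.marginals
        self.lnL_ = self.estimate_.fit.lnL
        return self

    def predict(self, method: str = "ml"):
        return self.estimate_.calls(method)


class SiteClassifier(TransformerMixin, BaseEstimator):
    """Per-site, per-path STABLE/UP/DOWN/OTHER labelling as a transformer.

    ``transform`` maps an accessibility matrix to the label table; the
    fitted attributes expose the per-path tallies and the derived masks.
    """

    def __init__(self, paths: Mapping[str, Sequence[str]] | None = None):
        self.paths = paths

    def fit(self, X, y=None):
        paths = self.paths if self.paths is not None else hp.LINEAGE_PATHS
        m = X if isinstance(X, AccessibilityMatrix) else _as_matrix(X, None)
        self.result_ = _cls.classify_matrix(m, paths)
        self.counts_ = self.result_.counts
        self.summary_ = _cls.summarize_across_paths(self.result_)
        self.other_mask_ = _cls.other_site_mask(self.result_)
        self.stable_everywhere_mask_ = _cls.stable_everywhere_mask(self.result_)
        return self

    def transform(self, X):
        self.fit(X)
        return self.result_.labels
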