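"""Validation and treelikeness metrics.

* Sensitivity/specificity of predicted internal-node states against the
  observed progenitor profiles, with "open" (1) as the positive class.
  Sites with ambiguous calls and sites STABLE on every lineage are excluded
  from the counts; the exclusion bookkeeping (including the overlap between
  the two masks, which is removed once but reported) is part of the result.

* Delta-plots: for each quartet, the three pairwise-distance sums
  m1 >= m2 >= m3 give delta = (m1 - m2) / (m1 - m3), ranging from 0
  (perfectly treelike: the four-point condition holds with a clear winner)
  to 1 (maximal conflict).  When all three sums are equal the quartet is
  treated as perfectly treelike (delta = 0), the limit-consistent choice.
  Both the per-quartet values and aggregate means are reported; no single
  scalar is privileged.

* Lineage-specific branch-change site selection (e.g. open-to-closed from
  LSK to CMP with no change on any other myeloid step) and Robinson-Foulds
  topology distances for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from ._tree import rf_distance_splits
from .data import AccessibilityMatrix
from .errors import ConfigurationError, ContractError, InputError
from .infer import DistanceMatrix

__all__ = [
    "ConfusionSummary", "sensitivity_specificity", "QuartetDelta",
    "quartet_delta", "delta_scores", "DeltaSummary", "branch_change_sites",
    "rf_distance",
]


@dataclass
class ConfusionSummary:
    """Prediction-vs-observation counts for one internal node."""

    node: str
    tp: int
    fp: int
    tn: int
    fn: int
    n_removed_ambiguous: int
    n_removed_stable: int
    n_removed_overlap: int

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    def as_dict(self) -> dict:
        return {"node": self.node, "TP": self.tp, "FP": self.fp,
                "TN": self.tn, "FN": self.fn,
                "n_evaluated": self.n_evaluated,
                "n_removed_ambiguous": self.n_removed_ambiguous,
                "n_removed_stable": self.n_removed_stable,
                "n_removed_overlap": self.n_removed_overlap,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def sensitivity_specificity(predicted: Sequence[int], observed: Sequence[int],
                            ambiguous_mask: Sequence[bool] | None = None,
                            stable_mask: Sequence[bool] | None = None,
                            node: str = "?") -> ConfusionSummary:
    """Confusion counts of predicted vs observed states, positive = open.

    ``predicted`` may contain the ambiguous code (-1); those sites are
    excluded (equivalently supplied via ``ambiguous_mask``).  ``stable_mask``
    flags sites STABLE on all lineages, excluded as uninformative.
    """
    pred = np.asarray(predicted)
    obs = np.asarray(observed)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ContractError("predicted and observed must be 1-D and equal length")
    amb = np.zeros(pred.shape, dtype=bool) if ambiguous_mask is None \
        else np.asarray(ambiguous_mask, dtype=bool)
    stab = np.zeros(pred.shape, dtype=bool) if stable_mask is None \
        else np.asarray(stable_mask, dtype=bool)
    if amb.shape != pred.shape or stab.shape != pred.shape:
        raise ContractError("mask length mismatch")
    amb = amb | (pred == -1)
    keep = ~(amb | stab)
    overlap = int((amb & stab).sum())
    p, o = pred[keep], obs[keep]
    return ConfusionSummary(
        node=node,
        tp=int(((p == 1) & (o == 1)).sum()),
        fp=int(((p == 1) & (o == 0)).sum()),
        tn=int(((p == 0) & (o == 0)).sum()),
        fn=int(((p == 0) & (o == 1)).sum()),
        n_removed_ambiguous=int(amb.sum()) - overlap,
        n_removed_stable=int(stab.sum()) - overlap,
        n_removed_overlap=overlap,
    )


@dataclass
class QuartetDelta:
    """Delta statistic for one quartet of taxa."""

    quartet: tuple[str, str, str, str]
    m1: float
    m2: float
    m3: float

    @property
    def delta(self) -> float:
        if self.m1 == self.m3:
            return 0.0
        return (self.m1 - self.m2) / (self.m1 - self.m3)


def quartet_delta(d: DistanceMatrix, quartet: Sequence[str]) -> QuartetDelta:
    """Delta of one quartet from the three pairwise-sum pairings."""
    q = tuple(quartet)
    if len(q) != 4 or len(set(q)) != 4:
        raise ContractError("a quartet needs 4 distinct taxa")
    a, b, c, e = q
    sums = sorted([d.get(a, b) + d.get(c, e),
                   d.get(a, c) + d.get(b, e),
                   d.get(a, e) + d.get(b, c)], reverse=True)
    return QuartetDelta(q, *sums)


@dataclass
class DeltaSummary:
    """All quartet deltas over a taxon subset plus the aggregates."""

    quartets: list[QuartetDelta]

    @property
    def values(self) -> np.ndarray:
        return np.array([q.delta for q in self.quartets])

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def per_taxon_mean(self) -> pd.Series:
        """Mean delta over the quartets containing each taxon (the per-taxon
        delta-bar reported by delta-plot implementations)."""
        taxa = sorted({t for q in self.quartets for t in q.quartet})
        out = {}
        for t in taxa:
            vals = [q.delta for q in self.quartets if t in q.quartet]
            out[t] = float(np.mean(vals))
        return pd.Series(out, name="delta_bar")


def delta_scores(d: DistanceMatrix, taxa: Sequence[str]) -> DeltaSummary:
    """Delta for every 4-subset of ``taxa`` (C(n,4) quartets)."""
    taxa = list(taxa)
    if len(taxa) < 4:
        raise InputError("delta scores need at least 4 taxa")
    missing = [t for t in taxa if t not in d.taxa]
    if missing:
        raise ConfigurationError(f"taxa {missing} absent from the distance matrix")
    return DeltaSummary([quartet_delta(d, q) for q in combinations(taxa, 4)])


_DIRECTIONS = {"open_to_closed": (1, 0), "closed_to_open": (0, 1)}


def branch_change_sites(matrix: AccessibilityMatrix, parent: str, child: str,
                        direction: str,
                        unchanged_in: Sequence[tuple[str, str]] = ()) -> list[str]:
    """Sites changing ``parent`` -> ``child`` in the given direction while
    every (parent, child) step in ``unchanged_in`` is constant.

    This is the lineage-specific change selection (e.g. open-to-closed from
    LSK to CMP with no change elsewhere in the myeloid hierarchy).
    """
    if direction not in _DIRECTIONS:
        raise ConfigurationError(
            f"direction must be one of {sorted(_DIRECTIONS)}")
    before, after = _DIRECTIONS[direction]
    sel = (matrix.column(parent) == before) & (matrix.column(child) == after)
    for p, c in unchanged_in:
        sel &= matrix.column(p) == matrix.column(c)
    ids = np.array(matrix.site_ids, dtype=object)
    return list(ids[sel])


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: non-trivial splits present in exactly one
    of the two trees (rooted trees are compared as unrooted)."""
    return rf_distance_splits(t1, t2)
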