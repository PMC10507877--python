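"""Site time-course classification along differentiation paths.

Each site's ordered open/closed states along one stem-to-terminal path fall
into four classes: STABLE (constant), UP (monotone gain of accessibility,
pattern 0...01...1), DOWN (monotone loss), and OTHER (non-monotone, i.e. at
least one gain and one loss along the path).  "Gradual" opening/closing is
formalised as monotone with at least one change -- for a binary sequence
that means exactly one transition point -- which is the only reading under
which a two-step path can never be OTHER.

The cross-path summary uses the precedence OTHER > mixed UP/DOWN > STABLE:
a site is summarised OTHER if it is OTHER on any path, STABLE only if it is
STABLE on every path, and otherwise carries the set of non-stable directions
seen across paths ("UP", "DOWN" or "UP+DOWN").
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import AccessibilityMatrix
from .errors import ConfigurationError, ContractError

__all__ = [
    "SiteClass", "ClassificationResult", "classify_path", "classify_states",
    "classify_matrix", "summarize_across_paths", "other_site_mask",
    "stable_everywhere_mask",
]


class SiteClass(str, Enum):
    STABLE = "STABLE"
    UP = "UP"
    DOWN = "DOWN"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_states(states: np.ndarray) -> np.ndarray:
    """Vectorised classification of many sites along one path.

    ``states`` has shape (n_sites, path_length) with entries in {0,1};
    returns an object array of :class:`SiteClass`.
    """
    states = np.asarray(states)
    if states.ndim != 2 or states.shape[1] < 2:
        raise ContractError("need a 2-D array with path length >= 2")
    if states.size and not np.isin(states, (0, 1)).all():
        raise ContractError("states must be 0 or 1")
    diffs = np.diff(states.astype(np.int8), axis=1)
    has_up = (diffs == 1).any(axis=1)
    has_down = (diffs == -1).any(axis=1)
    out = np.empty(states.shape[0], dtype=object)
    out[~has_up & ~has_down] = SiteClass.STABLE
    out[has_up & ~has_down] = SiteClass.UP
    out[~has_up & has_down] = SiteClass.DOWN
    out[has_up & has_down] = SiteClass.OTHER
    return out


def classify_path(states: Sequence[int]) -> SiteClass:
    """Classify one ordered binary state sequence along a path."""
    arr = np.asarray(list(states))
    if arr.ndim != 1 or arr.shape[0] < 2:
        raise ContractError("a path needs at least 2 states")
    return classify_states(arr[None, :])[0]


@dataclass
class ClassificationResult:
    """Per-site, per-path labels plus per-path tallies."""

    labels: pd.DataFrame      # index: site_id, columns: path names, values: SiteClass
    counts: pd.DataFrame      # index: path names, columns: the four classes

    @property
    def paths(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def n_sites(self) -> int:
        return len(self.labels)


def classify_matrix(matrix: AccessibilityMatrix,
                    paths: Mapping[str, Sequence[str]]) -> ClassificationResult:
    """Label every (site, path) pair and tally classes per path."""
    labels = {}
    for name, path in paths.items():
        missing = [c for c in path if c not in matrix.cell_names]
        if missing:
            raise ConfigurationError(
                f"path {name!r} references cells {missing} absent from the matrix")
        labels[name] = classify_states(matrix.columns(path))
    lab = pd.DataFrame(labels, index=matrix.site_ids)
    order = [c.value for c in SiteClass]
    counts = pd.DataFrame(
        {p: lab[p].map(lambda c: c.value).value_counts().reindex(order, fill_value=0)
         for p in lab.columns}).T
    counts.columns.name = "class"
    return ClassificationResult(lab, counts)


def summarize_across_paths(result: ClassificationResult) -> pd.Series:
    """One summary label per site across all paths.

    OTHER on any path dominates; STABLE requires STABLE everywhere; the
    remaining sites record which non-stable directions occur ("UP", "DOWN"
    or "UP+DOWN").
    """
    lab = result.labels
    is_other = (lab == SiteClass.OTHER).any(axis=1)
    is_stable = (lab == SiteClass.STABLE).all(axis=1)
    has_up = (lab == SiteClass.UP).any(axis=1)
    has_down = (lab == SiteClass.DOWN).any(axis=1)
    out = pd.Series("STABLE", index=lab.index, dtype=object, name="summary")
    out[has_up & ~has_down] = "UP"
    out[~has_up & has_down] = "DOWN"
    out[has_up & has_down] = "UP+DOWN"
    out[is_other] = "OTHER"
    out[is_stable] = "STABLE"
    return out


def other_site_mask(result: ClassificationResult) -> np.ndarray:
    """True for sites that are OTHER on at least one path (the sites removed
    in the "without OTHER" analysis variants)."""
    return (result.labels == SiteClass.OTHER).any(axis=1).to_numpy()


def stable_everywhere_mask(result: ClassificationResult) -> np.ndarray:
    """True for sites STABLE on every path (uninformative sites removed
    before validating ancestral reconstructions)."""
    return (result.labels == SiteClass.STABLE).all(axis=1).to_numpy()
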