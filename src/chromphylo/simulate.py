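"""Synthetic binary accessibility matrices with known ground truth.

The generator produces site x cell matrices down a known differentiation
tree so that every downstream stage (classification, tree inference,
ancestral reconstruction, validation) can be tested against recorded truth.
It is the minimal process producing the four observable site time-course
classes:

* STABLE_open / STABLE_closed sites are constant across all cells.
* UP sites start closed at the root and gain accessibility by exactly one
  0->1 event on a single branch (uniformly chosen by default), with no
  reversals; DOWN sites are the mirror image.  Single-event sites make the
  true ancestral states analytically recoverable and make the pairwise
  difference counts exactly tree-additive.
* OTHER sites start from a random root state and flip independently on each
  branch with probability ``other_flip_rate``; realisations that are still
  monotone on every observed lineage path are rejected and resampled, so
  OTHER sites are genuinely non-monotone (and, at useful flip rates,
  homoplasious).

Branch choice for the single UP/DOWN event is uniform over branches unless
explicit weights are given; the known hierarchy carries no branch-length
information that would justify anything else.

The observed matrix contains the stem cell, the named progenitors and the
terminal cells; nodes listed as unobserved (the lymphoid progenitor, by
default) are excluded from the emitted columns but their true states are
still recorded in the truth sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from . import hematopoiesis as hp
from ._tree import index_tree, parse_newick, to_newick
from .classify import SiteClass, classify_states
from .data import (AccessibilityMatrix, CellType, GenomicInterval,
                   write_accessibility_table)
from .errors import ConfigurationError

__all__ = [
    "DEFAULT_CLASS_MIX", "SimulationConfig", "SyntheticTruth",
    "simulate_matrix", "write_vision_like_table", "path_branches",
    "reference_topology",
]

#: Default generating-class proportions.  Chosen so the realised per-path
#: tallies loosely resemble the published myeloid lineage summaries (UP a
#: few-to-ten percent, DOWN somewhat more, OTHER roughly a quarter to a
#: third); these are approximations of figure-level summaries, not a
#: calibration.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "STABLE_open": 0.10,
    "STABLE_closed": 0.35,
    "UP": 0.12,
    "DOWN": 0.16,
    "OTHER": 0.27,
}

_CLASSES = tuple(DEFAULT_CLASS_MIX)


@dataclass
class SimulationConfig:
    """Parameters of the generative process.

    ``tree`` is a rooted differentiation tree whose internal nodes are
    labelled; ``class_mix`` gives proportions for the five generating
    classes (must sum to 1); ``event_branch_weights`` optionally biases the
    branch carrying the single UP/DOWN event (default uniform);
    ``other_flip_rate`` is the per-branch flip probability for OTHER sites.
    ``n_progenitor_only`` extra sites open at ``progenitor_only_node`` and
    closed everywhere else are appended after the ``n_sites`` mixture sites
    (they exercise the in-principle limits of reconstruction).
    """

    tree: str = hp.DIFFERENTIATION_NEWICK
    n_sites: int = 2000
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    event_branch_weights: Mapping[str, float] | None = None
    other_flip_rate: float = 0.25
    unobserved_nodes: tuple[str, ...] = ("Lym",)
    n_progenitor_only: int = 0
    progenitor_only_node: str = "CMP"
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 0 or self.n_progenitor_only < 0:
            raise ConfigurationError("site counts must be non-negative")
        unknown = set(self.class_mix) - set(_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown site classes {sorted(unknown)}")
        probs = np.array([float(self.class_mix.get(c, 0.0)) for c in _CLASSES])
        if (probs < 0).any() or (probs > 1).any():
            raise ConfigurationError("class proportions must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class proportions must sum to 1 (got {probs.sum()!r})")
        if not 0.0 <= self.other_flip_rate <= 1.0:
            raise ConfigurationError("other_flip_rate must lie in [0, 1]")
        if self.class_mix.get("OTHER", 0.0) > 0 and self.other_flip_rate == 0.0:
            raise ConfigurationError(
                "OTHER sites are unsatisfiable with other_flip_rate = 0")


@dataclass
class SyntheticTruth:
    """Everything the generator knows that an analyst would not.

    ``ancestral_states``: true 0/1 state of every internal node per site
    (including unobserved progenitors).  ``class_labels``: the generating
    per-path label for each site.  ``site_class``: the per-site generating
    class (one of the five mixture classes or ``PROGENITOR_ONLY``).
    ``events``: one row per state-change event placed on a branch, with a
    flag for events on branches incident to the root, where the outgroup
    alone cannot polarise the change.
    """

    tree: str
    ancestral_states: pd.DataFrame
    class_labels: pd.DataFrame
    site_class: pd.Series
    events: pd.DataFrame
    seed: int

    def events_for_site(self, site_id: str) -> pd.DataFrame:
        return self.events[self.events["site_id"] == site_id]


def _tree_machinery(config: SimulationConfig):
    tree = parse_newick(config.tree, rooted=True)
    it = index_tree(tree)
    names = []
    for i, node in enumerate(it.nodes):
        name = it.labels[i]
        if name is None:
            raise ConfigurationError("every node of the generating tree must be labelled")
        names.append(name)
    if len(set(names)) != len(names):
        raise ConfigurationError("node names in the generating tree must be unique")
    root = it.root
    branches = [i for i in range(it.n_nodes) if i != root]  # branch above node i
    # descendant sets (indices at/below each node)
    desc: list[list[int]] = [[] for _ in range(it.n_nodes)]
    for i in range(it.n_nodes):
        desc[i].append(i)
        for c in it.children[i]:
            desc[i].extend(desc[c])
    # observed root-to-leaf paths (unobserved node names dropped)
    unobserved = set(config.unobserved_nodes)
    paths: dict[str, list[str]] = {}
    full_paths: dict[str, list[int]] = {}
    for i in range(it.n_nodes):
        if it.children[i]:
            continue
        chain = [i]
        while it.parent[chain[-1]] != -1:
            chain.append(int(it.parent[chain[-1]]))
        chain.reverse()
        full_paths[names[i]] = chain
        paths[names[i]] = [names[j] for j in chain if names[j] not in unobserved]
    observed = [names[i] for i in range(it.n_nodes) if names[i] not in unobserved]
    # column order: root first, then internal nodes, then leaves (preorder-ish)
    order = [root] + [i for i in range(it.n_nodes) if i != root and it.children[i]] \
        + [i for i in range(it.n_nodes) if not it.children[i]]
    observed_order = [names[i] for i in order if names[i] not in unobserved]
    internal = [i for i in range(it.n_nodes) if it.children[i]]
    return tree, it, names, branches, desc, paths, full_paths, observed_order, internal


def path_branches(config: SimulationConfig, terminal: str) -> list[str]:
    """Names of the branches (child-node names) on the root->terminal path;
    the exact enumeration basis for per-path event probabilities."""
    _, it, names, _, _, _, full_paths, _, _ = _tree_machinery(config)
    if terminal not in full_paths:
        raise ConfigurationError(f"unknown terminal {terminal!r}")
    return [names[j] for j in full_paths[terminal][1:]]


def reference_topology(config: SimulationConfig) -> "dendropy.Tree":
    """The generating topology over the leaves an analyst sees: the root
    (stem cell) becomes a leaf attached where it stood, internal structure
    is preserved, labels are dropped.  This is the reference for
    Robinson-Foulds recovery comparisons against inferred trees."""
    tree = parse_newick(config.tree, rooted=True)
    root = tree.seed_node
    root_name = root.label or (root.taxon.label if root.taxon else None)
    if root_name is None:
        raise ConfigurationError("generating tree root must be named")

    def sub(node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "(" + ",".join(sub(c) for c in node.child_nodes()) + ")"

    parts = [root_name] + [sub(c) for c in root.child_nodes()]
    return parse_newick("(" + ",".join(parts) + ");", rooted=False)


def _roles(name: str) -> str:
    return hp.CELL_ROLES.get(name, "terminal")


def simulate_matrix(config: SimulationConfig) -> tuple[AccessibilityMatrix, SyntheticTruth]:
    """Draw a matrix plus its ground truth; identical config => identical output."""
    config.validate()
    (tree, it, names, branches, desc, paths, full_paths,
     observed_order, internal) = _tree_machinery(config)
    rng = np.random.default_rng(config.seed)
    root = it.root

    if config.event_branch_weights is None:
        weights = np.full(len(branches), 1.0 / len(branches))
    else:
        unknown = set(config.event_branch_weights) - {names[b] for b in branches}
        if unknown:
            raise ConfigurationError(f"unknown branches in weights: {sorted(unknown)}")
        weights = np.array([float(config.event_branch_weights.get(names[b], 0.0))
                            for b in branches])
        if (weights < 0).any() or weights.sum() <= 0:
            raise ConfigurationError("branch weights must be non-negative, not all zero")
        weights = weights / weights.sum()

    probs = [float(config.class_mix.get(c, 0.0)) for c in _CLASSES]
    site_classes = rng.choice(_CLASSES, size=config.n_sites, p=probs)

    n_total = config.n_sites + config.n_progenitor_only
    states = np.zeros((n_total, it.n_nodes), dtype=np.uint8)
    path_names = list(paths)
    labels = np.empty((n_total, len(path_names)), dtype=object)
    events: list[tuple[int, str, str, bool]] = []  # site_idx, branch, direction, root_adjacent

    path_branch_sets = {p: set(full_paths[p][1:]) for p in path_names}
    max_attempts = 10_000

    for s in range(config.n_sites):
        cls = site_classes[s]
        if cls == "STABLE_open":
            states[s, :] = 1
            labels[s, :] = SiteClass.STABLE
        elif cls == "STABLE_closed":
            labels[s, :] = SiteClass.STABLE
        elif cls in ("UP", "DOWN"):
            b = branches[rng.choice(len(branches), p=weights)]
            gain = cls == "UP"
            if gain:
                states[s, desc[b]] = 1
            else:
                states[s, :] = 1
                states[s, desc[b]] = 0
            events.append((s, names[b], "gain" if gain else "loss",
                           it.parent[b] == root))
            for j, p in enumerate(path_names):
                on_path = b in path_branch_sets[p]
                labels[s, j] = (SiteClass.UP if gain else SiteClass.DOWN) \
                    if on_path else SiteClass.STABLE
        else:  # OTHER: rejection-sample until non-monotone on >= 1 observed path
            for _ in range(max_attempts):
                root_state = int(rng.integers(0, 2))
                flips = rng.random(len(branches)) < config.other_flip_rate
                node_states = np.empty(it.n_nodes, dtype=np.uint8)
                node_states[root] = root_state
                flip_of = dict(zip(branches, flips))
                # propagate root -> leaves (postorder guarantees parent index
                # > child index, so the reversed walk sets parents first)
                for i in reversed(range(it.n_nodes)):
                    if i == root:
                        continue
                    node_states[i] = node_states[it.parent[i]] ^ int(flip_of[i])
                # classification uses observed columns only
                obs_seqs = {
                    p: node_states[[j for j in full_paths[p]
                                    if names[j] not in config.unobserved_nodes]]
                    for p in path_names}
                lab = {p: classify_states(obs_seqs[p][None, :])[0] for p in path_names}
                if any(v == SiteClass.OTHER for v in lab.values()):
                    states[s, :] = node_states
                    for j, p in enumerate(path_names):
                        labels[s, j] = lab[p]
                    for b in branches:
                        if flip_of[b]:
                            direction = "gain" if node_states[b] == 1 else "loss"
                            events.append((s, names[b], direction,
                                           it.parent[b] == root))
                    break
            else:
                raise ConfigurationError(
                    "could not realise an OTHER site; other_flip_rate too low "
                    "or all observed paths too short")

    # progenitor-only sites: open at one internal node, closed everywhere else
    if config.n_progenitor_only:
        try:
            node = names.index(config.progenitor_only_node)
        except ValueError:
            raise ConfigurationError(
                f"unknown progenitor node {config.progenitor_only_node!r}")
        for s in range(config.n_sites, n_total):
            states[s, node] = 1
            events.append((s, names[node], "gain", it.parent[node] == root))
            for c in it.children[node]:
                events.append((s, names[c], "loss", False))
            for j, p in enumerate(path_names):
                obs = states[s, [k for k in full_paths[p]
                                 if names[k] not in config.unobserved_nodes]]
                labels[s, j] = classify_states(obs[None, :])[0]

    site_class = pd.Series(
        list(site_classes) + ["PROGENITOR_ONLY"] * config.n_progenitor_only,
        name="site_class")

    sites = [GenomicInterval("chr1", i * 1000, i * 1000 + 300,
                             f"chr1:{i * 1000}-{i * 1000 + 300}")
             for i in range(n_total)]
    site_ids = [s.site_id for s in sites]
    site_class.index = site_ids

    name_to_idx = {n: i for i, n in enumerate(names)}
    cells = [CellType(n, _roles(n)) for n in observed_order]
    values = states[:, [name_to_idx[n] for n in observed_order]]
    matrix = AccessibilityMatrix(sites, cells, values)

    anc = pd.DataFrame({names[i]: states[:, i] for i in internal}, index=site_ids)
    class_labels = pd.DataFrame(labels, index=site_ids, columns=path_names)
    ev = pd.DataFrame(events, columns=["site_index", "branch", "direction",
                                       "root_adjacent"])
    ev.insert(1, "site_id", [site_ids[i] for i in ev["site_index"]])
    truth = SyntheticTruth(to_newick(tree), anc, class_labels, site_class, ev,
                           config.seed)
    return matrix, truth


def write_vision_like_table(matrix: AccessibilityMatrix, truth: SyntheticTruth,
                            out_dir) -> dict[str, str]:
    """Emit the matrix, the truth sidecars and the generating tree under
    ``out_dir``; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "matrix": str(out / "matrix.tsv"),
        "ancestral_states": str(out / "truth_ancestral_states.tsv"),
        "class_labels": str(out / "truth_class_labels.tsv"),
        "events": str(out / "truth_events.tsv"),
        "tree": str(out / "tree.nwk"),
        "meta": str(out / "meta.json"),
    }
    write_accessibility_table(matrix, manifest["matrix"])
    truth.ancestral_states.to_csv(manifest["ancestral_states"], sep="\t",
                                  index_label="site_id")
    truth.class_labels.map(lambda c: c.value if isinstance(c, SiteClass) else c) \
        .to_csv(manifest["class_labels"], sep="\t", index_label="site_id")
    truth.events.to_csv(manifest["events"], sep="\t", index=False)
    Path(manifest["tree"]).write_text(truth.tree + "\n")
    Path(manifest["meta"]).write_text(json.dumps({"seed": truth.seed}, indent=2) + "\n")
    return manifest
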