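"""Ancestral reconstruction: Fitch sets, ACCTRAN/DELTRAN semantics against
an explicit enumeration of all minimum-change labelings, and ML marginals
against a brute-force posterior."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import chromphylo as cp
from chromphylo import hematopoiesis as hp
from chromphylo._tree import (enumerate_topology_shapes, index_tree,
                              parse_newick, shape_to_newick)
from chromphylo.ancestral import (AMBIGUOUS, acctran, call_states,
                                  constraint_tree, deltran, fitch_state_sets,
                                  ml_marginals, reconstruct)
from chromphylo.errors import CapabilityError, ConfigurationError
from chromphylo.likelihood import SubstitutionModel
from chromphylo.parsimony import fitch_length
from conftest import make_matrix
from test_likelihood import transition_matrix_expm


class TestConstraintTree:
    def test_leaf_set(self):
        t = constraint_tree()
        assert {l.taxon.label for l in t.leaf_node_iter()} == set(hp.ANALYSIS_CELLS)

    def test_progenitor_nodes_distinct(self):
        t = constraint_tree()
        labels = {n.label for n in t.preorder_internal_node_iter()}
        assert {"CMP", "GMP", "MEP"} <= labels

    def test_binary_and_rooted(self):
        t = constraint_tree()
        assert t.is_rooted
        assert all(len(n.child_nodes()) == 2
                   for n in t.preorder_internal_node_iter())


class TestFitchStateSets:
    def test_constant_pattern(self):
        t = parse_newick("((A,B),(C,D));", rooted=True)
        down, final, score = fitch_state_sets(t, make_matrix([[1, 1, 1, 1]],
                                                             list("ABCD")))
        assert (down.iloc[0] == "1").all()
        assert (final.iloc[0] == "1").all()
        assert score[0] == 0

    def test_split_pattern_sets(self):
        t = parse_newick("((A,B)AB,(C,D)CD);", rooted=True)
        down, final, score = fitch_state_sets(t, make_matrix([[1, 1, 0, 0]],
                                                             list("ABCD")))
        assert down.loc[:, "AB"].iloc[0] == "1"
        assert down.loc[:, "CD"].iloc[0] == "0"
        assert down.loc[:, "root"].iloc[0] == "01"
        assert score[0] == 1

    def test_score_consistent_with_fitch_length(self, rng):
        t = parse_newick("(((A,B),C),(D,E));", rooted=True)
        m = make_matrix(rng.integers(0, 2, (40, 5)), list("ABCDE"))
        _, _, score = fitch_state_sets(t, m)
        assert score.sum() == fitch_length(t, m)

    def test_polytomy_rejected(self):
        t = parse_newick("((A,B,C),D);", rooted=True)
        with pytest.raises(CapabilityError):
            fitch_state_sets(t, make_matrix([[0, 1, 0, 1]], list("ABCD")))


def enumerate_mprs(tree, pattern_by_label):
    """All minimum-change internal labelings plus the edge-visit order used
    by the implementation's preorder resolution."""
    it = index_tree(tree)
    internal = [i for i in range(it.n_nodes) if it.children[i]]
    leaves = {i: pattern_by_label[it.labels[i]]
              for i in range(it.n_nodes) if not it.children[i]}
    edge_order = [c for i in reversed(range(it.n_nodes))
                  for c in it.children[i]]
    solutions = []
    for assign in product((0, 1), repeat=len(internal)):
        state = dict(leaves)
        state.update(dict(zip(internal, assign)))
        changes = sum(state[c] != state[int(it.parent[c])] for c in edge_order)
        solutions.append((changes, state))
    best = min(c for c, _ in solutions)
    mprs = [s for c, s in solutions if c == best]
    return it, internal, edge_order, best, mprs


def lexicographic_extreme(it, edge_order, mprs, prefer_change):
    keys = []
    for state in mprs:
        key = tuple(int(state[c] != state[int(it.parent[c])])
                    for c in edge_order)
        keys.append((key, state))
    keys.sort(key=lambda kv: kv[0], reverse=prefer_change)
    return keys[0][1]


class TestAcctranDeltran:
    def test_worked_example(self):
        # rooted via outgroup D (state 0); A=1, B=0, C=1
        t = parse_newick("(((A,B)AB,C)ABC,D);", rooted=True)
        m = make_matrix([[1, 0, 1, 0]], list("ABCD"))
        acc = acctran(t, m, outgroup="D")
        dele = deltran(t, m, outgroup="D")
        assert acc.loc[:, "AB"].iloc[0] == 1 and acc.loc[:, "ABC"].iloc[0] == 1
        assert dele.loc[:, "AB"].iloc[0] == 0 and dele.loc[:, "ABC"].iloc[0] == 0

    def test_constant_site_all_calls_constant(self):
        t = constraint_tree()
        m = make_matrix(np.ones((3, len(hp.ANALYSIS_CELLS)), dtype=int),
                        list(hp.ANALYSIS_CELLS))
        for rec in (acctran(t, m), deltran(t, m)):
            assert (rec == 1).all().all()

    def test_unknown_outgroup(self):
        t = constraint_tree()
        m = make_matrix(np.ones((1, len(hp.ANALYSIS_CELLS)), dtype=int),
                        list(hp.ANALYSIS_CELLS))
        with pytest.raises(ConfigurationError):
            acctran(t, m, outgroup="HSC")

    def _random_rooted_tree(self, rng, n):
        labels = [f"T{i}" for i in range(n)]
        shapes = list(enumerate_topology_shapes(labels))
        shape = shapes[rng.integers(len(shapes))]
        # root the unrooted shape on the pendant edge of labels[0]
        unrooted = parse_newick(shape_to_newick(shape, labels[0]), rooted=False)
        from chromphylo.infer import root_with_outgroup
        return root_with_outgroup(unrooted, labels[0]), labels

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_both_are_extremal_mprs(self, rng, n):
        """ACCTRAN/DELTRAN realise the Fitch score and are the
        lexicographically change-first / change-last optimal labelings in
        the implementation's preorder edge order."""
        for _ in range(25):
            tree, labels = self._random_rooted_tree(rng, n)
            pattern = rng.integers(0, 2, n)
            by_label = dict(zip(labels, pattern))
            og_state = by_label[labels[0]]
            it, internal, edge_order, best, mprs = enumerate_mprs(tree, by_label)
            # tie policy at the root: keep only MPRs compatible with
            # outgroup-side resolution when the root set is ambiguous
            root_states = {s[it.root] for s in mprs}
            if len(root_states) == 2:
                mprs = [s for s in mprs if s[it.root] == og_state]
            m = make_matrix([pattern], labels)
            acc = acctran(tree, m, outgroup=labels[0])
            dele = deltran(tree, m, outgroup=labels[0])
            names = {i: (it.labels[i] or ("root" if i == it.root else f"node{i}"))
                     for i in internal}
            want_acc = lexicographic_extreme(it, edge_order, mprs, True)
            want_del = lexicographic_extreme(it, edge_order, mprs, False)
            for i in internal:
                assert acc.loc[:, names[i]].iloc[0] == want_acc[i]
                assert dele.loc[:, names[i]].iloc[0] == want_del[i]
            # both achieve exactly the Fitch score
            for rec in (acc, dele):
                full = {i: by_label[it.labels[i]]
                        for i in range(it.n_nodes) if not it.children[i]}
                full.update({i: int(rec.loc[:, names[i]].iloc[0])
                             for i in internal})
                changes = sum(full[c] != full[int(it.parent[c])]
                              for c in edge_order)
                assert changes == best == fitch_length(tree, m)


def brute_force_marginal(tree, model, pattern_by_label, node_label):
    """Posterior P(open) at one internal node by total enumeration over
    internal states and rate categories (including the invariant class)."""
    it = index_tree(tree)
    internal = [i for i in range(it.n_nodes) if it.children[i]]
    names = {i: (it.labels[i] or ("root" if i == it.root else f"node{i}"))
             for i in internal}
    target = next(i for i in internal if names[i] == node_label)
    leaves = {i: pattern_by_label[it.labels[i]]
              for i in range(it.n_nodes) if not it.children[i]}
    rates, weights = model.category_rates_weights()
    pi = np.array([1.0 - model.pi1, model.pi1])
    num = den = 0.0
    for r, w in zip(rates, weights):
        P = {i: transition_matrix_expm(model.pi1, r, it.edge_length[i])
             for i in range(it.n_nodes) if it.parent[i] != -1}
        for assign in product((0, 1), repeat=len(internal)):
            state = dict(leaves)
            state.update(dict(zip(internal, assign)))
            prob = (1 - model.p_inv) * w * pi[state[it.root]]
            for i in range(it.n_nodes):
                if it.parent[i] != -1:
                    prob *= P[i][state[int(it.parent[i])], state[i]]
            den += prob
            if state[target] == 1:
                num += prob
    vals = set(leaves.values())
    if model.p_inv > 0 and len(vals) == 1:
        s = vals.pop()
        inv = model.p_inv * pi[s]
        den += inv
        if s == 1:
            num += inv
    return num / den


class TestMlMarginals:
    def test_all_open_short_branches(self):
        t = parse_newick("((A:1e-8,B:1e-8)AB:1e-8,(C:1e-8,D:1e-8)CD:1e-8);",
                         rooted=True)
        m = make_matrix(np.ones((2, 4), dtype=int), list("ABCD"))
        marg = ml_marginals(t, SubstitutionModel(), m)
        assert np.allclose(marg.to_numpy(), 1.0, atol=1e-6)

    def test_complement_symmetry_at_equal_frequencies(self):
        t = parse_newick("((A:0.2,B:0.3)AB:0.1,(C:0.15,D:0.4)CD:0.2);",
                         rooted=True)
        model = SubstitutionModel(pi1=0.5, p_inv=0.3, tag="BIN+I")
        m1 = make_matrix([[1, 0, 1, 1]], list("ABCD"))
        m2 = make_matrix([[0, 1, 0, 0]], list("ABCD"))
        a = ml_marginals(t, model, m1)
        b = ml_marginals(t, model, m2)
        assert np.allclose(a.to_numpy(), 1.0 - b.to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("tag", ["BIN", "BIN+I", "BIN+I+G"])
    def test_matches_enumeration_posterior(self, rng, tag):
        from test_likelihood import random_model
        from chromphylo.infer import root_with_outgroup
        for n in (4, 5):
            labels = [f"T{i}" for i in range(n)]
            shapes = list(enumerate_topology_shapes(labels))
            for _ in range(4):
                shape = shapes[rng.integers(len(shapes))]
                unrooted = parse_newick(shape_to_newick(shape, labels[0]),
                                        rooted=False)
                for e in unrooted.preorder_edge_iter():
                    if e.head_node is not unrooted.seed_node:
                        e.length = float(rng.uniform(0.05, 1.5))
                tree = root_with_outgroup(unrooted, labels[0])
                model = random_model(rng, tag)
                pattern = rng.integers(0, 2, n)
                by_label = dict(zip(labels, pattern))
                m = make_matrix([pattern], labels)
                marg = ml_marginals(tree, model, m)
                for node_label in marg.columns:
                    want = brute_force_marginal(tree, model, by_label, node_label)
                    assert marg.loc[:, node_label].iloc[0] == \
                        pytest.approx(want, abs=1e-10)

    def test_probabilities_proper(self, mixed_sim):
        _, matrix, _ = mixed_sim
        sub = cp.subset_cells(cp.filter_sites(
            matrix, np.arange(matrix.n_sites) < 200), hp.ANALYSIS_CELLS)
        est = reconstruct(sub, model_tag="BIN+I", max_sweeps=10)
        p = est.marginals.to_numpy()
        assert (p >= 0).all() and (p <= 1).all()


class TestCallStates:
    def test_argmax_and_tie(self):
        marg = pd.DataFrame({"X": [0.9, 0.5, 0.2]})
        calls = call_states(marg)
        assert calls["X"].tolist() == [1, AMBIGUOUS, 0]

    def test_threshold_mode(self):
        marg = pd.DataFrame({"X": [0.9, 0.6, 0.05]})
        calls = call_states(marg, threshold=0.7)
        assert calls["X"].tolist() == [1, AMBIGUOUS, 0]

    def test_ambiguous_counts_reported(self, updown_sim):
        _, matrix, _ = updown_sim
        sub = cp.filter_sites(matrix, np.arange(matrix.n_sites) < 500)
        est = reconstruct(sub, model_tag="BIN", max_sweeps=10)
        counts = est.ambiguous_counts()
        assert set(counts.index) == set(est.ml_calls.columns)
        assert (counts >= 0).all()


class TestRecovery:
    def test_homoplasy_free_sites_recover_truth(self, updown_sim):
        _, matrix, truth = updown_sim
        est = reconstruct(matrix, model_tag="BIN+I", max_sweeps=20)
        events = truth.events.set_index("site_id")
        safe = ~truth.events.groupby("site_id")["root_adjacent"].any()
        safe_ids = [s for s in matrix.site_ids
                    if events.index.get_indexer([s])[0] == -1 or safe.get(s, True)]
        for node in ("CMP", "GMP", "MEP"):
            obs = truth.ancestral_states.loc[safe_ids, node].to_numpy()
            for method in ("acctran", "deltran", "ml"):
                pred = est.calls(method).loc[safe_ids, node].to_numpy()
                assert (pred == obs).all(), (node, method)
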