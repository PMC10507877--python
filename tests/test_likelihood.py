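"""Two-state likelihood: closed forms, enumeration oracles, and fitting.

The brute-force oracle rebuilds the model from its definition -- matrix
exponentials of Q = mu[[-pi1, pi1], [pi0, -pi0]] and explicit sums over all
internal-state assignments and rate categories -- so it shares no code with
the pruning implementation beyond the model's parameter container.
"""

from itertools import product

import numpy as np
import pytest
from scipy.linalg import expm

from chromphylo._tree import (enumerate_topology_shapes, index_tree,
                              parse_newick, shape_to_newick)
from chromphylo.errors import ContractError
from chromphylo.infer import root_with_outgroup
from chromphylo.likelihood import (MODEL_TAGS, ModelFitResult,
                                   SubstitutionModel, log_likelihood, ml_fit,
                                   ml_search, select_model_aic,
                                   site_log_likelihood)
from conftest import make_matrix


def transition_matrix_expm(pi1, rate, t):
    pi0 = 1.0 - pi1
    mu = 1.0 / (2.0 * pi0 * pi1)
    Q = mu * np.array([[-pi1, pi1], [pi0, -pi0]])
    return expm(Q * rate * t)


def brute_force_loglik(tree, model, pattern_by_label):
    """Sum over all internal-node state assignments and rate categories."""
    it = index_tree(tree)
    internal = [i for i in range(it.n_nodes) if it.children[i]]
    leaves = {i: pattern_by_label[it.labels[i]]
              for i in range(it.n_nodes) if not it.children[i]}
    rates, weights = model.category_rates_weights()
    pi = np.array([1.0 - model.pi1, model.pi1])
    total = 0.0
    for k, (r, w) in enumerate(zip(rates, weights)):
        P = {i: transition_matrix_expm(model.pi1, r, it.edge_length[i])
             for i in range(it.n_nodes) if it.parent[i] != -1}
        cat = 0.0
        for assign in product((0, 1), repeat=len(internal)):
            state = dict(leaves)
            state.update(dict(zip(internal, assign)))
            prob = pi[state[it.root]]
            for i in range(it.n_nodes):
                if it.parent[i] != -1:
                    prob *= P[i][state[int(it.parent[i])], state[i]]
            cat += prob
        total += (1.0 - model.p_inv) * w * cat
    vals = set(leaves.values())
    if model.p_inv > 0 and len(vals) == 1:
        total += model.p_inv * pi[vals.pop()]
    return np.log(total)


class TestClosedForms:
    def test_two_taxon_quarter_transition(self):
        # total path ln(2)/2 at pi = 1/2: L = 0.5 * 0.5 * (1 - e^{-2t}) = 1/8
        t = np.log(2) / 4
        tree = parse_newick(f"(A:{t},B:{t});", rooted=True)
        model = SubstitutionModel()
        assert site_log_likelihood(tree, model, {"A": 0, "B": 1}) == \
            pytest.approx(np.log(0.125), abs=1e-12)

    def test_constant_site_short_branch_limit(self):
        tree = parse_newick("(A:1e-9,(B:1e-9,C:1e-9):1e-9);", rooted=True)
        model = SubstitutionModel(pi1=0.3)
        assert site_log_likelihood(tree, model, {"A": 1, "B": 1, "C": 1}) == \
            pytest.approx(np.log(0.3), abs=1e-6)

    def test_negative_branch_rejected(self):
        tree = parse_newick("(A:-0.1,B:0.1);", rooted=True)
        with pytest.raises(ContractError):
            site_log_likelihood(tree, SubstitutionModel(), {"A": 0, "B": 1})


def random_model(rng, tag):
    model = SubstitutionModel.from_tag(tag)
    from dataclasses import replace
    model = replace(model, pi1=float(rng.uniform(0.2, 0.8)))
    if "+I" in tag:
        model = replace(model, p_inv=float(rng.uniform(0.0, 0.5)))
    if model.rate_model == "gamma":
        model = replace(model, alpha=float(rng.uniform(0.3, 3.0)))
    if model.rate_model == "free":
        n = model.rates.size
        model = replace(model, rates=rng.uniform(0.1, 3.0, n),
                        weights=rng.uniform(0.2, 1.0, n))
    return model


class TestPruningOracle:
    @pytest.mark.parametrize("tag", ["BIN", "BIN+I", "BIN+I+G", "BIN+I+R4"])
    def test_matches_enumeration_on_random_trees(self, rng, tag):
        for n in (3, 4, 5):
            labels = [f"T{i}" for i in range(n)]
            shapes = list(enumerate_topology_shapes(labels))
            for _ in range(6):
                shape = shapes[rng.integers(len(shapes))]
                tree = parse_newick(shape_to_newick(shape, labels[0]),
                                    rooted=False)
                for e in tree.preorder_edge_iter():
                    if e.head_node is not tree.seed_node:
                        e.length = float(rng.uniform(0.01, 2.0))
                model = random_model(rng, tag)
                pattern = dict(zip(labels, rng.integers(0, 2, n)))
                got = site_log_likelihood(tree, model, pattern)
                want = brute_force_loglik(tree, model, pattern)
                assert got == pytest.approx(want, abs=1e-12)

    def test_root_placement_invariance(self, rng):
        tree = parse_newick("((A:0.3,B:0.7):0.2,(C:0.4,D:0.1):0.3,E:0.5);",
                            rooted=False)
        m = make_matrix(rng.integers(0, 2, size=(25, 5)), list("ABCDE"))
        model = SubstitutionModel(pi1=0.35, p_inv=0.2, tag="BIN+I")
        vals = [log_likelihood(root_with_outgroup(tree, og), model, m)
                for og in ("A", "C", "E")]
        assert max(vals) - min(vals) < 1e-10

    def test_total_equals_sum_of_sites(self, rng):
        tree = parse_newick("((A:0.3,B:0.7):0.2,C:0.4,D:0.1);", rooted=False)
        X = rng.integers(0, 2, size=(12, 4))
        m = make_matrix(X, list("ABCD"))
        model = SubstitutionModel(pi1=0.6)
        total = log_likelihood(tree, model, m)
        persite = sum(site_log_likelihood(tree, model, dict(zip("ABCD", row)))
                      for row in X)
        assert total == pytest.approx(persite, abs=1e-9)


def simulate_on_tree(tree, model, n_sites, rng):
    """Independent forward simulator under the model (expm transitions)."""
    it = index_tree(tree)
    rates, weights = model.category_rates_weights()
    pi1 = model.pi1
    labels = [it.labels[i] for i in range(it.n_nodes) if not it.children[i]]
    cols = {lab: np.empty(n_sites, dtype=np.uint8) for lab in labels}
    for s in range(n_sites):
        if rng.random() < model.p_inv:
            r = 0.0
        else:
            r = rates[rng.choice(len(weights), p=weights / weights.sum())]
        state = {it.root: int(rng.random() < pi1)}
        for i in reversed(range(it.n_nodes)):
            if it.parent[i] == -1:
                continue
            P = transition_matrix_expm(pi1, r, it.edge_length[i])
            state[i] = int(rng.random() < P[state[int(it.parent[i])], 1])
        for i in range(it.n_nodes):
            if not it.children[i]:
                cols[it.labels[i]][s] = state[i]
    return make_matrix(np.column_stack([cols[l] for l in labels]), labels)


class TestFitting:
    def test_parameter_recovery_single_rate(self, rng):
        newick = "((A:0.15,B:0.3):0.1,(C:0.2,D:0.25):0.12,E:0.2);"
        tree = parse_newick(newick, rooted=False)
        true = SubstitutionModel(pi1=0.4)
        m = simulate_on_tree(tree, true, 10_000, rng)
        fit = ml_fit(tree, m, "BIN")
        assert fit.model.pi1 == pytest.approx(0.4, abs=0.02)
        want = {}
        for e in tree.preorder_edge_iter():
            if e.head_node is not tree.seed_node and e.length:
                key = frozenset(l.taxon.label
                                for l in e.head_node.leaf_iter())
                want[key] = e.length
        got = {}
        for e in fit.tree.preorder_edge_iter():
            if e.head_node is not fit.tree.seed_node and e.length is not None:
                key = frozenset(l.taxon.label
                                for l in e.head_node.leaf_iter())
                got[key] = e.length
        for key, t_true in want.items():
            assert got[key] == pytest.approx(t_true, rel=0.10)
        # optimality: fitted lnL at least the truth's lnL
        assert fit.lnL >= log_likelihood(tree, true, m) - 1e-6

    def test_constant_matrix_degenerates_cleanly(self):
        tree = parse_newick("((A,B),(C,D));", rooted=False)
        m = make_matrix(np.ones((30, 4), dtype=int), list("ABCD"))
        fit = ml_fit(tree, m, "BIN+I", max_sweeps=10)
        assert fit.model.p_inv > 0.9
        assert all(e.length < 1e-4 for e in fit.tree.preorder_edge_iter()
                   if e.length is not None)

    def test_lnl_non_positive_and_k_bookkeeping(self, rng):
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);", rooted=False)
        m = make_matrix(rng.integers(0, 2, (40, 4)), list("ABCD"))
        ks = {}
        for tag in MODEL_TAGS:
            fit = ml_fit(tree, m, tag, max_sweeps=3)
            assert fit.lnL <= 0
            ks[tag] = fit.k
        base = 1 + (2 * 4 - 3)
        assert ks == {"BIN": base, "BIN+I": base + 1, "BIN+I+G": base + 2,
                      "BIN+I+R4": base + 1 + 6, "BIN+I+R8": base + 1 + 14,
                      "BIN+I+R12": base + 1 + 22}

    def test_aic_formula(self):
        r = ModelFitResult(SubstitutionModel(), None, lnL=-100.0, k=3)
        assert r.aic == 206.0

    def test_model_selection_prefers_parsimonious_on_single_rate_data(self, rng):
        tree = parse_newick("((A:0.2,B:0.3):0.15,(C:0.25,D:0.2):0.1,E:0.3);",
                            rooted=False)
        m = simulate_on_tree(tree, SubstitutionModel(pi1=0.45), 3000, rng)
        best, table = select_model_aic(tree, m, max_sweeps=12)
        assert set(table["model"]) == set(MODEL_TAGS)
        assert best.model.tag in ("BIN", "BIN+I")
        assert table["AIC"].is_monotonic_increasing


class TestSearch:
    def test_forced_topology_from_repeated_split(self):
        X = np.tile([0, 0, 1, 1, 1], (40, 1))
        X[::2, 0] = 0
        X[1::2] = 1 - X[1::2]
        m = make_matrix(np.vstack([np.tile([0, 0, 1, 1, 1], (30, 1)),
                                   np.tile([1, 1, 0, 0, 0], (30, 1)),
                                   np.tile([0, 1, 1, 0, 0], (5, 1))]),
                        list("ABCDE"))
        from chromphylo._tree import has_split
        tree = ml_search(m, "BIN", max_sweeps=8)
        assert has_split(tree, {"A", "B"})

    def test_exhaustive_matches_independent_maximum(self, rng, updown_sim):
        import chromphylo as cp
        _, matrix, _ = updown_sim
        sub = cp.subset_cells(
            cp.filter_sites(matrix, np.arange(matrix.n_sites) < 400),
            ["LSK", "Neu", "Mon", "Ery", "iMK"])
        tree = ml_search(sub, "BIN", mode="exhaustive", max_sweeps=8)
        best = tree.ml_result.lnL
        from chromphylo.parsimony import enumerate_topologies
        lnls = [ml_fit(t, sub, "BIN", max_sweeps=8).lnL
                for t in enumerate_topologies(sub.cell_names)]
        assert best == pytest.approx(max(lnls), abs=1e-6)

    def test_nni_never_below_start(self, updown_sim):
        import chromphylo as cp
        from chromphylo.infer import nj_tree, pairwise_difference_matrix
        _, matrix, _ = updown_sim
        sub = cp.subset_cells(
            cp.filter_sites(matrix, np.arange(matrix.n_sites) < 300),
            ["LSK", "Neu", "Mon", "Ery", "iMK", "B"])
        start = nj_tree(pairwise_difference_matrix(sub))
        start_lnl = ml_fit(start, sub, "BIN", max_sweeps=8).lnL
        tree = ml_search(sub, "BIN", max_sweeps=8)
        assert tree.ml_result.lnL >= start_lnl - 1e-9
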