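"""DAG mechanics, linear-Gaussian scores, move proposals and the MH chain."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bndissect.bayesnet import (
    ConstraintSet,
    Dag,
    GaussianNetworkData,
    MCMCChain,
    McmcConfig,
    NodeSpec,
    default_constraints,
    fit_parameters,
    legal_moves,
    mh_step,
    network_score,
    node_score,
    propose_move,
    random_legal_dag,
    run_mcmc,
    to_networkx,
    write_dot,
    write_graphml,
)
from bndissect.errors import DataError

FREE = ConstraintSet(banned_pairs=frozenset(), exogenous_roles=frozenset())


def _trait_nodes(names):
    return [NodeSpec(n, "trait") for n in names]


class TestDag:
    def test_cycle_rejected(self):
        with pytest.raises(DataError):
            Dag(("A", "B"), edges=[("A", "B"), ("B", "A")])

    def test_self_loop_rejected(self):
        with pytest.raises(DataError):
            Dag(("A",), edges=[("A", "A")])

    def test_parents_and_edges(self):
        d = Dag(("A", "B", "C"), edges=[("A", "C"), ("B", "C")])
        assert set(d.parents("C")) == {"A", "B"}
        assert d.n_edges == 2 and d.has_edge("A", "C")

    def test_key_distinguishes_structures(self):
        a = Dag(("A", "B"), edges=[("A", "B")])
        b = Dag(("A", "B"), edges=[("B", "A")])
        assert a.key() != b.key() and a != b


class TestNodeScore:
    def test_parentless_closed_form(self, rng):
        y = rng.standard_normal(500)
        sigma2 = y.var()
        expected = -0.5 * 500 * (math.log(2 * math.pi * sigma2) + 1)
        assert node_score(y, None, "loglik") == pytest.approx(expected, rel=1e-10)

    def test_adding_parent_never_decreases_loglik(self, rng):
        y = rng.standard_normal(200)
        u = rng.standard_normal((200, 3))
        for k in range(3):
            assert (
                node_score(y, u[:, : k + 1], "loglik")
                >= node_score(y, u[:, :k] if k else None, "loglik") - 1e-9
            )

    def test_exact_copy_parent_guarded_by_sigma_floor(self, rng):
        x = rng.standard_normal(100)
        s = node_score(x, x, "loglik")
        assert np.isfinite(s)

    def test_gram_cache_matches_direct_fit(self, rng):
        frame = pd.DataFrame(rng.standard_normal((300, 4)), columns=list("WXYZ"))
        frame["Y"] = 1.5 * frame["X"] - 0.5 * frame["W"] + rng.standard_normal(300)
        data = GaussianNetworkData(frame, _trait_nodes("WXYZ"), standardize=False)
        for child, parents in [(2, ()), (2, (1,)), (2, (0, 1)), (3, (0, 1, 2))]:
            direct = node_score(
                frame.iloc[:, child],
                frame.iloc[:, list(parents)] if parents else None,
                "bic",
            )
            assert data.node_score_idx(child, parents, "bic") == pytest.approx(
                direct, rel=1e-9
            )

    def test_too_few_observations_rejected(self):
        with pytest.raises(DataError):
            node_score(np.ones(3), np.ones((3, 2)))


class TestNetworkScore:
    def test_empty_graph_is_sum_of_parentless_scores(self, rng):
        frame = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("ABC"))
        data = GaussianNetworkData(frame, _trait_nodes("ABC"))
        empty = Dag(("A", "B", "C"))
        expected = sum(data.node_score_idx(j, (), "bic") for j in range(3))
        assert network_score(empty, data) == pytest.approx(expected)

    def test_add_move_delta_matches_full_rescoring(self, rng):
        frame = pd.DataFrame(rng.standard_normal((150, 3)), columns=list("ABC"))
        data = GaussianNetworkData(frame, _trait_nodes("ABC"))
        before = Dag(("A", "B", "C"))
        after = Dag(("A", "B", "C"), edges=[("A", "B")])
        delta_nodes = data.node_score_idx(1, (0,), "bic") - data.node_score_idx(1, (), "bic")
        delta_full = network_score(after, data, fresh=True) - network_score(
            before, data, fresh=True
        )
        assert delta_nodes == pytest.approx(delta_full, abs=1e-9)

    def test_reverse_changes_only_endpoint_scores(self, rng):
        frame = pd.DataFrame(rng.standard_normal((150, 3)), columns=list("ABC"))
        frame["B"] = 0.7 * frame["A"] + rng.standard_normal(150)
        data = GaussianNetworkData(frame, _trait_nodes("ABC"))
        before = Dag(("A", "B", "C"), edges=[("A", "B"), ("C", "B")])
        after = Dag(("A", "B", "C"), edges=[("B", "A"), ("C", "B")])
        delta_nodes = (
            data.node_score_idx(0, (1,), "bic")
            + data.node_score_idx(1, (2,), "bic")
            - data.node_score_idx(0, (), "bic")
            - data.node_score_idx(1, (0, 2), "bic")
        )
        delta_full = network_score(after, data, fresh=True) - network_score(
            before, data, fresh=True
        )
        assert delta_nodes == pytest.approx(delta_full, abs=1e-9)


class TestMoves:
    def test_two_node_neighborhood_is_both_adds(self):
        d = Dag(("A", "B"))
        moves = legal_moves(d, FREE, roles=("trait", "trait"))
        assert {(m.kind, m.source, m.target) for m in moves} == {
            ("add", "A", "B"),
            ("add", "B", "A"),
        }

    def test_banned_role_pairs_never_proposed(self):
        names = ("g1", "g2", "env", "Q")
        roles = ("gene", "gene", "environment", "trait")
        d = Dag(names)
        moves = legal_moves(d, default_constraints(), roles=roles, max_parents=5)
        pairs = {(m.source, m.target) for m in moves}
        assert ("g1", "g2") not in pairs and ("g2", "g1") not in pairs
        assert ("g1", "env") not in pairs and ("env", "g1") not in pairs
        assert ("Q", "g1") not in pairs  # trait -> gene banned
        assert ("g1", "Q") in pairs  # gene -> trait allowed

    def test_cycle_creating_add_excluded(self):
        d = Dag(("A", "B", "C"), edges=[("A", "B"), ("B", "C")])
        moves = legal_moves(d, FREE, roles=("trait",) * 3)
        assert ("add", "C", "A") not in {(m.kind, m.source, m.target) for m in moves}

    def test_parent_cap_respected(self):
        d = Dag(("A", "B", "C"), edges=[("A", "C"), ("B", "C")])
        moves = legal_moves(d, FREE, roles=("trait",) * 3, max_parents=2)
        targets = {(m.kind, m.target) for m in moves if m.kind == "add"}
        assert ("add", "C") not in targets

    def test_propose_move_uniform_and_seeded(self, rng):
        d = Dag(("A", "B"))
        m1 = propose_move(d, FREE, np.random.default_rng(3), roles=("trait", "trait"))
        m2 = propose_move(d, FREE, np.random.default_rng(3), roles=("trait", "trait"))
        assert m1 == m2 and m1.kind == "add"


class TestMhStep:
    def _data(self, rng, n=200):
        frame = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("ABC"))
        frame["B"] = 2.0 * frame["A"] + 0.1 * rng.standard_normal(n)
        return GaussianNetworkData(frame, _trait_nodes("ABC"))

    def test_uphill_moves_accepted(self, rng):
        # from the empty graph, adding A->B is a huge score gain: accepted
        data = self._data(rng)
        cfg = McmcConfig(seed=1)
        d = Dag(("A", "B", "C"))
        found_edge = False
        for seed in range(30):
            d2, accepted, _ = mh_step(d, data, cfg, np.random.default_rng(seed), FREE)
            if accepted and ("A", "B") in d2.edges():
                found_edge = True
                break
        assert found_edge

    def test_rejection_returns_identical_object(self, rng):
        data = self._data(rng)
        cfg = McmcConfig(seed=1)
        d = Dag(("A", "B", "C"), edges=[("A", "B")])
        saw_rejection = False
        for seed in range(100):
            d2, accepted, _ = mh_step(d, data, cfg, np.random.default_rng(seed), FREE)
            if not accepted:
                assert d2 is d
                saw_rejection = True
                break
        assert saw_rejection


class TestRunMcmc:
    def test_recovers_regression_direction_with_exogenous_source(self, rng):
        n = 500
        x = rng.standard_normal(n)
        frame = pd.DataFrame({"X": x, "Y": 2.0 * x + rng.standard_normal(n)})
        nodes = [NodeSpec("X", "environment"), NodeSpec("Y", "trait")]
        res = run_mcmc(frame, nodes, config=McmcConfig(iterations=500, seed=2))
        assert ("X", "Y") in res.best_dag.edges()

    def test_independent_columns_give_empty_graph_under_bic(self, rng):
        frame = pd.DataFrame(rng.standard_normal((400, 3)), columns=list("ABC"))
        res = run_mcmc(
            frame, _trait_nodes("ABC"), constraints=FREE,
            config=McmcConfig(iterations=2_000, seed=3),
        )
        assert res.best_dag.n_edges == 0

    def test_determinism_same_seed(self, rng):
        frame = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("ABCD"))
        cfg = McmcConfig(iterations=800, seed=4)
        a = run_mcmc(frame, _trait_nodes("ABCD"), constraints=FREE, config=cfg)
        b = run_mcmc(frame, _trait_nodes("ABCD"), constraints=FREE, config=cfg)
        assert a.best_dag == b.best_dag
        assert a.trace == b.trace

    def test_raw_mode_runs_and_respects_constraints(self, rng):
        frame = pd.DataFrame(rng.standard_normal((150, 4)), columns=["g1", "g2", "Q", "age"])
        nodes = [
            NodeSpec("g1", "gene"), NodeSpec("g2", "gene"),
            NodeSpec("Q", "trait"), NodeSpec("age", "environment"),
        ]
        cfg = McmcConfig(iterations=500, seed=5, score_kind="loglik", hastings=False)
        res = run_mcmc(frame, nodes, constraints=default_constraints(False), config=cfg)
        roles = {s.name: s.role for s in nodes}
        for u, v in res.best_dag.edges():
            assert not (roles[u] == "gene" and roles[v] == "gene")
            assert not (roles[u] == "trait" and roles[v] == "gene")


class TestChainInvariants:
    def test_trace_states_always_legal(self, rng):
        # every visited structure is acyclic and constraint-clean, audited
        # with networkx independently of the sampler's own bookkeeping
        frame = pd.DataFrame(rng.standard_normal((120, 5)),
                             columns=["g1", "g2", "age", "Q1", "dz"])
        nodes = [
            NodeSpec("g1", "gene"), NodeSpec("g2", "gene"),
            NodeSpec("age", "environment"), NodeSpec("Q1", "trait"),
            NodeSpec("dz", "disease"),
        ]
        data = GaussianNetworkData(frame, nodes)
        constraints = default_constraints()
        chain = MCMCChain(data, constraints=constraints, config=McmcConfig(seed=6))
        roles = dict(zip(data.names, data.roles))
        for _ in range(400):
            chain.step()
            g = to_networkx(chain.dag())
            assert nx.is_directed_acyclic_graph(g)
            for u, v in g.edges():
                assert constraints.allows(roles[u], roles[v])

    def test_incremental_score_tracks_full_rescore(self, rng):
        frame = pd.DataFrame(rng.standard_normal((150, 4)), columns=list("ABCD"))
        data = GaussianNetworkData(frame, _trait_nodes("ABCD"))
        chain = MCMCChain(data, constraints=FREE, config=McmcConfig(seed=7))
        for _ in range(300):
            chain.step()
        assert chain.score == pytest.approx(
            network_score(chain.dag(), data, fresh=True), abs=1e-9
        )


class TestFitParameters:
    def test_parentless_node_mean_and_mle_sd(self, rng):
        y = rng.standard_normal(400) * 2 + 1
        frame = pd.DataFrame({"A": y})
        params = fit_parameters(Dag(("A",)), frame)
        assert params["A"].intercept == pytest.approx(y.mean())
        assert params["A"].sigma == pytest.approx(y.std(), rel=1e-9)  # MLE, ddof=0

    def test_slope_recovery_and_normal_equations(self, rng):
        n = 10_000
        x = rng.standard_normal(n)
        y = 3.0 + 2.0 * x + rng.standard_normal(n)
        frame = pd.DataFrame({"X": x, "Y": y})
        params = fit_parameters(Dag(("X", "Y"), edges=[("X", "Y")]), frame)
        a1 = params["Y"].coefficients["X"]
        assert 1.95 <= a1 <= 2.05
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert a1 == pytest.approx(beta[1], abs=1e-8)


class TestExport:
    def test_graphml_and_dot_written(self, tmp_path):
        d = Dag(("A", "B"), edges=[("A", "B")])
        write_graphml(d, tmp_path / "g.graphml", roles=("gene", "trait"))
        write_dot(d, tmp_path / "g.dot", roles=("gene", "trait"),
                  edge_labels={("A", "B"): 7})
        g = nx.read_graphml(tmp_path / "g.graphml")
        assert set(g.edges()) == {("A", "B")}
        assert g.nodes["A"]["role"] == "gene"
        dot = (tmp_path / "g.dot").read_text()
        assert '"A" -> "B"' in dot and 'label="7"' in dot

    def test_random_legal_dag_obeys_constraints(self, rng):
        nodes = [NodeSpec(f"g{i}", "gene") for i in range(4)] + [
            NodeSpec("Q", "trait"), NodeSpec("age", "environment")
        ]
        constraints = default_constraints()
        roles = {s.name: s.role for s in nodes}
        for seed in range(10):
            d = random_legal_dag(nodes, constraints, np.random.default_rng(seed), density=0.5)
            assert nx.is_directed_acyclic_graph(to_networkx(d))
            for u, v in d.edges():
                assert constraints.allows(roles[u], roles[v])
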