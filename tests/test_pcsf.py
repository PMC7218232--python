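"""Terminal selection, PCSF solvers, grid search, ensemble and clustering."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from toxomix import pcsf as pc
from toxomix.netbuild import MultiLayerNetwork

from conftest import make_contrast


def make_net(edges, extra_nodes=()):
    g = nx.Graph()
    for a, b, c in edges:
        g.add_edge(a, b, cost=float(c))
    for n in extra_nodes:
        g.add_node(n)
    for n in g.nodes:
        g.nodes[n]["layer"] = "gene"
    return MultiLayerNetwork(graph=g)


def terminals(prizes):
    return pc.TerminalSet(table=pd.DataFrame({"prize": pd.Series(prizes, dtype=float), "modality": "mrna"}))


def random_instance(rng):
    n = int(rng.integers(4, 13))
    m = int(rng.integers(n - 1, 17))
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(10**6)))
    gg = nx.Graph()
    for a, b in g.edges():
        gg.add_edge(f"n{a}", f"n{b}", cost=float(rng.uniform(0.1, 1.1)))
    for a in g.nodes():
        gg.add_node(f"n{a}", layer="gene")
    net = MultiLayerNetwork(graph=gg)
    nt = max(1, int(rng.integers(1, n // 2 + 1)))
    tn = rng.choice([f"n{a}" for a in g.nodes()], size=nt, replace=False)
    term = pc.TerminalSet(table=pd.DataFrame({"prize": rng.uniform(0.2, 1.0, size=nt), "modality": "mrna"}, index=tn))
    cfg = pc.PcsfConfig(
        mu=float(rng.choice([0.0, 0.0005, 0.01])),
        omega=float(rng.uniform(0.2, 1.0)),
        beta=float(rng.uniform(0.5, 3.0)),
    )
    return net, term, cfg


# ---------------------------------------------------------------------------
# terminal selection
# ---------------------------------------------------------------------------


def fake_factor_results(weights_per_modality):
    from toxomix.factors import FactorResults

    w = {m: pd.DataFrame({"LF1": s}) for m, s in weights_per_modality.items()}
    scores = pd.DataFrame({"LF1": []})
    return FactorResults(scores=scores, weights=w, alpha=pd.DataFrame(), tau={},
                         r2=pd.DataFrame(), elbo_trajectory=[0.0], n_iter=1, converged=True)


def test_terminal_cap_at_200_per_modality():
    # 500 features qualify (>= 2x the mean normalized weight); only 200 kept
    w = pd.Series(np.r_[np.full(500, 1.0), np.full(1500, 0.01)], index=[f"f{i}" for i in range(2000)])
    res = fake_factor_results({"mrna": w})
    node_map = {f: f for f in w.index}
    ts = pc.select_terminals(res, "LF1", node_map)
    assert len(ts) == 200


def test_uniform_weights_yield_no_terminals():
    w = pd.Series(0.7, index=[f"f{i}" for i in range(50)])
    res = fake_factor_results({"mrna": w})
    ts = pc.select_terminals(res, "LF1", {f: f for f in w.index})
    assert len(ts) == 0


def test_single_nonzero_weight_gets_prize_one():
    w = pd.Series(0.0, index=[f"f{i}" for i in range(20)])
    w["f3"] = 2.5
    res = fake_factor_results({"mrna": w})
    ts = pc.select_terminals(res, "LF1", {f: f for f in w.index})
    assert list(ts.table.index) == ["f3"]
    assert ts.table.loc["f3", "prize"] == pytest.approx(1.0)


def test_unknown_factor_raises(mofa_results):
    with pytest.raises(IndexError):
        pc.select_terminals(mofa_results, "LF99", {})


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def test_two_node_instance_merges_or_splits_with_omega():
    net = make_net([("a", "b", 0.4)])
    t = terminals({"a": 1.0, "b": 1.0})
    merged = pc.solve_pcsf(net, t, pc.PcsfConfig(mu=0, omega=0.6, beta=1.0))
    assert merged.n_trees == 1 and len(merged.edges) == 1
    assert merged.objective == pytest.approx(0.4 + 0.6 - 2.0)
    split = pc.solve_pcsf(net, t, pc.PcsfConfig(mu=0, omega=0.2, beta=1.0))
    assert split.n_trees == 2 and len(split.edges) == 0
    assert split.objective == pytest.approx(0.4 - 2.0)


def test_zero_beta_gives_empty_solution():
    net = make_net([("a", "b", 0.4)])
    t = terminals({"a": 1.0, "b": 1.0})
    sol = pc.solve_pcsf(net, t, pc.PcsfConfig(mu=0, omega=0.6, beta=0.0))
    assert sol.nodes == [] and sol.objective == 0.0


def test_unreachable_terminals_reported():
    net = make_net([("a", "b", 0.4)])
    sol = pc.solve_pcsf(net, terminals({"zz": 1.0}), pc.PcsfConfig())
    assert sol.status == "no_terminal_in_network"


def test_heuristic_matches_exhaustive_oracle_on_small_instances():
    """50 random instances with <=12 nodes: objective within 5% of optimum on
    every instance and exact on at least 90%."""
    rng = np.random.default_rng(0)
    exact = within = 0
    for _ in range(50):
        net, term, cfg = random_instance(rng)
        opt = pc.solve_pcsf(net, term, cfg)
        heur = pc.solve_pcsf(net, term, cfg, force_heuristic=True)
        gap = heur.objective - opt.objective
        assert gap >= -1e-9
        rel = gap / max(abs(opt.objective), 1e-9)
        exact += gap <= 1e-9
        within += rel <= 0.05
    assert within == 50
    assert exact >= 45


def test_solutions_are_forests_with_prized_trees():
    rng = np.random.default_rng(3)
    for _ in range(20):
        net, term, cfg = random_instance(rng)
        for force in (False, True):
            sol = pc.solve_pcsf(net, term, cfg, force_heuristic=force)
            g = nx.Graph()
            g.add_nodes_from(sol.nodes)
            g.add_edges_from([(a, b) for a, b, _ in sol.edges])
            assert len(sol.edges) == len(sol.nodes) - len(sol.trees)  # acyclic
            prizes = term.prizes
            for tree in sol.trees:
                assert sum(prizes.get(v, 0.0) for v in tree) > 0


def test_objective_decomposition_is_recomputable():
    rng = np.random.default_rng(5)
    net, term, cfg = random_instance(rng)
    sol = pc.solve_pcsf(net, term, cfg)
    gain = {v: cfg.beta * term.prizes.get(v, 0.0) - cfg.mu * net.graph.degree(v) for v in net.graph.nodes}
    recomputed = sum(c for _, _, c in sol.edges) + cfg.omega * sol.n_trees - sum(gain[v] for v in sol.nodes)
    assert sol.objective == pytest.approx(recomputed, abs=1e-9)


def test_deterministic_under_fixed_seed():
    rng = np.random.default_rng(8)
    net, term, cfg = random_instance(rng)
    a = pc.solve_pcsf(net, term, cfg, force_heuristic=True)
    b = pc.solve_pcsf(net, term, cfg, force_heuristic=True)
    assert a.nodes == b.nodes and a.edges == b.edges and a.objective == b.objective


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


def test_grid_search_picks_smallest_beta_when_coverage_is_flat():
    # strongly prized pair: coverage 100% at every grid point
    net = make_net([("a", "b", 0.3), ("b", "c", 0.3)])
    t = terminals({"a": 1.0, "c": 0.9})
    cfg, curve = pc.grid_search(net, t, pc.PcsfConfig(mu=0.0), omegas=(0.5,), betas=(10, 20, 40), tree_band=(1, 30))
    assert cfg.beta == 10
    assert (curve["coverage_pct"] == 100.0).all()


def test_optimal_coverage_is_monotone_in_beta():
    rng = np.random.default_rng(11)
    for _ in range(10):
        net, term, cfg = random_instance(rng)
        prev = -1.0
        for beta in (0.3, 0.8, 1.5, 3.0, 6.0):
            sol = pc.solve_pcsf(net, term, pc.PcsfConfig(mu=cfg.mu, omega=cfg.omega, beta=beta))
            assert sol.coverage >= prev - 1e-12
            prev = sol.coverage


def test_empty_grid_raises(default_network, mofa_results):
    net, node_map, _ = default_network
    t = pc.select_terminals(mofa_results, 0, node_map)
    with pytest.raises(Exception):
        pc.grid_search(net, t, omegas=(), betas=())


def test_default_study_grid_choice_covers_most_terminals(default_network, mofa_results):
    net, node_map, _ = default_network
    t = pc.select_terminals(mofa_results, 0, node_map)
    cfg, curve = pc.grid_search(net, t, pc.PcsfConfig())
    sol = pc.solve_pcsf(net, t, cfg)
    assert sol.coverage >= 0.8
    lo, hi = 3, 30
    assert lo <= sol.n_trees <= hi


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


def test_zero_noise_ensemble_equals_single_run():
    net = make_net([("a", "b", 0.3), ("b", "c", 0.3), ("c", "d", 0.9)])
    t = terminals({"a": 1.0, "c": 0.8, "d": 0.7})
    cfg = pc.PcsfConfig(mu=0.0, omega=0.5, beta=2.0, ensemble_runs=5, noise=0.0)
    single = pc.solve_pcsf(net, t, cfg)
    ens = pc.ensemble_solve(net, t, cfg)
    assert set(ens.graph.nodes) == set(single.nodes)
    for _, _, d in ens.graph.edges(data=True):
        assert d["frequency"] == 1.0


def test_ensemble_frequencies_and_union_superset():
    rng = np.random.default_rng(13)
    net, term, cfg0 = random_instance(rng)
    cfg = pc.PcsfConfig(mu=cfg0.mu, omega=cfg0.omega, beta=cfg0.beta, ensemble_runs=8, noise=0.3, seed=5)
    ens = pc.ensemble_solve(net, term, cfg)
    for _, _, d in ens.graph.edges(data=True):
        assert 0 < d["frequency"] <= 1.0
        assert round(d["frequency"] * cfg.ensemble_runs, 6) == int(round(d["frequency"] * cfg.ensemble_runs))
    single = pc.solve_pcsf(net, term, pc.PcsfConfig(mu=cfg.mu, omega=cfg.omega, beta=cfg.beta))
    # the union is built from noisy runs; check it is a superset of at least
    # the noiseless solution's terminals when noise is moderate
    assert set(ens.graph.nodes) >= set(v for v in single.nodes if v in term.prizes)


def test_negative_noise_rejected():
    net = make_net([("a", "b", 0.3)])
    with pytest.raises(Exception):
        pc.ensemble_solve(net, terminals({"a": 1.0}), pc.PcsfConfig(noise=-0.1))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def test_two_triangles_with_bridge_split_at_the_bridge():
    edges = [("a", "b", 0.1), ("b", "c", 0.1), ("a", "c", 0.1),
             ("d", "e", 0.1), ("e", "f", 0.1), ("d", "f", 0.1),
             ("c", "d", 0.1)]
    cl = pc.cluster_network(make_net(edges))
    assert cl.n_clusters == 2
    assert cl.assignment["a"] == cl.assignment["b"] == cl.assignment["c"]
    assert cl.assignment["d"] == cl.assignment["e"] == cl.assignment["f"]
    assert cl.assignment["a"] != cl.assignment["d"]


def test_complete_graph_stays_one_cluster():
    edges = [(a, b, 0.1) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
    cl = pc.cluster_network(make_net(edges))
    assert cl.n_clusters == 1


def test_disconnected_components_are_never_merged():
    edges = [("a", "b", 0.1), ("c", "d", 0.1)]
    cl = pc.cluster_network(make_net(edges))
    assert cl.assignment["a"] == cl.assignment["b"]
    assert cl.assignment["c"] == cl.assignment["d"]
    assert cl.assignment["a"] != cl.assignment["c"]


def test_empty_network_raises():
    with pytest.raises(ValueError):
        pc.cluster_network(MultiLayerNetwork(graph=nx.Graph()))


# ---------------------------------------------------------------------------
# cluster profiles
# ---------------------------------------------------------------------------


def test_cluster_profiles_means_and_percentages():
    cl = pc.ClusteredNetwork(assignment={"A": 0, "B": 0, "C": 1}, modularity=0.0)
    ct = make_contrast([1.0, 1.0, -2.0], index=["fA", "fB", "fC"])
    ct.table["significant"] = [False, False, True]
    node_map = {"fA": "A", "fB": "B", "fC": "C"}
    prof = pc.cluster_profiles(cl, [ct], node_map)
    c0 = prof[prof["cluster"] == 0].iloc[0]
    assert c0["mean_log2fc"] == pytest.approx(1.0)
    assert c0["pct_significant"] == pytest.approx(0.0)
    c1 = prof[prof["cluster"] == 1].iloc[0]
    assert c1["mean_log2fc"] == pytest.approx(-2.0)
    assert c1["pct_significant"] == pytest.approx(100.0)


def test_cluster_without_measured_molecules_gives_null_row():
    cl = pc.ClusteredNetwork(assignment={"X": 0}, modularity=0.0)
    ct = make_contrast([1.0], index=["fA"])
    prof = pc.cluster_profiles(cl, [ct], {"fA": "other_node"})
    assert prof["n_molecules"].iloc[0] == 0
    assert np.isnan(prof["mean_log2fc"].iloc[0])
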