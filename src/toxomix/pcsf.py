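"""Prize-collecting Steiner forest over the aggregated molecular network.

Terminals are the most influential molecules of a latent factor: per
modality, absolute factor weights are normalized by the modality maximum,
features at or above twice the modality's mean normalized weight (the
chance expectation) are kept, truncated to the top 200, and the normalized
weights become prizes. The optimization minimizes

    sum_{e in F} c_e  +  sum_{v in F} mu * deg(v)  +  omega * (#trees)
    -  sum_{v in F} beta * p_v

over forests F of the network (deg is the node's degree in the full
network — a hub penalty). Internally the forest problem is reduced to a
rooted problem via a virtual root connected to every node at cost omega; a
Goemans-Williamson moat-growth phase followed by strong pruning gives the
heuristic solution, and an exhaustive subset solver (provably optimal) is
used automatically for instances with at most 12 nodes.

A grid search over (omega, beta) records terminal coverage and tree counts
and picks the smallest beta at which coverage saturates among omegas with a
"decent" number of trees; the final network is the union of several runs
with multiplicative noise on the edge costs; edge-betweenness (Girvan-
Newman) clustering cut at maximal modularity yields functional clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from ._utils import ConfigError
from .diffabund import ContrastTable
from .factors import FactorResults
from .netbuild import MultiLayerNetwork

logger = logging.getLogger(__name__)

MAX_TERMINALS_PER_MODALITY = 200
CHANCE_FOLD = 2.0
_EXACT_NODE_LIMIT = 12
_EPS = 1e-12


@dataclass
class PcsfConfig:
    mu: float = 0.0005
    omega: float = 0.6
    beta: float = 1000.0
    ensemble_runs: int = 10
    noise: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if min(self.mu, self.omega, self.beta, self.noise) < 0:
            raise ConfigError("mu, omega, beta and noise must be non-negative")
        if self.ensemble_runs < 1:
            raise ConfigError("ensemble_runs must be >= 1")


@dataclass
class TerminalSet:
    """Prized terminal nodes (already mapped onto network node ids)."""

    table: pd.DataFrame  # index node_id; columns: prize, modality

    @property
    def prizes(self) -> dict[str, float]:
        return self.table["prize"].to_dict()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ForestSolution:
    nodes: list[str]
    edges: list[tuple[str, str, float]]
    trees: list[list[str]]
    objective: float
    coverage: float
    steiner_nodes: list[str]
    status: str = "ok"

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class ClusteredNetwork:
    assignment: dict[str, int]
    modularity: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0


# ---------------------------------------------------------------------------
# terminal selection
# ---------------------------------------------------------------------------


def select_terminals(
    results: FactorResults,
    factor: str | int,
    node_map: dict[str, str],
    max_per_modality: int = MAX_TERMINALS_PER_MODALITY,
) -> TerminalSet:
    """Per-modality prize selection from the factor's weight vector."""
    names = results.factor_names
    fname = names[factor] if isinstance(factor, int) else fname_check(factor, names)
    rows = []
    for modality, w in results.weights.items():
        absw = w[fname].abs()
        mx = float(absw.max())
        if mx <= 0:
            continue
        wn = absw / mx
        expect = float(wn.mean())
        qualifying = wn[wn >= CHANCE_FOLD * expect]
        qualifying = qualifying.sort_values(ascending=False, kind="stable")
        qualifying = qualifying.iloc[:max_per_modality]
        n_unmapped = 0
        for feat, prize in qualifying.items():
            node = node_map.get(feat)
            if node is None:
                n_unmapped += 1
                continue
            rows.append({"node_id": node, "prize": float(prize), "modality": modality})
        if n_unmapped:
            logger.info("select_terminals[%s]: dropped %d qualifying features without network node", modality, n_unmapped)
    if not rows:
        return TerminalSet(table=pd.DataFrame(columns=["prize", "modality"]))
    df = pd.DataFrame(rows)
    # mRNA and protein hits on the same gene node: keep the larger prize
    df = (
        df.sort_values(["node_id", "prize"], ascending=[True, False])
        .groupby("node_id")
        .agg(prize=("prize", "max"), modality=("modality", lambda s: "+".join(sorted(set(s)))))
    )
    return TerminalSet(table=df)


def fname_check(factor: str, names: list[str]) -> str:
    if factor not in names:
        raise IndexError(f"factor {factor!r} not in model (have {names})")
    return factor


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _forest_objective(nodes, edges, gain: dict[str, float], omega: float) -> float:
    """Objective of a candidate forest; raises if the edge set has a cycle."""
    uf = _UnionFind(len(nodes))
    index = {v: i for i, v in enumerate(nodes)}
    cost = 0.0
    for a, b, c in edges:
        if not uf.union(index[a], index[b]):
            raise ValueError("candidate edge set contains a cycle")
        cost += c
    n_trees = len({uf.find(i) for i in range(len(nodes))})
    return cost + omega * n_trees - sum(gain[v] for v in nodes)


def _exhaustive_solve(nodes, edge_list, gain, omega):
    """Optimal node subset by enumeration; edges via MST with per-edge drops."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = sorted(((c, index[a], index[b], a, b) for a, b, c in edge_list))
    best_obj, best_sol = 0.0, ([], [])
    for mask in range(1, 1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        uf = _UnionFind(n)
        kept = []
        cost = 0.0
        for c, ia, ib, a, b in edges:
            if (mask >> ia & 1) and (mask >> ib & 1) and uf.union(ia, ib):
                # dropping an MST edge costs omega for the extra tree; worth
                # it exactly when c > omega
                if c <= omega:
                    kept.append((a, b, c))
                    cost += c
                else:
                    cost += omega
        n_comp = len({uf.find(i) for i in members})
        obj = cost + omega * n_comp - sum(gain[nodes[i]] for i in members)
        if obj < best_obj - _EPS or (
            abs(obj - best_obj) <= _EPS and len(members) < len(best_sol[0])
        ):
            best_obj = obj
            best_sol = ([nodes[i] for i in members], kept)
    return best_sol


def _gw_solve(nodes, edge_list, gain, omega):
    """Goemans-Williamson moat growth on the virtual-root graph + strong pruning."""
    n = len(nodes)
    root = n
    index = {v: i for i, v in enumerate(nodes)}
    eu = np.array([index[a] for a, b, c in edge_list] + list(range(n)), dtype=int)
    ev = np.array([index[b] for a, b, c in edge_list] + [root] * n, dtype=int)
    ecost = np.array([c for _, _, c in edge_list] + [omega] * n, dtype=float)
    m_real = len(edge_list)
    m = len(ecost)
    load = np.zeros(m)

    cluster = np.arange(n + 1)
    members: dict[int, list[int]] = {i: [i] for i in range(n + 1)}
    q = np.array([max(gain[v], 0.0) for v in nodes] + [0.0])
    active = np.zeros(n + 1, dtype=bool)
    active[:n] = q[:n] > 0
    surplus = q.copy()
    root_cluster = root
    merge_edges: list[int] = []

    guard = 0
    while active.any() and guard < 4 * (n + 2):
        guard += 1
        cu, cv = cluster[eu], cluster[ev]
        rate = active[cu].astype(float) + active[cv].astype(float)
        cross = cu != cv
        with np.errstate(divide="ignore", invalid="ignore"):
            te = np.where(cross & (rate > 0), (ecost - load) / np.where(rate > 0, rate, 1.0), np.inf)
        act_ids = np.where(active)[0]
        e_min = float(te.min()) if te.size else np.inf
        c_min = float(surplus[act_ids].min()) if act_ids.size else np.inf
        dt = min(e_min, c_min)
        if not np.isfinite(dt):
            break
        grow = cross & (rate > 0)
        load[grow] += rate[grow] * dt
        surplus[act_ids] -= dt
        if e_min <= c_min + _EPS:
            cand = np.where(te <= dt + 1e-12)[0]
            root_cand = cand[cand >= m_real]  # tie-break: root edges merge first
            ei = int(root_cand.min()) if root_cand.size else int(cand.min())
            ca, cb = int(cluster[eu[ei]]), int(cluster[ev[ei]])
            merge_edges.append(ei)
            if cb == root_cluster or (len(members[cb]) > len(members[ca]) and ca != root_cluster):
                ca, cb = cb, ca
            for vtx in members[cb]:
                cluster[vtx] = ca
            members[ca].extend(members.pop(cb))
            surplus[ca] = surplus[ca] + surplus[cb]
            active[cb] = False
            active[ca] = ca != root_cluster
        else:
            active[act_ids[int(np.argmin(surplus[act_ids]))]] = False

    # un-pruned forest: real edges of the root component (root edges dropped
    # split the component into candidate trees, handled by strong pruning)
    adj: dict[int, list[tuple[int, int]]] = {}
    for ei in merge_edges:
        a, b = int(eu[ei]), int(ev[ei])
        adj.setdefault(a, []).append((b, ei))
        adj.setdefault(b, []).append((a, ei))
    if root not in adj:
        return [], []
    seen = {root}
    stack = [root]
    comp = []
    while stack:
        v = stack.pop()
        comp.append(v)
        for w, _ in adj.get(v, []):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    cand_nodes = [nodes[v] for v in comp if v != root]
    cand_edges = [
        (nodes[min(int(eu[ei]), int(ev[ei]))], nodes[max(int(eu[ei]), int(ev[ei]))], float(ecost[ei]))
        for ei in merge_edges
        if ei < m_real and int(eu[ei]) in seen and int(ev[ei]) in seen
    ]
    return sorted(cand_nodes), cand_edges


def _strong_prune(cand_nodes, cand_edges, gain, omega):
    """Strong pruning of a candidate forest under the full objective.

    Bottom-up payoff W(v) = gain(v) + sum over kept children of (W(c) - e);
    a child edge is kept only when it is cheaper than starting a new tree
    (e <= omega) and pays for itself; otherwise the child subtree is
    reconsidered as its own candidate tree root (paying omega), recursively.
    """
    adj: dict[str, list[tuple[str, float]]] = {v: [] for v in cand_nodes}
    for a, b, c in cand_edges:
        adj[a].append((b, c))
        adj[b].append((a, c))

    kept_nodes: list[str] = []
    kept_edges: list[tuple[str, str, float]] = []
    visited_roots: set[str] = set()
    components: dict[str, str] = {}
    for start in sorted(cand_nodes):
        if start in components:
            continue
        stack = [start]
        components[start] = start
        while stack:
            v = stack.pop()
            for w, _ in adj[v]:
                if w not in components:
                    components[w] = start
                    stack.append(w)

    root_queue = sorted({components[v] for v in cand_nodes})
    while root_queue:
        r = root_queue.pop(0)
        if r in visited_roots:
            continue
        visited_roots.add(r)
        parent: dict[str, tuple[str | None, float]] = {r: (None, 0.0)}
        order = [r]
        stack = [r]
        while stack:
            v = stack.pop()
            for w, c in adj[v]:
                if w not in parent:
                    parent[w] = (v, c)
                    order.append(w)
                    stack.append(w)
        payoff: dict[str, float] = {}
        keep: dict[str, bool] = {}
        enqueue: list[str] = []
        for v in reversed(order):
            base = gain[v]
            for w, c in adj[v]:
                if parent.get(w, (None, 0.0))[0] == v:
                    if c <= omega + _EPS and payoff[w] - c > _EPS:
                        keep[w] = True
                        base += payoff[w] - c
                    else:
                        keep[w] = False
                        enqueue.append(w)
            payoff[v] = base
        if payoff[r] - omega > _EPS:
            stack = [r]
            while stack:
                v = stack.pop()
                kept_nodes.append(v)
                for w, c in adj[v]:
                    if parent.get(w, (None, 0.0))[0] == v and keep.get(w):
                        stack.append(w)
                        kept_edges.append((min(v, w), max(v, w), c))
        else:
            # tree not worth a root: reconsider its immediate subtrees
            for w, c in adj[r]:
                if parent.get(w, (None, 0.0))[0] == r:
                    enqueue.append(w)
        for w in enqueue:
            if w not in visited_roots and w not in kept_nodes:
                # re-root the subtree of w (detach from its parent)
                adj[parent[w][0]] = [(x, c) for x, c in adj[parent[w][0]] if x != w]
                adj[w] = [(x, c) for x, c in adj[w] if x != parent[w][0]]
                root_queue.append(w)
    return sorted(set(kept_nodes)), kept_edges


def _best_edges_for_nodes(node_set: set[str], edge_list, omega: float):
    """Optimal forest edges for a fixed node set: MST per induced component,
    with any MST edge costlier than omega dropped (splitting pays omega)."""
    nodes = sorted(node_set)
    index = {v: i for i, v in enumerate(nodes)}
    uf = _UnionFind(len(nodes))
    kept = []
    for a, b, c in sorted(edge_list, key=lambda e: (e[2], e[0], e[1])):
        if a in node_set and b in node_set and uf.union(index[a], index[b]) and c <= omega + _EPS:
            kept.append((a, b, c))
    return kept


def _polish(node_set, edge_list, gain, omega):
    """Local improvement: recompute best edges for the node set, then drop
    leaves and singleton trees that do not pay for themselves; iterate."""
    s = set(node_set)
    edges = []
    for _ in range(len(s) + 1):
        edges = _best_edges_for_nodes(s, edge_list, omega)
        deg: dict[str, int] = {v: 0 for v in s}
        inc: dict[str, float] = {}
        for a, b, c in edges:
            deg[a] += 1
            deg[b] += 1
            inc[a] = min(inc.get(a, np.inf), c)
            inc[b] = min(inc.get(b, np.inf), c)
        bad = [v for v in s if (deg[v] == 0 and gain[v] <= omega + _EPS)
               or (deg[v] == 1 and gain[v] < inc[v] - _EPS)]
        if not bad:
            break
        s -= set(bad)
    return sorted(s), edges


def _steiner_mst_candidate(g: nx.Graph, gain: dict[str, float], mu_deg: dict[str, float], omega: float):
    """Metric-closure MST over positive-gain terminals (node-cost-aware)."""
    terms = sorted(v for v, q in gain.items() if q > 0)
    if len(terms) < 2:
        return terms, []
    h = nx.Graph()
    for a, b, data in g.edges(data=True):
        h.add_edge(a, b, w=data["cost"] + 0.5 * (mu_deg[a] + mu_deg[b]))
    dist = {}
    paths = {}
    for t in terms:
        if t not in h:
            continue
        d, p = nx.single_source_dijkstra(h, t, weight="w")
        dist[t] = d
        paths[t] = p
    meta = nx.Graph()
    meta.add_nodes_from([t for t in terms if t in h])
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            if a in dist and b in dist.get(a, {}):
                meta.add_edge(a, b, w=dist[a][b])
    nodes_out: set[str] = set(t for t in terms)
    edges_out: set[tuple[str, str]] = set()
    for a, b in nx.minimum_spanning_edges(meta, weight="w", data=False):
        path = paths[a][b]
        nodes_out |= set(path)
        for u, v in zip(path[:-1], path[1:]):
            edges_out.add((min(u, v), max(u, v)))
    sub = nx.Graph()
    sub.add_nodes_from(nodes_out & set(g.nodes))
    for u, v in edges_out:
        sub.add_edge(u, v, cost=g[u][v]["cost"])
    mst_edges = []
    for u, v in nx.minimum_spanning_edges(sub, weight="cost", data=False):
        mst_edges.append((min(u, v), max(u, v), float(g[u][v]["cost"])))
    return sorted(sub.nodes), mst_edges


def solve_pcsf(net: MultiLayerNetwork, terminals: TerminalSet, config: PcsfConfig,
               _edge_costs: dict[tuple[str, str], float] | None = None,
               force_heuristic: bool = False) -> ForestSolution:
    """Solve the prize-collecting Steiner forest instance.

    ``_edge_costs`` optionally overrides edge costs (used by the noisy
    ensemble). Instances with at most 12 nodes are solved exactly unless
    ``force_heuristic`` is set.
    """
    config.validate()
    g = net.graph
    nodes = sorted(g.nodes)
    prizes = terminals.prizes
    in_graph = [t for t in prizes if t in g]
    if not in_graph:
        return ForestSolution(nodes=[], edges=[], trees=[], objective=0.0, coverage=0.0,
                              steiner_nodes=[], status="no_terminal_in_network")
    gain = {v: config.beta * prizes.get(v, 0.0) - config.mu * g.degree(v) for v in nodes}
    edge_list = []
    for a, b, data in g.edges(data=True):
        a2, b2 = (a, b) if a <= b else (b, a)
        c = (_edge_costs or {}).get((a2, b2), data["cost"])
        edge_list.append((a2, b2, float(c)))
    edge_list.sort()

    if len(nodes) <= _EXACT_NODE_LIMIT and not force_heuristic:
        candidates = [_exhaustive_solve(nodes, edge_list, gain, config.omega)]
    else:
        raw_nodes, raw_edges = _gw_solve(nodes, edge_list, gain, config.omega)
        candidates = [_strong_prune(raw_nodes, raw_edges, gain, config.omega)]
        if len(nodes) <= 400:
            # second candidate from a metric-closure Steiner MST (cheap only
            # on small instances)
            mu_deg = {v: config.mu * g.degree(v) for v in nodes}
            sn, se = _steiner_mst_candidate(g, gain, mu_deg, config.omega)
            candidates.append(_strong_prune(sn, se, gain, config.omega))
        candidates.append(([], []))

    # best-of, judged by the exact objective: add every profitable singleton
    # tree (gain > omega), then polish (optimal edges for the node set plus
    # removal of unprofitable leaves)
    best = None
    for cn, ce in candidates:
        cn = set(cn) | {v for v in nodes if gain[v] > config.omega + _EPS}
        if len(nodes) <= _EXACT_NODE_LIMIT and not force_heuristic:
            cn, ce = sorted(cn), ce  # exhaustive solution is already optimal
        else:
            cn, ce = _polish(cn, edge_list, gain, config.omega)
        obj = _forest_objective(cn, ce, gain, config.omega) if cn else 0.0
        key = (obj, len(cn), tuple(sorted(cn)))
        if best is None or key < best[0]:
            best = (key, list(cn), ce)
    _, sol_nodes, sol_edges = best

    sub = nx.Graph()
    sub.add_nodes_from(sol_nodes)
    sub.add_edges_from([(a, b) for a, b, _ in sol_edges])
    trees = [sorted(c) for c in nx.connected_components(sub)]
    trees.sort()
    objective = _forest_objective(sol_nodes, sol_edges, gain, config.omega) if sol_nodes else 0.0
    covered = sum(1 for t in in_graph if t in sub)
    solution = ForestSolution(
        nodes=sorted(sol_nodes),
        edges=sorted(sol_edges),
        trees=trees,
        objective=float(objective),
        coverage=covered / len(in_graph),
        steiner_nodes=sorted(v for v in sol_nodes if v not in prizes),
    )
    # decomposition check: the reported objective must be recomputable
    assert abs(solution.objective - (_forest_objective(solution.nodes, solution.edges, gain, config.omega) if solution.nodes else 0.0)) < 1e-9
    return solution


# ---------------------------------------------------------------------------
# grid search and ensemble
# ---------------------------------------------------------------------------


def grid_search(
    net: MultiLayerNetwork,
    terminals: TerminalSet,
    config: PcsfConfig | None = None,
    omegas=(0.2, 0.4, 0.6, 0.8, 1.0),
    betas=(100.0, 250.0, 500.0, 1000.0, 2000.0),
    tree_band: tuple[int, int] = (3, 30),
    saturation_gain_pp: float = 2.0,
):
    """Coverage/tree-count curve over the (omega, beta) grid and a chosen
    configuration: per eligible omega (tree count within ``tree_band``), the
    smallest beta whose coverage gain over the previous beta step is below
    ``saturation_gain_pp`` percentage points; across omegas, the highest
    coverage (ties: smaller omega, then smaller beta)."""
    if not omegas or not betas:
        raise ConfigError("empty grid")
    base = config or PcsfConfig()
    rows = []
    for om in omegas:
        for be in sorted(betas):
            sol = solve_pcsf(net, terminals, replace(base, omega=float(om), beta=float(be)))
            rows.append({"omega": om, "beta": be, "coverage_pct": 100.0 * sol.coverage, "n_trees": sol.n_trees})
    curve = pd.DataFrame(rows)
    lo, hi = tree_band
    candidates = []
    for om, sub in curve.groupby("omega"):
        sub = sub.sort_values("beta").reset_index(drop=True)
        eligible_beta = set(sub.loc[(sub["n_trees"] >= lo) & (sub["n_trees"] <= hi), "beta"])
        if not eligible_beta:
            continue
        chosen = None
        for i in range(len(sub)):
            if i == 0:
                # the smallest beta saturates if the next step adds nothing
                saturated = len(sub) == 1 or (sub.loc[1, "coverage_pct"] - sub.loc[0, "coverage_pct"] < saturation_gain_pp)
            else:
                saturated = (sub.loc[i, "coverage_pct"] - sub.loc[i - 1, "coverage_pct"]) < saturation_gain_pp
            if saturated and sub.loc[i, "beta"] in eligible_beta:
                chosen = sub.loc[i]
                break
        if chosen is not None:
            candidates.append((float(-chosen["coverage_pct"]), float(om), float(chosen["beta"])))
    if not candidates:
        best = curve.sort_values(["coverage_pct", "omega", "beta"], ascending=[False, True, True]).iloc[0]
        logger.warning("grid_search: no grid point with tree count in band %s; falling back to best coverage", tree_band)
        chosen_cfg = replace(base, omega=float(best["omega"]), beta=float(best["beta"]))
        return chosen_cfg, curve
    candidates.sort()
    _, om, be = candidates[0]
    return replace(base, omega=om, beta=be), curve


def ensemble_solve(net: MultiLayerNetwork, terminals: TerminalSet, config: PcsfConfig) -> MultiLayerNetwork:
    """Union of ``ensemble_runs`` solutions with multiplicative Uniform(-r, r)
    noise on edge costs; node/edge selection frequencies are annotated."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    runs = config.ensemble_runs
    node_count: dict[str, int] = {}
    edge_count: dict[tuple[str, str], int] = {}
    g = net.graph
    base_costs = {}
    for a, b, data in g.edges(data=True):
        key = (a, b) if a <= b else (b, a)
        base_costs[key] = data["cost"]
    for _ in range(runs):
        noisy = {k: c * (1.0 + rng.uniform(-config.noise, config.noise)) for k, c in base_costs.items()}
        sol = solve_pcsf(net, terminals, config, _edge_costs=noisy)
        for v in sol.nodes:
            node_count[v] = node_count.get(v, 0) + 1
        for a, b, _ in sol.edges:
            key = (a, b) if a <= b else (b, a)
            edge_count[key] = edge_count.get(key, 0) + 1
    logger.info("ensemble_solve: %d runs, union of %d nodes / %d edges", runs, len(node_count), len(edge_count))
    out = nx.Graph()
    prizes = terminals.prizes
    for v, cnt in node_count.items():
        out.add_node(v, layer=g.nodes[v].get("layer", ""), prize=float(prizes.get(v, 0.0)), frequency=cnt / runs)
    for (a, b), cnt in edge_count.items():
        out.add_edge(a, b, cost=float(base_costs[(a, b)]), provenance=g[a][b].get("provenance", ""), frequency=cnt / runs)
    return MultiLayerNetwork(graph=out)


# ---------------------------------------------------------------------------
# clustering and profiles
# ---------------------------------------------------------------------------


def cluster_network(net: MultiLayerNetwork) -> ClusteredNetwork:
    """Girvan-Newman edge-betweenness clustering cut at maximum modularity."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(g.nodes)
    if g.number_of_edges() == 0:
        return ClusteredNetwork(assignment={v: i for i, v in enumerate(nodes)}, modularity=0.0)
    index = {v: i for i, v in enumerate(nodes)}
    h = ig.Graph(n=len(nodes), edges=[(index[a], index[b]) for a, b in g.edges()])
    weights = [g[a][b].get("cost", 1.0) for a, b in g.edges()]  # cost as distance for betweenness
    dendro = h.community_edge_betweenness(directed=False, weights=weights)
    n_comp = len(h.connected_components())
    best = None
    for k in range(n_comp, len(nodes) + 1):
        try:
            clustering = dendro.as_clustering(k)
        except Exception:
            continue
        mod = h.modularity(clustering.membership)
        if best is None or mod > best[0] + 1e-12:
            best = (mod, clustering.membership)
    mod, membership = best
    return ClusteredNetwork(assignment={v: int(membership[index[v]]) for v in nodes}, modularity=float(mod))


def cluster_profiles(
    clustered: ClusteredNetwork,
    contrasts: list[ContrastTable],
    node_map: dict[str, str],
) -> pd.DataFrame:
    """Per cluster x contrast mean log2FC and percent FDR-significant molecules.

    Molecules measured in multiple modalities contribute once per modality.
    """
    node_features: dict[str, list[tuple[str, str]]] = {}
    for feat, node in node_map.items():
        node_features.setdefault(node, []).append((feat, ""))
    by_contrast: dict[tuple[str, int], list[ContrastTable]] = {}
    for ct in contrasts:
        by_contrast.setdefault((ct.group, ct.timepoint), []).append(ct)
    clusters = sorted(set(clustered.assignment.values()))
    rows = []
    for cl in clusters:
        members = [v for v, c in clustered.assignment.items() if c == cl]
        for (group, tp), tables in sorted(by_contrast.items()):
            fcs, sigs = [], []
            for v in members:
                for feat, _ in node_features.get(v, []):
                    for ct in tables:
                        if feat in ct.table.index:
                            fcs.append(float(ct.table.loc[feat, "logFC"]))
                            sigs.append(bool(ct.table.loc[feat, "significant"]))
            rows.append(
                {
                    "cluster": cl,
                    "group": group,
                    "timepoint": tp,
                    "n_molecules": len(fcs),
                    "mean_log2fc": float(np.mean(fcs)) if fcs else np.nan,
                    "pct_significant": 100.0 * float(np.mean(sigs)) if sigs else np.nan,
                }
            )
    return pd.DataFrame(rows)
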