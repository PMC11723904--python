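from itertools import combinations

import numpy as np
import pytest

from longaxon.graph import (
    EdgeWeightParams,
    WeightedSpatialGraph,
    build_edges,
    weigh_edges,
)
from longaxon.steiner import (
    SteinerError,
    approximate_steiner,
    exact_steiner_oracle,
    solution_to_skeleton,
)


def graph_from_edges(coords, edge_weights):
    """Explicit weighted graph (weights realised as edge lengths)."""
    nodes = np.asarray(coords, float)
    edges = np.array(sorted(edge_weights), dtype=int)
    g = WeightedSpatialGraph(
        nodes=nodes,
        roles=["x"] * len(nodes),
        edges=edges,
        length=np.array([edge_weights[tuple(e)] for e in edges]),
        o=np.ones(len(edges)),
        zeta=np.ones(len(edges)),
        gamma=np.ones(len(edges)),
    )
    return g


def random_geometric_graph(rng, n):
    pts = rng.uniform(0, 100, (n, 3))
    edges = build_edges(pts)
    return weigh_edges(
        pts, edges, ["x"] * n, EdgeWeightParams(source_point=pts[0], lambda_o=0.0)
    )


def brute_force_opt(graph, terminals):
    """Independent oracle: min MST weight over all Steiner-node subsets."""
    n = graph.n_nodes
    wmap = {tuple(e): w for e, w in zip(graph.edges.tolist(), graph.weights)}
    non_terms = [v for v in range(n) if v not in terminals]
    best = np.inf
    for r in range(len(non_terms) + 1):
        for extra in combinations(non_terms, r):
            nodes = set(terminals) | set(extra)
            # Prim over induced subgraph
            sub = {e: w for e, w in wmap.items() if e[0] in nodes and e[1] in nodes}
            seen = {min(nodes)}
            weight = 0.0
            while len(seen) < len(nodes):
                cand = [
                    (w, e)
                    for e, w in sub.items()
                    if (e[0] in seen) != (e[1] in seen)
                ]
                if not cand:
                    weight = np.inf
                    break
                w, e = min(cand)
                weight += w
                seen.update(e)
            best = min(best, weight)
    return best


class TestApproximation:
    def test_path_graph(self):
        g = graph_from_edges(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0]], {(0, 1): 1.0, (1, 2): 1.0}
        )
        sol = approximate_steiner(g, [0, 2])
        assert sol.total_weight == pytest.approx(2.0)
        assert sorted(sol.edges) == [(0, 1), (1, 2)]

    def test_star_hub_is_steiner_node(self):
        g = graph_from_edges(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
            {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0},
        )
        sol = approximate_steiner(g, [1, 2, 3])
        assert sol.total_weight == pytest.approx(3.0)
        assert sol.steiner_nodes() == {0}

    def test_unreachable_terminal(self):
        g = graph_from_edges(
            [[0, 0, 0], [1, 0, 0], [5, 5, 5], [6, 5, 5]],
            {(0, 1): 1.0, (2, 3): 1.0},
        )
        with pytest.raises(SteinerError, match="unreachable terminal"):
            approximate_steiner(g, [0, 2])

    def test_tree_structure_no_nonterminal_leaves(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = random_geometric_graph(rng, 14)
            terms = sorted(rng.choice(14, 4, replace=False).tolist())
            sol = approximate_steiner(g, terms)
            nodes = sol.nodes
            assert len(sol.edges) == len(nodes) - 1  # a tree
            degree = {}
            for a, b in sol.edges:
                degree[a] = degree.get(a, 0) + 1
                degree[b] = degree.get(b, 0) + 1
            for v, d in degree.items():
                assert d > 1 or v in terms


class TestExactOracle:
    def test_two_terminals_is_shortest_path(self):
        g = graph_from_edges(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 1, 0]],
            {(0, 1): 1.0, (1, 2): 1.0, (0, 3): 5.0, (3, 2): 5.0},
        )
        sol = exact_steiner_oracle(g, [0, 2])
        assert sol.total_weight == pytest.approx(2.0)

    def test_triangle_three_terminals(self):
        g = graph_from_edges(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0},
        )
        sol = exact_steiner_oracle(g, [0, 1, 2])
        assert sol.total_weight == pytest.approx(2.0)

    def test_star_matches_subset_enumeration(self):
        g = graph_from_edges(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
            {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0, (1, 2): 1.9},
        )
        sol = exact_steiner_oracle(g, [1, 2, 3])
        assert sol.total_weight == pytest.approx(brute_force_opt(g, [1, 2, 3]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_geometric_graph(rng, 8)
        terms = sorted(rng.choice(8, 3, replace=False).tolist())
        sol = exact_steiner_oracle(g, terms)
        assert sol.total_weight == pytest.approx(brute_force_opt(g, terms), rel=1e-9)

    def test_oracle_limit(self):
        rng = np.random.default_rng(1)
        g = random_geometric_graph(rng, 20)
        with pytest.raises(SteinerError, match="oracle limit exceeded"):
            exact_steiner_oracle(g, [0, 1])

    @pytest.mark.parametrize("seed", range(12))
    def test_approximation_bound(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 16))
        g = random_geometric_graph(rng, n)
        terms = sorted(rng.choice(n, int(rng.integers(2, 6)), replace=False).tolist())
        approx = approximate_steiner(g, terms).total_weight
        opt = exact_steiner_oracle(g, terms).total_weight
        assert opt - 1e-9 <= approx <= 2 * opt + 1e-9

    def test_cross_check_with_networkx(self):
        nx = pytest.importorskip("networkx")
        from networkx.algorithms.approximation import steiner_tree

        rng = np.random.default_rng(3)
        g = random_geometric_graph(rng, 12)
        G = nx.Graph()
        for (u, v), w in zip(g.edges, g.weights):
            G.add_edge(int(u), int(v), weight=float(w))
        terms = [0, 4, 9]
        nx_weight = sum(
            d["weight"] for _, _, d in steiner_tree(G, terms).edges(data=True)
        )
        opt = exact_steiner_oracle(g, terms).total_weight
        assert opt <= nx_weight + 1e-9


class TestSkeleton:
    def test_path_solution_single_polyline(self):
        g = graph_from_edges(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0]], {(0, 1): 1.0, (1, 2): 1.0}
        )
        sol = approximate_steiner(g, [0, 2])
        sk = solution_to_skeleton(sol, g, 0, [2])
        assert len(sk.branches) == 1
        assert np.allclose(sk.branches[0].points, [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert sk.branches[0].end_is_target

    def test_y_solution_three_branches(self):
        g = graph_from_edges(
            [[0, 0, 0], [1, 0, 0], [2, 1, 0], [2, -1, 0]],
            {(0, 1): 1.0, (1, 2): 1.5, (1, 3): 1.5},
        )
        sol = approximate_steiner(g, [0, 2, 3])
        sk = solution_to_skeleton(sol, g, 0, [2, 3])
        assert len(sk.branches) == 3
        targets = sorted(map(tuple, sk.target_points))
        assert np.allclose(targets, [(2, -1, 0), (2, 1, 0)])

    def test_target_coordinates_exact(self):
        rng = np.random.default_rng(7)
        g = random_geometric_graph(rng, 15)
        terms = [0, 5, 10]
        sol = approximate_steiner(g, terms)
        sk = solution_to_skeleton(sol, g, 0, [5, 10])
        branch_ends = {tuple(b.points[-1]) for b in sk.branches}
        for t in (5, 10):
            assert tuple(g.nodes[t]) in branch_ends

    def test_rootless_solution(self):
        g = graph_from_edges(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0]], {(0, 1): 1.0, (1, 2): 1.0}
        )
        sol = approximate_steiner(g, [1, 2])
        with pytest.raises(SteinerError, match="rootless solution"):
            solution_to_skeleton(sol, g, 0, [2])
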