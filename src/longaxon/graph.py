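"""Weighted spatial graph on which the long-range trunk is solved.

The point set is grown in the order: terminals (source + targets), evenly
spaced intermediate points on each source-target segment, Poisson-disk-style
random points in the bounding box, and the circumcentres of the Delaunay
tetrahedra (Voronoi vertices, discarded beyond the bounding box plus a
margin).  Close points are then merged (terminals survive) and, when an
atlas is present, points outside the brain are dropped.  A Delaunay
triangulation of the final set provides the edges, which are weighted as

    w_i = l_i * o_i * zeta_i * gamma_i

where l_i is the edge length, o_i penalises edges transverse to the
source-to-midpoint direction, zeta_i penalises edges cutting across the
atlas depth field, and gamma_i rewards edges inside the attraction field
(preferred regions such as projection tracts).  With the amplitude
coefficient of the attraction term restricted to (-1, 0], preferred regions
strictly lower edge weights and all weights stay positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .atlas import AttractionField, VoxelAtlas

__all__ = [
    "GraphBuildParams",
    "EdgeWeightParams",
    "WeightedSpatialGraph",
    "GraphError",
    "build_point_set",
    "build_edges",
    "weigh_edges",
]


class GraphError(ValueError):
    """Raised for degenerate graph construction inputs."""


@dataclass(frozen=True)
class GraphBuildParams:
    """Counts and radii controlling point-set enrichment (micrometres)."""

    n_intermediate: int = 10
    n_random: int = 50
    r_random: float = 50.0
    merge_radius: float | None = None  # default r_random / 2
    bbox_margin: float = 100.0

    def __post_init__(self) -> None:
        if min(self.n_intermediate, self.n_random) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_random > 0 and self.r_random <= 0:
            raise ValueError("r_random must be > 0 when n_random > 0")
        if self.merge_radius is None:
            object.__setattr__(self, "merge_radius", self.r_random / 2.0)
        if self.merge_radius < 0 or self.bbox_margin < 0:
            raise ValueError("radii must be >= 0")


@dataclass(frozen=True)
class EdgeWeightParams:
    """Amplitudes and exponents of the edge-weight terms.

    ``lambda_gamma`` must lie in (-1, 0] so that high-affinity regions lower
    the weight (gamma_i spans (1 + lambda_gamma, 1]).
    """

    source_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    lambda_o: float = 0.3
    alpha_o: float = 2.0
    lambda_zeta: float = 0.0
    alpha_zeta: float = 1.0
    lambda_gamma: float = 0.0
    alpha_gamma: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "source_point", np.asarray(self.source_point, float).reshape(3)
        )
        if min(self.alpha_o, self.alpha_zeta, self.alpha_gamma) <= 0:
            raise ValueError("alpha exponents must be > 0")
        if self.lambda_o < 0 or self.lambda_zeta < 0:
            raise ValueError("lambda_o and lambda_zeta must be >= 0")
        if not (-1.0 < self.lambda_gamma <= 0.0):
            raise ValueError("lambda_gamma must be in (-1, 0]")


@dataclass
class WeightedSpatialGraph:
    """Node coordinates, role tags and weighted undirected edges."""

    nodes: np.ndarray  # (n, 3)
    roles: list[str]  # source | target | intermediate | random | voronoi
    edges: np.ndarray  # (m, 2) int, sorted pairs
    length: np.ndarray  # l_i
    o: np.ndarray
    zeta: np.ndarray
    gamma: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return self.length * self.o * self.zeta * self.gamma

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> "np.ndarray":
        """Sparse CSR adjacency matrix of edge weights."""
        from scipy.sparse import coo_matrix

        w = self.weights
        i, j = self.edges[:, 0], self.edges[:, 1]
        n = self.n_nodes
        return coo_matrix(
            (np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        ).tocsr()

    def to_tables(self):
        """(node table, edge table) pandas DataFrames for inspection."""
        import pandas as pd

        nodes = pd.DataFrame(self.nodes, columns=["x", "y", "z"])
        nodes["role"] = self.roles
        edges = pd.DataFrame(
            {
                "A": self.edges[:, 0],
                "B": self.edges[:, 1],
                "l": self.length,
                "o": self.o,
                "zeta": self.zeta,
                "gamma": self.gamma,
                "w": self.weights,
            }
        )
        return nodes, edges


# ---------------------------------------------------------------------------
# Point set
# ---------------------------------------------------------------------------


def _circumcenters(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumcentres of Delaunay tetrahedra (rows of ``simplices``)."""
    a = points[simplices[:, 0]]
    rhs_pts = points[simplices[:, 1:]]  # (m, 3, 3)
    d = rhs_pts - a[:, None, :]
    rhs = 0.5 * (d**2).sum(axis=2)
    centers = np.full((len(simplices), 3), np.nan)
    for k in range(len(simplices)):
        try:
            centers[k] = a[k] + np.linalg.solve(d[k], rhs[k])
        except np.linalg.LinAlgError:
            pass  # flat tetrahedron: skip
    return centers[~np.isnan(centers).any(axis=1)]


def build_point_set(
    source: np.ndarray,
    targets: np.ndarray,
    params: GraphBuildParams = GraphBuildParams(),
    atlas: VoxelAtlas | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Enriched node set for the trunk graph.

    Returns (points, roles) with the source first, then the targets, so the
    terminal indices are 0..len(targets).
    """
    rng = rng or np.random.default_rng()
    source = np.asarray(source, float).reshape(3)
    targets = np.atleast_2d(np.asarray(targets, float))
    for t in targets:
        if np.linalg.norm(t - source) == 0:
            raise GraphError("degenerate segment: target equals source")

    points: list[np.ndarray] = [source, *targets]
    roles: list[str] = ["source"] + ["target"] * len(targets)

    # 1. evenly spaced interior points on each source->target segment
    for t in targets:
        for k in range(1, params.n_intermediate + 1):
            frac = k / (params.n_intermediate + 1)
            points.append(source + frac * (t - source))
            roles.append("intermediate")

    # 2. Poisson-disk-style random points in the bounding box
    arr = np.array(points)
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    placed = 0
    attempts = 0
    max_attempts = 200 * max(params.n_random, 1)
    while placed < params.n_random and attempts < max_attempts:
        attempts += 1
        cand = rng.uniform(lo, hi)
        d = np.linalg.norm(np.array(points) - cand, axis=1)
        if d.min() >= params.r_random:
            points.append(cand)
            roles.append("random")
            placed += 1

    # 3. Voronoi vertices (circumcentres of the Delaunay tetrahedra)
    arr = np.array(points)
    if len(arr) >= 5:
        try:
            tri = Delaunay(arr)
            centers = _circumcenters(arr, tri.simplices)
            lo_m, hi_m = lo - params.bbox_margin, hi + params.bbox_margin
            keep = np.all((centers >= lo_m) & (centers <= hi_m), axis=1)
            for c in centers[keep]:
                points.append(c)
                roles.append("voronoi")
        except Exception:  # degenerate (coplanar) input: no enrichment
            pass

    # 4. merge close points, keeping terminals
    arr = np.array(points)
    n_term = 1 + len(targets)
    if params.merge_radius > 0 and len(arr) > n_term:
        tree = cKDTree(arr)
        pairs = tree.query_pairs(params.merge_radius)
        parent = list(range(len(arr)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in pairs:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        clusters: dict[int, list[int]] = {}
        for i in range(len(arr)):
            clusters.setdefault(find(i), []).append(i)
        kept_idx: list[int] = []
        for members in clusters.values():
            terms = [i for i in members if i < n_term]
            if terms:
                kept_idx.extend(terms)
            else:
                centroid = arr[members].mean(axis=0)
                d = np.linalg.norm(arr[members] - centroid, axis=1)
                kept_idx.append(members[int(np.argmin(d))])
        kept_idx = sorted(set(kept_idx))
        arr = arr[kept_idx]
        roles = [roles[i] for i in kept_idx]

    # 5. discard points outside the brain (never terminals)
    if atlas is not None:
        keep = [
            i < 1 + len(targets) or atlas.contains(arr[i]) for i in range(len(arr))
        ]
        arr = arr[np.array(keep)]
        roles = [r for r, k in zip(roles, keep) if k]

    return arr, roles


# ---------------------------------------------------------------------------
# Edges
# ---------------------------------------------------------------------------


def build_edges(nodes: np.ndarray) -> np.ndarray:
    """Unique undirected Delaunay edges; complete graph on degenerate input."""
    nodes = np.atleast_2d(np.asarray(nodes, float))
    n = len(nodes)
    if n < 2:
        raise GraphError("not enough nodes")
    edges: set[tuple[int, int]] = set()
    if n >= 4:
        try:
            tri = Delaunay(nodes)
            for simplex in tri.simplices:
                for a, b in combinations(sorted(simplex), 2):
                    edges.add((int(a), int(b)))
        except Exception:
            warnings.warn("degenerate point set: falling back to complete graph")
    if not edges:
        if n >= 4:
            warnings.warn("Delaunay produced no edges: complete graph fallback")
        edges = {(a, b) for a, b in combinations(range(n), 2)}
    return np.array(sorted(edges), dtype=int)


def weigh_edges(
    nodes: np.ndarray,
    edges: np.ndarray,
    roles: list[str],
    wparams: EdgeWeightParams,
    atlas: VoxelAtlas | None = None,
    attraction: AttractionField | None = None,
) -> WeightedSpatialGraph:
    """Assign the multiplicative weight factors to every edge."""
    nodes = np.atleast_2d(np.asarray(nodes, float))
    edges = np.asarray(edges, dtype=int)
    if wparams.lambda_zeta != 0 and atlas is None:
        raise GraphError("atlas required when lambda_zeta != 0")
    if wparams.lambda_gamma != 0 and attraction is None:
        raise GraphError("attraction field required when lambda_gamma != 0")

    A = nodes[edges[:, 0]]
    B = nodes[edges[:, 1]]
    AB = B - A
    length = np.linalg.norm(AB, axis=1)
    if np.any(length == 0):
        raise GraphError("degenerate edge")

    # orientation factor: sin of the angle between AB and SC (C = midpoint)
    S = wparams.source_point
    C = 0.5 * (A + B)
    SC = C - S
    sc_norm = np.linalg.norm(SC, axis=1)
    cross = np.linalg.norm(np.cross(AB, SC), axis=1)
    denom = length * sc_norm
    sin_angle = np.zeros(len(edges))
    ok = denom > 0
    sin_angle[ok] = np.clip(cross[ok] / denom[ok], 0.0, 1.0)
    o = 1.0 + wparams.lambda_o * sin_angle**wparams.alpha_o

    # depth factor
    if wparams.lambda_zeta != 0:
        yA = np.array([atlas.depth_at(p) for p in A])
        yB = np.array([atlas.depth_at(p) for p in B])
        zeta = 1.0 + wparams.lambda_zeta * (np.abs(yA - yB) / length) ** wparams.alpha_zeta
    else:
        zeta = np.ones(len(edges))

    # attraction factor
    if wparams.lambda_gamma != 0:
        gA = attraction(A)
        gB = attraction(B)
        gamma = 1.0 + wparams.lambda_gamma * (
            1.0 - np.exp(-(gA + gB) / (2.0 * wparams.alpha_gamma))
        )
    else:
        gamma = np.ones(len(edges))

    return WeightedSpatialGraph(
        nodes=nodes,
        roles=list(roles),
        edges=edges,
        length=length,
        o=o,
        zeta=zeta,
        gamma=gamma,
    )
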