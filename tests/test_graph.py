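import numpy as np
import pytest

from longaxon.atlas import build_attraction
from longaxon.graph import (
    EdgeWeightParams,
    GraphBuildParams,
    GraphError,
    build_edges,
    build_point_set,
    weigh_edges,
)


class TestPointSet:
    def test_even_intermediate_spacing(self):
        pts, roles = build_point_set(
            np.zeros(3),
            np.array([[10.0, 0, 0]]),
            GraphBuildParams(n_intermediate=4, n_random=0, merge_radius=0.0),
            rng=np.random.default_rng(0),
        )
        inter = pts[np.array(roles) == "intermediate"]
        assert np.allclose(sorted(inter[:, 0]), [2, 4, 6, 8])

    def test_regular_tetrahedron_voronoi_center(self):
        # regular tetrahedron: single circumcentre at the centroid
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        from longaxon.graph import _circumcenters

        centers = _circumcenters(verts, np.array([[0, 1, 2, 3]]))
        assert np.allclose(centers[0], verts.mean(axis=0), atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_points_respect_exclusion_radius(self, seed):
        params = GraphBuildParams(n_intermediate=3, n_random=30, r_random=40.0,
                                  merge_radius=0.0)
        pts, roles = build_point_set(
            np.zeros(3),
            np.array([[500.0, 300.0, 200.0], [400.0, -200.0, 100.0]]),
            params,
            rng=np.random.default_rng(seed),
        )
        rand = pts[np.array(roles) == "random"]
        others = pts[np.array(roles) != "random"]
        for i, p in enumerate(rand):
            d_other = np.linalg.norm(others - p, axis=1).min()
            assert d_other >= params.r_random - 1e-9

    def test_terminals_survive_merge(self):
        src = np.zeros(3)
        tgt = np.array([[300.0, 0, 0], [0.0, 300.0, 0]])
        pts, roles = build_point_set(
            src, tgt, GraphBuildParams(n_random=40, r_random=30.0),
            rng=np.random.default_rng(3),
        )
        assert np.allclose(pts[0], src)
        assert np.allclose(pts[1], tgt[0]) and np.allclose(pts[2], tgt[1])
        assert roles[:3] == ["source", "target", "target"]

    def test_outside_brain_points_discarded(self, slab_atlas):
        src = np.array([200.0, 500.0, 500.0])
        tgt = np.array([[800.0, 500.0, 500.0]])
        pts, roles = build_point_set(
            src, tgt, GraphBuildParams(n_random=40, r_random=40.0,
                                       bbox_margin=400.0),
            atlas=slab_atlas,
            rng=np.random.default_rng(4),
        )
        for p in pts:
            assert slab_atlas.contains(p)

    def test_source_equals_target(self):
        with pytest.raises(GraphError, match="degenerate segment"):
            build_point_set(np.zeros(3), np.zeros((1, 3)), GraphBuildParams())


class TestEdges:
    def test_k4_for_tetrahedron(self):
        verts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        edges = build_edges(verts)
        assert len(edges) == 6

    def test_collinear_fallback_complete(self):
        pts = np.array([[float(i), 0, 0] for i in range(5)])
        with pytest.warns(UserWarning):
            edges = build_edges(pts)
        assert len(edges) == 10  # complete graph on 5 nodes

    def test_too_few_nodes(self):
        with pytest.raises(GraphError, match="not enough nodes"):
            build_edges(np.zeros((1, 3)))

    def test_edges_come_from_tetrahedra(self):
        from scipy.spatial import Delaunay

        pts = np.random.default_rng(5).uniform(0, 100, (30, 3))
        edges = {tuple(e) for e in build_edges(pts)}
        tri = Delaunay(pts)
        from itertools import combinations

        expected = set()
        for s in tri.simplices:
            expected.update(tuple(sorted(p)) for p in combinations(s, 2))
        assert edges == expected


class TestWeights:
    def _simple_graph(self, nodes, source):
        edges = np.array([[0, 1]])
        return nodes, edges, ["source", "target"]

    def test_parallel_edge_orientation_one(self):
        nodes = np.array([[10.0, 0, 0], [20.0, 0, 0]])
        g = weigh_edges(
            nodes, np.array([[0, 1]]), ["a", "b"],
            EdgeWeightParams(source_point=np.zeros(3), lambda_o=1.0, alpha_o=2.0),
        )
        assert g.o[0] == pytest.approx(1.0)
        assert g.weights[0] == pytest.approx(10.0)

    def test_perpendicular_edge_orientation_two(self):
        # AB perpendicular to SC: midpoint on the x-axis, AB along y
        nodes = np.array([[10.0, -5.0, 0], [10.0, 5.0, 0]])
        g = weigh_edges(
            nodes, np.array([[0, 1]]), ["a", "b"],
            EdgeWeightParams(source_point=np.zeros(3), lambda_o=1.0, alpha_o=2.0),
        )
        assert g.o[0] == pytest.approx(2.0)

    def test_depth_factor_limits(self, slab_atlas):
        p = EdgeWeightParams(
            source_point=np.zeros(3), lambda_o=0.0, lambda_zeta=1.0, alpha_zeta=1.0
        )
        # constant depth (edge along x): zeta = 1
        flat = np.array([[300.0, 500.0, 500.0], [400.0, 500.0, 500.0]])
        g = weigh_edges(flat, np.array([[0, 1]]), ["a", "b"], p, slab_atlas)
        assert g.zeta[0] == pytest.approx(1.0)
        # edge along the depth gradient: |dy|/|AB| = 1 so zeta = 2
        steep = np.array([[300.0, 400.0, 500.0], [300.0, 600.0, 500.0]])
        g = weigh_edges(steep, np.array([[0, 1]]), ["a", "b"], p, slab_atlas)
        assert g.zeta[0] == pytest.approx(2.0)

    def test_gamma_limits(self):
        nodes = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        far = build_attraction(None, np.array([[1e6, 0, 0]]), 100.0)
        p = EdgeWeightParams(source_point=np.array([-50.0, 0, 0]),
                             lambda_o=0.0, lambda_gamma=-0.9, alpha_gamma=0.5)
        g = weigh_edges(nodes, np.array([[0, 1]]), ["a", "b"], p, None, far)
        assert g.gamma[0] == pytest.approx(1.0)  # gamma(A)=gamma(B)=0
        # saturated attraction: gamma_i -> 1 + lambda_gamma = 0.1
        near = build_attraction(None, np.tile([50.0, 0, 0], (400, 1)), 1e4)
        g = weigh_edges(nodes, np.array([[0, 1]]), ["a", "b"], p, None, near)
        assert g.gamma[0] == pytest.approx(0.1, rel=1e-3)

    def test_pure_euclidean_when_disabled(self):
        rng = np.random.default_rng(6)
        nodes = rng.uniform(0, 100, (20, 3))
        edges = build_edges(nodes)
        g = weigh_edges(
            nodes, edges, ["x"] * 20,
            EdgeWeightParams(source_point=nodes[0], lambda_o=0.0),
        )
        assert np.allclose(g.weights, g.length)

    def test_attractor_lowers_weight_of_nearby_edge(self):
        # identical-length edges, one inside the attraction basin
        nodes = np.array(
            [[0.0, 0, 0], [100.0, 0, 0], [0.0, 1000.0, 0], [100.0, 1000.0, 0]]
        )
        edges = np.array([[0, 1], [2, 3]])
        field = build_attraction(None, np.array([[50.0, 0, 0]]), 100.0)
        p = EdgeWeightParams(source_point=np.array([-1000.0, 500.0, 0.0]),
                             lambda_o=0.0, lambda_gamma=-0.9)
        g = weigh_edges(nodes, edges, ["a"] * 4, p, None, field)
        assert g.weights[0] < g.weights[1]
        assert np.all(g.weights > 0)

    def test_degenerate_edge(self):
        nodes = np.array([[0.0, 0, 0], [0.0, 0, 0]])
        with pytest.raises(GraphError, match="degenerate edge"):
            weigh_edges(nodes, np.array([[0, 1]]), ["a", "b"],
                        EdgeWeightParams(source_point=np.ones(3)))

    def test_lambda_gamma_sign_restriction(self):
        with pytest.raises(ValueError, match="lambda_gamma"):
            EdgeWeightParams(lambda_gamma=0.5)
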