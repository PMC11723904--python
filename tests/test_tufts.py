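import numpy as np
import pytest

from longaxon.morphology import Morphology, MorphologyError, Section, total_cable_length
from longaxon.synthetic import ToyAxonSpec, make_random_tree, make_toy_axon
from longaxon.tufts import (
    Barcode,
    ClusteringParams,
    TrunkStats,
    cluster_terminals,
    compute_barcode,
    extract_trunk_stats,
    load_tuft_records,
    save_tuft_records,
    split_trunk_tufts,
)


def comb(points_chain):
    """Trunk along +x with one vertical terminal section at each chain point.

    Terminal k sits at x = points_chain[k]; path distance between adjacent
    terminals = branch gap along the trunk + 2 * branch height.
    """
    height = 10.0
    sections = []
    prev = None
    prev_pt = np.zeros(3)
    for i, x in enumerate(points_chain):
        node = np.array([x, 0.0, 0.0])
        sections.append(Section(np.array([prev_pt, node]), np.ones(2), prev, "trunk"))
        trunk_idx = len(sections) - 1
        tip = node + [0.0, height, 0.0]
        sections.append(
            Section(np.array([node, tip]), np.ones(2), trunk_idx, "trunk")
        )
        prev = trunk_idx
        prev_pt = node
    return Morphology(np.zeros(3), sections)


class TestClustering:
    def test_pair_within_both_thresholds(self):
        m = comb([50.0, 100.0])  # Euclid ~ sqrt(50^2) between tips, path 70
        a = cluster_terminals(m, ClusteringParams(100.0, 300.0))
        assert len(set(a.values())) == 1

    def test_pair_beyond_euclidean(self):
        m = comb([50.0, 200.0])  # 150 um apart horizontally
        a = cluster_terminals(m, ClusteringParams(100.0, 300.0))
        assert len(set(a.values())) == 2

    def test_pair_beyond_path_distance(self):
        # tips 80 um apart in Euclid, but path goes down and up: 80 + 20
        m = comb([50.0, 130.0])
        a1 = cluster_terminals(m, ClusteringParams(100.0, 300.0))
        a2 = cluster_terminals(m, ClusteringParams(100.0, 90.0))
        assert len(set(a1.values())) == 1
        assert len(set(a2.values())) == 2

    def test_transitive_merge(self):
        """A-B and B-C within thresholds, A-C outside: one tuft of three."""
        m = comb([0.0 + 10.0, 90.0, 170.0])
        params = ClusteringParams(100.0, 1000.0)
        a = cluster_terminals(m, params)
        assert len(set(a.values())) == 1
        # direct A-C distance really exceeds the Euclidean threshold
        tips = [m.sections[i].points[-1] for i in sorted(a)]
        assert np.linalg.norm(tips[0] - tips[-1]) > params.d_euclidean_max

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_thresholds(self, seed):
        m = make_random_tree(np.random.default_rng(seed), n_sections=14)
        base = len(set(cluster_terminals(m, ClusteringParams(40.0, 120.0)).values()))
        wider_e = len(set(cluster_terminals(m, ClusteringParams(80.0, 120.0)).values()))
        wider_p = len(set(cluster_terminals(m, ClusteringParams(40.0, 240.0)).values()))
        assert wider_e <= base
        assert wider_p <= base

    def test_order_independence(self):
        m, _ = make_toy_axon(rng=np.random.default_rng(3))
        a = cluster_terminals(m)
        # ids are canonical: recomputation yields the identical mapping
        assert a == cluster_terminals(m)

    def test_empty_axon(self):
        m = Morphology(
            np.zeros(3),
            [Section(np.array([[0, 0, 0], [1, 0, 0]], float), np.ones(2), None, "dendrite")],
        )
        with pytest.raises(MorphologyError, match="empty axon"):
            cluster_terminals(m)


class TestSplit:
    def test_toy_recovery(self, toy_axon):
        m, gt = toy_axon
        assignment = cluster_terminals(m)
        labeled, records = split_trunk_tufts(m, assignment)
        assert len(records) == len(set(gt.values()))
        # partition: every axonal section labeled trunk or tuft, disjoint
        labs = [s.label for s in labeled.sections]
        assert set(labs) <= {"trunk", "tuft"}
        # no trunk section is terminal
        kids = labeled.children_map()
        for i, s in enumerate(labeled.sections):
            if s.label == "trunk" and not kids[i]:
                pytest.fail("bare trunk terminal")

    def test_singleton_tuft_unbranched_axon(self):
        sections = [
            Section(np.array([[0, 0, 0], [100, 0, 0]], float), np.ones(2), None, "trunk"),
            Section(np.array([[100, 0, 0], [200, 0, 0]], float), np.ones(2), 0, "trunk"),
        ]
        m = Morphology(np.zeros(3), sections)
        labeled, records = split_trunk_tufts(m, cluster_terminals(m))
        assert len(records) == 1
        assert labeled.sections[0].label == "trunk"
        assert labeled.sections[1].label == "tuft"
        assert np.allclose(records[0].common_ancestor, [100, 0, 0])

    def test_degenerate_tuft_at_soma(self):
        m = Morphology(
            np.zeros(3),
            [Section(np.array([[0, 0, 0], [50, 0, 0]], float), np.ones(2), None, "trunk")],
        )
        with pytest.raises(MorphologyError, match="degenerate tuft at soma"):
            split_trunk_tufts(m, cluster_terminals(m))

    def test_common_ancestor_distance_consistent(self, toy_axon):
        m, _ = toy_axon
        labeled, records = split_trunk_tufts(m, cluster_terminals(m))
        from longaxon.morphology import path_distance

        for r in records:
            assert path_distance(labeled, r.common_ancestor) == pytest.approx(
                r.path_distance_to_soma
            )


class TestBarcode:
    def test_single_section(self):
        m = Morphology(
            np.zeros(3),
            [Section(np.array([[0, 0, 0], [100, 0, 0]], float), np.ones(2), None, "trunk")],
        )
        bc = compute_barcode(m)
        assert np.allclose(bc.bars, [[0.0, 100.0]])

    def test_y_tree_elder_rule(self, y_morphology):
        bc = compute_barcode(y_morphology)
        pers = sorted(bc.persistences)
        assert pers == pytest.approx([20.0, 80.0])
        assert sorted(bc.bars[:, 0]) == pytest.approx([0.0, 50.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_cable_conservation_and_bar_count(self, seed):
        rng = np.random.default_rng(seed)
        m = make_random_tree(rng, n_sections=int(rng.integers(1, 20)))
        bc = compute_barcode(m)
        assert len(bc) == len(m.terminal_sections())
        assert bc.persistences.sum() == pytest.approx(
            total_cable_length(m), rel=1e-9
        )

    def test_invalid_bars_rejected(self):
        with pytest.raises(ValueError, match="invalid barcode"):
            Barcode([(100.0, 100.0)])


class TestTrunkStats:
    def test_constant_segments(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0], [6, 0, 0]], float)
        m = Morphology(np.zeros(3), [Section(pts, np.ones(4), None, "trunk")])
        s = extract_trunk_stats(m)
        assert (s.segment_length_mean, s.segment_length_std) == (2.0, 0.0)

    def test_population_std(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [4, 0, 0]], float)
        m = Morphology(np.zeros(3), [Section(pts, np.ones(3), None, "trunk")])
        s = extract_trunk_stats(m)
        assert s.segment_length_mean == pytest.approx(2.0)
        assert s.segment_length_std == pytest.approx(1.0)

    def test_no_trunk_error(self):
        m = Morphology(
            np.zeros(3),
            [Section(np.array([[0, 0, 0], [1, 0, 0]], float), np.ones(2), None, "tuft")],
        )
        with pytest.raises(MorphologyError, match="no trunk sections"):
            extract_trunk_stats(m)

    def test_invariants(self):
        with pytest.raises(ValueError):
            TrunkStats(0.0, 1.0)


def test_records_json_round_trip(tmp_path, toy_axon):
    m, _ = toy_axon
    _, records = split_trunk_tufts(m, cluster_terminals(m))
    path = tmp_path / "records.jsonl"
    save_tuft_records(records, path)
    loaded = load_tuft_records(path)
    assert len(loaded) == len(records)
    for a, b in zip(records, loaded):
        assert np.allclose(a.common_ancestor, b.common_ancestor)
        assert np.allclose(a.barcode.bars, b.barcode.bars)
        assert a.total_path_length == pytest.approx(b.total_path_length)
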