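import numpy as np
import pytest
from scipy.stats import chisquare, norm

from longaxon.atlas import BoundaryParams
from longaxon.growth import (
    GrowthError,
    GrowthParams,
    TuftSelectionParams,
    choose_template,
    graft_tuft,
    grow_tuft,
    template_probabilities,
)
from longaxon.morphology import (
    Morphology,
    MorphologyError,
    Section,
    path_distance,
    total_cable_length,
)
from longaxon.synthetic import make_random_tree
from longaxon.tufts import Barcode, TuftRecord, compute_barcode


def record(length, dist):
    return TuftRecord(
        common_ancestor=np.zeros(3),
        total_path_length=length,
        path_distance_to_soma=dist,
        orientation=np.array([0.0, 1.0, 0.0]),
        barcode=Barcode([(0.0, length)]),
    )


class TestTemplateSelection:
    def test_symmetric_candidates_get_half(self):
        cands = [record(900.0, 450.0), record(1100.0, 550.0)]
        p = template_probabilities(
            cands, TuftSelectionParams(1000.0, 500.0, 100.0, 100.0)
        )
        assert np.allclose(p, [0.5, 0.5])
        assert p.sum() == pytest.approx(1.0)

    def test_exact_match_beats_far_candidate(self):
        cands = [record(1000.0, 500.0), record(3000.0, 2500.0)]
        p = template_probabilities(
            cands, TuftSelectionParams(1000.0, 500.0, 500.0, 500.0)
        )
        assert p[0] > p[1]

    def test_closed_form_density_ratio(self):
        # |l - l_j| = 1000 with sigma_l = 1000 -> length affinity is the
        # normal density at one sigma; distance affinities match exactly.
        cands = [record(1000.0, 500.0), record(2000.0, 500.0)]
        p = template_probabilities(
            cands, TuftSelectionParams(1000.0, 500.0, 1000.0, 1.0)
        )
        a0 = norm.pdf(0.0, scale=1000.0)
        a1 = norm.pdf(1000.0, scale=1000.0)
        assert p[1] / p[0] == pytest.approx(a1 / a0)
        assert a1 / norm.pdf(0, scale=1000.0) == pytest.approx(np.exp(-0.5))

    def test_permutation_equivariance(self):
        cands = [record(800.0, 300.0), record(1500.0, 700.0), record(400.0, 900.0)]
        p = template_probabilities(cands, TuftSelectionParams(1000.0, 500.0))
        q = template_probabilities(cands[::-1], TuftSelectionParams(1000.0, 500.0))
        assert np.allclose(p, q[::-1])

    def test_empty_candidates(self):
        with pytest.raises(GrowthError, match="no templates"):
            template_probabilities([], TuftSelectionParams(1.0, 1.0))

    def test_degenerate_affinities(self):
        cands = [record(1e9, 1e9)]
        with pytest.raises(GrowthError, match="degenerate affinities"):
            template_probabilities(cands, TuftSelectionParams(1.0, 1.0, 1.0, 1.0))

    def test_sampling_matches_probabilities(self):
        cands = [record(900.0, 450.0), record(1200.0, 500.0), record(2000.0, 800.0)]
        sel = TuftSelectionParams(1000.0, 500.0, 400.0, 400.0)
        p = template_probabilities(cands, sel)
        rng = np.random.default_rng(0)
        n = 4000
        counts = np.bincount(
            [choose_template(cands, sel, rng) for _ in range(n)], minlength=3
        )
        stat, pval = chisquare(counts, f_exp=p * n)
        assert pval > 0.01


class TestGrowTuft:
    def test_single_bar_deterministic_straight(self):
        t = grow_tuft(
            Barcode([(0.0, 100.0)]),
            GrowthParams(randomness=0.0, step_length_std=0.0,
                         target_direction=np.array([0.0, 1.0, 0.0])),
            np.zeros(3),
            rng=np.random.default_rng(0),
        )
        assert len(t.sections) == 1
        assert total_cable_length(t) == pytest.approx(100.0)
        assert np.allclose(t.sections[0].points[-1], [0, 100, 0])

    def test_two_bars_bifurcation_at_birth(self):
        t = grow_tuft(
            Barcode([(0.0, 80.0), (50.0, 70.0)]),
            GrowthParams(),
            np.zeros(3),
            rng=np.random.default_rng(1),
        )
        assert len(t.terminal_sections()) == 2
        # bifurcation happens at path distance 50 from the root
        fork = t.sections[0]
        assert path_distance(t, (0, len(fork.points) - 1)) == pytest.approx(50.0)
        assert total_cable_length(t) == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_terminal_count_matches_bars(self, seed):
        rng = np.random.default_rng(seed)
        m = make_random_tree(rng, n_sections=int(rng.integers(2, 14)))
        bc = compute_barcode(m)
        t = grow_tuft(bc, GrowthParams(), np.zeros(3), rng=rng)
        assert len(t.terminal_sections()) == len(bc)
        assert total_cable_length(t) == pytest.approx(
            bc.persistences.sum(), rel=0.15
        )

    def test_barcode_round_trip(self):
        """Barcode of a grown tuft equals the template barcode."""
        bars = Barcode([(0.0, 300.0), (120.0, 260.0), (120.0, 180.0)])
        t = grow_tuft(bars, GrowthParams(), np.zeros(3),
                      rng=np.random.default_rng(3))
        bc = compute_barcode(t)
        # 1-nm separator segments at coincident births shift lengths by <= 2e-3
        assert np.allclose(
            np.sort(bc.persistences), np.sort(bars.persistences), atol=5e-3
        )

    def test_boundary_containment_in_slab(self, slab_atlas):
        root = np.array([500.0, 880.0, 500.0])  # close to the +y wall
        params = GrowthParams(
            randomness=0.3,
            target_direction=np.array([0.0, 1.0, 0.0]),  # aimed at the wall
            boundary=BoundaryParams(alpha_b=0.05),
        )
        bc = Barcode([(0.0, 400.0), (100.0, 350.0), (150.0, 300.0)])
        for seed in range(5):
            t = grow_tuft(bc, params, root, slab_atlas, np.random.default_rng(seed))
            for sec in t.sections:
                for p in sec.points:
                    assert slab_atlas.contains(p)

    def test_invalid_barcode(self):
        with pytest.raises(ValueError, match="invalid barcode"):
            grow_tuft(Barcode([(0.0, 10.0), (50.0, 60.0)]), GrowthParams(),
                      np.zeros(3), rng=np.random.default_rng(0))


class TestGraft:
    def _trunk(self):
        pts = np.array([[0.0, 0, 0], [50.0, 0, 0], [100.0, 0, 0]])
        return Morphology(np.zeros(3), [Section(pts, np.ones(3), None, "trunk")])

    def test_graft_at_leaf_removes_terminal(self):
        trunk = self._trunk()
        target = np.array([100.0, 0, 0])
        tuft = grow_tuft(Barcode([(0.0, 60.0)]), GrowthParams(), target,
                         rng=np.random.default_rng(0))
        combined = graft_tuft(trunk, tuft, target)
        kids = combined.children_map()
        assert kids[0], "trunk leaf must gain the tuft as child"
        terminals = combined.terminal_sections()
        assert all(combined.sections[i].label == "tuft" for i in terminals)

    def test_node_count_conserved(self):
        trunk = self._trunk()
        target = np.array([100.0, 0, 0])
        tuft = grow_tuft(Barcode([(0.0, 60.0), (20.0, 50.0)]), GrowthParams(),
                         target, rng=np.random.default_rng(1))
        combined = graft_tuft(trunk, tuft, target)

        def unique_nodes(m):
            pts = np.concatenate([s.points for s in m.sections])
            return len({tuple(np.round(p, 9)) for p in pts})

        assert unique_nodes(combined) == unique_nodes(trunk) + unique_nodes(tuft) - 1

    def test_path_distance_additive(self):
        trunk = self._trunk()
        target = np.array([100.0, 0, 0])
        tuft = grow_tuft(Barcode([(0.0, 60.0)]), GrowthParams(), target,
                         rng=np.random.default_rng(2))
        combined = graft_tuft(trunk, tuft, target)
        ti = combined.terminal_sections()[0]
        tip = (ti, len(combined.sections[ti].points) - 1)
        assert path_distance(combined, tip) == pytest.approx(100.0 + 60.0)

    def test_off_trunk_graft_rejected(self):
        trunk = self._trunk()
        tuft = grow_tuft(Barcode([(0.0, 60.0)]), GrowthParams(),
                         np.array([55.0, 5.0, 0.0]), rng=np.random.default_rng(3))
        with pytest.raises(MorphologyError, match="graft point off trunk"):
            graft_tuft(trunk, tuft, np.array([55.0, 5.0, 0.0]))
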