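"""Self-contained benchmark experiments for the package's key guarantees.

Every function here builds its own synthetic inputs, runs the relevant part
of the pipeline and returns plain numbers, so the same experiments back both
the acceptance test-suite and the ``scripts/acceptance.py`` report.  Problem
sizes are the defaults used throughout the package's validation: hundreds of
seeded instances per property, on the slab atlas fixture.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chisquare

from .atlas import BoundaryParams, build_attraction, thin_attractors
from .config import SynthesisConfig
from .graph import (
    EdgeWeightParams,
    GraphBuildParams,
    build_edges,
    build_point_set,
    weigh_edges,
)
from .growth import GrowthParams, TuftSelectionParams, grow_tuft, template_probabilities
from .morphology import total_cable_length
from .pipeline import run_mimic, synthesize_trunk
from .steiner import approximate_steiner, exact_steiner_oracle, solution_to_skeleton
from .synthetic import (
    TRACT_REGION,
    ToyAxonSpec,
    make_random_tree,
    make_slab_atlas,
    make_toy_axon,
)
from .tufts import ClusteringParams, TrunkStats, cluster_terminals, compute_barcode
from .validation import mvs_score

__all__ = [
    "steiner_bound",
    "barcode_conservation",
    "growth_inversion",
    "template_sampling",
    "immovability",
    "clustering_recovery",
    "tract_preference",
    "attractor_ladder",
    "boundary_containment",
    "mimic_scale_ordering",
]


def _random_graph(rng, n):
    pts = rng.uniform(0, 100, (n, 3))
    edges = build_edges(pts)
    return weigh_edges(
        pts, edges, ["x"] * n, EdgeWeightParams(source_point=pts[0], lambda_o=0.0)
    )


def steiner_bound(n_graphs: int = 500, seed: int = 0) -> dict:
    """Approximation ratio vs the exact oracle over seeded random graphs."""
    rng = np.random.default_rng(seed)
    ratios = []
    violations = 0
    for _ in range(n_graphs):
        n = int(rng.integers(6, 17))
        g = _random_graph(rng, n)
        k = int(rng.integers(2, 6))
        terms = sorted(rng.choice(n, k, replace=False).tolist())
        approx = approximate_steiner(g, terms).total_weight
        opt = exact_steiner_oracle(g, terms).total_weight
        r = approx / opt if opt > 0 else 1.0
        ratios.append(r)
        if not (1.0 - 1e-9 <= r <= 2.0 + 1e-9):
            violations += 1
    return {
        "max_ratio": float(max(ratios)),
        "mean_ratio": float(np.mean(ratios)),
        "violations": violations,
        "n": n_graphs,
    }


def barcode_conservation(n_trees: int = 1000, seed: int = 0) -> dict:
    """Sum of bar persistences vs cable length; bar count vs terminal count."""
    rng = np.random.default_rng(seed)
    max_rel_err = 0.0
    count_mismatches = 0
    for _ in range(n_trees):
        m = make_random_tree(rng, n_sections=int(rng.integers(1, 25)))
        bc = compute_barcode(m)
        cable = total_cable_length(m)
        max_rel_err = max(max_rel_err, abs(bc.persistences.sum() - cable) / cable)
        if len(bc) != len(m.terminal_sections()):
            count_mismatches += 1
    return {
        "max_rel_err": float(max_rel_err),
        "count_mismatches": count_mismatches,
        "n": n_trees,
    }


def growth_inversion(n_runs: int = 500, seed: int = 0) -> dict:
    """Grown tuft terminal count / cable vs the driving barcode."""
    rng = np.random.default_rng(seed)
    term_ok = 0
    len_ok = 0
    for _ in range(n_runs):
        m = make_random_tree(rng, n_sections=int(rng.integers(1, 12)))
        bc = compute_barcode(m)
        t = grow_tuft(bc, GrowthParams(), np.zeros(3), rng=rng)
        if len(t.terminal_sections()) == len(bc):
            term_ok += 1
        want = bc.persistences.sum()
        if abs(total_cable_length(t) - want) / want <= 0.15:
            len_ok += 1
    return {
        "terminal_match_rate": 100.0 * term_ok / n_runs,
        "length_within_15pct_rate": 100.0 * len_ok / n_runs,
        "n": n_runs,
    }


def template_sampling(n_draws: int = 10_000, seed: int = 0) -> dict:
    """Chi-square goodness of fit of template draws to their probabilities."""
    from .tufts import Barcode, TuftRecord

    rng = np.random.default_rng(seed)
    cands = [
        TuftRecord(
            common_ancestor=np.zeros(3),
            total_path_length=length,
            path_distance_to_soma=dist,
            orientation=np.array([0.0, 1.0, 0.0]),
            barcode=Barcode([(0.0, length)]),
        )
        for length, dist in [(700.0, 300.0), (1000.0, 500.0), (1600.0, 900.0),
                             (2500.0, 1500.0)]
    ]
    sel = TuftSelectionParams(1200.0, 600.0, sigma_l=600.0, sigma_d=600.0)
    probs = template_probabilities(cands, sel)
    draws = rng.choice(len(cands), size=n_draws, p=probs)
    counts = np.bincount(draws, minlength=len(cands))
    _, pvalue = chisquare(counts, f_exp=probs * n_draws)
    return {"p_value": float(pvalue), "n": n_draws}


def immovability(seed: int = 0) -> dict:
    """Max displacement of source/bifurcation/target points through walk+graft."""
    from .morphology import path_distance  # noqa: F401  (documented entry point)

    spec = ToyAxonSpec(
        anchors=((300.0, 300.0, 500.0), (600.0, 450.0, 500.0), (880.0, 300.0, 600.0)),
        soma=(120.0, 500.0, 500.0),
    )
    worst = 0.0
    n = 0
    for k in range(5):
        rng = np.random.default_rng([seed, k])
        m, _ = make_toy_axon(spec, rng)
        res = run_mimic(m, SynthesisConfig(tuft_selection="matched"), rng=rng,
                        l1_voxel_sizes=None)
        ends = np.array([s.points[-1] for s in res.synthesized.sections])
        tree = cKDTree(ends)
        for r in res.records:
            d, _ = tree.query(r.common_ancestor)
            worst = max(worst, float(d))
            n += 1
        src = np.array(
            [s.points[0] for s in res.synthesized.sections if s.parent is None]
        )
        worst = max(worst, float(np.abs(src - m.soma_center).max()))
    return {"max_displacement": worst, "n": n}


def clustering_recovery(n_specs: int = 200, seed: int = 0) -> dict:
    """Generator/recovery round trip plus threshold monotonicity."""
    rng = np.random.default_rng(seed)
    recovered = 0
    monotone_violations = 0
    for _ in range(n_specs):
        n_tufts = int(rng.integers(1, 4))
        xs = 300.0 + 300.0 * np.arange(n_tufts)
        anchors = tuple(
            (x, float(rng.uniform(-80, 80)), float(rng.uniform(-80, 80)))
            for x in xs
        )
        spec = ToyAxonSpec(anchors=anchors, n_terminals=int(rng.integers(1, 5)))
        m, gt = make_toy_axon(spec, rng)
        found = cluster_terminals(m, ClusteringParams(spec.clustering_distance))

        def parts(assign):
            groups: dict[int, set] = {}
            for term, tid in assign.items():
                groups.setdefault(tid, set()).add(term)
            return sorted(map(frozenset, groups.values()), key=min)

        if parts(found) == parts(gt):
            recovered += 1
        n_base = len(set(found.values()))
        n_wide_e = len(
            set(cluster_terminals(m, ClusteringParams(2 * spec.clustering_distance)).values())
        )
        n_wide_p = len(
            set(
                cluster_terminals(
                    m,
                    ClusteringParams(spec.clustering_distance,
                                     6 * spec.clustering_distance),
                ).values()
            )
        )
        if n_wide_e > n_base or n_wide_p > n_base:
            monotone_violations += 1
    return {
        "recovery_rate": 100.0 * recovered / n_specs,
        "monotone_violations": monotone_violations,
        "n": n_specs,
    }


# ---------------------------------------------------------------------------
# Preferred regions
# ---------------------------------------------------------------------------


def _tract_fraction(atlas, trunk) -> tuple[float, float]:
    cable_in = cable_tot = 0.0
    for s in trunk.sections:
        mids = (s.points[:-1] + s.points[1:]) / 2.0
        lens = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        for mid, ln in zip(mids, lens):
            cable_tot += ln
            try:
                if atlas.region_at(mid) == TRACT_REGION:
                    cable_in += ln
            except Exception:
                pass
    return cable_in, cable_tot


def tract_preference(n_axons: int = 20, seed: int = 0) -> dict:
    """Pooled tract cable fraction with vs without the attraction term."""
    atlas = make_slab_atlas()
    tract_centers = atlas.origin + (
        np.argwhere(atlas.region_ids == TRACT_REGION) + 0.5
    ) * atlas.voxel_size
    attractors = thin_attractors(tract_centers, 100.0, np.random.default_rng(seed))
    field = build_attraction(atlas, attractors, 100.0)
    stats = TrunkStats(20.0, 4.0)
    fractions = {}
    for label, lam in (("with_attraction", -0.9), ("control", 0.0)):
        cable_in = cable_tot = 0.0
        for k in range(n_axons):
            rng = np.random.default_rng([seed, k])
            src = np.array([150.0, 480.0, 480.0])
            tgt = np.array([[850.0, 570.0, 570.0]])
            cfg = SynthesisConfig(
                graph=GraphBuildParams(n_intermediate=8, n_random=60, r_random=40.0),
                edge_weights=EdgeWeightParams(
                    lambda_o=0.0, lambda_gamma=lam, alpha_gamma=0.5
                ),
            )
            trunk, _, _ = synthesize_trunk(
                src, tgt, cfg, stats, rng, atlas,
                field if lam != 0 else None,
            )
            ci, ct = _tract_fraction(atlas, trunk)
            cable_in += ci
            cable_tot += ct
        fractions[label] = cable_in / cable_tot
    return {**fractions, "n": n_axons}


def _sample_polyline(poly: np.ndarray, step: float = 10.0) -> np.ndarray:
    out = []
    for a, b in zip(poly[:-1], poly[1:]):
        n = max(int(np.linalg.norm(b - a) / step), 1)
        for t in np.linspace(0.0, 1.0, n, endpoint=False):
            out.append(a + t * (b - a))
    out.append(poly[-1])
    return np.array(out)


def attractor_ladder(
    seed: int = 0,
    spacings=(100.0, 300.0, 500.0, 750.0),
    n_repeats: int = 12,
) -> dict:
    """Trunk-to-reference deviation as attractors get sparser.

    An L-shaped reference path is sampled into attractors thinned at each
    ladder spacing (fixed 50 um kernels); the directed Hausdorff distance
    from the Steiner trunk skeleton to the reference, averaged over
    ``n_repeats`` seeded graph realisations, is reported per spacing.
    Dense attractors make the trunk hug the L; sparse ones let it fall back
    to the straight diagonal.
    """
    atlas = make_slab_atlas()
    A = np.array([150.0, 150.0, 450.0])
    C = np.array([150.0, 750.0, 500.0])
    B = np.array([750.0, 750.0, 550.0])
    ref = _sample_polyline(np.array([A, C, B]))
    params = GraphBuildParams(n_intermediate=8, n_random=400, r_random=20.0)
    distances = []
    for spacing in spacings:
        field = build_attraction(atlas, thin_attractors(ref, spacing), 50.0)
        vals = []
        for k in range(n_repeats):
            rng = np.random.default_rng([seed, k])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nodes, roles = build_point_set(A, B[None, :], params, atlas, rng)
                edges = build_edges(nodes)
            g = weigh_edges(
                nodes, edges, roles,
                EdgeWeightParams(source_point=A, lambda_o=0.0, lambda_gamma=-0.9,
                                 alpha_gamma=0.2),
                atlas, field,
            )
            sol = approximate_steiner(g, [0, 1])
            sk = solution_to_skeleton(sol, g, 0, [1])
            trunk_pts = np.concatenate(
                [_sample_polyline(b.points) for b in sk.branches]
            )
            vals.append(float(cKDTree(ref).query(trunk_pts)[0].max()))
        distances.append(float(np.mean(vals)))
    return {"spacings": list(spacings), "hausdorff": distances, "n": n_repeats}


def boundary_containment(n_tufts: int = 50, n_mvs: int = 200, seed: int = 0) -> dict:
    """Containment near the surface; on/off distributional equivalence far away."""
    from .tufts import Barcode

    atlas = make_slab_atlas()
    bc = Barcode([(0.0, 400.0), (100.0, 350.0), (150.0, 300.0)])
    boundary = BoundaryParams(alpha_b=0.05)

    outside = 0
    for k in range(n_tufts):
        rng = np.random.default_rng([seed, k])
        root = np.array([500.0, 880.0, 500.0])  # 70 um below the +y wall
        params = GrowthParams(
            randomness=0.3,
            target_direction=np.array([0.0, 1.0, 0.0]),
            boundary=boundary,
        )
        t = grow_tuft(bc, params, root, atlas, rng)
        for sec in t.sections:
            outside += sum(0 if atlas.contains(p) else 1 for p in sec.points)

    # far from any wall the boundary term must not distort morphometrics
    center = np.array([500.0, 450.0, 500.0])
    small = Barcode([(0.0, 120.0), (40.0, 100.0), (60.0, 90.0)])
    samples: dict[bool, list[float]] = {True: [], False: []}
    for enabled in (True, False):
        for k in range(n_mvs):
            rng = np.random.default_rng([seed + 1, k])
            params = GrowthParams(
                randomness=0.3,
                target_direction=np.array([0.0, 1.0, 0.0]),
                boundary=boundary if enabled else None,
            )
            t = grow_tuft(small, params, center, atlas if enabled else None, rng)
            samples[enabled].extend(s.length for s in t.sections)
    mvs = mvs_score(samples[True], samples[False])
    return {
        "outside_points": outside,
        "n_tufts": n_tufts,
        "onoff_section_length_mvs": float(mvs),
        "n_mvs_tufts": n_mvs,
    }


def mimic_scale_ordering(n_runs: int = 5, seed: int = 0) -> dict:
    """Coarse vs fine multiscale L1 on mimic fixtures."""
    spec = ToyAxonSpec(
        anchors=((300.0, 300.0, 500.0), (600.0, 450.0, 500.0), (880.0, 300.0, 600.0)),
        soma=(120.0, 500.0, 500.0),
    )
    ok = 0
    curves = []
    for k in range(n_runs):
        rng = np.random.default_rng([seed, k])
        m, _ = make_toy_axon(spec, rng)
        res = run_mimic(m, SynthesisConfig(tuft_selection="matched"), rng=rng)
        curves.append(res.l1_curve)
        if res.l1_curve[500.0] < res.l1_curve[50.0]:
            ok += 1
    return {"coarse_lt_fine_runs": ok, "n": n_runs, "curves": curves}
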