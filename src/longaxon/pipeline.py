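"""End-to-end drivers: extract, mimic, synthesize, validate.

``run_extract`` turns reconstructed axons into the statistical inputs of
synthesis (tuft records + trunk segment statistics).  ``run_mimic``
re-synthesizes a single reconstruction: its clustered tufts' common
ancestors become the target points, its own voxel footprint builds the
attraction field, and its own tuft records seed the tufts.  ``run_synthesize``
generates populations of axons in an atlas from the probability matrices.
``run_validate`` compares two populations morphometrically.

Randomness is hierarchical: every axon consumes an independent substream
spawned from the global seed, so serial and parallel execution agree.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import AttractionField, VoxelAtlas, build_attraction, thin_attractors
from .config import SynthesisConfig
from .graph import build_edges, build_point_set, weigh_edges
from .growth import TuftSelectionParams, choose_template, graft_tuft, grow_tuft
from .morphology import Morphology, path_distance
from .steiner import approximate_steiner, solution_to_skeleton
from .tufts import (
    TrunkStats,
    TuftRecord,
    cluster_terminals,
    extract_trunk_stats,
    split_trunk_tufts,
    _atlas_frame,
)
from .validation import compare_populations, l1_multiscale, projection_grid
from .walk import refine_skeleton

__all__ = [
    "run_extract",
    "run_mimic",
    "run_synthesize",
    "run_validate",
    "MimicResult",
    "SynthesisResult",
]

log = logging.getLogger("longaxon")


# ---------------------------------------------------------------------------
# extract
# ---------------------------------------------------------------------------


def run_extract(
    morphologies: Sequence[Morphology],
    config: SynthesisConfig = SynthesisConfig(),
    atlas: VoxelAtlas | None = None,
) -> tuple[list[TuftRecord], TrunkStats, list[Morphology]]:
    """Cluster reconstructions into trunk+tufts and pool their statistics."""
    records: list[TuftRecord] = []
    labeled: list[Morphology] = []
    for i, morph in enumerate(morphologies):
        assignment = cluster_terminals(morph, config.clustering)
        lab, recs = split_trunk_tufts(morph, assignment, atlas)
        records.extend(recs)
        labeled.append(lab)
        log.debug("extract: morphology %d -> %d tufts", i, len(recs))
    stats = extract_trunk_stats(labeled)
    return records, stats, labeled


# ---------------------------------------------------------------------------
# shared trunk synthesis
# ---------------------------------------------------------------------------


def _world_orientation(
    record: TuftRecord, atlas: VoxelAtlas | None, point: np.ndarray
) -> np.ndarray:
    if record.frame == "atlas" and atlas is not None:
        rot = _atlas_frame(atlas, point)
        return rot.T @ record.orientation
    return record.orientation


def synthesize_trunk(
    source: np.ndarray,
    targets: np.ndarray,
    config: SynthesisConfig,
    trunk_stats: TrunkStats,
    rng: np.random.Generator,
    atlas: VoxelAtlas | None = None,
    attraction: AttractionField | None = None,
):
    """Graph -> Steiner tree -> guided walk.  Returns (trunk, skeleton, graph)."""
    wparams = replace(config.edge_weights, source_point=np.asarray(source, float))
    if attraction is None and wparams.lambda_gamma != 0:
        wparams = replace(wparams, lambda_gamma=0.0)
    nodes, roles = build_point_set(source, targets, config.graph, atlas, rng)
    edges = build_edges(nodes)
    graph = weigh_edges(nodes, edges, roles, wparams, atlas, attraction)
    terminals = list(range(1 + len(np.atleast_2d(targets))))
    solution = approximate_steiner(graph, terminals)
    skeleton = solution_to_skeleton(solution, graph, 0, terminals[1:])
    trunk = refine_skeleton(skeleton, trunk_stats, config.walk, rng, atlas=atlas)
    return trunk, skeleton, graph


# ---------------------------------------------------------------------------
# mimic
# ---------------------------------------------------------------------------


@dataclass
class MimicResult:
    synthesized: Morphology
    reference_labeled: Morphology
    records: list[TuftRecord]
    trunk: Morphology
    l1_curve: dict[float, float] | None


def axon_attraction_field(
    morph: Morphology,
    atlas: VoxelAtlas,
    spacing: float,
    rng: np.random.Generator,
) -> AttractionField:
    """Attractors at the centres of atlas voxels intersected by the axon.

    The candidate voxels are thinned so that surviving attractors are at
    least ``spacing`` apart; the kernel scale equals the spacing so the
    field's support tracks the attractor density.
    """
    lo = atlas.origin
    hi = atlas.origin + np.array(atlas.shape) * atlas.voxel_size
    grid = projection_grid(morph, atlas.voxel_size, (lo, hi))
    occupied = np.argwhere(grid.values > 0)
    centers = grid.origin + (occupied + 0.5) * atlas.voxel_size
    thinned = thin_attractors(centers, spacing, rng)
    return build_attraction(atlas, thinned, kernel_scale=spacing)


def run_mimic(
    reconstruction: Morphology,
    config: SynthesisConfig = SynthesisConfig(tuft_selection="matched"),
    atlas: VoxelAtlas | None = None,
    rng: np.random.Generator | None = None,
    l1_voxel_sizes: Sequence[float] | None = (50.0, 100.0, 250.0, 500.0),
) -> MimicResult:
    """Synthesize a look-alike of one reconstructed axon.

    Targets are the common ancestors of the reconstruction's clustered
    tufts; with an atlas and ``use_attraction`` the trunk is drawn toward
    the reconstruction's own voxel footprint.
    """
    rng = rng or np.random.default_rng(config.seed)
    assignment = cluster_terminals(reconstruction, config.clustering)
    labeled, records = split_trunk_tufts(reconstruction, assignment, atlas)
    trunk_stats = extract_trunk_stats(labeled)

    attraction = None
    if atlas is not None and config.use_attraction:
        attraction = axon_attraction_field(
            labeled, atlas, config.attractor_spacing, rng
        )

    source = reconstruction.soma_center
    targets = np.array([r.common_ancestor for r in records])
    trunk, skeleton, _graph = synthesize_trunk(
        source, targets, config, trunk_stats, rng, atlas, attraction
    )

    synthesized = trunk
    for k, record in enumerate(records):
        if config.tuft_selection == "matched":
            template = record
        else:
            sel = TuftSelectionParams(
                expected_length=record.total_path_length,
                query_path_distance=record.path_distance_to_soma,
                sigma_l=config.sigma_l,
                sigma_d=config.sigma_d,
            )
            template = records[choose_template(records, sel, rng)]
        gparams = replace(
            config.growth,
            target_direction=_world_orientation(
                template, atlas, record.common_ancestor
            ),
            boundary=config.boundary,
        )
        tuft = grow_tuft(
            template.barcode, gparams, record.common_ancestor, atlas, rng
        )
        synthesized = graft_tuft(synthesized, tuft, record.common_ancestor)
        log.debug("mimic: grafted tuft %d (%d bars)", k, len(template.barcode))

    curve = (
        l1_multiscale(labeled, synthesized, l1_voxel_sizes)
        if l1_voxel_sizes
        else None
    )
    return MimicResult(synthesized, labeled, records, trunk, curve)


# ---------------------------------------------------------------------------
# synthesize
# ---------------------------------------------------------------------------


@dataclass
class SynthesisResult:
    morphologies: list[Morphology]
    failures: list[tuple[int, str]]
    target_counts: list[int]


def _synthesize_one(
    source: np.ndarray,
    atlas: VoxelAtlas,
    src_matrix,
    proj_matrix,
    records: list[TuftRecord],
    trunk_stats: TrunkStats,
    config: SynthesisConfig,
    rng: np.random.Generator,
    attraction: AttractionField | None,
) -> tuple[Morphology, int]:
    from .targeting import pick_source_population, pick_target_points

    region = atlas.region_at(source)
    population = pick_source_population(region, src_matrix, rng)
    chosen = pick_target_points(
        population, proj_matrix, atlas, rng, config.n_targets
    )
    targets = np.array([pt for _, pt in chosen])
    trunk, skeleton, _ = synthesize_trunk(
        source, targets, config, trunk_stats, rng, atlas, attraction
    )
    mean_len = float(np.mean([r.total_path_length for r in records]))
    out = trunk
    for _, point in chosen:
        d_path = path_distance(trunk, point)
        sel = TuftSelectionParams(
            expected_length=mean_len,
            query_path_distance=d_path,
            sigma_l=config.sigma_l,
            sigma_d=config.sigma_d,
        )
        template = records[choose_template(records, sel, rng)]
        gparams = replace(
            config.growth,
            target_direction=_world_orientation(template, atlas, point),
            boundary=config.boundary,
        )
        tuft = grow_tuft(template.barcode, gparams, point, atlas, rng)
        out = graft_tuft(out, tuft, point)
    return out, len(chosen)


def run_synthesize(
    atlas: VoxelAtlas,
    src_matrix,
    proj_matrix,
    records: list[TuftRecord],
    trunk_stats: TrunkStats,
    n_axons: int,
    config: SynthesisConfig = SynthesisConfig(),
    source_point: np.ndarray | None = None,
    source_region: int | None = None,
    attraction: AttractionField | None = None,
    max_retries: int = 2,
) -> SynthesisResult:
    """Synthesize a population of axons in the atlas.

    Each axon uses an independent RNG substream spawned from the global
    seed; axons that fail after ``max_retries`` are recorded and skipped.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(n_axons)
    morphologies: list[Morphology] = []
    failures: list[tuple[int, str]] = []
    counts: list[int] = []
    for i in range(n_axons):
        rng = np.random.default_rng(streams[i])
        err: str | None = None
        for _attempt in range(max_retries + 1):
            try:
                if source_point is not None:
                    src = np.asarray(source_point, float)
                else:
                    regions = (
                        [source_region]
                        if source_region is not None
                        else sorted(
                            int(r)
                            for r in np.unique(atlas.region_ids)
                            if r != 0
                        )
                    )
                    voxels = atlas.region_voxels(regions)
                    vox = voxels[rng.integers(len(voxels))]
                    src = atlas.origin + (vox + 0.5) * atlas.voxel_size
                morph, n_targets = _synthesize_one(
                    src,
                    atlas,
                    src_matrix,
                    proj_matrix,
                    records,
                    trunk_stats,
                    config,
                    rng,
                    attraction,
                )
                morphologies.append(morph)
                counts.append(n_targets)
                err = None
                break
            except Exception as exc:  # failure policy: skip and record
                err = f"{type(exc).__name__}: {exc}"
                log.warning("axon %d failed: %s", i, err)
        if err is not None:
            failures.append((i, err))
    return SynthesisResult(morphologies, failures, counts)


# ---------------------------------------------------------------------------
# validate
# ---------------------------------------------------------------------------


def run_validate(
    ref: Sequence[Morphology],
    syn: Sequence[Morphology],
    metrics=None,
) -> pd.DataFrame:
    """Morphometric comparison report (one row per metric and part)."""
    from .morphology import METRICS

    return compare_populations(ref, syn, metrics or METRICS)
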