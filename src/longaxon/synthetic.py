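"""Deterministic synthetic inputs: slab atlas, toy axons, random trees, matrices.

These generators make every stage of the pipeline testable without any
external data.  The slab atlas is a layered cuboid (depth = world Y,
orientation = +Y toward the pia) wrapped in an outside margin, with one
embedded tube of voxels acting as a projection tract; its flat geometry
keeps boundary-field and depth-field answers analytic.  Toy axons have a
known trunk/tuft ground truth so clustering can be validated by
generator/recovery round-trips.  All generators are bit-deterministic under
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import VoxelAtlas
from .morphology import Morphology, Section
from .targeting import ProjectionMatrix, SourcePopulationMatrix

__all__ = [
    "SlabAtlasSpec",
    "ToyAxonSpec",
    "make_slab_atlas",
    "make_toy_axon",
    "make_random_tree",
    "make_matrices",
]

TRACT_REGION = 100


@dataclass(frozen=True)
class SlabAtlasSpec:
    """Layered slab atlas with an outside margin and a tract tube.

    Defaults give a 1 mm cube of 25 um voxels (CCFv3-like resolution) with
    four layers stacked along Y and a tract running along X.
    """

    shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: float = 25.0
    margin: int = 2  # outside-brain voxels on every face
    n_layers: int = 4
    tract_y: int | None = None  # tube centre voxel (defaults to mid-grid)
    tract_z: int | None = None
    tract_radius: int = 1  # tube half-width in voxels
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


def make_slab_atlas(spec: SlabAtlasSpec = SlabAtlasSpec()) -> VoxelAtlas:
    """Build the deterministic slab atlas described by ``spec``."""
    if min(spec.shape) < 8:
        raise ValueError("atlas too small")
    nx, ny, nz = spec.shape
    m = spec.margin
    region = np.zeros(spec.shape, dtype=int)

    # layers along Y inside the margin
    inner_y = ny - 2 * m
    bounds = np.linspace(m, ny - m, spec.n_layers + 1).astype(int)
    for layer in range(spec.n_layers):
        region[m : nx - m, bounds[layer] : bounds[layer + 1], m : nz - m] = layer + 1

    # tract tube along X
    ty = spec.tract_y if spec.tract_y is not None else ny // 2
    tz = spec.tract_z if spec.tract_z is not None else nz // 2
    r = spec.tract_radius
    region[m : nx - m, ty - r : ty + r + 1, tz - r : tz + r + 1] = TRACT_REGION

    origin = np.asarray(spec.origin, float)
    ys = origin[1] + (np.arange(ny) + 0.5) * spec.voxel_size
    depth = np.broadcast_to(ys[None, :, None], spec.shape).copy()

    orientation = np.zeros(spec.shape + (3,))
    orientation[..., 1] = 1.0

    return VoxelAtlas(
        origin=origin,
        voxel_size=spec.voxel_size,
        region_ids=region,
        depth=depth,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# Toy axons with ground-truth tufts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyAxonSpec:
    """Trunk waypoints with one terminal bush (tuft) hanging at each anchor."""

    anchors: tuple = ((300.0, 0.0, 0.0), (600.0, 150.0, 0.0), (900.0, 0.0, 100.0))
    soma: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_terminals: int = 3  # terminals per tuft
    spread: float = 60.0  # um, bush extent
    trunk_step: float = 20.0  # um, trunk sampling
    clustering_distance: float = 100.0  # intended d_euclidean_max


def _polyline(a: np.ndarray, b: np.ndarray, step: float) -> np.ndarray:
    n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    return a + np.outer(t, b - a)


def make_toy_axon(
    spec: ToyAxonSpec = ToyAxonSpec(),
    rng: np.random.Generator | None = None,
) -> tuple[Morphology, dict[int, int]]:
    """Toy axon plus ground truth ``terminal section index -> tuft id``.

    The trunk visits the anchors sequentially; at each anchor a bush of
    ``n_terminals`` short sections fans out within ``spread``.  Anchors must
    be far enough apart that the intended clustering distance separates the
    bushes, otherwise "tufts too close" is raised.
    """
    rng = rng or np.random.default_rng(0)
    anchors = np.asarray(spec.anchors, float).reshape(-1, 3)
    if len(anchors) < 1:
        raise ValueError("need at least one tuft anchor")
    stem_len = 0.3 * spec.spread
    branch_len = 0.4 * spec.spread
    reach = stem_len + branch_len
    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            if np.linalg.norm(anchors[i] - anchors[j]) <= (
                spec.clustering_distance + 2 * reach
            ):
                raise ValueError("tufts too close for spec")

    sections: list[Section] = []
    ground_truth: dict[int, int] = {}
    soma = np.asarray(spec.soma, float)

    prev_point = soma
    prev_sec: int | None = None
    for tid, anchor in enumerate(anchors):
        pts = _polyline(prev_point, anchor, spec.trunk_step)
        trunk_idx = len(sections)
        sections.append(Section(pts, np.ones(len(pts)), prev_sec, "trunk"))

        # bush: stem away from the trunk direction, then terminal fan
        trunk_dir = (anchor - prev_point) / np.linalg.norm(anchor - prev_point)
        up = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(up, trunk_dir)) > 0.9:
            up = np.array([0.0, 0.0, 1.0])
        stem_dir = up - np.dot(up, trunk_dir) * trunk_dir
        stem_dir /= np.linalg.norm(stem_dir)
        stem_end = anchor + stem_len * stem_dir
        stem_idx = len(sections)
        sections.append(
            Section(
                np.array([anchor, anchor + 0.5 * stem_len * stem_dir, stem_end]),
                np.full(3, 0.6),
                trunk_idx,
                "trunk",
            )
        )
        if spec.n_terminals == 1:
            tip = stem_end + branch_len * stem_dir
            term_idx = len(sections)
            sections.append(
                Section(
                    np.array([stem_end, 0.5 * (stem_end + tip), tip]),
                    np.full(3, 0.5),
                    stem_idx,
                    "tuft",
                )
            )
            ground_truth[term_idx] = tid
        else:
            for _k in range(spec.n_terminals):
                dev = rng.normal(size=3)
                dev -= np.dot(dev, stem_dir) * stem_dir
                nrm = np.linalg.norm(dev)
                dev = dev / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
                direction = 0.8 * stem_dir + 0.6 * dev
                direction /= np.linalg.norm(direction)
                tip = stem_end + branch_len * direction
                term_idx = len(sections)
                sections.append(
                    Section(
                        np.array([stem_end, 0.5 * (stem_end + tip), tip]),
                        np.full(3, 0.5),
                        stem_idx,
                        "tuft",
                    )
                )
                ground_truth[term_idx] = tid
        prev_point = anchor
        prev_sec = trunk_idx

    return Morphology(soma, sections), ground_truth


# ---------------------------------------------------------------------------
# Random trees (property-test workhorse)
# ---------------------------------------------------------------------------


def make_random_tree(
    rng: np.random.Generator,
    n_sections: int = 12,
    step: float = 15.0,
    branch_prob: float = 0.4,
) -> Morphology:
    """Random rooted axonal tree with ``n_sections`` sections."""
    soma = np.zeros(3)
    sections: list[Section] = []
    # (position, direction, parent section index)
    tips: list[tuple[np.ndarray, np.ndarray, int | None]] = [
        (soma.copy(), np.array([0.0, 1.0, 0.0]), None)
    ]
    while len(sections) < n_sections and tips:
        i = int(rng.integers(len(tips)))
        pos, direction, parent = tips.pop(i)
        n_pts = int(rng.integers(2, 6))
        pts = [pos.copy()]
        d = direction.copy()
        for _ in range(n_pts - 1):
            d = d + 0.6 * rng.normal(size=3)
            d /= np.linalg.norm(d)
            pos = pos + d * (step * rng.uniform(0.5, 1.5))
            pts.append(pos.copy())
        idx = len(sections)
        sections.append(
            Section(np.array(pts), np.full(len(pts), 0.5), parent, "trunk")
        )
        if rng.random() < branch_prob and len(sections) + len(tips) < n_sections:
            for _ in range(2):
                dd = d + rng.normal(size=3)
                dd /= np.linalg.norm(dd)
                tips.append((pos.copy(), dd, idx))
    return Morphology(soma, sections)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def make_matrices(
    regions,
    populations,
    rng: np.random.Generator,
) -> tuple[SourcePopulationMatrix, ProjectionMatrix]:
    """Random row-stochastic source-population and projection matrices.

    Every region receives every population with Dirichlet probabilities;
    every population projects to one target population per region (named
    ``T<region>``) with Dirichlet probabilities.
    """
    import pandas as pd

    regions = list(regions)
    populations = list(populations)
    if not regions:
        raise ValueError("need at least one region")

    src_rows = []
    for r in regions:
        probs = rng.dirichlet(np.ones(len(populations)))
        for p, pr in zip(populations, probs):
            src_rows.append({"source_region": r, "population": p, "probability": pr})
    src = SourcePopulationMatrix(pd.DataFrame(src_rows))

    proj_rows = []
    for p in populations:
        probs = rng.dirichlet(np.ones(len(regions)))
        for r, pr in zip(regions, probs):
            proj_rows.append(
                {
                    "population": p,
                    "target_population": f"T{r}",
                    "probability": pr,
                    "regions": str(r),
                }
            )
    proj = ProjectionMatrix(pd.DataFrame(proj_rows))
    return src, proj
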