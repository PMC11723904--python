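"""Voxel brain atlas: region lookup, depth field, attraction and boundary fields.

The atlas is an isotropic 3D grid of region ids (0 = outside the brain) with
a per-voxel depth field y(r) in micrometres and a per-voxel unit orientation
vector pointing toward the pia.  On top of it live two derived fields:

* an attraction field gamma(r), a sum of isotropic Gaussian kernels centred
  on attractor points, used to lower graph edge weights inside preferred
  regions such as projection tracts;
* a boundary field b(r), a per-voxel vector whose norm is the distance to
  the nearest brain boundary, exponentially attenuated into a repulsion
  vector that keeps growing tufts inside the brain.

For inside voxels the stored boundary vector points away from the nearest
boundary (into the brain) so that adding the attenuation vector to a step
direction repels growth from the surface; outside voxels point back toward
the brain with a fixed tiny norm (1e-3 um) making the exterior strongly
repulsive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelAtlas",
    "AtlasError",
    "AttractionField",
    "BoundaryParams",
    "region_at",
    "depth_at",
    "boundary_field",
    "boundary_vector_at",
    "attenuation_vector",
    "build_attraction",
    "attraction_at",
    "thin_attractors",
    "save_atlas",
    "load_atlas",
]


class AtlasError(ValueError):
    """Raised for out-of-atlas queries or malformed grids."""


@dataclass
class VoxelAtlas:
    """Isotropic voxel grid with region ids, depth and orientation."""

    origin: np.ndarray  # world coordinate of the grid corner (um)
    voxel_size: float  # um, isotropic
    region_ids: np.ndarray  # (nx, ny, nz) int
    depth: np.ndarray  # (nx, ny, nz) float, um
    orientation: np.ndarray  # (nx, ny, nz, 3) unit vectors toward pia

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.region_ids = np.asarray(self.region_ids)
        self.depth = np.asarray(self.depth, float)
        self.orientation = np.asarray(self.orientation, float)
        if self.voxel_size <= 0:
            raise AtlasError("voxel_size must be > 0")
        if self.depth.shape != self.region_ids.shape:
            raise AtlasError("depth grid shape mismatch")
        if self.orientation.shape != self.region_ids.shape + (3,):
            raise AtlasError("orientation grid shape mismatch")
        self._boundary_cache: np.ndarray | None = None
        self._boundary_cache_len: float | None = None

    # -- index arithmetic --------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.region_ids.shape

    def point_to_index(self, point: np.ndarray) -> tuple[int, int, int]:
        point = np.asarray(point, float).reshape(3)
        idx = np.floor((point - self.origin) / self.voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise AtlasError("out of atlas")
        return tuple(idx)

    def voxel_center(self, index) -> np.ndarray:
        return self.origin + (np.asarray(index, float) + 0.5) * self.voxel_size

    def contains(self, point: np.ndarray) -> bool:
        """True when the point maps to a voxel with a non-zero region id."""
        try:
            return self.region_ids[self.point_to_index(point)] != 0
        except AtlasError:
            return False

    def region_at(self, point: np.ndarray) -> int:
        return int(self.region_ids[self.point_to_index(point)])

    def depth_at(self, point: np.ndarray) -> float:
        return float(self.depth[self.point_to_index(point)])

    def orientation_at(self, point: np.ndarray) -> np.ndarray:
        return self.orientation[self.point_to_index(point)]

    def region_voxels(self, regions) -> np.ndarray:
        """(k, 3) integer indices of voxels whose id is in ``regions``."""
        mask = np.isin(self.region_ids, np.atleast_1d(regions))
        return np.argwhere(mask)


def region_at(atlas: VoxelAtlas, point) -> int:
    return atlas.region_at(point)


def depth_at(atlas: VoxelAtlas, point) -> float:
    return atlas.depth_at(point)


# ---------------------------------------------------------------------------
# Boundary field
# ---------------------------------------------------------------------------


def boundary_field(atlas: VoxelAtlas, outside_length: float = 1e-3) -> np.ndarray:
    """Per-voxel vector field (nx, ny, nz, 3) repelling from the brain boundary.

    Inside voxels: vector away from the nearest boundary voxel, norm = the
    centre-to-centre distance in micrometres.  Outside voxels: unit vector
    toward the nearest inside voxel, resized to ``outside_length``.
    """
    inside = atlas.region_ids != 0
    if inside.all() or (~inside).all():
        raise AtlasError("no boundary")
    if (
        atlas._boundary_cache is not None
        and atlas._boundary_cache_len == outside_length
    ):
        return atlas._boundary_cache

    grid_idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in atlas.shape], indexing="ij"), axis=-1
    ).astype(float)

    # inside voxels: nearest outside voxel
    dist_in, nearest_out = ndimage.distance_transform_edt(
        inside, return_indices=True
    )
    nearest_out = np.moveaxis(np.asarray(nearest_out, float), 0, -1)
    vec = (grid_idx - nearest_out) * atlas.voxel_size  # away from boundary

    # outside voxels: nearest inside voxel, tiny inward vector
    _, nearest_in = ndimage.distance_transform_edt(~inside, return_indices=True)
    nearest_in = np.moveaxis(np.asarray(nearest_in, float), 0, -1)
    vin = nearest_in - grid_idx
    norm = np.linalg.norm(vin, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    vin = vin / norm * outside_length

    field = np.where(inside[..., None], vec, vin)
    atlas._boundary_cache = field
    atlas._boundary_cache_len = outside_length
    return field


def boundary_vector_at(
    atlas: VoxelAtlas, point, outside_length: float = 1e-3
) -> np.ndarray:
    field = boundary_field(atlas, outside_length)
    return field[atlas.point_to_index(point)]


@dataclass(frozen=True)
class BoundaryParams:
    """Scale of the exponential boundary repulsion.

    ``alpha_b`` (1/um) sets how fast the repulsion decays away from the
    boundary; ``outside_length`` is the fixed norm given to outside-brain
    boundary vectors.
    """

    alpha_b: float = 0.01
    outside_length: float = 1e-3

    def __post_init__(self) -> None:
        if self.alpha_b <= 0:
            raise ValueError("alpha_b must be > 0")
        if self.outside_length <= 0:
            raise ValueError("outside_length must be > 0")


def attenuation_vector(
    b: np.ndarray,
    params: BoundaryParams,
    point: np.ndarray | None = None,
    voxel_center: np.ndarray | None = None,
) -> np.ndarray:
    """Attenuation vector a = b_hat * exp(-alpha_b * |b_refined|).

    When ``point`` and ``voxel_center`` are given, the voxel-resolution
    distance |b| is refined by projecting the vector from the current point
    to the voxel centre onto b_hat (the field direction is taken constant
    within a voxel).  The norm of the result lies in (0, 1].
    """
    b = np.asarray(b, float).reshape(3)
    norm = float(np.linalg.norm(b))
    if norm == 0:
        raise AtlasError("undefined direction")
    bhat = b / norm
    if point is not None and voxel_center is not None:
        norm = norm + float(
            np.dot(np.asarray(voxel_center, float) - np.asarray(point, float), bhat)
        )
        norm = max(norm, 0.0)
    return bhat * float(np.exp(-params.alpha_b * norm))


# ---------------------------------------------------------------------------
# Attraction field
# ---------------------------------------------------------------------------


@dataclass
class AttractionField:
    """Sum of unit-amplitude Gaussian kernels at the attractor points."""

    attractor_points: np.ndarray  # (k, 3)
    kernel_scale: float  # um

    def __post_init__(self) -> None:
        self.attractor_points = np.asarray(self.attractor_points, float).reshape(-1, 3)
        if self.kernel_scale <= 0:
            raise ValueError("kernel_scale must be > 0")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        if len(self.attractor_points) == 0:
            return np.zeros(len(points))
        d2 = (
            ((points[:, None, :] - self.attractor_points[None, :, :]) ** 2)
            .sum(axis=-1)
        )
        return np.exp(-d2 / (2.0 * self.kernel_scale**2)).sum(axis=1)


def build_attraction(
    atlas: VoxelAtlas | None,
    attractor_points: np.ndarray,
    kernel_scale: float,
) -> AttractionField:
    """Build gamma(r) from attractor points (atlas accepted for symmetry)."""
    return AttractionField(np.asarray(attractor_points, float), kernel_scale)


def attraction_at(field: AttractionField, point: np.ndarray) -> float:
    return float(field(np.asarray(point, float).reshape(1, 3))[0])


def thin_attractors(
    points: np.ndarray, min_distance: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Greedy thinning: keep a subset with pairwise distance >= min_distance.

    Candidates are visited in a (seeded) random order when ``rng`` is given,
    otherwise in input order.
    """
    points = np.asarray(points, float).reshape(-1, 3)
    if len(points) == 0:
        return points
    order = np.arange(len(points))
    if rng is not None:
        order = rng.permutation(len(points))
    kept: list[np.ndarray] = []
    for i in order:
        p = points[i]
        if all(np.linalg.norm(p - q) >= min_distance for q in kept):
            kept.append(p)
    return np.array(kept)


# ---------------------------------------------------------------------------
# Serialization (NPZ grids + JSON metadata)
# ---------------------------------------------------------------------------


def save_atlas(atlas: VoxelAtlas, prefix: str | Path) -> None:
    prefix = Path(prefix)
    np.savez(
        prefix.with_suffix(".npz"),
        region_ids=atlas.region_ids,
        depth=atlas.depth,
        orientation=atlas.orientation,
    )
    prefix.with_suffix(".json").write_text(
        json.dumps(
            {"origin": atlas.origin.tolist(), "voxel_size": atlas.voxel_size}
        )
    )


def load_atlas(prefix: str | Path) -> VoxelAtlas:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    grids = np.load(prefix.with_suffix(".npz"))
    return VoxelAtlas(
        origin=np.array(meta["origin"]),
        voxel_size=float(meta["voxel_size"]),
        region_ids=grids["region_ids"],
        depth=grids["depth"],
        orientation=grids["orientation"],
    )
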