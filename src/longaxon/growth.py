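"""Tuft template selection, barcode-guided growth, and grafting.

A synthesized tuft starts from a template :class:`~longaxon.tufts.TuftRecord`
drawn from the extracted dataset.  Template affinity combines two normal
densities, one on the mismatch between the expected and the template total
path length and one on the mismatch of path distances from the soma; the
selection probability is each affinity over the sum of all affinities.

Growth is a simplified barcode-guided stochastic grower: every bar of the
template's persistence barcode drives one tip; a tip bifurcates when its
path distance from the tuft root reaches a child bar's birth and terminates
at its own bar's death, so the number of terminals equals the number of
bars and the synthesized cable length matches the summed bar persistences.
Step directions blend the previous direction, the template orientation and
a random component; near the brain surface the boundary attenuation vector
is added to the step direction so that tufts never leave the brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .atlas import (
    BoundaryParams,
    VoxelAtlas,
    attenuation_vector,
    boundary_vector_at,
)
from .morphology import Morphology, MorphologyError, Section
from .tufts import Barcode, TuftRecord

__all__ = [
    "TuftSelectionParams",
    "GrowthParams",
    "GrowthError",
    "template_probabilities",
    "choose_template",
    "grow_tuft",
    "graft_tuft",
]


class GrowthError(ValueError):
    """Raised for degenerate selection inputs or invalid barcodes."""


@dataclass(frozen=True)
class TuftSelectionParams:
    """Query and bandwidths of the template affinity model (micrometres)."""

    expected_length: float
    query_path_distance: float
    sigma_l: float = 1000.0
    sigma_d: float = 1000.0

    def __post_init__(self) -> None:
        if self.sigma_l <= 0 or self.sigma_d <= 0:
            raise ValueError("sigma_l and sigma_d must be > 0")


def template_probabilities(
    candidates: list[TuftRecord], params: TuftSelectionParams
) -> np.ndarray:
    """Selection probability of each candidate template.

    Affinity of template j:
    ``A_j = N(0, sigma_l^2)(l_expected - l_j) * N(0, sigma_d^2)(d_query - d_j)``
    with N the normal density; probabilities are ``A_j / sum(A)``.
    """
    if not candidates:
        raise GrowthError("no templates")
    l_j = np.array([c.total_path_length for c in candidates])
    d_j = np.array([c.path_distance_to_soma for c in candidates])
    a = norm.pdf(params.expected_length - l_j, scale=params.sigma_l) * norm.pdf(
        params.query_path_distance - d_j, scale=params.sigma_d
    )
    total = a.sum()
    if total == 0:
        raise GrowthError("degenerate affinities")
    return a / total


def choose_template(
    candidates: list[TuftRecord],
    params: TuftSelectionParams,
    rng: np.random.Generator,
) -> int:
    probs = template_probabilities(candidates, params)
    return int(rng.choice(len(candidates), p=probs))


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Step statistics and guidance of the tuft grower."""

    step_length_mean: float = 10.0
    step_length_std: float = 2.0
    randomness: float = 0.2
    target_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0, 0.0])
    )
    direction_persistence: float = 0.7  # weight of the previous direction
    boundary: BoundaryParams | None = None
    radius: float = 0.5

    def __post_init__(self) -> None:
        if self.step_length_mean <= 0:
            raise ValueError("step_length_mean must be > 0")
        if not (0.0 <= self.randomness <= 1.0):
            raise ValueError("randomness must be in [0, 1]")
        v = np.asarray(self.target_direction, float).reshape(3)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("target_direction must be non-zero")
        object.__setattr__(self, "target_direction", v / n)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n == 0:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _bar_tree(barcode: Barcode) -> tuple[int, dict[int, list[int]]]:
    """Root bar index and parent->children map via inverse elder rule.

    A child attaches to the already-placed bar whose interval contains its
    birth; ties go to the bar with the longest remaining life.
    """
    bars = barcode.bars
    order = np.argsort(-(bars[:, 1] - bars[:, 0]), kind="stable")
    root = int(order[0])
    children: dict[int, list[int]] = {i: [] for i in range(len(bars))}
    placed = [root]
    for i in sorted(
        (j for j in range(len(bars)) if j != root), key=lambda j: (bars[j, 0], j)
    ):
        birth = bars[i, 0]
        hosts = [
            p for p in placed if bars[p, 0] <= birth < bars[p, 1]
        ]
        if not hosts:
            raise GrowthError("invalid barcode: bar not nested under any parent")
        host = max(hosts, key=lambda p: (bars[p, 1], -p))
        children[host].append(i)
        placed.append(i)
    for v in children.values():
        v.sort(key=lambda j: bars[j, 0])
    return root, children


def _step_length(params: GrowthParams, rng: np.random.Generator) -> float:
    if params.step_length_std == 0:
        return params.step_length_mean
    for _ in range(100):
        s = rng.normal(params.step_length_mean, params.step_length_std)
        if s > 0:
            return float(s)
    return params.step_length_mean


def _next_direction(
    prev_dir: np.ndarray,
    params: GrowthParams,
    rng: np.random.Generator,
    atlas: VoxelAtlas | None,
    pos: np.ndarray,
) -> np.ndarray:
    guided = _unit(
        params.direction_persistence * prev_dir
        + (1.0 - params.direction_persistence) * params.target_direction
    )
    if params.randomness > 0:
        direction = _unit(
            (1.0 - params.randomness) * guided
            + params.randomness * _random_unit(rng)
        )
    else:
        direction = guided
    if atlas is not None and params.boundary is not None:
        try:
            b = boundary_vector_at(atlas, pos, params.boundary.outside_length)
            center = atlas.voxel_center(atlas.point_to_index(pos))
            a = attenuation_vector(b, params.boundary, pos, center)
            direction = _unit(direction + a)
        except Exception:
            pass  # outside the grid: keep the unmodified direction
    return direction


def _safe_step(
    pos: np.ndarray,
    direction: np.ndarray,
    step: float,
    atlas: VoxelAtlas | None,
    params: GrowthParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one step, retreating inward if the move would exit the brain."""
    if atlas is None or params.boundary is None:
        return pos + step * direction, direction
    cand = pos + step * direction
    if atlas.contains(cand):
        return cand, direction
    # fall back to the purely inward boundary direction of the current voxel
    try:
        b = boundary_vector_at(atlas, pos, params.boundary.outside_length)
        inward = _unit(b)
    except Exception:
        inward = -direction
    for scale in (1.0, 0.5, 0.25):
        cand = pos + step * scale * inward
        if atlas.contains(cand):
            return cand, inward
    return pos + 1e-6 * inward, inward  # pinned against a corner: stall inward


def grow_tuft(
    barcode: Barcode,
    params: GrowthParams,
    root: np.ndarray,
    atlas: VoxelAtlas | None = None,
    rng: np.random.Generator | None = None,
) -> Morphology:
    """Grow a tuft whose topology realises the given barcode.

    The returned morphology is rooted at ``root`` (its soma centre is the
    root point for path-distance bookkeeping); terminal count equals the bar
    count and total cable length the summed persistences.
    """
    rng = rng or np.random.default_rng()
    root = np.asarray(root, float).reshape(3)
    bars = barcode.bars
    root_bar, children = _bar_tree(barcode)
    pending = {k: list(v) for k, v in children.items()}  # consumed as we grow

    sections: list[Section] = []

    def grow_branch(
        bar: int,
        start_pos: np.ndarray,
        start_dir: np.ndarray,
        d_start: float,
        parent_sec: int | None,
    ) -> None:
        """Grow bar's branch from path distance d_start to the next event."""
        kids = pending[bar]
        next_birth = bars[kids[0], 0] if kids else None
        d_stop = next_birth if next_birth is not None else bars[bar, 1]

        pts = [start_pos.copy()]
        direction = start_dir
        pos = start_pos.copy()
        d = d_start
        while d < d_stop - 1e-12:
            step = min(_step_length(params, rng), d_stop - d)
            direction = _next_direction(direction, params, rng, atlas, pos)
            pos, direction = _safe_step(pos, direction, step, atlas, params)
            # account path distance by the commanded step (equals the move
            # unless the boundary guard stalled the tip)
            d += step
            pts.append(pos.copy())
        sec_index = len(sections)
        if len(pts) < 2:  # zero-length event gap: force a tiny segment
            direction = _next_direction(direction, params, rng, atlas, pos)
            pos = pos + 1e-3 * direction
            pts.append(pos.copy())
        sections.append(
            Section(np.array(pts), np.full(len(pts), params.radius), parent_sec, "tuft")
        )
        if kids:
            child = kids.pop(0)
            # child branch direction: deflect off the current direction
            dev = _random_unit(rng)
            dev_perp = dev - np.dot(dev, direction) * direction
            if np.linalg.norm(dev_perp) > 1e-12:
                dev = _unit(dev_perp)
            else:
                axis = np.array([1.0, 0.0, 0.0])
                if abs(np.dot(axis, direction)) > 0.9:
                    axis = np.array([0.0, 0.0, 1.0])
                dev = _unit(np.cross(direction, axis))
            angle = rng.uniform(np.pi / 6, np.pi / 3)
            child_dir = _unit(np.cos(angle) * direction + np.sin(angle) * dev)
            cont_dir = _unit(np.cos(angle / 2) * direction - np.sin(angle / 2) * dev)
            grow_branch(child, pos, child_dir, d_stop, sec_index)
            grow_branch(bar, pos, cont_dir, d_stop, sec_index)

    start_dir = params.target_direction.copy()
    grow_branch(root_bar, root, start_dir, float(bars[root_bar, 0]), None)
    return Morphology(root.copy(), sections)


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------


def graft_tuft(
    trunk: Morphology,
    tuft: Morphology,
    target_point: np.ndarray,
    atol: float = 1e-6,
) -> Morphology:
    """Weld a tuft onto the trunk at an immovable trunk node.

    The target point must coincide with a trunk section's last point (a
    trunk leaf or an interior immovable node); the tuft's root sections
    become children of that section.
    """
    target_point = np.asarray(target_point, float).reshape(3)
    host = None
    for i, sec in enumerate(trunk.sections):
        if np.allclose(sec.points[-1], target_point, atol=atol):
            host = i
            break
    if host is None:
        raise MorphologyError("graft point off trunk")
    if not np.allclose(tuft.soma_center, target_point, atol=atol):
        raise MorphologyError("tuft is not rooted at the graft point")

    out = trunk.copy()
    offset = len(out.sections)
    for sec in tuft.sections:
        parent = host if sec.parent is None else sec.parent + offset
        pts = sec.points.copy()
        if sec.parent is None:
            pts[0] = out.sections[host].points[-1]  # bit-exact weld
        out.sections.append(Section(pts, sec.radii.copy(), parent, "tuft"))
    return Morphology(out.soma_center, out.sections, out.soma_radius)
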