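"""Guided correlated random walk that turns a Steiner skeleton into a trunk.

Between each pair of consecutive immovable points (source, bifurcations,
targets) a random walk is performed whose step direction is the renormalised
weighted sum of four unit vectors: toward the endpoint, toward the next
intermediate target, the (exponentially weighted) history of previous steps,
and a uniformly random direction.  Step lengths follow a truncated normal
distribution fitted to trunk segment-length statistics extracted from
reconstructions.

At every step the current intermediate target is reassessed: it counts as
reached when the distance to it increased relative to the previous step, or
fell below the mean step length times a reach coefficient.  The walk ends by
snapping exactly onto the endpoint once it comes within one step of it, so
source, bifurcation and target coordinates are preserved bit-exactly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .morphology import Morphology, Section
from .steiner import TrunkSkeleton
from .tufts import TrunkStats

__all__ = ["WalkParams", "WalkError", "guided_walk", "refine_skeleton"]


class WalkError(ValueError):
    """Raised when a walk fails to converge or parameters are inconsistent."""


@dataclass(frozen=True)
class WalkParams:
    """Direction weights and step statistics of the trunk random walk.

    The randomness weight must stay below the sum of the three guidance
    weights, otherwise the walk can lose its intermediate targets.
    """

    beta_ep: float = 1.0
    beta_nit: float = 2.0
    beta_hist: float = 1.0
    beta_rand: float = 1.5
    step_length_mean: float = 20.0
    step_length_std: float = 5.0
    history_span: int = 5
    history_decay: float = 0.5
    reach_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if min(self.beta_ep, self.beta_nit, self.beta_hist, self.beta_rand) < 0:
            raise WalkError("beta weights must be >= 0")
        if self.beta_rand >= self.beta_ep + self.beta_nit + self.beta_hist:
            raise WalkError("beta_rand must stay below the sum of the other weights")
        if self.step_length_mean <= 0:
            raise WalkError("step_length_mean must be > 0")
        if self.step_length_std < 0 or self.history_span < 0:
            raise WalkError("invalid walk parameters")

    def with_stats(self, stats: TrunkStats) -> "WalkParams":
        return WalkParams(
            beta_ep=self.beta_ep,
            beta_nit=self.beta_nit,
            beta_hist=self.beta_hist,
            beta_rand=self.beta_rand,
            step_length_mean=stats.segment_length_mean,
            step_length_std=stats.segment_length_std,
            history_span=self.history_span,
            history_decay=self.history_decay,
            reach_coefficient=self.reach_coefficient,
        )


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


def _step_length(params: WalkParams, rng: np.random.Generator) -> float:
    if params.step_length_std == 0:
        return params.step_length_mean
    for _ in range(100):
        s = rng.normal(params.step_length_mean, params.step_length_std)
        if s > 0:
            return float(s)
    return params.step_length_mean  # pathological std: fall back to the mean


def guided_walk(
    start: np.ndarray,
    end: np.ndarray,
    intermediates: np.ndarray | list,
    params: WalkParams,
    rng: np.random.Generator | None = None,
    max_steps: int | None = None,
    atlas=None,
) -> np.ndarray:
    """Polyline from ``start`` to ``end`` passing near the intermediate targets.

    The first point is exactly ``start`` and the last exactly ``end``.
    When an atlas is given, steps that would leave the brain mask are
    redirected toward the endpoint (and clamped as a last resort) so the
    trunk stays inside the brain.
    """
    rng = rng or np.random.default_rng()
    start = np.asarray(start, float).reshape(3)
    end = np.asarray(end, float).reshape(3)
    if np.array_equal(start, end):
        raise WalkError("start equals end")
    inter = [np.asarray(p, float).reshape(3) for p in np.atleast_2d(intermediates)] if (
        intermediates is not None and len(np.atleast_1d(intermediates)) > 0
    ) else []

    if max_steps is None:
        path_len = float(np.linalg.norm(end - start))
        pts = [start, *inter, end]
        path_len = sum(
            float(np.linalg.norm(pts[i + 1] - pts[i])) for i in range(len(pts) - 1)
        )
        max_steps = max(50, int(10 * path_len / params.step_length_mean))

    history: deque[np.ndarray] = deque(maxlen=max(params.history_span, 1))
    points = [start]
    pos = start.copy()
    next_i = 0
    prev_dist = np.inf

    for _ in range(max_steps):
        # reassess the current intermediate target
        while next_i < len(inter):
            d = float(np.linalg.norm(inter[next_i] - pos))
            if d > prev_dist or d < params.step_length_mean * params.reach_coefficient:
                next_i += 1
                prev_dist = np.inf
                continue
            prev_dist = d
            break

        step = _step_length(params, rng)
        if next_i >= len(inter) and np.linalg.norm(end - pos) <= step:
            points.append(end.copy())
            return np.array(points)

        u_ep = _unit(end - pos)
        u_nit = _unit(inter[next_i] - pos) if next_i < len(inter) else u_ep
        if history:
            decayed = sum(
                params.history_decay**j * h
                for j, h in enumerate(reversed(history))
            )
            u_hist = _unit(decayed)
        else:
            u_hist = np.zeros(3)
        u_rand = _random_unit(rng) if params.beta_rand > 0 else np.zeros(3)

        direction = (
            params.beta_ep * u_ep
            + params.beta_nit * u_nit
            + params.beta_hist * u_hist
            + params.beta_rand * u_rand
        )
        direction = _unit(direction)
        if np.linalg.norm(direction) == 0:
            direction = u_ep
        cand = pos + step * direction
        if atlas is not None and not atlas.contains(cand):
            # containment guard: head straight for the guidance targets
            for fallback, scale in ((u_nit, 1.0), (u_ep, 1.0), (u_ep, 0.25)):
                cand = pos + scale * step * fallback
                if atlas.contains(cand):
                    direction = fallback
                    break
            else:
                history.append(u_ep)
                continue  # pinned against the surface this step
        pos = cand
        points.append(pos.copy())
        history.append(direction)

    raise WalkError("walk did not converge")


def refine_skeleton(
    skeleton: TrunkSkeleton,
    trunk_stats: TrunkStats,
    params: WalkParams = WalkParams(),
    rng: np.random.Generator | None = None,
    radius: float = 1.0,
    atlas=None,
) -> Morphology:
    """Replace every skeleton branch by a guided random walk.

    Returns a trunk morphology rooted at the skeleton's source whose
    immovable points (source, bifurcations, targets) appear bit-exactly.
    """
    rng = rng or np.random.default_rng()
    wp = params.with_stats(trunk_stats)
    sections: list[Section] = []
    sec_of_branch: dict[int, int] = {}
    for bi, branch in enumerate(skeleton.branches):
        start = branch.points[0]
        end = branch.points[-1]
        inter = branch.points[1:-1]
        pts = guided_walk(start, end, inter, wp, rng, atlas=atlas)
        # walks keep endpoints exact; enforce bit-exact anchors anyway
        pts[0] = start
        pts[-1] = end
        parent = sec_of_branch.get(branch.parent) if branch.parent is not None else None
        sec_of_branch[bi] = len(sections)
        sections.append(
            Section(pts, np.full(len(pts), radius), parent, "trunk")
        )
    return Morphology(skeleton.source.copy(), sections)
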