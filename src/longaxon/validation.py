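"""Quantitative comparison of synthesized and reference morphologies.

Three complementary views:

* morphometric distributions per part (complete / trunk / tuft) with the
  MVS score — the absolute difference between two samples' medians divided
  by an estimate of their overall visible spread (here the envelope from
  the lower 5th to the upper 95th percentile of the pooled pair).  0 means
  the medians coincide; values approaching 1 mean dissimilar distributions.
* the projection grid: per-voxel cable length of one morphology on a 3D
  grid of a given voxel size;
* the normalized multi-scale L1 projection-intensity error
  ``L1 = sum|r_i - s_i| / (sum r_i + sum s_i)`` evaluated over a ladder of
  voxel sizes, separating the spatial scales that are synthesized
  accurately from those that are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .morphology import METRICS, Morphology, MorphologyError, morphometrics

__all__ = [
    "ProjectionGrid",
    "ValidationError",
    "projection_grid",
    "l1_projection_error",
    "l1_multiscale",
    "mvs_score",
    "compare_populations",
]


class ValidationError(ValueError):
    """Raised for mismatched grids or degenerate samples."""


@dataclass
class ProjectionGrid:
    """Per-voxel cable length (um) of one morphology."""

    origin: np.ndarray
    voxel_size: float
    values: np.ndarray  # (nx, ny, nz)

    def total(self) -> float:
        return float(self.values.sum())


def _segments(morph: Morphology, part: str | None) -> tuple[np.ndarray, np.ndarray]:
    starts, ends = [], []
    for sec in morph.sections:
        if part is not None and sec.label != part:
            continue
        if part is None and sec.label not in ("trunk", "tuft"):
            continue
        starts.append(sec.points[:-1])
        ends.append(sec.points[1:])
    if not starts:
        raise ValidationError("no cable")
    return np.concatenate(starts), np.concatenate(ends)


def projection_grid(
    morph: Morphology,
    voxel_size: float,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    part: str | None = None,
    mode: str = "length",
) -> ProjectionGrid:
    """Clip every segment against a voxel grid and accumulate cable per voxel.

    ``bounds`` is a (lower, upper) pair in um; by default the morphology's
    bounding box padded by one voxel.  ``mode='binary'`` records voxel
    occupancy instead of cable length.
    """
    if voxel_size <= 0:
        raise ValidationError("voxel_size must be > 0")
    p0, p1 = _segments(morph, part)

    if bounds is None:
        all_pts = np.concatenate([p0, p1])
        lo = all_pts.min(axis=0) - voxel_size
        hi = all_pts.max(axis=0) + voxel_size
    else:
        lo = np.asarray(bounds[0], float)
        hi = np.asarray(bounds[1], float)
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 1)
    values = np.zeros(tuple(shape))

    for a, b in zip(p0, p1):
        seg = b - a
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0:
            continue
        # crossing parameters with all voxel boundary planes
        ts = [0.0, 1.0]
        for axis in range(3):
            if seg[axis] == 0:
                continue
            k0 = np.floor((min(a[axis], b[axis]) - lo[axis]) / voxel_size)
            k1 = np.ceil((max(a[axis], b[axis]) - lo[axis]) / voxel_size)
            planes = lo[axis] + np.arange(k0, k1 + 1) * voxel_size
            t = (planes - a[axis]) / seg[axis]
            ts.extend(t[(t > 0) & (t < 1)].tolist())
        ts = np.unique(np.clip(ts, 0.0, 1.0))
        mids = a + np.outer((ts[:-1] + ts[1:]) / 2.0, seg)
        lens = np.diff(ts) * seg_len
        idx = np.floor((mids - lo) / voxel_size).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        for (i, j, k), ln in zip(idx[ok], lens[ok]):
            values[i, j, k] += ln

    if mode == "binary":
        values = (values > 0).astype(float)
    elif mode != "length":
        raise ValidationError(f"unknown mode {mode!r}")
    return ProjectionGrid(origin=lo, voxel_size=voxel_size, values=values)


def l1_projection_error(ref: ProjectionGrid, syn: ProjectionGrid) -> float:
    """Normalized L1 error between two projection grids, in [0, 1]."""
    if (
        ref.values.shape != syn.values.shape
        or not np.isclose(ref.voxel_size, syn.voxel_size)
        or not np.allclose(ref.origin, syn.origin, atol=1e-9)
    ):
        raise ValidationError("grid mismatch")
    denom = ref.values.sum() + syn.values.sum()
    if denom == 0:
        raise ValidationError("undefined error: both grids empty")
    return float(np.abs(ref.values - syn.values).sum() / denom)


def l1_multiscale(
    ref: Morphology,
    syn: Morphology,
    voxel_sizes: Sequence[float],
    part: str | None = None,
) -> dict[float, float]:
    """L1 projection error per voxel size, on a shared bounding box."""
    if len(voxel_sizes) == 0:
        raise ValidationError("need at least one voxel size")
    r0, r1 = _segments(ref, part)
    s0, s1 = _segments(syn, part)
    pts = np.concatenate([r0, r1, s0, s1])
    pad = max(voxel_sizes)
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    out: dict[float, float] = {}
    for vs in voxel_sizes:
        g_ref = projection_grid(ref, vs, (lo, hi), part)
        g_syn = projection_grid(syn, vs, (lo, hi), part)
        out[float(vs)] = l1_projection_error(g_ref, g_syn)
    return out


def mvs_score(sample_a: Iterable[float], sample_b: Iterable[float]) -> float:
    """Median-vs-spread distribution similarity score (0 = identical medians)."""
    a = np.asarray(list(sample_a), float)
    b = np.asarray(list(sample_b), float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("empty sample")
    med_diff = abs(np.median(a) - np.median(b))
    spread = max(np.percentile(a, 95), np.percentile(b, 95)) - min(
        np.percentile(a, 5), np.percentile(b, 5)
    )
    if spread == 0:
        if med_diff == 0:
            return 0.0
        raise ValidationError("degenerate spread")
    return float(med_diff / spread)


PARTS = ("complete", "trunk", "tuft")


def compare_populations(
    ref: Sequence[Morphology],
    syn: Sequence[Morphology],
    metrics: Iterable[str] = METRICS,
) -> pd.DataFrame:
    """Per metric and part: pooled medians, quartiles and the MVS score.

    Both populations must be trunk/tuft labelled (clustered); the output has
    one row per (metric, part) with part in complete/trunk/tuft.
    """
    if not ref or not syn:
        raise ValidationError("empty population")
    for m in list(ref) + list(syn):
        if not any(s.label == "tuft" for s in m.sections):
            raise MorphologyError("unlabeled morphology")
    metrics = list(metrics)
    rows = []
    for part in PARTS:
        p = None if part == "complete" else part
        for metric in metrics:
            va: list[float] = []
            vb: list[float] = []
            for m in ref:
                va.extend(morphometrics(m, [metric], p)[metric])
            for m in syn:
                vb.extend(morphometrics(m, [metric], p)[metric])
            if not va or not vb:
                continue
            rows.append(
                {
                    "metric": metric,
                    "part": part,
                    "median_ref": float(np.median(va)),
                    "median_syn": float(np.median(vb)),
                    "q1_ref": float(np.percentile(va, 25)),
                    "q3_ref": float(np.percentile(va, 75)),
                    "q1_syn": float(np.percentile(vb, 25)),
                    "q3_syn": float(np.percentile(vb, 75)),
                    "mvs": mvs_score(va, vb),
                    "n_ref": len(va),
                    "n_syn": len(vb),
                }
            )
    return pd.DataFrame(rows)
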