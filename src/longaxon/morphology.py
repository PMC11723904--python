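"""Rooted-tree neuron morphologies, SWC I/O and primitive morphometrics.

A morphology is a forest of :class:`Section` objects attached to a soma.
Axons are split conceptually into a *long-range trunk* that travels between
brain regions and local terminal *tufts*; every section carries one of the
labels ``trunk``, ``tuft``, ``dendrite`` or ``soma`` so that downstream
statistics can be computed on each part separately.

Coordinates are absolute micrometres in atlas space; reading a file never
re-centres the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "MorphologyError",
    "read_swc",
    "write_swc",
    "section_path_length",
    "path_distance",
    "morphometrics",
    "morphometrics_table",
    "total_cable_length",
    "METRICS",
]


class MorphologyError(ValueError):
    """Raised for malformed morphologies or SWC files."""


#: section label -> SWC structure-type integer used on export
SWC_TYPE_OF_LABEL = {"soma": 1, "trunk": 2, "dendrite": 3, "tuft": 7}
#: SWC structure-type integer -> section label used on import
LABEL_OF_SWC_TYPE = {1: "soma", 2: "trunk", 3: "dendrite", 4: "dendrite", 7: "tuft"}

AXONAL_LABELS = ("trunk", "tuft")


@dataclass
class Section:
    """An unbranched run of points between two topological events.

    ``points`` has shape (n, 3) with n >= 2 and no repeated consecutive
    points; ``radii`` has shape (n,).  ``parent`` is the index of the parent
    section in the owning :class:`Morphology` (``None`` for sections attached
    directly to the soma).  A non-root section's first point equals its
    parent's last point.
    """

    points: np.ndarray
    radii: np.ndarray
    parent: int | None = None
    label: str = "trunk"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(self.points) < 2:
            raise MorphologyError("section needs at least 2 points")
        if len(self.radii) != len(self.points):
            raise MorphologyError("radii/points length mismatch")
        seg = np.diff(self.points, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0.0):
            raise MorphologyError("consecutive points must be distinct")
        if np.any(self.radii <= 0):
            raise MorphologyError("radii must be positive")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        return float(self.segment_lengths.sum())


@dataclass
class Morphology:
    """A soma centre plus a forest of sections rooted at the soma."""

    soma_center: np.ndarray
    sections: list[Section] = field(default_factory=list)
    soma_radius: float = 1.0

    def __post_init__(self) -> None:
        self.soma_center = np.asarray(self.soma_center, dtype=float).reshape(3)
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        n = len(self.sections)
        for i, sec in enumerate(self.sections):
            if sec.parent is not None:
                if not (0 <= sec.parent < n) or sec.parent == i:
                    raise MorphologyError(f"section {i}: invalid parent {sec.parent}")
                par = self.sections[sec.parent]
                if not np.allclose(par.points[-1], sec.points[0], atol=1e-6):
                    raise MorphologyError(
                        f"section {i}: first point does not match parent's last point"
                    )
        # forest check: walking parents must terminate
        for i in range(n):
            seen = set()
            j: int | None = i
            while j is not None:
                if j in seen:
                    raise MorphologyError("cycle detected")
                seen.add(j)
                j = self.sections[j].parent

    @property
    def root_sections(self) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.parent is None]

    def children(self, index: int) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.parent == index]

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {i: [] for i in range(len(self.sections))}
        for i, s in enumerate(self.sections):
            if s.parent is not None:
                out[s.parent].append(i)
        return out

    def terminal_sections(self, labels: Sequence[str] = AXONAL_LABELS) -> list[int]:
        kids = self.children_map()
        return [
            i
            for i, s in enumerate(self.sections)
            if s.label in labels and not kids[i]
        ]

    def ancestors(self, index: int) -> list[int]:
        """Indices from the section's parent up to its root (inclusive)."""
        out = []
        j = self.sections[index].parent
        while j is not None:
            out.append(j)
            j = self.sections[j].parent
        return out

    def path_distance_to_start(self) -> np.ndarray:
        """Path distance from the soma to each section's first point."""
        dist = np.zeros(len(self.sections))
        order = self.topological_order()
        for i in order:
            p = self.sections[i].parent
            if p is not None:
                dist[i] = dist[p] + self.sections[p].length
        return dist

    def topological_order(self) -> list[int]:
        order: list[int] = []
        kids = self.children_map()
        stack = list(reversed(self.root_sections))
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(kids[i]))
        return order

    def copy(self) -> "Morphology":
        return Morphology(
            self.soma_center.copy(),
            [
                Section(s.points.copy(), s.radii.copy(), s.parent, s.label)
                for s in self.sections
            ],
            self.soma_radius,
        )

    def relabel(self, labels: dict[int, str]) -> "Morphology":
        m = self.copy()
        for i, lab in labels.items():
            m.sections[i].label = lab
        return m


def total_cable_length(
    morph: Morphology, labels: Sequence[str] = AXONAL_LABELS
) -> float:
    return float(sum(s.length for s in morph.sections if s.label in labels))


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------


def read_swc(path: str | Path) -> Morphology:
    """Read a 7-column whitespace-separated SWC file.

    Soma rows (type 1) are collapsed to their centroid; both one-row and
    three-row soma dialects are accepted.  SWC parent ids referring to a soma
    row attach the section to the soma.
    """
    path = Path(path)
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(f"parse error at line {lineno}: expected 7 columns")
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise MorphologyError(f"parse error at line {lineno}: {exc}") from exc
            rows[nid] = (ntype, x, y, z, r, parent)
            order.append(nid)

    if not rows:
        raise MorphologyError("parse error: empty SWC file")

    soma_ids = {nid for nid in order if rows[nid][0] == 1}
    for nid in order:
        par = rows[nid][5]
        if par != -1 and par not in rows:
            raise MorphologyError(f"broken topology: node {nid} references parent {par}")

    # cycle check over raw node graph
    for nid in order:
        seen = set()
        j = nid
        while j != -1:
            if j in seen:
                raise MorphologyError("cycle detected")
            seen.add(j)
            j = rows[j][5]

    if soma_ids:
        pts = np.array([rows[i][1:4] for i in sorted(soma_ids)])
        soma_center = pts.mean(axis=0)
        soma_radius = float(np.mean([rows[i][4] for i in sorted(soma_ids)]))
    else:
        # no explicit soma: use the first root node's coordinate
        roots = [nid for nid in order if rows[nid][5] == -1]
        soma_center = np.array(rows[roots[0]][1:4])
        soma_radius = 1.0

    # children map over neurite nodes; soma rows act as virtual roots
    children: dict[int, list[int]] = {}
    neurite_roots: list[int] = []
    for nid in order:
        if nid in soma_ids:
            continue
        par = rows[nid][5]
        if par == -1 or par in soma_ids:
            neurite_roots.append(nid)
        else:
            children.setdefault(par, []).append(nid)

    def node_point(nid: int) -> np.ndarray:
        return np.array(rows[nid][1:4])

    sections: list[Section] = []

    def build(start: int, first_pt: np.ndarray | None, first_r: float | None,
              parent_sec: int | None) -> None:
        """Collect an unbranched chain starting at node `start`."""
        pts: list[np.ndarray] = []
        rads: list[float] = []
        if first_pt is not None:
            pts.append(first_pt)
            rads.append(first_r if first_r is not None else rows[start][4])
        cur = start
        label = LABEL_OF_SWC_TYPE.get(rows[start][0], "trunk")
        while True:
            p = node_point(cur)
            if not pts or np.linalg.norm(p - pts[-1]) > 0:
                pts.append(p)
                rads.append(rows[cur][4])
            kids = children.get(cur, [])
            if len(kids) == 1 and rows[kids[0]][0] == rows[cur][0]:
                cur = kids[0]  # continue the chain within one structure type
                continue
            break
        if len(pts) < 2:
            # single-node root section: cannot form a segment on its own
            if not children.get(cur, []):
                raise MorphologyError(
                    f"broken topology: single-point section at node {start}"
                )
        sec_index = len(sections)
        sections.append(Section(np.array(pts), np.array(rads), parent_sec, label))
        for k in children.get(cur, []):
            build(k, node_point(cur), rows[cur][4], sec_index)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000 + 10 * len(rows)))
    try:
        for root in neurite_roots:
            build(root, None, None, None)
    finally:
        sys.setrecursionlimit(old_limit)

    return Morphology(soma_center, sections, soma_radius)


def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write a morphology as SWC (6-decimal coordinates, one soma row)."""
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    sc = morph.soma_center
    lines.append(
        f"1 1 {sc[0]:.6f} {sc[1]:.6f} {sc[2]:.6f} {morph.soma_radius:.6f} -1"
    )
    next_id = 2
    last_node_of_section: dict[int, int] = {}

    for i in morph.topological_order():
        sec = morph.sections[i]
        t = SWC_TYPE_OF_LABEL.get(sec.label, 2)
        if sec.parent is None:
            parent_node = 1
            start = 0  # root sections emit their first point
        else:
            parent_node = last_node_of_section[sec.parent]
            start = 1  # first point duplicates the parent's last node
        for j in range(start, len(sec.points)):
            x, y, z = sec.points[j]
            r = sec.radii[j]
            lines.append(
                f"{next_id} {t} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {parent_node}"
            )
            parent_node = next_id
            next_id += 1
        last_node_of_section[i] = parent_node

    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Path lengths
# ---------------------------------------------------------------------------


def section_path_length(section: Section) -> float:
    """Sum of Euclidean segment lengths along a section."""
    return section.length


def _locate_point(morph: Morphology, point: np.ndarray, atol: float) -> tuple[int, int]:
    point = np.asarray(point, dtype=float).reshape(3)
    for i, sec in enumerate(morph.sections):
        d = np.linalg.norm(sec.points - point, axis=1)
        j = int(np.argmin(d))
        if d[j] <= atol:
            return i, j
    raise MorphologyError("off-tree point")


def path_distance(
    morph: Morphology,
    point: np.ndarray | tuple[int, int],
    atol: float = 1e-6,
) -> float:
    """Path distance from the soma to a node of the tree.

    ``point`` is either a 3D coordinate that must coincide with a tree node
    (within ``atol``) or an explicit ``(section_index, point_index)`` pair.
    """
    if isinstance(point, tuple) and len(point) == 2 and isinstance(point[0], (int, np.integer)):
        si, pi = int(point[0]), int(point[1])
    else:
        si, pi = _locate_point(morph, np.asarray(point), atol)
    start = morph.path_distance_to_start()[si]
    sec = morph.sections[si]
    return float(start + sec.segment_lengths[:pi].sum())


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

METRICS = (
    "remote_bifurcation_angle",
    "section_length",
    "section_radial_distance",
    "section_term_radial_distance",
    "terminal_path_length",
    "section_tortuosity",
    "inter_segment_angle",
    "branch_order",
)


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.acos(c)


def _selected(morph: Morphology, part: str | None) -> list[int]:
    if part is None or part == "complete":
        labs = AXONAL_LABELS
    elif part in AXONAL_LABELS:
        labs = (part,)
    else:
        raise MorphologyError(f"unknown part {part!r}")
    return [i for i, s in enumerate(morph.sections) if s.label in labs]


def morphometrics(
    morph: Morphology,
    which: Iterable[str] = METRICS,
    part: str | None = None,
) -> dict[str, list[float]]:
    """Per-item morphometric values for a morphology.

    Angles are returned in radians.  ``part`` restricts the computation to
    ``trunk`` or ``tuft`` sections (default: all axonal sections).

    - remote bifurcation angle: angle at a bifurcation between the vectors
      from the fork to the two child sections' last points;
    - tortuosity: section path length over Euclidean end-to-end distance;
    - radial distances: Euclidean norm from the soma centre to the section's
      last point;
    - branch order: number of ancestor sections (roots have order 0);
    - inter-segment angle (experimental): angle between consecutive segments
      within a section.
    """
    which = list(which)
    for name in which:
        if name not in METRICS:
            raise MorphologyError(f"unknown metric {name!r}")

    sel = set(_selected(morph, part))
    kids = morph.children_map()
    start_dist = morph.path_distance_to_start()
    out: dict[str, list[float]] = {name: [] for name in which}

    for name in which:
        vals = out[name]
        if name == "remote_bifurcation_angle":
            for i in sel:
                ch = [c for c in kids[i] if c in sel]
                if len(ch) < 2:
                    continue
                fork = morph.sections[i].points[-1]
                for a in range(len(ch)):
                    for b in range(a + 1, len(ch)):
                        u = morph.sections[ch[a]].points[-1] - fork
                        v = morph.sections[ch[b]].points[-1] - fork
                        vals.append(_angle(u, v))
        elif name == "section_length":
            vals.extend(morph.sections[i].length for i in sorted(sel))
        elif name == "section_radial_distance":
            vals.extend(
                float(np.linalg.norm(morph.sections[i].points[-1] - morph.soma_center))
                for i in sorted(sel)
            )
        elif name == "section_term_radial_distance":
            for i in sorted(sel):
                if not [c for c in kids[i] if c in sel]:
                    vals.append(
                        float(
                            np.linalg.norm(
                                morph.sections[i].points[-1] - morph.soma_center
                            )
                        )
                    )
        elif name == "terminal_path_length":
            for i in sorted(sel):
                if not [c for c in kids[i] if c in sel]:
                    vals.append(float(start_dist[i] + morph.sections[i].length))
        elif name == "section_tortuosity":
            for i in sorted(sel):
                sec = morph.sections[i]
                chord = float(np.linalg.norm(sec.points[-1] - sec.points[0]))
                vals.append(sec.length / chord if chord > 0 else float("inf"))
        elif name == "inter_segment_angle":
            for i in sorted(sel):
                pts = morph.sections[i].points
                for j in range(len(pts) - 2):
                    vals.append(_angle(pts[j + 1] - pts[j], pts[j + 2] - pts[j + 1]))
        elif name == "branch_order":
            vals.extend(float(len(morph.ancestors(i))) for i in sorted(sel))
    return out


def morphometrics_table(
    morphologies: dict[str, Morphology] | Sequence[Morphology],
    which: Iterable[str] = METRICS,
    part: str | None = None,
):
    """Long-format table (morphology_id, metric, value) of morphometrics."""
    import pandas as pd

    if not isinstance(morphologies, dict):
        morphologies = {str(i): m for i, m in enumerate(morphologies)}
    rows = []
    for mid, morph in morphologies.items():
        for metric, values in morphometrics(morph, which, part).items():
            rows.extend({"morphology_id": mid, "metric": metric, "value": v} for v in values)
    return pd.DataFrame(rows, columns=["morphology_id", "metric", "value"])
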