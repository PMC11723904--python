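"""Trunk/tuft decomposition of reconstructed axons and tuft statistics.

Tufts are found by clustering axonal terminals pairwise: two terminals join
the same tuft when they are simultaneously within a Euclidean distance
``d_euclidean_max`` and a path distance (along the tree, terminal to
terminal) ``d_path_max``; transitive merging of pairs with a common terminal
yields the tuft partition.  Everything proximal to the tufts' common
ancestors is the long-range trunk, which by construction carries no bare
terminals.

Each tuft is summarised as a :class:`TuftRecord` (common-ancestor
coordinates, total path length, path distance to the soma, orientation
toward the tuft's centre of mass in the local atlas frame, and its
persistence :class:`Barcode`), the template currency of tuft synthesis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .morphology import Morphology, MorphologyError

__all__ = [
    "ClusteringParams",
    "Barcode",
    "TuftRecord",
    "TrunkStats",
    "cluster_terminals",
    "split_trunk_tufts",
    "compute_barcode",
    "extract_trunk_stats",
    "save_tuft_records",
    "load_tuft_records",
]


@dataclass(frozen=True)
class ClusteringParams:
    """Pairwise clustering thresholds, micrometres.

    The path threshold defaults to three times the Euclidean one, the ratio
    used throughout for the clustering-distance parameter scans.
    """

    d_euclidean_max: float = 100.0
    d_path_max: float | None = None

    def __post_init__(self) -> None:
        if self.d_euclidean_max <= 0:
            raise ValueError("d_euclidean_max must be > 0")
        if self.d_path_max is None:
            object.__setattr__(self, "d_path_max", 3.0 * self.d_euclidean_max)
        if self.d_path_max <= 0:
            raise ValueError("d_path_max must be > 0")


@dataclass
class Barcode:
    """Persistence barcode of a rooted tree's path-distance filtration.

    ``bars`` is an (n, 2) array of (birth, death) path distances with
    birth <= death; one bar per terminal; birth is the path distance of the
    merge event that kills the branch (0 for the root bar) and death the
    terminal's path distance, so the persistences sum exactly to the cable
    length of the tree.
    """

    bars: np.ndarray

    def __post_init__(self) -> None:
        self.bars = np.asarray(self.bars, dtype=float).reshape(-1, 2)
        if len(self.bars) == 0:
            raise ValueError("barcode needs at least one bar")
        if np.any(self.bars < 0):
            raise ValueError("bar endpoints must be >= 0")
        if np.any(self.bars[:, 1] <= self.bars[:, 0]):
            raise ValueError("invalid barcode: each bar needs death > birth")

    @property
    def persistences(self) -> np.ndarray:
        return self.bars[:, 1] - self.bars[:, 0]

    def __len__(self) -> int:
        return len(self.bars)


@dataclass
class TuftRecord:
    """Template statistics of one clustered tuft."""

    common_ancestor: np.ndarray
    total_path_length: float
    path_distance_to_soma: float
    orientation: np.ndarray
    barcode: Barcode
    source_region: int | None = None
    frame: str = "world"  # "atlas" when expressed in the local atlas frame

    def __post_init__(self) -> None:
        self.common_ancestor = np.asarray(self.common_ancestor, float).reshape(3)
        self.orientation = np.asarray(self.orientation, float).reshape(3)
        n = np.linalg.norm(self.orientation)
        if n == 0:
            raise ValueError("orientation must be non-zero")
        self.orientation = self.orientation / n
        if self.total_path_length <= 0:
            raise ValueError("total_path_length must be > 0")
        if self.path_distance_to_soma < 0:
            raise ValueError("path_distance_to_soma must be >= 0")


@dataclass(frozen=True)
class TrunkStats:
    """Mean and (population) standard deviation of trunk segment lengths."""

    segment_length_mean: float
    segment_length_std: float

    def __post_init__(self) -> None:
        if self.segment_length_mean <= 0:
            raise ValueError("segment_length_mean must be > 0")
        if self.segment_length_std < 0:
            raise ValueError("segment_length_std must be >= 0")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _terminal_info(morph: Morphology):
    """Terminal section ids, coordinates and soma path distances."""
    terms = morph.terminal_sections()
    if not terms:
        raise MorphologyError("empty axon")
    coords = np.array([morph.sections[i].points[-1] for i in terms])
    start = morph.path_distance_to_start()
    pdist = np.array([start[i] + morph.sections[i].length for i in terms])
    return terms, coords, pdist


def _lca_section(morph: Morphology, a: int, b: int) -> int | None:
    chain_a = [a] + morph.ancestors(a)
    set_a = set(chain_a)
    j: int | None = b
    while j is not None:
        if j in set_a:
            return j
        j = morph.sections[j].parent
    return None


def _fork_distance(morph: Morphology, a: int, b: int, start: np.ndarray) -> float:
    """Path distance from soma to the deepest node common to both root paths."""
    if a == b:
        return float(start[a] + morph.sections[a].length)
    lca = _lca_section(morph, a, b)
    if lca is None:
        return 0.0
    if lca == a or lca == b:  # one section on the other's root path
        return float(start[lca] + morph.sections[lca].length)
    return float(start[lca] + morph.sections[lca].length)


def cluster_terminals(
    morph: Morphology, params: ClusteringParams = ClusteringParams()
) -> dict[int, int]:
    """Partition axonal terminals into tufts.

    Returns a map ``terminal section index -> tuft id``; tuft ids are dense,
    ordered by each tuft's smallest terminal section index, hence independent
    of enumeration order.
    """
    terms, coords, pdist = _terminal_info(morph)
    n = len(terms)
    start = morph.path_distance_to_start()
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            de = float(np.linalg.norm(coords[i] - coords[j]))
            if de > params.d_euclidean_max:
                continue
            fork = _fork_distance(morph, terms[i], terms[j], start)
            dp = (pdist[i] - fork) + (pdist[j] - fork)
            if dp <= params.d_path_max:
                uf.union(i, j)
    roots = [uf.find(i) for i in range(n)]
    # canonical ids ordered by smallest terminal section index in each tuft
    rep_min: dict[int, int] = {}
    for i, r in enumerate(roots):
        rep_min[r] = min(rep_min.get(r, terms[i]), terms[i])
    ordered = sorted(rep_min, key=lambda r: rep_min[r])
    tuft_id = {r: k for k, r in enumerate(ordered)}
    return {terms[i]: tuft_id[roots[i]] for i in range(n)}


# ---------------------------------------------------------------------------
# Trunk / tuft split
# ---------------------------------------------------------------------------


def _atlas_frame(atlas, point: np.ndarray) -> np.ndarray:
    """Rotation matrix whose rows are the local frame axes (Y toward pia)."""
    y = np.asarray(atlas.orientation_at(point), float)
    y = y / np.linalg.norm(y)
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, y)) > 0.9:
        probe = np.array([0.0, 0.0, 1.0])
    x = probe - np.dot(probe, y) * y
    x /= np.linalg.norm(x)
    z = np.cross(x, y)
    return np.stack([x, y, z])


def split_trunk_tufts(
    morph: Morphology,
    assignment: dict[int, int],
    atlas=None,
) -> tuple[Morphology, list[TuftRecord]]:
    """Label trunk vs tuft sections and build one :class:`TuftRecord` per tuft.

    The common ancestor of a tuft is the last tree node shared by all of its
    terminals' root paths (for a singleton tuft, the terminal section's first
    point).  Sections on the paths from a common ancestor down to its tuft's
    terminals are labelled ``tuft``; the rest of the axon is ``trunk``.
    """
    if not assignment:
        raise MorphologyError("empty axon")
    tufts: dict[int, list[int]] = {}
    for term, tid in assignment.items():
        tufts.setdefault(tid, []).append(term)

    start = morph.path_distance_to_start()
    labels: dict[int, str] = {}
    records: list[TuftRecord] = []

    for tid in sorted(tufts):
        terms = sorted(tufts[tid])
        if len(terms) == 1:
            t = terms[0]
            parent = morph.sections[t].parent
            if parent is None:
                raise MorphologyError("degenerate tuft at soma")
            ca = morph.sections[t].points[0].copy()
            ca_dist = float(start[t])
            tuft_sections = {t}
        else:
            # deepest section common to all root paths
            common: set[int] | None = None
            for t in terms:
                chain = set([t] + morph.ancestors(t))
                common = chain if common is None else (common & chain)
            if not common:
                raise MorphologyError("degenerate tuft at soma")
            lca = max(common, key=lambda i: start[i])
            ca = morph.sections[lca].points[-1].copy()
            ca_dist = float(start[lca] + morph.sections[lca].length)
            tuft_sections = set()
            for t in terms:
                j: int | None = t
                while j is not None and j != lca:
                    tuft_sections.add(j)
                    j = morph.sections[j].parent
        for i in tuft_sections:
            labels[i] = "tuft"

        records.append(
            _make_record(morph, sorted(tuft_sections), ca, ca_dist, atlas)
        )

    labeled = morph.copy()
    for i, sec in enumerate(labeled.sections):
        if sec.label in ("trunk", "tuft"):
            sec.label = labels.get(i, "trunk")
    return labeled, records


def _make_record(
    morph: Morphology,
    tuft_sections: Sequence[int],
    ca: np.ndarray,
    ca_dist: float,
    atlas,
) -> TuftRecord:
    secs = [morph.sections[i] for i in tuft_sections]
    total = float(sum(s.length for s in secs))
    pts = np.concatenate([s.points for s in secs])
    com = pts.mean(axis=0)
    vec = com - ca
    if np.linalg.norm(vec) == 0:
        vec = np.array([0.0, 1.0, 0.0])
    frame = "world"
    region = None
    if atlas is not None:
        rot = _atlas_frame(atlas, ca)
        vec = rot @ vec
        frame = "atlas"
        region = int(atlas.region_at(ca))
    barcode = compute_barcode(morph, tuft_sections)
    return TuftRecord(
        common_ancestor=ca,
        total_path_length=total,
        path_distance_to_soma=ca_dist,
        orientation=vec,
        barcode=barcode,
        source_region=region,
        frame=frame,
    )


# ---------------------------------------------------------------------------
# Barcode (elder rule on the path-distance filtration)
# ---------------------------------------------------------------------------


def compute_barcode(
    morph: Morphology, sections: Sequence[int] | None = None
) -> Barcode:
    """Persistence barcode of a rooted (sub)tree.

    ``sections`` selects a subtree (sections whose parent is outside the
    set act as its roots); by default the whole axonal arbor is used with
    the soma as root.  At every merge the branch with the smaller maximal
    descendant path distance dies (elder rule); one bar per terminal; the
    persistences sum exactly to the subtree's cable length.
    """
    if sections is None:
        sections = [
            i for i, s in enumerate(morph.sections) if s.label in ("trunk", "tuft")
        ]
    subset = set(sections)
    if not subset:
        raise MorphologyError("empty axon")
    kids: dict[int, list[int]] = {i: [] for i in subset}
    roots = []
    for i in subset:
        p = morph.sections[i].parent
        if p is not None and p in subset:
            kids[p].append(i)
        else:
            roots.append(i)

    bars: list[tuple[float, float]] = []

    def walk(sec: int, d0: float) -> float:
        d1 = d0 + morph.sections[sec].length
        ch = sorted(kids[sec])
        if not ch:
            return d1
        maxima = sorted((walk(c, d1) for c in ch), reverse=True)
        bars.extend((d1, m) for m in maxima[1:])
        return maxima[0]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000 + 10 * len(subset)))
    try:
        root_maxima = sorted((walk(r, 0.0) for r in sorted(roots)), reverse=True)
    finally:
        sys.setrecursionlimit(old)
    bars.extend((0.0, m) for m in root_maxima[1:])
    bars.append((0.0, root_maxima[0]))
    return Barcode(np.array(bars))


# ---------------------------------------------------------------------------
# Trunk statistics
# ---------------------------------------------------------------------------


def extract_trunk_stats(morphologies: Morphology | Sequence[Morphology]) -> TrunkStats:
    """Mean/std of consecutive-point segment lengths over trunk sections."""
    if isinstance(morphologies, Morphology):
        morphologies = [morphologies]
    lengths: list[np.ndarray] = []
    for m in morphologies:
        for s in m.sections:
            if s.label == "trunk":
                lengths.append(s.segment_lengths)
    if not lengths:
        raise MorphologyError("no trunk sections")
    all_lengths = np.concatenate(lengths)
    return TrunkStats(
        segment_length_mean=float(all_lengths.mean()),
        segment_length_std=float(all_lengths.std()),  # population std
    )


# ---------------------------------------------------------------------------
# JSON-lines persistence of tuft records
# ---------------------------------------------------------------------------


def save_tuft_records(records: Sequence[TuftRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "common_ancestor": r.common_ancestor.tolist(),
                        "total_path_length": r.total_path_length,
                        "path_distance_to_soma": r.path_distance_to_soma,
                        "orientation": r.orientation.tolist(),
                        "bars": r.barcode.bars.tolist(),
                        "source_region": r.source_region,
                        "frame": r.frame,
                    }
                )
                + "\n"
            )


def load_tuft_records(path: str | Path) -> list[TuftRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            records.append(
                TuftRecord(
                    common_ancestor=np.array(d["common_ancestor"]),
                    total_path_length=d["total_path_length"],
                    path_distance_to_soma=d["path_distance_to_soma"],
                    orientation=np.array(d["orientation"]),
                    barcode=Barcode(np.array(d["bars"])),
                    source_region=d.get("source_region"),
                    frame=d.get("frame", "world"),
                )
            )
    return records
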