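"""Source-population and target-point selection from probability matrices.

Each axon draws a source population from the categorical distribution of its
soma's brain region (source population matrix), then a set of target
populations from the projection probability matrix, and finally one concrete
target point per chosen target population: a voxel picked uniformly among
the voxels of that population's brain regions plus a uniform shift inside
the voxel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import VoxelAtlas

__all__ = [
    "SourcePopulationMatrix",
    "ProjectionMatrix",
    "TargetingError",
    "pick_source_population",
    "pick_target_populations",
    "pick_target_points",
]


class TargetingError(ValueError):
    """Raised for unknown regions/populations or empty target regions."""


def _check_stochastic(df: pd.DataFrame, group: str, prob: str) -> None:
    if (df[prob] < 0).any():
        raise TargetingError("probabilities must be >= 0")
    sums = df.groupby(group)[prob].sum()
    if not np.allclose(sums.to_numpy(), 1.0, atol=1e-9):
        bad = sums[~np.isclose(sums, 1.0, atol=1e-9)].index.tolist()
        raise TargetingError(f"probabilities must sum to 1 per {group}: {bad}")


@dataclass
class SourcePopulationMatrix:
    """Rows (source_region, population, probability); row-stochastic per region."""

    table: pd.DataFrame

    COLUMNS = ("source_region", "population", "probability")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise TargetingError(f"missing columns: {sorted(missing)}")
        _check_stochastic(self.table, "source_region", "probability")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SourcePopulationMatrix":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ProjectionMatrix:
    """Rows (population, target_population, probability, regions).

    ``regions`` holds the brain-region ids of each target population as a
    semicolon-joined string in CSV form; in memory a list of ints is also
    accepted.
    """

    table: pd.DataFrame

    COLUMNS = ("population", "target_population", "probability", "regions")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise TargetingError(f"missing columns: {sorted(missing)}")
        _check_stochastic(self.table, "population", "probability")

    def regions_of(self, target_population) -> list[int]:
        rows = self.table[self.table["target_population"] == target_population]
        if rows.empty:
            raise TargetingError(f"unknown target population {target_population!r}")
        raw = rows.iloc[0]["regions"]
        if isinstance(raw, str):
            return [int(v) for v in raw.split(";") if v != ""]
        return [int(v) for v in np.atleast_1d(raw)]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProjectionMatrix":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def pick_source_population(
    region_id: int,
    matrix: SourcePopulationMatrix,
    rng: np.random.Generator,
):
    """Draw a source population for a soma located in ``region_id``."""
    rows = matrix.table[matrix.table["source_region"] == region_id]
    rows = rows.sort_values("population")
    if rows.empty:
        raise TargetingError(f"no source population for region {region_id}")
    probs = rows["probability"].to_numpy()
    idx = rng.choice(len(rows), p=probs / probs.sum())
    return rows.iloc[int(idx)]["population"]


def pick_target_populations(
    population,
    matrix: ProjectionMatrix,
    rng: np.random.Generator,
    n_targets: int | None = None,
) -> list:
    """Choose the target populations of one axon.

    By default each candidate row is kept with its own probability
    (independent Bernoulli draws; at least one is enforced by falling back
    to a single categorical draw).  With ``n_targets`` set, exactly that
    many are drawn from the row's categorical distribution (with
    replacement).
    """
    rows = matrix.table[matrix.table["population"] == population]
    rows = rows.sort_values("target_population")
    if rows.empty:
        raise TargetingError(f"no projection row for population {population!r}")
    probs = rows["probability"].to_numpy()
    names = rows["target_population"].tolist()
    if n_targets is not None:
        if n_targets < 1:
            raise TargetingError("n_targets must be >= 1")
        idx = rng.choice(len(names), size=n_targets, p=probs / probs.sum())
        return [names[int(i)] for i in idx]
    keep = rng.random(len(names)) < probs
    if not keep.any():
        idx = rng.choice(len(names), p=probs / probs.sum())
        return [names[int(idx)]]
    return [n for n, k in zip(names, keep) if k]


def pick_target_points(
    population,
    matrices: tuple[SourcePopulationMatrix, ProjectionMatrix] | ProjectionMatrix,
    atlas: VoxelAtlas,
    rng: np.random.Generator,
    n_targets: int | None = None,
) -> list[tuple[object, np.ndarray]]:
    """Concrete 3D target points for one axon.

    Returns ``[(target_population, point), ...]``; each point is a voxel
    chosen uniformly in the target population's regions plus a uniform shift
    inside the voxel, so it always maps back to those regions.
    """
    proj = matrices[1] if isinstance(matrices, tuple) else matrices
    chosen = pick_target_populations(population, proj, rng, n_targets)
    out: list[tuple[object, np.ndarray]] = []
    for tp in chosen:
        regions = proj.regions_of(tp)
        voxels = atlas.region_voxels(regions)
        if len(voxels) == 0:
            raise TargetingError(f"empty target region for population {tp!r}")
        vox = voxels[rng.integers(len(voxels))]
        point = atlas.origin + (vox + rng.uniform(0.0, 1.0, size=3)) * atlas.voxel_size
        out.append((tp, point))
    return out
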