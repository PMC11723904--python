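"""Validated configuration for the synthesis pipeline (TOML-backed).

The configuration mirrors the model symbols: clustering distances, graph
enrichment counts, edge-weight amplitudes/exponents (lambda_o, alpha_o,
lambda_zeta, alpha_zeta, lambda_gamma, alpha_gamma), random-walk weights
(beta_ep, beta_nit, beta_hist, beta_rand), tuft-selection bandwidths
(sigma_l, sigma_d), tuft growth step statistics, and the boundary repulsion
scale alpha_b.  Unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .atlas import BoundaryParams
from .graph import EdgeWeightParams, GraphBuildParams
from .growth import GrowthParams
from .tufts import ClusteringParams
from .walk import WalkParams

__all__ = ["SynthesisConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


def _build(cls, data: dict[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid [{section}]: {exc}") from exc


@dataclass
class SynthesisConfig:
    """All tunable parameters of the pipeline plus the global seed."""

    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    graph: GraphBuildParams = field(default_factory=GraphBuildParams)
    edge_weights: EdgeWeightParams = field(default_factory=EdgeWeightParams)
    walk: WalkParams = field(default_factory=WalkParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    boundary: BoundaryParams | None = None
    sigma_l: float = 1000.0  # template-affinity bandwidth on tuft length
    sigma_d: float = 1000.0  # template-affinity bandwidth on soma distance
    attractor_spacing: float = 300.0  # um, thinning distance & kernel scale
    use_attraction: bool = False
    tuft_selection: str = "probabilistic"  # or "matched" (mimic default)
    n_targets: int | None = None  # None: Bernoulli per projection row
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tuft_selection not in ("probabilistic", "matched"):
            raise ConfigError("tuft_selection must be 'probabilistic' or 'matched'")
        if self.attractor_spacing <= 0:
            raise ConfigError("attractor_spacing must be > 0")

    SECTIONS = {
        "clustering": ClusteringParams,
        "graph": GraphBuildParams,
        "edge_weights": EdgeWeightParams,
        "walk": WalkParams,
        "growth": GrowthParams,
        "boundary": BoundaryParams,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SynthesisConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        for name, sub_cls in cls.SECTIONS.items():
            if name in data:
                kwargs[name] = _build(sub_cls, data.pop(name), name)
        top_known = {f.name for f in dataclasses.fields(cls)} - set(cls.SECTIONS)
        unknown = set(data) - top_known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "SynthesisConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict[str, Any]:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if hasattr(obj, "tolist"):
                return obj.tolist()
            return obj

        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = enc(v)
        return out

    def manifest(self) -> str:
        """JSON run manifest: configuration plus library versions."""
        import numpy
        import pandas
        import scipy

        return json.dumps(
            {
                "config": self.to_dict(),
                "versions": {
                    "numpy": numpy.__version__,
                    "scipy": scipy.__version__,
                    "pandas": pandas.__version__,
                },
            },
            indent=2,
            default=str,
        )
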