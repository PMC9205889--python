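"""Run configuration.

A RunConfig bundles the generator block with every pipeline parameter. The
defaults are the study-design values: 5-minute gap rule, 5000-draw null
models, 1000 bootstrap samples, community weight exponent 1/4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthgen import SimConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    gap_limit: int = 5
    activity_thresholds: tuple = tuple(range(0, 201, 20))
    n_null: int = 5000
    n_boot: int = 1000
    community_exponent: float = 0.25
    ensemble_runs: int = 5000
    seed: int = 0
    weight_by: str = "episodes"  # or "minutes" (sensitivity analysis)
    distance: str = "inverse"  # weighted shortest-path distance = 1/w
    min_degree_for_clustering: int = 0  # optional exclusion for correlations

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; the ``sim`` block maps onto SimConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("sim", {})
    if "org_sizes" in sim_raw:
        sim_raw["org_sizes"] = tuple(sim_raw["org_sizes"])
    if "workday_minutes" in sim_raw:
        sim_raw["workday_minutes"] = tuple(sim_raw["workday_minutes"])
    if "activity_thresholds" in raw:
        raw["activity_thresholds"] = tuple(raw["activity_thresholds"])
    sim = SimConfig(**sim_raw)
    return RunConfig(sim=sim, **raw)
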