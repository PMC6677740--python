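"""Run configuration: nested dataclasses, strict YAML loading, overrides.

A :class:`RunConfig` fully determines a simulation run (lattice geometry,
model parameters, extrinsic gradient, integration settings, analysis
windows).  Loading is strict: unknown keys raise, every referenced
module's preconditions are validated at construction time, and resolved
configs round-trip to plain dicts for the run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .dynamics import GradientParams, ModelParams, SpatialProfile

__all__ = ["RunConfig", "default_config", "load_config", "config_to_dict"]


@dataclass
class LatticeConfig:
    n_cells: int = 1000
    box_width: float = 20.0
    box_height: float = 50.0
    disorder: float = 0.3
    lloyd_iterations: int = 20


@dataclass
class CouplingConfig:
    signaling_range: float = 1.0
    strength: float = 2.0
    cutoff_factor: float = 3.0
    normalized: bool = False


@dataclass
class ModelConfig:
    tau: float = 1.0
    f_steepness: float = 0.05
    f_threshold: float = 0.0
    noise_sigma: float = 0.02
    ligand_midpoint: float = 0.5
    ligand_steepness: float = 0.1
    fate_threshold: float | None = None

    def to_params(self) -> ModelParams:
        return ModelParams(**dataclasses.asdict(self))


@dataclass
class GradientConfig:
    """Extrinsic gradient: early negative template -> late flank signal.

    Bumps are ``[center, amplitude, width]`` triples in cell diameters;
    negative amplitudes are permissive notches.  Defaults encode a high
    early plateau with notches at the stripe-1/3/5 positions and a late
    profile of inhibitory shoulders around stripes 1 and 5 whose own
    centers stay permissive.
    """

    early_baseline: float = 1.0
    early_bumps: list = field(
        default_factory=lambda: [[2.0, -1.0, 1.2], [10.0, -1.0, 1.2], [18.0, -1.0, 1.2]]
    )
    late_baseline: float = 0.0
    late_bumps: list = field(
        default_factory=lambda: [
            [2.0, 0.9, 1.8], [2.0, -0.9, 0.8],
            [18.0, 0.9, 1.8], [18.0, -0.9, 0.8],
        ]
    )
    t_start: float = 8.0
    t_end: float = 16.0

    def to_params(self, period: float) -> GradientParams:
        return GradientParams(
            early=SpatialProfile(
                baseline=self.early_baseline,
                bumps=tuple(tuple(b) for b in self.early_bumps),
                period=period,
            ),
            late=SpatialProfile(
                baseline=self.late_baseline,
                bumps=tuple(tuple(b) for b in self.late_bumps),
                period=period,
            ),
            t_start=self.t_start,
            t_end=self.t_end,
        )


@dataclass
class SimulationConfig:
    t_end: float = 30.0
    dt: float = 0.02
    record_every: int = 25
    seed: int = 0


@dataclass
class AnalysisConfig:
    """Windows and bins for stripe detection and time-course readouts."""

    stripe_bin_width: float = 0.5
    template_snapshot_time: float = 8.0   # end of the pure-template phase
    pattern_snapshot_time: float = 20.0   # stripes established, pre-terminal
    stripe_center_x: float = 10.0         # stripe-3 position
    stripe_halfwidth: float = 2.4
    n_bins: int = 3
    central_region: list = field(default_factory=lambda: [4.0, 16.0])


@dataclass
class ProfilePipelineConfig:
    bin_width_um: float = 2.0
    range_um: float = 20.0
    threshold: float = 0.2
    statistic: str = "sum_minus_threshold"
    normalization: str = "percentile"


@dataclass
class RegimeConfig:
    late_inhibition_factor: float = 0.6


@dataclass
class RunConfig:
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    gradient: GradientConfig = field(default_factory=GradientConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    profile: ProfilePipelineConfig = field(default_factory=ProfilePipelineConfig)
    regimes: RegimeConfig = field(default_factory=RegimeConfig)
    regime: str = "wild_type"
    output_dir: str = "runs"

    def validate(self) -> "RunConfig":
        lat, sim, mod = self.lattice, self.simulation, self.model
        if lat.n_cells < 1:
            raise ValueError("lattice.n_cells must be >= 1")
        if lat.box_width <= 0 or lat.box_height <= 0:
            raise ValueError("lattice box dimensions must be positive")
        if not 0 <= lat.disorder <= 1:
            raise ValueError("lattice.disorder must lie in [0, 1]")
        if self.coupling.signaling_range <= 0:
            raise ValueError("coupling.signaling_range must be positive")
        if self.coupling.strength < 0:
            raise ValueError("coupling.strength must be >= 0")
        if sim.dt <= 0 or sim.dt > mod.tau / 10:
            raise ValueError("simulation.dt must satisfy 0 < dt <= tau/10")
        if self.gradient.t_start > self.gradient.t_end:
            raise ValueError("gradient.t_start must not exceed gradient.t_end")
        mod.to_params()                       # ModelParams invariants
        self.gradient.to_params(lat.box_width)  # profile invariants
        if self.profile.statistic not in ("sum_minus_threshold", "mean_intensity"):
            raise ValueError("profile.statistic must be sum_minus_threshold or mean_intensity")
        if self.profile.normalization not in ("max", "percentile", "none"):
            raise ValueError("profile.normalization must be max, percentile or none")
        return self


def default_config() -> RunConfig:
    """The calibrated wild-type configuration."""
    return RunConfig().validate()


# ---------------------------------------------------------------------------
# dict / YAML round-trip with strict key checking

def _from_dict(cls, data: dict, path: str = "") -> Any:
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping at {path or 'top level'}, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(path + k for k in unknown))}")
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        val = data[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.type, str) and f.type in _SECTION_TYPES
        ):
            sub_cls = _SECTION_TYPES[f.type] if isinstance(f.type, str) else f.type
            kwargs[name] = _from_dict(sub_cls, val, path=f"{path}{name}.")
        else:
            kwargs[name] = val
    return cls(**kwargs)


_SECTION_TYPES = {
    "LatticeConfig": LatticeConfig,
    "CouplingConfig": CouplingConfig,
    "ModelConfig": ModelConfig,
    "GradientConfig": GradientConfig,
    "SimulationConfig": SimulationConfig,
    "AnalysisConfig": AnalysisConfig,
    "ProfilePipelineConfig": ProfilePipelineConfig,
    "RegimeConfig": RegimeConfig,
}


def config_from_dict(data: dict) -> RunConfig:
    return _from_dict(RunConfig, data).validate()


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def apply_overrides(data: dict, overrides: "dict[str, Any]") -> dict:
    """Apply dotted-key overrides (e.g. ``coupling.strength=0``) to a config
    dict, parsing values as YAML scalars."""
    for dotted, raw in overrides.items():
        keys = dotted.split(".")
        node = data
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ValueError(f"cannot override through non-section key {k!r}")
        node[keys[-1]] = yaml.safe_load(raw) if isinstance(raw, str) else raw
    return data


def load_config(
    path: "str | Path | None" = None, overrides: "dict[str, Any] | None" = None
) -> RunConfig:
    """Load a YAML config (or the defaults) with optional dotted overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        data = loaded
    if overrides:
        data = apply_overrides(data, overrides)
    return config_from_dict(data)
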