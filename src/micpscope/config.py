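"""Run configuration: chip, imaging, segmentation and flow parameters.

All physical constants carry the experiment's defaults (0.29 um/px imaging,
50 um pore throats at 0.5 porosity, 0.018 uL/s cementation flow, calcite
density 2.71 g/cm^3 via the quantify module) so a configuration file only
needs to override what differs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .quantify import FlowConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full synthetic generate→segment→quantify run."""

    # chip geometry
    chip_kind: str = "homogeneous"
    throat_um: float = 50.0
    throat_min_um: float = 25.0
    throat_max_um: float = 350.0
    porosity: float = 0.5
    length_um: float = 990_000.0
    width_um: float = 3_000.0
    depth_um: float = 50.0
    # imaging
    pixel_size_um: float = 0.29
    field_x_um: float = 3_870.0  # longitudinal extent of one position
    field_y_um: float = 2_570.0  # transverse extent
    n_positions: int = 19
    excluded_positions: tuple[int, ...] = ()
    t_final_h: float = 12.0
    # synthetic scene
    bacteria_concentration_per_ml: float = 1.0e8
    noise_sigma: float = 0.02
    illumination_gradient: float = 0.05
    # segmentation sensitivities and filters
    sensitivity_grain: float = 0.45
    sensitivity_bacteria: float = 0.15
    sensitivity_crystal: float = 0.45
    bacteria_area_px: tuple[float, float] = (10.0, 900.0)
    grain_min_area_px: float = 1000.0
    closing_radius_px: int = 2
    thinness_cutoff: float = 0.25
    # flow
    flow: FlowConfig = field(default_factory=FlowConfig)
    cs_duration_s: float = 24_300.0  # 6 pore volumes at 0.018 uL/s ≈ 6.75 h
    # reproducibility
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitivity_grain", "sensitivity_bacteria", "sensitivity_crystal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        bad = [p for p in self.excluded_positions if not 1 <= p <= self.n_positions]
        if bad:
            raise ValueError(f"excluded positions out of range: {bad}")

    def position_x_um(self, position: int) -> float:
        """Field origin x (um) of a 1-based position, evenly spaced along L."""
        if not 1 <= position <= self.n_positions:
            raise ValueError(f"position must be in 1..{self.n_positions}")
        usable = self.length_um - self.field_x_um
        if self.n_positions == 1:
            return usable / 2.0
        return usable * (position - 1) / (self.n_positions - 1)

    def field_for_position(self, position: int) -> tuple[float, float, float, float]:
        x0 = self.position_x_um(position)
        y0 = (self.width_um - self.field_y_um) / 2.0
        if y0 < 0:
            raise ValueError("field_y_um exceeds channel width")
        return (x0, y0, self.field_x_um, self.field_y_um)

    def active_positions(self) -> list[int]:
        return [p for p in range(1, self.n_positions + 1) if p not in self.excluded_positions]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    flow = FlowConfig(**data.pop("flow", {}))
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("excluded_positions", "bacteria_area_px"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(flow=flow, **data)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    data["excluded_positions"] = list(config.excluded_positions)
    data["bacteria_area_px"] = list(config.bacteria_area_px)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
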