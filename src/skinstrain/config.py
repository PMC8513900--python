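"""Pipeline configuration: a small validated YAML-serializable record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob the pipeline honors, with its default.

    a0_cm2 : reference surface area at bloom for cumulative strains (cm^2).
    sigmoid_model : 'logistic' or 'gompertz' for area growth.
    deposition_model : 'exp_rise' or 'logistic' for mass-per-area kinetics.
    stiffness_window_frac : sliding-window length for the tensile maximum
        slope, as a fraction of the rising-branch samples.
    curvature_correction : correct punched-disc areas for fruit curvature.
    round_density / round_pct / round_strain : report rounding (decimals)
        for lenticel densities, percent strains, and cumulative strains.
    seed : seed for any stochastic step (none in the core pipeline; kept
        for provenance and for simulation runs).
    """

    a0_cm2: float = 1.0
    sigmoid_model: str = "logistic"
    deposition_model: str = "exp_rise"
    stiffness_window_frac: float = 0.1
    curvature_correction: bool = True
    round_density: int = 2
    round_pct: int = 1
    round_strain: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.a0_cm2 <= 0:
            raise ValueError("a0_cm2 must be > 0")
        if self.sigmoid_model not in ("logistic", "gompertz"):
            raise ValueError("sigmoid_model must be 'logistic' or 'gompertz'")
        if self.deposition_model not in ("exp_rise", "logistic"):
            raise ValueError("deposition_model must be 'exp_rise' or 'logistic'")
        if not 0.0 < self.stiffness_window_frac <= 0.5:
            raise ValueError("stiffness_window_frac must be in (0, 0.5]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
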