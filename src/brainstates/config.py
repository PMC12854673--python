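"""Analysis configuration: validated, serialisable, no hidden defaults.

Defaults mirror the standard analysis: K=6 states, D=10 latent
dimensions, 10 proximity bins per direction (20 categories), a 3-step
hemodynamic lag at a 1.25 s repetition time, 500 bootstrap samples in
steps of 100 with a 1e-5 centroid-stability tolerance, alpha 0.05 with
Bonferroni correction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["AnalysisConfig"]

_STAGES = ("simulate", "fit", "bootstrap", "assoc", "dynamics", "steering",
           "importance", "maps", "transfer")


@dataclass
class AnalysisConfig:
    K: int = 6
    D: int = 10
    n_bins: int = 10
    lag_steps: int = 3
    tr_s: float = 1.25
    alpha: float = 0.05
    correction: str = "bonferroni"
    seed: int = 0
    # bootstrap
    B: int = 500
    boot_step: int = 100
    boot_tol: float = 1e-5
    # fitting
    max_iter: int = 50
    n_restarts: int = 3
    fit_tol: float = 1e-6
    # synthetic study (used by the simulate stage)
    study: dict = field(default_factory=dict)
    # ingest paths: {"runs": [{"roi": ..., "paradigm": ...}, ...]} or {}
    paths: dict = field(default_factory=dict)
    # stages to run (subset of the canonical order)
    stages: list = field(default_factory=lambda: list(_STAGES))
    # transfer options
    n_null: int = 50
    top_transitions: int = 8

    def __post_init__(self) -> None:
        numeric = {"K": 1, "D": 1, "n_bins": 1, "lag_steps": 0, "B": 1,
                   "boot_step": 1, "max_iter": 1, "n_restarts": 1,
                   "n_null": 20, "top_transitions": 1}
        for name, lo in numeric.items():
            v = getattr(self, name)
            if not isinstance(v, int) or v < lo:
                raise ValueError(f"{name} must be an integer >= {lo}, got {v!r}")
        for name in ("tr_s", "alpha", "boot_tol", "fit_tol"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v <= 0:
                raise ValueError(f"{name} must be a positive number, got {v!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction '{self.correction}'")
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) \
                else json.load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            if str(path).endswith((".yml", ".yaml")):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
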