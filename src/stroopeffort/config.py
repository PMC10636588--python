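"""Run configuration: validated, defaulted, and losslessly round-trippable."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .stroop import CONDITIONS, StroopParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    """Configuration for the command-line pipeline.

    Defaults reproduce the baseline study conditions: action precision 1/4,
    64 presentations (instruction plus 63 stimuli), ``c = e = 0``.
    """

    c: float = 0.0
    e: float = 0.0
    lam: float = 0.25
    n_presentations: int = 64
    congruency: float = 0.5
    condition: str = "colour-naming"
    evidence_decay: float = 0.5
    planning_horizon: int = 3
    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1
    modality: str = "both"
    demand_grid: list[float] = field(
        default_factory=lambda: [round(0.05 * i, 2) for i in range(1, 20)])
    preference_grid: list[float] = field(
        default_factory=lambda: [round(0.25 * i, 2) for i in range(0, 13)])
    recovery_c: list[float] = field(
        default_factory=lambda: [-0.5, -0.25, 0.0, 0.25, 0.5])
    recovery_e: list[float] = field(
        default_factory=lambda: [-0.5, -0.25, 0.0, 0.25, 0.5])

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"config key 'condition' must be one of {CONDITIONS}")
        if self.modality not in {"both", "choice-only", "rt-only"}:
            raise ValueError("config key 'modality' is invalid")
        # delegate numeric validation
        self.stroop_params()

    def stroop_params(self) -> StroopParams:
        return StroopParams(
            c=self.c, e=self.e, lam=self.lam,
            n_presentations=self.n_presentations,
            congruency=self.congruency, condition=self.condition,
            evidence_decay=self.evidence_decay,
            planning_horizon=self.planning_horizon, seed=self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    payload = (yaml.safe_load(text) if path.suffix in {".yml", ".yaml"}
               else json.loads(text)) or {}
    if not isinstance(payload, dict):
        raise ValueError("config document must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**payload)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    payload = cfg.to_dict()
    if path.suffix in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the canonicalised config, for run manifests."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
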