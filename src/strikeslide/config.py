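"""Pipeline configuration: a flat YAML-backed mapping with validated keys.

Every threshold the analysis uses is an explicit configuration value with
its default drawn from the experimental protocol (sampling rate, onset and
contact criteria, R² and Bonferroni schemes); nothing is inferred at run
time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # experiment scale
    n_participants: int = 33
    trials_per_block: int = 10
    seed: int = 0

    # physical constants
    g: float = 9.81  # m/s^2, required to reproduce the optimal-speed table
    dt: float = 0.004  # s; 250 Hz motion capture

    # true surface friction coefficients (group-mean measured values)
    mu_aluminum: float = 0.37
    mu_balsa: float = 0.47
    cube_mass: float = 0.046  # kg

    # simulated participant
    subjective_mu0: float = 0.28
    learning_rate: float = 0.4
    motor_noise_sd: float = 0.05  # m/s
    marker_noise_sd: float = 0.0005  # m
    body_mass: float = 70.0  # kg
    forearm_length: float = 0.26  # m
    hand_length: float = 0.19  # m
    wrist_strategy_fraction: float = 14 / 33  # cohort share of wrist movers

    # detection thresholds
    onset_threshold: float = 0.04  # m/s, object movement onset
    stop_threshold: float = 0.04  # m/s, object stop (onset rule, reversed)
    contact_fraction: float = 0.4  # normalized-deceleration criterion

    # adaptation analysis
    r2_strong: float = 0.75
    r2_moderate: float = 0.50
    alpha_one_sample: float = 0.05 / 12
    alpha_paired: float = 0.05 / 4

    # paths
    session_dir: str = "session"
    results_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("n_participants", "trials_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("g", "dt", "mu_aluminum", "mu_balsa", "cube_mass",
                     "onset_threshold", "stop_threshold", "contact_fraction",
                     "r2_strong", "r2_moderate", "alpha_one_sample",
                     "alpha_paired"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 <= self.wrist_strategy_fraction <= 1:
            raise ValueError("wrist_strategy_fraction must be in [0, 1]")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a config from YAML, apply keyword overrides, validate keys.

    Unknown keys are reported exhaustively instead of being ignored.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config {path} must be a mapping")
            data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}; valid keys: {sorted(valid)}")
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
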