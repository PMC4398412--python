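"""Run configuration: a strict YAML schema shared by the CLI commands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import ModelParams


@dataclass
class RunConfig:
    """All knobs for a simulation / sweep / stripe run.

    Model parameters mirror :class:`creolang.model.ModelParams`; sweep
    settings control grids and replicate counts.  Unknown keys in a YAML
    file are rejected.
    """

    # model parameters
    gamma: float = 0.8
    delta: float = 0.1
    epsilon: float = 0.06
    n_total: int = 2000
    dominance_threshold: float = 0.8
    max_interactions_per_agent: int = 2000
    tail_window_fraction: float = 0.1
    creolize_only_on_change: bool = False
    epsilon_null_advances_time: bool = True
    weighting: str = "split"
    # sweep settings
    xs: list[float] = field(
        default_factory=lambda: [0.01, 0.05, 0.1, 0.2, 0.4, 0.7]
    )
    ys: list[float] = field(
        default_factory=lambda: [0.2, 0.4, 0.6, 0.8, 0.95]
    )
    replicates: int = 10
    y_tolerance: float = 0.02
    # bookkeeping
    seed: int = 0
    out_dir: str = "creolang-out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        try:
            self.model_params()  # delegate probability/range validation
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.n_total < 2:
            raise ConfigError("n_total must be at least 2")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    def model_params(self, **overrides) -> ModelParams:
        kw = dict(
            gamma=self.gamma,
            delta=self.delta,
            epsilon=self.epsilon,
            dominance_threshold=self.dominance_threshold,
            max_interactions_per_agent=self.max_interactions_per_agent,
            tail_window_fraction=self.tail_window_fraction,
            creolize_only_on_change=self.creolize_only_on_change,
            epsilon_null_advances_time=self.epsilon_null_advances_time,
            weighting=self.weighting,
            seed=self.seed,
        )
        kw.update(overrides)
        return ModelParams(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; unknown keys raise :class:`ConfigError`."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
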