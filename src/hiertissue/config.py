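"""Flat key-value run configuration (YAML) with strict schema validation."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    """Parameters shared by the CLI subcommands.

    All quantities use years as the time unit.  Scan subcommands read the
    list-valued fields; everything else reads the scalars.
    """

    N0: float = 1e4
    N: float = 1e15
    n: int | None = None
    gamma: float | None = None
    s: float = 0.1
    mu: float = 2.5e-6
    t_life: float = 80.0
    threshold: float = 0.02
    asym_fraction: float = 0.0
    stem_asym_fraction: float | None = None
    cell_number_rule: str = "geometric"
    mode: str = "proliferative"
    seed: int = 0
    replicates: int = 10_000
    grid_m: int = 2000
    s_values: list | None = None
    mu_values: list | None = None
    ratio_values: list | None = None

    _FLOAT_FIELDS = ("N0", "N", "gamma", "s", "mu", "t_life", "threshold",
                     "asym_fraction", "stem_asym_fraction")
    _INT_FIELDS = ("n", "seed", "replicates", "grid_m")
    _LIST_FIELDS = ("s_values", "mu_values", "ratio_values")

    def __post_init__(self) -> None:
        # YAML 1.1 reads exponent literals without a sign (1.0e6) as strings;
        # coerce every numeric field so flat configs stay forgiving
        try:
            for name in self._FLOAT_FIELDS:
                v = getattr(self, name)
                if v is not None:
                    setattr(self, name, float(v))
            for name in self._INT_FIELDS:
                v = getattr(self, name)
                if v is not None:
                    setattr(self, name, int(v))
            for name in self._LIST_FIELDS:
                v = getattr(self, name)
                if v is not None:
                    setattr(self, name, [float(x) for x in v])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"non-numeric value: {exc}") from exc
        if self.N < self.N0 or self.N0 < 1:
            raise ConfigError("require N >= N0 >= 1")
        if self.t_life <= 0:
            raise ConfigError("t_life must be positive")
        if not 0 < self.threshold < 1:
            raise ConfigError("threshold must lie in (0, 1)")
        if self.mode not in ("proliferative", "neutral_until_critical"):
            raise ConfigError(f"unknown driver mode {self.mode!r}")
        if self.grid_m < 10:
            raise ConfigError("grid_m too small")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a flat YAML mapping into a :class:`RunConfig`; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key-value mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # wrong value types
        raise ConfigError(str(exc)) from exc
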