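"""Run and mechanism configuration: YAML-backed, validated, lossless
round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from . import presets
from .dgm import DGMParams

MODES = ("simulate", "calibrate", "analyze", "summarize")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class RunConfig:
    """Configuration for a simulation run.

    ``dgms``/``sample_sizes``/``methods``/``libraries``/``folds`` select
    the grid; every stochastic path derives its stream from
    ``base_seed``.
    """

    mode: str = "simulate"
    dgms: list[str] = field(default_factory=lambda: ["simple-1"])
    sample_sizes: list[int] = field(default_factory=lambda: [200])
    methods: list[str] = field(default_factory=lambda: ["tmle"])
    libraries: list[str] = field(default_factory=lambda: ["glm-lasso"])
    folds: list = field(default_factory=lambda: ["none"])
    n_reps: int = 200
    base_seed: int = 1
    output_dir: str = "results"
    workers: int = 1
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode: '{self.mode}' not in {MODES}")
        for d in self.dgms:
            if d not in presets.DGM_NAMES:
                raise ConfigError(f"dgms: unknown mechanism '{d}'")
        for n in self.sample_sizes:
            if not (isinstance(n, int) and n >= 20):
                raise ConfigError(f"sample_sizes: invalid entry {n!r}")
        for m in self.methods:
            if m not in ("aipw", "tmle"):
                raise ConfigError(f"methods: unknown method '{m}'")
        for f in self.folds:
            if not (f == "none" or (isinstance(f, int) and f >= 2)):
                raise ConfigError(f"folds: invalid entry {f!r} (use 'none' or int >= 2)")
        if not (isinstance(self.n_reps, int) and self.n_reps >= 1):
            raise ConfigError(f"n_reps: invalid value {self.n_reps!r}")
        if not isinstance(self.base_seed, int):
            raise ConfigError(f"base_seed: invalid value {self.base_seed!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def load_dgm_config(path) -> tuple[DGMParams, int, int]:
    """Load a mechanism specification file: YAML with schema
    ``{dgm_name, n, seed, overrides}``.

    ``overrides`` maps :class:`~causalcf.dgm.DGMParams` field names to
    replacement values (lists are coerced to tuples), applied on top of
    the shipped default mechanism.  Returns ``(params, n, seed)``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"dgm_name", "n", "seed", "overrides"}
    if unknown:
        raise ConfigError(f"unknown mechanism-config fields: {sorted(unknown)}")
    if "dgm_name" not in raw:
        raise ConfigError("dgm_name: required")
    name = raw["dgm_name"]
    if name not in presets.DGM_NAMES:
        raise ConfigError(f"dgm_name: unknown mechanism '{name}'")
    n = raw.get("n", 500)
    seed = raw.get("seed", 1)
    params = presets.default_params(name)
    overrides = raw.get("overrides") or {}
    valid = {f.name for f in dataclasses.fields(DGMParams)}
    for key, value in overrides.items():
        if key not in valid:
            raise ConfigError(f"overrides.{key}: not a mechanism parameter")
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        params = dataclasses.replace(params, **{key: value})
    return params, int(n), int(seed)
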