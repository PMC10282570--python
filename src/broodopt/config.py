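"""Run configuration: YAML schema, validation, and CLI-flag overrides.

Defaults are the package's baseline illustration parameters (r0 = 0.5,
muJ = 0.2, L0 = 0.01, muA0 = 0.07); an empty config reproduces them.
Unknown keys are rejected and every violation names the offending key.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .casestudy import TwoStateEnvironment
from .environment import ResourceModel
from .params import LifeHistory


@dataclass
class RunConfig:
    # life history
    r0: float = 0.5
    muJ: float = 0.2
    L0: float = 0.01
    muA0: float = 0.07
    alpha: float = 0.0
    # environment
    cv: float = 1.0
    mean_r: float | None = None  # defaults to r0
    # two-state masting world
    pmast: float = 0.25
    rgood: float = 0.2
    rbad: float = 0.05
    alpha_good: float = 0.0
    alpha_bad: float = 0.5
    # simulation control
    years: int = 200
    replicates: int = 100
    n_individuals: int = 100
    mean_brood: float = 2.0
    seed: int = 0
    outdir: str = "broodopt_out"

    _CONSTRAINTS = {
        "r0": ("> 0", lambda v: v > 0),
        "muJ": (">= 0", lambda v: v >= 0),
        "L0": ("in (0, 1)", lambda v: 0 < v < 1),
        "muA0": ("in [0, 1)", lambda v: 0 <= v < 1),
        "alpha": (">= 0", lambda v: v >= 0),
        "cv": (">= 0", lambda v: v >= 0),
        "mean_r": ("> 0 or null", lambda v: v is None or v > 0),
        "pmast": ("in [0, 1]", lambda v: 0 <= v <= 1),
        "rgood": ("> 0", lambda v: v > 0),
        "rbad": ("> 0", lambda v: v > 0),
        "alpha_good": (">= 0", lambda v: v >= 0),
        "alpha_bad": (">= 0", lambda v: v >= 0),
        "years": ("positive integer", lambda v: isinstance(v, int) and v > 0),
        "replicates": ("positive integer", lambda v: isinstance(v, int) and v > 0),
        "n_individuals": ("positive integer", lambda v: isinstance(v, int) and v > 0),
        "mean_brood": (">= 0", lambda v: v >= 0),
        "seed": ("integer", lambda v: isinstance(v, int)),
        "outdir": ("string", lambda v: isinstance(v, str)),
    }

    def validate(self) -> "RunConfig":
        for name, (desc, check) in self._CONSTRAINTS.items():
            value = getattr(self, name)
            if not check(value):
                raise ValueError(f"config key '{name}' must be {desc}, "
                                 f"got {value!r}")
        return self

    # -- conversions -------------------------------------------------------
    def life_history(self) -> LifeHistory:
        return LifeHistory.from_values(r0=self.r0, muJ=self.muJ, L0=self.L0,
                                       muA0=self.muA0, alpha=self.alpha)

    def resource_model(self) -> ResourceModel:
        return ResourceModel(self.mean_r if self.mean_r is not None else self.r0,
                             self.cv)

    def two_state_environment(self) -> TwoStateEnvironment:
        return TwoStateEnvironment(p_good=self.pmast, r_good=self.rgood,
                                   r_bad=self.rbad, alpha_good=self.alpha_good,
                                   alpha_bad=self.alpha_bad)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def parse_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config (optional) and apply flag overrides on top.

    Flags win over file values; unknown keys in either source are rejected
    with a message naming the key.
    """
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        for key in loaded:
            if key not in known:
                raise ValueError(f"unknown config key '{key}'")
        values.update(loaded)
    for key, value in overrides.items():
        if key not in known:
            raise ValueError(f"unknown config key '{key}'")
        if value is not None:
            values[key] = value
    return RunConfig(**values).validate()
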