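"""Run configuration: defaults, validation, JSON/YAML round trip."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .diagnostics import DEFAULT_ACF_LAG
from . import model_izhikevich, model_levy_sv

__all__ = ["RunConfig", "parse_config", "MODEL_DEFAULTS"]

#: per-model study defaults: priors, initialization, sampler sizes
MODEL_DEFAULTS: dict[str, dict] = {
    "izhikevich": {
        "n_data": 500,
        "M": 50,
        "R": 64,
        "T_max": 1.163,
        "K": 10_000,
        "K_burn": 10_000,
        "theta0": list(model_izhikevich.INITIAL_PARAMS),
        "prior_bounds": {"a": [0.01, 0.04], "b": [0.1, 0.3],
                         "c": [-70.0, -55.0], "d": [4.0, 8.0]},
    },
    "levy_sv": {
        "n_data": 400,
        "M": 200,
        "R": 64,
        "T_max": 1.163,
        "K": 10_000,
        "K_burn": 10_000,
        "theta0": list(model_levy_sv.INITIAL_PARAMS),
        "prior_bounds": {"kappa": [0.01, 0.99], "delta": [0.1, 20.0],
                         "gamma": [0.1, 20.0], "lam": [0.01, 2.0]},
    },
}

_KNOWN_KEYS = {
    "model", "data", "n_data", "prior_bounds", "step_sizes", "step_fraction",
    "M", "R", "T_max", "K", "K_burn", "theta0", "seed", "outdir",
    "bin_widths", "acf_lag", "resampling_scheme",
}


@dataclass
class RunConfig:
    """Validated experiment configuration with model defaults filled in."""

    model: str
    seed: int
    data: str | None = None          # observations CSV; None -> generate
    n_data: int = 0
    prior_bounds: dict = field(default_factory=dict)
    step_sizes: dict | None = None   # None -> step_fraction of box width
    step_fraction: float = 0.02
    M: int = 0
    R: int = 0
    T_max: float = 0.0
    K: int = 0
    K_burn: int = 0
    theta0: list = field(default_factory=list)
    outdir: str = "runs/out"
    bin_widths: dict = field(default_factory=dict)
    acf_lag: int = DEFAULT_ACF_LAG
    resampling_scheme: str = "multinomial"

    def __post_init__(self) -> None:
        if self.model not in MODEL_DEFAULTS:
            raise ValueError(f"unknown model {self.model!r}; "
                             f"choose from {sorted(MODEL_DEFAULTS)}")
        defaults = MODEL_DEFAULTS[self.model]
        for key in ("n_data", "M", "R", "K", "K_burn", "T_max"):
            if not getattr(self, key):
                setattr(self, key, defaults[key])
        if not self.prior_bounds:
            self.prior_bounds = {k: list(v)
                                 for k, v in defaults["prior_bounds"].items()}
        if not self.theta0:
            self.theta0 = list(defaults["theta0"])
        for key in ("n_data", "M", "R", "K"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be >= 1, got {getattr(self, key)}")
        if self.K_burn < 0:
            raise ValueError(f"K_burn must be >= 0, got {self.K_burn}")
        if self.seed < 0:
            raise ValueError(f"seed must be a nonnegative integer, got {self.seed}")
        if self.T_max < 1.0:
            raise ValueError(f"T_max must be >= 1, got {self.T_max}")
        if self.acf_lag < 1:
            raise ValueError(f"acf_lag must be >= 1, got {self.acf_lag}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def parse_config(path: str | Path | None = None, **flags) -> RunConfig:
    """Build a RunConfig from a JSON/YAML file and/or keyword flags.

    Unknown keys are an error (listed by name); flags override file entries.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in flags.items() if v is not None})
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "model" not in raw or "seed" not in raw:
        raise ValueError("config requires at least 'model' and 'seed'")
    return RunConfig(**raw)
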