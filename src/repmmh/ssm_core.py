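"""Shared state-space-model machinery.

A state-space model couples a latent Markov process ``z_n ~ f(z_n | z_{n-1}, theta_f)``
with an observation process ``y_n ~ g(y_n | z_n, theta_g)``.  Only ``y_1:N`` is observed;
the goal of the samplers in this package is the marginal posterior ``p(Theta | y_1:N)``
with the latent path integrated out.

This module provides the containers every sampler shares: the observation series, named
parameter vectors with per-component proposal transforms, uniform box priors, and the
abstract contract a concrete model must implement for the bootstrap particle filter.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "ParameterVector",
    "PriorSpec",
    "ModelContract",
    "log_prior",
    "to_unconstrained",
    "from_unconstrained",
    "log_transform_jacobian",
]

_TRANSFORMS = ("identity", "log", "logit")


class ConfigurationError(ValueError):
    """Inconsistent run configuration (name mismatches, invalid bounds, ...)."""


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeries:
    """Scalar observations ``y_1..N`` plus an optional exogenous input per step.

    Time steps are 1-based (``n = 1..N``) in every log and report; internal arrays are
    0-based, so ``observations[n-1]`` is ``y_n``.
    """

    observations: np.ndarray
    exogenous_input: np.ndarray | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=float)
        object.__setattr__(self, "observations", obs)
        if obs.ndim != 1 or obs.size < 1:
            raise ValueError("observations must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(obs)):
            raise ValueError("observations must be finite")
        if self.exogenous_input is not None:
            exog = np.asarray(self.exogenous_input, dtype=float)
            object.__setattr__(self, "exogenous_input", exog)
            if exog.shape != obs.shape:
                raise ValueError(
                    f"exogenous_input length {exog.size} != observations length {obs.size}"
                )
            if not np.all(np.isfinite(exog)):
                raise ValueError("exogenous_input must be finite")

    @property
    def n_steps(self) -> int:
        return int(self.observations.size)

    def exog_at(self, n: int) -> float:
        """Exogenous input at 1-based step ``n`` (0.0 when absent)."""
        if self.exogenous_input is None:
            return 0.0
        return float(self.exogenous_input[n - 1])

    # -- CSV round trip (`n,y[,i_ext]`) -------------------------------------

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"n": np.arange(1, self.n_steps + 1), "y": self.observations})
        if self.exogenous_input is not None:
            df["i_ext"] = self.exogenous_input
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeSeries":
        df = pd.read_csv(path)
        if "y" not in df.columns:
            raise ValueError(f"{path}: expected a 'y' column, got {list(df.columns)}")
        if df["y"].isna().any():
            raise ValueError(f"{path}: missing values in 'y'")
        exog = df["i_ext"].to_numpy(float) if "i_ext" in df.columns else None
        return cls(df["y"].to_numpy(float), exog)


# ---------------------------------------------------------------------------
# parameters and transforms
# ---------------------------------------------------------------------------


def to_unconstrained(value: float, transform: str) -> float:
    """Map a parameter value to the unbounded proposal coordinate."""
    if transform == "identity":
        return value
    if transform == "log":
        return np.log(value)
    if transform == "logit":
        return np.log(value) - np.log1p(-value)
    raise ValueError(f"unknown transform {transform!r}")


def from_unconstrained(phi: float, transform: str) -> float:
    if transform == "identity":
        return phi
    if transform == "log":
        return np.exp(phi)
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-phi))
    raise ValueError(f"unknown transform {transform!r}")


def log_transform_jacobian(value: float, transform: str) -> float:
    """``log |d theta / d phi|`` evaluated at ``theta = value``.

    Random-walk proposals are symmetric in the unconstrained coordinate ``phi``; the
    acceptance ratio on the original scale then needs the change-of-variables factor
    ``J(theta*) / J(theta)`` with ``J = d theta / d phi``.
    """
    if transform == "identity":
        return 0.0
    if transform == "log":
        return np.log(value)
    if transform == "logit":
        return np.log(value) + np.log1p(-value)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class ParameterVector:
    """Named real parameters ``Theta = (theta_f, theta_g)`` with proposal transforms.

    ``roles`` tags each component as belonging to the system model (``"system"``) or the
    observation model (``"observation"``); samplers treat Theta as one block, the split is
    informational.  ``transforms`` selects the unconstrained proposal coordinate per
    component: ``identity``, ``log`` (positive-only) or ``logit`` (unit interval).
    """

    names: tuple[str, ...]
    values: np.ndarray
    transforms: tuple[str, ...] = ()
    roles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "names", tuple(self.names))
        if vals.ndim != 1 or len(self.names) != vals.size:
            raise ValueError("names and values must have matching 1-D shapes")
        transforms = tuple(self.transforms) or ("identity",) * vals.size
        roles = tuple(self.roles) or ("system",) * vals.size
        object.__setattr__(self, "transforms", transforms)
        object.__setattr__(self, "roles", roles)
        if len(transforms) != vals.size or len(roles) != vals.size:
            raise ValueError("transforms/roles length must match values")
        for t in transforms:
            if t not in _TRANSFORMS:
                raise ValueError(f"unknown transform {t!r}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("parameter values must be finite")
        for v, t, name in zip(vals, transforms, self.names):
            if t == "log" and v <= 0:
                raise ValueError(f"log-transformed parameter {name} must be > 0, got {v}")
            if t == "logit" and not (0.0 < v < 1.0):
                raise ValueError(f"logit-transformed parameter {name} must be in (0,1), got {v}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_unconstrained(self) -> np.ndarray:
        return np.array(
            [to_unconstrained(v, t) for v, t in zip(self.values, self.transforms)]
        )

    def from_unconstrained(self, phi: np.ndarray) -> "ParameterVector":
        vals = np.array(
            [from_unconstrained(p, t) for p, t in zip(phi, self.transforms)]
        )
        return self.with_values(vals)

    def log_jacobian(self) -> float:
        """Sum of ``log |d theta_i / d phi_i|`` over components."""
        return float(
            sum(log_transform_jacobian(v, t) for v, t in zip(self.values, self.transforms))
        )


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform box prior: per-parameter finite ``(lower, upper)`` bounds.

    The support is the open box; boundary points are out of support (this keeps log/logit
    proposal transforms away from their singularities).
    """

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        bounds = {k: (float(lo), float(hi)) for k, (lo, hi) in self.bounds.items()}
        object.__setattr__(self, "bounds", bounds)
        for name, (lo, hi) in bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"prior bounds for {name} must be finite")
            if not lo < hi:
                raise ValueError(f"prior for {name} has empty support [{lo}, {hi}]")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def width(self, name: str) -> float:
        lo, hi = self.bounds[name]
        return hi - lo


def log_prior(theta: ParameterVector, prior: PriorSpec) -> float:
    """Log density of the uniform box prior at ``theta``.

    Returns ``-sum log(upper - lower)`` inside the open box, ``-inf`` if any component
    lies on or outside its bounds.
    """
    if set(theta.names) != set(prior.names):
        raise ConfigurationError(
            f"parameter names {sorted(theta.names)} != prior names {sorted(prior.names)}"
        )
    total = 0.0
    for name, value in zip(theta.names, theta.values):
        lo, hi = prior.bounds[name]
        if not (lo < value < hi):
            return -np.inf
        total -= np.log(hi - lo)
    return total


# ---------------------------------------------------------------------------
# model contract
# ---------------------------------------------------------------------------


class ModelContract(abc.ABC):
    """Operations a state-space model must provide to the particle filter.

    States are stored as an ``(M, state_dim)`` float array.  Concrete models may
    additionally expose ``fast_loglik(values, data, M, seed) -> float`` — a fused,
    compiled implementation of the whole bootstrap filter — which the
    :func:`repmmh.smc.marginal_log_likelihood` dispatcher will prefer.
    """

    #: ordered parameter names of Theta
    param_names: tuple[str, ...]
    #: per-parameter proposal transform flags
    param_transforms: tuple[str, ...]
    #: per-parameter role: "system" (theta_f) or "observation" (theta_g)
    param_roles: tuple[str, ...]

    @abc.abstractmethod
    def sample_initial_states(self, M: int, rng: np.random.Generator,
                              theta: ParameterVector) -> np.ndarray:
        """Draw ``M`` latent states from ``p(z_1)``; shape ``(M, state_dim)``."""

    @abc.abstractmethod
    def propagate_states(self, states: np.ndarray, n: int, theta: ParameterVector,
                         rng: np.random.Generator, exog: float = 0.0) -> np.ndarray:
        """One system-model transition ``z_{n-1} -> z_n`` for every particle.

        ``n`` is the 1-based index of the step being entered; ``exog`` is the exogenous
        input driving that step.  Must preserve the ensemble size.
        """

    @abc.abstractmethod
    def log_observation_density(self, y_n: float, states: np.ndarray,
                                theta: ParameterVector) -> np.ndarray:
        """``log g(y_n | z_n^m, theta_g)`` per particle; finite or ``-inf``."""

    def make_theta(self, values: Sequence[float]) -> ParameterVector:
        return ParameterVector(self.param_names, np.asarray(values, float),
                               self.param_transforms, self.param_roles)
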