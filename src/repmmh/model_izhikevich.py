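"""Stochastic Izhikevich neuron as a state-space model.

Latent state z = (v, u): membrane potential and membrane recovery variable, with
quadratic voltage dynamics

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_ext + xi_v,
    du/dt = a (b v - u) + xi_u,

and the spike/reset rule: if v exceeds the threshold v_th = 30, then v <- c and
u <- u + d.  Discretization is Euler-Maruyama with dt = 1 (the standard Izhikevich
integration step); the per-step Gaussian system noises have standard deviations
sigma_v, sigma_u.  Observations are the membrane potential corrupted by N(0, sigma_y^2)
noise.  Only Theta = (a, b, c, d) is estimated; the noise scales, threshold and dt stay
fixed at the study values (sigma_v^2 = 0.25, sigma_u^2 = 1e-4, sigma_y^2 = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _izh_kernels
from .ssm_core import ModelContract, ParameterVector, TimeSeries

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "InputProtocol",
    "IzhikevichModel",
    "euler_step",
    "simulate_dataset",
    "default_protocol",
    "TRUE_PARAMS",
    "INITIAL_PARAMS",
]

#: generating parameters (a, b, c, d) of the study data
TRUE_PARAMS = (0.02, 0.2, -65.0, 6.0)
#: distant sampler initialization used throughout the experiments
INITIAL_PARAMS = (0.025, 0.15, -60.0, 5.5)


@dataclass(frozen=True)
class IzhikevichParams:
    """Model constants: estimated (a, b, c, d) plus fixed noise/integration settings."""

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 6.0
    sigma_v: float = 0.5     # per-step system noise std of v  (variance 0.25)
    sigma_u: float = 0.01    # per-step system noise std of u  (variance 1e-4)
    sigma_y: float = 1.0     # observation noise std
    v_th: float = 30.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_v < 0 or self.sigma_u < 0 or self.sigma_y < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class NeuronState:
    v: float
    u: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.v) and np.isfinite(self.u)):
            raise ValueError("neuron state must be finite")


@dataclass(frozen=True)
class InputProtocol:
    """Piecewise-constant external current: baseline plus (start, end, amplitude) pulses.

    Pulse bounds are 1-based inclusive step indices.
    """

    baseline: float = 0.0
    pulses: tuple[tuple[int, int, float], ...] = ()

    def current(self, N: int) -> np.ndarray:
        i_ext = np.full(N, self.baseline)
        for start, end, amp in self.pulses:
            if start < 1 or end > N or start > end:
                raise ValueError(f"pulse ({start},{end}) does not fit in 1..{N}")
            i_ext[start - 1:end] = amp
        return i_ext

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"baseline": self.baseline, "pulses": list(map(list, self.pulses))},
            indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "InputProtocol":
        obj = json.loads(Path(path).read_text())
        return cls(obj["baseline"], tuple(tuple(p) for p in obj["pulses"]))


def default_protocol(N: int = 500, amplitude: float = 10.0) -> InputProtocol:
    """Three current pulses covering ~60% of the record (the study's input drive).

    The pulse blocks sit at 10-30%, 40-60% and 70-90% of the record, eliciting several
    spike trains with varied inter-spike intervals.
    """
    f = lambda x: max(1, int(round(x * N)))
    pulses = ((f(0.10), f(0.30), amplitude),
              (f(0.40), f(0.60), amplitude),
              (f(0.70), f(0.90), amplitude))
    return InputProtocol(0.0, pulses)


def euler_step(state: NeuronState, i_ext: float, params: IzhikevichParams,
               rng: np.random.Generator | None = None) -> NeuronState:
    """One Euler-Maruyama transition with the post-update reset rule.

    Noise is added to both components before the threshold check; if the updated v
    exceeds v_th the reset (v <- c, u <- u + d) fires once.  |v| is clipped at 1e6 as
    an overflow guard.
    """
    p = params
    v, u = _izh_kernels.euler_update(state.v, state.u, i_ext, p.a, p.b, p.dt)
    if rng is not None:
        v += p.sigma_v * rng.standard_normal()
        u += p.sigma_u * rng.standard_normal()
    if v > p.v_th:
        v = p.c
        u = u + p.d
    if abs(v) > 1e6:
        import warnings

        warnings.warn("membrane potential clipped at |v| = 1e6")
        v = float(np.clip(v, -1e6, 1e6))
    return NeuronState(float(v), float(u))


class IzhikevichModel(ModelContract):
    """ModelContract implementation with a fused numba filter fast path.

    ``rest_state`` and ``rest_spread`` define p(z_1): particles start from a Gaussian
    around a configured resting point, identical for data generation and inference.
    """

    param_names = ("a", "b", "c", "d")
    param_transforms = ("identity",) * 4
    param_roles = ("system",) * 4

    def __init__(self, fixed: IzhikevichParams = IzhikevichParams(),
                 rest_state: tuple[float, float] = (-65.0, -13.0),
                 rest_spread: tuple[float, float] = (1.0, 0.2),
                 use_fast_filter: bool = True):
        self.fixed = fixed
        self.rest_state = rest_state
        self.rest_spread = rest_spread
        if not use_fast_filter:
            self.fast_loglik = None  # type: ignore[assignment]

    def _params(self, theta: ParameterVector) -> IzhikevichParams:
        from dataclasses import replace

        return replace(self.fixed, a=theta["a"], b=theta["b"], c=theta["c"],
                       d=theta["d"])

    # -- contract ops -------------------------------------------------------

    def sample_initial_states(self, M, rng, theta):
        v = self.rest_state[0] + self.rest_spread[0] * rng.standard_normal(M)
        u = self.rest_state[1] + self.rest_spread[1] * rng.standard_normal(M)
        return np.column_stack([v, u])

    def propagate_states(self, states, n, theta, rng, exog=0.0):
        p = self._params(theta)
        v, u = states[:, 0], states[:, 1]
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + exog
        du = p.a * (p.b * v - u)
        v_new = v + p.dt * dv + p.sigma_v * rng.standard_normal(v.size)
        u_new = u + p.dt * du + p.sigma_u * rng.standard_normal(u.size)
        fired = v_new > p.v_th
        v_new[fired] = p.c
        u_new[fired] += p.d
        np.clip(v_new, -1e6, 1e6, out=v_new)
        return np.column_stack([v_new, u_new])

    def log_observation_density(self, y_n, states, theta):
        sy = self.fixed.sigma_y
        r = (y_n - states[:, 0]) / sy
        return -0.5 * r * r - np.log(sy) - 0.5 * _izh_kernels.LOG_2PI

    # -- fused fast path ----------------------------------------------------

    def fast_loglik(self, values: np.ndarray, data: TimeSeries, M: int,
                    seed: int, scheme: str = "multinomial") -> float:
        p = self.fixed
        i_ext = (data.exogenous_input if data.exogenous_input is not None
                 else np.zeros(data.n_steps))
        return float(_izh_kernels.filter_loglik(
            float(values[0]), float(values[1]), float(values[2]), float(values[3]),
            p.sigma_v, p.sigma_u, p.sigma_y, p.v_th, p.dt,
            self.rest_state[0], self.rest_state[1],
            self.rest_spread[0], self.rest_spread[1],
            np.ascontiguousarray(data.observations, float),
            np.ascontiguousarray(i_ext, float), M, seed,
            scheme == "systematic"))


def simulate_dataset(params: IzhikevichParams, protocol: InputProtocol, N: int,
                     rng: np.random.Generator,
                     rest_state: tuple[float, float] = (-65.0, -13.0),
                     rest_spread: tuple[float, float] = (1.0, 0.2),
                     ) -> tuple[np.ndarray, TimeSeries]:
    """Generate a latent (v, u) path of length N and its noisy observations.

    The initial state is drawn from the same p(z_1) the filter uses; the return is
    ``(latent, ts)`` with ``latent`` of shape (N, 2) and ``ts`` carrying the external
    current so inference always sees the input that generated the data.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    i_ext = protocol.current(N)
    seed = int(rng.integers(0, 2**31 - 1))
    v, u, y = _izh_kernels.simulate_path(
        params.a, params.b, params.c, params.d,
        params.sigma_v, params.sigma_u, params.sigma_y, params.v_th, params.dt,
        rest_state[0], rest_state[1], rest_spread[0], rest_spread[1],
        np.ascontiguousarray(i_ext, float), N, seed)
    return np.column_stack([v, u]), TimeSeries(y, i_ext)


def count_spikes(latent: np.ndarray, params: IzhikevichParams) -> int:
    """Number of reset events in a simulated path (v jumps back to c)."""
    v = latent[:, 0]
    return int(np.sum((v[1:] == params.c) & (v[:-1] != params.c)))
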