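"""Shared fixtures: tiny oracle models with tractable posteriors.

Three toy state-space models support independent verification of the samplers:

* ``LinearGaussianModel`` — scalar AR(1) plus observation noise; the exact marginal
  likelihood comes from a hand-rolled Kalman filter (in the tests), giving an oracle
  for the particle filter's estimate.
* ``ConjugateToyModel`` — latent-free Gaussian location model; with one particle the
  "estimated" likelihood is exact, so PMMH reduces to plain MH whose stationary
  distribution is known in closed form (flat prior => N(ybar, s^2/N)).
* ``GridToyModel`` — one parameter on (0, n_cells) with a piecewise-constant
  log-likelihood table; every tempered stationary distribution is enumerable by
  normalizing exp(table / T) over cells.
"""

from __future__ import annotations

import numpy as np
import pytest

from repmmh.ssm_core import ModelContract, TimeSeries


class LinearGaussianModel(ModelContract):
    """z_n = phi z_{n-1} + N(0, q^2),  y_n = z_n + N(0, r^2),  z_1 ~ stationary."""

    param_names = ("phi", "q", "r")
    param_transforms = ("identity", "log", "log")
    param_roles = ("system", "system", "observation")

    def sample_initial_states(self, M, rng, theta):
        sd = theta["q"] / np.sqrt(1.0 - theta["phi"] ** 2)
        return (sd * rng.standard_normal(M))[:, None]

    def propagate_states(self, states, n, theta, rng, exog=0.0):
        z = theta["phi"] * states[:, 0] + theta["q"] * rng.standard_normal(states.shape[0])
        return z[:, None]

    def log_observation_density(self, y_n, states, theta):
        r = theta["r"]
        resid = (y_n - states[:, 0]) / r
        return -0.5 * resid**2 - np.log(r) - 0.5 * np.log(2 * np.pi)

    def simulate(self, theta, N, rng):
        z = np.empty(N)
        z[0] = self.sample_initial_states(1, rng, theta)[0, 0]
        for n in range(1, N):
            z[n] = self.propagate_states(z[None, n - 1 : n], n, theta, rng)[0, 0]
        y = z + theta["r"] * rng.standard_normal(N)
        return z, TimeSeries(y)


def kalman_log_likelihood(y: np.ndarray, phi: float, q: float, r: float) -> float:
    """Exact log p(y_1:N) for the scalar linear-Gaussian model (oracle)."""
    mean, var = 0.0, q**2 / (1.0 - phi**2)
    ll = 0.0
    for obs in y:
        s = var + r**2
        ll += -0.5 * (np.log(2 * np.pi * s) + (obs - mean) ** 2 / s)
        gain = var / s
        mean = mean + gain * (obs - mean)
        var = (1.0 - gain) * var
        mean, var = phi * mean, phi**2 * var + q**2
    return ll


class ConjugateToyModel(ModelContract):
    """Latent-free location model: y_n ~ N(mu, s^2); the filter estimate is exact."""

    param_names = ("mu",)
    param_transforms = ("identity",)
    param_roles = ("observation",)

    def __init__(self, s: float = 1.0):
        self.s = s

    def sample_initial_states(self, M, rng, theta):
        return np.zeros((M, 1))

    def propagate_states(self, states, n, theta, rng, exog=0.0):
        return states

    def log_observation_density(self, y_n, states, theta):
        resid = (y_n - theta["mu"]) / self.s
        return np.full(states.shape[0],
                       -0.5 * resid**2 - np.log(self.s) - 0.5 * np.log(2 * np.pi))


class GridToyModel(ModelContract):
    """One parameter on (0, n_cells); log-likelihood is a per-cell table lookup."""

    param_names = ("theta",)
    param_transforms = ("identity",)
    param_roles = ("observation",)

    def __init__(self, log_table: np.ndarray):
        self.log_table = np.asarray(log_table, float)

    @property
    def n_cells(self) -> int:
        return self.log_table.size

    def cell(self, value: float) -> int:
        return int(np.clip(np.floor(value), 0, self.n_cells - 1))

    def sample_initial_states(self, M, rng, theta):
        return np.zeros((M, 1))

    def propagate_states(self, states, n, theta, rng, exog=0.0):
        return states

    def log_observation_density(self, y_n, states, theta):
        return np.full(states.shape[0], self.log_table[self.cell(theta["theta"])])

    def tempered_cell_probabilities(self, T: float) -> np.ndarray:
        """Brute-force enumeration of the tempered stationary distribution."""
        w = np.exp((self.log_table - self.log_table.max()) / T)
        return w / w.sum()


@pytest.fixture(scope="session")
def grid_model() -> GridToyModel:
    return GridToyModel(np.array([0.0, 2.0, -1.0, 1.0, 0.5]))


@pytest.fixture(scope="session")
def single_obs() -> TimeSeries:
    # the observation value is irrelevant for the grid toy (table lookup)
    return TimeSeries(np.array([0.0]))


@pytest.fixture(scope="session")
def izhikevich_quiet_data():
    """Short spike-free neuron dataset (no input current -> resting dynamics)."""
    from repmmh import model_izhikevich as mi

    params = mi.IzhikevichParams(*mi.TRUE_PARAMS)
    protocol = mi.InputProtocol(0.0, ())
    latent, ts = mi.simulate_dataset(params, protocol, 150, np.random.default_rng(42))
    return params, latent, ts


@pytest.fixture(scope="session")
def izhikevich_study_data():
    """The N=500 step-pulse study dataset (same generator path as the experiments)."""
    from repmmh.config import RunConfig
    from repmmh.experiments import build_model, make_dataset

    cfg = RunConfig(model="izhikevich", seed=1)
    return build_model(cfg), make_dataset(cfg), cfg
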