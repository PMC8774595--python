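"""Bootstrap particle filter and the marginal-likelihood estimate.

The filter approximates ``p(z_1:N | y_1:N, Theta)`` by ``M`` weighted particles and
returns the unbiased estimate of the marginal likelihood

    p(y_1:N | Theta)  ~=  prod_n  (1/M) sum_m w_n^m ,

computed in the log domain as a sum of per-step log mean weights (log-sum-exp), since a
product of N*M small densities underflows long before N = 500.  Resampling happens at
every time step, unconditionally; the default scheme is multinomial with systematic
available for variance reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssm_core import ModelContract, ParameterVector, TimeSeries

__all__ = [
    "ParticleEnsemble",
    "FilterResult",
    "compute_weights",
    "resample",
    "run_filter",
    "marginal_log_likelihood",
]


class FilterNumericalError(RuntimeError):
    """NaN density or similar numerical failure inside the filter."""


@dataclass
class ParticleEnsemble:
    """``M`` latent-state particles with log and normalized weights at one time step."""

    states: np.ndarray          # (M, state_dim)
    log_weights: np.ndarray     # (M,)
    normalized_weights: np.ndarray  # (M,), sums to 1 unless degenerate

    @property
    def M(self) -> int:
        return self.states.shape[0]

    @classmethod
    def uniform(cls, states: np.ndarray) -> "ParticleEnsemble":
        M = states.shape[0]
        return cls(states, np.zeros(M), np.full(M, 1.0 / M))

    @property
    def degenerate(self) -> bool:
        return bool(np.all(np.isneginf(self.log_weights)))


@dataclass
class FilterResult:
    """Outcome of one bootstrap-filter pass.

    ``log_marginal_likelihood`` is the log of the product-of-averages estimator; it
    equals the sum of ``per_step_log_mean_weight``.  ``degenerate_flag`` marks a run
    where every particle weight vanished at some step, in which case the estimate is
    ``-inf`` (the MH layer then simply rejects the candidate).
    """

    log_marginal_likelihood: float
    per_step_log_mean_weight: np.ndarray
    degenerate_flag: bool = False


def compute_weights(ensemble: ParticleEnsemble, y_n: float, theta: ParameterVector,
                    model: ModelContract, n: int = 0) -> ParticleEnsemble:
    """Weight the ensemble against observation ``y_n`` (log-domain normalization)."""
    logw = np.asarray(model.log_observation_density(y_n, ensemble.states, theta), float)
    if np.any(np.isnan(logw)) or np.any(np.isposinf(logw)):
        raise FilterNumericalError(f"non-finite observation density at step n={n}")
    wmax = logw.max()
    if np.isneginf(wmax):
        norm = np.full(ensemble.M, np.nan)
    else:
        w = np.exp(logw - wmax)
        norm = w / w.sum()
    return ParticleEnsemble(ensemble.states, logw, norm)


def resample(ensemble: ParticleEnsemble, rng: np.random.Generator,
             scheme: str = "multinomial") -> ParticleEnsemble:
    """Draw ``M`` particles with replacement proportional to the normalized weights.

    Output weights are reset to the uniform ``1/M``.
    """
    w = ensemble.normalized_weights
    if ensemble.degenerate or np.any(np.isnan(w)):
        raise FilterNumericalError("cannot resample a degenerate ensemble")
    M = ensemble.M
    if scheme == "multinomial":
        idx = np.searchsorted(np.cumsum(w), rng.random(M))
        idx = np.clip(idx, 0, M - 1)
    elif scheme == "systematic":
        positions = (rng.uniform() + np.arange(M)) / M
        idx = np.searchsorted(np.cumsum(w), positions)
        idx = np.clip(idx, 0, M - 1)
    else:
        raise ValueError(f"unknown resampling scheme {scheme!r}")
    return ParticleEnsemble.uniform(ensemble.states[idx])


def run_filter(model: ModelContract, theta: ParameterVector, data: TimeSeries,
               M: int, rng: np.random.Generator, scheme: str = "multinomial",
               retain_trajectories: bool = False) -> FilterResult:
    """One bootstrap-filter pass; returns the log marginal-likelihood estimate.

    Initialization from ``p(z_1)``, then for each step: propagate (n >= 2), weight,
    resample.  ``retain_trajectories`` additionally stores the resampled states per step
    on the result (``.trajectories``) for debugging.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    N = data.n_steps
    per_step = np.empty(N)
    trajectories: list[np.ndarray] = []

    states = np.asarray(model.sample_initial_states(M, rng, theta), float)
    ensemble = ParticleEnsemble.uniform(states)
    for n in range(1, N + 1):
        if n > 1:
            new_states = model.propagate_states(ensemble.states, n, theta, rng,
                                                exog=data.exog_at(n))
            if new_states.shape[0] != M:
                raise FilterNumericalError(f"propagation changed ensemble size at n={n}")
            ensemble = ParticleEnsemble.uniform(np.asarray(new_states, float))
        ensemble = compute_weights(ensemble, float(data.observations[n - 1]), theta,
                                   model, n=n)
        if ensemble.degenerate:
            per_step[n - 1:] = -np.inf
            result = FilterResult(-np.inf, per_step, degenerate_flag=True)
            if retain_trajectories:
                result.trajectories = trajectories  # type: ignore[attr-defined]
            return result
        # log of the mean unnormalized weight, (1/M) sum_m w_n^m, in log domain
        wmax = ensemble.log_weights.max()
        per_step[n - 1] = wmax + np.log(np.exp(ensemble.log_weights - wmax).sum() / M)
        ensemble = resample(ensemble, rng, scheme=scheme)
        if retain_trajectories:
            trajectories.append(ensemble.states.copy())

    result = FilterResult(float(np.sum(per_step)), per_step, degenerate_flag=False)
    if retain_trajectories:
        result.trajectories = trajectories  # type: ignore[attr-defined]
    return result


def marginal_log_likelihood(model: ModelContract, theta: ParameterVector,
                            data: TimeSeries, M: int, rng: np.random.Generator,
                            scheme: str = "multinomial") -> float:
    """Marginal-likelihood estimate for ``theta``, preferring a compiled fast path.

    Models may expose ``fast_loglik(values, data, M, seed, scheme)`` (a fused filter
    kernel); otherwise the generic :func:`run_filter` runs.  Both implement the same
    algorithm; their RNG streams differ, which is immaterial for a pseudo-marginal
    sampler.
    """
    fast = getattr(model, "fast_loglik", None)
    if fast is not None:
        seed = int(rng.integers(0, 2**31 - 1))
        return float(fast(theta.values, data, M, seed, scheme))
    return run_filter(model, theta, data, M, rng,
                      scheme=scheme).log_marginal_likelihood


def dump_per_step_log_mean_weights(result: FilterResult, path) -> None:
    """Debug dump ``n,log_mean_w`` of the per-step log mean weights."""
    import pandas as pd

    n = np.arange(1, result.per_step_log_mean_weight.size + 1)
    pd.DataFrame({"n": n, "log_mean_w": result.per_step_log_mean_weight}).to_csv(
        path, index=False)
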