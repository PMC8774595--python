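"""Particle marginal Metropolis-Hastings (PMMH).

MH on the parameters Theta with the intractable marginal likelihood p(y_1:N | Theta)
replaced by the particle-filter estimate.  Pseudo-marginal bookkeeping: the incumbent's
stored estimate is reused, never recomputed — this is what makes the chain target the
exact marginal posterior despite the likelihood being estimated.

Proposals are independent Gaussian random walks per parameter on the transformed
(unconstrained) scale, hence symmetric there; the acceptance ratio carries the
change-of-variables terms back to the original scale.  An optional temperature T
tempers the unnormalized-posterior ratio with exponent 1/T (T = 1 is the plain
posterior); the tempered variant is the building block of the replica-exchange driver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .smc import marginal_log_likelihood
from .ssm_core import (ModelContract, ParameterVector, PriorSpec, TimeSeries,
                       log_prior)

__all__ = [
    "ChainState",
    "ProposalSpec",
    "propose",
    "accept_probability",
    "pmmh_step",
    "run_pmmh",
    "PMMHResult",
    "default_step_sizes",
]


@dataclass
class ChainState:
    """One chain's incumbent: parameters, stored likelihood estimate, log prior."""

    theta: ParameterVector
    log_marglik_hat: float
    log_prior: float
    iteration: int = 0

    @property
    def log_target(self) -> float:
        """Log of the unnormalized posterior estimate p(y|Theta)^ * p(Theta)."""
        return self.log_marglik_hat + self.log_prior


@dataclass(frozen=True)
class ProposalSpec:
    """Per-parameter Gaussian random-walk step sizes on the transformed scale.

    ``temperature_scale_exponent`` optionally widens steps at temperature T by
    T**exponent (0.0 = no scaling, 0.5 = sqrt-T scaling).
    """

    step_sizes: Mapping[str, float]
    temperature_scale_exponent: float = 0.0

    def __post_init__(self) -> None:
        steps = {k: float(v) for k, v in self.step_sizes.items()}
        object.__setattr__(self, "step_sizes", steps)
        for name, s in steps.items():
            if s < 0:
                raise ValueError(f"step size for {name} must be >= 0, got {s}")

    def step_array(self, names: tuple[str, ...], temperature: float = 1.0) -> np.ndarray:
        try:
            base = np.array([self.step_sizes[n] for n in names])
        except KeyError as exc:
            raise ValueError(f"no step size for parameter {exc.args[0]!r}") from exc
        return base * temperature**self.temperature_scale_exponent


def default_step_sizes(prior: PriorSpec, fraction: float = 0.02,
                       transforms: Mapping[str, str] | None = None) -> dict[str, float]:
    """Step sizes as a fraction of each prior-box width on the transformed scale.

    For identity-transformed parameters this is ``fraction * (upper - lower)``; for
    log/logit parameters the box width is measured in the transformed coordinate.
    """
    from .ssm_core import to_unconstrained

    transforms = transforms or {}
    out = {}
    for name in prior.names:
        lo, hi = prior.bounds[name]
        t = transforms.get(name, "identity")
        out[name] = fraction * abs(to_unconstrained(hi, t) - to_unconstrained(lo, t))
    return out


def propose(state: ChainState, spec: ProposalSpec, rng: np.random.Generator,
            temperature: float = 1.0) -> ParameterVector:
    """Symmetric Gaussian random-walk candidate on the transformed scale."""
    theta = state.theta
    phi = theta.to_unconstrained()
    steps = spec.step_array(theta.names, temperature)
    phi_new = phi + steps * rng.standard_normal(phi.size)
    return theta.from_unconstrained(phi_new)


def accept_probability(log_target_candidate: float, log_target_current: float,
                       temperature: float = 1.0,
                       log_proposal_correction: float = 0.0) -> float:
    """MH acceptance probability with tempering exponent 1/T on the target ratio.

    ``log_proposal_correction`` is ``log q(cur|cand) - log q(cand|cur)`` including the
    transform change-of-variables terms; it is applied untempered.
    """
    if np.isnan(log_target_candidate) or np.isnan(log_target_current):
        raise FloatingPointError("NaN log target in acceptance probability")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if np.isneginf(log_target_candidate):
        return 0.0
    log_ratio = ((log_target_candidate - log_target_current) / temperature
                 + log_proposal_correction)
    return float(np.exp(min(0.0, log_ratio)))


def pmmh_step(state: ChainState, model: ModelContract, data: TimeSeries,
              prior: PriorSpec, spec: ProposalSpec, M: int,
              rng: np.random.Generator, temperature: float = 1.0,
              scheme: str = "multinomial") -> tuple[ChainState, bool]:
    """One PMMH iteration: propose, filter, accept/reject.

    Returns ``(new_state, accepted)``.  A candidate outside the prior support is
    rejected without running the filter; on rejection the incumbent (including its
    stored likelihood estimate) is returned unchanged apart from the iteration count.
    """
    candidate = propose(state, spec, rng, temperature)
    cand_log_prior = log_prior(candidate, prior)
    it = state.iteration + 1
    if np.isneginf(cand_log_prior):
        return ChainState(state.theta, state.log_marglik_hat, state.log_prior, it), False

    cand_loglik = marginal_log_likelihood(model, candidate, data, M, rng, scheme)
    correction = candidate.log_jacobian() - state.theta.log_jacobian()
    p_acc = accept_probability(cand_loglik + cand_log_prior, state.log_target,
                               temperature, correction)
    if rng.uniform() < p_acc:
        return ChainState(candidate, cand_loglik, cand_log_prior, it), True
    return ChainState(state.theta, state.log_marglik_hat, state.log_prior, it), False


def init_chain(model: ModelContract, data: TimeSeries, prior: PriorSpec,
               theta0: ParameterVector, M: int, rng: np.random.Generator,
               scheme: str = "multinomial") -> ChainState:
    lp = log_prior(theta0, prior)
    if np.isneginf(lp):
        raise ValueError("initial parameters theta0 lie outside the prior support")
    loglik = marginal_log_likelihood(model, theta0, data, M, rng, scheme)
    return ChainState(theta0, loglik, lp, iteration=0)


@dataclass
class PMMHResult:
    """Post-burn-in samples (one row per kept sweep) and acceptance bookkeeping."""

    samples: pd.DataFrame           # columns: k, <params...>, log_marglik, accepted
    acceptance_rate: float          # over all K + K_burn iterations
    n_kept: int
    n_burn: int
    seed: int

    def chain(self, name: str) -> np.ndarray:
        return self.samples[name].to_numpy()


def _sweep_rng(seed: int, sweep: int, replica: int = 0) -> np.random.Generator:
    """Counter-based substream for one (sweep, replica) cell; order-independent."""
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence((seed, sweep, replica))))


def run_pmmh(model: ModelContract, data: TimeSeries, prior: PriorSpec,
             spec: ProposalSpec, M: int, K: int, K_burn: int,
             theta0: ParameterVector, seed: int, temperature: float = 1.0,
             scheme: str = "multinomial") -> PMMHResult:
    """Single-chain PMMH: ``K_burn`` discarded sweeps, then ``K`` kept samples."""
    if K < 1 or K_burn < 0:
        raise ValueError("require K >= 1 and K_burn >= 0")
    state = init_chain(model, data, prior, theta0, M, _sweep_rng(seed, 0), scheme)
    names = theta0.names
    rows = np.empty((K, len(names) + 1))
    accepted_flags = np.empty(K, bool)
    n_accept = 0
    total = K + K_burn
    for k in range(1, total + 1):
        state, accepted = pmmh_step(state, model, data, prior, spec, M,
                                    _sweep_rng(seed, k), temperature, scheme)
        n_accept += accepted
        if k > K_burn:
            i = k - K_burn - 1
            rows[i, :-1] = state.theta.values
            rows[i, -1] = state.log_marglik_hat
            accepted_flags[i] = accepted
    df = pd.DataFrame(rows, columns=list(names) + ["log_marglik"])
    df.insert(0, "k", np.arange(1, K + 1))
    df["accepted"] = accepted_flags
    return PMMHResult(df, n_accept / total, K, K_burn, seed)
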