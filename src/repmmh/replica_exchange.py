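"""Replica exchange PMMH (REPMMH).

R tempered PMMH chains run in parallel, replica r targeting the tempered marginal
posterior  pi_{T_r}(Theta | y)  ∝  [p(y | Theta) p(Theta)]^{1/T_r}  on a ladder
T_1 = 1 < ... < T_R.  After each sweep of within-replica MH moves, adjacent replicas
propose to exchange their parameter states with the Metropolis probability

    min{1, exp[(1/T_r - 1/T_{r+1}) (log t_{r+1} - log t_r)]},

where log t is the log unnormalized-posterior estimate.  High temperatures flatten the
target (in the T -> inf limit it reduces to the prior), so replicas escape local modes
there and carry good states down to T_1; only the T_1 samples are the posterior output.

Pseudo-marginal bookkeeping across swaps: the stored likelihood estimate travels with
Theta (it is a property of the parameter value, not of the temperature slot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pmmh import (ChainState, ProposalSpec, _sweep_rng, init_chain, pmmh_step)
from .ssm_core import ModelContract, ParameterVector, PriorSpec, TimeSeries

__all__ = [
    "TemperatureLadder",
    "ReplicaSystem",
    "build_ladder",
    "exchange_log_ratio",
    "swap_sweep",
    "run_repmmh",
    "REPMMHResult",
]

_SWAP_STREAM = 1 << 24  # replica index reserved for the swap RNG substream


@dataclass(frozen=True)
class TemperatureLadder:
    """Ordered temperatures ``T_1 = 1.0 <= ... <= T_R``."""

    temperatures: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, float)
        object.__setattr__(self, "temperatures", T)
        if T.ndim != 1 or T.size < 1:
            raise ValueError("ladder must hold at least one temperature")
        if T[0] != 1.0:
            raise ValueError(f"T_1 must be exactly 1.0, got {T[0]}")
        if np.any(T <= 0) or np.any(np.diff(T) < 0):
            raise ValueError("temperatures must be positive and nondecreasing")

    @property
    def R(self) -> int:
        return int(self.temperatures.size)


def build_ladder(R: int, T_max: float, scheme: str = "geometric") -> TemperatureLadder:
    """Geometric ladder ``T_r = T_max^((r-1)/(R-1))`` from 1 to ``T_max``."""
    if scheme != "geometric":
        raise ValueError(f"unknown ladder scheme {scheme!r}")
    if R < 1:
        raise ValueError("R must be >= 1")
    if T_max < 1.0:
        raise ValueError(f"T_max must be >= 1, got {T_max}")
    if R == 1:
        return TemperatureLadder(np.array([1.0]))
    T = T_max ** (np.arange(R) / (R - 1))
    T[0] = 1.0
    return TemperatureLadder(T)


@dataclass
class ReplicaSystem:
    """R chains bound to a ladder, plus per-adjacent-pair swap statistics."""

    chains: list[ChainState]
    ladder: TemperatureLadder
    swap_attempt: np.ndarray = None  # (R-1,) attempts for pair (r, r+1)
    swap_accept: np.ndarray = None
    sweep: int = 0

    def __post_init__(self) -> None:
        R = self.ladder.R
        if len(self.chains) != R:
            raise ValueError("chains and ladder must have equal length")
        if self.swap_attempt is None:
            self.swap_attempt = np.zeros(max(R - 1, 0), dtype=int)
        if self.swap_accept is None:
            self.swap_accept = np.zeros(max(R - 1, 0), dtype=int)

    @property
    def R(self) -> int:
        return self.ladder.R

    def swap_rates(self) -> dict[str, float]:
        """Acceptance rate per adjacent pair, keyed ``"r:r+1"`` (1-based)."""
        out = {}
        for i in range(self.R - 1):
            att = int(self.swap_attempt[i])
            out[f"{i + 1}:{i + 2}"] = float(self.swap_accept[i]) / att if att else np.nan
        return out


def exchange_log_ratio(log_target_r: float, log_target_r1: float,
                       T_r: float, T_r1: float) -> float:
    """Log Metropolis ratio for swapping replicas at ``T_r`` and ``T_r1``."""
    if np.isnan(log_target_r) or np.isnan(log_target_r1):
        raise FloatingPointError("NaN log target in exchange ratio")
    if T_r <= 0 or T_r1 <= 0:
        raise ValueError("temperatures must be > 0")
    return (1.0 / T_r - 1.0 / T_r1) * (log_target_r1 - log_target_r)


def swap_sweep(system: ReplicaSystem, rng: np.random.Generator,
               random_offset: bool = False) -> ReplicaSystem:
    """One pass of nearest-neighbor exchange attempts over disjoint pairs.

    The starting offset r_EX in {1, 2} alternates with sweep parity (or is drawn
    uniformly when ``random_offset``); pairs (r_EX, r_EX+1), (r_EX+2, r_EX+3), ... are
    attempted.  An accepted swap exchanges the full chain states — parameters, stored
    likelihood estimates and log priors — and only permutes them, never mutates.
    """
    R = system.R
    if R < 2:
        return system
    if random_offset:
        offset = int(rng.integers(1, 3))
    else:
        offset = 1 if system.sweep % 2 == 0 else 2
    T = system.ladder.temperatures
    r = offset
    while r <= R - 1:
        lo, hi = r - 1, r  # 0-based chain indices of the (r, r+1) pair
        log_ratio = exchange_log_ratio(system.chains[lo].log_target,
                                       system.chains[hi].log_target,
                                       T[lo], T[hi])
        system.swap_attempt[lo] += 1
        if rng.uniform() < np.exp(min(0.0, log_ratio)):
            system.chains[lo], system.chains[hi] = system.chains[hi], system.chains[lo]
            system.swap_accept[lo] += 1
        r += 2
    return system


@dataclass
class REPMMHResult:
    """Post-burn-in samples for all replicas plus acceptance/exchange bookkeeping."""

    samples: pd.DataFrame     # columns: k, replica, temperature, <params...>, log_marglik
    ladder: TemperatureLadder
    swap_rates: dict[str, float]
    mh_acceptance: np.ndarray  # per-replica MH acceptance rate over all sweeps
    n_kept: int
    n_burn: int
    seed: int

    @property
    def posterior_samples(self) -> pd.DataFrame:
        """Samples of the T_1 = 1 replica slot: the marginal posterior output."""
        return self.samples[self.samples["replica"] == 1].reset_index(drop=True)

    def chain(self, name: str) -> np.ndarray:
        return self.posterior_samples[name].to_numpy()


def run_repmmh(model: ModelContract, data: TimeSeries, prior: PriorSpec,
               spec: ProposalSpec, M: int, R: int, T_max: float, K: int,
               K_burn: int, theta0: ParameterVector, seed: int,
               scheme: str = "multinomial", random_offset: bool = False,
               keep_all_replicas: bool = True) -> REPMMHResult:
    """REPMMH driver: per sweep, one tempered PMMH step per replica, then swaps.

    Every replica starts at ``theta0``.  Within a sweep the R inner PMMH steps use
    independent counter-based RNG substreams keyed by (seed, sweep, replica), so they
    are reproducible regardless of execution order; the swap pass is a serial barrier
    with its own substream.  With ``R = 1`` this reduces to plain PMMH.
    """
    if K < 1 or K_burn < 0 or M < 1 or R < 1:
        raise ValueError("require K >= 1, K_burn >= 0, M >= 1, R >= 1")
    ladder = build_ladder(R, T_max) if R > 1 else build_ladder(1, 1.0)
    chains = [init_chain(model, data, prior, theta0, M, _sweep_rng(seed, 0, r),
                         scheme) for r in range(R)]
    system = ReplicaSystem(chains, ladder)

    names = theta0.names
    n_rows = K * (R if keep_all_replicas else 1)
    rows = np.empty((n_rows, len(names) + 1))
    ks = np.empty(n_rows, int)
    reps = np.empty(n_rows, int)
    n_accept = np.zeros(R, dtype=int)
    total = K + K_burn
    i = 0
    for k in range(1, total + 1):
        for r in range(R):
            system.chains[r], acc = pmmh_step(
                system.chains[r], model, data, prior, spec, M,
                _sweep_rng(seed, k, r), temperature=float(ladder.temperatures[r]),
                scheme=scheme)
            n_accept[r] += acc
        system.sweep = k - 1
        swap_sweep(system, _sweep_rng(seed, k, _SWAP_STREAM),
                   random_offset=random_offset)
        if k > K_burn:
            kept = range(R) if keep_all_replicas else (0,)
            for r in kept:
                rows[i, :-1] = system.chains[r].theta.values
                rows[i, -1] = system.chains[r].log_marglik_hat
                ks[i] = k - K_burn
                reps[i] = r + 1
                i += 1

    df = pd.DataFrame(rows, columns=list(names) + ["log_marglik"])
    df.insert(0, "temperature", ladder.temperatures[reps - 1])
    df.insert(0, "replica", reps)
    df.insert(0, "k", ks)
    return REPMMHResult(df, ladder, system.swap_rates(), n_accept / total,
                        K, K_burn, seed)
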