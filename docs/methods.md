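# Methods

## Model class and goal

A state-space model specifies latent dynamics `z_n ~ f(z_n | z_{n-1}, θ_f)` and an
observation law `y_n ~ g(y_n | z_n, θ_g)`.  Given scalar observations y_1:N (and,
for the neuron model, a known exogenous input series), the target is the marginal
posterior p(Θ | y_1:N) ∝ p(y_1:N | Θ) p(Θ) with the latent path integrated out.  The
marginal likelihood is intractable for the models here, but it can be estimated
unbiasedly by a particle filter, which is all a pseudo-marginal sampler needs.

## Bootstrap particle filter

`smc.run_filter` initializes M particles from p(z_1), then per step propagates
through the system model, weights by the observation density, and resamples —
unconditionally at every step (no ESS-triggered adaptivity), with multinomial
resampling by default and systematic available by configuration.  The estimate

    log p̂(y_1:N | Θ) = Σ_n log[(1/M) Σ_m w_n^m]

is accumulated in the log domain via log-sum-exp; a naive product of N·M Gaussian
densities underflows long before the study sizes (N = 500).  If every particle
weight vanishes at some step the filter reports −∞ and a degeneracy flag; the MH
layer then simply rejects the candidate rather than aborting.

Unbiasedness is checked against an exact scalar Kalman filter on a linear-Gaussian
model (agreement of the mean estimate within Monte Carlo error; the log-scale
Jensen bias shrinks monotonically over M ∈ {5, 50, 500}).

## PMMH

`pmmh.run_pmmh` is Metropolis–Hastings on Θ with p̂ in place of p.  Two conventions
make this exact-in-distribution ("pseudo-marginal"):

* the incumbent's stored estimate is reused, never recomputed — refreshing it would
  change the invariant distribution;
* an accepted candidate carries the estimate that was computed for it.

Proposals are independent Gaussian random walks on transformed coordinates —
identity for unconstrained parameters, log for positive-only (δ, γ, λ), logit for
the unit interval (κ).  The proposal is symmetric in the transformed space; the
acceptance ratio therefore carries only the change-of-variables terms
log J(Θ*) − log J(Θ), with J = ∏ dθ_i/dφ_i, applied untempered.  Default step sizes
are 2% of each prior-box width measured on the transformed scale.

Priors are independent uniform boxes (the minimal choice when nothing further is
known); the support is the open box, so prior ratios cancel for in-support
candidates and out-of-support candidates are rejected before any filtering work.
Boundary points are excluded to keep the transforms finite.

## Replica exchange

`replica_exchange.run_repmmh` runs R chains, chain r targeting
π_r(Θ) ∝ [p(y|Θ) p(Θ)]^{1/T_r}.  The tempering exponent is applied to the full
unnormalized-posterior ratio inside each chain's MH step; without it all replicas
would target the same distribution and exchanges would be vacuous.  The partition
function of each tempered target cancels from every acceptance and swap ratio and
is never computed.

After each sweep of within-replica moves, disjoint adjacent pairs attempt swaps:
the starting offset alternates deterministically between 1 and 2 with sweep parity
(a randomized offset is available).  The swap log-ratio reduces to
(1/T_r − 1/T_{r+1})(log t_{r+1} − log t_r) where log t = log p̂ + log prior.  A swap
exchanges the full chain states — parameters *and* stored likelihood estimates —
because the estimate belongs to the parameter value, not to the temperature slot;
swapping anything less breaks pseudo-marginal validity.  Correctness surrogates on
an enumerable 5-cell discrete target: T_1 occupation matches the normalized
posterior, the hot replica at T = 10^6 is uniform over the support, and swap-level
flows between mirrored configurations are symmetric (detailed balance).

The ladder is geometric, T_r = T_max^{(r−1)/(R−1)}, with T_1 = 1 exactly.  The
study value T_max = 1.163 is kept for all replica runs.  Each (sweep, replica) cell
owns a counter-based RNG substream derived from (seed, sweep, replica), so results
are reproducible regardless of execution order and the R inner steps of a sweep
could run concurrently; swaps are a serial barrier with their own substream.

## Izhikevich neuron model

Latent state (v, u): membrane potential and recovery variable,
dv = 0.04 v² + 5v + 140 − u + I_ext, du = a(bv − u), with the spike reset v→c,
u→u+d once v exceeds v_th = 30.  The published description is a continuous-time
SDE with per-step noise variances, which implies a discrete-time reading: we use
Euler–Maruyama with dt = 1 (the standard integration step for this model), adding
N(0, 0.25) to v and N(0, 10⁻⁴) to u per step, reset applied after the noisy update,
once per step; the observation is the post-reset v plus N(0, 1) noise.  Only
Θ = (a, b, c, d) is estimated; noise scales, threshold and dt stay fixed at the
study values.  |v| is clipped at 10⁶ (with a warning) purely as an overflow guard
for absurd parameter proposals.

The study's input current is not tabulated, so the generator's default protocol is
pinned here: baseline 0 with amplitude-10 pulses over 10–30%, 40–60% and 70–90% of
the record (60% coverage), which elicits several spike trains with varied
inter-spike intervals at the generating parameters (0.02, 0.2, −65, 6) and N = 500.
The protocol is an explicit config object, written out with the data, and identical
for generation and inference.  p(z_1) is Gaussian around the rest state (−65, −13)
with spreads (1.0, 0.2), also shared between generation and inference.

Inference settings (the study gives none): uniform priors a ∈ (0.01, 0.04),
b ∈ (0.1, 0.3), c ∈ (−70, −55), d ∈ (4, 8) — boxes containing both the generating
values and the distant initialization (0.025, 0.15, −60, 5.5) with margin — and the
2% step-size rule, giving steps (0.0006, 0.004, 0.3, 0.08).

## Lévy-driven stochastic-volatility model

Returns y_n ~ N(μΔ + β σ_n², σ_n²), where σ_n² is the integrated volatility over one
interval of an OU process dσ²(t) = −λσ²(t)dt + dz(λt) driven by a pure-jump Lévy
process chosen so σ² has a tempered-stable TS(κ, δ, γ) marginal.  The exact
discretization updates σ²(nΔ) = e^{−λΔ}σ²((n−1)Δ) + η_σ and z by η_z, and
σ_n² = λ⁻¹[Δz − Δσ²] ≥ 0.  The innovation pair comes from a shot-noise series:
stable-envelope terms min{(a_i κ / (AλΔ))^{−1/κ}, e_i v_i^{1/κ}} over unit-rate
Poisson arrivals a_i, plus a compound-Poisson part with Gamma(1−κ) jumps; η_σ damps
every term by e^{−λΔr}, r uniform, so 0 ≤ η_σ ≤ η_z always.

The printed series constants are typographically ambiguous; the readings adopted
(pinned in `_sv_kernels`, validated by the property tests) follow from deriving the
background driving Lévy process of the TS-OU marginal:
A = 2^κ κ δ / Γ(1−κ), exponential/gamma scale 2γ^{−1/κ}, compound-Poisson count
mean λΔ·δ·γ·κ.  The infinite series is truncated at the first stable-envelope term
below ε (default 10⁻¹⁰, hard cap 10⁵ terms); the expected truncation length scales
as ε^{−κ}, and a convergence test verifies halving ε moves the mean of η_z by <1%.
μ = β = 0 for generation and inference, the convention of the particle-MCMC
literature this model follows.  Θ = (κ, δ, γ, λ) is sampled on
(logit, log, log, log) scales.  The transition density is only ever simulated,
never evaluated — the reason the marginal-likelihood (PMMH) route applies where
particle-Gibbs-style samplers cannot.

## Diagnostics

`diagnostics` reports, per parameter: the histogram mode with bin centers on
integer multiples of the bin width (widths 0.0005 / 0.005 / 0.25 / 0.05 for
a, b, c, d and 0.01 / 0.05 / 0.05 / 0.01 for κ, δ, γ, λ — the print granularity of
the study tables; ties break toward the bin nearest the median), the standard
deviation, and the biased-normalized sample ACF (cross-checked against statsmodels)
at lag 30.  The ACF "time constant" is defined here as the smallest lag below 1/e,
censored at max_lag + 1; an exponential-fit definition would be equally defensible,
so the full ACF curve is exported alongside.  All summaries use post-burn-in T_1
samples only.

## Scaled experiment sizes

The study's full-scale runs (K = 10⁶ sweeps; R = 64) are far beyond desk scale.
The package's scaled reproductions (`experiments.SCALED_TABLE_RUNS`) use the same
data (N = 500), particle counts and temperatures with shorter chains:

* stuck PMMH: R = 1, M = 50, 4 000 burn-in + 20 000 kept sweeps, proposal scale
  2% of the prior-box width (the package default);
* recovery: R = 16, T_max = 1.163, M = 50, 3 500 + 6 000 sweeps, proposal scale 3%
  (the kept window sized so the histogram-mode estimator of d, whose bin is half a
  posterior standard deviation, has stabilized);
* particle-starved: R = 64, M = 10, 800 + 4 500 sweeps, proposal scale 2%.

The recovery run's 3% proposal scale comes from pilot mobility studies over several
seeds: at 2% the replica system's escape from the initialization-adjacent optimum
is a seed-level coin flip within the scaled horizon (the glue of a lucky likelihood
estimate, ~2.5×10³ nats of noise, can outlast 8×10³ sweeps), while at 3% it escapes
within ~10 sweeps in every pilot; at 5% even the single chain escapes, erasing the
trapping phenomenon.  Each run targets the identical posterior regardless of scale,
so this is mixing tuning, not result tuning — and the contrast between the columns
is not an artifact of the differing scales: the R = 16 system escapes at 2% for
most seeds, and the R = 1 chain remains trapped at 3% for most seeds.  Full-scale
runs would not need the distinction.

These runs use the systematic resampler.  Both resampling schemes give unbiased
likelihood estimates and therefore the same exact posterior; they differ only in
estimator variance, and through the Jensen gap of E[log p̂] that variance sets the
effective roughness of the landscape the chain sees.  With multinomial resampling
the escape of the R = 16 system was a seed-level coin flip at these horizons;
systematic resampling makes the escape reliable (within ~15 sweeps in every pilot
seed) while the single-chain run remains firmly trapped for the whole 2×10⁴ sweeps
(acceptance ≈ 8×10⁻⁴), so the R = 1 vs R = 16 vs M = 10 contrasts stay clean.
Histogram modes are additionally robust to the shortened burn-in because a mode
only needs a plurality of post-escape samples.  The full-scale SV recovery run is
an overnight configuration; its desk-scale surface is the property suite
(η ordering, count mean, truncation convergence, OU lag-1 autocorrelation e^{−λΔ}).

## What the synthetic generators do and do not emulate

The neuron generator produces exactly the study's observation process — noisy
membrane potentials under a known step drive — but real intracellular recordings
have drift, filtering, unknown inputs and model mismatch none of which is present;
passing tests show sampler correctness on the model class, not robustness to
misspecification.  The SV generator shares its innovation sampler with the
inference model (one truncation, one constants reading), so parameter-recovery
checks validate the generator/inference pairing rather than any external market
data.

## Numerical choices and known limitations

* All weight and acceptance arithmetic is in the log domain; −∞ marks impossible
  states/candidates and propagates as rejection, never as NaN.
* Degenerate ensembles return −∞ estimates instead of raising (candidate rejected).
* The likelihood-estimate distribution for the spiking neuron is heavy-tailed
  (a filter pass that misses one spike loses thousands of log-units), which is what
  makes plain PMMH stick and is faithfully reproduced, not smoothed over.
* Proposal step sizes are fixed, not adaptive; no delayed acceptance or correlated
  pseudo-marginal variants; swaps are nearest-neighbor only; temperature placement
  is geometric, not tuned — all deliberate scope bounds.
* With very few particles (M ≲ 10) the estimator noise dominates and the sampler
  freezes wherever an optimistic estimate lands; this failure mode is itself one of
  the reproduced results.
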