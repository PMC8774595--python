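# repmmh — replica exchange particle marginal Metropolis–Hastings

Bayesian parameter estimation for nonlinear state-space models whose likelihood is
intractable.  A state-space model couples latent dynamics with noisy observations,

```
z_n ~ f(z_n | z_{n-1}, θ_f)        (system model)
y_n ~ g(y_n | z_n, θ_g)            (observation model)
```

and the object of interest is the marginal posterior p(Θ | y_1:N) of the parameters
Θ = (θ_f, θ_g) with the latent path z_1:N integrated out.  This package implements:

* a **bootstrap particle filter** (`repmmh.smc`) producing the unbiased marginal-
  likelihood estimate  p̂(y_1:N | Θ) = ∏_n (1/M) Σ_m w_n^m  in the log domain;
* **PMMH** (`repmmh.pmmh`) — pseudo-marginal Metropolis–Hastings on Θ using that
  estimate, with Gaussian random-walk proposals on transformed (log/logit)
  coordinates and uniform box priors;
* **REPMMH** (`repmmh.replica_exchange`) — R tempered PMMH chains targeting
  π_r(Θ) ∝ [p(y|Θ) p(Θ)]^{1/T_r} on a geometric ladder T_1 = 1 < … < T_R, with
  nearest-neighbor replica swaps accepted with probability
  min{1, exp[(1/T_r − 1/T_{r+1})(log t_{r+1} − log t_r)]}.  High temperatures flatten
  the target so chains escape the local optima that trap plain PMMH near a bad
  initialization; the T_1 chain is the posterior output;
* two study models: the **stochastic Izhikevich neuron** (`repmmh.model_izhikevich`;
  quadratic membrane-potential dynamics, spike reset v→c, u→u+d at v_th = 30,
  Euler–Maruyama with per-step noise, Gaussian observation of v) and the
  **Lévy-driven stochastic-volatility model** (`repmmh.model_levy_sv`; tempered-stable
  Ornstein–Uhlenbeck volatility simulated by a truncated shot-noise series, Gaussian
  returns with variance equal to the integrated volatility), each with a synthetic-data
  generator;
* **diagnostics** (`repmmh.diagnostics`): histogram modes, standard deviations, sample
  autocorrelation functions and their 1/e time constants — the summaries used to judge
  sampling efficiency.

The Izhikevich and volatility filters have fused numba kernels (the samplers run
10^5–10^6 filter passes); a generic numpy filter implements the identical algorithm
and the tests check the two agree.

## Worked example

Generate a 500-step noisy membrane-potential recording (true parameters
a = 0.02, b = 0.2, c = −65, d = 6, driven by three current pulses) and run a scaled
replica-exchange inference from the deliberately distant start
Θ0 = (0.025, 0.15, −60, 5.5):

```bash
repmmh repmmh --model izhikevich --seed 1 --r 16 --m 50 \
              --k 6000 --k-burn 3500 --t-max 1.163 \
              --scheme systematic --step-fraction 0.03 --outdir runs/demo
```

which prints the posterior summary of the T_1 chain (about ten minutes on one CPU):

```
parameter statistic      value
        a      mode   0.020500
        a       std   0.000598
        a       acf   0.096800
        b      mode   0.200000
        b       std   0.003291
        b       acf   0.066179
        c      mode -65.000000
        c       std   0.318375
        c       acf   0.252968
        d      mode   6.000000
        d       std   0.089590
        d       acf   0.176192
```

Every histogram mode sits at the generating value (a 0.0205, b 0.200, c −65.0,
d 6.00 at bin widths 0.0005 / 0.005 / 0.25 / 0.05) even though all sixteen replicas
started far away, and the lag-30 autocorrelations are small — the replica exchanges
carry states through higher temperatures where the tempered posterior is flatter.
Running the same configuration with `--r 1` (plain PMMH) leaves the a, b, c modes
stuck near the initialization with a lag-30 autocorrelation of ≈ 1.  The run
directory collects `data.csv`, `protocol.json`, `samples.csv`, `posterior.csv`,
`summary.csv`, `acf.csv`, `swaps.json` and `run.log`.

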