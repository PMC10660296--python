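# delaymcmc

Simulation-based Bayesian inference of kinetic parameters and distributed
time delays in gene regulatory networks from noisy, discretely sampled
observations of only some of the network's products.

## The problem

Gene regulation involves sequences of steps — transcription, translation,
folding, maturation, target search — most of which are invisible to
time-lapse fluorescence microscopy. A standard modelling response is to
collapse the unobserved sequential steps into a *distributed time delay*:
a reaction initiates at a state-dependent rate h_k(z(t)) and completes
only after a random lag drawn from a delay distribution η_k (here a Gamma,
or a sum of independent Gammas). The resulting stochastic kinetics are
non-Markovian, and when some molecular species are never measured the
likelihood involves a latent space whose dimension grows with the number
of observations.

`delaymcmc` implements an MCMC scheme for exactly this setting. The
working example throughout is the **two-step activation model**: an
unobserved activator X is produced at rate A_X and diluted at rate B; X
drives production of an observed reporter Y through a Michaelis–Menten
propensity A_Y·X/(K_M+X) whose completions lag by the convolution of a
regulation delay τ_X and a maturation delay τ_Y (both Gamma); Y is diluted
at the same rate B; and measurements are Y(t) corrupted by Gaussian noise
with state-dependent variance Y(t)+σ_e at t = 0, 1, …, T minutes.

## The method

* **Completion propensity.** The effective rate of completions at time t
  is f_k(t) = ∫ h_k(z(t−s)) dη_k(s). On the unit observation grid the
  package uses the linear-interpolation approximation: f̂_k(i), the
  expected number of completions of reaction k in (i−1, i], reduces to a
  weighted sum of the propensity history, with weights that depend only on
  η_k (and reduce to the trapezoid rule for zero delay).

* **Approximate likelihood.** Given per-interval completion counts r_ki,
  the count likelihood is a product of Poisson factors
  f̂_k(i)^r e^{−f̂_k(i)}/r!, valid when the trajectory is exactly the
  stoichiometric reconstruction of the counts; multiplying by the Gaussian
  observation factor gives the joint likelihood of counts and parameters.

* **Simulation-based sampler.** Latent counts are proposed by simulating
  the model itself (delayed τ-leaping on the observation grid), so the
  count-likelihood factor cancels from the Metropolis–Hastings ratio and
  no proposal variances need tuning; kinetic rates that enter the
  propensities linearly are then Gibbs-updated from conjugate Gamma
  conditionals, and delay rates by an adaptive log-scale random walk.
  The implementation applies the same simulation-proposal trick to path
  *windows* and reaction *blocks* (with the exact proposal density in the
  ratio), which mixes the latent space much faster at desk scale; see
  `docs/methods.md`.

An exact delayed stochastic simulation algorithm (pending-completion
queue) generates ground-truth data, and a synthetic-benchmark module
reproduces the standard two-step experiments end to end.

## Worked example

```python
import numpy as np
from delaymcmc import (
    ExperimentConfig, generate_dataset, run_mcmc, ParameterSet,
    summarize_posterior,
)

# 10 cells of the steady-state benchmark: AX=10, AY=60, KM=100, B=0.05,
# tauX ~ Gamma(3.6, 0.6), tauY ~ Gamma(3.6, 0.6), noise N(0, Y+10)
cfg = ExperimentConfig.steady_state(seed=7, n_traj=10)
data = generate_dataset(cfg)
net, truth = cfg.network()

# fix KM, the tauY distribution and the tauX shape; sample the rest
init = ParameterSet(truth.values, {"AX", "AY", "B", "tauX_rate"})
post = run_mcmc(net, data.yobs, init, om=cfg.sigma_e,
                n_iter=8000, burn_in=4000, thin=4, seed=7, n_chains=4)
print(summarize_posterior(post, normalize_by=data.truth_params)
      .loc[["AX_over_KM", "mu_tauX", "AY", "B"], ["mean", "sd", "mean±sd"]])
```

Output (as printed by this exact configuration):

```
                 mean         sd        mean±sd
parameter
AX_over_KM   0.105302   0.020236    0.105±0.020
mu_tauX      6.312462   0.534661      6.31±0.53
AY          62.314868  12.984536          62±13
B            0.050726   0.005326  0.0507±0.0053
```

All four recovered posteriors centre within ~5% of the generative values
(A_X/K_M = 0.1, μ_τX = 6 min, A_Y = 60/min, B = 0.05/min) with the truth
inside the central 95% interval. `AX_over_KM` and `mu_tauX` are derived
columns: only the ratio A_X/K_M and the delay *mean* are identifiable from
observations of Y alone, so K_M is fixed (here to 100) and the Gamma shape
of τ_X is fixed with its rate sampled.

The same pipeline is scriptable from a shell:

```bash
delaymcmc generate --regime steady --n-traj 40 --seed 1 --out-dir data/
delaymcmc infer --config data/config.yaml --obs data/obs.csv \
    --free AX,AY,B,tauX_rate --n-iter 20000 --n-chains 4 --seed 7 \
    --out posterior.csv
delaymcmc summarize --posterior posterior.csv --truth AX=10 --truth B=0.05
```

## Layout

| module | contents |
|---|---|
| `delaymcmc.network`   | delay distributions, reactions, networks, the two-step model builder |
| `delaymcmc.simulate`  | exact delayed SSA, delayed τ-leaping, reconstruction/χ checks |
| `delaymcmc.likelihood`| completion propensities, count and observation likelihoods |
| `delaymcmc.inference` | the MH-within-Gibbs sampler, priors, initialisers, multi-chain pooling |
| `delaymcmc.synthetic` | the benchmark generators (steady-state and short-horizon regimes) |
| `delaymcmc.io`, `delaymcmc.cli` | CSV/YAML I/O, posterior summaries, run manifests, the `delaymcmc` CLI |

See `docs/methods.md` for the model, the numerical choices and the known
limitations.
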