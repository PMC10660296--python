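# Methods

## Model

A delayed reaction network has species Z_1..Z_u and reactions R_1..R_v,
each with reactant and product stoichiometries, an initiation propensity
h_k(z, θ_k) of one of three forms — constant c, linear mass action c·z_s,
Michaelis–Menten A·z_s/(K+z_s) — and a delay distribution η_k between
initiation and completion (degenerate at zero, Gamma, or a sum of
independent Gammas). State changes apply at completion; for reactions with
reactants the exact simulator consumes them at initiation and delivers
products at completion (irrelevant for the built-in model, whose delayed
reaction is pure production).

The two-step activation model is
```
R1: 0 -> X   h = AX          no delay
R2: X -> 0   h = B X         no delay
R3: 0 -> Y   h = AY X/(KM+X) delay = tauX + tauY (independent Gammas)
R4: Y -> 0   h = B Y         no delay
```
with everything starting at zero copies (induction at t = 0) and an empty
pending queue. The regulation delay (activator synthesis, diffusion,
target search) and the reporter maturation delay are composed into the
single delayed reaction R3: an intermediate species would be unobservable
and only the delay *sum* affects the law of Y, so a convolved delay
reproduces the identical observable process with fewer latent variables.
X production itself carries no delay; upstream sequential steps are
absorbed into tauX.

Observations are y_obs(t) = Y(t) + ε(t), ε(t) ~ N(0, Y(t)+σ_e),
independently at t = 0, 1, …, T (the t = 0 point is included). The noise
floor σ_e is treated as known (default 10 counts²); values may undershoot
zero at low counts and are not truncated.

## Completion propensities on the unit grid

The effective completion rate is f_k(t) = ∫₀^t h_k(z(t−s)) dη_k(s).
Interpolating the propensity history linearly between grid points and
integrating over the interval (i−1, i] gives

    fhat_k(i) = Σ_{m<i} W0_k[m]·h_k(z(i−1−m)) + W1_k[m]·h_k(z(i−m)),

where the weights are integrals of piecewise-quadratic kernels against
η_k; W0_m + W1_m integrates the unit tent at lag m, so for a constant
propensity the fhat values sum the reachable delay mass, and for a zero
delay the formula is exactly the trapezoid rule ½(h(i−1)+h(i)). Only lags
m < i enter, which automatically restricts η to [0, i]: an initiation
cannot predate induction.

Numerics: weights are computed from per-cell delay masses on a uniform
grid of 0.0025 min, truncated at the 1−1e-8 tail quantile (truncated mass
is renormalised into the support) or at the horizon, whichever is smaller.
For a single Gamma the cell masses are exact CDF differences. For a sum,
the CDF is built by convolving the exact cell masses of one component with
the partner's CDF at cell midpoints (FFT); this "mass × CDF" quadrature is
second-order accurate uniformly in the shape parameter, whereas a
density-level trapezoid loses several digits when a component shape is
below two (singular density derivative at the origin). Measured accuracy:
equal-rate Gamma sums match the closed-form Gamma CDF to ~1e-8; fhat
matches brute-force double quadrature to ~5e-7 on the reference ramp case.

## Likelihood

Given per-interval completion counts r = (r_ki), the count likelihood is

    L̂(r, θ, Δ | z) = Π_{i,k} Pois(r_ki | fhat_k(i)) · χ(z | r),

where χ enforces that z is the nonnegative stoichiometric reconstruction
of r. The exponential normaliser is Σ fhat_k(i) because fhat_k(i) is
already the integral of the interpolated completion propensity over its
interval — no separate time integral is needed. The joint likelihood
multiplies in the Gaussian observation factor of the observed rows of the
reconstruction; the unobserved rows enter only through χ. All computation
is in log space with log-factorials via log-gamma.

## Simulators

* **Exact delayed SSA**: exponential initiation clocks from the current
  total propensity, a pending-completion min-heap, completions applied in
  time order (ties by initiation order), trajectory sampled at integer
  times, counts binned into (i−1, i] by completion time. Events still
  pending at T stay in the event log but are excluded from counts.

* **Delayed τ-leaping** on the unit grid: for interval i, counts are
  Poisson with mean fhat_k(i) evaluated from the trajectory so far — the
  not-yet-known endpoint z(i) in the m = 0 term is replaced by z(i−1)
  (zero-order hold). Within an interval, pure-production reactions are
  drawn first; consuming reactions are drawn from Poissons truncated to
  the feasible range, so the counts always reconstruct the trajectory.
  The simulator reproduces the SSA's moments at the benchmark parameters
  up to a small systematic transient bias (up to ~3% of the mean Y
  mid-ramp, where the endpoint hold lags the rising death rate; unbiased
  at steady state and within Monte-Carlo error there). This bias is a
  property of unit-grid leaping, not of the inference: the sampler
  corrects for the simulator's proposal density exactly (below).

## Sampler

One sweep updates, in order:

1. **Latent counts, per cell.** A window/block variant of the
   simulation-based proposal: draw one move per cell from a mixture of
   (a) full-path regeneration, (b) tail regeneration from a start time
   chosen so the window length is log-uniform on {1..T}, and (c) channel
   blocks that re-simulate only the reactions touching unobserved species
   given the others' counts, or vice versa. Every move simulates the
   model forward over the window with non-window counts held fixed, and
   the kernel returns the exact log-density of what it sampled (including
   the endpoint hold, the feasibility truncation, and a small floor of
   0.01 on the proposal rate that keeps the proposal's support full). The
   MH ratio is then observation-likelihood ratio × count-likelihood
   ratio of the kept reactions × (target/proposal) correction of the
   resampled block — for a pure full-path move with the hold ignored this
   collapses to the classical observation-ratio-only acceptance, which is
   also exposed as `acceptance_probability`. The windowed mixture with
   exact correction was validated against exhaustive enumeration of a
   tiny two-step instance (total variation ≈ 0.006, at the Monte-Carlo
   resolution of the check).

2. **Conjugate kinetic rates.** Any free parameter that multiplies its
   reactions' propensities linearly (AX, AY at fixed KM, B through its two
   dilution reactions) has a Gamma full conditional: shape a₀ + total
   counts, rate b₀ + total exposure, where the exposure is Σ fhat with the
   parameter divided out. Default priors are Gamma(1, 0.01) — nearly flat
   over minute-scale rates.

3. **Delay rates.** Gamma-delay rate parameters enter the weights
   nonlinearly and are updated by a log-scale random walk (prior and
   Jacobian included) whose step size adapts toward 30% acceptance during
   burn-in with a diminishing schedule, frozen afterwards. Delay shapes
   are fixed by design: shape and rate are not separately identifiable
   from downstream observations, only the mean shape/rate is, which is
   reported as the derived column `mu_<name>`.

KM and σ_e are fixed (free KM or a free shape raises an error rather than
silently mixing badly). Multi-chain runs (`n_chains > 1`) start each chain
from the supplied values jittered by a log-normal factor (sd 0.15) on each
free parameter and pool the post-burn-in draws; a split-chain potential
scale reduction per parameter is reported in `config["rhat"]`. Pooling is
the package's default way to obtain honest interval widths, because
single chains understate uncertainty along weakly identified directions
(below).

## Identifiability and its consequences

Observations of Y alone leave three structural degeneracies:

* (AX, KM) only through their ratio — simulated observables under
  (AX, KM) and (c·AX, c·KM) are statistically indistinguishable, so KM is
  fixed and AX/KM reported;
* (tauX, tauY) only through the sum of their means — with both delay
  rates free the posterior of (μ_τX, μ_τY) is a ridge with correlation
  near −1 whose sum matches the generative total;
* shape vs rate of each delay — only the mean is identifiable.

Beyond these exact degeneracies there is a *soft* ridge: increasing AX/KM
(saturating the activation earlier), lengthening the regulation delay and
lowering AY produce nearly the same mean onset of Y, and with few cells
the likelihood distinguishes ridge points only weakly. Two practical
consequences, stated openly:

* Gibbs chains traverse this ridge by slow diffusion (the parameter
  conditionals given latent paths are far narrower than the marginal
  posterior), so runs started far from the posterior bulk can take far
  more sweeps than a desk-scale budget to arrive. The packaged recovery
  experiments therefore start chains at the generative values (jittered
  across chains) — a stationarity-style check: the chains are free to
  leave, and with enough cells the data hold them in place. For real data
  the `moment_init_two_step` (deterministic mean + fluctuation fit) and
  `profile_init_two_step` (pilot-chain scoring along the ridge)
  initialisers are provided; at 10–20 cells neither ranks ridge points
  reliably, and results from distant starts should be interpreted with
  the reported R-hat in hand.
* Short observation windows (T = 50, before steady state) leave the
  dilution rate B underidentified and biased low, because the dilution
  terms B·X and B·Y are small through the transient; B must then be fixed
  from independent measurements, after which the remaining parameters are
  recovered. The benchmark suite reproduces this bias.

## Synthetic benchmarks

The generator simulates the two-step model with the exact delayed SSA
(keeping the generative process distinct from the τ-leaping used inside
inference) and adds the Gaussian observation noise to the Y series only.
Defaults are the study conditions: AX = 10/min, AY = 60/min, KM = 100,
B = 0.05/min, tauX ~ Γ(3.6, 0.6) and tauY ~ Γ(3.6, 0.6) (mean 6 min
each), σ_e = 10, with 40 cells at t = 0..100 min in the steady-state
regime and t = 0..50 in the short regime. Each cell uses an RNG stream
seeded base_seed + index, so any single cell regenerates bit-exactly.
Companion generators produce the production-ratio degeneracy pair
((AX, KM) vs (2AX, 2KM)) and the delay-split pair ((3.6, 0.6)+(3.6, 0.6)
vs (1.2, 0.6)+(6.0, 0.6), identical convolutions).

What the synthetic data do *not* emulate: cell-to-cell parameter
variability, cell division and lineage structure, fluorescence-to-count
conversion, photobleaching, or non-Gaussian measurement error. Passing
recovery tests therefore demonstrates correctness of the machinery under
the model's own assumptions, not robustness to their violation.

## Problem sizes in the shipped experiments

Recovery runs use 10 cells × (4 chains × 8000 sweeps) in the test suite
and 20 cells × (3 chains × 6000 sweeps) in the acceptance script, chosen
so chain length exceeds the latent-path autocorrelation time many times
over while a full run stays within minutes on one CPU; the short-horizon
bias experiment uses ten replicates of 6 cells × 1200 sweeps. The
enumeration validation caps counts at 5 per reaction-interval (~1% of
mass outside the cap at the chosen rates).

## Degenerate inputs and edge rules

Zero rates are legal in simulation (empty state is absorbing; proposals
are all-zero); the two-step builder and the priors require strictly
positive rates. Delay CDF below t = 0 is zero by convention. A zero
completion propensity with a positive count gives log-likelihood −∞, as
does any count matrix whose reconstruction goes negative. σ_e = 0 with
y = 0 raises a degenerate-variance error. All simulators and samplers are
bit-reproducible given (inputs, seed) on a fixed software stack.
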