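# Methods

## Model

The package implements the general unified threshold model of survival
(GUTS) for a population exposed to a time-varying stressor C(t)
(concentration, e.g. nmol/l) observed as a series of survivor counts.

**Damage kinetics.** A latent scaled damage D(t) follows first-order
kinetics,

    dD/dt = k_e (C(t) − D(t)),   D(0) = 0,

where k_e (1/day) is the dominant rate constant — the slowest process
governing recovery. C(t) is the linear interpolation of the measured
concentrations; beyond the last measurement it is held constant at the last
value (needed because observation times may slightly outrun the exposure
record). Within each linear segment the equation has a closed form, which
is propagated exactly across segment boundaries, so the damage trajectory
is exact for the piecewise-linear exposure — no ODE solver is involved.

**Hazard.** An individual with tolerance threshold z has hazard

    h_z(t) = k_k max(D(t) − z, 0) + h_b,

with killing rate k_k (1/(day·concentration unit)) and background mortality
rate h_b (1/day). Thresholds vary across the population with density
f(z); population survival is

    S(t) = ∫ exp(−k_k ∫₀ᵗ max(D(τ) − z, 0) dτ − h_b t) f(z) dz.

Three flavours are supported:

* **full / "proper"** — lognormal f(z) parameterised by its mean `mn` and
  standard deviation `sd` (both in damage = concentration units); five
  parameters (hb, ke, kk, mn, sd).
* **stochastic death (SD)** — delta-distributed threshold (all individuals
  share z = mn); four parameters, no sd.
* **individual tolerance (IT)** — k_k → ∞, an individual dies at the first
  up-crossing of its threshold; four parameters, no kk. Then
  S(t) = exp(−h_b t)(1 − F(max_{τ≤t} D(τ))) with F the threshold CDF.

**Likelihood.** Survivor counts y_0 ≥ y_1 ≥ … ≥ y_n at times t_0=0 < … <
t_n give interval death counts that are multinomial with window
probabilities S_{i−1} − S_i (terminal window to infinity has probability
S_n). The log-likelihood kernel omits the parameter-independent
multinomial coefficient. Conventions: 0·ln 0 := 0 for windows without
deaths; a window with deaths and survival mass ≤ 1e−300 yields −∞.

## Fast evaluation

The double integral is discretised with M equidistant time-grid points
(spacing Δτ = t_n/M, left Riemann rule over grid points strictly before
each observation time) and N points on the threshold axis. Sorting the
thresholds, binning every damage value into the threshold intervals
(strict inequalities; a value exactly equal to a threshold counts as *not*
exceeding it — a measure-zero tie resolved deterministically) and keeping
suffix sums of per-bin damage totals and counts turns the O(N·M) sum into
O(M) binning plus O(N) per observation time.

For the lognormal flavour the thresholds are, by default, a deterministic
log-uniform grid z_j = exp(x_j) with x_j equidistant on [μ−4σ, μ+4σ],
μ = ln(mn) − σ²/2 and σ² = ln(1 + sd²/mn²), with importance weights
ln f(z_j)/g(z_j) = −(μ − ln z_j)²/(2σ²) in the exponent (the constant is
irrelevant after normalisation). The survival vector is normalised by its
first unnormalised element, which makes S(0) = 1 exact. Determinism keeps
the likelihood smooth in the parameters, which matters for MCMC; a plain
random threshold sample is available behind an explicit `rng` argument.

Numerical choices:

* All partial sums are accumulated in log space with a running-max shift
  (logsumexp), so killing rates up to the prior bound cannot underflow
  double precision. This is done unconditionally rather than behind a
  magnitude test; it is equivalent and simpler to reason about.
* The damage closed form contains k_e⁻¹ terms that cancel as k_e → 0. The
  ramp term is computed as slope·dt·φ(k_e·dt) with φ(x) = (x + expm1(−x))/x
  and a Taylor branch φ(x) ≈ x/2 − x²/6 + x³/24 for |x| < 1e−4, so tiny
  rate constants (which the sampler visits) are handled without
  catastrophic cancellation; k_e = 0 returns identically zero damage.
* Exposure measurement times need not lie on the refined grid: every grid
  point is evaluated with the closed form of its own segment, so no
  interpolation error is introduced at segment boundaries. A consequence
  is that low-order digits can differ from implementations that insert the
  measurement times into the grid; the worked-example log-likelihood is
  reproduced to within ~0.03 of the published value at the default
  N = 1000, M = 10000.
* IT uses the running maximum of damage over grid points before t_i
  combined with the exact damage at t_i itself.

Defaults N = 1000 and M = 10000 follow standard practice for this model
family; one three-experiment likelihood evaluation costs ≈ 4 ms on one
core.

## Inference

Priors are uniform with lower bound 0 for every parameter. Upper bounds
are infinite except for k_k < 30, whose posterior is heavy-tailed enough
that unbounded chains can diverge; 30 l/(day·nmol) is practically
indistinguishable from the IT regime k_k = ∞.

**MAP.** A hand-rolled Hooke–Jeeves pattern search (deterministic,
derivative-free, box-constrained) maximises the log posterior. Default
start (0.05, 0.1, 3, 20, 10) and box upper bounds (1, 1, 30, 40, 20) for
(hb, ke, kk, mn, sd); step sizes start at 10% of the box width and halve
on failed exploration until the largest relative step is below 1e−7.
Choosing sensible boxes remains expert knowledge; these defaults suit
pulsed-exposure invertebrate assays on a scale of weeks.

**MCMC.** A robust adaptive Metropolis sampler: proposals x + S·u with u
standard normal; during the adaptation phase the Cholesky factor S gets
the rank-one update S S′ ← S (I + η_n (α − α*) u u′/‖u‖²) S′ with step
η_n = min(1, d·n^(−2/3)), driving the realised acceptance probability α
toward the target α* = 0.4. The initial S is diagonal with 10% of the
initial parameter values as standard deviations plus a 1e−12 jitter
(guarding against zero components). Defaults: 50,000 iterations, 20,000
adaptation, burn-in 10,000. Quantiles are computed on the unthinned
post-burn-in chain (thinning is for plotting economy only); the reported
`maxpost` is the best-log-posterior draw seen anywhere in the chain.
All randomness flows through a single integer seed.

**Prediction.** For each retained posterior draw the scenario's survival
curve is computed and *one* multinomial death vector is sampled (n0
trials, window probabilities S_{i−1} − S_i plus the terminal bin), so
predictive spread blends parametric and demographic stochasticity — the
same observation model as the likelihood. Quantiles are empirical with
linear interpolation; the terminal bin is sampled (conserving n0 exactly)
but not reported.

## Synthetic data

`reference_oracle.simulate_survival` draws one threshold per individual
from f(z), accumulates the cumulative hazard on the refined grid with the
same left-Riemann rule as the engine, and inverts it at a
standard-exponential variate by linear interpolation between grid points
(bias O(Δτ), negligible at the default grids). The recovery studies use
the three diazinon exposure designs with 70 individuals each — the
experimental layout this class of assays actually uses — at truth
(hb, ke, kk, mn, sd) = (0.05, 0.1, 1.8, 15, 6).

What the generator does *not* emulate: concentration measurement error,
inter-replicate heterogeneity beyond the threshold distribution,
time-varying background mortality, and censoring. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model, not robustness to model misspecification in real assays.

## Scaled-down study sizes

The slower verification studies are run at reduced sizes chosen to keep a
full run in the tens of minutes on one core while leaving the conclusions
unchanged: recursion-vs-naive identity at N=50, M=200 (the identity is
exact at any size); quadrature cross-checks at N=4000, M=40000;
simulator consistency at 50,000 individuals; parameter recovery with 20
replicates of chains of 8,000 iterations at N=100, M=1000. The headline
diazinon calibration always runs at the full N=1000, M=10000 with 50,000
iterations.

## Known limitations

* Only lognormal and delta threshold families are implemented.
* No automated convergence diagnostics beyond the realised acceptance
  rate; inspect chains (e.g. with arviz) before trusting quantiles.
* The k_k posterior's heavy tail makes its median the least stable summary
  (expect ~10–25% run-to-run variation at 50,000 iterations).
* Multiple simultaneously acting stressors (hazard addition) and
  alternative dose metrics are out of scope.
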