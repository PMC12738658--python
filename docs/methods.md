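# Methods

This note documents the models, statistical constructions and numerical
choices behind `cilkit`, including the parts where the design was genuinely
open and a choice had to be made.

## 1. Forward models and their intrinsic variability

### Chaotic ODE (Lorenz-63)

The default chaotic system is Lorenz-63 with the classical parameters
(σ=10, ρ=28, β=8/3); the system registry is pluggable
(`register_system`).  Trajectories are integrated with SciPy's adaptive
Runge–Kutta (rtol 1e−6, atol 1e−9 by default) and are bit-reproducible for
fixed inputs.  `sample_attractor` perturbs the initial state with a seeded
normal perturbation (ε=1e−3 by default), discards a transient (20 time
units) and samples every `dt` time units.  The sampling interval matters
statistically: states must be far enough apart in time to be only weakly
dependent; the reference conditions use `dt=0.5`, a little under one orbit
of the attractor.

### Reaction–diffusion (Schnakenberg)

Two components on a cell-centred uniform grid with no-flux boundaries:

    u_t = d_u Δu + γ(a − u + u²v),   v_t = d_v Δv + γ(b − u²v).

Defaults a=0.1, b=0.9, γ=1, d_u=1, d_v=40 lie well inside the
Turing-instability region (verified against the analytic dispersion
relation, which is exposed as `dispersion_growth_rate` and used in tests to
check that the dominant discrete-cosine mode of simulated patterns matches
the fastest-growing admissible wavenumber).

**Time integration** is a fixed-step IMEX scheme: diffusion implicit
(backward Euler; the dense resolvent `(I − dt·d·L)⁻¹` per axis is
precomputed once — grids are small, so a dense inverse beats repeated
banded solves), reaction explicit.  In 2-D the two one-dimensional implicit
sweeps are composed by Lie splitting.  The integrator is *batched*: a whole
ensemble of initial conditions advances simultaneously, making each step a
single BLAS product.  This is what allows the calibration experiments
(thousands of pattern simulations) to run in minutes on one CPU.  The
explicit reaction step bounds the usable step size: at the default
parameters the spatially uniform mode relaxes as a damped oscillation with
eigenvalues −0.1 ± 0.995i, and explicit Euler is stable for it only when
dt < 0.2.  The default dt = 0.15 respects this margin.

A run integrates until the max-norm relative change per unit time drops
below 1e−6 (configurable) or `t_max` is reached; stationarity is recorded
as per-pattern metadata, not enforced — the likelihood construction is
equally valid for transient snapshots, and the reference pattern conditions
deliberately use t=150 (not fully stationary) for richer ensemble
variability.

With `ic_amplitude = 0` the homogeneous steady state
(u*, v*) = (a+b, b/(a+b)²) is an exact fixed point of the discretisation up
to round-off (the reaction vanishes identically and the discrete Laplacian
annihilates constants), which the tests assert.

### Nonlocal colony growth

Volumetric density n(x,t) on R³ with ∂t n = α(k*n)(1−n), k the normalised
indicator of a ball of radius σ_k (3-D integral 1), initial condition a
full ball of radius σ_s.  For radial symmetry the 3-D convolution reduces
exactly to a 1-D integral,

    (k*n)(r) = (2π/r) ∫ s n(s) [∫_{|r−s|}^{r+s} t K(t) dt] ds,

with the inner integral in closed form for the ball profile.  The kernel is
discretised as a matrix on the radial grid (trapezoidal weights); rows whose
kernel support lies inside the domain are normalised so that constant
density maps to exactly 1 — without this correction the r=0 row carries an
O(h) quadrature error from the truncated indicator.  Time integration is
SciPy's adaptive RK (rtol 1e−6); the right-hand side keeps n in [0,1]
analytically, and the solver's excursions are recorded as an `overshoot`
diagnostic.  Output times are absolute (the initial ball is defined at
t=0).  If appreciable density reaches the outer boundary the solver raises
a domain-overflow error rather than silently losing mass.

The observable is the radius enclosing a mass fraction (default 95%) of
∫p dr with p = 4πr²n: cumulative trapezoidal mass, strict ">" threshold,
linear interpolation between grid nodes (this removes the grid-resolution
bias of a raw infimum over nodes).  On the initial density the closed form
(0.95)^{1/3}σ_s is available and is reproduced to ~5e−4 relative at 1201
grid nodes.

Measurements are multiplicative-lognormal: log r_obs = log r_true + N(0, σ_o²).

## 2. Correlation-integral likelihood

Internally both data modes reduce to "item matrices": one row per
trajectory state or per flattened pattern.  The eCDF vector at bin radii
R_1<…<R_M is computed by sorting the pooled cross distances and counting
strictly below each radius; ties at a bin edge count as outside.  Distances
between patterns are grid-weighted norms (L2 default, L1/Linf available,
registry extensible); partial observation is expressed through a component
mask before flattening.

**Bin placement.** Radii sit at equally spaced quantiles of the pooled
training distances.  Discrete distance distributions can duplicate
quantiles; duplicates are collapsed with a warning and the bin count
reduced.  Fewer than two distinct radii is an error.

**Statistics estimation.** The training items are partitioned into `n_ens`
contiguous blocks of N (optionally after one seeded shuffle); every
unordered block pair contributes one realisation of the eCDF vector, giving
n_ens(n_ens−1)/2 realisations for the sample mean μ and covariance Σ.  Σ is
regularised as Σ + λ·tr(Σ)/M·I with λ = 1e−8, escalated tenfold until the
Cholesky factorisation succeeds; if the realisation count does not exceed
M, a rank-deficiency warning is issued.

**How many subsets are enough.** Two effects bias the cost when `n_ens` is
small.  First, with m realisations of an M-dimensional vector the plug-in
Mahalanobis cost follows a scaled Hotelling-T² law with mean
≈ M(m−1)/(m−M−2), not M — at m=15, M=10 that is a 4.7-fold inflation.
Second, realisations from subset pairs are positively correlated (pairs
share subsets), which biases the sample covariance low by roughly a factor
(1 − 4ρ/n_ens).  Both effects vanish as n_ens grows.  The reference
conditions therefore use n_ens = 40 (patterns; 780 realisations) and
n_ens = 60 (trajectory blocks), at which the measured mean cost is within
4% of M and the replicate distribution passes a KS test against χ²(M) with
p ≈ 0.3–0.8.

**Pattern ensemble dimensionality.** 1-D Schnakenberg on a few dozen cells
converges to a handful of discrete stationary states, so pattern distances
form atoms and the Gaussian limit for the eCDF vector is poor.  The
reference pattern conditions use a 2-D 32×32 grid (box length 40, about
four pattern wavelengths per side) at t=150, where the ensemble of spot
arrangements provides quasi-continuous distance variability.

**Cost evaluation at a candidate θ** simulates N fresh items, forms the
eCDF against one seeded-randomly chosen training subset and returns the
Mahalanobis cost.  The cost is stochastic by construction; MCMC treats
−f/2 as the log-target.

**SCIL.** For limited data the statistics are estimated from simulations at
the candidate θ.  The realisation structure mirrors the data vector: the
pool provides `n_ens_sim` reference subsets of N items *and* `n_ens_sim`
pseudo-data groups of `n_data` items, and each (pseudo-group, subset) pair
yields one realisation.  Matching the structure matters: an eCDF over
n_data·N distances has a different sampling variance than one over N²
distances, and reusing the N×N pairing rule would mis-calibrate the
single-snapshot cost.  With n_data=1 the measured replicate distribution at
the true parameter remains χ²(M)-consistent (mean ratio ≈ 1.04).

## 3. Bayesian building blocks

All positive parameters are log-transformed; priors are Gaussians on the
log scale.  The colony study uses wide priors (variance 4 per log
component, i.e. a geometric standard deviation of e²) centred at the
configured values — the posterior is likelihood-dominated.  Normalising
constants are dropped except the σ_o-dependent term of the colony
likelihood, which must be kept because σ_o is estimated.  Forward-model
failures during sampling map to V = +∞ (zero posterior mass) with a
warning instead of aborting the chain.

The posterior-coverage experiment draws 10 measurements on t ∈ [0, 10] at
θ* = (α 0.3, σ_k 1.5, σ_s 2.0, σ_o 0.05) and runs 5000-step
adaptive-Metropolis chains (burn-in 2000, adaptation from step 200).
Chains of ~1000 post-burn samples at acceptance ≈ 0.2 estimate the 2.5%
and 97.5% quantiles too tightly and visibly undercover; 3000 post-burn
samples suffice for the nominal ≈95% marginal coverage.

## 4. Samplers

**Metropolis / Metropolis–Hastings.** Standard acceptance rules; the
Hastings correction uses the usual log q ratio.  With a symmetric proposal
the two algorithms consume the random stream identically and produce
bit-identical chains.  For stochastic targets the candidate is re-evaluated
at every proposal while the current state's value is cached from when it
was accepted; a `refresh_current` flag re-evaluates the current state each
step instead (no claim of equivalence between the two policies).

**Adaptive Metropolis.** Proposal covariance sd·cov(history) + sd·ε·I after
an initial period t0 (default 200) with fixed covariance; sd = 2.38²/d,
ε = 1e−8.  The history covariance is maintained recursively and matches a
batch recomputation to 1e−8.  Setting t0 ≥ n_steps disables adaptation and
reduces the algorithm exactly to Metropolis.

**Diagnostics.** ESS per dimension via the autocorrelation sum truncated at
the first negative pair of consecutive autocorrelations; default burn-in
fraction 0.3; constant chains are flagged and given ESS 1.

**Unadjusted Langevin.** Euler–Maruyama X' = X − h∇V + √(2h)ξ, batched over
particles (potentials may register a vectorised `grad_batch`).  On
V = θ²/2 the chain is exactly AR(1) with stationary variance 1/(1 − h/2),
which the tests verify within Monte-Carlo error at h ∈ {0.2, 0.1, 0.05}.
Divergent particles are frozen and flagged rather than poisoning the
ensemble.

**SVGD.** Particle ODE

    dθ_i/dt = −(1/N) Σ_j ∇K(θ_i−θ_j) − (1/N) Σ_j K(θ_i−θ_j) ∇V(θ_j),

advanced by explicit Euler (default dt 0.1) until the maximum per-step
displacement falls below a tolerance; non-convergence returns a flag, not
an error.  The kernel is a Gaussian RBF with the median heuristic
h = median²/log(N+1) recomputed every iteration (a fixed bandwidth may be
supplied).  One particle reduces exactly to K(0)-scaled gradient descent;
coincident particles at a critical point are a fixed point; the dynamics
are deterministic after initialisation.  SVGD is known to under-estimate
the target variance at finite N; the convergence assertion is therefore on
the particle mean only.

**Gradient-flow samplers and CIL costs.** ∇V of the stochastic CIL cost is
not meaningfully defined, so the Langevin/SVGD samplers are wired to smooth
analytic potentials only; CIL posteriors are sampled with the
Metropolis-family algorithms.

## 5. Fokker–Planck reference solver

1-D, uniform grid, no-flux boundaries.  Face fluxes use exponential
fitting (Scharfetter–Gummel / Chang–Cooper weights B(w) = w/(e^w − 1) with
w the potential difference across the face), which makes the discrete
Boltzmann density e^{−V} stationary *exactly* and conserves the discrete
mass to round-off (the generator's columns sum to zero).  Time stepping is
explicit Euler with a positivity-preserving stability limit
dt·max|Q_ii| ≤ 1; violations raise an error carrying a suggested step.
The grid must contain the tails of both the target *and* the initial
density (≈ 6–8 standard deviations): the trapezoidal mass differs from the
conserved lattice sum by boundary-node terms, so visible boundary density
shows up as apparent mass drift.  KL(ρ_t‖ρ_∞) evaluated by trapezoidal
quadrature (0·log 0 = 0; absolute-continuity violations yield +∞ with a
warning) decays monotonically along the flow and is exposed as a Lyapunov
diagnostic; on the Gaussian target the variance follows the exact
Ornstein–Uhlenbeck law 1 + (σ₀²−1)e^{−2t} to grid accuracy.

## 6. Synthetic data, and what the tests do and do not show

All experiments run on data generated by the package's own simulators: the
generator defines the study conditions (sample sizes, noise levels and
parameter values listed above) and doubles as the fixture generator for the
CLI (`cil fixture`), with JSON manifests making regeneration byte-identical.
Synthetic data are exactly model-consistent — there is no model
misspecification, no measurement outliers, no irregular sampling, and the
noise law is exactly the one assumed by the likelihood.  Passing tests
therefore demonstrate internal correctness and calibration of the methods
(χ² law at the true parameter, nominal posterior coverage, convergence of
the samplers), not robustness to the model errors real data would bring.

## 7. Known limitations

* The all-pairs covariance estimator is biased low for small subset counts
  (quantified in §2); the package warns but does not bias-correct.
* The 2-D IMEX integrator's Lie splitting is first-order in dt; pattern
  *statistics* are insensitive to this, but trajectories of the transient
  are not high-accuracy solutions.
* `chi2_calibration`'s KS test treats replicate costs as i.i.d.; replicates
  sharing a training subset are weakly dependent, which slightly inflates
  the KS statistic.
* The Fokker–Planck solver is 1-D by design (a reference oracle, not a
  general-purpose PDE solver).
* Config-driven pipelines expose one-parameter-subset inference for the
  CIL modes (`infer = ...` on the log scale); joint inference over all
  model parameters is available through the library API.
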