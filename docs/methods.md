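# Methods

## The model

`gridcomp` estimates the composition of tree taxa — the vector of
per-taxon proportions θ(s) on the unit simplex — at every cell of a
regular lattice, from counts of surveyed trees.  Counts may be recorded
per grid cell or aggregated over irregular areal units ("townships") that
overlap several cells.

**Data model.**  At cell i the observed count vector is multinomial,
y_i ~ Multinomial(n_i, θ(s_i)), without overdispersion.  The proportions
are linked to P latent Gaussian fields α_p through a multinomial probit:
each tree j carries utilities W_ijp ~ N(α_p(s_i), 1), independent across
taxa and trees, and the observed taxon is the argmax over p.  This gives
θ_p(s_i) = Prob(W_p = max_p' W_p'), a quantity without closed form for
P > 2 that the package evaluates by Monte Carlo (below).

**Spatial priors.**  Two Gaussian Markov random field priors are
available for each field α_p over the m lattice cells:

* *CAR* — the intrinsic conditional autoregression with precision
  Q = D − C, where C is the four-cardinal-neighbor adjacency and D its
  degree diagonal.  Q has rank m − 1 (one improper level per connected
  component); the per-taxon precision is Q/σ_p², and the field mean is
  fixed at zero because the improper level makes a free mean
  unidentifiable.
* *SPDE* — the lattice approximation of a Gaussian process with Matérn
  ν = 1 correlation (in the √(2ν)·d/ρ parameterization).  With
  a = 4 + 1/ρ², the unscaled template is Q(ρ) = (aI − C)²: interior
  diagonal 4 + a², cardinal entries −2a, diagonal-neighbor entries 2,
  second-order cardinal entries 1.  The per-taxon precision is
  Q(ρ_p)/(σ_p²·4πρ_p²) and the field has a free mean μ_p.  The template
  is built on the finite (buffered) lattice exactly as the interior
  stencil implies, with no extra boundary correction; the buffer exists
  to push boundary artifacts away from the cells that are reported.

A note on scale: under this parameterization the marginal variance of an
SPDE field grows like σ²ρ⁴ (verified numerically against the template
inverse), so "σ = 1, ρ = 3" describes fields with marginal standard
deviation near 9 — strongly separated, nearly one-hot compositions.  The
synthetic generator uses the same convention, so recovery experiments are
internally consistent.

ρ is measured in grid-cell units.  Smoothness ν is fixed at 1; the ν = 2
variant is not implemented because only the ν = 1 stencil has a concrete
lattice form here.

**Hyperpriors.**  Uniform on σ_p with upper bound 1000; for the SPDE
model additionally flat μ_p truncated at ±10 and uniform ρ_p on
(0.1, e⁵).  All bounds are configurable (`HyperpriorBounds`); narrower
bounds are useful for prior-invariance testing.

**Township (change-of-support) extension.**  A township t contributes
counts without within-unit locations.  Each township tree j gets a latent
membership cell c_tj with prior mass ψ_ti proportional to the
township-cell areal overlap (normalized to sum to one; zero-overlap cells
are dropped).  Given the current memberships, township trees enter the
sufficient statistics exactly like gridded trees.

## The sampler

One iteration of the MCMC:

1. **Latent utilities.**  For every tree, the observed taxon's utility is
   drawn from N(α_y, 1) truncated below at the maximum of the other
   utilities; each other utility is then drawn truncated above at the new
   winner.  The argmax invariant therefore holds after every sweep.
   Truncated normals use plain rejection for cutoffs below 0.45 and
   Robert's translated-exponential rejection above, which is exact and
   numerically stable for truncation points beyond ±40 (a naive
   inverse-CDF underflows past about ±8).
2. **Memberships.**  Each township tree's cell is redrawn from the
   discrete posterior ∝ ψ_ti · Π_p N(W_tjp; α_p(s_i), 1), computed in log
   space so deep mismatches cannot underflow to an all-zero weight
   vector; draws never leave the township's support.
3. **Sufficient statistics.**  A_ii = trees currently in cell i; w̄_ip =
   mean utility of those trees (zero where A_ii = 0).
4. **Fields and hyperparameters.**  Per taxon, α_p is drawn from its
   Gaussian full conditional N((A+Q_p)⁻¹(A w̄_p + Q_p μ_p 1), (A+Q_p)⁻¹),
   then the hyperparameter blocks are updated by *cross-level* joint
   Metropolis moves: propose the block by an adaptive random walk, pair
   it with a fresh full-conditional field draw, and accept with the
   ratio of α-marginalized posteriors of the block given W.  Blocks are
   log σ_p (CAR) or μ_p followed by (log σ_p, log ρ_p) (SPDE; a single
   joint 3-D block is available as an option).  The plain Gibbs field
   draw before the blocks is the package's choice: both moves are valid
   kernels, and the extra draw keeps the field moving in iterations whose
   block proposals are rejected.  `MCMCConfig.hyper_sweeps` repeats the
   block updates within an iteration (default 1); the utility sweep
   dominates per-iteration cost, so extra hyperparameter sweeps buy
   mixing along the correlated (σ, ρ) ridge almost for free.

**Marginal block posterior.**  Up to a block-independent constant,
log p(φ_p | W) = ½log|Q_p| − ½log|A+Q_p| + ½ b'(A+Q_p)⁻¹b
− ½ Σ_i A_ii (w̄_ip − μ_p)² + log σ_p (+ log ρ_p), with
b = A(w̄_p − μ_p 1).  This *centered* form is algebraically identical to
the textbook expression with b = A w̄ + Q_p μ 1 but avoids a catastrophic
cancellation between the quadratic form and the prior mean term when Q_p
is extremely large (tiny σ), which in early testing produced a spurious
ratchet toward σ → 0.  The log-scale Jacobians implement the uniform
priors on σ and ρ sampled on the log scale.  For the improper CAR prior
the determinant term uses the generalized determinant, rank m − k with k
the number of lattice components.  Proposals whose scale factors leave
the representable floating-point range are rejected outright; these lie
in regions of vanishing posterior mass.

**Exact field draws without a sparse Cholesky.**  The draw is
α = μ + M⁻¹(A(w̄−μ) + A^{1/2}ε₁ + R'ε₂) with M = A + Q_p and R any matrix
with R'R = Q_p: the oriented edge incidence matrix of the lattice
(divided by σ) for CAR, and the symmetric factor (aI − C)/√(σ²4πρ²) for
SPDE.  Its distribution is exactly the full conditional.  M is banded in
the row-major cell ordering (bandwidth one lattice row for CAR, two for
SPDE), so solves and log-determinants come from a banded Cholesky
(LAPACK `dpbtrf`/`dpbtrs`); the SPDE template's own log-determinant uses
the closed-form lattice spectrum of C (products of path-graph cosine
eigenvalues).  A singular conditional precision — possible for CAR when a
connected component holds no trees — falls back to a logged ridge of
1e-8 times the largest diagonal entry.

**Adaptation.**  Scalar blocks target an acceptance rate of 0.44 and the
2-D (and optional 3-D) blocks 0.23, by Robbins–Monro scale adjustment in
batches of 50 with Haario-style empirical covariance for the
multidimensional blocks; adaptation is frozen at the end of burn-in so
the retained chain uses a fixed kernel.

**Initialization.**  α = 0, σ = 1, ρ = 1, μ = 0; W is drawn once from
N(α, 1) and the observed taxon's entry raised, where needed, to exceed
the others by 0.5; memberships are drawn from ψ.  Taxa whose total count
falls below a configurable threshold (default 1) are dropped with a
warning.  Retained draws are evenly spaced over post-burn-in iterations.

**Verification.**  The transition kernel was checked by a
successive-conditional (Geweke-style) test: alternating the kernel with
data regeneration from the current fields leaves the prior invariant,
and the chain's hyperparameter moments match direct prior draws within
autocorrelation-adjusted Monte Carlo error (`tests/test_sampler.py`).
The marginal block posterior is checked against 2-D quadrature and dense
marginalization oracles to 1e-8, and the field full conditional against
dense linear algebra.

## Composition estimates

For each retained field draw, θ is estimated by simulating n_mc
hypothetical trees per cell (default 10,000) and recording how often each
taxon attains the maximum utility; each (draw, cell) pair uses an
independent RNG substream spawned from one master seed, so results do not
depend on evaluation order.  Argmax ties — a measure-zero event in
floating point — resolve to the lowest taxon index.  Each per-cell vector
is an empirical frequency; a final one-ulp adjustment guarantees the
floating-point sum is exactly 1.  For two taxa the closed form
Φ((α₁−α₂)/√2) serves as an independent oracle: Monte Carlo at 10⁶
samples agrees within 0.002.

## Holdout evaluation

Two designs: hold out all trees from a random fraction of data-bearing
cells (interpolation skill), or hold out individual trees at random
(estimation skill).  Metrics, each computable at the posterior-mean θ and
per retained draw: the multi-category Brier score averaged over held-out
trees; the log predictive density under the multinomial likelihood, with
predicted proportions of exactly zero floored at 1/100,000 when the
corresponding count is positive (the floor is configurable; without it a
finite Monte Carlo θ estimate of zero would send the log density to
−∞); tree-weighted RMSPE and MAE of
predicted vs. empirical held-out proportions; and coverage/length of
central predictive intervals for held-out proportions in cells with at
least 50 held-out trees, built by drawing one multinomial predictive
count vector per posterior draw and taking proportion-scale quantiles.
Model comparison reports, per metric, the fraction of retained draws on
which one model scores lower; ties count one half.  Interval coverage is
pooled over (cell, taxon) pairs by default.

## Synthetic data

The generator emulates the survey's statistical structure: smooth latent
fields drawn exactly from the chosen prior (sparse solves for SPDE; dense
eigendecomposition of the proper subspace, level pinned at zero, for
CAR), multinomial counts with Poisson tree totals per cell
(zero-truncated, default mean 124 matching the survey's per-cell
average; recovery presets use 150), optional missing-cell masks (95% and
80% presets mirroring the sparse-coverage experiments), and rectangular
township blocks with optional boundary jitter and uniform-by-area
overlap weights.  Hidden truth (fields, θ, per-cell counts before
aggregation) is returned alongside.

What it does not emulate: surveyor bias and correction factors,
time-transgressive sampling, real township polygon geometry, and any
spatial covariates.  Passing recovery tests therefore demonstrates
correctness of the inference machinery under the model's own
assumptions, not robustness to survey artifacts.

## Problem sizes used by the test suite

The suite must run on one CPU in limited time, so the simulation-based
checks run at reduced sizes, chosen as follows and stated here as the
package's own configuration:

* *Parameter recovery* (SPDE, σ=1, ρ=3, P=3, ~150 trees/cell): 12×12
  grid, three replicates, 35,000 iterations each (12,000 burn-in).  The
  binding constraint is mixing, not grid size: with fields of marginal
  sd ≈ σρ² ≈ 9, most cells are deeply censored (a taxon observed zero
  times among ~150 trees), and in such cells the latent-utility/field
  pair performs a random walk with steps of order 1/√150, requiring tens
  of thousands of iterations to traverse the field amplitude.  A
  full-length 25×25 run at 20,000 iterations was observed to still be in
  this transient.  Coverage is assessed pooled over replicates, taxa and
  the two hyperparameters, against the 80% threshold.
* *Change of support*: 8×8 grid, two taxa, ~300 trees/cell, CAR fits of
  6,000 iterations — enough that the cellwise posterior-mean difference
  between the gridded fit and the 1×1-block township fit is dominated by
  the 0.01 agreement threshold rather than by MCMC noise.
* *Interval calibration*: 25×25, P=3, with moderate-contrast fields
  (σ=0.3, ρ=1.5).  Under the near-one-hot dense-grid conditions most
  intervals are degenerate points at 0 or 1 and coverage is trivially
  ≈ 0.99 by discreteness; moderate contrasts make the intervals
  informative, which is what a calibration check is for.
* *Prior invariance (Geweke)*: 3×3 grid, two taxa, ~1 tree/cell, 12,000
  sweeps with narrowed hyperprior bounds.  Weak data keep the
  successive-conditional chain mixing quickly across the prior, which is
  what gives the test its power; informative data make that chain
  random-walk slowly and mimic bias.

## Known limitations

* Probit data augmentation mixes slowly where compositions are extreme;
  production-quality hyperparameter inference at survey scale needs
  chains in the 10⁵ range.  The proportions
  themselves converge much faster than the hyperparameters.
* The ICAR level is left unconstrained (the probit link and the data
  identify contrasts); the ridge fallback is numerical, not a prior.
* Single chain per run; users wanting convergence diagnostics should
  launch several runs with different seeds.
* The SPDE model shows boundary effects near the lattice edge; the
  buffered grid mitigates but does not remove them.
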