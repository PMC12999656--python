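# Methods

## Model overview

`thermoevo` studies how unpredictable temperature fluctuations shape the
evolution of *competition* thermal performance curves (TPCs) in a
population of ectotherms. The model couples three layers:

1. **A bounded stochastic temperature process.** Dimensionless temperature
   on (0, 1) evolves in discrete time as

       tau_t = (tau0 + m sin(omega t)) * sigmoid(sigma_eps X_t),
       X_t ~ N(0, 1) i.i.d.,

   where `sigmoid(z) = 1/(1+exp(-z))`. The sinusoid is the predictable
   component (vertical shift `tau0`, magnitude `m`, frequency `omega` in
   radians per step); the sigmoid-transformed Gaussian multiplies it with
   a random factor in (0, 1), so temperatures stay strictly inside (0, 1)
   whenever `tau0 - m > 0` and `tau0 + m < 1`. With `sigma_eps = 0` the
   factor is exactly 1/2, giving the deterministic wave
   `(tau0 + m sin(omega t))/2`; with `m = 0` (or `omega` a multiple of pi,
   which kills the sine at integer steps) the long-run mean is exactly
   `tau0/2` by the symmetry of the sigmoid under `X -> -X`. For `m > 0`
   and other frequencies the mean is only approximately `tau0/2`.

2. **Temperature-driven Ricker ecology.** Population size follows
   `N_{t+1} = N_t exp(r(tau_t)(1 - N_t/k(tau_t)))` with a saturating
   growth-rate curve `r(tau) = r0 exp(-c/tau) + r1` and a bell-shaped
   carrying capacity `k(tau) = k0 exp(-(tau - tau_m)^2 / sigma_k)`.
   Demographic stochasticity is neglected (populations are assumed
   large); all randomness enters through `tau_t`. Reference parameter
   values: `r0 = c = r1 = 0.1`, `k0 = 2`, `tau_m = 0.5`, `sigma_k = 0.05`
   (an alternative `r0 = 5, k0 = 1` set produces periodic/chaotic Ricker
   regimes and is available through the configuration layer).

3. **Density-ratio competition between TPC variants.** Each type carries
   a competition TPC: a beta probability density `beta(tau; mu, s)` with
   mean `mu` in (0,1) and breadth-scaling `s > 0`. We use the standard
   beta shape parameters `a = mu/s`, `b = (1-mu)/s` — the unique choice
   consistent with both derived statistics used throughout:
   thermal optimum `tau_opt = (mu - s)/(1 - 2s)` (the mode, for
   interior-unimodal curves) and squared performance breadth
   `sigma^2 = s mu (1-mu)/(s+1)` (the variance). Because the density
   integrates to one, breadth trades off against height: generalists are
   flatter than specialists. Competition coefficients between a resident
   `N` and a rare mutant `M` are density ratios at the current
   temperature, `alpha_MN(tau_t) = beta_N(tau_t)/beta_M(tau_t)` and its
   exact reciprocal, entering a two-type Ricker competition system.

   A note on reported statistics: the breadth is reported both as
   `sigma^2 = s mu (1-mu)/(s+1)` (`tpc_breadth_squared`) and its square
   root (`tpc_breadth`). Published figure annotations in this literature
   sometimes label the *variance* as "sigma"; exposing both avoids
   guessing which convention a reader expects.

## Invasion analysis

The invasion fitness of a rare mutant is the long-run average of its
per-capita log growth rate on the resident's attractor,

    lambda_bar = (1/L') * sum_{t=burn_in}^{L-1}
                 r(tau_t) (1 - alpha_MN(tau_t) N_t / k(tau_t)),

with the mutant strictly non-feedback (true rarity limit). Two structural
facts make this cheap and smooth:

* the resident's own coefficient is identically 1, so the resident
  trajectory is *independent of the resident's TPC* — one frozen
  (temperature, N_t) realization per regime serves every evaluation;
* comparative quantities (finite-difference stencils, nullclines,
  sweeps) are evaluated on that same frozen realization (common random
  numbers), so they are smooth deterministic functions of the traits.

Selection gradients are central finite differences of invasion fitness in
the mutant traits at the resident (step `fd_step = 1e-4`; the traits are
O(0.1), the fitness O(0.1), so truncation and round-off are both far
below the 1% agreement demanded of the analytic score-function form
`mean(w_t d log beta(tau_t)/d theta)`, `w_t = r N_t / k`, which the test
suite checks independently through scipy's beta implementation). The
Hessian of mutant fitness uses second-order central stencils at step
`10 * fd_step`. The rare-mutant limit is additionally cross-checked
against direct co-simulation of the two-type system with
`M_0 = 1e-8` — valid only while `lambda_bar * window` stays small, which
the tests enforce by perturbing mutants at the stencil scale.

## Canonical dynamics and singularities

Gradual evolution follows the canonical equations
`d(mu,s)/dt = 1/2 * Ne * E * g`, with `Ne` the attractor mean of `N_t`,
`E` the 2x2 mutational covariance (identity by default), and the factor
1/2 the fraction of favourable mutations surviving drift. Absolute time
units are arbitrary; only endpoints and signs are interpreted.
Singularity location is independent of `E` and `Ne` (they rescale the
flow but cannot move roots of `g`); the tests assert this invariance
under random SPD covariances.

Numerical strategy:

* **Explicit Euler** for trajectories, with each displacement capped at
  0.02 in trait space. We deliberately do *not* use a gradient-norm
  line-search safeguard: along a genuine boundary-convergence path
  (breadth collapsing in a constant environment) the gradient norm grows
  as `s` shrinks, so a norm-monotonicity rule freezes exactly the flows
  that must reach the boundary.
* **Damped multi-start Newton** on the gradient map for singularity
  location (FD Jacobian, step 1e-3), starting from the supplied guess and
  a handful of standard interior points. Multi-start matters because the
  density-ratio model has a secondary runaway basin toward very broad,
  boundary-divergent (U-shaped) TPCs at the upper `s` box face; a single
  unlucky start can drift there and miss a locally stable interior
  singularity.
* **Boundary convergence as a first-class outcome.** Traits live in
  `mu in [0.01, 0.99]`, `s in [0.005, 1.99]`. If no interior root exists,
  the canonical flow adjudicates: pinned at an `s` face with outward
  gradient, the remaining `g_mu = 0` equation is solved along the face
  and the report flags the clamp. The constant-environment limit
  (`sigma_eps = 0`, `omega = 2 pi`) ends this way: the optimum aligns
  with the constant temperature `tau0/2` and breadth collapses to the
  box floor.
* **Classification.** Convergence stability from the eigenvalues of the
  Jacobian of the canonical field in the *resident* traits; evolutionary
  stability from negative-definiteness of the mutant-fitness Hessian;
  CSS requires both. At a boundary point only the free coordinate is
  assessed. Complex Jacobian eigenvalues count as stable iff both real
  parts are negative.
* **Nullclines** are zero contours of each gradient component, linearly
  interpolated along the edges of a rectangular trait grid.

## Experiment orchestration and problem sizes

Default averaging horizons: `L = 1e5` with `burn_in = 1e3` for single
evaluations (transients die within ~100 steps; the burn-in carries a 10x
margin), and `L = 2e4` per cell in `(sigma_eps, omega)` sweeps — at that
length the realization scatter of singular trait coordinates is about
1e-3, comfortably inside the reporting tolerances, and a 6x6 two-`m`
sweep completes in seconds. Singularity searches behind the acceptance
script use `L = 5e4`. Per-cell noise seeds derive deterministically from
a master seed and the cell index, so sweeps are bit-reproducible yet
cells are independent.

Sweep trend checks (optimum non-increasing, breadth non-decreasing in
noise magnitude at fixed frequency) are evaluated on the unimodal
low-to-moderate noise range (`sigma_eps <= 1.1`): past the transition
into cold-boundary J-shaped TPCs the breadth statistic is capped by the
class change and genuinely dips by ~0.005, so the monotone claim does
not extend across the transition. The emergence of J-shaped cells at
high noise is asserted separately.

## What the generator emulates — and what it does not

The synthetic thermal regimes reproduce the study conditions: bounded
multiplicative noise around a sinusoid, i.i.d. across steps. Real
thermal environments are autocorrelated (coloured noise), seasonal
beyond a single sinusoid, and measured in physical units; none of that
is modelled, so passing tests demonstrate internal consistency of the
eco-evolutionary machinery under the stated white-noise model, not
predictions for any field system. Demographic stochasticity, multi-
species interactions, gene flow and the joint evolution of the growth
and capacity curves are likewise out of scope.

## Known limitations

* The invasion average over a finite window leaves a residual
  `O(1/window)` in resident neutrality (~1e-5 at `L = 1e5`); gradients
  inherit a corresponding realization dependence, which common random
  numbers turn into a smooth, reproducible bias rather than jitter.
* Near `s = 0.5` the closed-form optimum `(mu-s)/(1-2s)` has a pole; it
  is only ever evaluated in the interior-unimodal regime
  (`s < min(mu, 1-mu) < 0.5`), which the classification-aware dispatch
  guarantees.
* U-shaped TPCs have unbounded density at both boundaries; their
  "optimum" is degenerate and flagged, and the runaway basin toward them
  is reported as boundary convergence rather than suppressed.
* Euler integration of the canonical flow is first-order; it is used for
  basins and endpoints, with Newton supplying the precise root.
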