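# Methods

## Model

The package implements an energy-balance growth model for an individual
animal.  Ingested energy `S` (J/day) is assimilated with efficiency `e`
(losses to egestion and excretion are the implicit `(1−e)·S`); the
assimilated flux pays feeding costs `R_F`, maintenance `R_M`, growth
overhead `R_G = E_S(W)·dW/dt` and the energy bound in new tissue
`G = E_M(W)·dW/dt`.  Solving the balance for `dW/dt` gives the growth
equation integrated by the engine.  Because the rate is *defined* by the
balance, the budget closes identically; `energy_budget_series` verifies
closure to floating-point rounding (observed residuals ~1e-16 relative),
so the closure check guards implementation consistency, not model fit.

Assumptions inherited from the model family:

- ingestion capacity is allometric, `S_max = α·W^β`, with an optional
  break mass above which the allometry may be held or capped;
- feeding costs are a monotone function of ingestion, by default
  proportional (`R_F = k_F·S`), so only the lumped `e − k_F` enters the
  simplified growth equation;
- tissue composition enters through constant (or mass-dependent, via
  hooks) fractions: reproductive share of growth `f_R`, cell-enlargement
  share of somatic growth `f_G`, carbohydrate/protein and lipid shares
  `f_CP`, `f_L`;
- maintenance is basal (`γ_B·W`, non-negotiable) plus negotiable defence.
  The defence share of total maintenance is `ρ = a_N·W^{b_N}·φ^δ`,
  strictly below 1; maintenance is `γ_B·W/(1−ρ)` per tissue.  Somatic
  and reproductive tissue may carry separate `γ_B`, `a_N`, `b_N`; with
  identical parameters, or no reproductive mass, the two-tissue sum
  reduces exactly to the lumped form.

Temperature dependence is out of scope: all rates are isothermal
constants for the rearing temperature the parameter set describes.
Moulting is not a separate term (absorbed in the somatic growth
overhead).  Post-maturity bookkeeping (defence downregulation funding
egg production) is not modelled; integration stops at the growth fixed
point.

The `variant` field selects the maintenance path: `"full"` evaluates the
two-tissue maintenance with the reproductive mass share `p_R(W)`;
`"simplified"` treats all mass as somatic.  The further ad-libitum
special case (`b_N = 1`, `φ = 1`, giving
`dW/dt = a·W^β − c·W/(1 − a_N·W)` with `a = (e−k_F)·α/(E_M+E_S)` and
`c = γ_B/(E_M+E_S)`) is a parameter choice within `"simplified"`, not a
third code path; the fitting registry exposes it directly as the
four-parameter model `"MGM"`.

## Units and default parameters

Mass in mg, time in days, energy in J, fixed package-wide.

Composition constants: `E_CP = 17 J/mg` and `E_L = 34 J/mg` are
literature values for carbohydrate/protein and lipid tissue.  The
default fresh-tissue fractions `f_CP = 0.29`, `f_L = 0.06` (remainder
water/ash at zero energy density) put `E_M = 6.97 J/mg`, the canonical
~7 J/mg of fresh animal tissue.  The synthesis overhead defaults to
`E_S = 2 J/mg` (E_SSD = E_SSG = E_SR = 2), a package choice of the right
order for biosynthesis overheads.

The default cricket-like set (`presets.cricket_params`) was chosen once
to emulate house-cricket growth: `α = 5.13 J·mg^-0.75·day^-1`,
`β = 0.75`, `e = 0.8`, `k_F = 0.1`, `γ_B = 0.44 J·mg^-1·day^-1`,
`a_N = 0.001125 mg^-1`, `b_N = 1`, `δ = 1`, hatchling mass
`W0 = 0.67 mg`.  The defence normalisation puts the ad libitum defence
share at 0.45 near the asymptote, which yields an ultimate mass of
~401 mg, a growth-rate hump at `ω* ≈ 0.485` of ultimate mass (past the
`1/e` ceiling of supply-minus-linear-expenditure models — the regime the
model exists to capture) and `t95 ≈ 76` days, all in the range of
cricket rearing experience.  Two constraints shaped the choice: the
hump had to sit above `1/e`, and the defence share at the asymptote had
to satisfy `ρ_U·(1+δ) < 1`, which is the analytic condition for ultimate
mass to *decrease* under food restriction (differentiate the fixed-point
equation with respect to `φ`); at `ρ_U = 0.45`, both `δ = 0.5` and
`δ = 1` give the monotone response — smaller and later final size under
restriction — that the restriction sweep checks.

For the mass-independent defence regime (`b_N = 0`), `a_N` is a
dimensionless share and defaults to 0.15.  In this regime the growth
equation is von Bertalanffy (`dW/dt = a·W^β − b·W` with
`b = γ_B/[(E_M+E_S)(1−a_N·φ^δ)]`) and the age at a given fraction of
ultimate mass depends on `φ` only through two opposing channels: the
starting-mass ratio `(W0/W_U(φ))^{1−β}` (earlier normalized ages under
restriction) and the defence relief in `b(φ)` (later ages under
restriction).  `a_N = 0.15` was chosen so the two channels roughly
cancel over `φ ∈ [0.6, 1]`, reproducing the classical
restriction-invariant normalized growth curves of standard models; the
sweep test asserts < 5% spread in ages at the 0.5/0.75/0.95 fractions.

## Numerics

- Integration: `scipy.integrate.solve_ivp` with LSODA (adaptive,
  stiffness-switching), `rtol = 1e-9`, `atol = 1e-12 mg`, dense output.
  Piecewise-constant `φ` schedules integrate segment by segment so the
  solver never steps across a discontinuity.
- Singular maintenance denominators raise an error rather than being
  clamped — growth termination must emerge from the energy balance, not
  from silent saturation.  The engine installs a terminal guard event
  just below the analytic singular mass as a diagnostic backstop.
- Ultimate mass: bracketing Brent root-find of the rate between the
  start mass and either the analytic singular mass or a geometrically
  expanded bound; relative tolerance ~1e-13.  The rate at the returned
  root vanishes to < 1e-10.
- Hump location `W*`, `Ẇ_max`: bounded scalar maximization of the
  analytic rate on `(0, W_U)` (no trajectory-grid artifacts); ages at
  mass fractions by Brent root-finding on the dense solution.
- `Ω` is defined as `Ẇ_max / [(W95 − W0)/t95]` — maximum over average
  lifetime growth rate with "lifetime" operationalized as `t95`, a
  package definition.
- Fitting: trust-region-reflective least squares within finite bounds,
  from one deterministic data-driven start plus seeded Latin-hypercube
  starts (default 16 total); scale parameters are sampled log-uniformly.
  Predictions integrate from the first observed age with the initial
  mass fixed at the first observed mass (hatchling mass treated as
  known).  Integration failures and singular-rate evaluations return a
  large penalty so the optimizer can route around invalid regions.
  Default bounds: `a, c ∈ (0, 10^3]`, `β ∈ [0.4, 1.2]`,
  `a_N ∈ [0, 0.999/W_max)` to keep denominators positive over the data.
  Identical data and seed reproduce results bit for bit.
- Degenerate inputs raise typed errors: `φ` outside [0,1], non-positive
  masses, composition fractions exceeding 1, all-equal observed series
  in the GF denominator, concave-up rate quadratics (flagged, no
  maximum), quadratics with no root above `W0`.

## Cohort reduction pipeline

Averaging pools all individuals of a starting density (never a mean of
cohort means).  Growth rates are forward-difference ratios of the
averaged series at interval midpoints, linearly interpolated back to
the observation ages with one-sided endpoint values — a convention
choice; the smooth rate curve is an ordinary least-squares quadratic in
mass (vertex = `(W*, Ẇ_max)`), and the smooth mass-at-age curve is the
quadratic's flow from `W0`, whose asymptote (the quadratic's smallest
root above `W0`) gives `W_U`.  A quadratic is a biased approximation of
the true rate curve — strongly restricted groups depart from it at late
ages — so `smooth_rate_curve` offers a one-pass residual trim (drop
points above the vertex with residuals beyond twice the RMS, refit
once).  On noiseless synthetic cohorts the full pipeline recovers the
engine's `W*`, `Ẇ_max` and `W_U` within 2%; the residual bias is the
quadratic itself, not noise.

Normalised food availability maps starting densities to
`min(log10 d)/log10 d ∈ (0, 1]`, equal to 1 at the lowest density.

## Synthetic cohorts

The generator emulates a self-thinning design: densities
{5, 10, 20, 40, 80} share a fixed ration, emulated by imposing
`φ(density)` = normalised food availability (restriction is an input,
not an emergent outcome of competition).  Each individual gets one
multiplicative lognormal scale factor (mean 1, CV 10% by default)
applied to its density's deterministic trajectory, lognormal measurement
noise (CV 3%) per observation, an exponential death age at a constant
hazard (0.005/day), and a maturation record when its noiseless scaled
curve crosses a 50 mg threshold — a value picked so maturation occurs at
every density of the design (the most restricted group plateaus near
72 mg).  Sampling is weekly from 0 to 140 days, covering the ad libitum
`t95 ≈ 76 d` plus plateau.

What passing tests on these cohorts do **not** show about real data:
individual variation in real cohorts is not a single multiplicative
scale (growth trajectories cross), restriction emerges from competition
and changes over time as cohorts thin, mortality is size- and
density-dependent, maturation is not a fixed mass threshold (real
restricted cohorts mature *smaller*, not just later), and measurement
ages carry handling error.  The generator's role is to give every
pipeline stage a ground truth, not to simulate cricket biology.

## Known limitations

- **(c, a_N) identifiability.**  In the four-parameter reduced model the
  expenditure term `c·W/(1−a_N·W)` supports a long likelihood ridge:
  lowering `c` while raising `a_N` leaves the fitted curve nearly
  unchanged wherever the data weight is concentrated.  With the default
  cricket-like truth, 15 ages and 5% multiplicative noise, the
  linearized estimator SDs under the unweighted SSE are about 5% for
  `a`, 0.15 for `β`, but ~160% for `c` and ~90% for `a_N`; a profile at
  `a_N` fixed to 0.5–1.5x truth moves `c` by −64% to +189% at an SSE
  cost far below the noise floor.  Point estimates of `c` and `a_N` from
  single noisy growth curves should therefore not be interpreted
  individually; the well-determined quantities are `a`, `β` and the
  curve-level descriptors (`W_U`, `ω*`, `t95`).  Independent maintenance
  measurements (e.g. respirometry) are the realistic route to pinning
  `c`.
- The supplementary-level refinements of the source model family —
  mass-dependent reproductive allocation, cell-size-dependent basal
  maintenance, composition trajectories — are exposed only as
  function-of-mass hooks with constant defaults.
- `W_break` handling offers only the two documented policies; no smooth
  post-maturation ingestion decline is modelled.
- The restriction sweep and summaries require constant `φ` per run;
  piecewise schedules integrate but are not summarized.
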