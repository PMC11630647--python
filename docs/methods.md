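# Methods

## Process model

A fed-batch production phase is described by four states: total biomass
`X` (g/L), intracellular product `P` (g/L), substrate `G` (g/L) and broth
volume `V` (L):

    dX/dt = mu*X - (f/V)*X
    dP/dt = pi*X - (f/V)*P
    dG/dt = -gamma*X + (f_sub*Gf - f*G)/V
    dV/dt = f

`f` is the total volumetric feed: the substrate feed (a mass flow in g/h
divided by the feed concentration `Gf`) plus the base feed added for pH
control, modeled as `f_base = X*V*(a*mu + b)` clamped at zero.  The base
feed dilutes all concentrations but carries no substrate, hence the split
between `f_sub*Gf` and `f*G` in the substrate balance.  Antifoam addition
and gaseous volume changes are neglected (minor and mutually cancelling).
Sampling withdrawals are instantaneous volume drops; concentrations are
continuous across them.

The product is part of the biomass, so only the residual biomass
`Xr = X - P` is metabolically active.  Total specific uptake per residual
biomass splits additively into growth, production and maintenance channels,

    gamma_circ = gamma_mu + gamma_pi + gamma_alpha,

with observable rates `pi = gamma_pi * Y_PG * Xr/X` and
`mu = pi + gamma_mu * Y_XrG * Xr/X`, and uptake per total biomass
`gamma = gamma_circ * Xr/X`.  The yields `Y_XrG` (growth) and `Y_PG`
(product) are supplied externally (e.g. from a genome-scale model) and
exclude maintenance, which is why they are higher than whole-process
yields.

Kinetics: uptake and production are Michaelis–Menten terms (in `G` and in
the surplus `gamma_circ - gamma_alpha` respectively, the surplus clamped
at zero — production cannot run on a negative surplus) with optional
non-competitive inhibition factors `1/(1 + i/K_i)` in the substrate,
generations since induction `n = log2` of the withdrawal-corrected biomass
ratio, product load `P/X` and biomass `X`.  Maintenance is a baseline
multiplied by optional linear activation factors `(1 + i/K_i)` in the same
covariates plus `gamma_circ` itself.  Each rate's scale is either a single
constant or a 4-parameter temperature law

    E0 * (kB*T/h) * exp(-dG_cat/(R*T)) / (1 + exp[(dH_eq/R)(1/T_eq - 1/T)]),

a transition-state rate multiplied by the active fraction of a two-state
(active/heat-inactivated) enzyme pool.  `E0` absorbs the `kB*T/h`
magnitude and is not physically interpretable; internally the law is
handled through its value at a 31 °C reference, which is well conditioned.
Counting temperature laws as active, the three rate equations carry
9 parameters each: 27 fittable parameters, 29 with the two yields.

`gamma_mu` is a definition, not a constraint: it may go negative
(starvation), and the simulator does not floor it.

### Simulator

`scipy.integrate.solve_ivp` (LSODA) integrates piecewise between sampling
events, with a tighter absolute tolerance on the stiff substrate state
(1e-8 g/L class) than on biomass and product.  Generations are computed
algebraically from the state with a cumulative withdrawal correction
(`rem`, the product of kept-volume fractions over past samplings), so `n`
never drops at an event.

## Rate estimation (differential method)

Measured concentrations are smoothed with cubic smoothing splines whose
smoothing factor defaults to `n_points * (rel_noise * mean)^2`, i.e. the
residual level expected under the assumed relative measurement noise
(3% biomass, 15% product, 5% substrate).  Inverting the ODEs with the
splines and the online feed gives observed rates at the sample times.

Numerically, the derivative-bearing splines are fitted to the
withdrawal-corrected amounts `A_x = x*V/rem` rather than to
concentrations: between events `d(XV)/dt = mu*XV`, `d(PV)/dt = pi*XV` and
`d(GV)/dt = -gamma*XV + f_sub*Gf`, so the amount trajectories are smooth
across sampling events (no dilution kinks) and the base feed cancels from
the substrate balance exactly.  The amount splines are quintic where the
data allow (>= 6 points): on the 2 h sampling grid the quintic's
higher-order derivative convergence measurably reduces the differential
method's bias.  The inverted rates are algebraically identical to the
concentration-form expressions.

The broth volume is not measured; it is reconstructed by integrating the
online substrate feed (mass to volume via `Gf`), the base-feed model and
the sampling withdrawals.  Because the base feed needs the growth rate,
which needs the volume, the reconstruction iterates: a feed-only pass,
then two refinement passes whose growth rate comes from the biomass-amount
spline.  On noise-free data the reconstruction is accurate to < 0.01%.

Design choices that matter:

* **Endpoint rows carry zero weight.**  First/last derivative estimates
  are one-sided, and their bias is coherent across runs (identical
  protocol), which measurably shifted weakly identified constants by ~5%.
  Downweighting was insufficient; they are flagged with weight 0.
* **Two evaluation grids.**  Uptake-kinetics rows live only on the sample
  times (the support where substrate is actually measured).  Maintenance
  and production rows are enriched with an interior dense grid (0.5 h
  spacing, offset from the knots, 0.5 h margin from the boundaries):
  their covariates (observed uptake, product load, generations) are well
  interpolated between samples, unlike the substrate concentration.
* Runs whose substrate stays below the limit of quantification (default
  0.1 g/L) cannot constrain uptake kinetics; their uptake is computed
  with substrate quasi-steady and flagged invalid for uptake fitting.

## Parameter fitting and term selection

Each rate equation is fitted separately by globally minimizing the
weighted squared error over all runs and time points with seeded
differential evolution (population 30 per dimension unit, Sobol
initialization, tolerance 1e-10, up to 600 generations, followed by an
L-BFGS-B polish).  A smaller population collapsed prematurely on the
uptake ridge (scale/Km/K_G are strongly correlated when substrate spans
a limited range), hence the larger, more diverse default; a conservative
preset (population 15, tolerance 1e-8, 2000 generations) is available as
`DEOptions.strict()`.  Positive constants are searched in log10 space;
the temperature law is searched as (value at 31 °C, dG_cat, T_eq, dH_eq).
Default bounds: dG_cat 10–200 kJ/mol, T_eq 300–325 K, dH_eq 50–1000
kJ/mol; saturation constants within [1e-3, 1e3] and inhibition/activation
constants within [1e-3, 1e6] times the covariate's observed scale (the
upper side reaches far enough that a constant driven to its bound is
numerically indistinguishable from an absent term, keeping reduced models
nested).  The rate-scale upper bound is data-driven: 30 times the largest
observed rate.  A scale far above every observation exists only on
degenerate ridges where a collapsed saturation or inhibition factor
cancels it (`scale/(1+X/K) ~ scale*K/X` for tiny K), a fit mode that
matches training data but extrapolates arbitrarily; the data-driven cap
removes it without constraining any physically meaningful fit.

Backward elimination: fit the working model, fit one model per removable
term with that term left out (warm-started from the projected full
solution), compute per-term F-tests

    F = ((rss_reduced - rss_full)/df_removed) / (rss_full/df_residual)

with `df_removed` = 1 (or 3 when the temperature unit collapses to a
constant) and `df_residual` = points − parameters, and remove the term
with the largest p-value while it is >= alpha.  The two Michaelis
constants are structural and never removable: dropping the uptake one
allows negative simulated substrate, and dropping the production one
leaves a discontinuous all-or-nothing rate at zero surplus (observed to
produce degenerate, badly extrapolating fits).  A reduced fit that
numerically beats the full fit is floored
(p = 1); when that happens the full fit is additionally refined from the
embedded reduced solution.  At most seven iterations per rate can occur
(six removable terms plus the final all-significant check).  The greedy
removal order does not depend on alpha — alpha only sets the stopping
point — so the elimination path is computed once and reused across the
whole alpha grid during cross-validation.

The significance level alpha is a hyperparameter selected on a 13-level
grid (0.001–0.5) by leave-one-run-out cross-validation of the squared
error of the predicted final product-to-biomass yield `YPX`; ties prefer
the smaller (more pruning) alpha.  An exhaustive alternative fits every
admissible mask per rate and picks the lowest corrected AIC, computed
exactly as

    AICC = #p*(log(RSS/#v) + 1) + 2*#v + #v*(1+#v)/(#p - #v - 3)

(`#p` points, `#v` parameters; note `RSS/#v` inside the logarithm and the
`#p - #v - 3` denominator).  The textbook small-sample AICc is provided
separately (`aicc_standard`); the two are not interchangeable — with the
printed form the parsimony penalty dominates only at small `#p`.

Goodness of fit: `R2 = 1 - RSS/TSS` with TSS around the measured mean;
`R2_adj = 1 - (RSS/df_res)/(TSS/df_tot)` with `df_res = #p - #v - 1`,
`df_tot = #p - 1`; relative errors are `(measured - predicted)` over the
measured mean.

### Known limitations of the selection stage

* The F-test presumes stochastic residuals.  On *noise-free* synthetic
  data the residuals are the (tiny, systematic) discretization bias of
  the spline differential method, and relative-improvement tests become
  degenerate: a spurious term that absorbs a share of the bias can test
  as "significant", and on the default fixture that share (~1e-8 in RSS)
  exceeds the genuine contribution of the weakly identified substrate
  self-inhibition term.  No threshold separates them, so exact mask
  recovery from noise-free *trajectory* data is not a property this
  implementation can promise; mask recovery is exact when the rate
  observations themselves are exact (see `validation.
  exact_rate_observations`), and parameters of the truth-active terms are
  recovered to better than 1% from the noise-free trajectory fixture
  either way.
* Within the finite parameter bounds a reduced model is only nested in
  the full one up to the bound-edge neutrality error (~0.2% of the
  factor), so the elimination path's RSS may dip slightly at a removal
  step; the F-test flooring absorbs this.
* The temperature law is weakly identified from five design temperatures
  under 15% product noise; the fitted law can hit its bounds on noisy
  folds with compensating parameters.  Its *predictions inside the design
  range* remain usable; extrapolation beyond it is not.  This is also the
  dominant contribution to held-out final-yield prediction error, which
  the reproduction script measures (roughly at, and on unlucky folds
  above, the 10% level under the default 15% product noise); collinearity
  of the generations and biomass covariates within runs contributes as
  well (either can substitute for the other during selection, and the
  substitutes extrapolate differently).

## Optimal control

The fitted model is transcribed by orthogonal collocation on finite
elements (default 100; the validation studies use 24–96 and state their
sizes) over time scaled to [0, 1].  States live on element boundaries;
degree-1 collocation closes each element — Gauss–Legendre point 0.5
(implicit midpoint) for biomass, product and volume, Gauss–Radau point 1
(backward Euler) for the stiff substrate.  Controls (feed g/h,
temperature °C) are piecewise linear on the elements.  Sampling
withdrawals are fixed volume jumps folded into the stepping equality of
the element ending at the event time; element boundaries are aligned with
the event times.  The withdrawal correction for the generations covariate
is computed from the decision variables themselves, so no outer fixed
point is needed.

Objective: maximize `YPX = P(tend)/X(tend)` minus a control-smoothness
penalty `sum_i c_i sum_j h_j [(u_i(j)-u_i(j+1))/(u_i(j)+u_i(j+1))]^2`
(defaults `c = 1e-4` per control, small enough not to perturb the yield
by more than ~0.1% in the validation problems).  The case-study
constraints are `X0 = 30 g/L`, `V0 = 1.3 L`, `Gf = 390 g/L`, 35 mL
samplings at t = 2,4,6,8,10 h, `V <= Vmax`, `tend = 12 h` (the horizon is
kept fixed; the optimum sits at the bound in all validation problems),
temperature within 25–40 °C.  Decision variables are scaled to O(1).

The NLP is solved with SciPy's `trust-constr` (interior-point style;
SLSQP is available through the same interface — note that restarting
`trust-constr` at its own solution re-initializes the barrier, so
fixed-point restart checks use SLSQP).  The initial guess is a forward
simulation of an exponential-feed reference process.  Every solution is
cross-checked by re-simulating the returned controls with the forward
simulator; collocated and re-simulated final yields agree within 1% at
the validation problem sizes.

The quasi-steady variant removes the substrate state: all fed substrate
is consumed instantly (`G = 0`), the feed sets the uptake
(`gamma_circ = f_mass/(V*Xr)`), and an inequality keeps the implied
uptake below the kinetic capacity `max_G gamma_circ(G, T)`.  On the
validation model the full and quasi-steady optima agree to well under 1%
in final yield.

A least-squares linear approximation of the optimal feed profile is
provided; re-simulation quantifies the (sub-0.1%) effect on the final
yield, biomass and product.

## Response-surface baseline

Endpoint yield versus the exponential-feed coefficient and temperature is
fitted by ordinary least squares on the full six-term quadratic basis, on
the natural variable scale (a coded-units option exists for textbook CCD
comparability).  The optimum is the stationary point when it is an
interior maximum (classified by the Hessian eigenvalues), otherwise the
box-boundary maximum, found exactly from the edge quadratics.

## Synthetic data generator

The generator emulates the training-study structure: a central composite
design over (mu_f, T) with 4 center replicates, 4 star points and 4
factorial points (12 runs), a 12 h production phase sampled every 2 h
with 35 mL withdrawals at t = 2..10 h, exponential feed
`f0 = mu_f*X0*V0/Y_XrG`, online feed and temperature stored noise-free,
and multiplicative log-normal measurement noise (3% X, 15% P, 5% G)
that can never produce negative concentrations.  Substrate measurements
below the limit of quantification are stored censored.

Conditions chosen once, for realism and identifiability, and documented
here: design center (0.12 1/h, 31 °C) with steps (0.03 1/h, 2 °C) — the
wider feed spread is what makes the uptake saturation constants
identifiable from a 12-run design; initial biomass fixed at 30 g/L
(an option exists to vary it); initial substrate at its quasi-steady
working level, since the emulated protocol induces production during a
running fed-batch (a zero initial substrate would add an unresolvable
fast transient between the first two samples and bias the spline
derivatives).  The documented truth parameter set (`reduced_default`) has
the 12-active-parameter reduced structure: uptake with substrate
self-inhibition (c = 1.4 g/g/h, Km = 1 g/L, K_G = 10 g/L), maintenance
with uptake and product-load activation (c = 0.04 g/g/h, K_gamma = 0.25,
K_PX = 0.1), and temperature-dependent production (value 0.08 g/g/h at
31 °C, dG_cat = 120 kJ/mol, T_eq = 308.5 K, dH_eq = 400 kJ/mol; the law
peaks near 33.7 °C, a few degrees above the design center) with surplus
saturation Km = 0.1 and generation inhibition K_n = 1.  Yields
Y_XrG = 0.55, Y_PG = 0.9 g/g.  The center run grows from 30 to ~53 g/L
with ~8.8 g/L product (YPX ~ 0.17) over 12 h; maintenance consumes an
increasing share of uptake late in the run.

What passing tests on this generator do **not** show about real data:
the generator has no pH/DO/off-gas channels, no batch phase, no
model-structure mismatch (the truth lies exactly in the fitted family),
and its noise is independent across time points.  Recovery results are
therefore upper bounds on what the same pipeline achieves on real runs.

## Problem sizes used in the validation studies

Collocation checks use 24/48/96 elements; optimal-control solutions in
tests and the reproduction script use 8–24 elements (the discretization
error at 24 elements is ~0.1% in the final yield, well below the effects
being measured); held-out prediction uses three representative folds
(one center, one star, one factorial run); the type-I study uses 200
replicates of a 200-row single-rate problem.
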