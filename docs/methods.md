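# Methods

## Batch kinetic model

Biomass x(t) (g/l) follows logistic growth with maximum specific growth
rate μ_m (1/h) and carrying capacity x_m (g/l). Product (rhamnolipid) and
substrate kinetics follow the Luedeking–Piret law: the production rate is
α·dx/dt + β·x, a linear combination of a growth-associated term
(coefficient α, g product per g biomass) and a non-growth-associated term
(β, g per g biomass per hour); substrate depletion is the mirror image with
coefficients γ and η. Because the logistic equation has a closed-form
solution, both laws integrate exactly:

    p(t) = p0 + α·A(t) + β·B(t),   s(t) = s0 − γ·A(t) − η·B(t),

with A(t) = x(t) − x0 and B(t) = ∫₀ᵗ x dτ = (x_m/μ_m)·ln(1 − (x0/x_m)(1 − e^{μ_m t})).
Some published renderings of these formulas are typographically corrupted
(a stray x_m inside the logistic denominator, an undefined rate symbol in
the B(t) factor, and a parenthesization of the logarithm that diverges);
we implement the unique forms consistent with the logistic solution and
with the Luedeking–Piret model as named. Numerically, A(t) is evaluated as
(x_m − x0)(1 − e^{−μt})/(1 + r e^{−μt}) with r = (x_m − x0)/x0 and B(t)
through log1p/expm1 (with a log-sum-exp fallback for μt > 500), so both are
exactly zero at t = 0 and overflow-free at any horizon.

Model invariants: μ_m > 0, 0 < x0 < x_m, initial concentrations
nonnegative. Substrate predictions are floored at zero; callers can ask
for the depletion mask that marks floored (censored) samples.

Specific rates for the fed-batch balances come in two equivalent
parameterizations: the Luedeking–Piret form q = γμ + η (the model's native
basis) and the Pirt yield form q_s = μ/Y_{x/s} (+ maintenance M on the
carbon source), q_p = μ/Y_{p/s}. They coincide under γ = 1/Y, η = M. The
specific-rate laws treat the published tables' "U_s" as the instantaneous
specific growth rate μ — the only dimensionally consistent reading.

## Published constants

`rhamnopt.tables` ships three fixture blocks verbatim as printed, including
negative yield coefficients and internal inconsistencies between tables
(e.g. two different growth rates for the same feeding condition, or a
substrate coefficient printed as 2.4 in one table and 22.4 in another).
Nothing is corrected; `signed_magnitude` splits a printed coefficient into
magnitude and sign for use in the consumption-positive model. The batch
constants table is read as: substrate rows carry the per-substrate
depletion pairs (γ, η), the rhamnolipid row the product pair (α, β) — the
only reading under which it covers both substrate depletion and product
formation.

## Parameter estimation

Stage 1 fits the logistic closed form to the biomass series by bounded
nonlinear least squares (trust-region reflective, ftol = xtol = gtol =
1e-15) with multi-start initialization: x_m starts at 1.05× the maximum
observed biomass, μ_m at the log-linear slope of the sub-half-saturation
phase plus a fixed ladder of fallback starts (0.05, 0.2, 0.5 1/h), x0 at
the first observation. x0 can be fitted (default) or held at the measured
inoculum — both defensible, so both are exposed. Series with fewer than 4
points, non-positive values, or under 2 % total variation are rejected as
carrying no growth signal.

Stage 2 is ordinary least squares of the zero-intercept response
(p − p0, or s0 − s) on the two regressors [A(t), B(t)] evaluated from the
stage-1 fit; p0/s0 are taken from the first observation, so the regression
is exactly the integrated Luedeking–Piret law with no nuisance intercept.
Substrate samples reported as exactly zero after a positive start are
excluded: they are censored by the nonnegativity floor and would otherwise
bias the fit. A design-matrix condition number above 1e8 sets
`condition_warning`. Yield coefficients are whole-run ratios
Δbiomass/Δsubstrate, reported signed as observed (negative when substrate
falls while biomass rises, matching the sign convention of the published
tables); product yield uses the glucose change.

No confidence intervals are produced (none are reported for the original
fits this mirrors).

## Fed-batch simulation

State (V, X, P, S₁..S₃) evolves under the standard dilution-corrected
balances with up to three independent feed streams, each with its own feed
concentration s_F. Growth laws: logistic μ = μ_m(1 − X/x_m) (default — the
batch model's basis) or substrate-limited Monod with inhibition
μ = μ_m S/(K_s + S + S²/K_i), gated to zero at or below the growth
threshold S_i, for the case where the tabulated K_s/K_i/S_i constants are
to be used. Consumption of an exhausted substrate is gated to zero.

Integration is segment-wise (scipy `solve_ivp`, LSODA, default rtol 1e-9 /
atol 1e-12) between feed-law breakpoints, so piecewise-constant switches
never sit inside a solver step; output is sampled on the 4-h control grid.
Alongside the state, the integrator accumulates ∫q_s X V dt (consumed
mass) and ∫F dt (fed volume) per substrate, and `mass_balance_audit`
compares total input V₀S₀ + s_F∫F dt against V_f S_f + consumed mass; a
converged run closes to ~1e-10 relative, and the closure degrades
monotonically as solver tolerances are loosened, which makes the audit a
cheap integration-quality check.

Negative feed rates (which appear as a lower bound in the published
optimizer settings, unexplained there) are clamped to zero by default; an
explicit withdrawal mode integrates them as reverse feeding. Sampling
losses, temperature and pH dynamics are out of scope.

## Tabu search

Decision vector: one feed rate per 4-h control interval (12 variables per
substrate over 48 h), box-bounded. Per-substrate optimization (three
independent 12-variable runs) is the default, matching the per-substrate
profile presentation; a joint 36-variable mode exists. The objective is
the 48-h product concentration; volumetric productivity P·V/t_f is
available by configuration. Neither objective is imposed by the source
tables, so this is a package design choice.

The loop: evaluate a random initial solution; each iteration draws
N_neigh = 20 uniform box perturbations of per-coordinate radius
S(k)·(upper − lower), where S(k) = 1/(1 + e^{n(k/m − k_center)}) is the
sigmoid schedule (n = 10, k_center = 0.5 by default): S equals 0.5 exactly
at the k_center fraction of the run, giving coarse global moves early and
fine local moves late. An optional fixed `step_scale` replaces the
schedule with a constant-radius local walk. Tabu membership on a
continuous space needs a radius: a candidate is tabu if it lies within
tabu_radius (default 1e-3 of the box width, max-norm, strict inequality)
of any solution in the recency list (FIFO deque, capacity L = 10; L = 0
disables the memory). Aspiration overrides tabu status only on strict
improvement over the incumbent best. The best admissible neighbour becomes
the next current solution; when it does not improve on the current
solution it is added to the tabu list. After 0.2·m iterations without
improvement the search restarts from the best-so-far. A frequency-based
second list (visit-count penalty) is implemented but off by default, since
only the recency list has fully specified semantics. Failures of the
objective are treated as infeasible candidates, excluded from selection
and counted in the result.

Everything is reproducible from the seed; the result carries the best
candidate, the per-iteration best-so-far trace (nondecreasing by
construction), the accepted-solution trajectory, and evaluation/failure
counts. Ladder runs (5/25/50/100 iterations at the published settings)
warm-start each stage from the previous best, so the ladder trace is
nondecreasing.

## Genetic algorithm (comparison method)

Binary coding with 4 bits per variable mapped affinely onto the bounds —
16 levels, one level spanning 1/16 of the range (1/32 at 5 bits);
endpoints are exactly representable. Roulette-wheel (fitness-proportional)
selection with a shift fallback (f − min f + ε) whenever fitness values
are negative or all zero; single-point crossover at rate Pc = 0.7 (cut
uniform over interior positions, suffixes swapped — bit multisets are
conserved positionwise across the pair); independent per-bit mutation at
Pm = 0.08. Elitism (carrying the single best individual) is on by default:
without it the plateau-termination criterion is noisy; it can be disabled.
Termination: generation budget, best-fitness plateau (default 30
generations), or target fitness. No inversion operator and no adaptive
rates.

## Synthetic data

The batch generator evaluates the closed forms on the 0–48 h grid at 4-h
spacing (13 points — the study's sampling design) for one biomass, one
rhamnolipid and three substrate series, then applies measurement noise
(default multiplicative Gaussian, σ = 0.05 — typical assay-level scatter;
the original measurement error is uncharacterized) and truncates negatives
at zero. Ground truth defaults: μ_m = 0.13 1/h, x_m = 3.04 g/l, product
(α, β) = (0.3091, −9e-6), per-substrate (γ, η) from the published batch
constants, initial substrate levels from the culture-medium recipe
(glucose 10.0, nitrogen 1.7, phosphorous 3.0 g/l) and x0 = 0.1 g/l — none
of the initial concentrations are printed in the source, so these are the
package's defaults and all are configurable. Generating parameters are
embedded in the output metadata so recovery tests are self-describing.
The fed-batch generator wraps the simulator the same way (noise on
measured concentrations, not on the pump-derived volume).

What the generator does **not** emulate: autocorrelated sensor drift,
heteroscedasticity beyond the multiplicative model, irregular or missing
samples, lag phases, product inhibition (no governing equation is printed
for it), or any mismatch between the generating model and the fitted
model. Passing recovery tests therefore demonstrate estimator correctness
under the model's own assumptions, not robustness to model misspecification.

## Validation problem sizes

The optimizer oracle is a deliberately small instance: 3 control intervals
× 5 feed levels = 125 candidates, exhaustively enumerated, under
substrate-limited (inhibited) growth so the optimum is an interior feeding
policy rather than the trivial zero-feed corner that pure logistic growth
produces. Distinct level combinations are memoized, so the 100-seed
success-rate studies reuse the 125 simulated values. Monte-Carlo studies
use 100–500 seeds as noted per test; the published-settings optimization
runs the full 5/25/50/100 ladder for all three substrates at N_neigh = 20.
These sizes are the package's validation design and keep the whole
suite comfortably interactive.

## Known limitations

- The fed-batch ODE system and the optimizer objective are reconstructed
  from standard practice (the source prints neither); the mass-balance
  audit and analytic-limit tests pin down the implementation, not the
  original code's behaviour.
- Published endpoint values (X_f, P_f, S_f) are shipped for qualitative
  comparison only; with the printed constants taken verbatim the simulator
  does not — and is not made to — reproduce them numerically.
- Tabu search on a continuous space has no convergence guarantee; the
  oracle equivalence holds on the discretized instance.
- Withdrawal mode models a negative feed as reverse feeding (mass leaves
  at the feed concentration), which is a bookkeeping convention, not a
  physical sampling model.
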