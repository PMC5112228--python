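# rhamnopt

Kinetic modelling and feed-profile optimisation for fed-batch rhamnolipid
fermentation.

Rhamnolipids are glycolipid biosurfactants produced by *Pseudomonas
aeruginosa*. Their titres in fed-batch culture depend strongly on how the
limiting substrates — glucose, nitrogen and phosphorous — are fed over the
run. This package provides, for bioprocess engineers and modellers, the
full computational chain for that problem:

1. **Batch kinetics** — closed-form logistic growth and integrated
   Luedeking–Piret product/substrate laws;
2. **Parameter estimation** — nonlinear least squares for the growth
   constants, then multiple linear regression for the product and
   substrate-depletion coefficients, plus whole-run yield coefficients;
3. **Fed-batch simulation** — dilution-corrected ODE balances under
   piecewise-constant or exponential-then-constant multi-substrate feeding,
   with a mass-balance audit;
4. **Optimal control** — tabu search over the substrate feed-rate profile
   (the decision variable: one rate per 4-h interval over 48 h), with a
   binary-coded genetic algorithm as the comparison method;
5. **Synthetic data** — a generator that emulates the study design
   (13 samples at 4-h spacing, three substrate series, measurement noise)
   so every stage is testable without wet-lab data.

## Model

Biomass follows the Verhulst logistic equation

```
dx/dt = μ_m (1 − x/x_m) x,    x(t) = x_m x_0 e^{μ_m t} / (x_m − x_0 + x_0 e^{μ_m t}),
```

and product/substrate follow the Luedeking–Piret law, integrated against
the logistic solution:

```
p(t) = p_0 + α A(t) + β B(t),      s(t) = s_0 − γ A(t) − η B(t),
A(t) = x(t) − x_0,                 B(t) = ∫₀ᵗ x dτ = (x_m/μ_m) ln(1 − (x_0/x_m)(1 − e^{μ_m t})).
```

α, γ are growth-associated coefficients (g/g); β, η non-growth-associated
(g/(g·h)). The fed-batch simulator uses the standard balances
`dV/dt = ΣF`, `dX/dt = μX − (ΣF/V)X`,
`dS_i/dt = −q_{s,i}X + (F_i s_{F,i} − ΣF·S_i)/V`, `dP/dt = q_p X − (ΣF/V)P`
with specific rates either in Luedeking–Piret form (q = γμ + η) or Pirt
yield form (q = μ/Y + M). Published constants (batch Luedeking–Piret pairs,
fed-batch constants and 48-h endpoints, per-strategy model parameters) ship
as a verbatim JSON fixture in `rhamnopt.tables`.

## Worked example

```python
import rhamnopt as rp

# 1. synthesize a noisy batch run from the published constants
tc = rp.generate_batch_timecourse(noise=rp.NoiseModel(sigma=0.05, seed=3))

# 2. recover the kinetic constants
fit = rp.fit_batch_kinetics(tc)
print(fit.growth.mu_max, fit.product.growth_coeff, fit.product.nongrowth_coeff)
```

prints (seed 3)

```
0.14155534583783655 0.31160133286092434 -0.0003135358947038448
```

i.e. at 5 % assay noise the growth rate μ_m = 0.13 1/h is recovered to ~9 %
and the growth-associated product coefficient α = 0.3091 g/g to ~1 %; with
`sigma=0` the recovery is exact to ≈1e-13 relative. The same run from the
shell:

```
rhamnopt synth --seed 3 --out tc.csv
rhamnopt fit tc.csv
rhamnopt optimize-tabu --seed 4 --out profile.csv --report-out report.json
```

The optimizer prints the best 48-h product concentration it found (e.g.
`best P(48h) = 43.1773 g/l` for the default reduced iteration ladder) and
writes the optimal feed-rate schedule, one rate per 4-h interval, to
`profile.csv`.

## Data formats

Time courses are plain CSV (`time_h, biomass_g_l, product_g_l,
glucose_g_l, nitrogen_g_l, phosphorous_g_l[, volume_l]`) with an optional
`#`-prefixed JSON metadata header carrying generator/simulator provenance.
A missing substrate column means "not measured", not zero. Configurations
are JSON; see `rhamnopt.pipeline.StudyConfig`.
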