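# Methods

## Scope

`seastock` implements a two-stage assessment of a seasonally migrating
small-pelagic stock observed only through commercial fishery records
(vessel-day catches with position, month and vessel identity):

1. **Index standardization.** A seasonal spatio-temporal Poisson-link delta
   model turns haul-level records into seasonal relative-abundance indices
   `D_t`, alongside a conventional additive (GAM-style) standardization used
   as a benchmark.
2. **Stock assessment.** An index-only (data-limited) Schaefer
   surplus-production assessment with Monte-Carlo filtering of
   `(r, K_q)` parameter pairs produces relative reference points
   (`F/F_MSY`, `B/B_MSY`, `MSY_q`), Kobe status and status probabilities.

A synthetic-data generator with known latent truth replaces the
request-only commercial dataset and drives all recovery tests.

## Observation model

A record `i` with offset `a_i` (effort in vessel-days, nominal swept area 1
per day) and catch `b_i` follows the Poisson-link delta form:

    p_i = 1 − exp(−a_i n_i)                 encounter probability
    c_i = a_i n_i w_i / p_i                 positive-catch rate
    b_i = 0             with prob 1 − p_i
    b_i ~ LogNormal(median c_i, sigma_obs)  with prob p_i

`n_i` is latent numbers density and `w_i` mean weight; the identity
`p_i c_i = a_i n_i w_i` means density and weight act multiplicatively on
expected catch. The log-normal positive distribution is parameterized by
its median, matching the log link; one observation-variance group is used.

## Latent structure

For each component `X ∈ {n, w}`:

    log X_i = beta_X(t_i) + omega_X(s_i) + xi_Xu(s_i, u_i)
              + xi_Xy(s_i, y_i) + eps_X(s_i, t_i) + vessel_X(V_i)

with `t` the calendar-ordered (year, season) step, `u` the season, `y` the
year and `s` the nearest knot. Fields:

- `omega`: static spatial field; `xi_u`: one field per season; `xi_y`: one
  per year. Each is a zero-mean Gaussian field over knots with exponential
  (Matérn ν = 1/2) correlation `exp(−d/range)` over planar km distances,
  one shared decorrelation range. The SPDE mesh machinery of the large
  estimation toolchains is deliberately replaced by this exact dense
  formulation: identical modelling intent, and exact at 10–100 knots.
- `eps`: year-season fields chained by a stationary AR(1),
  `eps_t = rho · eps_{t−1} + sqrt(1 − rho²) · innov_t`, one lag-1
  coefficient per component (`rho_n`, `rho_w`). These coefficients are the
  scientific focus of the recovery experiments.
- `vessel`: iid normal intercepts keyed by vessel id (catchability
  heterogeneity). An optional fixed vessel-length slope exists in the
  generator; the model's default keeps it off.

Knots are placed by seeded k-means on observed locations; each observation
and each extrapolation-grid cell attaches to its nearest knot, and knot
areas `a_s` partition the extrapolation region exactly (cell area
`(111.32·Δ°)²·cos(lat)`).

## Estimation

The marginal likelihood over all random fields is approximated by the
Laplace method. The inner problem (random fields plus the year-season
intercepts `beta`, which carry a flat prior) is solved by a damped Newton
iteration with analytic gradients and Hessians; the intercepts are
*profiled*: they join the inner optimization but are excluded from the
Laplace log-determinant, mirroring the "profile" feature of TMB-style
tools. The outer problem (field SDs, range, AR(1) coefficients,
observation SD — 14 parameters in the full model) is maximized by L-BFGS-B
on finite-difference gradients (forward differences for the coarse phase,
central differences with step 1e-4 for refinement), followed by a Newton
polish on a finite-difference fixed-effect Hessian until the maximum
absolute gradient is at or below 1e-4.

Convergence is declared iff the final maximum absolute fixed-effect
gradient is ≤ 1e-4 **and** the fixed-effect Hessian is positive definite.
For replicated experiments where only parameter estimates are consumed,
`refine=False` stops after the coarse phase: the estimates are essentially
unchanged (point differences below 0.003 on the AR(1) coefficients in
side-by-side runs) at roughly a third of the wall time, and such fits do
not claim the convergence contract.
Log-SDs are bounded below at −4 (σ ≈ 0.018, indistinguishable from zero at
data scale); gradients are projected at active bounds.

Numerical notes: `p` is computed as `−expm1(−a·n)`; the zero-catch
contribution is exactly `a·n`; inner Newton tolerance is 1e-8 on the
maximum gradient with step-halving line search and adaptive diagonal
damping when the Hessian is not positive definite.

## Derived quantities

- **Index.** `D_t = Σ_s a_s · n_{s,t} · w_{s,t}` over extrapolation knots,
  with vessel effects excluded (population-level index) and no additional
  retransformation correction. Standard errors come from ≥100 seeded draws
  of all inner effects from the approximate joint precision (the inner
  Hessian at the optimum) with the variance parameters held at their
  estimates.
- **Centre of gravity.** `COG_t = Σ_s a_s n w x_s / D_t` in km easting and
  northing; its monotone trend is tested by a two-sided, tie-corrected
  Mann-Kendall test with continuity correction (constant series: tau 0,
  p 1 by convention).
- Seasonal series are the `D_t` at each season's step; the fourth annual
  index is the arithmetic mean of the three seasons.

## Conventional benchmark

Log CPUE of positive records is fitted with Year and Month factors,
B-spline smooths for longitude, latitude and vessel length, and all six
pairwise interactions (factor × factor, factor × spline, spline × spline)
on a ridge-stabilized design built with patsy. The annual index averages
back-transformed predictions (half-variance log-normal correction,
toggleable) over a balanced grid — all months × a spatial lattice × the
median vessel length — so the index is not confounded by effort
allocation. Zero-CPUE rows are dropped and counted; the model is a
deliberate benchmark and keeps the known weaknesses of log-only
standardization.

## AMSY assessment

All quantities are catchability-scaled: with index `A_t = q·B_t`, Schaefer
dynamics give `Cq_t = A_t + r·A_t(1 − A_t/K_q) − A_{t+1}`, and
`MSY_q = r·K_q/4`, `B_MSY_q = K_q/2`, `F/F_MSY = 2·Cq_t/(r·A_t)`,
`B/B_MSY = 2·A_t/K_q`.

`(log r, log K_q)` pairs are sampled from a bivariate normal: the r
marginal moment-matches the uniform-like prior range (midpoint as mean,
quarter-range as SD on the natural scale; default 0.6–1.5, the
high-resilience small-pelagic setting), the `K_q` marginal is centred at
`A_anchor / midpoint(B/K prior)` with spread from the window edges, and
the log-scale correlation is configurable (default 0). Each pair runs
`n_trials = 10` trials with multiplicative log-normal observation error on
the index and process error on production (both CV 0.1); a pair is
*viable* iff at least one trial yields `Cq_t ≥ 0` at every step and an
anchor-year `B/K` inside the prior window ("about half" → (0.4, 0.6),
applied at the first index year by default). Reference points are medians
and 2.5/97.5 percentiles across viable pairs; Kobe regions use the
convention green (`B ≥ B_MSY`, `F ≤ F_MSY`), yellow (`B ≥ B_MSY`,
overfishing), orange (depleted, `F ≤ F_MSY`), red (both violated), with
boundaries resolved toward the safer region. Catches exist for all but the
final year, so the final-year status combines final-year `B/B_MSY` with
the last available `F/F_MSY`; status probabilities are viable-pair
fractions per region. Defaults (30,000 tested pairs, 10 trials, CV 0.1)
follow the published index-only assessment implementation and are
config-exposed.

## Cross-validation and comparison

`RE_y = (pred − obs)/obs` and `ARE = mean |RE_y|`. Two labelled schemes:

- `loo` (default): drop year y, re-filter the viable cloud on the rest,
  and predict `A_y` by one Schaefer step from `A_{y−1}` with the held-out
  catch approximated by the most recent observed exploitation rate. The
  first year has no predecessor and is not predicted.
- `insample`: median forward trajectory of the viable pairs, driven by the
  median implied catch series, against the observed index.

The 95% RE band is computed across years and labelled as such.

## Synthetic-data generator

The generator mirrors the model exactly (fields drawn on the cell lattice
with the same exponential correlation and AR(1) chaining, records drawn
from the Poisson-link delta observation model), plus two deterministic,
model-external features of the study system: an interannual log-abundance
trend (default +0.06/yr, a steadily recovering stock that stays below
carrying capacity over nine years) and a Gaussian density hotspot drifting
northeast (default 14 km/yr at the eastward-dominant heading implied by
~12 km/yr east and ~7.5 km/yr north), which generates the centre-of-gravity
signal. Default frame: nine years, months March–November split into three
seasons, a 0.25° grid over 34–46° N × 144–163° E, CPUE in kg per vessel-day,
30 vessels with log-normal-ish length spread and iid catchability effects.
Interannual field SDs (`xi_y` 0.15, `eps` 0.25) are set so seasonal index
series vary 15–40% between years, the range typical of small-pelagic CPUE;
much larger values would produce year-to-year index jumps that no Schaefer
dynamics can reproduce.

Two presets:

- `SimConfig.desk()`: the same structure on a 6°×6°, 0.5° grid, 4 years —
  used for fast end-to-end runs and the convergence experiment.
- `SimConfig.recovery()`: the parameter-recovery frame (5 years × 3
  seasons): no hotspot and no drift (a deterministic migrating bump is
  model-external structure that would load onto the year-season field and
  bias the very coefficient under test), `sigma_eps = 0.8` dominant over
  the nuisance fields (0.15–0.3), observation SD 0.25, range 200 km,
  ~3,800 records. This is the standard design for an
  autocorrelation-recovery study: the target parameter must carry the
  dominant signal to be identified at 15 knots × 15 time steps.

What the generator does **not** emulate: environmental covariates,
preferential/adaptive fleet targeting beyond the density link, vessel
movement dynamics, multi-species interactions, hyperstability or
hyperdepletion of CPUE. Passing recovery tests therefore show the
estimators are correct under their own assumptions plus mild
misspecification (spatial coarsening to knots, the migrating hotspot);
they do not certify behaviour under fleet-behaviour confounding.

## Known limitations and numerical caveats

- Estimated field SDs at knot level are attenuated relative to cell-level
  generating values (within-knot averaging); the AR(1) coefficients are
  much less affected because temporal averaging of an AR(1) preserves its
  lag-1 coefficient, but a small attenuation toward zero remains visible
  for the weight component (≈ +0.04 at the recovery frame's scale).
- With 15 time steps the AR(1) maximum-likelihood estimates carry an
  O(1/T) small-sample bias (the year-season intercepts absorb the spatial
  mean of each step, a Nickell-type effect); replicate means should be
  read with the reported Monte-Carlo error.
- The Laplace approximation is accurate to ~1e-2 log-likelihood units at
  a few observations per random effect and improves with information; the
  quadrature cross-check isolates implementation error by testing in the
  near-Gaussian regime.
- Desk-scale problem sizes (15–25 knots, 3–5 years, 2,000–4,000 records)
  are the package's default study sizes; the 100-knot, 9-year frame of the
  full study runs with the same code but longer wall times.
- AMSY requires the index to be dynamically feasible under Schaefer growth
  (`A_{t+1}/A_t ≲ 1 + r/4` near `K_q`); indices with extreme interannual
  jumps reject all sampled pairs, and the filter then raises rather than
  returning an empty result.
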