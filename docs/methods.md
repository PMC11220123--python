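# Methods

## Scope and data model

The package evaluates a balanced panel of n DMUs × T years.  Inputs and
outputs must be strictly positive (a radial DEA requirement, enforced at
load time); environmental covariates are unrestricted reals.  The default
schema mirrors a provincial primary-healthcare indicator system: inputs
institutions/personnel/beds, outputs consultations/admissions (unit: ten
thousand), environment GDP per capita (yuan), population density
(persons/km²), urbanization rate (%), government health expenditure
(billions).

## Stage 1: DEA

Efficiency is measured against a *contemporaneous* frontier — each year is
its own technology.  The per-province summary scores are arithmetic means
of the yearly scores.  A pooled frontier over all DMU-years is available
(`frontier_scope: pooled`); per-year is the default because it is the
frontier concept the Malmquist machinery needs anyway, but on short noisy
panels the pooled variant discriminates better between units.

Numerical choices: LPs are solved with HiGHS; a score within 1e-6 of 1 is
reported as exactly 1; within-year scores are clipped to (0, 1]; the RTS
classification uses a ±1e-6 band around Σλ = 1.  Slack values come from a
second LP that maximizes total slack at the fixed radial score — phase-1
slack values are not unique, the phase-2 optimum is (up to degenerate
ties).

The stage-2 dependent variable is the *total input excess*
(1 − θ_VRS)·x + phase-2 slack, i.e. everything the unit could shed; the
`slack_definition: slack_only` switch restricts it to the phase-2 part.
The total-excess definition follows the three-stage tradition of treating
the full input surplus as the quantity the environment must explain.

## Stage 2: SFA on slacks

The composed-error regression S = Zβ + v + u uses the cost-frontier sign
(+u): slack is a bad, so inefficiency adds to it.  u is half-normal —
zero-mode truncated normal; a free truncation point is out of scope.  One
regression per input, pooled over all DMU-years, no year effects.  The
likelihood is parameterized by (β, ln σ², logit γ), optimized by
Nelder–Mead + BFGS from OLS-based starts over a γ grid (0.05…0.95) with
moment-matched σ² and an intercept shifted by the half-normal mean.
The reported MLE never falls below the γ = 0 (OLS) likelihood; the LR
statistic 2(ln L − ln L_OLS) is tested against the 50:50 χ²₀/χ²₁ mixture
(5% critical value 2.706).

**Bounded γ.**  DEA slack vectors contain an atom of exact zeros (every
strongly efficient unit).  As γ → 1 the composed likelihood then
degenerates onto a flat "lower-envelope" fit with β → 0 and the
likelihood still rising, so an unconstrained optimizer destroys the very
slope the adjustment needs.  γ is therefore bounded at 0.99 during
optimization.  The bound is inactive in well-behaved continuous-error
problems (the parameter-recovery tests at γ = 0.8–0.9 estimate interior
optima) and binds exactly in the zero-atom regime, where it plays the
role of the finite convergence tolerance that classical frontier software
relies on, at the cost of attenuating β toward zero (the fitted
environment effect is a conservative, partial level-adjustment).

Residuals are decomposed with the JLMS conditional expectation for the
+u composition: with μ* = ε σ_u²/σ² and σ*² = σ_u²σ_v²/σ²,
E[u|ε] = μ* + σ*·φ(μ*/σ*)/Φ(μ*/σ*), computed in log-space for tail
stability; v̂ = ε̂ − E[u|ε̂].  The input adjustment takes its maxima over
the pooled DMU-year sample per input (per-year maxima would re-level each
year separately and break the panel's comparability).  A constant slack
vector (e.g. all units efficient) short-circuits to a degenerate fit with
zero adjustment.

Coefficient signs read as in the three-stage literature: positive =
slack-increasing = efficiency-decreasing, negative the reverse.  Standard
errors come from a central-difference Hessian at the optimum.

## Stage 3 and Malmquist

Stage 3 re-runs the full DEA on adjusted inputs with original outputs.
The Malmquist index uses the geometric-mean form with CRS cross-period
distances and VRS own-period distances; SECH = EFFCH/PECH.  It is
computed on the stage-3 (adjusted) panel by default
(`malmquist_source: raw` switches to the raw panel).  VRS cross-period
programs can be infeasible; affected records are flagged, reported as
missing and excluded from summaries — no CRS fallback is substituted.
Summaries are geometric means (arithmetic means would break the
multiplicative identities, and on the packaged published table only the
geometric means reproduce the printed mean row).

## Spatial statistics

Weights are queen-style land-border contiguity from the packaged 31-unit
fixture (Hainan–Guangdong strait join keeps the graph connected; the
31-unit frame excludes Taiwan) or k-nearest-neighbour (default k = 5,
ties broken by label order), row-standardized by default.  Global Moran's
I uses the S² = (1/n)Σz² scaling, which makes Σᵢ Iᵢ = I·S0 an exact
identity; inference is two-sided permutation (999 relabellings by
default, seeded) plus the closed-form randomization variance normal
approximation.  Local significance uses conditional permutation (the
unit's own value held fixed).  The pipeline feeds yearly *stage-3 TE* to
the spatial stage; LISA significance filtering is a reporting option,
default off.

## Synthetic generator

The generator emulates the panel anatomy the three-stage method assumes:

* outputs: lognormal sizes with a CES aggregate
  (a·ỹ₁^p + (1−a)·ỹ₂^p)^(1/p), p = 2 — p ≥ 1 keeps the production set
  convex, so noise-free draws are exactly DEA-efficient (the
  no-inefficiency limit is a sharp test);
* efficient inputs: fixed per-input scale constants × aggregate, shrunk
  by gᵗ (Hicks-neutral technical change; default g = 0.97, a mild
  regress matching a sector whose TFP drifts down);
* inefficiency u = max(0, δ·z + SAR(ρ) + half-normal(σ_u)) applied as
  exp(u) on inputs, with standardized covariates z, default
  δ = (−0.08, −0.05, +0.06, +0.05) (favourable economy/density, adverse
  urbanization/expenditure), ρ = 0.5, σ_spatial = 0.2 over the
  row-standardized contiguity matrix via (I − ρW)⁻¹, σ_u = 0.2;
* lognormal measurement noise σ_v = 0.05 per input;
* environment: covariates carry a west-to-east gradient (from the fixture
  longitudes) so they are spatially smooth, as provincial economies are;
  GDP and expenditure drift upward over years.

What it does *not* emulate: the real panel's magnitudes and units, serial
correlation in the idiosyncratic inefficiency, input-mix heterogeneity
beyond noise, and any feedback from outputs to environment.  Passing
recovery tests therefore demonstrates that the estimators recover the
assumed data-generating structure, not that the published point estimates
are correct.

A structural consequence worth knowing: stage 3 deliberately removes
environment-driven variation, and in the generator the environment is the
spatially smoothest inefficiency channel.  Stage-1 efficiency therefore
shows clear positive Moran's I while stage-3 efficiency is much less
clustered — residual clustering survives only through the SAR management
component, which on a 31-node graph yields noisy yearly estimates.  A
strongly positive stage-3 Moran (as benchmark studies report on real
data) implies spatially structured *management* quality, which the
generator induces only through ρ and σ_spatial.

## Robustness layer

`sensitivity_analysis` re-runs the whole model with one variable removed
(inputs propagate through all stages; environmental covariates only alter
stage 2) and compares per-DMU mean stage-3 TE with the full model via
Wilcoxon signed-rank (p = 1 with a flag when all differences are zero),
paired Cohen's d (|mean diff|/sd(diff); infinite for a constant nonzero
shift, since there is no within-pair spread), and Spearman rank
correlation.  `year_stability` applies the same statistics to adjacent
years.

## Determinism and audits

Config + seed fully determine every output file; the yearly Moran seeds
are seed + year.  Every pipeline run asserts TE = PTE·SE,
TFPCH = EFFCH·TECHCH, EFFCH = PECH·SECH (to 1e-9) and Σ local I = I·S0
before writing reports.  Reported scores are rounded to 3 decimals;
ranks (competition ranking, ties share the best rank) are computed before
rounding.

## Problem sizes

The bundled analyses and tests run the full 31 × 9 panel (279 DMU-years,
≈1,100 envelopment LPs per stage plus ≈1,500 cross-period LPs for the
Malmquist block) and scale simulation-based checks (SFA recovery
n = 2000, permutation calibration 100–150 replicates, power studies
20–40 replicates) to sizes where Monte-Carlo error is comfortably below
the asserted tolerances.
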