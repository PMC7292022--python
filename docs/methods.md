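# Methods

This note records the modelling choices behind `initsens`: what the
surrogate simulator does and does not emulate, where every tunable constant
comes from, the conventions fixed where several were defensible, and what
the passing test suite does and does not demonstrate about real ecosystem
models.

## The problem

An end-to-end ecosystem model is initialised at a virgin (unfished) state:
numbers-at-age and mean weight-at-age for each age-structured species
group, and a single nitrogen biomass (plus silicate for two algal groups)
for each biomass-pool group. Those numbers carry uncertainty that varies by
group — some stocks are well assessed, plankton pools are barely
constrained. The analysis pipeline perturbs the initial state, simulates an
ensemble, and asks two questions: (1) which groups retain between-run
variability (measured as the cross-run CV of annual biomass) and which
converge; (2) which group attributes explain the retained variability,
found by stepwise GLM selection.

## The ecosystem fixture

`src/initsens/fixtures/chatham.yaml` describes a deep-sea shelf ecosystem
with 55 species groups: 37 age-structured and 18 pools. The keystone ranks
(1–37, each used exactly once) and informance ratings (1 = best informed …
4 = poorly specified; all pools rated 4) are the published characterisation
of this system. Everything else — age-class counts, trophic levels, virgin
biomasses, background mortality rates, lifespans, asymptotic lengths,
responsiveness ranks, catchability, depth affinity — is invented but
plausible, fixed in the versioned file so the structural bookkeeping is
exact: age-class counts are 2–10 with 10 most common and sum to 341 over
the 37 groups, giving 361 perturbable variables (341 numbers-at-age + 18
pool nitrogen + 2 silicate) and 57 scalars (37 + 18 + 2).

Diet availabilities are not stored as an explicit 55×55×2 table; they are
derived deterministically from trophic levels: a predator of level TL is
offered prey in [TL − 2.5, TL − 0.3], Gaussian-weighted around one level
below (0.7 below for juveniles), rows normalised. Spatial distributions
come from a per-group `depth_affinity` scalar through a softmax over a
shallow-to-deep box gradient, juveniles shifted half a unit shallower. Both
rules are pure functions of the fixture contents, so repeated loads are
identical.

## The surrogate simulator

The simulator generates the output structure the downstream analysis needs
— biomass trajectories, numbers-at-age, a predator→prey consumption ledger
— with simple, fully owned dynamics. It is *not* a reimplementation of any
production ecosystem model. Per 12-hour timestep (in order):

1. **Consumption.** Holling type-II: each predator entity (juvenile stage,
   adult stage, or predator pool) takes
   `I = I_max · B_pred · A·X / (ΣA·X + K_s)` per box, where A are diet
   availabilities and X local prey biomass. `I_max = 4 yr⁻¹` (maximum
   annual ration per unit predator biomass) and `K_s = 1000` biomass units
   (half-saturation) were chosen once so a balanced toy web neither
   collapses nor blooms; removals are capped at 10% of a prey's local
   biomass per step and the ledger records the *realized* flows, so
   consumption equals biomass removed exactly (a tested invariant).
2. **Predation mortality**, applied multiplicatively and uniformly over a
   prey's age classes (never subtraction below zero).
3. **Background mortality**: survival `exp(−m_L · T_corr)` with
   `T_corr = 2^((T−15)/10)` of the local box temperature. `m_L` values are
   defined per 12-h step and rescaled linearly when the model runs at a
   coarser step (tests use 1- to 5-day steps). Temperature is parametric:
   box offsets plus a seasonal sinusoid, so the applied rate genuinely
   varies spatially and temporally.
4. **Growth**: consumers convert intake to weight with assimilation
   efficiency 0.3 (capped at 2%/step and 3× reference weight); autotroph
   pools grow logistically at 10 yr⁻¹ toward 2×B0 capacity; heterotroph
   pools get assimilated intake plus a weaker logistic renewal (3 yr⁻¹)
   standing in for production the explicit web does not resolve.
5. **Fishing**: `exp(−q · effort)` on adults; effort is 0 before the start
   year (default 1975) and ramps to 1 over 5 years.
6. **Year boundary**: plus-group ageing, then Beverton–Holt recruitment
   (steepness 0.75) from mature biomass relative to the virgin state.

The virgin state sets proportions-at-age to `exp(−Z·a)` at the group's
total mortality, scales numbers so each group's biomass equals B0, and
spreads over boxes by the stage's spatial weights. All stochasticity lives
in the perturbation plans; the simulator is bit-deterministic, and runs
whose biomass exceeds 1000×B0 are flagged `diverged` and excluded from the
ensemble statistics.

**What the surrogate does not emulate.** No nutrient cycling, oxygen or
chemistry tracers; migrating groups are closed within the domain; no
environmental stochasticity (in real systems much of the low-trophic-level
variability is environmental); and the pool renewal term actively damps
pool variability — in this surrogate the biomass pools therefore show
*smaller* between-run CVs than age-structured groups, whereas systems
without such intrinsic stabilisation tend to show the opposite. Passing
tests demonstrate the pipeline's correctness and the recoverability of
planted effects, not the dynamics of any real ecosystem.

## Perturbation conventions

The stochastic sets draw a deviation `s ~ N(0, σ)` and multiply by `1 + s`;
a literal multiplicative N(0, σ) scalar would collapse groups near zero,
and the ±50% reading of the σ = 0.25 design implies the 1 + s form. Draws
with s ≤ −0.9 are redrawn so multipliers stay positive. One draw is made
per group per run (not per variable), matching the one-scalar-per-group
design; silicate-tracked pools carry an independent scalar for silicate.
Ensemble sizes for sets 2–3 default to 20 per (set × fishing flag) — a
desk-scale size giving stable CVs — and per-run seeds are derived from the
master seed by stable hashing of (set, flag, run index), so one plan's seed
never influences another's draws.

## Indicator conventions

The modified Kempton's Q is computed over groups at TL ≥ 3, biomasses
ranked descending, with `R_L` the biomass at rank ⌈0.25·S⌉, `R_U` at rank
⌈0.75·S⌉ and natural logs: `Q = S / (2 ln(R_L/R_U))`. The quartile-rank and
log-base conventions vary across the literature; this one is fixed here
and used consistently by tests and pipeline. Q is undefined (NaN in
series) when fewer than 4 eligible groups exist or the quartile biomasses
coincide. Indicators are computed on annual biomass, not sub-daily states.

## Mortality decomposition

Applied background mortality per stage is the weighted distribution of
`m_L · T_corr` over all boxes × timesteps of one seasonal cycle (weights:
the stage's spatial distribution), annualised; quantiles use linear
interpolation on the weighted CDF. Realized Z comes from an OLS fit of log
proportions-at-age against age from the unfished run, excluding the plus
group (it accumulates survivors and violates pure decay) and dropping
zero-count ages; at least 3 usable ages are required. The forced proportion
applied-median/Z may exceed 1 — the temperature scaling makes the applied
rate only an approximation of the realized background component — and such
values are kept and flagged, not clipped.

## Stepwise GLM conventions

Response: CV^(1/3) (the cube root stabilises residual spread against
fitted values better than log or identity). Candidates: every single
attribute plus every unordered pairwise interaction, each treated as one
unit; interactions enter as bare products without forcing main effects in,
and interactions with the categorical run label expand over its levels
A–F. Selection greedily maximises the *null*-deviance fraction explained
and stops when the best increment is below 10%; ties break by enumeration
order and selected terms leave the candidate pool. Rows with missing
attribute values are dropped per fit. The final fit is a Gaussian
identity-link GLM (statsmodels); when a design is saturated the
coefficients come from least squares directly and Pearson residuals of an
(effectively) perfect fit are defined as zero. Variant candidate lists:
age-structured models see all 12 attributes; all-species and pool-only
models see only the attributes defined for every group (TL, primary
connections, lifespan, B0, run label), with the top-prey proportion
additionally excluded for pools because many pools are not predators.

Per-year fits cover every reporting year (116 over a 1900–2015 span);
years with degenerate frames are skipped but still counted as attempted.
Summary fits pool 1910–2015 by default, the window over which per-year
selections are roughly consistent.

## Problem sizes

The shipped analyses run at desk scale by choice: toy ecosystems of 3–8
age-structured groups and 2–3 pools, 1- to 5-day timesteps, 10–20 simulated
years and ensembles of 3–6 runs per label in the tests; the acceptance
script uses a 6-group ecosystem, 15 years, 32 runs. The structural
bookkeeping (55 groups, 361 variables, 57 scalars, 116 yearly fits) is
exact at full scale because it depends only on the fixture, not on
simulation length.

## Known limitations

- The surrogate's functional forms are the package's own; conclusions
  about which attributes explain stability transfer to real models only as
  a methodology, not as numbers.
- Realised diets under perturbation are recorded but not analysed.
- Keystoneness and responsiveness are carried as fixture data, not
  recomputed from the dynamics.
- Oceanographic bootstrapping and recruitment-parameter uncertainty are
  out of scope; initial conditions are the only perturbed axis.
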