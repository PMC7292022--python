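# initsens

**Initialisation-uncertainty analysis for end-to-end ecosystem models.**

Ecosystem models start from initial conditions — virgin numbers-at-age for
age-structured species groups, nitrogen (and silicate) biomass for pool
groups — that are never known exactly. `initsens` asks what that
uncertainty does to the model's dynamics: it perturbs the initial state,
runs an ensemble, and quantifies which species groups and which system-level
indicators keep the imprint of the perturbation and which forget it.

It is aimed at ecosystem modellers who want an uncertainty envelope around
multi-species simulation results rather than a single trajectory, and at
methodologists studying when complex food-web models are stable to their
starting point.

## What it computes

**Perturbation ensembles.** Three designs over the virgin state, each
crossed with a fishing on/off flag and labelled `ChaosAlt` A–F:

| Set | Labels | Design |
|-----|--------|--------|
| 1 | A / B | all groups share one scalar from {0.5, 0.8, 0.9, 0.95, 1.05, 1.1, 1.2, 1.5} |
| 2 | C / D | per-group multiplier 1 + s, s ~ N(0, σ), σ from the group's informance rating (1→0.025, 2→0.05, 3→0.1, 4→0.25) |
| 3 | E / F | only the top-10 keystone-ranked groups and all biomass pools, σ = 0.25 (central 95% ≈ ±0.5); everyone else untouched |

One scalar covers every age class of a group, so proportions-at-age — and
hence the implied natural mortality — are preserved exactly.

**Ecosystem indicators** per run and year: biomass-weighted mean trophic
level (MTL), modified Kempton's Q diversity index
`Q = S / (2 ln(R_L / R_U))` over groups at TL ≥ 3 (R_L, R_U the biomasses at
the descending ranks ⌈0.25 S⌉ and ⌈0.75 S⌉), and the pelagic-to-total
biomass ratio.

**Species-group characterization**: top-prey proportion, counts of
primary/secondary/tertiary trophic connections (1% consumption cut-off),
and the forced share of natural mortality — the applied background rate
m_L · T_corr with T_corr = 2^((T−15)/10), summarised over space and season,
divided by the realized total mortality Z fitted from unfished
proportions-at-age.

**Stability attribution.** Between-run biomass CVs per group, year and
label; cube-root-transformed CVs explained by stepwise Gaussian GLMs that
greedily add the single attribute or pairwise interaction explaining the
largest fraction of the null deviance, stopping below 10%. Fits run per
year (116 fits over a 1900–2015 span) and pooled (1910–2015), in three
variants: all groups, age-structured only, biomass pools only.

Because the original study's simulation engine is not desk-runnable, the
package ships a deterministic surrogate simulator (Holling II consumption,
temperature-scaled background mortality, Beverton–Holt recruitment,
plus-group ageing, a mid-1970s fishing ramp) that reproduces the *output
structure* the analysis consumes. A 55-group ecosystem fixture (37
age-structured groups with published keystone/informance ratings, 18
pools) drives the structural bookkeeping.

## Worked example

Enumerate the fixture's perturbable state:

```bash
$ initsens perturb --fixture --out demo --sets 1,2,3 --fishing both --n-runs 5 --seed 1
plans=36 variables=361 scalars=57 (age-structured 37) -> demo/manifest.json
```

361 variables (341 numbers-at-age entries + 18 pool nitrogen + 2 silicate)
collapse to 57 scalars because each age-structured group shares one scalar;
37 of the 57 belong to age-structured groups. 36 plans = 8 fixed scalars × 2
fishing flags + two stochastic sets × 5 runs × 2 flags.

Run the full pipeline on a toy ecosystem:

```bash
$ initsens all --toy 4,2 --years 1985:1999 --burn-in 3 --sets 1,2 \
      --fishing both --n-runs 4 --seed 1 --out demo2
runs=24 ok=24 models=['ALL', 'AS', 'AS_fished', 'AS_unfished', 'BP']
  ALL: terms=['ChaosAlt:Lifespan', 'ChaosAlt:B0'] r2=0.629
  AS: terms=['ChaosAlt:TL', 'ChaosAlt:propJuvM'] r2=0.577
  AS_fished: terms=['ChaosAlt:PropByTopPrey'] r2=0.267
  AS_unfished: terms=['ChaosAlt:propAdM', 'ChaosAlt:B0'] r2=0.627
  BP: terms=['ChaosAlt:B0'] r2=0.656
```

Each line is one pooled stepwise GLM: the ordered interaction terms it
selected and the cumulative fraction of null deviance explained. Here the
age-structured model's between-run CVs are best explained by how the
initial conditions were perturbed interacting with trophic level
(`ChaosAlt:TL`) — groups lower in the food web hold more of the
perturbation, and the perturbation design modulates how strongly. The
output directory also contains the ensemble manifest, annual biomass and
consumption ledgers (CSV + NetCDF), indicator series, attribute table, CV
tables, per-year selection summaries and Pearson residuals (see
`docs/data_dictionary.md`).

## Layout

- `src/initsens/config.py` — species groups, diets, environment, fixture loading
- `src/initsens/simulator.py` — the surrogate ecosystem simulator
- `src/initsens/perturbation.py` — perturbation sets, manifests, bookkeeping
- `src/initsens/indicators.py` — MTL, Kempton's Q, pelagic ratio
- `src/initsens/characterization.py` — per-group explanatory attributes
- `src/initsens/stability.py` — CV tables and stepwise GLM machinery
- `src/initsens/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
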