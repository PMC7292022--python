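# Data dictionary

Files written by `run_pipeline` / the `initsens all` CLI verb.

## manifest.json
Ensemble definition: `config_hash`, `master_seed`, and one record per plan
with `plan_id`, `set_id` (1–3), `chaos_alt` (A–F), `fishing_on`, `seed`,
`scalars` (group → multiplier) and `silicate_scalars`.

## scalars.csv
Run × group multiplier table (silicate columns suffixed ` (silicate)`).
Index: `plan_id`.

## attributes.csv
One row per species group; columns `Informance, TL, Keystone, Response,
NumL1cons, Lifespan, propAdM, propJuvM, B0, PropByTopPrey, Linf`. NaN where
an attribute is undefined for the group (e.g. stage mortality shares for
pools, top prey for non-predators).

## annual_biomass.csv
Long form: `run_id, year, group, biomass` (reporting years only, biomass in
model units summed over boxes).

## consumption.csv
Long-form ledger: `run_id, year, predator, prey, flow` — biomass of prey
consumed by predator over the year and whole region.

## trajectories.nc
NetCDF (scipy/NetCDF3 backend). Dims: `run, year, group, as_group,
age_class`. Variables: `biomass(run, year, group)`,
`numbers_at_age(run, year, as_group, age_class)`,
`weight_at_age(run, year, as_group, age_class)`. Attribute
`burn_in_years` marks how many leading years are burn-in.

## indicators.csv
`run_id, chaos_alt, year, indicator, value` with indicator one of
`mean_trophic_level`, `kemptons_q`, `pelagic_ratio`; NaN where undefined.

## cv_tables.csv
`chaos_alt, group, year, cv` — between-run CV of annual biomass across the
runs sharing that label.

## selection_summary_<MODEL>.csv
Per-year stepwise selections for model variant `<MODEL>` (`ALL`, `BP`,
`AS`, `AS_fished`, `AS_unfished`): `term, r2_min, r2_max, years_selected` —
the range of incremental null-deviance fractions and the number of years
(out of those fitted) the term was selected.

## summary_fit_<MODEL>.csv
Pooled-years stepwise fit: `term, incremental_r2, cumulative_r2` in
selection order.

## summary_coefficients_<MODEL>.csv
Final-fit coefficients, one row per design column (categorical levels
expanded, e.g. `ChaosAlt[C]:TL`).

## summary_residuals_<MODEL>.csv
`fitted, observed, pearson_residual` plus the design columns of the
selected terms, one row per frame row used in the pooled fit.

## log.jsonl
One JSON object per stage: `stage, seconds` plus stage-specific fields
(run counts, diverged run ids, model labels). Timings are the only
non-reproducible outputs.
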