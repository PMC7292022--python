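"""Desk-scale surrogate ecosystem simulator.

A deterministic, end-to-end multi-species simulator producing the output
structure a whole-of-ecosystem model produces — numbers-at-age and
weight-at-age for age-structured groups, nitrogen (and silicate) biomass for
pool groups, and a predator-to-prey consumption ledger — so that ensemble,
indicator and attribution analyses can run at desk scale. The functional
forms are deliberately simple and owned by this package:

* consumption: Holling type-II response over diet-availability-weighted prey
  biomass, with spatial overlap through box weights;
* predation applied as a multiplicative survival, never subtraction below
  zero, with removals capped at a fraction of local prey biomass per step
  (the ledger records the realized removals, so consumption and removal
  agree exactly);
* background (additional) linear mortality ``m_L`` per timestep, scaled by
  the temperature correction 2**((T-15)/10) of the local box temperature;
* growth from assimilated consumption (fixed assimilation efficiency) for
  consumers, logistic renewal for autotroph/detrital pools;
* fishing as catchability x effort on adults;
* annual ageing with a plus group, and Beverton-Holt recruitment from
  mature biomass.

All stochasticity lives upstream in the perturbation plans: the simulator is
bit-deterministic given its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AGE_STRUCTURED, EcosystemConfig, SpeciesGroupSpec

# fixed dynamical constants of the surrogate (see docs/methods.md)
MAX_INTAKE_PER_YEAR = 4.0     # maximum annual consumption per unit predator biomass
HALF_SATURATION = 1000.0      # available-prey biomass at half the maximum intake
ASSIMILATION_EFFICIENCY = 0.3
AUTOTROPH_GROWTH_PER_YEAR = 10.0
POOL_RENEWAL_PER_YEAR = 3.0   # intrinsic turnover of heterotroph pools
AUTOTROPH_CAPACITY_FACTOR = 2.0
BH_STEEPNESS = 0.75
MAX_PREY_REMOVAL_PER_STEP = 0.1   # cap on the fraction of a prey's local biomass
REFERENCE_TIMESTEP_HOURS = 12.0   # timestep at which m_L values are defined
SILICATE_TO_NITROGEN = 0.3


class SimulationError(RuntimeError):
    """Hard numerical failure (NaN/Inf) naming the group and timestep."""


def temperature_correction(temperature_c: float | np.ndarray) -> float | np.ndarray:
    """Temperature scaling of background mortality: 2**((T - 15) / 10).

    Equals 1 at the 15 degC base temperature, doubles every +10 degC and
    halves every -10 degC; strictly increasing and positive.
    """
    t = np.asarray(temperature_c, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    out = np.power(2.0, (t - 15.0) / 10.0)
    return float(out) if np.isscalar(temperature_c) or out.ndim == 0 else out


@dataclass
class ModelState:
    """Instantaneous simulator state.

    numbers_at_age: (n_age_structured, max_age_classes, n_boxes)
    weight_at_age:  (n_age_structured, max_age_classes) mass per individual
    pool_biomass:   (n_pools, n_boxes) nitrogen biomass
    pool_silicate:  (n_pools, n_boxes), zero for untracked pools
    """

    numbers_at_age: np.ndarray
    weight_at_age: np.ndarray
    pool_biomass: np.ndarray
    pool_silicate: np.ndarray
    time: int = 0

    def copy(self) -> "ModelState":
        return ModelState(
            self.numbers_at_age.copy(),
            self.weight_at_age.copy(),
            self.pool_biomass.copy(),
            self.pool_silicate.copy(),
            self.time,
        )


@dataclass
class ForcingSeries:
    """External forcing: fishing effort by simulated year and (optionally) a
    temperature realization per box and within-year step overriding the
    parametric field."""

    years: np.ndarray                      # all simulated years, burn-in included
    effort: np.ndarray                     # effort multiplier per year, >= 0
    temperature: np.ndarray | None = None  # (steps_per_year, n_boxes) annual cycle

    def __post_init__(self) -> None:
        if (np.asarray(self.effort) < 0).any():
            raise ValueError("fishing effort must be >= 0")


@dataclass
class Trajectory:
    """Per-run annual outputs: biomass, numbers-at-age, consumption ledger."""

    years: np.ndarray                 # simulated years (burn-in included)
    group_names: list[str]
    as_names: list[str]
    biomass: np.ndarray               # (n_years, n_groups) summed over boxes
    numbers_at_age: np.ndarray        # (n_years, n_as, max_ages) summed over boxes
    weight_at_age: np.ndarray         # (n_years, n_as, max_ages)
    consumption: np.ndarray           # (n_years, n_groups, n_groups) pred x prey
    burn_in_years: int
    fishing_on: bool
    plan_id: str = "base"
    status: str = "ok"                # 'ok' | 'diverged'
    failure_info: str | None = None

    @property
    def reporting_mask(self) -> np.ndarray:
        return np.arange(len(self.years)) >= self.burn_in_years

    @property
    def reporting_years(self) -> np.ndarray:
        return self.years[self.reporting_mask]

    def biomass_frame(self, reporting_only: bool = True) -> pd.DataFrame:
        mask = self.reporting_mask if reporting_only else slice(None)
        return pd.DataFrame(
            self.biomass[mask], index=self.years[mask], columns=self.group_names
        )

    def consumption_ledger(self, reporting_only: bool = True) -> pd.DataFrame:
        """Long-form ledger: year, predator, prey, flow (biomass consumed)."""
        idx = np.nonzero(self.reporting_mask)[0] if reporting_only else range(len(self.years))
        rows = []
        for i in idx:
            pred_i, prey_i = np.nonzero(self.consumption[i])
            for p, q in zip(pred_i, prey_i):
                rows.append(
                    (int(self.years[i]), self.group_names[p], self.group_names[q],
                     float(self.consumption[i, p, q]))
                )
        return pd.DataFrame(rows, columns=["year", "predator", "prey", "flow"])


def make_forcing(config: EcosystemConfig, fishing_on: bool) -> ForcingSeries:
    """Default forcing: zero effort before the fishery start year, then the
    configured ramp; parametric temperature."""
    first = config.start_year - config.burn_in_years
    years = np.arange(first, config.end_year + 1)
    if fishing_on:
        effort = np.array([config.fishery.effort(y) for y in years])
    else:
        effort = np.zeros(len(years))
    return ForcingSeries(years=years, effort=effort)


# ---------------------------------------------------------------------------
# initial state
# ---------------------------------------------------------------------------

def _reference_weights(group: SpeciesGroupSpec) -> np.ndarray:
    """Weight-at-age from a von Bertalanffy cubic length curve, scaled so the
    virgin age structure carries biomass b0 (done by the caller)."""
    n = group.n_age_classes
    k = 2.0 / n
    length = 1.0 - np.exp(-k * (np.arange(n) + 1.0))
    return length**3


def initial_state_from_config(config: EcosystemConfig) -> ModelState:
    """Virgin (unfished) state.

    Proportions-at-age follow exponential decay at the group's total
    mortality ``m_total`` (uniform when it is zero); total biomass of each
    group equals its virgin biomass b0; pools start at b0 spread over boxes
    by their spatial distribution.
    """
    as_groups = config.age_structured
    pools = config.pools
    n_boxes = config.n_boxes
    a_max = max((g.n_age_classes for g in as_groups), default=1)

    numbers = np.zeros((len(as_groups), a_max, n_boxes))
    weights = np.zeros((len(as_groups), a_max))
    env = config.environment
    for i, g in enumerate(as_groups):
        n = g.n_age_classes
        props = np.exp(-g.m_total * np.arange(n))
        props /= props.sum()
        w = _reference_weights(g)
        total_numbers = g.b0 / float(np.sum(props * w))
        n_at_age = total_numbers * props
        mat = g.maturity_age_class or max(1, n // 2)
        d_j = env.spatial_distribution[(g.name, "juvenile")]
        d_a = env.spatial_distribution[(g.name, "adult")]
        for a in range(n):
            dist = d_a if (a + 1) >= mat else d_j
            numbers[i, a] = n_at_age[a] * dist
        weights[i, :n] = w

    pool_b = np.zeros((len(pools), n_boxes))
    pool_si = np.zeros((len(pools), n_boxes))
    for k, g in enumerate(pools):
        pool_b[k] = g.b0 * env.spatial_distribution[(g.name, "adult")]
        if g.silicate_tracked:
            pool_si[k] = SILICATE_TO_NITROGEN * pool_b[k]
    return ModelState(numbers, weights, pool_b, pool_si)


# ---------------------------------------------------------------------------
# dynamics engine
# ---------------------------------------------------------------------------

class _Engine:
    """Precomputed arrays and the per-step update for one configuration."""

    def __init__(
        self,
        config: EcosystemConfig,
        *,
        enable_predation: bool = True,
        enable_recruitment: bool = True,
        enable_growth: bool = True,
    ):
        self.config = config
        self.enable_predation = enable_predation
        self.enable_recruitment = enable_recruitment
        self.enable_growth = enable_growth

        self.as_groups = config.age_structured
        self.pools = config.pools
        self.names = [g.name for g in self.as_groups] + [g.name for g in self.pools]
        self.n_as = len(self.as_groups)
        self.n_pool = len(self.pools)
        self.n_total = self.n_as + self.n_pool
        self.n_boxes = config.n_boxes
        self.a_max = max((g.n_age_classes for g in self.as_groups), default=1)
        self.spy = config.steps_per_year
        self.dt = 1.0 / self.spy
        # m_L values are defined per 12-h step; rescale if the step differs
        self.ml_scale = config.timestep_hours / REFERENCE_TIMESTEP_HOURS

        env = config.environment
        self.adult_mask = np.zeros((self.n_as, self.a_max), dtype=bool)
        self.age_mask = np.zeros((self.n_as, self.a_max), dtype=bool)
        for i, g in enumerate(self.as_groups):
            n = g.n_age_classes
            mat = g.maturity_age_class or max(1, n // 2)
            self.age_mask[i, :n] = True
            self.adult_mask[i, mat - 1 : n] = True
        self.juv_mask = self.age_mask & ~self.adult_mask

        # per-age m_L (per reference step) and catchability
        self.ml_age = np.zeros((self.n_as, self.a_max))
        self.q = np.array([g.catchability for g in self.as_groups])
        for i, g in enumerate(self.as_groups):
            self.ml_age[i, self.juv_mask[i]] = g.m_linear_juvenile
            self.ml_age[i, self.adult_mask[i]] = g.m_linear_adult
        self.ml_pool = np.array([g.m_linear_adult for g in self.pools])
        self.pool_autotroph = np.array(
            [(not g.is_predator) and g.trophic_level <= 1.0 for g in self.pools]
        )
        self.pool_capacity = np.stack(
            [
                AUTOTROPH_CAPACITY_FACTOR * g.b0 * env.spatial_distribution[(g.name, "adult")]
                for g in self.pools
            ]
        ) if self.n_pool else np.zeros((0, self.n_boxes))

        # predator entities: (group_global_index, stage, age submask or pool idx)
        diet_j = config.diet.stage("juvenile").to_numpy()
        diet_a = config.diet.stage("adult").to_numpy()
        order = [config.group_names.index(n) for n in self.names]
        diet_j = diet_j[np.ix_(order, order)]
        diet_a = diet_a[np.ix_(order, order)]

        ent_avail, ent_kind, ent_owner, ent_masks = [], [], [], []
        for i, g in enumerate(self.as_groups):
            if not g.is_predator:
                continue
            for stage, mask, diet in (("juvenile", self.juv_mask[i], diet_j),
                                      ("adult", self.adult_mask[i], diet_a)):
                if not mask.any():
                    continue
                ent_avail.append(diet[i])
                ent_kind.append("as")
                ent_owner.append(i)
                ent_masks.append(mask)
        for k, g in enumerate(self.pools):
            if not g.is_predator:
                continue
            ent_avail.append(diet_a[self.n_as + k])
            ent_kind.append("pool")
            ent_owner.append(k)
            ent_masks.append(None)
        self.ent_avail = np.array(ent_avail) if ent_avail else np.zeros((0, self.n_total))
        self.ent_kind = ent_kind
        self.ent_owner = ent_owner
        self.ent_masks = ent_masks
        self.n_ent = len(ent_kind)
        # map entity -> predator row in the group-level ledger
        self.ent_group = np.array(
            [o if k == "as" else self.n_as + o for k, o in zip(ent_kind, ent_owner)],
            dtype=int,
        )
        # selection matrices: entity biomass = sel_as @ (N*W).flat + sel_pool @ P
        self.sel_as = np.zeros((self.n_ent, self.n_as * self.a_max))
        self.sel_pool = np.zeros((self.n_ent, self.n_pool))
        for e in range(self.n_ent):
            if self.ent_kind[e] == "as":
                flat = np.zeros((self.n_as, self.a_max))
                flat[self.ent_owner[e]] = self.ent_masks[e]
                self.sel_as[e] = flat.ravel()
            else:
                self.sel_pool[e, self.ent_owner[e]] = 1.0

        # annual temperature cycle per (step-in-year, box)
        fracs = (np.arange(self.spy) + 0.5) / self.spy
        self.temp_cycle = np.stack([env.temperature(f) for f in fracs])

        # recruitment baselines from the virgin state
        virgin = initial_state_from_config(config)
        vb = virgin.numbers_at_age * virgin.weight_at_age[:, :, None]
        self.ssb0 = np.array(
            [vb[i][self.adult_mask[i]].sum() for i in range(self.n_as)]
        )
        self.r0 = virgin.numbers_at_age[:, 0, :].sum(axis=1)
        self.w_ref = virgin.weight_at_age.copy()
        self.recruit_dist = np.stack(
            [env.spatial_distribution[(g.name, "juvenile")] for g in self.as_groups]
        ) if self.n_as else np.zeros((0, self.n_boxes))
        self.b0_all = np.array([g.b0 for g in self.as_groups + self.pools])

    # -- helpers ---------------------------------------------------------
    def biomass_by_box(self, state: ModelState) -> np.ndarray:
        """(n_total, n_boxes) biomass of every group per box."""
        x = np.empty((self.n_total, self.n_boxes))
        b_as = (state.numbers_at_age * state.weight_at_age[:, :, None]).sum(axis=1)
        x[: self.n_as] = b_as
        x[self.n_as :] = state.pool_biomass
        return x

    def step(
        self, state: ModelState, step_index: int, effort: float,
        temperature: np.ndarray | None = None, inplace: bool = False,
    ) -> tuple[ModelState, np.ndarray]:
        """Advance one timestep; returns (new_state, group-level flow matrix)."""
        s = state if inplace else state.copy()
        step_in_year = step_index % self.spy
        temp = self.temp_cycle[step_in_year] if temperature is None else temperature
        tcorr = temperature_correction(temp)

        x = self.biomass_by_box(s)
        flows_groups = np.zeros((self.n_total, self.n_total))

        # (1)-(2) consumption + predation mortality
        intake_per_entity = np.zeros(self.n_ent)
        if self.enable_predation and self.n_ent:
            nw_flat = (s.numbers_at_age * s.weight_at_age[:, :, None]).reshape(
                self.n_as * self.a_max, self.n_boxes
            )
            pred_b = self.sel_as @ nw_flat + self.sel_pool @ s.pool_biomass
            avail_x = self.ent_avail[:, :, None] * x[None, :, :]    # (E,P,B)
            total_avail = avail_x.sum(axis=1)                        # (E,B)
            rate = MAX_INTAKE_PER_YEAR * pred_b * self.dt / (total_avail + HALF_SATURATION)
            flows = avail_x * rate[:, None, :]                       # (E,P,B)
            removal = flows.sum(axis=0)                              # (P,B)
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(
                    removal > 0,
                    np.minimum(1.0, MAX_PREY_REMOVAL_PER_STEP * x / np.where(removal > 0, removal, 1.0)),
                    1.0,
                )
            flows *= scale[None, :, :]
            removal = flows.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(x > 0, removal / np.where(x > 0, x, 1.0), 0.0)
            survival = 1.0 - frac
            # uniform across ages: preserves proportions-at-age within a step
            s.numbers_at_age *= survival[: self.n_as][:, None, :]
            s.pool_biomass *= survival[self.n_as :]
            flows_by_group = flows.sum(axis=2)                        # (E,P)
            np.add.at(flows_groups, self.ent_group, flows_by_group)
            intake_per_entity = flows_by_group.sum(axis=1)

        # (3) background linear mortality, temperature scaled
        surv_ml = np.exp(
            -self.ml_age[:, :, None] * self.ml_scale * tcorr[None, None, :]
        )
        s.numbers_at_age *= surv_ml
        if self.n_pool:
            s.pool_biomass *= np.exp(-self.ml_pool[:, None] * self.ml_scale * tcorr[None, :])

        # (4) growth
        if self.enable_growth:
            if self.n_as:
                nw_flat = (s.numbers_at_age * s.weight_at_age[:, :, None]).reshape(
                    self.n_as * self.a_max, self.n_boxes
                )
                stage_b = (self.sel_as @ nw_flat).sum(axis=1)         # (E,)
                with np.errstate(divide="ignore", invalid="ignore"):
                    fac_e = np.where(
                        stage_b > 0,
                        1.0
                        + ASSIMILATION_EFFICIENCY
                        * intake_per_entity
                        / np.where(stage_b > 0, stage_b, 1.0),
                        1.0,
                    )
                fac_e = np.minimum(fac_e, 1.02)
                # stage masks are disjoint per group, so factors combine additively
                fac_flat = 1.0 + self.sel_as.T @ (fac_e - 1.0)
                new_w = s.weight_at_age * fac_flat.reshape(self.n_as, self.a_max)
                s.weight_at_age = np.minimum(new_w, 3.0 * self.w_ref)
            if self.n_pool:
                # logistic renewal: full primary production for autotrophs, a
                # weaker intrinsic turnover for heterotroph pools (standing in
                # for production not resolved by the explicit food web)
                p = s.pool_biomass
                r = np.where(self.pool_autotroph, AUTOTROPH_GROWTH_PER_YEAR, POOL_RENEWAL_PER_YEAR)
                growth = r[:, None] * self.dt * p * (1.0 - p / self.pool_capacity)
                s.pool_biomass = np.maximum(p + growth, 0.0)
                gains = self.sel_pool.T @ (ASSIMILATION_EFFICIENCY * intake_per_entity)
                totals = s.pool_biomass.sum(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    pf = np.where(totals > 0, 1.0 + gains / np.where(totals > 0, totals, 1.0), 1.0)
                s.pool_biomass *= pf[:, None]

        # (5) fishing on adults
        if effort > 0:
            f = self.q[:, None, None] * effort * self.dt
            surv_f = np.where(self.adult_mask[:, :, None], np.exp(-f), 1.0)
            s.numbers_at_age *= surv_f

        s.time = state.time + 1
        return s, flows_groups

    def year_boundary(self, state: ModelState) -> ModelState:
        """Ageing (plus group) and Beverton-Holt recruitment."""
        s = state.copy()
        for i, g in enumerate(self.as_groups):
            n = g.n_age_classes
            if n >= 2:
                s.numbers_at_age[i, n - 1] += s.numbers_at_age[i, n - 2]
                s.numbers_at_age[i, 1 : n - 1] = state.numbers_at_age[i, 0 : n - 2]
                s.numbers_at_age[i, 0] = 0.0
            if self.enable_recruitment and self.ssb0[i] > 0:
                b = s.numbers_at_age[i] * s.weight_at_age[i][:, None]
                ssb = b[self.adult_mask[i]].sum()
                ratio = ssb / self.ssb0[i]
                h = BH_STEEPNESS
                rec = self.r0[i] * 4 * h * ratio / ((1 - h) + (5 * h - 1) * ratio)
                s.numbers_at_age[i, 0] = rec * self.recruit_dist[i]
        return s

    def check_health(self, state: ModelState, step_index: int) -> str | None:
        arrays = (state.numbers_at_age, state.weight_at_age, state.pool_biomass)
        for arr, label in zip(arrays, ("numbers_at_age", "weight_at_age", "pool_biomass")):
            if not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(arr))[0]
                name = self.names[bad[0]] if label != "weight_at_age" else self.as_groups[bad[0]].name
                raise SimulationError(
                    f"non-finite {label} for group {name!r} at timestep {step_index}"
                )
        totals = self.biomass_by_box(state).sum(axis=1)
        cap = self.config.biomass_cap_factor * self.b0_all
        over = totals > cap
        if over.any():
            return self.names[int(np.argmax(over))]
        return None


def step_dynamics(
    state: ModelState,
    config: EcosystemConfig,
    forcing: ForcingSeries | None = None,
    timestep: int = 0,
    **engine_flags,
) -> ModelState:
    """Advance the model by a single timestep (convenience wrapper).

    For multi-year runs use :func:`run_simulation`, which reuses the
    precomputed engine and records the consumption ledger.
    """
    engine = _Engine(config, **engine_flags)
    year_index = timestep // engine.spy
    if forcing is not None and year_index < len(forcing.effort):
        effort = float(forcing.effort[year_index])
    else:
        effort = 0.0
    new_state, _ = engine.step(state, timestep, effort)
    engine.check_health(new_state, timestep)
    return new_state


def run_simulation(
    config: EcosystemConfig,
    initial_state: ModelState | None = None,
    forcing: ForcingSeries | None = None,
    fishing_on: bool = False,
    plan_id: str = "base",
    *,
    enable_predation: bool = True,
    enable_recruitment: bool = True,
    enable_growth: bool = True,
) -> Trajectory:
    """Run burn-in plus reporting years and collect annual outputs.

    Deterministic: identical inputs give bit-identical trajectories. If any
    group's biomass exceeds ``config.biomass_cap_factor * b0`` the run is
    flagged 'diverged' and the partial trajectory is returned.
    """
    engine = _Engine(
        config,
        enable_predation=enable_predation,
        enable_recruitment=enable_recruitment,
        enable_growth=enable_growth,
    )
    if initial_state is None:
        initial_state = initial_state_from_config(config)
    if forcing is None:
        forcing = make_forcing(config, fishing_on)

    years = forcing.years
    n_years = len(years)
    n_total, n_as, a_max = engine.n_total, engine.n_as, engine.a_max
    biomass = np.zeros((n_years, n_total))
    numbers = np.zeros((n_years, n_as, a_max))
    weights = np.zeros((n_years, n_as, a_max))
    consumption = np.zeros((n_years, n_total, n_total))

    state = initial_state.copy()
    status, failure = "ok", None
    spy = engine.spy
    for yi in range(n_years):
        effort = float(forcing.effort[yi])
        for si in range(spy):
            step_index = yi * spy + si
            temp = forcing.temperature[si] if forcing.temperature is not None else None
            state, flows = engine.step(state, step_index, effort, temperature=temp, inplace=True)
            consumption[yi] += flows
        engine.check_health(state, yi * spy + spy - 1)
        state = engine.year_boundary(state)
        biomass[yi] = engine.biomass_by_box(state).sum(axis=1)
        numbers[yi] = state.numbers_at_age.sum(axis=2)
        weights[yi] = state.weight_at_age
        offender = engine.check_health(state, yi * spy + spy - 1)
        if offender is not None:
            status, failure = "diverged", f"biomass cap exceeded by {offender!r} in year {years[yi]}"
            biomass = biomass[: yi + 1]
            numbers = numbers[: yi + 1]
            weights = weights[: yi + 1]
            consumption = consumption[: yi + 1]
            years = years[: yi + 1]
            break

    return Trajectory(
        years=np.asarray(years),
        group_names=engine.names,
        as_names=[g.name for g in engine.as_groups],
        biomass=biomass,
        numbers_at_age=numbers,
        weight_at_age=weights,
        consumption=consumption,
        burn_in_years=config.burn_in_years,
        fishing_on=fishing_on,
        plan_id=plan_id,
        status=status,
        failure_info=failure,
    )
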