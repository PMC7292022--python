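"""Initial-condition perturbation schemes and ensemble bookkeeping.

Three ensemble designs perturb the virgin initial state, each crossed with a
fishing on/off flag and labelled A-F ("ChaosAlt"):

* **Set 1 (A/B, all up or down)** — every group's initial numbers (or pool
  biomass) multiplied by one shared scalar from the fixed list
  {0.5, 0.8, 0.9, 0.95, 1.05, 1.1, 1.2, 1.5}, spanning slight (+-5%) to
  extreme (+-50%) mis-specification.
* **Set 2 (C/D, by uncertainty)** — each group gets an independent
  multiplier 1 + s, s ~ N(0, sigma) with sigma set by its informance rating
  (1: 0.025, 2: 0.05, 3: 0.1, 4: 0.25); biomass pools are treated as poorly
  specified (sigma 0.25).
* **Set 3 (E/F, by keystoneness)** — only the top-10 keystone-ranked groups
  and all biomass pools are perturbed, with sigma 0.25 (central 95% interval
  of s approximately +-0.5); all other groups keep scalar exactly 1.

A single scalar applies to every age class of an age-structured group, so
proportions-at-age are preserved exactly; silicate-tracked pools carry an
independent scalar for their silicate content. Draws with s <= -0.9 are
redrawn so multipliers stay positive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import INFORMANCE_SIGMA, EcosystemConfig
from .simulator import ModelState

SET1_SCALARS = (0.5, 0.8, 0.9, 0.95, 1.05, 1.1, 1.2, 1.5)
KEYSTONE_TOP = 10
SET3_SIGMA = 0.25
REDRAW_FLOOR = -0.9

#: perturbation set x fishing flag -> ChaosAlt label
CHAOS_ALT = {(1, False): "A", (1, True): "B",
             (2, False): "C", (2, True): "D",
             (3, False): "E", (3, True): "F"}


@dataclass(frozen=True)
class PerturbationPlan:
    """One ensemble member: per-group multipliers plus provenance."""

    plan_id: str
    set_id: int
    chaos_alt: str
    fishing_on: bool
    scalars: dict[str, float]            # group -> multiplier (> 0)
    silicate_scalars: dict[str, float]   # silicate-tracked pool -> multiplier
    seed: int | None = None
    sigma_map: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in {**self.scalars, **self.silicate_scalars}.items():
            if s <= 0:
                raise ValueError(f"plan {self.plan_id}: scalar for {name!r} must be > 0")
        expected = CHAOS_ALT[(self.set_id, self.fishing_on)]
        if self.chaos_alt != expected:
            raise ValueError(
                f"plan {self.plan_id}: chaos_alt {self.chaos_alt!r} inconsistent with "
                f"set {self.set_id} / fishing={self.fishing_on} (expected {expected!r})"
            )


@dataclass(frozen=True)
class EnsembleManifest:
    """Ordered plans plus the master seed and a config fingerprint."""

    plans: tuple[PerturbationPlan, ...]
    config_hash: str
    master_seed: int | None

    def __post_init__(self) -> None:
        ids = [p.plan_id for p in self.plans]
        if len(set(ids)) != len(ids):
            raise ValueError("plan ids must be unique")

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "master_seed": self.master_seed,
                "plans": [
                    {
                        "plan_id": p.plan_id,
                        "set_id": p.set_id,
                        "chaos_alt": p.chaos_alt,
                        "fishing_on": p.fishing_on,
                        "seed": p.seed,
                        "scalars": p.scalars,
                        "silicate_scalars": p.silicate_scalars,
                    }
                    for p in self.plans
                ],
            },
            indent=2,
            sort_keys=True,
        )

    def scalar_table(self) -> pd.DataFrame:
        """Run x group multiplier table (silicate columns suffixed)."""
        rows = {}
        for p in self.plans:
            row = dict(p.scalars)
            row.update({f"{k} (silicate)": v for k, v in p.silicate_scalars.items()})
            rows[p.plan_id] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def config_fingerprint(config: EcosystemConfig) -> str:
    payload = json.dumps(
        [(g.name, g.structure, g.n_age_classes, g.informance, g.keystone_rank)
         for g in config.groups]
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def count_perturbable(config: EcosystemConfig) -> tuple[int, int, int]:
    """(n_variables, n_scalars, n_scalars_age_structured).

    Variables are the individually perturbable state entries: one per age
    class of each age-structured group, one nitrogen entry per pool, plus
    one silicate entry per silicate-tracked pool. Scalars count one shared
    multiplier per age-structured group, one per pool nitrogen and one per
    silicate variable.
    """
    n_as = len(config.age_structured)
    n_ages = sum(g.n_age_classes for g in config.age_structured)
    n_pools = len(config.pools)
    n_sil = sum(1 for g in config.pools if g.silicate_tracked)
    n_variables = n_ages + n_pools + n_sil
    n_scalars = n_as + n_pools + n_sil
    return n_variables, n_scalars, n_as


# ---------------------------------------------------------------------------
# plan generation
# ---------------------------------------------------------------------------

def _uniform_plan(config, scalar, set_id, fishing_on, plan_id, seed=None, sigma_map=None):
    scalars = {g.name: float(scalar) for g in config.groups}
    sil = {g.name: float(scalar) for g in config.pools if g.silicate_tracked}
    return PerturbationPlan(
        plan_id=plan_id,
        set_id=set_id,
        chaos_alt=CHAOS_ALT[(set_id, fishing_on)],
        fishing_on=fishing_on,
        scalars=scalars,
        silicate_scalars=sil,
        seed=seed,
        sigma_map=sigma_map or {},
    )


def set1_plans(config: EcosystemConfig, fishing_on: bool) -> list[PerturbationPlan]:
    """One plan per fixed scalar, shared by every group."""
    alt = CHAOS_ALT[(1, fishing_on)]
    return [
        _uniform_plan(config, s, 1, fishing_on, plan_id=f"set1-{alt}-x{s:g}")
        for s in SET1_SCALARS
    ]


def draw_multiplier(rng: np.random.Generator, sigma: float) -> float:
    """1 + s with s ~ N(0, sigma), redrawn until s > REDRAW_FLOOR."""
    while True:
        s = rng.normal(0.0, sigma)
        if s > REDRAW_FLOOR:
            return 1.0 + s


def _run_seed(master_seed: int, set_id: int, fishing_on: bool, run: int) -> int:
    """Stable per-run seed below 2**31 derived from the master seed."""
    key = f"{master_seed}:{set_id}:{int(fishing_on)}:{run}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def set2_plans(
    config: EcosystemConfig, n_runs: int, fishing_on: bool, master_seed: int
) -> list[PerturbationPlan]:
    """Uncertainty-based plans: sigma from each group's informance rating."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    alt = CHAOS_ALT[(2, fishing_on)]
    plans = []
    for r in range(n_runs):
        seed = _run_seed(master_seed, 2, fishing_on, r)
        rng = np.random.default_rng(seed)
        scalars, sil = {}, {}
        for g in config.groups:
            sigma = INFORMANCE_SIGMA[4] if not g.is_age_structured else INFORMANCE_SIGMA[g.informance]
            scalars[g.name] = draw_multiplier(rng, sigma)
        for g in config.pools:
            if g.silicate_tracked:
                sil[g.name] = draw_multiplier(rng, INFORMANCE_SIGMA[4])
        plans.append(
            PerturbationPlan(
                plan_id=f"set2-{alt}-r{r:03d}",
                set_id=2,
                chaos_alt=alt,
                fishing_on=fishing_on,
                scalars=scalars,
                silicate_scalars=sil,
                seed=seed,
                sigma_map=dict(INFORMANCE_SIGMA),
            )
        )
    return plans


def set3_plans(
    config: EcosystemConfig, n_runs: int, fishing_on: bool, master_seed: int
) -> list[PerturbationPlan]:
    """Keystone-based plans: top-10 keystone groups and all pools perturbed
    with sigma 0.25; every other group keeps scalar exactly 1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    missing = [g.name for g in config.age_structured if g.keystone_rank is None]
    if missing:
        raise ValueError(f"age-structured groups lack keystone ranks: {missing}")
    alt = CHAOS_ALT[(3, fishing_on)]
    plans = []
    for r in range(n_runs):
        seed = _run_seed(master_seed, 3, fishing_on, r)
        rng = np.random.default_rng(seed)
        scalars, sil = {}, {}
        for g in config.groups:
            perturb = (not g.is_age_structured) or (g.keystone_rank <= KEYSTONE_TOP)
            scalars[g.name] = draw_multiplier(rng, SET3_SIGMA) if perturb else 1.0
        for g in config.pools:
            if g.silicate_tracked:
                sil[g.name] = draw_multiplier(rng, SET3_SIGMA)
        plans.append(
            PerturbationPlan(
                plan_id=f"set3-{alt}-r{r:03d}",
                set_id=3,
                chaos_alt=alt,
                fishing_on=fishing_on,
                scalars=scalars,
                silicate_scalars=sil,
                seed=seed,
                sigma_map={"all": SET3_SIGMA},
            )
        )
    return plans


def build_manifest(
    config: EcosystemConfig,
    sets: tuple[int, ...] = (1, 2, 3),
    fishing: str = "both",
    n_runs: int = 20,
    master_seed: int = 0,
) -> EnsembleManifest:
    """Assemble the full ensemble for the requested sets and fishing modes."""
    flags = {"on": (True,), "off": (False,), "both": (False, True)}[fishing]
    plans: list[PerturbationPlan] = []
    for set_id in sets:
        for flag in flags:
            if set_id == 1:
                plans.extend(set1_plans(config, flag))
            elif set_id == 2:
                plans.extend(set2_plans(config, n_runs, flag, master_seed))
            elif set_id == 3:
                plans.extend(set3_plans(config, n_runs, flag, master_seed))
            else:
                raise ValueError(f"unknown perturbation set: {set_id}")
    return EnsembleManifest(
        plans=tuple(plans),
        config_hash=config_fingerprint(config),
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def apply_plan(
    initial_state: ModelState, plan: PerturbationPlan, config: EcosystemConfig
) -> ModelState:
    """Scale the virgin state by the plan's multipliers.

    Numbers-at-age of each age-structured group are multiplied by its single
    scalar (all age classes equally, so the age composition is untouched);
    pool nitrogen and, where tracked, silicate are multiplied by their own
    scalars. Weight-at-age is never perturbed.
    """
    missing = [g.name for g in config.groups if g.name not in plan.scalars]
    if missing:
        raise ValueError(f"plan {plan.plan_id} lacks scalars for: {missing}")
    state = initial_state.copy()
    for i, g in enumerate(config.age_structured):
        state.numbers_at_age[i] *= plan.scalars[g.name]
    for k, g in enumerate(config.pools):
        state.pool_biomass[k] *= plan.scalars[g.name]
        if g.silicate_tracked:
            state.pool_silicate[k] *= plan.silicate_scalars.get(g.name, plan.scalars[g.name])
    return state
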