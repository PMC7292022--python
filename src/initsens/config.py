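"""Ecosystem configuration: species groups, diets, environment, fishery.

The configuration layer encodes a multi-species ecosystem the way whole-of-
ecosystem simulators describe one: a list of species groups (either
age-structured, tracked as numbers-at-age and weight-at-age, or biomass
pools tracked as a single nitrogen mass), a diet-availability matrix, a
spatially and seasonally varying temperature environment over a small set of
boxes, and a fishery with per-group catchability.

Two entry points build configurations:

* :func:`load_chatham_fixture` — a deep-sea shelf ecosystem with 37
  age-structured groups and 18 biomass pools (55 groups total), carrying the
  published keystone ranks and informance ratings; all quantities not
  published for that system (age-class counts, trophic levels, virgin
  biomasses, background mortality, diets) are plausible values stored in a
  versioned fixture file shipped with the package.
* :func:`make_toy_config` — small reproducible configurations for fast tests
  and desk-scale ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

AGE_STRUCTURED = "age-structured"
BIOMASS_POOL = "biomass-pool"
STAGES = ("juvenile", "adult")

#: informance rating (1 = best informed .. 4 = poorly specified) -> the
#: perturbation standard deviation used by the uncertainty-based ensemble set.
INFORMANCE_SIGMA = {1: 0.025, 2: 0.05, 3: 0.1, 4: 0.25}


@dataclass(frozen=True)
class SpeciesGroupSpec:
    """Static description of one species group.

    ``m_linear_adult`` / ``m_linear_juvenile`` are the linear additional
    (background) mortality rates applied per 12-hour timestep; the simulator
    rescales them when run at a different step. ``m_total`` is the annual
    total mortality Z shaping the virgin exponential-decay age structure.
    Biomass is in abstract model units throughout (all downstream statistics
    are unit-free ratios, CVs and ranks).
    """

    name: str
    structure: str
    trophic_level: float
    informance: int
    b0: float
    n_age_classes: int | None = None
    keystone_rank: int | None = None
    responsiveness_rank: int | None = None
    lifespan_years: float | None = None
    linf_cm: float | None = None
    m_linear_adult: float = 0.0
    m_linear_juvenile: float = 0.0
    m_total: float = 0.3
    maturity_age_class: int | None = None
    is_pelagic_fish: bool = False
    is_predator: bool = True
    silicate_tracked: bool = False
    migrates: bool = False
    catchability: float = 0.0
    depth_affinity: float = 0.0

    @property
    def is_age_structured(self) -> bool:
        return self.structure == AGE_STRUCTURED


@dataclass(frozen=True)
class DietMatrix:
    """Per-life-stage prey availability weights, predator rows x prey columns.

    Pools that predate use their 'adult' row; non-predators have all-zero
    rows. Availabilities are relative weights, not realized diet fractions —
    realized diets emerge from prey abundance and spatial overlap in the
    simulator.
    """

    availability: Mapping[str, pd.DataFrame]

    def stage(self, stage: str) -> pd.DataFrame:
        return self.availability[stage]


@dataclass(frozen=True)
class EnvironmentSpec:
    """Parametric temperature field and per-group spatial distributions.

    Temperature in box b at year-fraction f is
    ``mean + box_offsets[b] + amplitude * sin(2*pi*f)`` (deg C), so the
    applied background mortality genuinely varies spatially and temporally.
    ``spatial_distribution[(group, stage)]`` are box weights summing to 1.
    """

    mean_temperature_c: float
    seasonal_amplitude_c: float
    box_offsets_c: tuple[float, ...]
    spatial_distribution: Mapping[tuple[str, str], np.ndarray]

    @property
    def n_boxes(self) -> int:
        return len(self.box_offsets_c)

    def temperature(self, year_fraction: float) -> np.ndarray:
        """Temperature per box at the given fraction of the year."""
        seasonal = self.seasonal_amplitude_c * math.sin(2.0 * math.pi * year_fraction)
        return self.mean_temperature_c + np.asarray(self.box_offsets_c) + seasonal


@dataclass(frozen=True)
class FisherySpec:
    """Fishing regime: effort 0 before ``start_year``, linear ramp to 1 over
    ``ramp_years``, then constant. Heavy fishing establishing in the
    mid-1970s is the default."""

    start_year: int = 1975
    ramp_years: int = 5

    def effort(self, year: float) -> float:
        if year < self.start_year:
            return 0.0
        if self.ramp_years <= 0:
            return 1.0
        return min(1.0, (year - self.start_year) / self.ramp_years)


@dataclass(frozen=True)
class EcosystemConfig:
    """A complete, runnable ecosystem description."""

    name: str
    groups: tuple[SpeciesGroupSpec, ...]
    diet: DietMatrix
    environment: EnvironmentSpec
    fishery: FisherySpec
    timestep_hours: float = 12.0
    start_year: int = 1900
    end_year: int = 2015
    burn_in_years: int = 35
    biomass_cap_factor: float = 1e3

    def __post_init__(self) -> None:
        problems = validate_config(self)
        if problems:
            raise ValueError("invalid EcosystemConfig:\n" + "\n".join(problems))

    # -- lookups ----------------------------------------------------------
    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def age_structured(self) -> list[SpeciesGroupSpec]:
        return [g for g in self.groups if g.is_age_structured]

    @property
    def pools(self) -> list[SpeciesGroupSpec]:
        return [g for g in self.groups if not g.is_age_structured]

    @property
    def n_boxes(self) -> int:
        return self.environment.n_boxes

    @property
    def steps_per_year(self) -> int:
        return max(1, round(8760.0 / self.timestep_hours))

    @property
    def reporting_years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))

    def group(self, name: str) -> SpeciesGroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"unknown species group: {name!r}")

    def with_timestep(self, hours: float) -> "EcosystemConfig":
        return replace(self, timestep_hours=hours)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_config(config: EcosystemConfig) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the configuration is valid. Each message names the
    offending group and the rule it breaks.
    """
    problems: list[str] = []
    names = [g.name for g in config.groups]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        problems.append(f"duplicate group names: {dupes}")

    for g in config.groups:
        if g.structure not in (AGE_STRUCTURED, BIOMASS_POOL):
            problems.append(f"{g.name}: unknown structure {g.structure!r}")
            continue
        if g.is_age_structured:
            if g.n_age_classes is None or not (2 <= g.n_age_classes <= 10):
                problems.append(
                    f"{g.name}: age-structured groups need 2 <= n_age_classes <= 10, "
                    f"got {g.n_age_classes}"
                )
            if g.silicate_tracked:
                problems.append(f"{g.name}: silicate_tracked is only valid for biomass pools")
            if g.maturity_age_class is not None and g.n_age_classes is not None:
                if not (1 <= g.maturity_age_class <= g.n_age_classes):
                    problems.append(f"{g.name}: maturity_age_class out of range")
        else:
            if g.n_age_classes is not None:
                problems.append(f"{g.name}: biomass pools must not define n_age_classes")
        if g.informance not in (1, 2, 3, 4):
            problems.append(f"{g.name}: informance must be in 1..4, got {g.informance}")
        if g.b0 <= 0:
            problems.append(f"{g.name}: b0 must be > 0")
        if g.trophic_level < 1:
            problems.append(f"{g.name}: trophic_level must be >= 1")
        if g.m_linear_adult < 0 or g.m_linear_juvenile < 0:
            problems.append(f"{g.name}: linear mortality m_L must be >= 0")
        if g.keystone_rank is not None and g.keystone_rank < 1:
            problems.append(f"{g.name}: keystone_rank must be a positive integer")

    # diet dimensions and predator rows
    for stage in STAGES:
        av = config.diet.stage(stage)
        if list(av.index) != names or list(av.columns) != names:
            problems.append(f"diet[{stage}]: rows/columns must match the group list")
            continue
        if (av.to_numpy() < 0).any():
            problems.append(f"diet[{stage}]: availabilities must be >= 0")
        for g in config.groups:
            if not g.is_predator and av.loc[g.name].to_numpy().sum() > 0:
                problems.append(f"{g.name}: non-predator has a nonzero diet row ({stage})")

    # environment
    env = config.environment
    if not np.all(np.isfinite(np.asarray(env.box_offsets_c))):
        problems.append("environment: box temperature offsets must be finite")
    for g in config.groups:
        for stage in STAGES:
            w = np.asarray(env.spatial_distribution.get((g.name, stage)))
            if w is None or w.shape != (env.n_boxes,):
                problems.append(f"{g.name}: missing spatial distribution for stage {stage}")
            elif not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-8):
                problems.append(
                    f"{g.name}: spatial weights for {stage} sum to {w.sum():.4f}, not 1"
                )
            elif (w < 0).any():
                problems.append(f"{g.name}: spatial weights for {stage} must be >= 0")

    if config.timestep_hours <= 0:
        problems.append("timestep_hours must be > 0")
    if config.end_year < config.start_year:
        problems.append("end_year before start_year")
    if config.burn_in_years < 0:
        problems.append("burn_in_years must be >= 0")
    return problems


# ---------------------------------------------------------------------------
# derived structure: diets and spatial distributions
# ---------------------------------------------------------------------------

def build_diet_from_trophic_levels(groups: tuple[SpeciesGroupSpec, ...]) -> DietMatrix:
    """Derive diet availabilities from trophic levels by a fixed kernel rule.

    A predator of trophic level TL is offered prey with trophic level in
    [TL - 2.5, TL - 0.3], weighted by a Gaussian kernel centred one level
    below the predator (0.7 below for juveniles, which feed lower). Rows are
    normalized to sum to 1 for predators; non-predators get all-zero rows.
    The rule is deterministic: the same group list always yields the same
    matrix.
    """
    names = [g.name for g in groups]
    tl = np.array([g.trophic_level for g in groups])
    mats: dict[str, pd.DataFrame] = {}
    for stage, offset in (("juvenile", 0.7), ("adult", 1.0)):
        a = np.zeros((len(groups), len(groups)))
        for i, pred in enumerate(groups):
            if not pred.is_predator:
                continue
            gap = pred.trophic_level - tl  # positive when prey is below predator
            w = np.exp(-0.5 * ((gap - offset) / 0.5) ** 2)
            w[(gap < 0.3) | (gap > 2.5)] = 0.0
            w[i] = 0.0  # no self-predation
            total = w.sum()
            if total > 0:
                a[i] = w / total
        mats[stage] = pd.DataFrame(a, index=names, columns=names)
    return DietMatrix(availability=mats)


def build_spatial_distribution(
    groups: tuple[SpeciesGroupSpec, ...], n_boxes: int
) -> dict[tuple[str, str], np.ndarray]:
    """Box weights from each group's depth_affinity by a softmax gradient.

    Boxes are ordered shallow to deep; a positive affinity skews a group
    deep, negative skews it shallow. Juveniles sit half a unit shallower
    than adults. Weights sum to 1 by construction.
    """
    grad = np.linspace(-1.0, 1.0, n_boxes)
    out: dict[tuple[str, str], np.ndarray] = {}
    for g in groups:
        for stage, shift in (("juvenile", -0.5), ("adult", 0.0)):
            z = (g.depth_affinity + shift) * grad
            w = np.exp(z - z.max())
            out[(g.name, stage)] = w / w.sum()
    return out


# ---------------------------------------------------------------------------
# fixture loading
# ---------------------------------------------------------------------------

_FIXTURE_PACKAGE = "initsens.fixtures"


def load_chatham_fixture() -> EcosystemConfig:
    """Load the 55-group deep-sea shelf ecosystem fixture.

    The fixture carries the 37 age-structured groups (with their published
    keystone ranks 1-37 and informance ratings) and 18 biomass pools, of
    which diatoms and microphytobenthos additionally track silicate. The
    call is pure: repeated loads return identical configurations.
    """
    text = resources.files(_FIXTURE_PACKAGE).joinpath("chatham.yaml").read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - corrupt install
        raise ValueError(f"fixture file is not valid YAML: {exc}") from exc
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> EcosystemConfig:
    """Build a validated config from a fixture/user dictionary (YAML form)."""
    groups = []
    for rec in raw["groups"]:
        try:
            groups.append(SpeciesGroupSpec(**rec))
        except TypeError as exc:
            raise ValueError(f"bad group record {rec.get('name', '<unnamed>')!r}: {exc}") from exc
    groups = tuple(groups)

    env_raw = raw.get("environment", {})
    n_boxes = int(raw.get("n_boxes", 4))
    offsets = env_raw.get("box_offsets_c")
    if offsets is None:
        offsets = list(np.linspace(1.5, -1.5, n_boxes))
    env = EnvironmentSpec(
        mean_temperature_c=float(env_raw.get("mean_temperature_c", 11.0)),
        seasonal_amplitude_c=float(env_raw.get("seasonal_amplitude_c", 2.0)),
        box_offsets_c=tuple(float(x) for x in offsets),
        spatial_distribution=build_spatial_distribution(groups, len(offsets)),
    )
    fish_raw = raw.get("fishery", {})
    fishery = FisherySpec(
        start_year=int(fish_raw.get("start_year", 1975)),
        ramp_years=int(fish_raw.get("ramp_years", 5)),
    )
    return EcosystemConfig(
        name=str(raw.get("name", "unnamed")),
        groups=groups,
        diet=build_diet_from_trophic_levels(groups),
        environment=env,
        fishery=fishery,
        timestep_hours=float(raw.get("timestep_hours", 12.0)),
        start_year=int(raw.get("start_year", 1900)),
        end_year=int(raw.get("end_year", 2015)),
        burn_in_years=int(raw.get("burn_in_years", 35)),
    )


# ---------------------------------------------------------------------------
# toy configurations
# ---------------------------------------------------------------------------

def make_toy_config(
    n_age_structured: int,
    n_pools: int,
    seed: int,
    *,
    n_age_classes: int = 4,
    n_boxes: int = 3,
    timestep_hours: float = 24.0,
    start_year: int = 1960,
    end_year: int = 2000,
    burn_in_years: int = 10,
    with_silicate: bool = False,
) -> EcosystemConfig:
    """Small, valid, reproducible configuration for fast experiments.

    Trophic levels span 2.2..4.6 for age-structured groups; the first pool is
    an autotroph (TL 1) so the food web has a base. The highest-TL group is
    fished. Same seed, same arguments -> identical config.
    """
    if n_age_structured < 1 or n_pools < 1:
        raise ValueError("need at least one age-structured group and one pool")
    rng = np.random.default_rng(seed)
    groups: list[SpeciesGroupSpec] = []
    tls = np.linspace(4.6, 2.2, n_age_structured)
    for i in range(n_age_structured):
        tl = float(tls[i])
        groups.append(
            SpeciesGroupSpec(
                name=f"fish_{i + 1}",
                structure=AGE_STRUCTURED,
                n_age_classes=n_age_classes,
                trophic_level=tl,
                keystone_rank=i + 1,
                responsiveness_rank=n_age_structured - i,
                informance=int(rng.integers(1, 5)),
                lifespan_years=float(10 + 5 * i),
                linf_cm=float(40 + 20 * i),
                b0=float(rng.uniform(50.0, 200.0)),
                m_linear_adult=float(rng.uniform(0.5, 2.0) * 1e-4),
                m_linear_juvenile=float(rng.uniform(0.5, 2.0) * 1e-4),
                m_total=float(rng.uniform(0.2, 0.5)),
                maturity_age_class=max(1, n_age_classes // 2),
                is_pelagic_fish=(i == n_age_structured - 1),
                is_predator=True,
                catchability=(0.3 if i == 0 else 0.0),
                depth_affinity=float(rng.uniform(-1, 1)),
            )
        )
    pool_tls = np.linspace(1.0, 2.0, n_pools)
    for j in range(n_pools):
        tl = float(pool_tls[j])
        groups.append(
            SpeciesGroupSpec(
                name=f"pool_{j + 1}",
                structure=BIOMASS_POOL,
                trophic_level=tl,
                informance=4,
                lifespan_years=(2.0 if tl > 1.5 else 0.5),
                b0=float(rng.uniform(300.0, 800.0)),
                m_linear_adult=float(rng.uniform(0.5, 2.0) * 1e-4),
                m_linear_juvenile=float(rng.uniform(0.5, 2.0) * 1e-4),
                is_predator=tl > 1.5,
                silicate_tracked=(with_silicate and j == 0),
                depth_affinity=float(rng.uniform(-1, 1)),
            )
        )
    groups_t = tuple(groups)
    env = EnvironmentSpec(
        mean_temperature_c=11.0,
        seasonal_amplitude_c=2.0,
        box_offsets_c=tuple(np.linspace(1.5, -1.5, n_boxes)),
        spatial_distribution=build_spatial_distribution(groups_t, n_boxes),
    )
    return EcosystemConfig(
        name=f"toy-{n_age_structured}as-{n_pools}bp-seed{seed}",
        groups=groups_t,
        diet=build_diet_from_trophic_levels(groups_t),
        environment=env,
        fishery=FisherySpec(start_year=(start_year + end_year) // 2, ramp_years=3),
        timestep_hours=timestep_hours,
        start_year=start_year,
        end_year=end_year,
        burn_in_years=burn_in_years,
    )
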