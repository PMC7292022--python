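"""Per-group attributes offered to the stability GLMs.

From an unfished base run this module derives, for every species group, the
explanatory-variable vector used downstream: informance, trophic level,
keystone and responsiveness ranks, number of primary trophic connections,
lifespan, the forced share of natural mortality for adults and juveniles,
virgin biomass B0, the proportion of diet from the single top prey, and
maximum length.

The forced-mortality decomposition compares the *applied* background
mortality (the per-step linear rate m_L scaled by the local temperature
correction, summarised over boxes and timesteps weighted by the stage's
spatial distribution) with the *realized* total mortality Z estimated by
fitting exponential decay to the unfished proportions-at-age. Because the
temperature scaling makes the applied rate only approximately the realized
background rate, the forced proportion can exceed 1; such values are kept
and flagged rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .config import EcosystemConfig
from .simulator import REFERENCE_TIMESTEP_HOURS, Trajectory, temperature_correction

CONNECTION_CUTOFF = 0.01

#: canonical explanatory-variable columns (plus group name)
ATTRIBUTE_COLUMNS = [
    "Informance", "TL", "Keystone", "Response", "NumL1cons", "Lifespan",
    "propAdM", "propJuvM", "B0", "PropByTopPrey", "Linf",
]


@dataclass(frozen=True)
class MortalityDecomposition:
    """Applied vs realized mortality for one group (annualized rates)."""

    applied_adult: dict[str, float]     # quantile summary, keys q025..q975
    applied_juvenile: dict[str, float]
    realized_z: float
    prop_adult_forced: float
    prop_juvenile_forced: float
    weighted_forced: float
    exceeds_one: bool


# ---------------------------------------------------------------------------
# diet-derived attributes
# ---------------------------------------------------------------------------

def _total_flows(ledger: pd.DataFrame) -> pd.DataFrame:
    """Predator x prey total consumption summed over years (and boxes)."""
    return ledger.pivot_table(
        index="predator", columns="prey", values="flow", aggfunc="sum", fill_value=0.0
    )


def top_prey_proportion(ledger: pd.DataFrame, predator: str) -> float | None:
    """Largest single-prey share of the predator's summed consumption.

    Flows are summed over the whole region and all reporting years first, so
    a predator alternating between two prey looks the same as one eating
    both steadily. Returns None for groups with no consumption (non-
    predators have no defined value).
    """
    flows = ledger.loc[ledger["predator"] == predator, ["prey", "flow"]]
    total = flows["flow"].sum()
    if total <= 0:
        return None
    by_prey = flows.groupby("prey")["flow"].sum()
    return float(by_prey.max() / total)


def connection_graph(ledger: pd.DataFrame, cutoff: float = CONNECTION_CUTOFF) -> nx.Graph:
    """Undirected trophic graph with negligible links removed.

    An edge joins predator and prey iff the prey makes up at least ``cutoff``
    of the predator's total consumption, or the predator applies at least
    ``cutoff`` of the prey's total predation losses.
    """
    totals = _total_flows(ledger)
    g = nx.Graph()
    g.add_nodes_from(totals.index)
    g.add_nodes_from(totals.columns)
    pred_totals = totals.sum(axis=1)
    prey_totals = totals.sum(axis=0)
    for pred in totals.index:
        for prey in totals.columns:
            flow = totals.loc[pred, prey]
            if flow <= 0:
                continue
            diet_share = flow / pred_totals[pred] if pred_totals[pred] > 0 else 0.0
            loss_share = flow / prey_totals[prey] if prey_totals[prey] > 0 else 0.0
            if diet_share >= cutoff or loss_share >= cutoff:
                g.add_edge(pred, prey)
    return g


def trophic_connection_counts(
    ledger: pd.DataFrame, group: str, cutoff: float = CONNECTION_CUTOFF,
    graph: nx.Graph | None = None,
) -> tuple[int, int, int]:
    """(primary, secondary, tertiary) connection counts at exact distances.

    Primary connections are groups at graph distance exactly 1, secondary at
    exactly 2, tertiary at exactly 3 — each excluding nodes already counted
    at a shorter distance and the focal group itself.
    """
    g = connection_graph(ledger, cutoff) if graph is None else graph
    if group not in g:
        raise KeyError(f"group {group!r} not present in the consumption ledger")
    dists = nx.single_source_shortest_path_length(g, group, cutoff=3)
    counts = [0, 0, 0]
    for node, d in dists.items():
        if 1 <= d <= 3:
            counts[d - 1] += 1
    return tuple(counts)


# ---------------------------------------------------------------------------
# mortality decomposition
# ---------------------------------------------------------------------------

def _weighted_quantiles(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    """Weighted quantiles with linear interpolation on the weighted CDF."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) - 0.5 * w
    cdf /= w.sum()
    return np.interp(qs, cdf, v)


def applied_additional_mortality(
    group: str, stage: str, config: EcosystemConfig
) -> dict[str, float]:
    """Quantile summary of the annualized applied background mortality.

    The applied rate in box b at time t is m_L * T_corr(T(b, t)); its
    distribution over all boxes and timesteps of one seasonal cycle is
    weighted by the stage's spatial distribution and annualized by the
    number of steps per year. Keys: q025, q25, q50, q75, q975.
    """
    spec = config.group(group)
    if not spec.is_age_structured:
        raise ValueError(f"{group!r} is a biomass pool; stages are undefined")
    m_l = spec.m_linear_adult if stage == "adult" else spec.m_linear_juvenile
    keys = ("q025", "q25", "q50", "q75", "q975")
    if m_l == 0:
        return {k: 0.0 for k in keys}
    env = config.environment
    spy = config.steps_per_year
    ml_scale = config.timestep_hours / REFERENCE_TIMESTEP_HOURS
    fracs = (np.arange(spy) + 0.5) / spy
    temps = np.stack([env.temperature(f) for f in fracs])       # (spy, B)
    rates = m_l * ml_scale * temperature_correction(temps) * spy  # annualized
    weights = np.tile(env.spatial_distribution[(group, stage)], (spy, 1)) / spy
    qs = _weighted_quantiles(rates.ravel(), weights.ravel(), [0.025, 0.25, 0.5, 0.75, 0.975])
    return dict(zip(keys, (float(q) for q in qs)))


def realized_total_mortality(numbers_at_age: np.ndarray, drop_plus_group: bool = True) -> float:
    """Total mortality Z from exponential decay of proportions-at-age.

    Ordinary least squares of log proportions against age index, slope
    negated. The plus group accumulates survivors and violates pure decay,
    so it is excluded by default. Interior zero counts are dropped; fewer
    than 3 usable ages is an error.
    """
    n = np.asarray(numbers_at_age, dtype=float)
    if drop_plus_group and len(n) > 3:
        n = n[:-1]
    ages = np.arange(len(n))
    keep = n > 0
    if keep.sum() < 3:
        raise ValueError("need at least 3 age classes with positive numbers")
    props = n[keep] / n[keep].sum()
    slope = np.polyfit(ages[keep], np.log(props), 1)[0]
    return float(-slope)


def forced_mortality_proportion(
    applied_adult: dict[str, float],
    applied_juvenile: dict[str, float],
    realized_z: float,
    adult_numbers: float,
    juvenile_numbers: float,
) -> MortalityDecomposition:
    """Forced (applied/realized) share of natural mortality per stage, and
    the stage-weighted combination. Values above 1 are retained and flagged."""
    if realized_z <= 0:
        raise ValueError("realized total mortality must be > 0")
    prop_ad = applied_adult["q50"] / realized_z
    prop_juv = applied_juvenile["q50"] / realized_z
    total = adult_numbers + juvenile_numbers
    weighted = (
        (prop_ad * adult_numbers + prop_juv * juvenile_numbers) / total
        if total > 0 else float("nan")
    )
    return MortalityDecomposition(
        applied_adult=applied_adult,
        applied_juvenile=applied_juvenile,
        realized_z=realized_z,
        prop_adult_forced=prop_ad,
        prop_juvenile_forced=prop_juv,
        weighted_forced=weighted,
        exceeds_one=(prop_ad > 1) or (prop_juv > 1),
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_attributes(config: EcosystemConfig, base: Trajectory) -> pd.DataFrame:
    """One attribute row per group, computed from the unfished base run.

    The base run must be unfished so the realized mortality fitted from its
    proportions-at-age is entirely natural. Attributes that are undefined
    for a group (stage mortality shares for pools, top prey for
    non-predators) are NaN.
    """
    if base is None:
        raise ValueError("a completed unfished base trajectory is required")
    if base.fishing_on:
        raise ValueError("attributes must be computed from an unfished base run")
    ledger = base.consumption_ledger()
    graph = connection_graph(ledger)
    rows = []
    for g in config.groups:
        row: dict[str, float | str | None] = {"group": g.name}
        row["Informance"] = g.informance
        row["TL"] = g.trophic_level
        row["Keystone"] = g.keystone_rank if g.keystone_rank is not None else np.nan
        row["Response"] = (
            g.responsiveness_rank if g.responsiveness_rank is not None else np.nan
        )
        try:
            primary, _, _ = trophic_connection_counts(ledger, g.name, graph=graph)
        except KeyError:
            primary = 0
        row["NumL1cons"] = primary
        row["Lifespan"] = g.lifespan_years if g.lifespan_years is not None else np.nan
        row["B0"] = g.b0
        row["Linf"] = g.linf_cm if g.linf_cm is not None else np.nan
        top = top_prey_proportion(ledger, g.name)
        row["PropByTopPrey"] = top if top is not None else np.nan
        if g.is_age_structured:
            decomp = _mortality_for_group(config, base, g.name)
            row["propAdM"] = decomp.prop_adult_forced
            row["propJuvM"] = decomp.prop_juvenile_forced
        else:
            row["propAdM"] = np.nan
            row["propJuvM"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")[ATTRIBUTE_COLUMNS]


def _mortality_for_group(
    config: EcosystemConfig, base: Trajectory, group: str
) -> MortalityDecomposition:
    spec = config.group(group)
    gi = base.as_names.index(group)
    # mean unfished age composition over reporting years
    numbers = base.numbers_at_age[base.reporting_mask, gi, : spec.n_age_classes].mean(axis=0)
    applied_ad = applied_additional_mortality(group, "adult", config)
    applied_juv = applied_additional_mortality(group, "juvenile", config)
    try:
        realized = realized_total_mortality(numbers)
    except ValueError:
        realized = float("nan")
    mat = spec.maturity_age_class or max(1, spec.n_age_classes // 2)
    adult_n = float(numbers[mat - 1 :].sum())
    juv_n = float(numbers[: mat - 1].sum())
    if not np.isfinite(realized) or realized <= 0:
        return MortalityDecomposition(
            applied_ad, applied_juv, realized, float("nan"), float("nan"),
            float("nan"), False,
        )
    return forced_mortality_proportion(applied_ad, applied_juv, realized, adult_n, juv_n)
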