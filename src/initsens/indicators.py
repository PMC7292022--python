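"""Ecosystem indicators computed per run and year.

Three indicators that respond to fishing pressure but need no catch data:

* **Mean trophic level (MTL)** — biomass-weighted mean trophic level over
  age-structured groups.
* **Modified Kempton's Q** — a diversity index from the slope of the ranked
  biomass distribution between the quartile ranks, restricted to groups at
  or above trophic level 3: with S retained groups ranked by descending
  biomass, Q = S / (2 ln(R_L / R_U)) where R_L is the biomass at rank
  ceil(0.25 S) and R_U at rank ceil(0.75 S). Invariant under uniform
  rescaling of all biomasses.
* **Pelagic ratio** — biomass of pelagic fish groups over total
  age-structured biomass.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import EcosystemConfig
from .simulator import Trajectory

KEMPTON_TL_THRESHOLD = 3.0
INDICATORS = ("mean_trophic_level", "kemptons_q", "pelagic_ratio")


class UndefinedIndicatorError(ValueError):
    """The indicator is mathematically undefined for the given biomasses."""


def mean_trophic_level(biomasses, trophic_levels) -> float:
    """Biomass-weighted mean trophic level: sum(B_i TL_i) / sum(B_i)."""
    b = np.asarray(biomasses, dtype=float)
    tl = np.asarray(trophic_levels, dtype=float)
    total = b.sum()
    if total <= 0:
        raise UndefinedIndicatorError("mean trophic level needs positive total biomass")
    return float((b * tl).sum() / total)


def modified_kemptons_q(
    biomasses, trophic_levels, tl_threshold: float = KEMPTON_TL_THRESHOLD
) -> float:
    """Kempton's Q over groups with TL >= threshold (see module docstring)."""
    b = np.asarray(biomasses, dtype=float)
    tl = np.asarray(trophic_levels, dtype=float)
    keep = b[tl >= tl_threshold]
    s = len(keep)
    if s < 4:
        raise UndefinedIndicatorError(
            f"Kempton's Q needs >= 4 groups at TL >= {tl_threshold}, got {s}"
        )
    ranked = np.sort(keep)[::-1]
    r_l = ranked[math.ceil(0.25 * s) - 1]
    r_u = ranked[math.ceil(0.75 * s) - 1]
    if r_u <= 0 or r_l <= 0 or math.isclose(r_l, r_u):
        raise UndefinedIndicatorError("Kempton's Q undefined: quartile biomasses equal or zero")
    return float(s / (2.0 * math.log(r_l / r_u)))


def pelagic_biomass_ratio(biomasses, pelagic_flags) -> float:
    """Pelagic-fish biomass over total (age-structured) biomass, in [0, 1]."""
    b = np.asarray(biomasses, dtype=float)
    flags = np.asarray(pelagic_flags, dtype=bool)
    total = b.sum()
    if total <= 0:
        raise UndefinedIndicatorError("pelagic ratio needs positive total biomass")
    return float(b[flags].sum() / total)


def indicator_series(
    trajectories, config: EcosystemConfig, reporting_only: bool = True
) -> pd.DataFrame:
    """Annual indicator values per run, long form.

    Columns: run_id, chaos_alt (empty when the trajectory has no plan
    labelling), year, indicator, value. Undefined per-year values propagate
    as NaN rather than failures.
    """
    as_names = [g.name for g in config.age_structured]
    tl = np.array([g.trophic_level for g in config.age_structured])
    pelagic = np.array([g.is_pelagic_fish for g in config.age_structured])
    rows = []
    for traj in trajectories:
        frame = traj.biomass_frame(reporting_only=reporting_only)
        b_as = frame[as_names].to_numpy()
        for yi, year in enumerate(frame.index):
            for name, fn in (
                ("mean_trophic_level", lambda b: mean_trophic_level(b, tl)),
                ("kemptons_q", lambda b: modified_kemptons_q(b, tl)),
                ("pelagic_ratio", lambda b: pelagic_biomass_ratio(b, pelagic)),
            ):
                try:
                    value = fn(b_as[yi])
                except UndefinedIndicatorError:
                    value = float("nan")
                rows.append((traj.plan_id, int(year), name, value))
    out = pd.DataFrame(rows, columns=["run_id", "year", "indicator", "value"])
    return out
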