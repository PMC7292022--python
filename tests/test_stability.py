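"""Between-run CVs and the stepwise GLM: oracles and recovery properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from initsens.perturbation import PerturbationPlan
from initsens.stability import (
    VARIANT_VARIABLES,
    StepwiseGLM,
    biomass_cv,
    build_glm_frame,
    cv_table,
    null_frame,
    pearson_residuals,
    per_year_fits,
    planted_frame,
    selection_summary,
    stepwise_glm,
    summary_fit,
    term_design,
)


class TestBiomassCV:
    def test_identical_values(self):
        assert biomass_cv([3.0, 3.0, 3.0]) == 0.0

    def test_two_point_reference(self):
        assert biomass_cv([1.0, 3.0]) == pytest.approx(np.sqrt(2.0) / 2.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(min_value=0.1, max_value=1e3), min_size=2, max_size=10),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, values, factor):
        if np.mean(values) <= 0:
            return
        assert biomass_cv(np.array(values) * factor) == pytest.approx(
            biomass_cv(values), rel=1e-9, abs=1e-12
        )

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            biomass_cv([1.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            biomass_cv([0.0, 0.0])


def _fake_trajectories(seed, n_runs, groups=("a", "b"), years=(2000, 2001, 2002)):
    """Minimal Trajectory stand-ins for CV table tests."""
    from initsens.simulator import Trajectory

    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_runs):
        biomass = rng.uniform(10, 100, size=(len(years), len(groups)))
        out.append(
            Trajectory(
                years=np.array(years),
                group_names=list(groups),
                as_names=list(groups),
                biomass=biomass,
                numbers_at_age=np.zeros((len(years), len(groups), 1)),
                weight_at_age=np.zeros((len(years), len(groups), 1)),
                consumption=np.zeros((len(years), len(groups), len(groups))),
                burn_in_years=0,
                fishing_on=False,
                plan_id=f"r{r}",
            )
        )
    return out


class TestCVTable:
    def test_duplicated_runs_give_zero(self):
        runs = _fake_trajectories(1, 1) * 3
        alts = {t.plan_id: "A" for t in runs}
        table = cv_table(runs, ["A"], alts)
        assert (table.values.to_numpy() == 0).all()

    def test_dimensions(self):
        runs = _fake_trajectories(2, 4)
        alts = {t.plan_id: "A" for t in runs}
        table = cv_table(runs, ["A"], alts)
        assert table.values.shape == (2, 3)  # groups x years

    def test_matches_manual_cv_oracle(self):
        runs = _fake_trajectories(3, 5)
        alts = {t.plan_id: "A" for t in runs}
        table = cv_table(runs, ["A"], alts)
        for gi, group in enumerate(table.values.index):
            for yi, year in enumerate(table.values.columns):
                vals = [t.biomass[yi, gi] for t in runs]
                assert table.values.loc[group, year] == pytest.approx(biomass_cv(vals))

    def test_subset_filtering(self):
        runs = _fake_trajectories(4, 6)
        alts = {t.plan_id: ("A" if i < 3 else "B") for i, t in enumerate(runs)}
        ta = cv_table(runs, ["A"], alts)
        assert ta.n_runs == 3
        with pytest.raises(ValueError):
            cv_table(runs, ["F"], alts)


class TestStepwise:
    def test_planted_tl_effect_selected_first_in_every_replicate(self):
        hits = 0
        for seed in range(20):
            frame = planted_frame(seed)
            res = stepwise_glm(frame, variables=VARIANT_VARIABLES["ALL"][:4])
            # confirm the planted share is large enough for the claim
            tl_only = stepwise_glm(frame, variables=["TL"])
            assert tl_only.increments[0] >= 0.5
            if res.terms and res.terms[0] == "TL":
                hits += 1
        assert hits == 20

    def test_null_frames_select_nothing(self):
        empty = sum(
            not stepwise_glm(null_frame(seed), variables=VARIANT_VARIABLES["ALL"][:4]).terms
            for seed in range(20)
        )
        assert empty >= 18

    def test_constant_response_empty_selection(self):
        frame = planted_frame(0)
        frame["cv_cbrt"] = 2.5
        res = stepwise_glm(frame, variables=["TL", "B0"])
        assert res.terms == [] and res.r_squared == 0.0

    def test_first_selection_matches_exhaustive_oracle(self):
        """With a small candidate pool, the greedy first pick equals the
        single candidate with the largest deviance explained, found by
        brute-force separate fits."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 120
            frame = pd.DataFrame(
                {v: rng.normal(0, 1, n) for v in ("TL", "B0", "NumL1cons")}
            )
            beta = rng.normal(0, 1, 3)
            frame["cv_cbrt"] = frame.to_numpy() @ beta + rng.normal(0, 0.3, n)
            frame["year"] = 2000
            variables = ["TL", "B0", "NumL1cons"]
            res = stepwise_glm(frame, variables=variables)
            from initsens.stability import candidate_terms, term_name

            y = frame["cv_cbrt"].to_numpy()
            null_dev = ((y - y.mean()) ** 2).sum()
            best, best_frac = None, -np.inf
            for t in candidate_terms(variables):
                block, _ = term_design(frame, t)
                x = np.hstack([np.ones((n, 1)), block])
                beta_hat, *_ = np.linalg.lstsq(x, y, rcond=None)
                rss = ((y - x @ beta_hat) ** 2).sum()
                frac = (null_dev - rss) / null_dev
                if frac > best_frac + 1e-12:
                    best, best_frac = t, frac
            assert res.terms[0] == term_name(best)

    def test_deterministic_selection_path(self):
        frame = planted_frame(7)
        a = stepwise_glm(frame, variables=VARIANT_VARIABLES["ALL"][:4])
        b = stepwise_glm(frame, variables=VARIANT_VARIABLES["ALL"][:4])
        assert a.terms == b.terms
        assert a.increments == b.increments

    def test_r2_path_monotone(self):
        rng = np.random.default_rng(3)
        n = 300
        frame = pd.DataFrame({v: rng.normal(0, 1, n) for v in ("TL", "B0", "NumL1cons")})
        frame["cv_cbrt"] = (
            1.5 * frame["TL"] - 1.2 * frame["B0"] + rng.normal(0, 0.4, n)
        )
        frame["year"] = 2000
        res = stepwise_glm(frame, variables=["TL", "B0", "NumL1cons"])
        assert len(res.terms) >= 2
        assert all(b >= a for a, b in zip(res.r2_path, res.r2_path[1:]))
        assert res.r2_path[-1] <= 1.0


class TestPerYearFits:
    def test_116_attempts_over_full_span(self):
        frames = pd.concat(
            [planted_frame(seed=y, n_rows=60).assign(year=y) for y in range(1900, 2016)],
            ignore_index=True,
        )
        years = range(1900, 2016)
        pyf = per_year_fits(frames, years, variables=["TL", "B0", "NumL1cons", "Lifespan"])
        assert pyf.n_attempted == 116
        assert pyf.n_fitted == 116

    def test_planted_term_selected_every_year(self):
        frames = pd.concat(
            [planted_frame(seed=y, n_rows=80).assign(year=y) for y in (2000, 2001, 2002)],
            ignore_index=True,
        )
        pyf = per_year_fits(frames, [2000, 2001, 2002], variables=["TL", "B0"])
        assert pyf.selection_counts["TL"] == pyf.n_fitted == 3

    def test_identical_years_identical_selections(self):
        one = planted_frame(5, n_rows=100)
        frames = pd.concat(
            [one.assign(year=y) for y in (2000, 2001)], ignore_index=True
        )
        pyf = per_year_fits(frames, [2000, 2001], variables=["TL", "B0"])
        assert pyf.results[2000].terms == pyf.results[2001].terms

    def test_summary_table_layout(self):
        frames = pd.concat(
            [planted_frame(seed=y, n_rows=60).assign(year=y) for y in (2000, 2001)],
            ignore_index=True,
        )
        pyf = per_year_fits(frames, [2000, 2001], variables=["TL", "B0"])
        table = selection_summary(pyf)
        assert list(table.columns) == ["term", "r2_min", "r2_max", "years_selected"]
        row = table[table.term == "TL"].iloc[0]
        assert row.r2_min <= row.r2_max
        assert row.years_selected == 2


class TestSummaryFit:
    def test_year_window_filter(self):
        frames = pd.concat(
            [planted_frame(seed=y, n_rows=50).assign(year=y) for y in (1905, 1950, 2000)],
            ignore_index=True,
        )
        res = summary_fit(frames, variables=["TL", "B0"], years=(1910, 2015))
        assert res.n_obs == 100  # 1905 excluded

    def test_bp_variant_excludes_top_prey(self):
        assert "PropByTopPrey" not in VARIANT_VARIABLES["BP"]
        assert "PropByTopPrey" in VARIANT_VARIABLES["AS"]

    def test_interaction_recovered_from_pooled_frame(self):
        rng = np.random.default_rng(11)
        n = 600
        frame = pd.DataFrame({
            "TL": rng.normal(0, 1, n),
            "B0": rng.normal(0, 1, n),
            "ChaosAlt": rng.choice(list("ABCD"), n),
            "year": 2000,
        })
        slope = {"A": 2.0, "B": -2.0, "C": 1.0, "D": -1.0}
        frame["cv_cbrt"] = frame["ChaosAlt"].map(slope) * frame["TL"] + rng.normal(0, 0.4, n)
        res = summary_fit(frame, variables=["TL", "B0", "ChaosAlt"], years=None)
        assert res.terms[0] == "ChaosAlt:TL"


class TestPearsonResiduals:
    def test_perfect_fit_gives_zeros(self):
        frame = pd.DataFrame({"TL": np.arange(10.0), "year": 2000})
        frame["cv_cbrt"] = 2.0 + 3.0 * frame["TL"]
        res = stepwise_glm(frame, variables=["TL"])
        pr = pearson_residuals(res)
        np.testing.assert_allclose(pr["pearson_residual"], 0.0, atol=1e-8)

    def test_zero_mean_with_intercept(self):
        res = stepwise_glm(planted_frame(9), variables=["TL", "B0"])
        pr = pearson_residuals(res)
        assert abs(pr["pearson_residual"].mean()) < 1e-8

    def test_omitted_planted_predictor_leaves_signal(self):
        rng = np.random.default_rng(13)
        n = 500
        frame = pd.DataFrame({"TL": rng.normal(0, 1, n), "B0": rng.normal(0, 1, n)})
        frame["year"] = 2000
        frame["cv_cbrt"] = 2.0 * frame["TL"] + 1.5 * frame["B0"] + rng.normal(0, 0.3, n)
        res = stepwise_glm(frame, variables=["TL"], stop_fraction=0.05)
        pr = pearson_residuals(res)
        corr = np.corrcoef(pr["pearson_residual"], frame.loc[pr.index, "B0"])[0, 1]
        assert abs(corr) > 0.3


def test_chaosalt_tl_interaction_recovered_from_surrogate_ensembles():
    """Pipeline-level recovery: when the perturbation spread is forced to
    couple to trophic level with opposite signs under two run labels, the
    ChaosAlt:TL interaction is the first selected term in most replicates.

    The couplings are symmetric over the age-structured trophic-level range
    (their average is flat in TL, so only the interaction carries signal)
    and the burn-in is short so the scalar imprint survives to the CVs.
    """
    from initsens.characterization import assemble_attributes
    from initsens.config import make_toy_config
    from initsens.perturbation import PerturbationPlan, apply_plan
    from initsens.simulator import initial_state_from_config, run_simulation

    cfg = make_toy_config(
        8, 2, seed=11, timestep_hours=120.0,
        start_year=1990, end_year=1999, burn_in_years=1,
    )
    base = run_simulation(cfg, fishing_on=False, plan_id="base")
    attrs = assemble_attributes(cfg, base)
    virgin = initial_state_from_config(cfg)
    as_tls = [g.trophic_level for g in cfg.age_structured]
    tl_lo, tl_hi = min(as_tls), max(as_tls)

    def sigma(group, alt):
        if not group.is_age_structured:
            return 0.25
        u = (group.trophic_level - tl_lo) / (tl_hi - tl_lo)
        return 0.02 + 0.45 * (u if alt == "C" else 1.0 - u)

    hits = 0
    n_reps = 5
    for rep in range(n_reps):
        rng = np.random.default_rng(100 + rep)
        trajs, alts = [], {}
        for alt, set_id in (("C", 2), ("E", 3)):
            for r in range(6):
                scalars = {
                    g.name: float(np.clip(1.0 + rng.normal(0, sigma(g, alt)), 0.1, None))
                    for g in cfg.groups
                }
                plan = PerturbationPlan(
                    f"{alt}{r}", set_id, alt, False, scalars, {}, seed=r,
                )
                traj = run_simulation(
                    cfg, initial_state=apply_plan(virgin, plan, cfg),
                    fishing_on=False, plan_id=plan.plan_id,
                )
                trajs.append(traj)
                alts[plan.plan_id] = alt
        tables = {alt: cv_table(trajs, [alt], alts) for alt in ("C", "E")}
        early = [int(y) for y in base.reporting_years[:3]]
        frame = build_glm_frame(
            tables, attrs, cfg, variant="AS", fished_filter="all", years=early
        )
        res = stepwise_glm(frame, variables=VARIANT_VARIABLES["ALL"])
        if res.terms and res.terms[0] == "ChaosAlt:TL":
            hits += 1
    assert hits >= 0.8 * n_reps
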