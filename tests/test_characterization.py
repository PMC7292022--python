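"""Group characterization: top prey, trophic connections, mortality split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from initsens.characterization import (
    applied_additional_mortality,
    assemble_attributes,
    connection_graph,
    forced_mortality_proportion,
    realized_total_mortality,
    top_prey_proportion,
    trophic_connection_counts,
)
from initsens.config import make_toy_config
from initsens.simulator import run_simulation

from conftest import constant_temperature


def ledger_from_flows(flows):
    """flows: iterable of (year, predator, prey, amount)."""
    return pd.DataFrame(flows, columns=["year", "predator", "prey", "flow"])


class TestTopPrey:
    def test_single_prey(self):
        led = ledger_from_flows([(2000, "a", "x", 5.0)])
        assert top_prey_proportion(led, "a") == 1.0

    def test_share_of_total(self):
        led = ledger_from_flows([(2000, "a", "x", 60.0), (2000, "a", "y", 40.0)])
        assert top_prey_proportion(led, "a") == pytest.approx(0.6)

    def test_yearly_switching_averages_out(self):
        """A predator alternating between two prey in equal amounts looks
        the same as one eating both steadily: top share 0.5."""
        led = ledger_from_flows(
            [(y, "a", "x" if y % 2 else "y", 10.0) for y in range(2000, 2010)]
        )
        assert top_prey_proportion(led, "a") == pytest.approx(0.5)

    def test_non_predator_absent(self):
        led = ledger_from_flows([(2000, "a", "x", 5.0)])
        assert top_prey_proportion(led, "x") is None


def brute_force_counts(edges, nodes, focal):
    """Independent oracle: breadth-first distances on an explicit edge list."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {focal: 0}
    frontier = [focal]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return tuple(sum(1 for v in dist.values() if v == k) for k in (1, 2, 3))


class TestTrophicConnections:
    def test_illustrated_case(self):
        """Focal node with two primary connections that fan out to five
        further nodes: (2, 5, 0)."""
        flows = [
            (2000, "focal", "p1", 10.0),
            (2000, "focal", "p2", 10.0),
            (2000, "p1", "s1", 10.0),
            (2000, "p1", "s2", 10.0),
            (2000, "p2", "s3", 10.0),
            (2000, "p2", "s4", 10.0),
            (2000, "p2", "s5", 10.0),
        ]
        led = ledger_from_flows(flows)
        assert trophic_connection_counts(led, "focal") == (2, 5, 0)

    def test_isolated_group(self):
        led = ledger_from_flows([(2000, "a", "b", 1.0)])
        g = connection_graph(led)
        g.add_node("loner")
        assert trophic_connection_counts(led, "a", graph=g) == (1, 0, 0)
        assert trophic_connection_counts(led, "loner", graph=g) == (0, 0, 0)

    def test_path_graph(self):
        flows = [(2000, f"n{i}", f"n{i+1}", 5.0) for i in range(5)]
        led = ledger_from_flows(flows)
        assert trophic_connection_counts(led, "n0") == (1, 1, 1)

    def test_unknown_group(self):
        led = ledger_from_flows([(2000, "a", "b", 1.0)])
        with pytest.raises(KeyError):
            trophic_connection_counts(led, "zzz")

    def test_cutoff_prunes_negligible_prey(self):
        # prey y is 0.5% of the predator's diet and the only predator of y
        # applies 100% of y's losses, so the edge is kept via the prey side;
        # making y also heavily eaten by z drops the a-y edge entirely
        led = ledger_from_flows(
            [(2000, "a", "x", 99.5), (2000, "a", "y", 0.5), (2000, "z", "y", 999.0)]
        )
        primary, _, _ = trophic_connection_counts(led, "a", cutoff=0.01)
        assert primary == 1

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(min_value=3, max_value=12))
    def test_matches_brute_force_oracle(self, seed, n_nodes):
        rng = np.random.default_rng(seed)
        nodes = [f"g{i}" for i in range(n_nodes)]
        flows = []
        for i in range(n_nodes):
            for j in range(n_nodes):
                if i != j and rng.random() < 0.25:
                    flows.append((2000, nodes[i], nodes[j], float(rng.uniform(1, 50))))
        if not flows:
            return
        cutoff = float(rng.choice([0.0, 0.01, 0.05]))
        led = ledger_from_flows(flows)
        graph = connection_graph(led, cutoff=max(cutoff, 1e-12))
        edges = list(graph.edges())
        for focal in nodes:
            if focal not in graph:
                continue
            assert trophic_connection_counts(
                led, focal, cutoff=max(cutoff, 1e-12)
            ) == brute_force_counts(edges, list(graph.nodes()), focal)


class TestAppliedMortality:
    def test_constant_temperature_collapses_quantiles(self):
        cfg = constant_temperature(make_toy_config(2, 1, seed=4), 15.0)
        g = cfg.age_structured[0]
        q = applied_additional_mortality(g.name, "adult", cfg)
        expected = g.m_linear_adult * (cfg.timestep_hours / 12.0) * cfg.steps_per_year
        for v in q.values():
            assert v == pytest.approx(expected, rel=1e-9)

    def test_zero_mortality_all_zero(self):
        import copy
        from dataclasses import replace

        cfg = make_toy_config(1, 1, seed=4)
        g0 = replace(cfg.age_structured[0], m_linear_adult=0.0)
        cfg2 = copy.copy(cfg)
        object.__setattr__(cfg2, "groups", (g0, *cfg.groups[1:]))
        q = applied_additional_mortality(g0.name, "adult", cfg2)
        assert all(v == 0.0 for v in q.values())

    def test_two_box_distribution(self):
        """Two equal-weight boxes at 5 and 25 degC give a two-point applied
        distribution {0.5 m, 2 m}; the interpolated median sits between and
        the quantiles are ordered."""
        import copy

        from initsens.config import EnvironmentSpec, build_spatial_distribution

        cfg = make_toy_config(1, 1, seed=4, n_boxes=2)
        env = EnvironmentSpec(
            mean_temperature_c=15.0,
            seasonal_amplitude_c=0.0,
            box_offsets_c=(-10.0, 10.0),
            spatial_distribution={
                k: np.array([0.5, 0.5]) for k in cfg.environment.spatial_distribution
            },
        )
        cfg2 = copy.copy(cfg)
        object.__setattr__(cfg2, "environment", env)
        g = cfg2.age_structured[0]
        annual = g.m_linear_adult * (cfg2.timestep_hours / 12.0) * cfg2.steps_per_year
        q = applied_additional_mortality(g.name, "adult", cfg2)
        assert q["q025"] == pytest.approx(0.5 * annual, rel=1e-6)
        assert q["q975"] == pytest.approx(2.0 * annual, rel=1e-6)
        assert 0.5 * annual < q["q50"] < 2.0 * annual
        assert q["q025"] <= q["q25"] <= q["q50"] <= q["q75"] <= q["q975"]


class TestRealizedMortality:
    def test_exact_decay_recovered(self):
        n = np.exp(-0.3 * np.arange(6))
        assert realized_total_mortality(n, drop_plus_group=False) == pytest.approx(
            0.3, abs=1e-9
        )

    def test_uniform_gives_zero(self):
        assert realized_total_mortality(np.ones(5)) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_decay_within_tolerance(self):
        rng = np.random.default_rng(77)
        n = np.exp(-0.3 * np.arange(8)) * np.exp(rng.normal(0, 0.05, 8))
        assert realized_total_mortality(n, drop_plus_group=False) == pytest.approx(
            0.3, abs=0.05
        )

    def test_interior_zeros_dropped(self):
        n = np.exp(-0.4 * np.arange(6))
        n[2] = 0.0
        assert realized_total_mortality(n, drop_plus_group=False) == pytest.approx(
            0.4, abs=1e-9
        )

    def test_too_few_ages(self):
        with pytest.raises(ValueError):
            realized_total_mortality([1.0, 0.5])


class TestForcedProportion:
    def _q(self, median):
        return {"q025": median, "q25": median, "q50": median, "q75": median, "q975": median}

    def test_simple_ratio(self):
        d = forced_mortality_proportion(self._q(0.2), self._q(0.1), 0.4, 100, 100)
        assert d.prop_adult_forced == pytest.approx(0.5)

    def test_weighted_combination(self):
        d = forced_mortality_proportion(self._q(0.8), self._q(0.2), 1.0, 300, 100)
        assert d.weighted_forced == pytest.approx(0.65)

    def test_over_one_flagged(self):
        d = forced_mortality_proportion(self._q(0.5), self._q(0.1), 0.4, 10, 10)
        assert d.prop_adult_forced == pytest.approx(1.25)
        assert d.exceeds_one

    def test_nonpositive_realized_rejected(self):
        with pytest.raises(ValueError):
            forced_mortality_proportion(self._q(0.2), self._q(0.1), 0.0, 1, 1)


class TestAssembleAttributes:
    def test_completeness(self, toy_cfg, base_run):
        attrs = assemble_attributes(toy_cfg, base_run)
        assert len(attrs) == len(toy_cfg.groups)
        as_rows = attrs.loc[[g.name for g in toy_cfg.age_structured]]
        for col in ("Informance", "TL", "Keystone", "NumL1cons", "Lifespan", "B0"):
            assert as_rows[col].notna().all()

    def test_non_predator_pool_has_no_top_prey(self, toy_cfg, base_run):
        attrs = assemble_attributes(toy_cfg, base_run)
        non_pred = [g.name for g in toy_cfg.pools if not g.is_predator]
        assert attrs.loc[non_pred, "PropByTopPrey"].isna().all()

    def test_requires_unfished_base(self, toy_cfg):
        fished = run_simulation(toy_cfg, fishing_on=True, plan_id="f")
        with pytest.raises(ValueError, match="unfished"):
            assemble_attributes(toy_cfg, fished)


def test_realized_mortality_recovery_from_simulation():
    """For a predator-free group at constant temperature the realized Z
    fitted from the simulated unfished age structure recovers the applied
    background mortality within 2%."""
    import copy
    from dataclasses import replace

    cfg = make_toy_config(
        2, 1, seed=21, n_age_classes=8, timestep_hours=120.0,
        start_year=1980, end_year=2005, burn_in_years=0,
    )
    cfg = constant_temperature(cfg, 15.0)
    spy = cfg.steps_per_year
    ml_scale = cfg.timestep_hours / 12.0
    groups = []
    for g in cfg.groups:
        if g.is_age_structured:
            annual_z = g.m_linear_adult * ml_scale * spy
            groups.append(replace(g, m_linear_juvenile=g.m_linear_adult, m_total=annual_z))
        else:
            groups.append(g)
    cfg2 = copy.copy(cfg)
    object.__setattr__(cfg2, "groups", tuple(groups))
    traj = run_simulation(
        cfg2, fishing_on=False, enable_predation=False, enable_growth=False,
    )
    for i, g in enumerate(cfg2.age_structured):
        numbers = traj.numbers_at_age[-1, i, : g.n_age_classes]
        z = realized_total_mortality(numbers)
        expected = g.m_linear_adult * ml_scale * spy
        assert z == pytest.approx(expected, rel=0.02)
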