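import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import democonv
from democonv import (
    WorkingAgeBounds,
    cohort_turnover,
    dasgupta_two_factor,
    deaths_at_working_ages,
    decompose_change,
    decompose_working_age_effect,
    decompose_yearly,
    merge_events,
    migration_at_working_ages,
    residual_deaths,
    residual_migration,
)
from democonv.panels import PanelError

from .conftest import two_cluster_config, uniform_panel

TINY_BOUNDS = WorkingAgeBounds(1, 4)

positive = st.floats(min_value=1e-2, max_value=1e6, allow_nan=False)
flows = st.floats(min_value=-1e5, max_value=1e5, allow_nan=False)


class TestDasGupta:
    def test_offsetting_changes(self):
        # TSR stays 2.0: the two effects cancel exactly
        nw_eff, w_eff = dasgupta_two_factor(100, 110, 50, 55)
        assert nw_eff == pytest.approx(-0.1909091, abs=1e-7)
        assert w_eff == pytest.approx(0.1909091, abs=1e-7)
        assert nw_eff + w_eff == pytest.approx(0.0, abs=1e-12)

    def test_identity_case(self):
        assert dasgupta_two_factor(100, 100, 50, 50) == (0.0, 0.0)

    def test_pure_nw_change(self):
        nw_eff, w_eff = dasgupta_two_factor(100, 100, 50, 40)
        assert nw_eff == pytest.approx(0.5, rel=1e-12)
        assert w_eff == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dasgupta_two_factor(100, 100, 0, 50)

    @given(W1=positive, W2=positive, NW1=positive, NW2=positive)
    @settings(max_examples=200, deadline=None)
    def test_additivity_identity(self, W1, W2, NW1, NW2):
        nw_eff, w_eff = dasgupta_two_factor(W1, W2, NW1, NW2)
        total = W2 / NW2 - W1 / NW1
        # tolerance relative to the largest term (cancellation-aware)
        scale = max(1.0, abs(nw_eff), abs(w_eff), abs(total))
        assert abs(nw_eff + w_eff - total) <= 1e-12 * scale


class TestBalanceResiduals:
    def test_residual_migration_example(self):
        assert residual_migration(1000, 1010, 20, 15) == pytest.approx(5.0)

    def test_no_change_zero(self):
        assert residual_migration(1000, 1000, 0, 0) == 0.0

    def test_residual_deaths_example(self):
        assert residual_deaths(1000, 1010, 20, 5) == pytest.approx(15.0)

    def test_closed_population_zero_deaths(self):
        assert residual_deaths(1000, 1020, 20, 0) == 0.0

    @given(W1=positive, W2=positive, CT=flows, D_W=st.floats(min_value=0, max_value=1e5))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, W1, W2, CT, D_W):
        M_W = residual_migration(W1, W2, CT, D_W)
        assert residual_deaths(W1, W2, CT, M_W) == pytest.approx(D_W, rel=1e-9, abs=1e-9)
        # and the balance closes exactly
        assert W1 + CT + M_W - D_W == pytest.approx(W2, rel=1e-12, abs=1e-9)


class TestWorkingAgeEffect:
    def test_worked_example(self):
        ct, mg, mt = decompose_working_age_effect(50, 55, CT=8, M_W=5, D_W=3)
        assert ct == pytest.approx(0.1527273, abs=1e-7)
        assert mg == pytest.approx(0.0954545, abs=1e-7)
        assert mt == pytest.approx(-0.0572727, abs=1e-7)
        # sums to the w effect of the matching Das Gupta example (W: 100 -> 110)
        _, w_eff = dasgupta_two_factor(100, 110, 50, 55)
        assert ct + mg + mt == pytest.approx(w_eff, rel=1e-12)

    def test_zero_case(self):
        assert decompose_working_age_effect(50, 55, 0, 0, 0) == (0.0, 0.0, -0.0)

    def test_linearity(self):
        one = decompose_working_age_effect(50, 55, 8, 5, 3)
        two = decompose_working_age_effect(50, 55, 16, 10, 6)
        for a, b in zip(one, two):
            assert b == pytest.approx(2 * a, rel=1e-12)

    def test_nonpositive_nw_rejected(self):
        with pytest.raises(ValueError):
            decompose_working_age_effect(0, 55, 8, 5, 3)


class TestCohortTurnover:
    def _panel(self, years=(2000,)):
        panel = uniform_panel(count=1000.0, open_age=100, years=years)
        panel.loc[panel.age == 14, "count"] = 1200.0
        panel.loc[panel.age == 64, "count"] = 1000.0
        return panel

    def test_one_year_interval(self):
        panel = self._panel(years=(2000, 2001))
        assert cohort_turnover(panel, "R1", (2000, 2001)) == 200.0

    def test_uniform_is_zero(self):
        panel = uniform_panel(count=10.0, open_age=100, years=(2000, 2001))
        assert cohort_turnover(panel, "R1", (2000, 2001)) == 0.0

    def test_two_year_interval_sums(self):
        panel = self._panel(years=(2000, 2001, 2002))
        panel.loc[(panel.year == 2001) & (panel.age == 14), "count"] = 900.0
        two = cohort_turnover(panel, "R1", (2000, 2002))
        one_a = cohort_turnover(panel, "R1", (2000, 2001))
        one_b = cohort_turnover(panel, "R1", (2001, 2002))
        assert two == one_a + one_b == 200.0 - 100.0

    def test_missing_year_errors(self):
        panel = self._panel(years=(2000, 2001))
        with pytest.raises(PanelError):
            cohort_turnover(panel, "R1", (2000, 2003))


class TestFlowSums:
    def _events(self, value, col, years=(2000,)):
        rows = [("R1", y, a, value) for y in years for a in range(101)]
        return pd.DataFrame(rows, columns=["region", "year", "age", col])

    def test_zero_deaths(self):
        events = self._events(0.0, "deaths")
        assert deaths_at_working_ages(events, "R1", (2000, 2001)) == 0.0

    def test_uniform_deaths(self):
        # 5 deaths at every age, [15, 65) covers 50 ages -> 250
        events = self._events(5.0, "deaths")
        assert deaths_at_working_ages(events, "R1", (2000, 2001)) == 250.0

    def test_bounds_difference(self):
        events = self._events(5.0, "deaths")
        narrow = deaths_at_working_ages(events, "R1", (2000, 2001), WorkingAgeBounds(15, 65))
        wide = deaths_at_working_ages(events, "R1", (2000, 2001), WorkingAgeBounds(15, 70))
        at_65_69 = events[(events.age >= 65) & (events.age < 70)]["deaths"].sum()
        assert wide - narrow == at_65_69 == 25.0

    def test_migration_sum(self):
        events = self._events(-2.0, "net_migration")
        assert migration_at_working_ages(events, "R1", (2000, 2001)) == -100.0

    def test_missing_interval_errors(self):
        events = self._events(5.0, "deaths")
        with pytest.raises(PanelError, match="2001"):
            deaths_at_working_ages(events, "R1", (2000, 2002))


class TestTinyFixture:
    """Hand-verified arithmetic for region A of the tiny fixture, [1, 4) bounds.

    2000 stocks [10, 20, 30, 40, 50], 2001 stocks [12, 9.5, 17, 27, 88]:
    W1=90, NW1=60, W2=53.5, NW2=100, CT=10-40=-30, D_W=1+2+3=6,
    M_W = 53.5-90+30+6 = -0.5 (equals the migration panel sum 0.5-1+0).
    """

    def test_region_a_against_hand_arithmetic(self, tiny):
        table = decompose_change(
            tiny["population"], tiny["deaths"], (2000, 2001), TINY_BOUNDS, mode="observed"
        )
        a = table[table.region == "A"].iloc[0]
        assert a["tsr1"] == pytest.approx(1.5, rel=1e-12)
        assert a["tsr2"] == pytest.approx(0.535, rel=1e-12)
        assert a["CT"] == -30.0
        assert a["D_W"] == 6.0
        assert a["M_W"] == pytest.approx(-0.5, abs=1e-12)
        assert a["g"] == pytest.approx(-0.965, rel=1e-12)
        assert a["nw"] == pytest.approx(-0.4783333333, abs=1e-9)
        assert a["w"] == pytest.approx(-0.4866666667, abs=1e-9)
        assert a["ct"] == pytest.approx(-0.4, rel=1e-9)
        assert a["mg"] == pytest.approx(-0.0066666667, abs=1e-9)
        assert a["mt"] == pytest.approx(-0.08, rel=1e-9)

    def test_projected_mode_recovers_deaths(self, tiny):
        table = decompose_change(
            tiny["population"], tiny["migration"], (2000, 2001), TINY_BOUNDS, mode="projected"
        )
        a = table[table.region == "A"].iloc[0]
        assert a["M_W"] == pytest.approx(-0.5, abs=1e-12)
        assert a["D_W"] == pytest.approx(6.0, abs=1e-12)

    def test_additivity_all_regions(self, tiny):
        events = merge_events(tiny["deaths"], tiny["migration"])
        for mode in ("observed", "projected"):
            table = decompose_change(tiny["population"], events, (2000, 2002), TINY_BOUNDS, mode)
            assert np.allclose(table["g"], table["nw"] + table["w"], rtol=1e-12, atol=1e-12)
            assert np.allclose(table["w"], table["ct"] + table["mg"] + table["mt"], rtol=1e-12, atol=1e-12)


class TestDecomposeChange:
    def test_no_change_gives_zero_components(self, stationary):
        table = decompose_change(
            stationary["population"], stationary["deaths"], (2000, 2005), mode="observed"
        )
        for col in ("g", "nw", "w", "ct", "mg", "mt", "M_W", "D_W", "CT"):
            assert (table[col] == 0.0).all(), col

    def test_mode_consistency_on_simulator_output(self, small_scenario):
        config, population, deaths, migration = small_scenario
        events = merge_events(deaths, migration)
        for t in range(config.start_year, config.end_year):
            obs = decompose_change(population, events, (t, t + 1), mode="observed")
            proj = decompose_change(population, events, (t, t + 1), mode="projected")
            truth_m = obs.merge(
                migration[(migration.year == t) & (migration.age >= 15) & (migration.age < 65)]
                .groupby("region", as_index=False)["net_migration"].sum(),
                on="region",
            )
            assert np.allclose(truth_m["M_W"], truth_m["net_migration"], atol=1e-9)
            truth_d = proj.merge(
                deaths[(deaths.year == t) & (deaths.age >= 15) & (deaths.age < 65)]
                .groupby("region", as_index=False)["deaths"].sum(),
                on="region",
            )
            assert np.allclose(truth_d["D_W"], truth_d["deaths"], atol=1e-9)

    def test_multi_year_flows_sum_over_years(self, small_scenario):
        config, population, deaths, migration = small_scenario
        decade = decompose_change(population, deaths, (2003, 2008), mode="observed")
        yearly = decompose_yearly(population, deaths, mode="observed", years=list(range(2003, 2008)))
        summed = yearly.groupby("region")[["CT", "D_W"]].sum()
        merged = decade.set_index("region")[["CT", "D_W"]].join(summed, rsuffix="_sum")
        assert np.allclose(merged["CT"], merged["CT_sum"], rtol=1e-12)
        assert np.allclose(merged["D_W"], merged["D_W_sum"], rtol=1e-12)

    def test_unknown_mode_rejected(self, tiny):
        with pytest.raises(ValueError, match="mode"):
            decompose_change(tiny["population"], tiny["deaths"], (2000, 2001), TINY_BOUNDS, "both")

    def test_mode_requires_matching_column(self, tiny):
        with pytest.raises(PanelError, match="net_migration"):
            decompose_change(tiny["population"], tiny["deaths"], (2000, 2001), TINY_BOUNDS, "projected")


class TestClusterMortalityContrast:
    def test_east_mt_more_negative_than_west(self):
        """2.5x working-age mortality drags east mt below west, paired over 20 seeds."""
        gaps = []
        for seed in range(20):
            config = two_cluster_config(seed=seed)
            population, deaths, migration = democonv.generate_scenario(config)
            table = decompose_change(population, deaths, (2003, 2008), mode="observed")
            means = table.groupby("cluster")["mt"].mean()
            gaps.append(means["east"] - means["west"])
        gaps = np.asarray(gaps)
        assert (gaps < 0).all()
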