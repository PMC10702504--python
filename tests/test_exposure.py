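"""Smoke impact days, coverage stratification, yearly summaries, attainment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smokesep.datasets import PUBLISHED_AVERAGE, national_smoke_summary
from smokesep.exposure import (
    ExposureSummary, annual_means, attainment, coverage_mask, design_values,
    excess_percent, exposure_summary, significant_smoke_area,
    smoke_impact_days, summarize_years,
)
from smokesep.grid import GridDefinition


def est_frame(cells, days, total, smoke):
    return pd.DataFrame({
        "cell_id": cells, "day": days,
        "pm_total": total, "pm_background": np.asarray(total) - np.asarray(smoke),
        "pm_smoke": smoke,
    })


class TestSmokeImpactDays:
    @pytest.mark.parametrize("smoke,total,expected", [
        (2.0, 10.0, 0),     # 0.20
        (3.0, 10.0, 1),     # 0.30
        (2.5, 10.0, 0),     # exactly 0.25: strict
        (1.0, 0.0, 0),      # zero total never counts
    ])
    def test_threshold_semantics(self, smoke, total, expected):
        est = est_frame([0], [0], [total], [smoke])
        days = smoke_impact_days(est)
        got = 0 if not len(days) else int(days["n_impact_days"].iloc[0])
        assert got == expected

    @given(st.integers(0, 10**6))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_counting_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 120))
        est = est_frame(rng.integers(0, 6, n), rng.integers(0, 40, n),
                        rng.uniform(0, 20, n), rng.uniform(0, 10, n))
        est["pm_smoke"] = np.minimum(est["pm_smoke"], est["pm_total"])
        got = smoke_impact_days(est, days_per_year=20)
        expect = {}
        for _, r in est.iterrows():
            if r.pm_total > 0 and r.pm_smoke / r.pm_total > 0.25:
                key = (r.cell_id, r.day // 20)
                expect[key] = expect.get(key, 0) + 1
        got_map = {(r.cell_id, r.year): r.n_impact_days
                   for r in got.itertuples() if r.n_impact_days > 0}
        assert got_map == expect

    def test_raising_threshold_never_increases_counts(self):
        rng = np.random.default_rng(7)
        est = est_frame(rng.integers(0, 10, 300), rng.integers(0, 30, 300),
                        rng.uniform(0.1, 20, 300), rng.uniform(0, 10, 300))
        prev = None
        for t in (0.1, 0.25, 0.5, 0.9):
            total = smoke_impact_days(est, fraction_threshold=t)["n_impact_days"].sum()
            if prev is not None:
                assert total <= prev
            prev = total


class TestCoverageMask:
    grid = GridDefinition(10, 10, 1.0)

    def test_no_monitors_all_uncovered(self):
        assert not coverage_mask(self.grid, np.empty((0, 2))).any()

    def test_monitor_at_cell_center_covers_it(self):
        mask = coverage_mask(self.grid, np.array([[2.5, 3.5]]))
        assert mask[3 * 10 + 2]

    @given(st.integers(0, 10**6))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_bruteforce_distances(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (int(rng.integers(1, 8)), 2))
        mask = coverage_mask(self.grid, pts, radius_km=3.0)
        centers = self.grid.cell_centers()
        for i in rng.choice(self.grid.n_cells, 30, replace=False):
            d = np.hypot(centers[i, 0] - pts[:, 0], centers[i, 1] - pts[:, 1])
            assert mask[i] == (d.min() <= 3.0)


class TestExposureSummary:
    def test_uniform_world_one_day_everywhere(self):
        est = est_frame(np.arange(4), [0, 0, 0, 0], [10.0] * 4, [5.0] * 4)
        s = exposure_summary(est, np.full(4, 100.0), np.array([True, True, False, False]))
        assert s.impact_days_covered == pytest.approx(1.0)
        assert s.impact_days_uncovered == pytest.approx(1.0)
        assert s.smoke_impacted_population == pytest.approx(400.0)

    def test_hand_built_four_cell_world(self):
        # two days; cell pm values chosen so strata stats are hand-computable
        est = est_frame(
            cells=[0, 1, 2, 3, 0, 1, 2, 3],
            days=[0, 0, 0, 0, 1, 1, 1, 1],
            total=[10.0, 8.0, 6.0, 4.0, 10.0, 8.0, 6.0, 4.0],
            smoke=[5.0, 0.0, 3.0, 0.0, 0.0, 0.0, 3.0, 0.0],
        )
        pop = np.array([10.0, 30.0, 20.0, 40.0])
        covered = np.array([True, True, False, False])
        s = exposure_summary(est, pop, covered, days_per_year=2)
        assert s.total_population == 100.0
        assert s.population_uncovered == 60.0
        # impacted cells: 0 (day 0) and 2 (both days)
        assert s.smoke_impacted_population == 30.0
        assert s.smoke_impacted_population_uncovered == 20.0
        assert s.impact_days_covered == pytest.approx((1 * 10 + 0 * 30) / 40)
        assert s.impact_days_uncovered == pytest.approx((2 * 20 + 0 * 40) / 60)
        assert s.total_pm_covered == pytest.approx((10 * 10 + 8 * 30) / 40)
        assert s.total_pm_uncovered == pytest.approx((6 * 20 + 4 * 40) / 60)
        assert s.smoke_pm_covered == pytest.approx((2.5 * 10 + 0 * 30) / 40)
        assert s.smoke_pm_uncovered == pytest.approx((3.0 * 20 + 0 * 40) / 60)
        # strata are exhaustive and exclusive
        assert s.population_uncovered + pop[covered].sum() == s.total_population

    def test_identical_years_average_to_the_row(self):
        row = ExposureSummary(0, 100.0, 40.0, 90.0, 38.0, 10.0, 14.0,
                              11.0, 9.0, 0.5, 0.7)
        rows = [ExposureSummary(y, *list(row.__dict__.values())[1:])
                for y in range(3)]
        ys = summarize_years(rows)
        assert ys.averages["impact_days_covered"] == pytest.approx(10.0)
        assert ys.excess_days_pct == pytest.approx(40.0)
        assert ys.per_year_excess_days_pct.nunique() == 1


class TestPublishedSummaryWorkedExample:
    def test_yearly_means_reproduce_published_average_row(self):
        ys = summarize_years(national_smoke_summary())
        avg = ys.averages
        assert avg["total_population"] == pytest.approx(
            PUBLISHED_AVERAGE["total_population"], abs=0.05)
        assert avg["smoke_impacted_population"] == pytest.approx(
            PUBLISHED_AVERAGE["smoke_impacted_population"], abs=0.05)
        assert avg["impact_days_covered"] == pytest.approx(
            PUBLISHED_AVERAGE["impact_days_covered"], abs=0.1)
        assert avg["impact_days_uncovered"] == pytest.approx(
            PUBLISHED_AVERAGE["impact_days_uncovered"], abs=0.1)
        assert round(ys.excess_days_pct) == 34

    def test_published_concentration_excesses(self):
        assert round(excess_percent(PUBLISHED_AVERAGE["total_pm_covered"],
                                    PUBLISHED_AVERAGE["total_pm_uncovered"])) == 22
        assert round(excess_percent(PUBLISHED_AVERAGE["smoke_pm_uncovered"],
                                    PUBLISHED_AVERAGE["smoke_pm_covered"])) == 30

    def test_random_year_table_matches_recomputation(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "year": np.arange(6),
            "total_population": rng.uniform(200, 300, 6),
            "population_uncovered": rng.uniform(50, 80, 6),
            "smoke_impacted_population": rng.uniform(150, 250, 6),
            "smoke_impacted_population_uncovered": rng.uniform(40, 70, 6),
            "impact_days_covered": rng.uniform(5, 30, 6),
            "impact_days_uncovered": rng.uniform(5, 40, 6),
            "total_pm_covered": rng.uniform(8, 12, 6),
            "total_pm_uncovered": rng.uniform(7, 11, 6),
            "smoke_pm_covered": rng.uniform(0.2, 1.0, 6),
            "smoke_pm_uncovered": rng.uniform(0.2, 1.2, 6),
        })
        ys = summarize_years(df)
        for col in df.columns.drop("year"):
            assert ys.averages[col] == pytest.approx(df[col].mean())
        a, b = df["impact_days_uncovered"].mean(), df["impact_days_covered"].mean()
        assert ys.excess_days_pct == pytest.approx(100 * (a - b) / b)


class TestAttainment:
    def test_zero_concentrations_zero_nonattainment(self):
        annual = np.zeros((3, 10))
        pop = np.full(10, 5.0)
        rep = attainment(annual, annual, pop, np.ones(10, bool))
        assert (rep["nonattainment_population"] == 0).all()

    def test_design_value_threshold_is_inclusive(self):
        annual = np.full((1, 4), 9.5)
        pop = np.full(4, 10.0)
        rep = attainment(annual, annual, pop, np.ones(4, bool), standards=(9.0, 10.0))
        by = rep.set_index(["standard", "scenario"])
        assert by.loc[(9.0, "with_smoke"), "nonattainment_population"] == 40.0
        assert by.loc[(10.0, "with_smoke"), "nonattainment_population"] == 0.0
        exact = attainment(np.full((1, 4), 10.0), np.full((1, 4), 10.0),
                           pop, np.ones(4, bool), standards=(10.0,))
        assert (exact["nonattainment_population"] == 40.0).all()

    def test_design_values_trailing_three_year_window(self):
        annual = np.array([[6.0], [12.0], [12.0], [3.0]])
        dv = design_values(annual)
        np.testing.assert_allclose(dv.ravel(), [6.0, 9.0, 10.0, 9.0])

    def test_background_never_worse_than_with_smoke(self):
        rng = np.random.default_rng(9)
        total = rng.uniform(5, 15, (4, 50))
        smoke = rng.uniform(0, 4, (4, 50))
        rep = attainment(total, total - smoke, np.full(50, 2.0),
                         rng.uniform(size=50) < 0.3)
        w = rep[rep["scenario"] == "with_smoke"].set_index(["standard", "year"])
        b = rep[rep["scenario"] == "background_only"].set_index(["standard", "year"])
        assert (b["nonattainment_population"] <= w["nonattainment_population"]).all()
        assert (b["monitor_fraction"] <= w["monitor_fraction"]).all()

    def test_annual_means_roundtrip(self):
        est = est_frame([0, 0, 1, 1], [0, 1, 0, 1], [4.0, 6.0, 10.0, 14.0],
                        [1.0, 1.0, 2.0, 2.0])
        years, total, background = annual_means(est, n_cells=2, days_per_year=2)
        np.testing.assert_allclose(total, [[5.0, 12.0]])
        np.testing.assert_allclose(background, [[4.0, 10.0]])


class TestSignificantSmokeArea:
    def test_zero_field(self):
        mask, frac = significant_smoke_area(np.zeros(50))
        assert frac == 0.0 and not mask.any()

    def test_half_field(self):
        vals = np.concatenate([np.full(25, 2.0), np.zeros(25)])
        _, frac = significant_smoke_area(vals)
        assert frac == 0.5

    @given(st.integers(0, 10**6))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_bruteforce_count(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 3, int(rng.integers(4, 200)))
        mask, frac = significant_smoke_area(vals)
        assert frac == pytest.approx(sum(v > 1.0 for v in vals) / len(vals))
        np.testing.assert_array_equal(mask, vals > 1.0)
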