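"""Population exposure to fire smoke and attainment under candidate standards.

A *smoke impact day* is a cell-day on which the estimated smoke component
exceeds a quarter of the estimated total PM2.5.  Cells are stratified by
regulatory-monitor coverage (within 5 km of a reference monitor) and the
strata compared on population-weighted smoke-impact-day counts and annual
mean concentrations — quantifying how much exposure the monitor network's
vicinity misses.  Attainment compares each cell's design value (trailing
three-year mean of annual mean PM2.5) against candidate annual standards,
with and without the smoke component.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import GridDefinition

IMPACT_FRACTION_THRESHOLD = 0.25
COVERAGE_RADIUS_KM = 5.0
ATTAINMENT_STANDARDS = (9.0, 10.0, 12.0)
SIGNIFICANT_SMOKE_UGM3 = 1.0


def smoke_impact_days(estimates: pd.DataFrame,
                      fraction_threshold: float = IMPACT_FRACTION_THRESHOLD,
                      days_per_year: int = 365) -> pd.DataFrame:
    """Per (cell, year) count of days with smoke strictly over the threshold share.

    A day counts iff pm_total > 0 and pm_smoke / pm_total > fraction_threshold.
    """
    total = estimates["pm_total"].to_numpy(float)
    smoke = estimates["pm_smoke"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        hit = (total > 0) & (smoke / np.where(total > 0, total, 1.0) > fraction_threshold)
    df = pd.DataFrame({
        "cell_id": estimates["cell_id"].to_numpy(),
        "year": estimates["day"].to_numpy() // days_per_year,
        "hit": hit.astype(int),
    })
    return (df.groupby(["cell_id", "year"], observed=True)["hit"].sum()
            .rename("n_impact_days").reset_index())


def coverage_mask(grid: GridDefinition, monitor_xy: np.ndarray,
                  radius_km: float = COVERAGE_RADIUS_KM) -> np.ndarray:
    """Boolean per cell: center within ``radius_km`` of any reference monitor."""
    mask = np.zeros(grid.n_cells, dtype=bool)
    monitor_xy = np.atleast_2d(np.asarray(monitor_xy, float))
    if monitor_xy.size == 0:
        return mask
    tree = cKDTree(monitor_xy)
    d, _ = tree.query(grid.cell_centers(), k=1)
    return d <= radius_km


@dataclass
class ExposureSummary:
    """One year's exposure stratified by monitor coverage.

    Population columns are persons; day columns are population-weighted mean
    smoke impact days per person; concentration columns are
    population-weighted annual means (ug/m3).
    """

    year: int
    total_population: float
    population_uncovered: float
    smoke_impacted_population: float
    smoke_impacted_population_uncovered: float
    impact_days_covered: float
    impact_days_uncovered: float
    total_pm_covered: float
    total_pm_uncovered: float
    smoke_pm_covered: float
    smoke_pm_uncovered: float


def _pw_mean(values: np.ndarray, weights: np.ndarray) -> float:
    w = weights.sum()
    return float((values * weights).sum() / w) if w > 0 else float("nan")


def exposure_summary(estimates: pd.DataFrame, population: np.ndarray,
                     covered: np.ndarray, year: int = 0,
                     fraction_threshold: float = IMPACT_FRACTION_THRESHOLD,
                     days_per_year: int = 365,
                     population_multiplier: float = 1.0) -> ExposureSummary:
    """Stratified exposure for one year of estimates.

    ``population`` is persons per cell (year-static; ``population_multiplier``
    emulates year-to-year population change), ``covered`` the boolean
    coverage mask.  Smoke-impacted population counts persons in cells with at
    least one smoke impact day in the year.
    """
    pop = np.asarray(population, float) * population_multiplier
    covered = np.asarray(covered, bool)
    est = estimates[estimates["day"] // days_per_year == year]
    days = smoke_impact_days(est, fraction_threshold, days_per_year)
    n_cells = len(pop)
    counts = np.zeros(n_cells)
    counts[days["cell_id"].to_numpy()] = days["n_impact_days"].to_numpy()
    ann = est.groupby("cell_id", observed=True)[["pm_total", "pm_smoke"]].mean()
    ann_total = np.zeros(n_cells)
    ann_smoke = np.zeros(n_cells)
    ann_total[ann.index.to_numpy()] = ann["pm_total"].to_numpy()
    ann_smoke[ann.index.to_numpy()] = ann["pm_smoke"].to_numpy()

    impacted = counts >= 1
    return ExposureSummary(
        year=year,
        total_population=float(pop.sum()),
        population_uncovered=float(pop[~covered].sum()),
        smoke_impacted_population=float(pop[impacted].sum()),
        smoke_impacted_population_uncovered=float(pop[impacted & ~covered].sum()),
        impact_days_covered=_pw_mean(counts[covered], pop[covered]),
        impact_days_uncovered=_pw_mean(counts[~covered], pop[~covered]),
        total_pm_covered=_pw_mean(ann_total[covered], pop[covered]),
        total_pm_uncovered=_pw_mean(ann_total[~covered], pop[~covered]),
        smoke_pm_covered=_pw_mean(ann_smoke[covered], pop[covered]),
        smoke_pm_uncovered=_pw_mean(ann_smoke[~covered], pop[~covered]),
    )


def excess_percent(without: float, with_: float) -> float:
    """Relative excess of ``without`` over ``with_`` in percent: 100 (a - b) / b."""
    return 100.0 * (without - with_) / with_


@dataclass
class YearsSummary:
    averages: pd.Series                     # unweighted mean over years per column
    excess_days_pct: float                  # uncovered over covered, from the averages
    total_pm_excess_covered_pct: float      # covered over uncovered
    smoke_pm_excess_uncovered_pct: float    # uncovered over covered
    per_year_excess_days_pct: pd.Series

    def rounded(self) -> dict:
        return {
            "excess_days_pct": round(self.excess_days_pct),
            "total_pm_excess_covered_pct": round(self.total_pm_excess_covered_pct),
            "smoke_pm_excess_uncovered_pct": round(self.smoke_pm_excess_uncovered_pct),
        }


def summarize_years(summaries) -> YearsSummary:
    """Average yearly exposure summaries and derive relative-difference stats.

    Accepts a list of :class:`ExposureSummary` or an equivalent DataFrame.
    The averages row is the unweighted mean over years of each column; the
    excess percentages compare the uncovered and covered strata of that row
    (day counts and smoke PM: uncovered over covered; total PM: covered over
    uncovered, where monitors sit).
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame([asdict(s) for s in summaries])
    num = df.drop(columns=[c for c in ("year",) if c in df.columns])
    avg = num.mean()
    per_year = pd.Series(
        excess_percent(df["impact_days_uncovered"].to_numpy(),
                       df["impact_days_covered"].to_numpy()),
        index=df["year"] if "year" in df.columns else df.index,
        name="excess_days_pct",
    )
    return YearsSummary(
        averages=avg,
        excess_days_pct=excess_percent(avg["impact_days_uncovered"],
                                       avg["impact_days_covered"]),
        total_pm_excess_covered_pct=excess_percent(avg["total_pm_covered"],
                                                   avg["total_pm_uncovered"]),
        smoke_pm_excess_uncovered_pct=excess_percent(avg["smoke_pm_uncovered"],
                                                     avg["smoke_pm_covered"]),
        per_year_excess_days_pct=per_year,
    )


def annual_means(estimates: pd.DataFrame, n_cells: int,
                 days_per_year: int = 365) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(years, annual mean total, annual mean background) as (n_years, n_cells) arrays."""
    work = estimates.copy()
    work["year"] = work["day"] // days_per_year
    years = np.sort(work["year"].unique())
    total = np.zeros((len(years), n_cells))
    background = np.zeros((len(years), n_cells))
    for i, y in enumerate(years):
        g = work[work["year"] == y].groupby("cell_id", observed=True)[
            ["pm_total", "pm_background"]].mean()
        total[i, g.index.to_numpy()] = g["pm_total"].to_numpy()
        background[i, g.index.to_numpy()] = g["pm_background"].to_numpy()
    return years, total, background


def design_values(annual: np.ndarray) -> np.ndarray:
    """Trailing three-year mean of annual means; shorter window in the first years."""
    annual = np.atleast_2d(annual)
    out = np.empty_like(annual, dtype=float)
    for y in range(annual.shape[0]):
        out[y] = annual[max(0, y - 2): y + 1].mean(axis=0)
    return out


def attainment(annual_total: np.ndarray, annual_background: np.ndarray,
               population: np.ndarray, monitor_cells: np.ndarray,
               standards: tuple[float, ...] = ATTAINMENT_STANDARDS) -> pd.DataFrame:
    """Nonattainment population and monitor fraction per standard and scenario.

    Nonattainment: design value >= standard.  Scenario "with_smoke" uses the
    total-PM2.5 annual means, "background_only" the background-only means
    (excluding the fire contribution).
    """
    pop = np.asarray(population, float)
    monitor_cells = np.asarray(monitor_cells, bool)
    rows = []
    for scenario, annual in (("with_smoke", annual_total),
                             ("background_only", annual_background)):
        dv = design_values(annual)
        for std in standards:
            non = dv >= std
            for y in range(dv.shape[0]):
                rows.append({
                    "standard": std, "scenario": scenario, "year": y,
                    "nonattainment_population": float(pop[non[y]].sum()),
                    "monitor_fraction": float(non[y][monitor_cells].mean())
                    if monitor_cells.any() else 0.0,
                })
    return pd.DataFrame(rows)


def significant_smoke_area(annual_mean_smoke: np.ndarray,
                           threshold: float = SIGNIFICANT_SMOKE_UGM3
                           ) -> tuple[np.ndarray, float]:
    """Cells whose annual mean smoke strictly exceeds the threshold, and their area fraction."""
    flat = np.asarray(annual_mean_smoke, float).ravel()
    mask = flat > threshold
    return mask, float(mask.mean())
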