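"""Integration of all inputs onto the common 1 km grid.

Coarse predictors (CTM runs, coarse AOD, meteorology when coarse) are
interpolated to the fine grid with inverse distance weighting; satellite AOD
gaps are filled in two steps (daily regression on a full-coverage coarse AOD
proxy and meteorology, then spatial smoothing of the residual field); plume
polygons become per-cell duration and density summaries; and everything is
assembled into one feature row per cell-day, with the observed PM2.5 target
attached where a monitor reports.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .grid import CellDayField, GridDefinition

logger = logging.getLogger(__name__)

IDW_POWER = 2.0
IDW_K = 4
DAYTIME_HOURS = (6, 18)


def idw_weights(coarse_grid: GridDefinition, fine_grid: GridDefinition,
                power: float = IDW_POWER, k: int = IDW_K) -> tuple[np.ndarray, np.ndarray]:
    """k-nearest-neighbour IDW weights from coarse to fine cell centers.

    Returns (indices, weights), each (n_fine, k); a fine center coinciding
    with a coarse center takes that coarse value exactly.
    """
    coarse_pts = coarse_grid.cell_centers()
    fine_pts = fine_grid.cell_centers()
    k = min(k, len(coarse_pts))
    tree = cKDTree(coarse_pts)
    dist, idx = tree.query(fine_pts, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    exact = dist[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[exact] = 0.0
    w[exact, 0] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    return idx, w


def idw_regrid(coarse: CellDayField, grid: GridDefinition,
               power: float = IDW_POWER, k: int = IDW_K) -> CellDayField:
    """Interpolate a coarse field to ``grid`` by inverse distance weighting."""
    idx, w = idw_weights(coarse.grid, grid, power, k)
    flat = coarse.flat()                       # (n_days, n_coarse)
    vals = (flat[:, idx] * w[None]).sum(axis=2)  # (n_days, n_fine)
    return CellDayField(grid, vals.reshape(-1, grid.n_rows, grid.n_cols),
                        coarse.units, coarse.name)


def daytime_average(hourly: np.ndarray, hours: tuple[int, int] = DAYTIME_HOURS,
                    axis: int = -1) -> np.ndarray:
    """Average hourly values over the daytime window [start, end) along ``axis``.

    Used to reduce hourly meteorology to the daily values the models consume.
    """
    start, end = hours
    sl = [slice(None)] * hourly.ndim
    sl[axis] = slice(start, end)
    return np.asarray(hourly)[tuple(sl)].mean(axis=axis)


def _nanaware_smooth(field2d: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaNs (normalized convolution)."""
    mask = np.isfinite(field2d)
    filled = np.where(mask, field2d, 0.0)
    num = gaussian_filter(filled, sigma, mode="reflect")
    den = gaussian_filter(mask.astype(float), sigma, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = 0.0
    return out


def gap_fill_aod(aod: CellDayField, covariates: dict[str, CellDayField],
                 smooth_sigma_cells: float = 3.0) -> CellDayField:
    """Fill AOD gaps: daily regression on covariates, then residual smoothing.

    Step 1 regresses observed AOD on the covariate fields (pooled over cells,
    per day; ordinary least squares) and predicts at the gaps.  Step 2
    smooths the observed-minus-predicted residual field spatially and adds it
    back at the gaps.  Observed cells are returned unchanged.  A day with no
    observed cells falls back to a global model pooled over all days.
    """
    grid = aod.grid
    nd = aod.n_days
    y = aod.flat().copy()
    X = np.stack([c.flat() if c.n_days == nd else np.broadcast_to(c.flat(), y.shape)
                  for c in covariates.values()], axis=-1)   # (nd, n_cells, p)
    ones = np.ones((*y.shape, 1))
    X = np.concatenate([ones, X], axis=-1)

    obs_mask = np.isfinite(y)
    # global pooled fallback model
    go = obs_mask.ravel()
    global_beta = (np.linalg.lstsq(X.reshape(-1, X.shape[-1])[go], y.ravel()[go], rcond=None)[0]
                   if go.any() else np.zeros(X.shape[-1]))

    out = y.copy()
    for d in range(nd):
        m = obs_mask[d]
        if m.sum() >= X.shape[-1] + 2:
            beta = np.linalg.lstsq(X[d][m], y[d][m], rcond=None)[0]
        else:
            logger.info("day %d has %d observed AOD cells; using global fit", d, int(m.sum()))
            beta = global_beta
        pred = X[d] @ beta
        resid = np.full(grid.n_cells, np.nan)
        resid[m] = y[d][m] - pred[m]
        sm = _nanaware_smooth(resid.reshape(grid.n_rows, grid.n_cols),
                              smooth_sigma_cells).ravel()
        filled = pred + sm
        out[d][~m] = filled[~m]
    return CellDayField(grid, out.reshape(nd, grid.n_rows, grid.n_cols),
                        aod.units, aod.name)


def plume_summaries(plumes: list, grid: GridDefinition) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell plume duration (hours) and duration-weighted density for one day.

    Duration sums over every polygon containing the cell center; density is
    the duration-weighted mean of the polygons' density classes, 0 where no
    polygon covers the cell.
    """
    duration = np.zeros(grid.n_cells)
    dens_wsum = np.zeros(grid.n_cells)
    centers = grid.cell_centers()
    for p in plumes:
        inside = shapely.contains_xy(p.geometry, centers[:, 0], centers[:, 1])
        duration[inside] += p.duration_h
        dens_wsum[inside] += p.duration_h * p.density_class
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(duration > 0, dens_wsum / duration, 0.0)
    return duration.reshape(grid.n_rows, grid.n_cols), density.reshape(grid.n_rows, grid.n_cols)


def all_plume_summaries(plumes_by_day: dict[int, list], grid: GridDefinition,
                        n_days: int) -> tuple[CellDayField, CellDayField]:
    dur = np.zeros((n_days, grid.n_rows, grid.n_cols))
    den = np.zeros_like(dur)
    for d in range(n_days):
        if plumes_by_day.get(d):
            dur[d], den[d] = plume_summaries(plumes_by_day[d], grid)
    return (CellDayField(grid, dur, "h", "plume_duration"),
            CellDayField(grid, den, "", "plume_density"))


BACKGROUND_FEATURES = [
    "ctm_background", "aod_filled", "rh", "temp", "wind_u", "wind_v",
    "cloud_fraction", "population",
]
SMOKE_ONLY_FEATURES = ["plume_duration", "plume_density"]


def assemble_features(
    grid: GridDefinition,
    fields: dict[str, CellDayField],
    records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One feature row per (cell, day), with observed targets where available.

    ``fields`` maps predictor names to fields on ``grid`` (day-static fields
    broadcast).  ``records`` are accepted daily monitor records (reference
    plus selected adjusted low-cost) with columns x_km, y_km, day and a value
    column ``adjusted_pm25`` (preferred) or ``pm25_daily``; multiple monitors
    in one cell-day are averaged.  Climate-region codes become indicator
    columns.  Rows without a monitor carry NaN targets (prediction rows).
    """
    n_days = max(f.n_days for f in fields.values())
    cell_ids = np.arange(grid.n_cells)
    df = pd.DataFrame({
        "cell_id": np.tile(cell_ids, n_days),
        "day": np.repeat(np.arange(n_days), grid.n_cells),
    })
    centers = grid.cell_centers()
    df["x_km"] = centers[df["cell_id"], 0]
    df["y_km"] = centers[df["cell_id"], 1]
    for name, f in fields.items():
        flat = f.flat()
        if f.n_days == 1 and n_days > 1:
            df[name] = np.tile(flat[0], n_days)
        else:
            df[name] = flat.ravel()
    if "climate_region" in df.columns:
        codes = df.pop("climate_region").astype(int)
        for r in np.unique(codes):
            df[f"climate_{r}"] = (codes == r).astype(float)

    df["observed_pm25"] = np.nan
    if records is not None and len(records):
        val_col = "adjusted_pm25" if "adjusted_pm25" in records.columns else "pm25_daily"
        rec = records.copy()
        rec["cell_id"] = grid.cell_of(rec["x_km"].to_numpy(), rec["y_km"].to_numpy())
        tgt = rec.groupby(["cell_id", "day"], observed=True)[val_col].mean().rename("observed_pm25")
        df = df.merge(tgt, on=["cell_id", "day"], how="left", suffixes=("_drop", ""))
        df = df.drop(columns=["observed_pm25_drop"])
    df["oversampled"] = False
    bad = df.drop(columns=["observed_pm25"]).isna().any()
    if bad.any():
        raise ValueError(f"missing predictor values after assembly: {list(bad[bad].index)}")
    return df
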