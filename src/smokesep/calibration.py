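"""Quality control and geographically weighted calibration of low-cost sensors.

Low-cost optical particle counters over-read PM2.5 at high relative humidity.
After hourly-to-daily quality control (completeness, channel agreement,
physical range), low-cost stations are matched to reference monitors within a
small radius and adjusted with regional geographically weighted regression
(GWR): at each anchor (a matched low-cost site), reference PM2.5 is regressed
on low-cost PM2.5, relative humidity and temperature with Gaussian kernel
weights in distance, so the correction varies smoothly over space.  The
domain is split into four quadrant regions with a buffer along each internal
boundary in which adjacent regions' predictions are blended, making the
adjusted surface continuous across region seams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import GridDefinition

logger = logging.getLogger(__name__)

MIN_VALID_HOURS = 16
CHANNEL_REL_DIFF_MAX = 0.30
PM_MAX = 1000.0
TEMP_RANGE_F = (-20.0, 140.0)
RH_RANGE = (0.0, 100.0)
LOWCOST_TRAINING_THRESHOLD = 12.0   # ug/m3, annual-standard cut for inclusion


# ---------------------------------------------------------------------------
# daily QC

def _check_hours(hours: np.ndarray) -> None:
    h = np.asarray(hours)
    if h.size and (not np.issubdtype(h.dtype, np.integer) or h.min() < 0 or h.max() > 23):
        raise ValueError("malformed hour indices: hours must be integers in [0, 23]")


def qc_daily(hourly: pd.DataFrame) -> dict:
    """Quality-control the hourly records of one station-day.

    Returns a dict with ``status`` "accepted" (and the daily record fields) or
    "rejected" (and a ``qc_flag`` naming the failed rule).  Rules: at least 16
    valid hours; for low-cost sensors, daily channel means within 30% relative
    difference; daily PM2.5 <= 1000 ug/m3, temperature in [-20, 140] F,
    humidity in [0, 100]%.  Malformed hour indices raise ValueError (an input
    error, distinct from QC rejection).
    """
    _check_hours(hourly["hour"].to_numpy())
    network = hourly["network"].iloc[0]
    row = {
        "station_id": hourly["station_id"].iloc[0],
        "network": network,
        "x_km": float(hourly["x_km"].iloc[0]),
        "y_km": float(hourly["y_km"].iloc[0]),
        "day": int(hourly["day"].iloc[0]),
    }

    def reject(flag: str) -> dict:
        return {**row, "status": "rejected", "qc_flag": flag}

    ok = np.isfinite(hourly["pm25"].to_numpy())
    valid = hourly[ok]
    if network == "lowcost":
        a = valid[valid["channel"] == "A"]
        b = valid[valid["channel"] == "B"]
        both = np.intersect1d(a["hour"].to_numpy(), b["hour"].to_numpy())
        if len(set(a["hour"])) != len(a) or len(set(b["hour"])) != len(b):
            raise ValueError("malformed hour indices: duplicate hours within a channel")
        if len(both) < MIN_VALID_HOURS:
            return reject("completeness")
        mean_a = float(a[a["hour"].isin(both)]["pm25"].mean())
        mean_b = float(b[b["hour"].isin(both)]["pm25"].mean())
        denom = 0.5 * (mean_a + mean_b)
        rel = abs(mean_a - mean_b) / denom if denom > 0 else 0.0
        if rel > CHANNEL_REL_DIFF_MAX:
            return reject("channel_disagreement")
        pm = 0.5 * (mean_a + mean_b)
        met = valid[valid["hour"].isin(both)]
    else:
        if len(set(valid["hour"])) != len(valid):
            raise ValueError("malformed hour indices: duplicate hours")
        if len(valid) < MIN_VALID_HOURS:
            return reject("completeness")
        pm = float(valid["pm25"].mean())
        met = valid
    rh = float(met["rh"].mean())
    temp = float(met["temp"].mean())
    if pm > PM_MAX:
        return reject("range_pm")
    if not (TEMP_RANGE_F[0] <= temp <= TEMP_RANGE_F[1]):
        return reject("range_temp")
    if not (RH_RANGE[0] <= rh <= RH_RANGE[1]):
        return reject("range_rh")
    return {**row, "status": "accepted", "qc_flag": "ok",
            "pm25_daily": pm, "rh": rh, "temp": temp}


def _range_flags(agg: pd.DataFrame) -> pd.Series:
    """First failed daily-range rule per row, or "ok"; checked in a fixed order."""
    flag = pd.Series("ok", index=agg.index)
    flag[(flag == "ok") & (agg["pm25_daily"] > PM_MAX)] = "range_pm"
    flag[(flag == "ok") & ~agg["temp"].between(*TEMP_RANGE_F)] = "range_temp"
    flag[(flag == "ok") & ~agg["rh"].between(*RH_RANGE)] = "range_rh"
    return flag


def qc_all(monitors: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized daily QC over a long table of hourly records.

    Applies the same rules as :func:`qc_daily` to every station-day.  Returns
    (accepted daily records, rejected station-days with ``qc_flag``).
    """
    _check_hours(monitors["hour"].to_numpy())
    m = monitors[np.isfinite(monitors["pm25"].to_numpy())]
    meta_cols = ["station_id", "network", "x_km", "y_km", "day"]
    parts = []

    ref = m[m["network"] == "reference"]
    if len(ref):
        agg = ref.groupby(["station_id", "day"], observed=True).agg(
            n_hours=("hour", "nunique"), pm25_daily=("pm25", "mean"),
            rh=("rh", "mean"), temp=("temp", "mean"),
            x_km=("x_km", "first"), y_km=("y_km", "first"),
        ).reset_index()
        agg["network"] = "reference"
        flag = _range_flags(agg)
        flag[agg["n_hours"] < MIN_VALID_HOURS] = "completeness"
        agg["qc_flag"] = flag
        parts.append(agg)

    lcs = m[m["network"] == "lowcost"]
    if len(lcs):
        wide = lcs.pivot_table(index=["station_id", "day", "hour"], columns="channel",
                               values="pm25", aggfunc="mean", observed=True)
        for ch in ("A", "B"):
            if ch not in wide:
                wide[ch] = np.nan
        both = wide[np.isfinite(wide["A"]) & np.isfinite(wide["B"])].reset_index()
        met = lcs.drop_duplicates(["station_id", "day", "hour"])[
            ["station_id", "day", "hour", "x_km", "y_km", "rh", "temp"]]
        both = both.merge(met, on=["station_id", "day", "hour"], how="left")
        agg = both.groupby(["station_id", "day"], observed=True).agg(
            n_hours=("hour", "nunique"), mean_a=("A", "mean"), mean_b=("B", "mean"),
            rh=("rh", "mean"), temp=("temp", "mean"),
            x_km=("x_km", "first"), y_km=("y_km", "first"),
        ).reset_index()
        agg["network"] = "lowcost"
        agg["pm25_daily"] = 0.5 * (agg["mean_a"] + agg["mean_b"])
        denom = agg["pm25_daily"].to_numpy()
        rel = np.where(denom > 0, np.abs(agg["mean_a"] - agg["mean_b"]) / np.where(denom > 0, denom, 1.0), 0.0)
        flag = _range_flags(agg)
        flag[rel > CHANNEL_REL_DIFF_MAX] = "channel_disagreement"
        flag[agg["n_hours"] < MIN_VALID_HOURS] = "completeness"
        agg["qc_flag"] = flag
        parts.append(agg)

    cols = meta_cols + ["pm25_daily", "rh", "temp"]
    if not parts:
        return (pd.DataFrame(columns=cols), pd.DataFrame(columns=meta_cols + ["qc_flag"]))
    allrows = pd.concat(parts, ignore_index=True)
    acc = allrows[allrows["qc_flag"] == "ok"][cols].reset_index(drop=True)
    rej = allrows[allrows["qc_flag"] != "ok"][meta_cols + ["qc_flag"]].reset_index(drop=True)
    return acc, rej


# ---------------------------------------------------------------------------
# pairing and regions

def pair_within_radius(lowcost_stations: pd.DataFrame, ref_stations: pd.DataFrame,
                       radius_km: float = 5.0) -> pd.DataFrame:
    """All (low-cost, reference) station pairs within ``radius_km`` (inclusive)."""
    cols = ["lcs_id", "ref_id", "distance_km"]
    if not len(lowcost_stations) or not len(ref_stations):
        return pd.DataFrame(columns=cols)
    lxy = lowcost_stations[["x_km", "y_km"]].to_numpy(float)
    rxy = ref_stations[["x_km", "y_km"]].to_numpy(float)
    tree = cKDTree(rxy)
    rows = []
    for i, hits in enumerate(tree.query_ball_point(lxy, r=radius_km)):
        for j in sorted(hits):
            d = float(np.hypot(*(lxy[i] - rxy[j])))
            rows.append((lowcost_stations["station_id"].iloc[i],
                         ref_stations["station_id"].iloc[j], d))
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class QuadrantRegions:
    """Four calibration regions obtained by splitting the domain at its midlines.

    Region ids: 0 = SW, 1 = SE, 2 = NW, 3 = NE.  ``buffer_km`` is the
    half-width of the blending zone along each internal boundary.
    """

    x_mid: float
    y_mid: float
    buffer_km: float = 20.0

    @classmethod
    def for_grid(cls, grid: GridDefinition, buffer_km: float = 20.0) -> "QuadrantRegions":
        w, h = grid.extent_km
        return cls(grid.origin[0] + w / 2, grid.origin[1] + h / 2, buffer_km)

    def region_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y) >= self.y_mid).astype(int) * 2 + (np.asarray(x) >= self.x_mid)

    def blend_weights(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """(n, 4) blending weights over the four regions.

        Along each internal boundary the neighbouring region's weight ramps
        linearly from 0 at the buffer edge to 0.5 on the boundary itself, so
        the blended prediction is continuous and equals the plain two-region
        mean on the boundary.
        """
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        tx = 0.5 * (1.0 - np.clip(np.abs(x - self.x_mid) / self.buffer_km, 0, 1))
        ty = 0.5 * (1.0 - np.clip(np.abs(y - self.y_mid) / self.buffer_km, 0, 1))
        east = (x >= self.x_mid)
        north = (y >= self.y_mid)
        wx = np.empty((len(x), 2))     # weight on (west, east) halves
        wx[:, 0] = np.where(east, tx, 1 - tx)
        wx[:, 1] = np.where(east, 1 - tx, tx)
        wy = np.empty((len(y), 2))     # weight on (south, north) halves
        wy[:, 0] = np.where(north, ty, 1 - ty)
        wy[:, 1] = np.where(north, 1 - ty, ty)
        w = np.empty((len(x), 4))
        w[:, 0] = wx[:, 0] * wy[:, 0]  # SW
        w[:, 1] = wx[:, 1] * wy[:, 0]  # SE
        w[:, 2] = wx[:, 0] * wy[:, 1]  # NW
        w[:, 3] = wx[:, 1] * wy[:, 1]  # NE
        return w


# ---------------------------------------------------------------------------
# GWR

_GWR_COLS = ["lcs_pm", "rh", "temp"]


def _design(df: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in _GWR_COLS])


def _wls_at(anchor: np.ndarray, xy: np.ndarray, X: np.ndarray, y: np.ndarray,
            bandwidth: float) -> np.ndarray:
    """Locally weighted least squares at one anchor; widens the kernel if singular."""
    d2 = ((xy - anchor) ** 2).sum(axis=1)
    b = bandwidth
    for attempt in range(8):
        w = np.exp(-d2 / (2 * b * b))
        Xw = X * w[:, None]
        A = Xw.T @ X
        if np.linalg.cond(A) < 1e10:
            return np.linalg.solve(A, Xw.T @ y)
        b *= 2.0
        logger.info("singular local design at anchor %s; widening bandwidth to %.1f km",
                    anchor, b)
    return np.linalg.lstsq(X * np.exp(-d2 / (2 * b * b))[:, None], y, rcond=None)[0]


@dataclass
class GWRFit:
    """A fitted regional GWR: one coefficient vector per anchor site."""

    region_id: int
    anchors: np.ndarray            # (m, 2) anchor locations, km
    coefficients: np.ndarray       # (m, 4): intercept, lowcost-PM, RH, temp
    bandwidth: float               # Gaussian kernel bandwidth, km
    cv_rmse: float = np.nan

    def local_coefficients(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Kernel-weight interpolation of anchor coefficients to (x, y); (n, 4)."""
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]).astype(float)
        d2 = ((pts[:, None, :] - self.anchors[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2 * self.bandwidth**2))
        # degenerate case: all anchors far away -> fall back to nearest anchor
        far = w.sum(axis=1) <= 0
        if far.any():
            nearest = np.argmin(d2[far], axis=1)
            w[far] = 0.0
            w[np.where(far)[0], nearest] = 1.0
        w = w / w.sum(axis=1, keepdims=True)
        return w @ self.coefficients

    def predict(self, x, y, lcs_pm, rh, temp) -> np.ndarray:
        beta = self.local_coefficients(x, y)
        X = np.column_stack([
            np.ones(len(beta)), np.atleast_1d(lcs_pm).astype(float),
            np.atleast_1d(rh).astype(float), np.atleast_1d(temp).astype(float),
        ])
        return (beta * X).sum(axis=1)


def fit_regional_gwr(pair_days: pd.DataFrame,
                     bandwidth_grid: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0),
                     region_id: int = 0) -> GWRFit:
    """Fit a regional GWR of reference PM2.5 on (low-cost PM2.5, RH, temp).

    ``pair_days`` has one row per matched pair and day with columns
    x_km, y_km (low-cost location), lcs_pm, rh, temp, ref_pm and lcs_id.
    Anchors are the distinct low-cost sites.  The bandwidth is chosen from
    ``bandwidth_grid`` by leave-one-site-out cross-validated RMSE.
    """
    if len(pair_days) < 10:
        raise ValueError("need at least 10 paired station-days to fit a regional GWR")
    xy = pair_days[["x_km", "y_km"]].to_numpy(float)
    X = _design(pair_days)
    y = pair_days["ref_pm"].to_numpy(float)
    sites = pair_days["lcs_id"].to_numpy()
    unique_sites, site_ix = np.unique(sites, return_inverse=True)
    anchors = np.array([xy[site_ix == s].mean(axis=0) for s in range(len(unique_sites))])

    best_b, best_rmse = bandwidth_grid[0], np.inf
    if len(unique_sites) >= 2:
        for b in bandwidth_grid:
            sse, n = 0.0, 0
            for s in range(len(unique_sites)):
                held = site_ix == s
                beta = _wls_at(anchors[s], xy[~held], X[~held], y[~held], b)
                resid = y[held] - X[held] @ beta
                sse += float((resid**2).sum())
                n += int(held.sum())
            rmse = np.sqrt(sse / n)
            if rmse < best_rmse:
                best_b, best_rmse = b, rmse
    else:
        best_b = bandwidth_grid[-1]
        best_rmse = np.nan

    coefs = np.array([_wls_at(anchors[s], xy, X, y, best_b)
                      for s in range(len(unique_sites))])
    return GWRFit(region_id=region_id, anchors=anchors, coefficients=coefs,
                  bandwidth=best_b, cv_rmse=best_rmse)


def build_pair_table(daily: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Join QC-accepted daily records of matched stations, aligned by day."""
    lcs = daily[daily["network"] == "lowcost"][
        ["station_id", "day", "pm25_daily", "rh", "temp", "x_km", "y_km"]
    ].rename(columns={"station_id": "lcs_id", "pm25_daily": "lcs_pm"})
    ref = daily[daily["network"] == "reference"][
        ["station_id", "day", "pm25_daily"]
    ].rename(columns={"station_id": "ref_id", "pm25_daily": "ref_pm"})
    t = pairs.merge(lcs, on="lcs_id").merge(ref, on=["ref_id", "day"])
    return t


def fit_calibration(daily: pd.DataFrame, pairs: pd.DataFrame, regions: QuadrantRegions,
                    bandwidth_grid: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0),
                    ) -> dict[int, GWRFit]:
    """Fit one GWR per quadrant region from the matched pair-day table.

    A region's training data includes pair-days inside the region or within
    its boundary buffer, so adjacent fits share data near the seams.  Regions
    with too few pairs are skipped (blending renormalizes over fitted ones).
    """
    table = build_pair_table(daily, pairs)
    fits: dict[int, GWRFit] = {}
    if not len(table):
        return fits
    x = table["x_km"].to_numpy(float)
    y = table["y_km"].to_numpy(float)
    rid = regions.region_of(x, y)
    near_x = np.abs(x - regions.x_mid) <= regions.buffer_km
    near_y = np.abs(y - regions.y_mid) <= regions.buffer_km
    for r in range(4):
        in_r = rid == r
        # include buffer neighbours: flip the side across a nearby boundary
        use = in_r.copy()
        use |= (rid == (r ^ 1)) & near_x
        use |= (rid == (r ^ 2)) & near_y
        use |= (rid == (r ^ 3)) & near_x & near_y
        sub = table[use]
        if len(sub) >= 10 and sub["lcs_id"].nunique() >= 1:
            fits[r] = fit_regional_gwr(sub, bandwidth_grid, region_id=r)
        else:
            logger.info("region %d has %d pair-days; skipped", r, len(sub))
    return fits


def apply_calibration(records: pd.DataFrame, fits: dict[int, GWRFit],
                      regions: QuadrantRegions) -> pd.DataFrame:
    """Adjust low-cost daily records with the regional GWR fits.

    Adds ``adjusted_pm25`` (clipped at 0), ``region_id`` and ``blended``.
    Within a boundary buffer the adjacent regions' predictions are blended
    with weights that reach the plain mean on the boundary itself.  Reference
    records pass through with ``adjusted_pm25 = pm25_daily``.
    """
    out = records.copy()
    x = out["x_km"].to_numpy(float)
    y = out["y_km"].to_numpy(float)
    out["region_id"] = regions.region_of(x, y)
    is_lcs = (out["network"] == "lowcost").to_numpy()
    out["adjusted_pm25"] = out["pm25_daily"].astype(float)
    out["blended"] = False
    if not is_lcs.any():
        return out
    if not fits:
        raise ValueError("no fitted calibration regions")
    sub = out[is_lcs]
    w = regions.blend_weights(sub["x_km"].to_numpy(float), sub["y_km"].to_numpy(float))
    have = np.array([r in fits for r in range(4)])
    w = w * have[None, :]
    w = w / w.sum(axis=1, keepdims=True)
    preds = np.zeros((len(sub), 4))
    for r in range(4):
        if have[r]:
            preds[:, r] = fits[r].predict(
                sub["x_km"].to_numpy(float), sub["y_km"].to_numpy(float),
                sub["pm25_daily"].to_numpy(float), sub["rh"].to_numpy(float),
                sub["temp"].to_numpy(float))
    adj = np.clip((w * preds).sum(axis=1), 0, None)
    out.loc[is_lcs, "adjusted_pm25"] = adj
    out.loc[is_lcs, "blended"] = (w > 1e-12).sum(axis=1) > 1
    return out


def select_training_lowcost(records: pd.DataFrame,
                            threshold: float = LOWCOST_TRAINING_THRESHOLD) -> pd.DataFrame:
    """Keep reference records and low-cost records strictly above ``threshold``.

    Only adjusted low-cost observations above the annual standard enter model
    training; values exactly at the threshold are excluded.
    """
    is_ref = records["network"] == "reference"
    keep = is_ref | (records["adjusted_pm25"] > threshold)
    return records[keep].reset_index(drop=True)
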