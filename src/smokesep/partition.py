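"""Smoke-region partition from CTM smoke ratio and plume membership.

The CTM pair gives a simulated smoke fraction of total PM2.5 per cell-day
(clipped at zero, with a small floor on the total to avoid unstable ratios).
A cell-day is smoke-impacted when a plume polygon covers it or the smoke
ratio exceeds a threshold; the threshold is chosen by scanning a grid of
candidates for the one that best balances the two models' training sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CellDayField

RATIO_FLOOR = 0.1          # ug/m3; below this total, the ratio is defined as 0
SMOKE_RATIO_THRESHOLD = 0.03
THRESHOLD_GRID = tuple(np.round(np.arange(0.01, 0.101, 0.01), 2))


def ctm_smoke_ratio(ctm_full: CellDayField, ctm_nofire: CellDayField,
                    floor: float = RATIO_FLOOR) -> CellDayField:
    """Smoke fraction of CTM total PM2.5: max(full - nofire, 0) / full.

    Zero where the total is at or below ``floor``; never negative and never
    above 1.
    """
    full = ctm_full.values
    smoke = np.clip(full - ctm_nofire.values, 0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(full > floor, smoke / full, 0.0)
    return CellDayField(ctm_full.grid, np.clip(r, 0.0, 1.0), "", "smoke_ratio")


def label_regions(ratio: CellDayField, plume_duration: CellDayField,
                  threshold: float = SMOKE_RATIO_THRESHOLD) -> CellDayField:
    """Boolean smoke-impacted label per cell-day.

    Smoke-impacted iff the cell-day lies inside a plume polygon (duration
    > 0) or its CTM smoke ratio is strictly greater than ``threshold``.
    """
    lab = (plume_duration.values > 0) | (ratio.values > threshold)
    return CellDayField(ratio.grid, lab.astype(float), "", "smoke_region")


@dataclass
class ThresholdScan:
    table: pd.DataFrame        # threshold, n_smoke, n_nosmoke, balance
    best_threshold: float


def scan_threshold_balance(ratio: CellDayField, plume_duration: CellDayField,
                           features: pd.DataFrame,
                           thresholds: tuple[float, ...] = THRESHOLD_GRID) -> ThresholdScan:
    """Training-set balance of the two models across candidate ratio thresholds.

    Counts smoke / no-smoke rows among feature rows with observed targets and
    scores each threshold by balance = min(count) / max(count) (0 when either
    side is empty).  Returns the scan table and the balance-maximizing
    threshold (ties broken toward the smaller threshold).
    """
    obs = features[np.isfinite(features["observed_pm25"])]
    flat_ratio = ratio.flat()
    flat_dur = plume_duration.flat()
    cell = obs["cell_id"].to_numpy()
    day = obs["day"].to_numpy()
    r = flat_ratio[day, cell]
    in_plume = flat_dur[day, cell] > 0
    rows = []
    for t in thresholds:
        smoke = in_plume | (r > t)
        n_s = int(smoke.sum())
        n_n = int(len(smoke) - n_s)
        balance = (min(n_s, n_n) / max(n_s, n_n)) if max(n_s, n_n) > 0 else 0.0
        rows.append({"threshold": t, "n_smoke": n_s, "n_nosmoke": n_n, "balance": balance})
    table = pd.DataFrame(rows)
    best = table.loc[table["balance"].idxmax(), "threshold"]
    return ThresholdScan(table=table, best_threshold=float(best))
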