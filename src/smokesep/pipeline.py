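"""End-to-end pipeline over a synthetic world.

Chains every stage — monitor QC, low-cost calibration, regridding and
gap-filling, plume summaries, smoke-region labelling, two-forest fitting,
and smoke estimation — and scores the recovered smoke field against the
retained ground truth and against the raw regridded CTM smoke proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import integration as integ
from . import partition
from .evaluation import _metrics
from .grid import CellDayField
from .model import ModelConfig, SmokeModelResults, TwoStageSmokeModel
from .world import SyntheticWorld, WorldConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    world: SyntheticWorld
    daily: pd.DataFrame                 # QC-accepted daily records
    rejected: pd.DataFrame
    calibrated: pd.DataFrame            # with adjusted_pm25
    fits: dict
    features: pd.DataFrame              # one row per cell-day, labelled
    threshold_scan: partition.ThresholdScan | None
    results: SmokeModelResults
    estimates: pd.DataFrame             # cell_id, day, pm_total/background/smoke
    metrics: dict                       # recovery vs truth, proxy comparison, calibration

    def save(self, path: str | Path, write_features: bool = False) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.calibrated.to_csv(path / "calibrated_monitors.csv", index=False)
        self.estimates.to_csv(path / "estimates.csv", index=False)
        if self.threshold_scan is not None:
            self.threshold_scan.table.to_csv(path / "threshold_scan.csv", index=False)
        if write_features:
            self.features.to_csv(path / "features.csv", index=False)
        import json
        (path / "metrics.json").write_text(json.dumps(self.metrics, indent=2))


def run_pipeline(config: WorldConfig | None = None,
                 model_config: ModelConfig | None = None,
                 world: SyntheticWorld | None = None,
                 smoke_ratio_threshold: float = partition.SMOKE_RATIO_THRESHOLD,
                 run_threshold_scan: bool = False,
                 fit_seed: int | None = None) -> PipelineResult:
    """Run the full chain on a (given or generated) synthetic world."""
    if world is None:
        world = SyntheticWorld.generate(config or WorldConfig())
    config = world.config
    grid = world.grid
    if fit_seed is None:
        fit_seed = config.seed

    # --- sensor QC and calibration ------------------------------------------
    daily, rejected = cal.qc_all(world.monitors)
    regions = cal.QuadrantRegions.for_grid(grid)
    st = world.stations
    pairs = cal.pair_within_radius(st[st["network"] == "lowcost"],
                                   st[st["network"] == "reference"])
    fits = cal.fit_calibration(daily, pairs, regions)
    calibrated = cal.apply_calibration(daily, fits, regions)
    selected = cal.select_training_lowcost(calibrated)

    # --- integration ---------------------------------------------------------
    ctm_total = integ.idw_regrid(world.ctm.full, grid)
    ctm_total.name = "ctm_total"
    ctm_background = integ.idw_regrid(world.ctm.nofire, grid)
    ctm_background.name = "ctm_background"
    cams_fine = integ.idw_regrid(world.aod.cams, grid)
    aod_filled = integ.gap_fill_aod(
        world.aod.aod,
        {"cams": cams_fine, "rh": world.latent.rh, "temp": world.latent.temp})
    dur, den = integ.all_plume_summaries(world.plumes, grid, config.n_days)

    fields = {
        "ctm_total": ctm_total,
        "ctm_background": ctm_background,
        "aod_filled": aod_filled,
        "rh": world.latent.rh,
        "temp": world.latent.temp,
        "wind_u": world.latent.wind_u,
        "wind_v": world.latent.wind_v,
        "plume_duration": dur,
        "plume_density": den,
        "cloud_fraction": world.aod.cloud_fraction,
        "population": world.latent.population,
        "climate_region": CellDayField(grid, world.latent.climate_region[None].astype(float)),
    }
    features = integ.assemble_features(grid, fields, selected)

    # --- smoke-region partition ---------------------------------------------
    ratio = partition.ctm_smoke_ratio(ctm_total, ctm_background)
    scan = None
    if run_threshold_scan:
        scan = partition.scan_threshold_balance(ratio, dur, features)
    labels = partition.label_regions(ratio, dur, smoke_ratio_threshold)
    cell = features["cell_id"].to_numpy()
    day = features["day"].to_numpy()
    features["smoke_region"] = labels.flat()[day, cell].astype(bool)

    # --- model ---------------------------------------------------------------
    model = TwoStageSmokeModel(features, config=model_config)
    results = model.fit(seed=fit_seed)
    estimates = results.estimate_smoke(features)

    # --- recovery metrics vs ground truth ------------------------------------
    truth = world.latent.smoke_true.flat()[day, cell]
    proxy = np.clip(ctm_total.flat() - ctm_background.flat(), 0, None)[day, cell]
    m_r2, _, m_rmse = _metrics(truth, estimates["pm_smoke"].to_numpy())
    p_r2, _, p_rmse = _metrics(truth, proxy)

    # calibration diagnostics: collocated truth at low-cost station cells
    lcs = calibrated[calibrated["network"] == "lowcost"]
    t_flat = (world.latent.background.values + world.latent.smoke_true.values
              ).reshape(config.n_days, -1)
    lcs_cell = grid.cell_of(lcs["x_km"].to_numpy(), lcs["y_km"].to_numpy())
    lcs_truth = t_flat[lcs["day"].to_numpy(), lcs_cell]
    raw_r2, _, raw_rmse = _metrics(lcs_truth, lcs["pm25_daily"].to_numpy())
    adj_r2, _, adj_rmse = _metrics(lcs_truth, lcs["adjusted_pm25"].to_numpy())

    metrics = {
        "n_cell_days": int(len(features)),
        "n_target_rows": int(np.isfinite(features["observed_pm25"]).sum()),
        "n_smoke_rows": int(features.loc[np.isfinite(features["observed_pm25"]),
                                         "smoke_region"].sum()),
        "smoke_r2": m_r2, "smoke_rmse": m_rmse,
        "proxy_r2": p_r2, "proxy_rmse": p_rmse,
        "calibration_raw_r2": raw_r2, "calibration_raw_rmse": raw_rmse,
        "calibration_adjusted_r2": adj_r2, "calibration_adjusted_rmse": adj_rmse,
    }
    return PipelineResult(world=world, daily=daily, rejected=rejected,
                          calibrated=calibrated, fits=fits, features=features,
                          threshold_scan=scan, results=results,
                          estimates=estimates, metrics=metrics)
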