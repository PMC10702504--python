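"""Cross-validated skill of the two-stage model.

Three 20-fold schemes: *overall* assigns rows to folds at random; *spatial*
keeps all rows of a location together, testing transport to unmonitored
places; *temporal* keeps all rows of a calendar day together, testing
transport to unobserved days.  Both forests are refit per fold, SMOTE is
applied inside each fold's training set only, and metrics are pooled over
out-of-fold predictions (oversampled synthetic rows never enter evaluation).
Daily out-of-fold pairs can be aggregated to station-month and station-year
means before recomputing the metrics; unbiased daily errors shrink under
averaging, so aggregated R2 typically rises.

R2 is the squared Pearson correlation of observed and predicted values (the
convention in this literature); the 1 - SSE/SST variant is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelConfig, TwoStageSmokeModel

logger = logging.getLogger(__name__)

N_FOLDS = 20
DAYS_PER_MONTH = 30
DAYS_PER_YEAR = 360


def _metrics(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    """(pearson R2, 1 - SSE/SST, RMSE); R2 is 0 for degenerate inputs."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if len(obs) < 2 or obs.std() == 0 or pred.std() == 0:
        return 0.0, 0.0, rmse
    r = float(np.corrcoef(obs, pred)[0, 1])
    sst = float(((obs - obs.mean()) ** 2).sum())
    r2_sse = 1.0 - float(((obs - pred) ** 2).sum()) / sst if sst > 0 else 0.0
    return r * r, r2_sse, rmse


@dataclass
class CVReport:
    scheme: str
    n_folds: int
    level: str                  # daily / monthly / annual
    r2: float                   # squared Pearson correlation
    r2_sse: float               # 1 - SSE/SST
    rmse: float
    n: int
    per_fold: pd.DataFrame | None = None
    oof: pd.DataFrame | None = None     # out-of-fold (cell_id, day, obs, pred)

    def summary(self) -> str:
        return (f"{self.scheme} {self.n_folds}-fold CV ({self.level}): "
                f"R2={self.r2:.3f} (1-SSE/SST={self.r2_sse:.3f}), "
                f"RMSE={self.rmse:.2f} ug/m3, n={self.n}")

    def plot(self, ax=None):
        """Observed vs predicted scatter of the out-of-fold pairs."""
        import matplotlib.pyplot as plt

        if self.oof is None:
            raise ValueError("no out-of-fold pairs stored")
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.oof["obs"], self.oof["pred"], s=4, alpha=0.4)
        lim = [0, max(self.oof["obs"].max(), self.oof["pred"].max())]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("observed PM2.5 (ug/m3)")
        ax.set_ylabel("predicted PM2.5 (ug/m3)")
        ax.set_title(self.summary())
        return ax


def make_folds(rows: pd.DataFrame, scheme: str, n_folds: int = N_FOLDS,
               seed: int = 0, temporal_contiguous: bool = False) -> np.ndarray:
    """Fold id per row under the given scheme.

    overall: random row assignment with sizes differing by at most one.
    spatial: all rows of one cell share a fold.  temporal: all rows of one
    day share a fold (random days by default; ``temporal_contiguous`` uses
    consecutive blocks of days instead).
    """
    rng = np.random.default_rng([seed, 0xF01D])
    n = len(rows)
    if scheme == "overall":
        folds = np.empty(n, int)
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            folds[chunk] = f
        return folds
    key_col = {"spatial": "cell_id", "temporal": "day"}.get(scheme)
    if key_col is None:
        raise ValueError(f"unknown CV scheme: {scheme!r}")
    keys = rows[key_col].to_numpy()
    uniq = np.unique(keys)
    if scheme == "temporal" and temporal_contiguous:
        order = np.sort(uniq)
    else:
        order = rng.permutation(uniq)
    group_fold = {}
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        for g in chunk:
            group_fold[g] = f
    return np.array([group_fold[k] for k in keys], int)


def cross_validate(features: pd.DataFrame, scheme: str = "overall",
                   config: ModelConfig | None = None, n_folds: int = N_FOLDS,
                   seed: int = 0, target_col: str = "observed_pm25",
                   temporal_contiguous: bool = False) -> CVReport:
    """Pooled out-of-fold skill, refitting both forests per fold.

    ``features`` must contain only rows with observed targets.  SMOTE runs
    inside each fold's training split, so synthetic rows never leak across
    the boundary; empty test folds are merged into the next fold.
    """
    rows = features[np.isfinite(features[target_col].to_numpy(float))].reset_index(drop=True)
    folds = make_folds(rows, scheme, n_folds, seed, temporal_contiguous)
    oof_parts, fold_stats = [], []
    fold_ids = [f for f in range(n_folds) if (folds == f).any()]
    n_empty = n_folds - len(fold_ids)
    if n_empty:
        logger.info("%d folds empty after exclusions; merged", n_empty)
    for f in fold_ids:
        test = folds == f
        train = rows[~test]
        model = TwoStageSmokeModel(train, config=config, target_col=target_col)
        res = model.fit(seed=seed * n_folds + f)
        tf = rows[test]
        label = tf[model.label_col].astype(bool).to_numpy()
        pred = res.predict_background(tf)
        if label.any():
            pred[label] = res.predict_total(tf[label])
        part = pd.DataFrame({
            "cell_id": tf["cell_id"].to_numpy(), "day": tf["day"].to_numpy(),
            "obs": tf[target_col].to_numpy(float), "pred": np.clip(pred, 0, None),
            "fold": f,
        })
        oof_parts.append(part)
        r2, r2s, rmse = _metrics(part["obs"], part["pred"])
        fold_stats.append({"fold": f, "n": len(part), "r2": r2, "rmse": rmse})
    oof = pd.concat(oof_parts, ignore_index=True)
    r2, r2s, rmse = _metrics(oof["obs"], oof["pred"])
    return CVReport(scheme=scheme, n_folds=n_folds, level="daily", r2=r2, r2_sse=r2s,
                    rmse=rmse, n=len(oof), per_fold=pd.DataFrame(fold_stats), oof=oof)


def aggregate_cv(oof: pd.DataFrame, scheme: str = "overall", n_folds: int = N_FOLDS,
                 days_per_month: int = DAYS_PER_MONTH,
                 days_per_year: int = DAYS_PER_YEAR) -> dict[str, CVReport]:
    """Recompute CV metrics on station-month and station-year mean pairs.

    Observed and predicted values are averaged within (cell, month) and
    (cell, year) before the metrics are recomputed, mirroring monthly and
    annual exposure aggregation.
    """
    out = {}
    work = oof.copy()
    work["month"] = work["day"] // days_per_month
    work["year"] = work["day"] // days_per_year
    for level, key in (("monthly", "month"), ("annual", "year")):
        agg = work.groupby(["cell_id", key], observed=True)[["obs", "pred"]].mean()
        r2, r2s, rmse = _metrics(agg["obs"], agg["pred"])
        out[level] = CVReport(scheme=scheme, n_folds=n_folds, level=level, r2=r2,
                              r2_sse=r2s, rmse=rmse, n=len(agg))
    return out
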