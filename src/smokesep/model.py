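"""Two-stage random-forest separation of smoke and background PM2.5.

In the smoke-impacted region a random forest is trained on observed total
PM2.5 with the fire-run CTM total and plume descriptors among its predictors
(PM(s,t) ~ X'(s,t) + Z'(s,t)); in the no-smoke region a second forest is
trained on observed total PM2.5 — assumed there to be all background — with
the no-fire CTM among its predictors (PM_B(s,t) ~ X(s,t) + Z(s,t)).  The
background forest also predicts background inside the smoke region, and the
smoke component is the clipped difference of the two predictions:

    PM_F(s,t) = max(PM(s,t) - PM_B(s,t), 0)   in the smoke region,
    PM_F(s,t) = 0                             elsewhere.

High observed concentrations are rare in monitor data, so rows above the
24-hour standard are oversampled with a regression variant of SMOTE before
fitting: each seed row spawns synthetic rows interpolated (features and
target jointly) toward one of its nearest neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import NearestNeighbors

from .integration import BACKGROUND_FEATURES, SMOKE_ONLY_FEATURES

logger = logging.getLogger(__name__)

SMOTE_ONCE_BAND = (35.0, 100.0)   # oversampled once: 24h-standard exceedances
SMOTE_TWICE_THRESHOLD = 100.0     # oversampled twice above this


@dataclass
class ModelConfig:
    """Hyperparameters of the two forests and the SMOTE step."""

    n_estimators: int = 200
    max_features: str | float = "sqrt"
    min_samples_leaf: int = 3
    smote_k: int = 5
    smote_mode: str = "feature"   # "feature" (standardized predictors) or "geographic"
    smote_once_band: tuple[float, float] = SMOTE_ONCE_BAND
    smote_twice_threshold: float = SMOTE_TWICE_THRESHOLD


def smote_oversample(
    rows: pd.DataFrame,
    feature_cols: list[str],
    target_col: str = "observed_pm25",
    k: int = 5,
    seed: int = 0,
    mode: str = "feature",
    once_band: tuple[float, float] = SMOTE_ONCE_BAND,
    twice_threshold: float = SMOTE_TWICE_THRESHOLD,
    fixed_lambda: float | None = None,
) -> pd.DataFrame:
    """Oversample high-concentration rows by convex interpolation.

    Rows with target strictly above ``once_band[0]`` and at or below
    ``once_band[1]`` get one synthetic copy; rows strictly above
    ``twice_threshold`` get two.  Each synthetic row lies at a uniform
    convex combination of its seed row and one of the seed's k nearest
    neighbours among all input rows — in standardized feature space by
    default, or in geographic (x, y) space — interpolating the listed
    features and the target jointly.  Synthetic rows are flagged
    ``oversampled = True``; input rows are returned unchanged.  A
    ``fixed_lambda`` pins the interpolation weight (0 duplicates the seed
    row exactly).
    """
    out = rows.copy()
    if "oversampled" not in out.columns:
        out["oversampled"] = False
    t = rows[target_col].to_numpy(float)
    lo, hi = once_band
    n_rep = np.where(t > twice_threshold, 2, np.where((t > lo) & (t <= hi), 1, 0))
    seeds_ix = np.where(n_rep > 0)[0]
    if not len(seeds_ix) or len(rows) < 2:
        return out

    if mode == "geographic":
        space = rows[["x_km", "y_km"]].to_numpy(float)
    else:
        space = rows[feature_cols].to_numpy(float)
        sd = space.std(axis=0)
        sd[sd == 0] = 1.0
        space = (space - space.mean(axis=0)) / sd
    k_eff = min(k, len(rows) - 1)
    if k_eff < k:
        logger.info("only %d neighbours available for SMOTE (k=%d requested)", k_eff, k)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(space)
    _, nbr = nn.kneighbors(space[seeds_ix])

    rng = np.random.default_rng([seed, 0x5307E])
    interp_cols = list(dict.fromkeys(feature_cols + [target_col]))
    base = rows[interp_cols].to_numpy(float)
    new_rows = []
    for row_pos, i in enumerate(seeds_ix):
        # drop self from the neighbour list
        cand = [j for j in nbr[row_pos] if j != i][:k_eff]
        for _ in range(int(n_rep[i])):
            j = cand[int(rng.integers(len(cand)))]
            lam = rng.uniform() if fixed_lambda is None else fixed_lambda
            synth = rows.iloc[i].copy()
            synth[interp_cols] = base[i] + lam * (base[j] - base[i])
            synth["oversampled"] = True
            new_rows.append(synth)
    return pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)


def _feature_sets(columns: list[str]) -> tuple[list[str], list[str]]:
    """(background features X+Z, smoke features X'+Z') present in the table."""
    climate = sorted(c for c in columns if c.startswith("climate_"))
    z = [c for c in BACKGROUND_FEATURES if c != "ctm_background" and c in columns] + climate
    bg = [c for c in ["ctm_background"] if c in columns] + z
    smoke = [c for c in ["ctm_total"] if c in columns] + z \
        + [c for c in SMOKE_ONLY_FEATURES if c in columns]
    return bg, smoke


class TwoStageSmokeModel:
    """Model object holding the training table and configuration.

    ``features`` needs one row per training cell-day with the predictor
    columns, an ``observed_pm25`` target, and a ``smoke_region`` label
    (truthy = smoke-impacted).  Rows without a target are ignored at fit
    time.  ``fit(seed)`` trains both forests (after in-region SMOTE) and
    returns a :class:`SmokeModelResults`.
    """

    def __init__(self, features: pd.DataFrame, config: ModelConfig | None = None,
                 target_col: str = "observed_pm25", label_col: str = "smoke_region"):
        self.config = config or ModelConfig()
        self.target_col = target_col
        self.label_col = label_col
        self.features = features
        self.background_features, self.smoke_features = _feature_sets(list(features.columns))
        if not self.background_features or not self.smoke_features:
            raise ValueError("feature table lacks the CTM predictor columns")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TwoStageSmokeModel":
        return cls(df, **kwargs)

    def _training_split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        obs = self.features[np.isfinite(self.features[self.target_col].to_numpy(float))]
        smoke = obs[obs[self.label_col].astype(bool)]
        nosmoke = obs[~obs[self.label_col].astype(bool)]
        if not len(smoke):
            raise ValueError("no training rows in the smoke-impacted region")
        if not len(nosmoke):
            raise ValueError("no training rows in the no-smoke region")
        return smoke, nosmoke

    def fit(self, seed: int = 0) -> "SmokeModelResults":
        cfg = self.config
        smoke, nosmoke = self._training_split()
        smoke_aug = smote_oversample(
            smoke, self.smoke_features, self.target_col, k=cfg.smote_k,
            seed=seed, mode=cfg.smote_mode, once_band=cfg.smote_once_band,
            twice_threshold=cfg.smote_twice_threshold)
        nosmoke_aug = smote_oversample(
            nosmoke, self.background_features, self.target_col, k=cfg.smote_k,
            seed=seed + 1, mode=cfg.smote_mode, once_band=cfg.smote_once_band,
            twice_threshold=cfg.smote_twice_threshold)

        def make_rf(rs: int) -> RandomForestRegressor:
            return RandomForestRegressor(
                n_estimators=cfg.n_estimators, max_features=cfg.max_features,
                min_samples_leaf=cfg.min_samples_leaf, random_state=rs, n_jobs=1)

        rf_smoke = make_rf(int(seed) & 0x7FFFFFFF)
        rf_smoke.fit(smoke_aug[self.smoke_features].to_numpy(float),
                     smoke_aug[self.target_col].to_numpy(float))
        rf_bg = make_rf((int(seed) + 1) & 0x7FFFFFFF)
        rf_bg.fit(nosmoke_aug[self.background_features].to_numpy(float),
                  nosmoke_aug[self.target_col].to_numpy(float))
        return SmokeModelResults(
            model=self, rf_smoke=rf_smoke, rf_background=rf_bg, seed=seed,
            n_train_smoke=len(smoke), n_train_nosmoke=len(nosmoke),
            n_oversampled_smoke=len(smoke_aug) - len(smoke),
            n_oversampled_nosmoke=len(nosmoke_aug) - len(nosmoke),
        )


@dataclass
class SmokeModelResults:
    """Fitted two-forest bundle with prediction and diagnostics."""

    model: TwoStageSmokeModel
    rf_smoke: RandomForestRegressor
    rf_background: RandomForestRegressor
    seed: int
    n_train_smoke: int
    n_train_nosmoke: int
    n_oversampled_smoke: int
    n_oversampled_nosmoke: int

    def predict_total(self, rows: pd.DataFrame) -> np.ndarray:
        """Smoke-region forest prediction of total PM2.5."""
        return self.rf_smoke.predict(rows[self.model.smoke_features].to_numpy(float))

    def predict_background(self, rows: pd.DataFrame) -> np.ndarray:
        return self.rf_background.predict(
            rows[self.model.background_features].to_numpy(float))

    def estimate_smoke(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Per cell-day total, background, and smoke PM2.5 estimates.

        In smoke-impacted rows the total comes from the smoke forest and the
        background from the background forest (predicting background inside
        the smoke region); smoke is their difference clipped at zero.  In
        no-smoke rows total = background and smoke = 0.
        """
        label = rows[self.model.label_col].astype(bool).to_numpy()
        pm_background = np.clip(self.predict_background(rows), 0, None)
        pm_total = pm_background.copy()
        if label.any():
            pm_total[label] = np.clip(self.predict_total(rows[label]), 0, None)
        pm_smoke = np.where(label, np.clip(pm_total - pm_background, 0, None), 0.0)
        return pd.DataFrame({
            "cell_id": rows["cell_id"].to_numpy() if "cell_id" in rows else np.arange(len(rows)),
            "day": rows["day"].to_numpy() if "day" in rows else 0,
            "region_label": label,
            "pm_total": pm_total,
            "pm_background": pm_background,
            "pm_smoke": pm_smoke,
        })

    def variable_importance(self) -> dict[str, pd.Series]:
        """Impurity-based importances per model, normalized, descending."""
        out = {}
        for name, rf, feats in (
            ("smoke", self.rf_smoke, self.model.smoke_features),
            ("background", self.rf_background, self.model.background_features),
        ):
            imp = pd.Series(rf.feature_importances_, index=feats)
            s = imp.sum()
            if s > 0:
                imp = imp / s
            out[name] = imp.sort_values(ascending=False)
        return out

    def summary(self) -> str:
        imp = self.variable_importance()
        cfg = self.model.config
        lines = [
            "Two-stage smoke PM2.5 separation (random forests)",
            "=" * 52,
            f"forests: {cfg.n_estimators} trees, max_features={cfg.max_features}, "
            f"min_samples_leaf={cfg.min_samples_leaf}, seed={self.seed}",
            f"smoke-impacted model:  {self.n_train_smoke} rows "
            f"(+{self.n_oversampled_smoke} SMOTE)",
            f"no-smoke model:        {self.n_train_nosmoke} rows "
            f"(+{self.n_oversampled_nosmoke} SMOTE)",
            "",
            "top predictors (impurity importance):",
        ]
        for name in ("smoke", "background"):
            top = imp[name].head(5)
            lines.append(f"  {name}: " + ", ".join(f"{k}={v:.3f}" for k, v in top.items()))
        return "\n".join(lines)

    def plot_importance(self, ax=None):
        """Horizontal bar chart of the two models' predictor importances."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(10, 4))
        for a, (name, imp) in zip(np.ravel(ax), self.variable_importance().items()):
            imp.iloc[::-1].plot.barh(ax=a)
            a.set_title(f"{name} model")
            a.set_xlabel("importance")
        return ax
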