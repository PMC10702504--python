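import numpy as np
import pandas as pd
import pytest

from smokesep import SyntheticWorld, WorldConfig, run_pipeline
from smokesep.model import ModelConfig


def small_config(seed: int = 3, **overrides) -> WorldConfig:
    """A quick 24 km world exercising every pipeline stage."""
    base = dict(
        n_rows=24, n_cols=24, n_days=40, n_ref_monitors=25, n_lcs_monitors=50,
        n_smoke_events=3, ctm_coarse_factor=4, seed=seed,
    )
    base.update(overrides)
    return WorldConfig(**base)


def easy_config(seed: int = 0, **overrides) -> WorldConfig:
    """A world where the CTM equals the truth and monitors are dense and clean."""
    base = dict(
        n_rows=20, n_cols=20, n_days=30, n_ref_monitors=150, n_lcs_monitors=10,
        n_smoke_events=2, ctm_coarse_factor=1, seed=seed,
        ctm_bias_sd=0.0, ctm_smoke_bias_sd=0.0, ctm_noise_sd=0.0,
        ref_noise_sd=0.01, lcs_corruption_fraction=0.0,
    )
    base.update(overrides)
    return WorldConfig(**base)


FAST_MODEL = ModelConfig(n_estimators=50)


@pytest.fixture(scope="session")
def small_world() -> SyntheticWorld:
    return SyntheticWorld.generate(small_config())


@pytest.fixture(scope="session")
def small_pipeline(small_world):
    return run_pipeline(world=small_world, model_config=FAST_MODEL,
                        run_threshold_scan=True)


@pytest.fixture(scope="session")
def target_rows(small_pipeline) -> pd.DataFrame:
    """Feature rows of the small world that carry observed targets."""
    f = small_pipeline.features
    return f[np.isfinite(f["observed_pm25"])].reset_index(drop=True)
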