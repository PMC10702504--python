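"""Synthetic world generator: determinism, ground truth, and stage contracts."""

import numpy as np
import pytest
import shapely
from scipy.stats import chisquare, spearmanr

from smokesep.grid import GridDefinition
from smokesep.world import (
    PuffEvent, SyntheticWorld, WorldConfig, _place_stations, block_average,
    make_world, simulate_aod, simulate_ctm, simulate_monitors, simulate_plumes,
)
from conftest import small_config


def tiny_config(**kw):
    base = dict(n_rows=12, n_cols=12, n_days=8, n_ref_monitors=5,
                n_lcs_monitors=8, n_smoke_events=2, ctm_coarse_factor=3, seed=5)
    base.update(kw)
    return WorldConfig(**base)


class TestMakeWorld:
    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            WorldConfig(n_rows=0)
        with pytest.raises(ValueError):
            WorldConfig(n_days=-1)

    def test_no_events_means_no_smoke(self):
        _, latent = make_world(tiny_config(n_smoke_events=0))
        assert np.all(latent.smoke_true.values == 0)

    def test_background_strictly_positive(self):
        _, latent = make_world(tiny_config())
        assert np.all(latent.background.values > 0)

    def test_same_seed_identical_fields(self):
        _, a = make_world(tiny_config())
        _, b = make_world(tiny_config())
        for name in ("background", "smoke_true", "rh", "temp", "wind_u", "wind_v"):
            np.testing.assert_array_equal(getattr(a, name).values,
                                          getattr(b, name).values)
        np.testing.assert_array_equal(a.population.values, b.population.values)

    def test_puff_field_matches_bruteforce_rerun(self):
        """The smoke field equals an independent scripted evaluation of the
        stored puff trajectories, and so does the >1 ug/m3 exceedance fraction."""
        cfg = WorldConfig(n_rows=32, n_cols=32, n_days=30, n_smoke_events=3,
                          n_ref_monitors=5, n_lcs_monitors=5, seed=7)
        grid, latent = make_world(cfg)
        xs = grid.x_centers()
        ys = grid.y_centers()
        oracle = np.zeros((cfg.n_days, 32, 32))
        for ev in latent.events:
            for a in range(ev.lifespan):
                d = ev.day0 + a
                if d >= cfg.n_days:
                    break
                for r in range(32):
                    dy2 = (ys[r] - ev.centers_y[a]) ** 2
                    dx2 = (xs - ev.centers_x[a]) ** 2
                    oracle[d, r] += ev.amplitudes[a] * np.exp(
                        -(dx2 + dy2) / (2 * ev.sigmas[a] ** 2))
        np.testing.assert_allclose(latent.smoke_true.values, oracle, rtol=1e-9)
        assert (latent.smoke_true.values > 1).mean() == (oracle > 1).mean()
        assert 0 < (oracle > 1).mean() < 1

    def test_smoke_zero_outside_event_days(self):
        cfg = tiny_config()
        _, latent = make_world(cfg)
        active = np.zeros(cfg.n_days, bool)
        for ev in latent.events:
            active[ev.day0: ev.day0 + ev.lifespan] = True
        assert np.all(latent.smoke_true.values[~active] == 0)


class TestCTM:
    def test_no_smoke_runs_identical(self):
        cfg = tiny_config(n_smoke_events=0)
        grid, latent = make_world(cfg)
        ctm = simulate_ctm(latent, grid, cfg)
        np.testing.assert_array_equal(ctm.full.values, ctm.nofire.values)

    def test_noise_free_limit_is_exact(self):
        cfg = tiny_config(ctm_coarse_factor=1, ctm_bias_sd=0.0,
                          ctm_smoke_bias_sd=0.0, ctm_noise_sd=0.0)
        grid, latent = make_world(cfg)
        ctm = simulate_ctm(latent, grid, cfg)
        np.testing.assert_allclose(
            ctm.full.values, latent.background.values + latent.smoke_true.values)

    def test_difference_matches_stored_bias_recomputation(self):
        cfg = small_config()
        grid, latent = make_world(cfg)
        ctm = simulate_ctm(latent, grid, cfg)
        avg_bg = block_average(latent.background.values, cfg.ctm_coarse_factor)
        avg_smoke = block_average(latent.smoke_true.values, cfg.ctm_coarse_factor)
        full = np.clip(ctm.bias[None] * (avg_bg + ctm.smoke_bias[None] * avg_smoke)
                       + ctm.noise, 0, None)
        nofire = np.clip(ctm.bias[None] * avg_bg + ctm.noise, 0, None)
        np.testing.assert_allclose(ctm.full.values, full, rtol=1e-12)
        np.testing.assert_allclose(ctm.nofire.values, nofire, rtol=1e-12)

    def test_proxy_correlates_with_true_smoke(self):
        cfg = small_config()
        grid, latent = make_world(cfg)
        ctm = simulate_ctm(latent, grid, cfg)
        proxy = ctm.full.values - ctm.nofire.values
        truth = block_average(latent.smoke_true.values, cfg.ctm_coarse_factor)
        sel = truth > 0
        assert np.corrcoef(proxy[sel], truth[sel])[0, 1] > 0

    def test_difference_nonnegative(self):
        cfg = small_config()
        grid, latent = make_world(cfg)
        ctm = simulate_ctm(latent, grid, cfg)
        assert np.all(ctm.full.values - ctm.nofire.values >= -1e-12)

    def test_block_average_ragged_edge(self):
        vals = np.arange(1 * 5 * 7, dtype=float).reshape(1, 5, 7)
        out = block_average(vals, 3)
        assert out.shape == (1, 2, 3)
        np.testing.assert_allclose(out[0, 1, 2], vals[0, 3:5, 6:7].mean())


class TestPlumes:
    def test_no_smoke_no_false_positives_empty(self):
        cfg = tiny_config(n_smoke_events=0, plume_false_positive_rate=0.0)
        _, latent = make_world(cfg)
        plumes = simulate_plumes(latent, cfg)
        assert all(len(v) == 0 for v in plumes.values())

    def test_exact_contouring_covers_all_exceeding_cells(self):
        cfg = small_config(plume_shape_jitter_km=0.0, plume_omission_rate=0.0,
                           plume_false_positive_rate=0.0)
        grid, latent = make_world(cfg)
        plumes = simulate_plumes(latent, cfg)
        centers = grid.cell_centers()
        for d in range(cfg.n_days):
            exceed = (latent.smoke_true.values[d] > cfg.plume_detect_threshold).ravel()
            if not exceed.any():
                assert not plumes[d]
                continue
            covered = np.zeros(grid.n_cells, bool)
            for p in plumes[d]:
                covered |= shapely.contains_xy(p.geometry, centers[:, 0], centers[:, 1])
            assert covered[exceed].all()

    def test_deterministic_replay(self):
        cfg = small_config()
        _, latent = make_world(cfg)
        a = simulate_plumes(latent, cfg)
        b = simulate_plumes(latent, cfg)
        assert {d: len(v) for d, v in a.items()} == {d: len(v) for d, v in b.items()}
        for d in a:
            for pa, pb in zip(a[d], b[d]):
                assert pa.geometry.equals(pb.geometry)
                assert pa.duration_h == pb.duration_h
                assert pa.density_class == pb.density_class


class TestAOD:
    def test_zero_missing_fraction_full_coverage(self):
        cfg = tiny_config(aod_missing_fraction=0.0)
        _, latent = make_world(cfg)
        out = simulate_aod(latent, cfg)
        assert not np.isnan(out.aod.values).any()

    def test_noise_free_aod_rank_correlates_within_day(self):
        cfg = tiny_config(aod_noise_sd=0.0, aod_smoke_lofting_sd=0.0,
                          aod_missing_fraction=0.0)
        _, latent = make_world(cfg)
        out = simulate_aod(latent, cfg)
        for d in range(cfg.n_days):
            rho = spearmanr(out.aod.values[d].ravel(), latent.total[d].ravel())[0]
            assert rho > 0.9999

    def test_realized_missing_fraction_near_target(self):
        cfg = small_config()
        _, latent = make_world(cfg)
        out = simulate_aod(latent, cfg)
        assert abs(out.aod.missing_fraction() - cfg.aod_missing_fraction) < 0.05


class TestMonitors:
    def test_identity_bias_channels_track_truth(self):
        cfg = tiny_config(lcs_rh_bias_coef=0.0, lcs_corruption_fraction=0.0,
                          lcs_noise_sd=0.5)
        grid, latent = make_world(cfg)
        monitors, stations, _ = simulate_monitors(latent, grid, cfg)
        lcs = monitors[monitors["network"] == "lowcost"]
        daily = lcs.groupby(["station_id", "day"], observed=True)["pm25"].mean()
        truth_flat = latent.total.reshape(cfg.n_days, -1)
        st = stations.set_index("station_id")
        for (sid, day), val in daily.items():
            t = truth_flat[day, int(st.loc[sid, "cell_id"])]
            assert abs(val - t) < 5 * 0.5 / np.sqrt(48)

    def test_uniform_placement_when_alpha_zero(self):
        grid = GridDefinition(40, 40, 1.0)
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pop = rng.uniform(1, 5000, (40, 40))    # alpha=0 must neutralize this
            placed = _place_stations(rng, grid, pop, 500, alpha=0.0)
            x, y = placed[:, 1], placed[:, 2]
            quad = (x >= 20).astype(int) + 2 * (y >= 20).astype(int)
            counts = np.bincount(quad, minlength=4)
            if chisquare(counts)[1] < 0.01:
                rejections += 1
        assert rejections <= 5

    def test_corruption_bookkeeping(self):
        cfg = tiny_config(n_lcs_monitors=25, n_days=8, lcs_corruption_fraction=0.1)
        grid, latent = make_world(cfg)
        _, _, log = simulate_monitors(latent, grid, cfg)
        assert len(log) == round(0.1 * 25 * 8)
        assert not log.duplicated(["station_id", "day"]).any()

    def test_reference_reports_24_hourly_values(self):
        cfg = tiny_config()
        grid, latent = make_world(cfg)
        monitors, _, _ = simulate_monitors(latent, grid, cfg)
        ref = monitors[monitors["network"] == "reference"]
        assert (ref.groupby(["station_id", "day"], observed=True)["hour"]
                .nunique() == 24).all()


class TestSerialization:
    def test_roundtrip_and_byte_determinism(self, tmp_path):
        cfg = tiny_config()
        w1 = SyntheticWorld.generate(cfg)
        w2 = SyntheticWorld.generate(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        w1.save(d1)
        w2.save(d2)
        for rel in ("monitors.csv", "background.npy", "smoke_true.npy",
                    "grid.json", "plumes/plumes_0000.geojson"):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
        loaded = SyntheticWorld.load(d1)
        np.testing.assert_array_equal(loaded.latent.smoke_true.values,
                                      w1.latent.smoke_true.values)
        np.testing.assert_array_equal(loaded.ctm.full.values, w1.ctm.full.values)
        assert len(loaded.monitors) == len(w1.monitors)
        assert {d: len(v) for d, v in loaded.plumes.items()} == \
               {d: len(v) for d, v in w1.plumes.items()}
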