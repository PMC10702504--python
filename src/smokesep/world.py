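"""Synthetic study worlds with retained ground truth.

Generates every input the estimation pipeline consumes — a latent background
PM2.5 field, episodic advected smoke plumes, a biased/noisy chemical-transport
model (CTM) pair run with and without fire emissions, imperfect analyst-style
plume polygons, aerosol optical depth (AOD) with cloud-driven missingness,
meteorology, a sparse urban-biased reference monitor network, a denser
humidity-biased low-cost network, and population density — while keeping the
true smoke field so that downstream recovery is testable.

Randomness is split into independent, replayable streams (one per stage)
derived from the world seed, so regenerating any one stage with the same
config reproduces it bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon, mapping, shape
import shapely
from skimage import measure

from .grid import CellDayField, GridDefinition, load_field, load_grid, save_field, save_grid

# per-stage random stream ids
_RS_FIELDS, _RS_CTM, _RS_PLUMES, _RS_AOD, _RS_MONITORS = range(5)


@dataclass
class WorldConfig:
    """Configuration of one synthetic world.

    The defaults define the package's standard study conditions: a 64 km x
    64 km domain at 1 km resolution over 120 days, 60 reference and 150
    low-cost monitors, and 6 smoke events.
    """

    n_rows: int = 64
    n_cols: int = 64
    cell_km: float = 1.0
    n_days: int = 120
    n_ref_monitors: int = 60
    n_lcs_monitors: int = 150
    n_smoke_events: int = 6
    ctm_coarse_factor: int = 8
    seed: int = 0

    # background field (ug/m3)
    background_mean: float = 8.0
    background_spatial_sd: float = 0.4    # lognormal sd of the spatial pattern
    background_temporal_sd: float = 0.2   # lognormal sd of the day factor
    background_noise_sd: float = 0.15     # lognormal sd of space-time noise
    background_corr_cells: float = 6.0    # spatial correlation length, cells
    urban_bump: float = 3.0               # ug/m3 added at the population peak
    urban_bump_sigma_km: float = 5.0

    # smoke events (Gaussian puffs advected by the daily wind)
    event_amplitude_range: tuple[float, float] = (40.0, 160.0)
    event_lifespan_range: tuple[int, int] = (4, 12)
    event_decay_days_range: tuple[float, float] = (2.0, 5.0)
    event_sigma_km_range: tuple[float, float] = (3.0, 7.0)
    event_growth_km_per_day_range: tuple[float, float] = (0.3, 1.0)

    # meteorology
    rh_mean: float = 55.0
    temp_mean_f: float = 65.0
    wind_speed_scale: float = 8.0         # km/day

    # population
    n_urban_centers: int = 3
    rural_floor: float = 20.0             # persons/km2
    n_climate_regions: int = 6

    # CTM distortion
    ctm_bias_sd: float = 0.25             # lognormal sd of the shared bias
    ctm_smoke_bias_sd: float = 0.3        # extra lognormal bias on the smoke term
    ctm_noise_sd: float = 1.5             # additive noise, ug/m3, shared by both runs

    # plume detection/perturbation
    plume_detect_threshold: float = 2.0   # ug/m3
    plume_shape_jitter_km: float = 1.0
    plume_omission_rate: float = 0.1
    plume_false_positive_rate: float = 0.5  # expected spurious polygons per day
    plume_density_light_max: float = 5.0
    plume_density_medium_max: float = 20.0

    # AOD: affine in total PM2.5 with day-varying coefficients (boundary-layer
    # and aerosol-profile variability make the column-to-surface relation
    # unstable from day to day)
    aod_intercept: float = 0.02
    aod_slope: float = 0.008              # per ug/m3
    aod_slope_daily_sd: float = 0.3       # lognormal sd of the daily slope factor
    aod_intercept_daily_sd: float = 0.01
    aod_smoke_lofting_sd: float = 0.8     # lognormal sd of the daily smoke lofting
                                          # factor (plumes aloft decouple column
                                          # AOD from surface smoke PM2.5)
    aod_noise_sd: float = 0.05
    aod_missing_fraction: float = 0.40
    cams_noise_sd: float = 0.01

    # monitor networks
    ref_placement_alpha: float = 1.0      # placement probability ~ population^alpha
    lcs_placement_alpha: float = 0.3
    ref_noise_sd: float = 1.0             # hourly, ug/m3
    lcs_noise_sd: float = 2.0
    lcs_rh_bias_coef: float = 0.004       # multiplicative bias = 1 + coef * RH(%)
    lcs_corruption_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "n_rows", "n_cols", "n_days", "n_ref_monitors",
            "n_lcs_monitors", "ctm_coarse_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_smoke_events < 0:
            raise ValueError("n_smoke_events must be >= 0")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")

    def grid(self) -> GridDefinition:
        return GridDefinition(self.n_rows, self.n_cols, self.cell_km)


@dataclass
class PuffEvent:
    """One smoke event: a Gaussian puff advected by the domain-mean wind.

    ``centers_x/y``, ``amplitudes`` and ``sigmas`` are the realized per-age
    trajectories (length ``lifespan``), so the field contribution can be
    recomputed from this record alone.
    """

    day0: int
    lifespan: int
    centers_x: list[float]
    centers_y: list[float]
    amplitudes: list[float]
    sigmas: list[float]

    def evaluate(self, grid: GridDefinition, n_days: int) -> np.ndarray:
        """Contribution of this event to the smoke field, shape (n_days, nr, nc)."""
        out = np.zeros((n_days, grid.n_rows, grid.n_cols))
        xx, yy = np.meshgrid(grid.x_centers(), grid.y_centers())
        for a in range(self.lifespan):
            d = self.day0 + a
            if d >= n_days:
                break
            s2 = 2.0 * self.sigmas[a] ** 2
            out[d] += self.amplitudes[a] * np.exp(
                -((xx - self.centers_x[a]) ** 2 + (yy - self.centers_y[a]) ** 2) / s2
            )
        return out


@dataclass
class LatentFields:
    """Ground-truth fields of one world; all on the fine grid."""

    background: CellDayField       # ug/m3, strictly positive
    smoke_true: CellDayField       # ug/m3, >= 0, zero on event-free days
    rh: CellDayField               # %
    temp: CellDayField             # deg F
    wind_u: CellDayField           # km/day
    wind_v: CellDayField           # km/day
    population: CellDayField       # persons/km2, day-static
    climate_region: np.ndarray     # int region code per cell, (nr, nc)
    events: list[PuffEvent] = field(default_factory=list)

    @property
    def total(self) -> np.ndarray:
        return self.background.values + self.smoke_true.values


def _smooth2d(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _smooth3d(rng: np.random.Generator, shape: tuple[int, int, int],
              sigma: tuple[float, float, float]) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _ar1(rng: np.random.Generator, n: int, rho: float = 0.7) -> np.ndarray:
    """Unit-variance AR(1) series."""
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = rho * x[t - 1] + np.sqrt(1 - rho**2) * e[t]
    return x


def make_world(config: WorldConfig) -> tuple[GridDefinition, LatentFields]:
    """Generate the latent ground-truth fields of a synthetic world.

    The background is a positive, spatially correlated lognormal field with an
    urban bump at the population maximum; smoke is a sum of advected,
    time-decaying Gaussian puffs; population is a mixture of urban kernels
    over a rural floor.  Identical configs (including seed) give identical
    fields.
    """
    grid = config.grid()
    rng = np.random.default_rng([config.seed, _RS_FIELDS])
    nr, nc, nd = config.n_rows, config.n_cols, config.n_days
    xx, yy = np.meshgrid(grid.x_centers(), grid.y_centers())

    # population: urban kernels over a rural floor
    pop = np.full((nr, nc), config.rural_floor)
    w, h = grid.extent_km
    for _ in range(config.n_urban_centers):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        amp = rng.uniform(1000, 5000)
        sig = rng.uniform(3, 6)
        pop += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2))

    # background: lognormal spatial pattern x lognormal day factor x smooth noise
    s_bg = _smooth2d(rng, (nr, nc), config.background_corr_cells)
    base = config.background_mean * np.exp(config.background_spatial_sd * s_bg)
    pk = np.unravel_index(np.argmax(pop), pop.shape)
    bump = config.urban_bump * np.exp(
        -((xx - xx[pk]) ** 2 + (yy - yy[pk]) ** 2) / (2 * config.urban_bump_sigma_km**2)
    )
    day_factor = np.exp(config.background_temporal_sd * _ar1(rng, nd))
    noise3 = _smooth3d(rng, (nd, nr, nc), (2.0, 4.0, 4.0))
    background = (base + bump)[None] * day_factor[:, None, None] * np.exp(
        config.background_noise_sd * noise3
    )

    # meteorology
    rh = np.clip(
        config.rh_mean
        + 15 * _smooth2d(rng, (nr, nc), config.background_corr_cells)[None]
        + 12 * _ar1(rng, nd)[:, None, None]
        + 8 * _smooth3d(rng, (nd, nr, nc), (2.0, 4.0, 4.0)),
        2.0, 98.0,
    )
    temp = (
        config.temp_mean_f
        + 12 * _smooth2d(rng, (nr, nc), config.background_corr_cells)[None]
        + 10 * _ar1(rng, nd)[:, None, None]
        + 5 * _smooth3d(rng, (nd, nr, nc), (2.0, 4.0, 4.0))
    )
    wu_t = config.wind_speed_scale * _ar1(rng, nd, rho=0.6)
    wv_t = config.wind_speed_scale * _ar1(rng, nd, rho=0.6)
    wind_u = wu_t[:, None, None] + 2.0 * _smooth3d(rng, (nd, nr, nc), (2.0, 4.0, 4.0))
    wind_v = wv_t[:, None, None] + 2.0 * _smooth3d(rng, (nd, nr, nc), (2.0, 4.0, 4.0))

    # climate regions: Voronoi partition of a few random centers
    n_cl = min(config.n_climate_regions, grid.n_cells)
    cl_pts = np.column_stack([rng.uniform(0, w, n_cl), rng.uniform(0, h, n_cl)])
    d2 = (xx[..., None] - cl_pts[:, 0]) ** 2 + (yy[..., None] - cl_pts[:, 1]) ** 2
    climate = np.argmin(d2, axis=-1).astype(int)

    # smoke events
    events: list[PuffEvent] = []
    u_mean = wind_u.mean(axis=(1, 2))
    v_mean = wind_v.mean(axis=(1, 2))
    for _ in range(config.n_smoke_events):
        day0 = int(rng.integers(0, max(1, nd - 2)))
        lifespan = int(rng.integers(config.event_lifespan_range[0],
                                    config.event_lifespan_range[1] + 1))
        lifespan = min(lifespan, nd - day0)
        x0, y0 = rng.uniform(0, w), rng.uniform(0, h)
        amp = rng.uniform(*config.event_amplitude_range)
        tau = rng.uniform(*config.event_decay_days_range)
        sig0 = rng.uniform(*config.event_sigma_km_range)
        growth = rng.uniform(*config.event_growth_km_per_day_range)
        cx, cy = [x0], [y0]
        for a in range(1, lifespan):
            d = min(day0 + a, nd - 1)
            cx.append(cx[-1] + u_mean[d])
            cy.append(cy[-1] + v_mean[d])
        events.append(PuffEvent(
            day0=day0, lifespan=lifespan,
            centers_x=cx, centers_y=cy,
            amplitudes=[amp * np.exp(-a / tau) for a in range(lifespan)],
            sigmas=[sig0 + growth * a for a in range(lifespan)],
        ))

    smoke = np.zeros((nd, nr, nc))
    for ev in events:
        smoke += ev.evaluate(grid, nd)

    latent = LatentFields(
        background=CellDayField(grid, background, "ug/m3", "background"),
        smoke_true=CellDayField(grid, smoke, "ug/m3", "smoke_true"),
        rh=CellDayField(grid, rh, "%", "rh"),
        temp=CellDayField(grid, temp, "degF", "temp"),
        wind_u=CellDayField(grid, wind_u, "km/day", "wind_u"),
        wind_v=CellDayField(grid, wind_v, "km/day", "wind_v"),
        population=CellDayField(grid, pop[None], "persons/km2", "population"),
        climate_region=climate,
        events=events,
    )
    return grid, latent


# ---------------------------------------------------------------------------
# CTM pair

def block_average(values: np.ndarray, factor: int) -> np.ndarray:
    """Block-average (n_days, nr, nc) onto a coarse grid; ragged edges use partial blocks."""
    if factor == 1:
        return values.copy()
    nd, nr, nc = values.shape
    crn = -(-nr // factor)
    ccn = -(-nc // factor)
    padded = np.full((nd, crn * factor, ccn * factor), np.nan)
    padded[:, :nr, :nc] = values
    blocks = padded.reshape(nd, crn, factor, ccn, factor)
    with np.errstate(invalid="ignore"):
        return np.nanmean(blocks, axis=(2, 4))


@dataclass
class CTMPair:
    """Coarse CTM fields from paired runs with and without fire emissions.

    Both runs share the same multiplicative bias field and additive noise
    realization (same model physics, different emissions), so their
    difference is a non-negative but distorted smoke proxy.  ``bias``,
    ``smoke_bias`` and ``noise`` are retained for verification.
    """

    full: CellDayField
    nofire: CellDayField
    coarse_grid: GridDefinition
    bias: np.ndarray          # (crn, ccn), multiplicative, shared
    smoke_bias: np.ndarray    # (crn, ccn), multiplicative, smoke term only
    noise: np.ndarray         # (n_days, crn, ccn), additive, shared

    def __iter__(self):
        return iter((self.full, self.nofire))


def simulate_ctm(latent: LatentFields, grid: GridDefinition, config: WorldConfig) -> CTMPair:
    """Distorted coarse-resolution CTM runs with and without fire emissions.

    The truth is block-averaged to the CTM's native resolution
    (``cell_km * ctm_coarse_factor``), multiplied by a smooth lognormal bias
    shared between the two runs (the smoke term carries an extra lognormal
    bias of its own), then perturbed by additive noise shared between the
    runs and clipped at zero.
    """
    rng = np.random.default_rng([config.seed, _RS_CTM])
    f = config.ctm_coarse_factor
    avg_bg = block_average(latent.background.values, f)
    avg_smoke = block_average(latent.smoke_true.values, f)
    nd, crn, ccn = avg_bg.shape
    coarse_grid = GridDefinition(crn, ccn, grid.cell_km * f, grid.origin)

    bias = np.exp(config.ctm_bias_sd * _smooth2d(rng, (crn, ccn), 2.0))
    smoke_bias = np.exp(config.ctm_smoke_bias_sd * _smooth2d(rng, (crn, ccn), 2.0))
    noise = rng.normal(0, config.ctm_noise_sd, (nd, crn, ccn)) if config.ctm_noise_sd > 0 \
        else np.zeros((nd, crn, ccn))

    full = np.clip(bias[None] * (avg_bg + smoke_bias[None] * avg_smoke) + noise, 0, None)
    nofire = np.clip(bias[None] * avg_bg + noise, 0, None)
    return CTMPair(
        full=CellDayField(coarse_grid, full, "ug/m3", "ctm_full"),
        nofire=CellDayField(coarse_grid, nofire, "ug/m3", "ctm_nofire"),
        coarse_grid=coarse_grid,
        bias=bias, smoke_bias=smoke_bias, noise=noise,
    )


# ---------------------------------------------------------------------------
# plume polygons

@dataclass
class Plume:
    geometry: Polygon
    duration_h: float
    density_class: int      # 1 light / 2 medium / 3 heavy


def _mask_contour_polygons(mask: np.ndarray, grid: GridDefinition) -> list[Polygon]:
    """Closed polygons around True regions of a cell mask, in km coordinates.

    The mask is zero-padded so every contour closes; contours interpolate at
    0.5 between cell centers, so every True cell center is strictly inside
    its polygon.
    """
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2))
    padded[1:-1, 1:-1] = mask.astype(float)
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        # contour rows/cols are fractional padded indices
        x = grid.origin[0] + (contour[:, 1] - 0.5) * grid.cell_km
        y = grid.origin[1] + (contour[:, 0] - 0.5) * grid.cell_km
        if len(x) >= 4:
            p = Polygon(np.column_stack([x, y]))
            if not p.is_valid:
                p = p.buffer(0)
            if not p.is_empty:
                polys.append(p)
    return polys


def simulate_plumes(latent: LatentFields, config: WorldConfig) -> dict[int, list[Plume]]:
    """Analyst-style daily smoke polygons with omissions and false alarms.

    Polygons trace the region where true smoke exceeds the detection
    threshold, then are dilated/eroded by a random buffer, dropped at the
    omission rate, and supplemented with spurious small polygons at the
    false-positive rate.  Duration (hours) is random per polygon; the density
    class (1/2/3) reflects the mean enclosed true smoke.
    """
    rng = np.random.default_rng([config.seed, _RS_PLUMES])
    grid = latent.smoke_true.grid
    centers = grid.cell_centers()
    w, h = grid.extent_km
    out: dict[int, list[Plume]] = {}
    for d in range(latent.smoke_true.n_days):
        plumes: list[Plume] = []
        smoke = latent.smoke_true.values[d]
        mask = smoke > config.plume_detect_threshold
        if mask.any():
            for poly in _mask_contour_polygons(mask, grid):
                inside = shapely.contains_xy(poly, centers[:, 0], centers[:, 1])
                mean_smoke = float(smoke.ravel()[inside].mean()) if inside.any() else 0.0
                duration = float(rng.uniform(3, 24))
                jitter = rng.normal(0, config.plume_shape_jitter_km)
                omitted = rng.uniform() < config.plume_omission_rate
                if config.plume_shape_jitter_km > 0:
                    poly = poly.buffer(jitter)
                    if poly.is_empty or poly.area == 0:
                        continue
                if omitted:
                    continue
                if mean_smoke <= config.plume_density_light_max:
                    cls = 1
                elif mean_smoke <= config.plume_density_medium_max:
                    cls = 2
                else:
                    cls = 3
                plumes.append(Plume(poly, duration, cls))
        n_fp = rng.poisson(config.plume_false_positive_rate)
        for _ in range(n_fp):
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            radius = rng.uniform(1, 3)
            duration = float(rng.uniform(2, 8))
            plumes.append(Plume(Point(cx, cy).buffer(radius), duration, 1))
        out[d] = plumes
    return out


# ---------------------------------------------------------------------------
# AOD

@dataclass
class AODOutputs:
    aod: CellDayField             # with NaN where cloudy
    cloud_fraction: CellDayField  # in [0, 1], full coverage
    cams: CellDayField            # coarse full-coverage AOD analog


def simulate_aod(latent: LatentFields, config: WorldConfig) -> AODOutputs:
    """AOD as an affine, noisy transform of total PM2.5, masked by clouds.

    A smooth space-time "cloud" field is thresholded at the quantile matching
    the target missing fraction; AOD is missing where cloudy.  A coarse
    full-coverage AOD analog (block-averaged signal plus its own noise)
    stands in for a reanalysis product and supports gap-filling.
    """
    rng = np.random.default_rng([config.seed, _RS_AOD])
    grid = latent.smoke_true.grid
    total = latent.total
    nd = total.shape[0]
    slope_d = config.aod_slope * np.exp(
        config.aod_slope_daily_sd * rng.standard_normal(nd))
    icpt_d = config.aod_intercept + config.aod_intercept_daily_sd * rng.standard_normal(nd)
    loft_d = np.exp(config.aod_smoke_lofting_sd * rng.standard_normal(nd))
    column = latent.background.values + loft_d[:, None, None] * latent.smoke_true.values
    signal = icpt_d[:, None, None] + slope_d[:, None, None] * column
    noise = rng.normal(0, config.aod_noise_sd, total.shape) if config.aod_noise_sd > 0 else 0.0
    aod = np.clip(signal + noise, 0, None)

    cloud = _smooth3d(rng, total.shape, (1.5, 5.0, 5.0))
    from scipy.stats import norm
    cloud_fraction = norm.cdf(cloud)
    if config.aod_missing_fraction > 0:
        thr = np.quantile(cloud, 1.0 - config.aod_missing_fraction)
        aod = np.where(cloud > thr, np.nan, aod)

    f = config.ctm_coarse_factor
    cams_vals = block_average(signal, f)
    cams_vals = np.clip(
        cams_vals + rng.normal(0, config.cams_noise_sd, cams_vals.shape), 0, None
    )
    crn, ccn = cams_vals.shape[1:]
    coarse_grid = GridDefinition(crn, ccn, grid.cell_km * f, grid.origin)
    return AODOutputs(
        aod=CellDayField(grid, aod, "", "aod"),
        cloud_fraction=CellDayField(grid, cloud_fraction, "", "cloud_fraction"),
        cams=CellDayField(coarse_grid, cams_vals, "", "cams_aod"),
    )


# ---------------------------------------------------------------------------
# monitor networks

def _place_stations(rng: np.random.Generator, grid: GridDefinition, pop: np.ndarray,
                    n: int, alpha: float) -> np.ndarray:
    """Sample n distinct cells with probability ~ population^alpha; jitter within cell."""
    p = pop.ravel().astype(float) ** alpha
    p = p / p.sum()
    n = min(n, grid.n_cells)
    cells = rng.choice(grid.n_cells, size=n, replace=False, p=p)
    centers = grid.cell_centers()[cells]
    jitter = rng.uniform(-0.5, 0.5, (n, 2)) * grid.cell_km
    return np.column_stack([cells, centers + jitter])


def simulate_monitors(
    latent: LatentFields, grid: GridDefinition, config: WorldConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Hourly records from the reference and low-cost networks.

    Reference monitors report true total PM2.5 plus small unbiased hourly
    noise.  Low-cost monitors report two channels (A/B), each the truth times
    a humidity-dependent multiplicative bias plus additive noise.  A
    configurable fraction of low-cost station-days is corrupted (channel
    disagreement, spikes, or hour dropout) to exercise quality control.

    Returns (hourly records, station table, corruption log).
    """
    rng = np.random.default_rng([config.seed, _RS_MONITORS])
    pop = latent.population.values[0]
    nd = latent.background.n_days
    truth = latent.total            # (nd, nr, nc)
    rh = latent.rh.values
    temp = latent.temp.values

    ref_pl = _place_stations(rng, grid, pop, config.n_ref_monitors, config.ref_placement_alpha)
    lcs_pl = _place_stations(rng, grid, pop, config.n_lcs_monitors, config.lcs_placement_alpha)

    stations = pd.DataFrame({
        "station_id": [f"R{i:03d}" for i in range(len(ref_pl))]
        + [f"L{i:03d}" for i in range(len(lcs_pl))],
        "network": ["reference"] * len(ref_pl) + ["lowcost"] * len(lcs_pl),
        "cell_id": np.concatenate([ref_pl[:, 0], lcs_pl[:, 0]]).astype(int),
        "x_km": np.concatenate([ref_pl[:, 1], lcs_pl[:, 1]]),
        "y_km": np.concatenate([ref_pl[:, 2], lcs_pl[:, 2]]),
    })

    frames = []

    def cellvals(field3d: np.ndarray, cells: np.ndarray) -> np.ndarray:
        return field3d.reshape(nd, -1)[:, cells]        # (nd, n_st)

    # reference: 24 hourly values per day, single channel
    ref_cells = ref_pl[:, 0].astype(int)
    n_ref = len(ref_cells)
    t_ref = cellvals(truth, ref_cells)
    hourly = t_ref[:, :, None] + rng.normal(0, config.ref_noise_sd, (nd, n_ref, 24))
    hourly = np.clip(hourly, 0, None)
    day_ix, st_ix, hr_ix = np.meshgrid(
        np.arange(nd), np.arange(n_ref), np.arange(24), indexing="ij")
    frames.append(pd.DataFrame({
        "station_id": np.array([f"R{i:03d}" for i in range(n_ref)])[st_ix.ravel()],
        "network": "reference",
        "x_km": ref_pl[st_ix.ravel(), 1],
        "y_km": ref_pl[st_ix.ravel(), 2],
        "day": day_ix.ravel(),
        "hour": hr_ix.ravel(),
        "channel": "",
        "pm25": hourly.ravel(),
        "rh": cellvals(rh, ref_cells)[day_ix.ravel(), st_ix.ravel()],
        "temp": cellvals(temp, ref_cells)[day_ix.ravel(), st_ix.ravel()],
    }))

    # low cost: two channels, humidity-inflated
    lcs_cells = lcs_pl[:, 0].astype(int)
    n_lcs = len(lcs_cells)
    t_lcs = cellvals(truth, lcs_cells)
    rh_lcs = cellvals(rh, lcs_cells)
    mult = 1.0 + config.lcs_rh_bias_coef * rh_lcs
    biased = t_lcs * mult
    chan = {}
    for ch in ("A", "B"):
        v = biased[:, :, None] + rng.normal(0, config.lcs_noise_sd, (nd, n_lcs, 24))
        chan[ch] = np.clip(v, 0, None)

    # corruption of a fixed number of station-days
    n_sd = nd * n_lcs
    n_corrupt = int(round(config.lcs_corruption_fraction * n_sd))
    corrupt_ix = rng.choice(n_sd, size=n_corrupt, replace=False) if n_corrupt else np.array([], int)
    modes = rng.choice(["channel_disagreement", "spike", "dropout"], size=n_corrupt)
    drop_hours = np.zeros((nd, n_lcs, 24), dtype=bool)
    log_rows = []
    for ix, mode in zip(corrupt_ix, modes):
        d, s = divmod(int(ix), n_lcs)
        if mode == "channel_disagreement":
            chan["B"][d, s, :] *= rng.uniform(1.6, 3.0)
        elif mode == "spike":
            hrs = rng.choice(24, size=8, replace=False)
            spike = rng.uniform(4000, 8000, 8)
            chan["A"][d, s, hrs] = spike
            chan["B"][d, s, hrs] = spike
        else:  # dropout: keep fewer than 16 hours
            keep = rng.choice(24, size=int(rng.integers(4, 15)), replace=False)
            m = np.ones(24, dtype=bool)
            m[keep] = False
            drop_hours[d, s] = m
        log_rows.append({"station_id": f"L{s:03d}", "day": d, "mode": mode})
    corruption_log = pd.DataFrame(log_rows, columns=["station_id", "day", "mode"])

    day_ix, st_ix, hr_ix = np.meshgrid(
        np.arange(nd), np.arange(n_lcs), np.arange(24), indexing="ij")
    keep = ~drop_hours.ravel()
    for ch in ("A", "B"):
        frames.append(pd.DataFrame({
            "station_id": np.array([f"L{i:03d}" for i in range(n_lcs)])[st_ix.ravel()[keep]],
            "network": "lowcost",
            "x_km": lcs_pl[st_ix.ravel()[keep], 1],
            "y_km": lcs_pl[st_ix.ravel()[keep], 2],
            "day": day_ix.ravel()[keep],
            "hour": hr_ix.ravel()[keep],
            "channel": ch,
            "pm25": chan[ch].ravel()[keep],
            "rh": rh_lcs[day_ix.ravel()[keep], st_ix.ravel()[keep]],
            "temp": cellvals(temp, lcs_cells)[day_ix.ravel()[keep], st_ix.ravel()[keep]],
        }))

    monitors = pd.concat(frames, ignore_index=True)
    monitors["station_id"] = monitors["station_id"].astype("category")
    monitors["network"] = monitors["network"].astype("category")
    monitors["channel"] = monitors["channel"].astype("category")
    return monitors, stations, corruption_log


# ---------------------------------------------------------------------------
# world container and serialization

@dataclass
class SyntheticWorld:
    """A fully generated synthetic world: inputs plus retained ground truth."""

    config: WorldConfig
    grid: GridDefinition
    latent: LatentFields
    ctm: CTMPair
    plumes: dict[int, list[Plume]]
    aod: AODOutputs
    monitors: pd.DataFrame
    stations: pd.DataFrame
    corruption_log: pd.DataFrame

    @classmethod
    def generate(cls, config: WorldConfig) -> "SyntheticWorld":
        grid, latent = make_world(config)
        ctm = simulate_ctm(latent, grid, config)
        plumes = simulate_plumes(latent, config)
        aod = simulate_aod(latent, config)
        monitors, stations, log = simulate_monitors(latent, grid, config)
        return cls(config, grid, latent, ctm, plumes, aod, monitors, stations, log)

    def save(self, path: str | Path) -> None:
        """Serialize to a directory: JSON descriptors, npy rasters, CSV, GeoJSON."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        save_grid(path / "grid.json", self.grid)
        cfg = asdict(self.config)
        (path / "config.json").write_text(json.dumps(cfg, indent=2))
        for name in ("background", "smoke_true", "rh", "temp", "wind_u", "wind_v", "population"):
            save_field(path / f"{name}.npy", getattr(self.latent, name))
        np.save(path / "climate_region.npy", self.latent.climate_region)
        (path / "events.json").write_text(json.dumps([asdict(e) for e in self.latent.events]))
        save_grid(path / "ctm_grid.json", self.ctm.coarse_grid)
        save_field(path / "ctm_full.npy", self.ctm.full)
        save_field(path / "ctm_nofire.npy", self.ctm.nofire)
        np.save(path / "ctm_bias.npy", self.ctm.bias)
        np.save(path / "ctm_smoke_bias.npy", self.ctm.smoke_bias)
        np.save(path / "ctm_noise.npy", self.ctm.noise)
        save_field(path / "aod.npy", self.aod.aod)
        save_field(path / "cloud_fraction.npy", self.aod.cloud_fraction)
        save_field(path / "cams_aod.npy", self.aod.cams)
        # %.17g keeps the CSV round-trip bit-exact for doubles
        self.monitors.to_csv(path / "monitors.csv", index=False, float_format="%.17g")
        self.stations.to_csv(path / "stations.csv", index=False, float_format="%.17g")
        self.corruption_log.to_csv(path / "corruption_log.csv", index=False)
        plume_dir = path / "plumes"
        plume_dir.mkdir(exist_ok=True)
        for d, plist in self.plumes.items():
            fc = {
                "type": "FeatureCollection",
                "features": [
                    {
                        "type": "Feature",
                        "geometry": mapping(p.geometry),
                        "properties": {"duration_h": p.duration_h,
                                       "density_class": p.density_class},
                    }
                    for p in plist
                ],
            }
            (plume_dir / f"plumes_{d:04d}.geojson").write_text(json.dumps(fc))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticWorld":
        path = Path(path)
        config = WorldConfig(**json.loads((path / "config.json").read_text()))
        # tuples arrive as lists from JSON
        for f_ in (
            "event_amplitude_range", "event_lifespan_range", "event_decay_days_range",
            "event_sigma_km_range", "event_growth_km_per_day_range",
        ):
            setattr(config, f_, tuple(getattr(config, f_)))
        grid = load_grid(path / "grid.json")
        fields = {
            name: load_field(path / f"{name}.npy", grid, name=name)
            for name in ("background", "smoke_true", "rh", "temp", "wind_u", "wind_v", "population")
        }
        events = [PuffEvent(**e) for e in json.loads((path / "events.json").read_text())]
        latent = LatentFields(
            climate_region=np.load(path / "climate_region.npy"),
            events=events, **fields,
        )
        cgrid = load_grid(path / "ctm_grid.json")
        ctm = CTMPair(
            full=load_field(path / "ctm_full.npy", cgrid, name="ctm_full"),
            nofire=load_field(path / "ctm_nofire.npy", cgrid, name="ctm_nofire"),
            coarse_grid=cgrid,
            bias=np.load(path / "ctm_bias.npy"),
            smoke_bias=np.load(path / "ctm_smoke_bias.npy"),
            noise=np.load(path / "ctm_noise.npy"),
        )
        aod = AODOutputs(
            aod=load_field(path / "aod.npy", grid, name="aod"),
            cloud_fraction=load_field(path / "cloud_fraction.npy", grid, name="cloud_fraction"),
            cams=load_field(path / "cams_aod.npy", cgrid, name="cams_aod"),
        )
        monitors = pd.read_csv(path / "monitors.csv", keep_default_na=False,
                               dtype={"channel": str}, float_precision="round_trip")
        stations = pd.read_csv(path / "stations.csv", float_precision="round_trip")
        log = pd.read_csv(path / "corruption_log.csv")
        plumes: dict[int, list[Plume]] = {}
        for f_ in sorted((path / "plumes").glob("plumes_*.geojson")):
            d = int(f_.stem.split("_")[1])
            fc = json.loads(f_.read_text())
            plumes[d] = [
                Plume(shape(feat["geometry"]), feat["properties"]["duration_h"],
                      feat["properties"]["density_class"])
                for feat in fc["features"]
            ]
        return cls(config, grid, latent, ctm, plumes, aod, monitors, stations, log)
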