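"""Synthetic closed-basin scenes with known ground truth.

Emulates the data situation of a high-altitude endorheic basin: a DEM high
in the northwest and low in the southeast, elevation-lapsed temperature,
elevation-dependent precipitation, spatially autocorrelated categorical
land-use / soil fields, continuous pressure layers (grazing, population,
soil organic carbon), and a monthly EVI series built from a seasonal
harmonic, a per-pixel linear trend, driver-dependent baselines, climate
anomaly coupling and white noise:

    EVI(p, y, m) = clip( b(p) + a*season(m) + tau(p)*(y - y0)
                         + c_T*Tanom(p, y) + c_P*Panom(p, y) + eps, 0, 1 )

Every generated coefficient is recorded in the scene's ``truth`` record so
downstream estimators (trend slopes, geodetector q ranks, PLS paths) can be
scored against it.  All randomness derives from the scene seed; a fixed
(config, seed) pair reproduces every layer bit for bit.

Random fields are Gaussian white noise smoothed with a uniform
moving-average kernel — crude relative to geostatistical simulators, but
with controllable correlation length and no extra dependencies.

``generate_pls_dataset`` draws an indicator table from a composite
population model (blocks defined as exact weighted composites of their
indicators) so that PLS path modeling is a consistent estimator of the
planted loadings and structural coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ClassifiedGrid, Grid, GridStack, GridTransform, slope_aspect

__all__ = [
    "DemParams",
    "ClimateParams",
    "EviParams",
    "CategoricalParams",
    "SceneConfig",
    "SceneBundle",
    "generate_dem",
    "generate_climate",
    "generate_evi_series",
    "generate_categorical",
    "generate_scene",
    "generate_pls_dataset",
]


def _smooth_field(rng, shape, smoothing: float) -> np.ndarray:
    """Zero-mean, unit-sd moving-average-smoothed Gaussian field."""
    noise = rng.standard_normal(shape)
    if smoothing and smoothing > 1:
        noise = ndimage.uniform_filter(noise, size=int(smoothing), mode="reflect")
    sd = noise.std()
    return (noise - noise.mean()) / (sd if sd > 0 else 1.0)


@dataclass(frozen=True)
class DemParams:
    relief_amplitude_m: float = 250.0     # sd of the smoothed relief component
    smoothing_cells: int = 10
    elevation_range_m: tuple = (3173.0, 5279.0)   # closed-basin span
    ramp_fraction: float = 0.8            # share of the span carried by the NW->SE ramp


@dataclass(frozen=True)
class ClimateParams:
    t_sea_level_c: float = 23.5           # extrapolated sea-level temperature
    lapse_c_per_m: float = 0.006
    t_interannual_sd_c: float = 0.5
    t_noise_sd_c: float = 0.3
    precip_base_mm: float = 150.0         # at zero elevation offset
    precip_elev_coeff_mm_per_m: float = 0.065
    precip_elev_quad: float = 0.0         # optional mid-elevation optimum
    p_interannual_sd_mm: float = 25.0
    p_noise_sd_mm: float = 15.0
    elevation_ref_m: float = 0.0


@dataclass(frozen=True)
class EviParams:
    # defaults keep the deterministic signal strictly inside [0, 1]: the
    # planted trend appears in annual means only while nothing saturates
    baseline: float = 0.45
    seasonal_amplitude: float = 0.2
    landuse_effect_sd: float = 0.05       # spread of per-class baseline offsets
    trend_improve: float = 0.002          # per-year, planted west block
    trend_degrade: float = -0.002         # per-year, planted southeast block
    temperature_coeff: float = 0.02       # per sd of temperature anomaly
    precipitation_coeff: float = 0.02     # per sd of precipitation anomaly
    noise_sd: float = 0.02
    periods_per_month: int = 1            # 2 emulates 16-day composites


@dataclass(frozen=True)
class CategoricalParams:
    n_landuse_classes: int = 6
    n_soil_classes: int = 5
    patch_smoothing_cells: int = 8


@dataclass(frozen=True)
class SceneConfig:
    shape: tuple = (100, 100)
    cell_size_m: float = 250.0
    years: tuple = (2001, 2022)
    seed: int = 0
    dem_params: DemParams = field(default_factory=DemParams)
    climate_params: ClimateParams = field(default_factory=ClimateParams)
    evi_params: EviParams = field(default_factory=EviParams)
    categorical_params: CategoricalParams = field(default_factory=CategoricalParams)

    def __post_init__(self) -> None:
        if self.years[1] - self.years[0] + 1 < 3:
            raise ValueError("year span must cover at least 3 years")
        if self.shape[0] < 3 or self.shape[1] < 3:
            raise ValueError("scene must be at least 3x3 cells")

    @property
    def year_list(self):
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def transform(self) -> GridTransform:
        return GridTransform(0.0, self.shape[0] * self.cell_size_m,
                             self.cell_size_m, self.cell_size_m)

    def rng(self, stream: int):
        """Independent deterministic generator per named stream."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SceneBundle:
    config: SceneConfig
    dem: Grid
    slope: Grid
    aspect: Grid
    temperature: GridStack
    precipitation: GridStack
    evi_monthly: GridStack
    landuse: ClassifiedGrid
    soil_type: ClassifiedGrid
    soc: Grid
    grazing: Grid
    popdensity: Grid
    truth: dict


# per-layer rng stream ids
_S_DEM, _S_CLIMATE, _S_EVI, _S_LANDUSE, _S_SOIL, _S_PRESSURE = range(1, 7)


def generate_dem(config: SceneConfig) -> Grid:
    """Smooth random relief over a NW-high / SE-low ramp, clipped to range."""
    p = config.dem_params
    rows, cols = config.shape
    rng = config.rng(_S_DEM)
    lo, hi = p.elevation_range_m
    rr, cc = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols),
                         indexing="ij")
    ramp = 1.0 - (rr + cc) / 2.0                  # 1 at NW corner, 0 at SE
    base = lo + p.ramp_fraction * (hi - lo) * ramp + 0.5 * (1 - p.ramp_fraction) * (hi - lo)
    relief = p.relief_amplitude_m * _smooth_field(rng, config.shape, p.smoothing_cells)
    dem = np.clip(base + relief, lo, hi)
    return Grid(dem, config.transform, units="m")


def generate_climate(dem: Grid, config: SceneConfig):
    """Per-year temperature and precipitation stacks tied to elevation.

    Temperature: T0 - lapse*elevation + year effect + pixel noise.
    Precipitation: base + linear (optionally quadratic) elevation term +
    year effect + pixel noise, floored at zero.
    """
    p = config.climate_params
    rng = config.rng(_S_CLIMATE)
    years = config.year_list
    elev = dem.values - p.elevation_ref_m
    t_grids, p_grids = [], []
    for year in years:
        t_year = rng.normal(0.0, p.t_interannual_sd_c)
        p_year = rng.normal(0.0, p.p_interannual_sd_mm)
        t = (p.t_sea_level_c - p.lapse_c_per_m * elev + t_year
             + rng.normal(0.0, p.t_noise_sd_c, dem.shape) if p.t_noise_sd_c > 0
             else p.t_sea_level_c - p.lapse_c_per_m * elev + t_year)
        pr = (p.precip_base_mm + p.precip_elev_coeff_mm_per_m * elev
              + p.precip_elev_quad * elev ** 2 + p_year)
        if p.p_noise_sd_mm > 0:
            pr = pr + rng.normal(0.0, p.p_noise_sd_mm, dem.shape)
        t_grids.append(dem.with_values(np.asarray(t)))
        p_grids.append(dem.with_values(np.maximum(pr, 0.0)))
        t_grids[-1].units, p_grids[-1].units = "degC", "mm"
    return (GridStack(t_grids, [(y,) for y in years]),
            GridStack(p_grids, [(y,) for y in years]))


def generate_categorical(config: SceneConfig, n_classes: int,
                         seed_offset: int = 0) -> ClassifiedGrid:
    """Spatially autocorrelated label field (smoothed field cut at quantiles)."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_classes > config.shape[0] * config.shape[1]:
        raise ValueError("more classes than cells")
    rng = config.rng(_S_LANDUSE + seed_offset)
    f = _smooth_field(rng, config.shape,
                      config.categorical_params.patch_smoothing_cells)
    qs = np.quantile(f, np.linspace(0, 1, n_classes + 1)[1:-1])
    codes = np.digitize(f, qs).astype(np.int64) + 1
    classes = {c: f"class {c}" for c in range(1, n_classes + 1)}
    return ClassifiedGrid(Grid(codes, config.transform), classes)


def _trend_field(config: SceneConfig) -> np.ndarray:
    """Planted per-pixel trend: improving west strip, degrading SE block."""
    p = config.evi_params
    rows, cols = config.shape
    tau = np.zeros(config.shape)
    tau[:, : cols // 3] = p.trend_improve
    tau[2 * rows // 3:, 2 * cols // 3:] = p.trend_degrade
    return tau


def _seasonal(month: np.ndarray | int) -> np.ndarray:
    """Growing-season harmonic in [-1, 1], peaking in July."""
    return np.cos(2.0 * np.pi * (np.asarray(month) - 7) / 12.0)


def _standardized_anomalies(stack: GridStack) -> np.ndarray:
    cube = np.stack([g.values for g in stack.grids]).astype(float)
    mean = cube.mean(axis=0)
    sd = cube.std(axis=0)
    sd[sd == 0] = 1.0
    return (cube - mean) / sd


def generate_evi_series(dem: Grid, temperature: GridStack,
                        precipitation: GridStack, landuse: ClassifiedGrid,
                        config: SceneConfig):
    """Monthly EVI stack plus the truth record of its generating coefficients."""
    p = config.evi_params
    rng = config.rng(_S_EVI)
    years = config.year_list
    tau = _trend_field(config)
    class_effects = {c: float(e) for c, e in zip(
        landuse.codes,
        rng.normal(0.0, p.landuse_effect_sd, len(landuse.codes)))}
    baseline = p.baseline + np.vectorize(class_effects.get)(landuse.grid.values)
    t_anom = _standardized_anomalies(temperature)
    p_anom = _standardized_anomalies(precipitation)
    grids, stamps = [], []
    for yi, year in enumerate(years):
        drift = tau * (year - years[0])
        climate = (p.temperature_coeff * t_anom[yi]
                   + p.precipitation_coeff * p_anom[yi])
        for month in range(1, 13):
            det = baseline + p.seasonal_amplitude * _seasonal(month) + drift + climate
            for period in range(1, p.periods_per_month + 1):
                noise = (rng.normal(0.0, p.noise_sd, config.shape)
                         if p.noise_sd > 0 else 0.0)
                evi = np.clip(det + noise, 0.0, 1.0)
                grids.append(Grid(evi, config.transform, units="EVI"))
                stamps.append((year, month, period) if p.periods_per_month > 1
                              else (year, month))
    truth = {
        "trend": Grid(tau, config.transform, units="EVI/a"),
        "baseline": Grid(baseline, config.transform, units="EVI"),
        "class_effects": class_effects,
        "temperature_coeff": p.temperature_coeff,
        "precipitation_coeff": p.precipitation_coeff,
        "seasonal_amplitude": p.seasonal_amplitude,
        "noise_sd": p.noise_sd,
    }
    return GridStack(grids, stamps), truth


def generate_scene(config: SceneConfig = None) -> SceneBundle:
    """Compose a full co-registered scene with its ground-truth record."""
    config = config or SceneConfig()
    dem = generate_dem(config)
    slope, aspect = slope_aspect(dem)
    temperature, precipitation = generate_climate(dem, config)
    landuse = generate_categorical(config, config.categorical_params.n_landuse_classes,
                                   seed_offset=0)
    soil = generate_categorical(config, config.categorical_params.n_soil_classes,
                                seed_offset=1)
    rng = config.rng(_S_PRESSURE)
    soc = dem.with_values(
        np.maximum(8.0 - 0.001 * (dem.values - dem.values.min())
                   + 1.5 * _smooth_field(rng, config.shape, 6), 0.1))
    grazing = dem.with_values(
        np.maximum(1.0 + _smooth_field(rng, config.shape, 6), 0.0))
    popdensity = dem.with_values(
        np.exp(0.8 * _smooth_field(rng, config.shape, 10)))
    soc.units, grazing.units, popdensity.units = "kg/m2", "SU/ha", "persons/km2"
    evi_monthly, truth = generate_evi_series(dem, temperature, precipitation,
                                             landuse, config)
    truth["lapse_c_per_m"] = config.climate_params.lapse_c_per_m
    truth["precip_elev_coeff"] = config.climate_params.precip_elev_coeff_mm_per_m
    return SceneBundle(config=config, dem=dem, slope=slope, aspect=aspect,
                       temperature=temperature, precipitation=precipitation,
                       evi_monthly=evi_monthly, landuse=landuse, soil_type=soil,
                       soc=soc, grazing=grazing, popdensity=popdensity,
                       truth=truth)


# ---------------------------------------------------------------------------
# tabular generator for PLS path-model recovery
# ---------------------------------------------------------------------------

def generate_pls_dataset(paths: dict, blocks: dict, loading: float = 0.8,
                         n: int = 2000, seed: int = 0):
    """Sample an indicator table from a composite population model.

    ``paths`` maps (source, target) latent pairs to standardized structural
    coefficients over an acyclic graph; ``blocks`` maps each latent to its
    number of indicators.  Latents are unit-variance composites of their
    indicators; within-block correlations are chosen so every indicator has
    composite loading ``loading``, and cross-block indicator covariance is
    loading_i * loading_j * corr(latents).  Returns ``(DataFrame, truth)``
    where truth holds the implied latent correlation matrix, the loadings
    and the structural coefficients.
    """
    import pandas as pd

    latents = list(blocks)
    k = len(latents)
    order = _toposort(latents, paths)
    psi = np.eye(k)                        # latent correlation matrix
    idx = {lat: i for i, lat in enumerate(latents)}
    for lat in order:
        parents = [s for (s, d) in paths if d == lat]
        if not parents:
            continue
        pi = [idx[p] for p in parents]
        beta = np.array([paths[(p, lat)] for p in parents])
        var_expl = beta @ psi[np.ix_(pi, pi)] @ beta
        if var_expl >= 1.0:
            raise ValueError(f"paths into {lat!r} imply variance >= 1")
        i = idx[lat]
        for j in range(k):
            if j == i:
                continue
            psi[i, j] = psi[j, i] = beta @ psi[pi, j]
        psi[i, i] = 1.0
    # indicator covariance
    names, lat_of = [], []
    for lat in latents:
        m = int(blocks[lat])
        if m < 1:
            raise ValueError("each block needs >= 1 indicator")
        for a in range(m):
            names.append(f"{lat}_x{a + 1}")
            lat_of.append(lat)
    p_tot = len(names)
    sigma = np.empty((p_tot, p_tot))
    # within-block correlation c giving composite loading `loading`
    within = {}
    for lat in latents:
        m = blocks[lat]
        if m == 1:
            within[lat] = 1.0
            continue
        c = (m * loading ** 2 - 1.0) / (m - 1.0)
        if not -1.0 / (m - 1) < c <= 1.0:
            raise ValueError(f"loading {loading} infeasible for block size {m}")
        within[lat] = c
    eff_loading = {lat: (1.0 if blocks[lat] == 1 else loading) for lat in latents}
    for a in range(p_tot):
        for b in range(p_tot):
            la, lb = lat_of[a], lat_of[b]
            if a == b:
                sigma[a, b] = 1.0
            elif la == lb:
                sigma[a, b] = within[la]
            else:
                sigma[a, b] = (eff_loading[la] * eff_loading[lb]
                               * psi[idx[la], idx[lb]])
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(p_tot))
    data = rng.standard_normal((n, p_tot)) @ chol.T
    frame = pd.DataFrame(data, columns=names)
    truth = {"latent_corr": psi, "latents": latents,
             "loadings": {nm: eff_loading[lv] for nm, lv in zip(names, lat_of)},
             "paths": dict(paths)}
    return frame, truth


def _toposort(latents, paths):
    order, seen, active = [], set(), set()

    def visit(node):
        if node in seen:
            return
        if node in active:
            raise ValueError("structural graph contains a cycle")
        active.add(node)
        for (s, d) in paths:
            if d == node:
                visit(s)
        active.discard(node)
        seen.add(node)
        order.append(node)

    for lat in latents:
        visit(lat)
    return order
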