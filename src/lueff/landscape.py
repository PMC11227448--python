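"""Synthetic landscape generation.

Builds a fishnet grid of ~1 km^2 landscape units (LUs) over a planar study
polygon, draws per-LU land-use/land-cover (LULC) composition from an archetype
mixture, and populates driver fields, point layers and raw ecosystem-service
indicator layers.  Everything is driven by a single seeded generator so that
identical ``(config, seed)`` pairs reproduce the landscape bit for bit.

Grid rules: cells are axis-aligned squares anchored at the lower-left corner
of the study polygon's bounding box; cells wholly outside the polygon are
dropped, as are cells whose clipped intersection area falls below the
comparability threshold (default 0.999 km^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon, box
from shapely.geometry.base import BaseGeometry

from .config import FOREST, LULC_CLASSES, ScenarioConfig

__generator_version__ = "1.0"

M2_PER_KM2 = 1e6


@dataclass
class LandscapeUnit:
    """One grid cell: geometry, LULC composition, terrain, drivers and the raw
    layers the ecosystem-service indicators are computed from."""

    lu_id: int
    row: int
    col: int
    polygon: BaseGeometry
    area_km2: float
    lulc_shares: np.ndarray = field(default_factory=lambda: np.zeros(len(LULC_CLASSES)))
    # terrain
    slope_pct: float = 0.0
    elev_m: float = 0.0
    # drivers of change
    pop_density: float = 0.0
    road_density: float = 0.0
    natura_share: float = 0.0
    dist_heritage_m: float = 0.0
    # point counts and proximity
    heritage_sites_n: int = 0
    intangible_sites_n: int = 0
    nearest_water_m: float = 0.0
    nearest_peak_m: float = 0.0
    # raw indicator layers
    tree_species_n: int = 0
    huntable_species_n: int = 0
    shot_animals_per_ha: float = 0.0
    growing_stock_m3_ha: float = 0.0
    chestnut_m3_ha: float = 0.0
    gathering_households_n: int = 0
    soil_index: float = 0.0
    erosion_measure_share: float = 0.0
    carnivore_territory_share: float = 0.0
    visitation_surrogate: float = 0.0
    scenic_surrogate: float = 0.0
    archetype: str = ""

    @property
    def n_lulc(self) -> int:
        """Number of LULC classes with strictly positive share."""
        return int(np.count_nonzero(self.lulc_shares > 0))

    @property
    def forest_share(self) -> float:
        return float(self.lulc_shares[LULC_CLASSES.index(FOREST)])

    @property
    def centroid(self) -> Point:
        # Centroid of the nominal (unclipped) square; distances are measured
        # from cell centroids.
        return self.polygon.centroid


@dataclass
class SyntheticLandscape:
    """A generated landscape: config echo, LUs, point layers, provenance."""

    config: ScenarioConfig
    units: list[LandscapeUnit]
    heritage_points: np.ndarray  # (k, 2) planar coordinates in meters
    intangible_points: np.ndarray
    water_points: np.ndarray
    peak_points: np.ndarray
    seed: int = 0
    generator_version: str = __generator_version__

    def __len__(self) -> int:
        return len(self.units)

    @property
    def lu_ids(self) -> np.ndarray:
        return np.array([u.lu_id for u in self.units])

    def shares_matrix(self) -> np.ndarray:
        return np.vstack([u.lulc_shares for u in self.units])

    def shares_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.shares_matrix(), index=self.lu_ids, columns=list(LULC_CLASSES)
        ).rename_axis("lu_id")

    def drivers_frame(self) -> pd.DataFrame:
        """Driver-of-change covariates, one row per LU."""
        rows = {
            "pop_density": [u.pop_density for u in self.units],
            "natura_share": [u.natura_share for u in self.units],
            "road_density": [u.road_density for u in self.units],
            "slope_pct": [u.slope_pct for u in self.units],
            "elev_m": [u.elev_m for u in self.units],
            "n_lulc": [u.n_lulc for u in self.units],
            "dist_heritage_m": [u.dist_heritage_m for u in self.units],
        }
        return pd.DataFrame(rows, index=self.lu_ids).rename_axis("lu_id")


def default_study_polygon(config: ScenarioConfig) -> Polygon:
    """Rectangle exactly tiling the configured grid."""
    return box(
        0.0, 0.0, config.n_cols * config.cell_size_m, config.n_rows * config.cell_size_m
    )


def build_grid(
    study_polygon: BaseGeometry,
    cell_size_m: float,
    min_area_km2: float = 0.999,
) -> list[LandscapeUnit]:
    """Fishnet the study polygon into square landscape-unit skeletons.

    Cells are anchored at the lower-left corner of the polygon's bounding box.
    Cells wholly outside the polygon, or whose clipped area is below
    ``min_area_km2``, are excluded to keep LUs comparable in size.
    """
    if study_polygon is None or study_polygon.is_empty:
        raise ValueError("study polygon is empty")
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")

    minx, miny, maxx, maxy = study_polygon.bounds
    n_cols = int(np.ceil((maxx - minx) / cell_size_m - 1e-12))
    n_rows = int(np.ceil((maxy - miny) / cell_size_m - 1e-12))
    units: list[LandscapeUnit] = []
    lu_id = 0
    for r in range(n_rows):
        for c in range(n_cols):
            cell = box(
                minx + c * cell_size_m,
                miny + r * cell_size_m,
                minx + (c + 1) * cell_size_m,
                miny + (r + 1) * cell_size_m,
            )
            clipped = cell.intersection(study_polygon)
            area_km2 = clipped.area / M2_PER_KM2
            if area_km2 <= 0 or area_km2 < min_area_km2 - 1e-12:
                continue
            units.append(
                LandscapeUnit(lu_id=lu_id, row=r, col=c, polygon=cell, area_km2=area_km2)
            )
            lu_id += 1
    if not units:
        raise ValueError(
            f"no landscape units retained: polygon bounds {study_polygon.bounds} "
            f"with {cell_size_m} m cells leave every cell below {min_area_km2} km^2"
        )
    return units


def sample_composition(
    config: ScenarioConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-LU LULC share vectors from the archetype mixture.

    For each LU an archetype is drawn by mixture weight; the forest share
    comes from the archetype's Beta law; the remaining mass is split over a
    random subset of the eight non-forest classes by a Dirichlet draw.  A
    standard-normal latent ``z_het`` controls how many non-forest classes are
    present, so landscape heterogeneity can later be copula-coupled to road
    density.

    Returns ``(shares, archetype_idx, z_het)``; rows of ``shares`` sum to 1.
    """
    arts = config.archetypes
    weights = np.array([a.weight for a in arts])
    if np.any(np.array([a.forest_conc for a in arts]) <= 0):
        raise ValueError("degenerate concentration parameters")
    art_idx = rng.choice(len(arts), size=n, p=weights)
    z_het = rng.standard_normal(n)
    shares = np.zeros((n, len(LULC_CLASSES)))
    forest_i = LULC_CLASSES.index(FOREST)
    nonforest = [i for i in range(len(LULC_CLASSES)) if i != forest_i]
    for j in range(n):
        a = arts[art_idx[j]]
        f = rng.beta(a.forest_mean * a.forest_conc, (1 - a.forest_mean) * a.forest_conc)
        # number of non-forest classes: 1 + Binomial(7, p), quantile-coupled
        # to the latent heterogeneity score
        k = 1 + int(stats.binom.ppf(stats.norm.cdf(z_het[j]), 7, a.extra_class_p))
        w = np.asarray(a.class_weights, dtype=float)
        chosen = rng.choice(nonforest, size=k, replace=False, p=w / w.sum())
        alloc = rng.dirichlet(np.full(k, a.split_conc))
        shares[j, forest_i] = f
        shares[j, chosen] = (1.0 - f) * alloc
    return shares, art_idx, z_het


def _poisson_points(
    rng: np.random.Generator, intensity_per_km2: float, polygon: BaseGeometry
) -> np.ndarray:
    """Homogeneous Poisson process on the polygon (sampled on the bounding box
    and thinned to the polygon)."""
    minx, miny, maxx, maxy = polygon.bounds
    bbox_km2 = (maxx - minx) * (maxy - miny) / M2_PER_KM2
    n = rng.poisson(intensity_per_km2 * bbox_km2)
    if n == 0:
        return np.empty((0, 2))
    pts = np.column_stack(
        [rng.uniform(minx, maxx, size=n), rng.uniform(miny, maxy, size=n)]
    )
    keep = [polygon.covers(Point(p)) for p in pts]
    return pts[np.array(keep, dtype=bool)]


def _coupled_latent(
    target: np.ndarray, rank_corr: float, rng: np.random.Generator
) -> np.ndarray:
    """Standard-normal latent whose monotone transforms attain a given
    Spearman correlation with ``target``.

    ``target`` is typically heavily tied (an integer count), which attenuates
    any fixed Gaussian-copula coupling; the mixing weight is therefore
    calibrated on the realized sample by bisection.  Any strictly increasing
    transform of the returned latent preserves the correlation.
    """
    n = len(target)
    if not -1.0 < rank_corr < 1.0:
        raise ValueError("rank correlation must lie strictly in (-1, 1)")
    eps = rng.standard_normal(n)
    if rank_corr == 0.0 or n < 3 or np.all(target == target[0]):
        return eps
    m = stats.norm.ppf(stats.rankdata(target, method="average") / (n + 1.0))
    m = (m - m.mean()) / m.std()

    def realized(lam: float) -> float:
        z = lam * m + np.sqrt(1.0 - lam * lam) * eps
        return float(stats.spearmanr(z, target).statistic)

    lo, hi = (0.0, 0.999999) if rank_corr > 0 else (-0.999999, 0.0)
    if abs(realized(hi if rank_corr > 0 else lo)) < abs(rank_corr):
        lam = hi if rank_corr > 0 else lo  # target unattainable; use maximum
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if realized(mid) < rank_corr:
                lo = mid
            else:
                hi = mid
        lam = 0.5 * (lo + hi)
    return lam * m + np.sqrt(1.0 - lam * lam) * eps


def _nearest_distance(centroids: np.ndarray, points: np.ndarray, cap_m: float) -> np.ndarray:
    if len(points) == 0:
        return np.full(len(centroids), cap_m)
    d = np.sqrt(
        ((centroids[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    return np.minimum(d, cap_m)


def _counts_in_cells(units: list[LandscapeUnit], points: np.ndarray) -> np.ndarray:
    counts = np.zeros(len(units), dtype=int)
    if len(points) == 0:
        return counts
    for i, u in enumerate(units):
        minx, miny, maxx, maxy = u.polygon.bounds
        inside = (
            (points[:, 0] >= minx)
            & (points[:, 0] < maxx)
            & (points[:, 1] >= miny)
            & (points[:, 1] < maxy)
        )
        counts[i] = int(inside.sum())
    return counts


def sample_drivers_and_layers(
    config: ScenarioConfig,
    units: list[LandscapeUnit],
    study_polygon: BaseGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Populate driver fields, terrain, point layers and raw indicator layers
    on LUs whose ``lulc_shares`` are already set.

    Road density is coupled to landscape heterogeneity (the per-LU count of
    distinct LULC classes) through a rank-calibrated Gaussian copula hitting
    the configured Spearman correlation.  Distances are measured from cell
    centroids to the nearest point of each layer and capped.

    Returns the four point layers (heritage, intangible, water, peaks).
    """
    if not units:
        raise ValueError("grid is empty")
    dp = config.drivers
    ip = config.indicators
    eff = config.effects
    n = len(units)
    shares = np.vstack([u.lulc_shares for u in units])
    forest = shares[:, LULC_CLASSES.index(FOREST)]
    urban = shares[:, LULC_CLASSES.index("urban_artificial")]
    agri = (
        shares[:, LULC_CLASSES.index("fields_gardens")]
        + shares[:, LULC_CLASSES.index("other_agricultural")]
        + shares[:, LULC_CLASSES.index("permanent_cultures")]
    )
    # terrain: forests sit on steeper, higher ground (ground-truth coupling)
    slope = np.maximum(
        0.0,
        dp.slope_base_pct
        + eff.slope_forest_gain * forest
        + rng.normal(0.0, dp.slope_noise_sd, n),
    )
    elev = np.maximum(
        0.0,
        dp.elev_base_m
        + eff.elev_forest_gain * forest
        + rng.normal(0.0, dp.elev_noise_sd, n),
    )

    pop = rng.lognormal(dp.pop_density_logmean, dp.pop_density_logsd, n)
    z_road = _coupled_latent(
        np.count_nonzero(shares > 0, axis=1), dp.road_nlulc_rank_corr, rng
    )
    road = np.exp(dp.road_density_logmean + dp.road_density_logsd * z_road)
    natura = rng.beta(
        dp.natura_mean * dp.natura_conc, (1 - dp.natura_mean) * dp.natura_conc, n
    )

    heritage = _poisson_points(rng, dp.heritage_intensity, study_polygon)
    intangible = _poisson_points(rng, dp.intangible_intensity, study_polygon)
    water = _poisson_points(rng, dp.spring_intensity, study_polygon)
    peaks = _poisson_points(rng, dp.peak_intensity, study_polygon)

    centroids = np.array([[u.centroid.x, u.centroid.y] for u in units])
    d_heritage = _nearest_distance(centroids, heritage, dp.distance_cap_m)
    d_water = _nearest_distance(centroids, water, dp.distance_cap_m)
    d_peak = _nearest_distance(centroids, peaks, dp.distance_cap_m)
    c_heritage = _counts_in_cells(units, heritage)
    c_intangible = _counts_in_cells(units, intangible)

    tree_n = rng.poisson(ip.tree_species_base + ip.tree_species_forest_gain * forest)
    hunt_n = rng.poisson(ip.huntable_base + ip.huntable_forest_gain * forest)
    shot = rng.gamma(2.0, 0.5, n) * ip.shot_animals_scale * (0.15 + forest)
    stock = np.maximum(
        0.0, forest * rng.normal(ip.growing_stock_mean, ip.growing_stock_sd, n)
    )
    chestnut = forest * rng.gamma(2.0, ip.chestnut_scale / 2.0, n)
    areas = np.array([u.area_km2 for u in units])
    households = pop * areas / ip.household_size
    gathering = rng.poisson(ip.gathering_rate * households)
    soil = np.clip(
        rng.normal(ip.soil_index_base + ip.soil_index_agri_gain * agri, ip.soil_index_sd),
        0.0,
        100.0,
    )
    erosion = rng.beta(
        ip.erosion_measure_mean * ip.erosion_measure_conc,
        (1 - ip.erosion_measure_mean) * ip.erosion_measure_conc,
        n,
    )
    carniv = np.clip(
        ip.carnivore_base + ip.carnivore_forest_gain * forest
        + rng.normal(0.0, 0.08, n),
        0.0,
        1.0,
    )
    visitation = rng.gamma(2.0, 1.0, n) * (0.3 + 0.7 * natura)
    scenic = rng.gamma(2.0, 1.0, n) * (1.0 - urban)

    for i, u in enumerate(units):
        u.slope_pct = float(slope[i])
        u.elev_m = float(elev[i])
        u.pop_density = float(pop[i])
        u.road_density = float(road[i])
        u.natura_share = float(natura[i])
        u.dist_heritage_m = float(d_heritage[i])
        u.heritage_sites_n = int(c_heritage[i])
        u.intangible_sites_n = int(c_intangible[i])
        u.nearest_water_m = float(d_water[i])
        u.nearest_peak_m = float(d_peak[i])
        u.tree_species_n = int(tree_n[i])
        u.huntable_species_n = int(hunt_n[i])
        u.shot_animals_per_ha = float(shot[i])
        u.growing_stock_m3_ha = float(stock[i])
        u.chestnut_m3_ha = float(chestnut[i])
        u.gathering_households_n = int(gathering[i])
        u.soil_index = float(soil[i])
        u.erosion_measure_share = float(erosion[i])
        u.carnivore_territory_share = float(carniv[i])
        u.visitation_surrogate = float(visitation[i])
        u.scenic_surrogate = float(scenic[i])
    return heritage, intangible, water, peaks


def generate_scenario(
    config: ScenarioConfig, study_polygon: BaseGeometry | None = None
) -> SyntheticLandscape:
    """Generate a complete synthetic landscape for ``config``.

    The draw order (composition, then drivers/layers) is fixed so that a given
    ``(config, seed)`` pair always reproduces the identical landscape.
    """
    if study_polygon is None:
        study_polygon = default_study_polygon(config)
    rng = config.rng()
    units = build_grid(study_polygon, config.cell_size_m, config.min_area_km2)
    shares, art_idx, _ = sample_composition(config, len(units), rng)
    for i, u in enumerate(units):
        u.lulc_shares = shares[i]
        u.archetype = config.archetypes[art_idx[i]].name
    heritage, intangible, water, peaks = sample_drivers_and_layers(
        config, units, study_polygon, rng
    )
    return SyntheticLandscape(
        config=config,
        units=units,
        heritage_points=heritage,
        intangible_points=intangible,
        water_points=water,
        peak_points=peaks,
        seed=config.seed,
    )
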