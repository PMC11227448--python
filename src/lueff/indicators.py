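"""Proxy indicators for the 17 mapped ecosystem services (ESs).

Each landscape unit (LU) receives one benefit-oriented raw value per ES:
higher always means greater potential supply.  Indicators follow the common
proxy families used in ES mapping: area shares (protected areas, wildlife
territories, erosion-control measures), LULC-weighted means (soil carbon),
point or count densities (heritage sites, tree species), inverse distances
(water, mountain peaks), a six-component recreation potential index, and
direct pass-through of surveyed quantities (growing stock, soil index,
visitation and scenic surrogate surfaces).

The 17 columns partition into three CICES-style groups: 2 regulating,
9 cultural and 6 provisioning services.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import LULC_CLASSES
from .landscape import LandscapeUnit, SyntheticLandscape

#: Fixed column order of the ES matrix.
ES_COLUMNS: tuple[str, ...] = (
    "erosion_control",
    "climate_regulation",
    "educational",
    "touristic",
    "flora_observation",
    "fauna_observation",
    "inspirational",
    "hunting",
    "spiritual",
    "recreation",
    "esthetic",
    "crops",
    "medicinal_plants",
    "water",
    "wild_plants",
    "wild_animals",
    "timber_production",
)

#: ES group per column (2 regulating / 9 cultural / 6 provisioning).
ES_GROUPS: dict[str, str] = {
    "erosion_control": "regulating",
    "climate_regulation": "regulating",
    "educational": "cultural",
    "touristic": "cultural",
    "flora_observation": "cultural",
    "fauna_observation": "cultural",
    "inspirational": "cultural",
    "hunting": "cultural",
    "spiritual": "cultural",
    "recreation": "cultural",
    "esthetic": "cultural",
    "crops": "provisioning",
    "medicinal_plants": "provisioning",
    "water": "provisioning",
    "wild_plants": "provisioning",
    "wild_animals": "provisioning",
    "timber_production": "provisioning",
}


def area_share_indicator(share: float, direction: str = "benefit") -> float:
    """Area-share proxy: the share itself (benefit) or its complement
    (inverse, for layers whose presence signals *lower* potential)."""
    if not 0.0 <= share <= 1.0:
        raise ValueError(f"share {share} outside [0, 1]")
    if direction == "benefit":
        return float(share)
    if direction == "inverse":
        return float(1.0 - share)
    raise ValueError(f"direction must be 'benefit' or 'inverse', got {direction!r}")


def weighted_mean_by_lulc(
    lulc_shares: np.ndarray, class_values: dict[str, float]
) -> float:
    """Share-weighted arithmetic mean of a per-class value over the classes
    present in the LU."""
    shares = np.asarray(lulc_shares, dtype=float)
    total = 0.0
    weight = 0.0
    for i, cls in enumerate(LULC_CLASSES):
        if shares[i] > 0:
            if cls not in class_values:
                raise ValueError(f"no class value for present class {cls!r}")
            total += shares[i] * class_values[cls]
            weight += shares[i]
    return total / weight


def density_indicator(count: float, area_km2: float) -> float:
    """Count per km^2."""
    if count < 0:
        raise ValueError(f"negative count {count}")
    if area_km2 <= 0:
        raise ValueError(f"non-positive area {area_km2}")
    return float(count) / float(area_km2)


def inverse_distance_indicator(distance_m: float, cap_m: float) -> float:
    """Linear proximity benefit ``cap - distance``; any affine inversion is
    equivalent after min-max normalization.  Distances beyond the cap are
    clamped (with a warning) rather than rejected."""
    if distance_m < 0:
        raise ValueError(f"negative distance {distance_m}")
    if distance_m > cap_m:
        import warnings

        warnings.warn(
            f"distance {distance_m} exceeds cap {cap_m}; clamping", stacklevel=2
        )
        distance_m = cap_m
    return float(cap_m - distance_m)


def _minmax01(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.full_like(col, 1.0, dtype=float)
    return (col - lo) / (hi - lo)


def recreation_potential(landscape: SyntheticLandscape) -> np.ndarray:
    """Recreation potential index: the unweighted mean of six sub-indicators,
    each min-max normalized to [0, 1] across the LU set.

    Sub-indicators: protected-area recreation value (Natura share), degree of
    naturalness (1 minus artificial/cropped shares), water proximity, LULC
    richness, terrain roughness (slope), and mountain-peak proximity.
    """
    units = landscape.units
    if len(units) < 2:
        raise ValueError("recreation potential needs at least 2 LUs to normalize")
    cap = landscape.config.drivers.distance_cap_m
    idx = {c: LULC_CLASSES.index(c) for c in LULC_CLASSES}
    shares = landscape.shares_matrix()
    artificial = (
        shares[:, idx["urban_artificial"]]
        + shares[:, idx["fields_gardens"]]
        + shares[:, idx["permanent_cultures"]]
    )
    subs = np.column_stack(
        [
            np.array([u.natura_share for u in units]),
            1.0 - artificial,
            np.array([inverse_distance_indicator(u.nearest_water_m, cap) for u in units]),
            np.array([u.n_lulc for u in units], dtype=float),
            np.array([u.slope_pct for u in units]),
            np.array([inverse_distance_indicator(u.nearest_peak_m, cap) for u in units]),
        ]
    )
    normed = np.column_stack([_minmax01(subs[:, j]) for j in range(subs.shape[1])])
    return normed.mean(axis=1)


def passthrough_indicator(lu: LandscapeUnit, field: str) -> float:
    """Return a raw generator/survey field unchanged."""
    if not hasattr(lu, field):
        raise ValueError(f"landscape unit has no field {field!r}")
    return float(getattr(lu, field))


def compute_es_matrix(
    landscape: SyntheticLandscape, erosion_inverse: bool = True
) -> pd.DataFrame:
    """Compute the raw (unnormalized) LU x 17 ES matrix.

    ``erosion_inverse`` controls the orientation of the erosion-control proxy:
    by default the presence of erosion-control measures signals ecosystems
    with *lower* intrinsic erosion-control potential, so the share is
    complemented.
    """
    units = landscape.units
    cfg = landscape.config
    cap = cfg.drivers.distance_cap_m
    recreation = recreation_potential(landscape)
    rows = []
    for i, u in enumerate(units):
        try:
            row = {
                "erosion_control": area_share_indicator(
                    u.erosion_measure_share,
                    "inverse" if erosion_inverse else "benefit",
                ),
                "climate_regulation": weighted_mean_by_lulc(
                    u.lulc_shares, cfg.carbon_table
                ),
                "educational": area_share_indicator(u.natura_share),
                "touristic": passthrough_indicator(u, "visitation_surrogate"),
                "flora_observation": density_indicator(u.tree_species_n, u.area_km2),
                "fauna_observation": area_share_indicator(u.carnivore_territory_share),
                "inspirational": density_indicator(u.heritage_sites_n, u.area_km2),
                "hunting": density_indicator(u.huntable_species_n, u.area_km2),
                "spiritual": density_indicator(u.intangible_sites_n, u.area_km2),
                "recreation": float(recreation[i]),
                "esthetic": passthrough_indicator(u, "scenic_surrogate"),
                "crops": passthrough_indicator(u, "soil_index"),
                "medicinal_plants": density_indicator(
                    u.gathering_households_n, u.area_km2
                ),
                "water": inverse_distance_indicator(u.nearest_water_m, cap),
                "wild_plants": passthrough_indicator(u, "chestnut_m3_ha"),
                "wild_animals": passthrough_indicator(u, "shot_animals_per_ha"),
                "timber_production": passthrough_indicator(u, "growing_stock_m3_ha"),
            }
        except ValueError as exc:
            raise ValueError(f"indicator failure on LU {u.lu_id}: {exc}") from exc
        rows.append(row)
    es = pd.DataFrame(rows, index=landscape.lu_ids, columns=list(ES_COLUMNS))
    es.index.name = "lu_id"
    if es.isna().any().any():
        bad = es.columns[es.isna().any()].tolist()
        raise ValueError(f"missing values in ES columns {bad}")
    return es
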