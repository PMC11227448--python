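"""Scenario configuration for the synthetic landscape generator.

A :class:`ScenarioConfig` bundles everything the generator needs to emulate a
temperate cultural landscape: grid geometry, the nine-class land-use/land-cover
(LULC) catalogue with per-class management costs (EUR ha^-1 yr^-1) and topsoil
carbon densities (Mg C km^-2), archetype mixture parameters controlling the
forest-share distribution, driver-field marginals, and the ground-truth effect
parameters that couple terrain to landscape composition.

Defaults are calibrated to the study region the package emulates: a karst
cultural landscape of roughly 720 km^2 where forests cover ~65% of the area,
the Natura 2000 network ~70%, population density is ~40 persons km^-2 and
elevation spans roughly 200-800 m.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

#: Canonical LULC class keys, in fixed catalogue order.
LULC_CLASSES: tuple[str, ...] = (
    "forests",
    "pastureland",
    "old_field_succession",
    "other_agricultural",
    "urban_artificial",
    "other_non_agricultural",
    "permanent_cultures",
    "fields_gardens",
    "water_bodies",
)

FOREST = "forests"
URBAN = "urban_artificial"


def _load_default_tables() -> tuple[dict[str, float], dict[str, float]]:
    cost: dict[str, float] = {}
    carbon: dict[str, float] = {}
    text = (
        resources.files("lueff").joinpath("data/default_costs.csv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("lulc_class"):
            continue
        name, c, sc = line.split(",")
        cost[name] = float(c)
        carbon[name] = float(sc)
    return cost, carbon


_DEFAULT_COST, _DEFAULT_CARBON = _load_default_tables()


@dataclass
class ArchetypeParams:
    """One landscape archetype: a Beta law for the forest share plus a rule
    for how the non-forest remainder is split.

    ``forest_mean``/``forest_conc`` parametrise Beta(mean*conc, (1-mean)*conc).
    ``extra_class_p`` is the success probability of the Binomial(7, p) draw for
    the number of non-forest classes beyond the first, so each LU carries between
    2 and 9 LULC classes. ``class_weights`` weight the choice of which
    non-forest classes are present (catalogue order, forest omitted).
    """

    name: str
    weight: float
    forest_mean: float
    forest_conc: float = 25.0
    extra_class_p: float = 0.4
    class_weights: tuple[float, ...] = (0.30, 0.14, 0.12, 0.10, 0.10, 0.10, 0.10, 0.04)
    split_conc: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.forest_mean < 1.0:
            raise ValueError("forest_mean must lie strictly inside (0, 1)")
        if self.forest_conc <= 0 or self.split_conc <= 0:
            raise ValueError("concentration parameters must be positive")
        if len(self.class_weights) != len(LULC_CLASSES) - 1:
            raise ValueError("class_weights must cover the 8 non-forest classes")


def default_archetypes() -> list[ArchetypeParams]:
    """Mixture spanning the three Hladnik forest-share bands.

    Weights solve w1*0.93 + w2*0.65 + w3*0.20 = 0.65 so the aggregate mean
    forest share equals the configured regional value of 65%.
    """
    return [
        ArchetypeParams(
            name="forest",
            weight=0.3214,
            forest_mean=0.93,
            forest_conc=40.0,
            extra_class_p=0.25,
            class_weights=(0.28, 0.30, 0.08, 0.06, 0.14, 0.05, 0.04, 0.05),
        ),
        ArchetypeParams(
            name="forested_mosaic",
            weight=0.4786,
            forest_mean=0.65,
            forest_conc=25.0,
            extra_class_p=0.45,
            class_weights=(0.34, 0.16, 0.12, 0.10, 0.08, 0.08, 0.08, 0.04),
        ),
        ArchetypeParams(
            name="agricultural_urban",
            weight=0.2000,
            forest_mean=0.20,
            forest_conc=15.0,
            extra_class_p=0.65,
            class_weights=(0.24, 0.06, 0.16, 0.18, 0.04, 0.16, 0.14, 0.02),
        ),
    ]


@dataclass
class DriverParams:
    """Marginal distributions of the driver fields and point-layer intensities.

    Intensities are points km^-2; densities follow lognormal laws given by the
    log-scale mean/sd; ``road_nlulc_rank_corr`` is the target Spearman
    correlation between road density and the number of distinct LULC classes,
    imposed through a Gaussian copula.
    """

    pop_density_logmean: float = 3.4  # exp(3.4+0.9^2/2) ~ 45 persons km^-2
    pop_density_logsd: float = 0.9
    road_density_logmean: float = 0.5  # km km^-2
    road_density_logsd: float = 0.5
    road_nlulc_rank_corr: float = 0.5
    natura_mean: float = 0.70
    natura_conc: float = 4.0
    heritage_intensity: float = 0.6
    intangible_intensity: float = 0.25
    spring_intensity: float = 0.15
    peak_intensity: float = 0.066  # ~48 peaks over ~720 km^2
    slope_base_pct: float = 4.0
    slope_noise_sd: float = 4.0
    elev_base_m: float = 230.0
    elev_noise_sd: float = 80.0
    distance_cap_m: float = 20_000.0

    def __post_init__(self) -> None:
        if not -1.0 < self.road_nlulc_rank_corr < 1.0:
            raise ValueError("road_nlulc_rank_corr must lie strictly in (-1, 1)")
        for name in (
            "heritage_intensity",
            "intangible_intensity",
            "spring_intensity",
            "peak_intensity",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.distance_cap_m <= 0:
            raise ValueError("distance_cap_m must be positive")


@dataclass
class GroundTruthEffects:
    """Signed couplings between landscape structure and the latent cost/ES
    fields; consumed by the generator and inspected only by tests.

    ``slope_forest_gain`` makes steeper cells more forested (forests sit on
    terrain unsuited to agriculture), which transmits a positive slope ->
    efficiency effect through the cheap forest management cost.  Heterogeneous
    cells draw more of the expensive agricultural classes, giving the number
    of distinct LULCs a negative effect on efficiency.
    """

    slope_forest_gain: float = 22.0  # slope % added per unit forest share
    elev_forest_gain: float = 380.0  # m added per unit forest share


@dataclass
class IndicatorParams:
    """Parameters of the raw per-LU indicator layers (tree species richness,
    growing stock, hunting bags, soil index, surrogate surfaces...)."""

    tree_species_base: float = 3.0
    tree_species_forest_gain: float = 12.0
    huntable_base: float = 2.0
    huntable_forest_gain: float = 6.0
    shot_animals_scale: float = 0.04  # n ha^-1 at full forest cover
    growing_stock_mean: float = 280.0  # m^3 ha^-1 on forest area
    growing_stock_sd: float = 45.0
    chestnut_scale: float = 8.0  # m^3 ha^-1
    household_size: float = 2.5
    gathering_rate: float = 0.379  # share of households gathering wild plants
    soil_index_base: float = 15.0
    soil_index_agri_gain: float = 65.0
    soil_index_sd: float = 8.0
    erosion_measure_mean: float = 0.10
    erosion_measure_conc: float = 3.0
    carnivore_base: float = 0.15
    carnivore_forest_gain: float = 0.65


@dataclass
class ScenarioConfig:
    """Full, seedable description of one synthetic landscape scenario."""

    n_rows: int = 25
    n_cols: int = 25
    cell_size_m: float = 1000.0
    seed: int = 42
    min_area_km2: float = 0.999
    lulc_catalogue: tuple[str, ...] = LULC_CLASSES
    cost_table: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_COST))
    carbon_table: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CARBON))
    archetypes: list[ArchetypeParams] = field(default_factory=default_archetypes)
    drivers: DriverParams = field(default_factory=DriverParams)
    effects: GroundTruthEffects = field(default_factory=GroundTruthEffects)
    indicators: IndicatorParams = field(default_factory=IndicatorParams)

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if tuple(self.lulc_catalogue) != LULC_CLASSES:
            raise ValueError(
                "lulc_catalogue must be the nine canonical classes in order"
            )
        missing = [c for c in LULC_CLASSES if c not in self.cost_table]
        if missing:
            raise ValueError(f"cost_table missing classes: {missing}")
        missing = [c for c in LULC_CLASSES if c not in self.carbon_table]
        if missing:
            raise ValueError(f"carbon_table missing classes: {missing}")
        if any(v < 0 for v in self.cost_table.values()):
            raise ValueError("costs must be non-negative")
        if any(v < 0 for v in self.carbon_table.values()):
            raise ValueError("carbon densities must be non-negative")
        w = sum(a.weight for a in self.archetypes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"archetype weights must sum to 1, got {w}")

    @property
    def mean_forest_share(self) -> float:
        """Mixture expectation of the forest share."""
        return float(sum(a.weight * a.forest_mean for a in self.archetypes))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["lulc_catalogue"] = list(d["lulc_catalogue"])
        for a in d["archetypes"]:
            a["class_weights"] = list(a["class_weights"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "lulc_catalogue" in d:
            d["lulc_catalogue"] = tuple(d["lulc_catalogue"])
        if "archetypes" in d:
            d["archetypes"] = [
                a if isinstance(a, ArchetypeParams) else ArchetypeParams(
                    **{**a, "class_weights": tuple(a["class_weights"])}
                )
                for a in d["archetypes"]
            ]
        for key, typ in (
            ("drivers", DriverParams),
            ("effects", GroundTruthEffects),
            ("indicators", IndicatorParams),
        ):
            if key in d and not isinstance(d[key], typ):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} did not parse to a mapping")
        try:
            return cls.from_dict(d)
        except TypeError as exc:  # unknown/missing key -> name it
            raise ValueError(f"invalid config {path}: {exc}") from exc
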