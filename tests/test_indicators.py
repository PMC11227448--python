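"""Proxy-indicator computations for the 17 ecosystem services."""

import numpy as np
import pytest

from lueff import ES_COLUMNS, ES_GROUPS, ScenarioConfig, compute_es_matrix, generate_scenario
from lueff.config import LULC_CLASSES, ArchetypeParams
from lueff.indicators import (
    area_share_indicator,
    density_indicator,
    inverse_distance_indicator,
    passthrough_indicator,
    recreation_potential,
    weighted_mean_by_lulc,
)
from lueff.landscape import LandscapeUnit, SyntheticLandscape
from shapely.geometry import box


class TestAreaShare:
    @pytest.mark.parametrize(
        "share,direction,expected",
        [(0.0, "inverse", 1.0), (0.25, "inverse", 0.75), (0.70, "benefit", 0.70)],
    )
    def test_values(self, share, direction, expected):
        assert area_share_indicator(share, direction) == pytest.approx(expected)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match="outside"):
            area_share_indicator(1.2)
        with pytest.raises(ValueError, match="direction"):
            area_share_indicator(0.5, "sideways")


class TestWeightedMean:
    def test_single_class(self):
        shares = np.zeros(9)
        shares[0] = 1.0
        vals = dict.fromkeys(LULC_CLASSES, 0.0)
        vals["forests"] = 9500.0
        assert weighted_mean_by_lulc(shares, vals) == 9500.0

    def test_two_class_mean(self):
        shares = np.zeros(9)
        shares[0], shares[1] = 0.5, 0.5
        vals = {"forests": 9000.0, "pastureland": 5000.0}
        assert weighted_mean_by_lulc(shares, vals) == pytest.approx(7000.0)

    def test_symmetric_in_class_order(self):
        rng = np.random.default_rng(0)
        shares = rng.dirichlet(np.ones(9))
        vals = {c: float(v) for c, v in zip(LULC_CLASSES, rng.uniform(0, 1e4, 9))}
        ref = weighted_mean_by_lulc(shares, vals)
        perm = rng.permutation(9)
        # permuting value lookups does not matter as lookup is by name
        assert weighted_mean_by_lulc(shares, dict(list(vals.items())[::-1])) == ref

    def test_missing_class_named_in_error(self):
        shares = np.zeros(9)
        shares[2] = 1.0
        with pytest.raises(ValueError, match="old_field_succession"):
            weighted_mean_by_lulc(shares, {"forests": 1.0})


class TestDensityAndDistance:
    @pytest.mark.parametrize(
        "count,area,expected", [(0, 1.0, 0.0), (6, 1.0, 6.0), (3, 0.999, 3.003003003003003)]
    )
    def test_density(self, count, area, expected):
        assert density_indicator(count, area) == pytest.approx(expected, abs=1e-9)

    def test_density_negative_count_errors(self):
        with pytest.raises(ValueError, match="negative"):
            density_indicator(-1, 1.0)

    @pytest.mark.parametrize(
        "d,cap,expected", [(0.0, 20000.0, 20000.0), (20000.0, 20000.0, 0.0), (5000.0, 20000.0, 15000.0)]
    )
    def test_inverse_distance(self, d, cap, expected):
        assert inverse_distance_indicator(d, cap) == expected

    def test_beyond_cap_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert inverse_distance_indicator(25_000.0, 20_000.0) == 0.0


def _toy_landscape(units):
    cfg = ScenarioConfig(n_rows=1, n_cols=len(units))
    return SyntheticLandscape(
        config=cfg,
        units=units,
        heritage_points=np.empty((0, 2)),
        intangible_points=np.empty((0, 2)),
        water_points=np.empty((0, 2)),
        peak_points=np.empty((0, 2)),
    )


def _unit(lu_id, **kw):
    shares = kw.pop("lulc_shares", None)
    u = LandscapeUnit(
        lu_id=lu_id,
        row=0,
        col=lu_id,
        polygon=box(lu_id * 1000, 0, (lu_id + 1) * 1000, 1000),
        area_km2=1.0,
    )
    if shares is not None:
        u.lulc_shares = np.asarray(shares, dtype=float)
    for k, v in kw.items():
        setattr(u, k, v)
    return u


class TestRecreation:
    def _three_units(self):
        # forest-only shares: naturalness sub-indicator constant at 1
        pure = np.zeros(9)
        pure[0] = 1.0
        mixed = np.zeros(9)
        mixed[0], mixed[4] = 0.5, 0.5  # half urban: naturalness 0.5
        u0 = _unit(0, lulc_shares=pure, natura_share=0.0, nearest_water_m=20000.0,
                   slope_pct=0.0, nearest_peak_m=20000.0)
        u1 = _unit(1, lulc_shares=mixed, natura_share=0.5, nearest_water_m=10000.0,
                   slope_pct=10.0, nearest_peak_m=10000.0)
        u2 = _unit(2, lulc_shares=pure, natura_share=1.0, nearest_water_m=0.0,
                   slope_pct=20.0, nearest_peak_m=0.0)
        return [u0, u1, u2]

    def test_hand_computed_three_unit_landscape(self):
        # hand normalization: natura (0,.5,1); naturalness (1,.5,1)->(1,0,1);
        # water proximity (0,.5,1); n_lulc (1,2,1)->(0,1,0); slope (0,.5,1);
        # peak proximity (0,.5,1)
        ls = _toy_landscape(self._three_units())
        rec = recreation_potential(ls)
        expected = [
            np.mean([0, 1, 0, 0, 0, 0]),
            np.mean([0.5, 0, 0.5, 1, 0.5, 0.5]),
            np.mean([1, 1, 1, 0, 1, 1]),
        ]
        np.testing.assert_allclose(rec, expected, atol=1e-12)

    def test_extremes_hit_zero_and_one(self):
        urban = np.zeros(9)
        urban[4] = 1.0  # fully artificial: naturalness 0, single LULC class
        natural = np.array([0.5, 0.5] + [0.0] * 7)  # forest+pasture: naturalness 1
        worst = _unit(0, lulc_shares=urban, natura_share=0.0, nearest_water_m=20000.0,
                      slope_pct=0.0, nearest_peak_m=20000.0)
        best = _unit(1, lulc_shares=natural, natura_share=1.0, nearest_water_m=0.0,
                     slope_pct=30.0, nearest_peak_m=0.0)
        rec = recreation_potential(_toy_landscape([worst, best]))
        assert rec[0] == pytest.approx(0.0)
        assert rec[1] == pytest.approx(1.0)

    def test_single_unit_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            recreation_potential(_toy_landscape(self._three_units()[:1]))


class TestPassthrough:
    def test_identity(self):
        u = _unit(0, growing_stock_m3_ha=300.0, soil_index=0.0)
        assert passthrough_indicator(u, "growing_stock_m3_ha") == 300.0
        assert passthrough_indicator(u, "soil_index") == 0.0

    def test_missing_field_errors(self):
        with pytest.raises(ValueError, match="no field"):
            passthrough_indicator(_unit(0), "not_a_field")


class TestESMatrix:
    def test_shape_and_group_partition(self, small_landscape):
        es = compute_es_matrix(small_landscape)
        assert list(es.columns) == list(ES_COLUMNS)
        assert len(es.columns) == 17
        groups = [ES_GROUPS[c] for c in es.columns]
        assert groups.count("regulating") == 2
        assert groups.count("cultural") == 9
        assert groups.count("provisioning") == 6
        assert not es.isna().any().any()

    def test_surrogate_columns_match_generator_fields(self, small_landscape):
        es = compute_es_matrix(small_landscape)
        np.testing.assert_array_equal(
            es["touristic"].to_numpy(),
            [u.visitation_surrogate for u in small_landscape.units],
        )
        np.testing.assert_array_equal(
            es["esthetic"].to_numpy(),
            [u.scenic_surrogate for u in small_landscape.units],
        )

    def test_forest_only_landscape_columns(self):
        arch = [ArchetypeParams(name="pure", weight=1.0, forest_mean=0.97,
                                forest_conc=3000.0, extra_class_p=0.01)]
        ls = generate_scenario(ScenarioConfig(n_rows=4, n_cols=4, archetypes=arch, seed=3))
        es = compute_es_matrix(ls)
        assert (es["timber_production"] > 0).all()
        np.testing.assert_array_equal(
            es["crops"].to_numpy(), [u.soil_index for u in ls.units]
        )

    def test_benefit_orientation_monotone(self, small_landscape):
        """Increasing a favorable underlying quantity never lowers the indicator."""
        es = compute_es_matrix(small_landscape)
        u = small_landscape.units[0]
        u2 = _unit(0, natura_share=min(1.0, u.natura_share + 0.1),
                   carnivore_territory_share=min(1.0, u.carnivore_territory_share + 0.1),
                   erosion_measure_share=max(0.0, u.erosion_measure_share - 0.1))
        assert area_share_indicator(u2.natura_share) >= es["educational"].iloc[0]
        assert area_share_indicator(u2.carnivore_territory_share) >= es["fauna_observation"].iloc[0]
        assert area_share_indicator(u2.erosion_measure_share, "inverse") >= es["erosion_control"].iloc[0]

    def test_single_unit_landscape_errors_with_lu_context(self):
        arch = [ArchetypeParams(name="pure", weight=1.0, forest_mean=0.9)]
        ls = generate_scenario(ScenarioConfig(n_rows=1, n_cols=1, archetypes=arch, seed=4))
        with pytest.raises(ValueError, match="at least 2"):
            compute_es_matrix(ls)
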