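"""Water yield, topographic index, retention chain and valuation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karst_gep.geodata import RasterError
from karst_gep.hydrology import (
    HydroLayers, WaterPrice, topographic_index, water_retention,
    water_retention_value, water_yield,
)
from conftest import make_grid


def hydro_layers(precip=1000.0, aet=400.0, velocity=498.0, ksat=150.0,
                 drainage=100.0, soil_depth=10.0, slope=1.0, **kw):
    g = lambda v: make_grid([[float(v)]])
    return HydroLayers(
        precip=g(precip), aet=g(aet), velocity=g(velocity), ksat=g(ksat),
        drainage_area=g(drainage), soil_depth=g(soil_depth), slope_pct=g(slope), **kw,
    )


class TestWaterYield:
    @pytest.mark.parametrize(
        "p, a, expected", [(1000.0, 0.0, 1000.0), (500.0, 500.0, 0.0), (1000.0, 400.0, 600.0), (0.0, 0.0, 0.0)]
    )
    def test_point_values(self, p, a, expected):
        out = water_yield(make_grid([[p]]), make_grid([[a]]))
        assert out.values[0, 0] == pytest.approx(expected)

    def test_aet_above_precip_reports_cell(self):
        with pytest.raises(RasterError, match=r"\(0, 1\)"):
            water_yield(make_grid([[500.0, 500.0]]), make_grid([[100.0, 600.0]]))


class TestTopographicIndex:
    @pytest.mark.parametrize(
        "da, sd, sl, expected",
        [(10.0, 10.0, 1.0, 0.0), (100.0, 10.0, 1.0, 1.0), (1.0, 10.0, 10.0, -2.0)],
    )
    def test_log10_values(self, da, sd, sl, expected):
        out = topographic_index(make_grid([[da]]), make_grid([[sd]]), make_grid([[sl]]))
        assert out.values[0, 0] == pytest.approx(expected)

    def test_natural_log_switch(self):
        out = topographic_index(make_grid([[np.e * 10.0]]), make_grid([[10.0]]),
                                make_grid([[1.0]]), log_base="e")
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_nonpositive_argument_becomes_nodata(self):
        out = topographic_index(make_grid([[100.0, 100.0]]),
                                make_grid([[10.0, 0.0]]), make_grid([[1.0, 1.0]]))
        assert np.isfinite(out.values[0, 0]) and np.isnan(out.values[0, 1])


class TestWaterRetention:
    def test_all_caps_saturate_gives_yield(self):
        layers = hydro_layers(velocity=100.0, ksat=400.0, drainage=1e6, soil_depth=10.0, slope=1.0)
        wr = water_retention(layers)
        assert wr.values[0, 0] == pytest.approx(600.0)  # Yx = 1000 - 400

    def test_zero_yield_annihilates(self):
        layers = hydro_layers(precip=400.0, aet=400.0)
        assert water_retention(layers).values[0, 0] == pytest.approx(0.0)

    def test_factor_by_factor(self):
        # Velocity 498 → 0.5; TI = 5/3 → 0.5; Ksat 150 → 0.5; Yx = 600
        layers = hydro_layers(velocity=498.0, ksat=150.0,
                              drainage=10.0 ** (5.0 / 3.0) * 10.0, soil_depth=10.0, slope=1.0)
        assert water_retention(layers).values[0, 0] == pytest.approx(75.0, rel=1e-9)

    def test_nonpositive_velocity_fails(self):
        with pytest.raises(RasterError, match="Velocity"):
            water_retention(hydro_layers(velocity=0.0))

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(100.0, 2000.0), st.floats(0.0, 1.0), st.floats(1.0, 5000.0),
        st.floats(1.0, 500.0), st.floats(1.0, 1e6),
    )
    def test_retention_never_exceeds_yield(self, p, aet_frac, vel, ksat, da):
        layers = hydro_layers(precip=p, aet=p * aet_frac, velocity=vel, ksat=ksat, drainage=da)
        wr = water_retention(layers).values[0, 0]
        yx = water_yield(layers.precip, layers.aet).values[0, 0]
        assert 0.0 <= wr <= yx + 1e-9

    def test_monotone_in_ksat_and_velocity(self):
        base = water_retention(hydro_layers(ksat=100.0, velocity=500.0)).values[0, 0]
        more_ksat = water_retention(hydro_layers(ksat=200.0, velocity=500.0)).values[0, 0]
        more_vel = water_retention(hydro_layers(ksat=100.0, velocity=1000.0)).values[0, 0]
        assert more_ksat >= base >= more_vel


class TestWaterValue:
    def test_unit_chain(self):
        # 1 mm over 1 hm² = 10 t; at $0.43/t → $4.30
        wr = make_grid([[1.0]], cell_area=1.0)
        mask = make_grid([[1.0]], cell_area=1.0)
        value, tonnes = water_retention_value(wr, mask, WaterPrice(0.43))
        assert tonnes == pytest.approx(10.0)
        assert value == pytest.approx(4.30)

    def test_zero_retention_zero_value(self):
        wr = make_grid([[0.0]], cell_area=1.0)
        mask = make_grid([[1.0]], cell_area=1.0)
        assert water_retention_value(wr, mask, WaterPrice(0.43))[0] == 0.0

    def test_linear_in_price_volume_fixed(self):
        wr = make_grid([[2.0, 3.0]], cell_area=0.5)
        mask = make_grid([[1.0, 1.0]], cell_area=0.5)
        v1, t1 = water_retention_value(wr, mask, WaterPrice(0.43))
        v2, t2 = water_retention_value(wr, mask, WaterPrice(0.86))
        assert t1 == t2 and v2 == pytest.approx(2 * v1)

    def test_additive_over_disjoint_masks(self):
        wr = make_grid([[2.0, 3.0], [4.0, 5.0]], cell_area=1.0)
        m1 = make_grid([[1.0, 0.0], [0.0, 1.0]], cell_area=1.0)
        m2 = make_grid([[0.0, 1.0], [1.0, 0.0]], cell_area=1.0)
        both = make_grid(np.ones((2, 2)), cell_area=1.0)
        price = WaterPrice(0.43)
        assert (water_retention_value(wr, m1, price)[0] + water_retention_value(wr, m2, price)[0]
                == pytest.approx(water_retention_value(wr, both, price)[0]))
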