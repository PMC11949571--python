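"""RUSLE retention and the two-part soil valuation."""

import numpy as np
import pytest

from karst_gep.soil import (
    RusleLayers, SoilValuationParams, fertilizer_retention_value, rusle_retention,
    sediment_reduction_value, soil_retention_value,
)
from conftest import make_grid


def layers(r=1.0, k=1.0, ls=1.0, c=0.0, p=1.0, cell_area=1.0):
    g = lambda v: make_grid([[float(v)]], cell_area=cell_area)
    return RusleLayers(r_factor=g(r), k_factor=g(k), ls_factor=g(ls),
                       c_factor=g(c), p_factor=g(p))


def salaxi_params():
    return SoilValuationParams(
        bulk_density=1.4,
        nutrient_content={"N": 0.002, "P": 0.00031, "K": 0.0109, "OM": 0.4095},
    )


class TestRusle:
    def test_full_cover_cell_contributes_nothing(self):
        qsr, _ = rusle_retention(layers(r=100.0, k=0.5, ls=3.0, c=1.0, p=0.9))
        assert qsr == pytest.approx(0.0)

    def test_unit_product_on_unit_cell(self):
        qsr, _ = rusle_retention(layers())
        assert qsr == pytest.approx(1.0)

    def test_direct_product(self):
        qsr, _ = rusle_retention(layers(r=100.0, k=0.3, ls=2.0, c=0.4, p=0.8))
        assert qsr == pytest.approx(28.8)

    def test_standard_bracket_switch(self):
        qsr, _ = rusle_retention(layers(r=100.0, k=0.3, ls=2.0, c=0.4, p=0.8),
                                 bracket="standard")
        assert qsr == pytest.approx(100.0 * 0.3 * 2.0 * (1 - 0.4 * 0.8))

    def test_mask_restricts_sum(self):
        g = lambda v: make_grid(np.full((1, 2), float(v)), cell_area=1.0)
        lyr = RusleLayers(r_factor=g(2.0), k_factor=g(1.0), ls_factor=g(1.0),
                          c_factor=g(0.0), p_factor=g(1.0))
        mask = make_grid([[1.0, 0.0]], cell_area=1.0)
        assert rusle_retention(lyr, mask)[0] == pytest.approx(2.0)

    def test_c_out_of_range_rejected(self):
        with pytest.raises(Exception, match="C factor"):
            layers(c=1.5)


class TestSedimentValue:
    def test_one_cubic_metre(self):
        # Qsr = ρ means exactly 1 m³ of soil; 0.24 × 5.96 = 1.4304
        assert sediment_reduction_value(1.4, salaxi_params()) == pytest.approx(1.4304)

    def test_zero(self):
        assert sediment_reduction_value(0.0, salaxi_params()) == 0.0

    def test_linear_in_mass(self):
        p = salaxi_params()
        assert sediment_reduction_value(50.0, p) == pytest.approx(50 * sediment_reduction_value(1.0, p))


class TestFertilizerValue:
    def test_nitrogen_contribution(self):
        # 100 t retained soil × 0.2% N = 0.2 t N; /0.14 → diammonium-phosphate
        # equivalent; × $434.25/t
        _, breakdown = fertilizer_retention_value(100.0, salaxi_params())
        assert breakdown["N"] == pytest.approx((0.2 / 0.14) * 434.25)

    def test_zero_contents_zero_value(self):
        p = SoilValuationParams(bulk_density=1.4,
                                nutrient_content={k: 0.0 for k in ("N", "P", "K", "OM")})
        v2, _ = fertilizer_retention_value(100.0, p)
        assert v2 == 0.0

    def test_organic_matter_unit_divisor(self):
        p = salaxi_params()
        _, breakdown = fertilizer_retention_value(100.0, p)
        assert breakdown["OM"] == pytest.approx(100.0 * 0.4095 * 121.33)

    def test_missing_nutrient_named(self):
        p = SoilValuationParams(bulk_density=1.4, nutrient_content={"Se": 0.01})
        with pytest.raises(KeyError, match="Se"):
            fertilizer_retention_value(1.0, p)

    def test_contributions_nonnegative_and_sum(self):
        v2, breakdown = fertilizer_retention_value(123.4, salaxi_params())
        assert all(v >= 0 for v in breakdown.values())
        assert v2 == pytest.approx(sum(breakdown.values()), rel=1e-12)


class TestTotalSoilValue:
    def test_additivity(self):
        p = salaxi_params()
        total, report = soil_retention_value(100.0, p)
        assert total == pytest.approx(report["sediment_reduction"] + report["fertilizer_retention"])

    def test_hand_computed_oracle(self):
        # independent hand chain for Salaxi constants at 100 t
        p = salaxi_params()
        v1 = 100.0 / 1.4 * 0.24 * 5.96
        v2 = ((100 * 0.002 / 0.14) * 434.25 + (100 * 0.00031 / 0.15) * 434.25
              + (100 * 0.0109 / 0.50) * 333.49 + (100 * 0.4095 / 1.00) * 121.33)
        total, _ = soil_retention_value(100.0, p)
        assert total == pytest.approx(v1 + v2, rel=1e-12)

    def test_linear_in_qsr(self):
        p = salaxi_params()
        assert soil_retention_value(7.0, p)[0] == pytest.approx(7 * soil_retention_value(1.0, p)[0])


def test_percent_contents_converted_exactly_once():
    """Config stores printed percentages; soil params expose fractions."""
    from karst_gep.config import StudyAreaConfig

    cfg = StudyAreaConfig(
        name="x", area_natural=1.0, area_artificial=0.0, total_land_area=10.0,
        gc_natural_pua=1.0, gc_artificial_pua=0.0, bulk_density=1.4,
        nutrient_content_percent={"N": 0.2, "P": 0.031, "K": 1.09, "OM": 40.95},
        soc_density=100.0, tier_prices=(1.0, 2.0, 3.0, 4.0), alpha=0.5,
    )
    params = cfg.soil_params()
    assert params.nutrient_content["N"] == pytest.approx(0.002)
    assert params.nutrient_content["OM"] == pytest.approx(0.4095)
    # calling twice must not divide twice
    assert cfg.soil_params().nutrient_content["N"] == pytest.approx(0.002)
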