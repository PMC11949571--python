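"""Raster container, TIFF round-trip, bare-rock index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karst_gep.geodata import (
    NdriNormalization, RasterError, bare_rock_fraction, compute_ndri,
    read_raster, write_raster, zonal_mean,
)
from conftest import make_grid


class TestRasterIO:
    def test_round_trip_identity(self, tmp_path):
        grid = make_grid([[1.5, 2.5], [3.5, -9999.0]], cell_area=0.25,
                         nodata=-9999.0, crs_tag="utm")
        path = tmp_path / "g.tif"
        write_raster(path, grid)
        back = read_raster(path)
        np.testing.assert_array_equal(back.values, grid.values)
        assert back.nodata == -9999.0
        assert back.cell_area == pytest.approx(0.25)
        assert back.crs_tag == "utm"

    def test_nodata_cells_flagged_missing(self, tmp_path):
        grid = make_grid([[1.0, -9999.0], [-9999.0, 2.0]], nodata=-9999.0)
        path = tmp_path / "g.tif"
        write_raster(path, grid)
        mask = read_raster(path).mask()
        assert mask.tolist() == [[True, False], [False, True]]

    def test_ten_metre_cells_are_hundredth_hectare(self, tmp_path):
        # 10 m × 10 m = 100 m² = 0.01 hm²
        grid = make_grid(np.ones((3, 3)), cell_area=0.01)
        path = tmp_path / "g.tif"
        write_raster(path, grid)
        assert read_raster(path).cell_area == pytest.approx(0.01)

    def test_unreadable_file_names_the_file(self, tmp_path):
        bad = tmp_path / "nope.tif"
        bad.write_bytes(b"not a tiff")
        with pytest.raises(RasterError, match="nope.tif"):
            read_raster(bad)


class TestNdri:
    @pytest.mark.parametrize(
        "b3, b8, expected",
        [(0.2, 0.2, 0.0), (0.0, 0.4, 1.0), (0.1, 0.3, 0.5)],
    )
    def test_point_values(self, b3, b8, expected):
        out = compute_ndri(make_grid([[b3]]), make_grid([[b8]]))
        assert out.values[0, 0] == pytest.approx(expected)

    def test_zero_sum_cell_is_nodata(self):
        out = compute_ndri(make_grid([[0.0, 0.1]]), make_grid([[0.0, 0.3]]))
        assert np.isnan(out.values[0, 0]) and np.isfinite(out.values[0, 1])

    def test_misaligned_inputs_report_shapes(self):
        with pytest.raises(RasterError, match=r"\(1, 2\).*\(2, 1\)"):
            compute_ndri(make_grid([[0.1, 0.2]]), make_grid([[0.1], [0.2]]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
           st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_antisymmetric_under_band_swap(self, a, b):
        g1 = make_grid(np.array(a).reshape(2, 2))
        g2 = make_grid(np.array(b).reshape(2, 2))
        np.testing.assert_allclose(
            compute_ndri(g1, g2).values, -compute_ndri(g2, g1).values, atol=1e-12
        )


class TestBareRockFraction:
    def ramp(self):
        return make_grid(np.linspace(0.0, 1.0, 101).reshape(1, 101))

    def test_anchor_cells_map_to_zero_and_one(self):
        fr = bare_rock_fraction(self.ramp())
        vals = fr.values.ravel()
        # 1st/99th percentile anchors of the uniform ramp
        assert vals[0] == 0.0 and vals[1] == pytest.approx(0.0, abs=1e-12)
        assert vals[-1] == 1.0

    def test_midpoint_of_ramp_near_half(self):
        fr = bare_rock_fraction(self.ramp())
        assert fr.values[0, 50] == pytest.approx(0.5, abs=0.02)

    def test_output_clamped_to_unit_interval(self):
        fr = bare_rock_fraction(self.ramp(), NdriNormalization(10, 90))
        ok = np.isfinite(fr.values)
        assert fr.values[ok].min() >= 0.0 and fr.values[ok].max() <= 1.0

    def test_invariant_to_positive_affine_rescale(self):
        base = self.ramp()
        scaled = make_grid(3.0 * base.values - 0.7)
        np.testing.assert_allclose(
            bare_rock_fraction(base).values, bare_rock_fraction(scaled).values, atol=1e-9
        )

    def test_constant_raster_degenerate(self):
        with pytest.raises(RasterError, match="degenerate"):
            bare_rock_fraction(make_grid(np.full((3, 3), 0.4)))

    def test_printed_form_nonpositive_below_high_anchor(self):
        fr = bare_rock_fraction(self.ramp(), as_printed=True)
        # literal published normalization: (NDRI - NDRIr)/(NDRIr - NDRI0)
        assert (fr.values.ravel()[:-1] <= 0).all()


class TestZonalMean:
    def test_constant_layer(self):
        layer = make_grid(np.full((2, 2), 7.0))
        mask = make_grid([[1.0, 0.0], [1.0, 1.0]])
        assert zonal_mean(layer, mask) == pytest.approx(7.0)

    def test_selects_masked_cells(self):
        layer = make_grid([[1.0, 2.0], [3.0, 4.0]])
        mask = make_grid([[0.0, 1.0], [0.0, 1.0]])
        assert zonal_mean(layer, mask) == pytest.approx(3.0)

    def test_empty_zone_errors(self):
        layer = make_grid([[1.0, 2.0]])
        with pytest.raises(RasterError, match="empty"):
            zonal_mean(layer, make_grid([[0.0, 0.0]]))

    def test_nonbinary_mask_rejected(self):
        layer = make_grid([[1.0, 2.0]])
        with pytest.raises(RasterError, match="binary"):
            zonal_mean(layer, make_grid([[0.5, 1.0]]))
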