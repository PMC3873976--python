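"""Derived covariate formulas: decay, densities, proportions, TRI, CTI."""

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point, box

import stresscape as sc
from stresscape.covariates import CTI_SLOPE_FLOOR, _priority_flood_fill
from conftest import make_template


# -- distance decay ---------------------------------------------------------

class TestDistanceDecay:
    def test_value_one_on_feature_and_exact_decay(self, template):
        # vertical road through the centre of column 2 (x = 2500)
        road = LineString([(2500, -1e6), (2500, 1e6)])
        out = sc.distance_decay_surface([road], template)
        np.testing.assert_allclose(out.values[:, 2], 1.0, atol=1e-15)
        # column 4 centres sit 2000 m away: e^(-0.002*2000) = e^-4
        np.testing.assert_allclose(
            out.values[:, 4], np.exp(-4.0), rtol=1e-12
        )

    def test_empty_features_give_zero(self, template):
        out = sc.distance_decay_surface([], template)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_monotone_in_distance_and_adding_features(self, template):
        road = LineString([(0, -1e6), (0, 1e6)])
        out = sc.distance_decay_surface([road], template)
        row = out.values[0]
        assert np.all(np.diff(row) < 0)  # farther columns decay
        more = sc.distance_decay_surface(
            [road, Point(5500, 5500)], template
        )
        assert np.all(more.values >= out.values - 1e-15)

    def test_decay_constant_validation(self):
        with pytest.raises(sc.ConfigurationError):
            sc.DecayConfig(a=0.0)


# -- linear density ---------------------------------------------------------

class TestLinearDensity:
    def test_edge_to_edge_segment_is_unit_density(self, template):
        # through cell (row 9 = y in [0,1000]), y=500, x spanning col 0
        seg = LineString([(0, 500), (1000, 500)])
        out = sc.linear_density_surface([seg], template)
        assert out.values[9, 0] == pytest.approx(1.0, abs=1e-9)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_diagonal_is_sqrt_two(self, template):
        seg = LineString([(0, 0), (1000, 1000)])
        out = sc.linear_density_surface([seg], template)
        assert out.values[9, 0] == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_no_lines_zero(self, template):
        out = sc.linear_density_surface([], template)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_additive_over_disjoint_subsets(self, template, vectors):
        lines = [r["geometry"] for r in vectors["secondary_lines"]]
        full = sc.linear_density_surface(lines, template)
        part1 = sc.linear_density_surface(lines[::2], template)
        part2 = sc.linear_density_surface(lines[1::2], template)
        np.testing.assert_allclose(
            full.values, part1.values + part2.values, atol=1e-9
        )


# -- area proportion --------------------------------------------------------

class TestAreaProportion:
    def test_full_half_none(self, template):
        full = box(0, 0, 1000, 1000)        # covers cell (9, 0) exactly
        half = box(1000, 0, 1500, 1000)     # west half of cell (9, 1)
        out = sc.area_proportion_surface([full, half], template)
        assert out.values[9, 0] == pytest.approx(1.0)
        assert out.values[9, 1] == pytest.approx(0.5)
        assert out.values[0, 9] == 0.0

    def test_invalid_polygon_rejected(self, template):
        bowtie = shapely.Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(sc.GeometryError, match="index 0"):
            sc.area_proportion_surface([bowtie], template)

    def test_additivity_and_overlap_not_double_counted(self, template):
        a = box(0, 0, 3000, 3000)
        b = box(3000, 0, 6000, 3000)
        both = sc.area_proportion_surface([a, b], template)
        sep = (sc.area_proportion_surface([a], template).values
               + sc.area_proportion_surface([b], template).values)
        np.testing.assert_allclose(both.values, sep, atol=1e-9)
        dup = sc.area_proportion_surface([a, a], template)
        np.testing.assert_allclose(
            dup.values, sc.area_proportion_surface([a], template).values,
            atol=1e-12,
        )


# -- harvest age split ------------------------------------------------------

def _block(year):
    return {"geometry": box(0, 0, 10, 10), "properties": {"year": year}}


@pytest.mark.parametrize(
    "year, young", [(2008, True), (1993, True), (1992, False)]
)
def test_harvest_age_boundaries(year, young):
    """Age <= 15 years (inclusive) is the young class."""
    y, o = sc.harvest_age_split([_block(year)], reference_year=2008)
    assert (len(y), len(o)) == ((1, 0) if young else (0, 1))


def test_harvest_split_requires_year():
    with pytest.raises(ValueError, match="year"):
        sc.harvest_age_split([{"geometry": box(0, 0, 1, 1), "properties": {}}],
                             reference_year=2008)


# -- protected proportion ---------------------------------------------------

class TestProtectedProportion:
    def test_full_coverage_and_no_parks(self):
        template = make_template(4, 4, cell=1000.0)
        everywhere = box(-20000, -20000, 24000, 24000)
        out = sc.protected_proportion_surface([everywhere], template)
        np.testing.assert_allclose(out.values, 1.0, atol=1e-12)
        none = sc.protected_proportion_surface([], template)
        np.testing.assert_array_equal(none.values, 0.0)

    def test_half_plane_park_boundary_cell_is_half(self):
        # single cell centred at (500, 500); park is the half plane x <= 500
        template = make_template(1, 1, cell=1000.0)
        half_plane = box(-1e6, -1e6, 500, 1e6)
        out = sc.protected_proportion_surface([half_plane], template)
        assert out.values[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_invariant_to_park_subdivision(self):
        template = make_template(3, 3, cell=1000.0)
        whole = [box(0, 0, 2000, 3000)]
        halves = [box(0, 0, 2000, 1500), box(0, 1500, 2000, 3000)]
        a = sc.protected_proportion_surface(whole, template)
        b = sc.protected_proportion_surface(halves, template)
        np.testing.assert_allclose(a.values, b.values, atol=1e-6)


# -- terrain ruggedness -----------------------------------------------------

class TestTerrainRuggedness:
    def test_flat_dem_is_zero(self, template):
        template.values[:] = 321.0
        out = sc.terrain_ruggedness(template)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_single_peak_sqrt_eight(self):
        dem = make_template(3, 3)
        dem.values[1, 1] = 1.0
        out = sc.terrain_ruggedness(dem)
        assert out.values[1, 1] == pytest.approx(np.sqrt(8.0))

    def test_matches_bruteforce_neighbourhood_oracle(self):
        rng = np.random.default_rng(0)
        dem = make_template(6, 6)
        dem.values[:] = rng.normal(1000, 50, size=(6, 6))
        out = sc.terrain_ruggedness(dem)
        z = dem.values
        for r in range(6):
            for c in range(6):
                sq = 0.0
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (dr, dc) != (0, 0) and 0 <= rr < 6 and 0 <= cc < 6:
                            sq += (z[rr, cc] - z[r, c]) ** 2
                assert out.values[r, c] == pytest.approx(np.sqrt(sq))

    def test_translation_invariance_and_linear_scaling(self):
        rng = np.random.default_rng(1)
        dem = make_template(5, 5)
        dem.values[:] = rng.normal(0, 10, size=(5, 5))
        base = sc.terrain_ruggedness(dem).values
        shifted = sc.terrain_ruggedness(dem.like(dem.values + 500.0)).values
        scaled = sc.terrain_ruggedness(dem.like(dem.values * 3.0)).values
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-9)

    def test_nodata_propagates(self):
        dem = make_template(3, 3)
        dem.values[:] = 10.0
        dem.values[0, 0] = dem.nodata
        out = sc.terrain_ruggedness(dem)
        assert out.values[0, 0] == dem.nodata
        assert out.values[1, 1] == 0.0


# -- compound topographic index --------------------------------------------

class TestCTI:
    def test_ramp_closed_form_at_the_top(self):
        # uniform west-facing ramp, 10 m drop per 1-km cell; the eastmost
        # column drains only itself: CTI = ln(cell_size / tan(slope))
        dem = make_template(5, 5)
        dem.values[:] = np.arange(5) * -10.0  # falls to the east... so the
        # WEST column (col 0) is highest and accumulates nothing
        out = sc.compound_topographic_index(dem)
        tanb = 10.0 / 1000.0
        expected = np.log(1000.0 / tanb)
        np.testing.assert_allclose(out.values[1:-1, 0], expected, rtol=1e-9)

    def test_valley_bottom_wetter_than_slopes(self):
        # V-valley along the central column: bottom cells accumulate flow
        dem = make_template(7, 7)
        dem.values[:] = np.abs(np.arange(7) - 3)[None, :] * 20.0
        # tilt slightly south so the valley axis drains
        dem.values += np.arange(7)[:, None] * 1.0
        out = sc.compound_topographic_index(dem)
        assert out.values[3, 3] > out.values[3, 1]

    def test_constant_dem_clamps_and_warns(self):
        dem = make_template(4, 4)
        dem.values[:] = 100.0
        with pytest.warns(RuntimeWarning, match="constant DEM"):
            out = sc.compound_topographic_index(dem)
        assert np.all(np.isfinite(out.values))
        # every cell accumulates only itself on a flat: ln(cell/floor)
        np.testing.assert_allclose(
            out.values, np.log(1000.0 / CTI_SLOPE_FLOOR)
        )

    def test_pit_filling_drains_depressions(self):
        dem = make_template(5, 5)
        dem.values[:] = 100.0
        dem.values[2, 2] = 10.0  # closed pit
        filled = _priority_flood_fill(dem.values)
        assert filled[2, 2] == 100.0
        with pytest.warns(RuntimeWarning):  # filled surface is constant
            out = sc.compound_topographic_index(dem)
        assert np.all(np.isfinite(out.values))


# -- assembly ---------------------------------------------------------------

def test_assemble_stack_kinds_and_rsf_range(fields):
    stack = sc.assemble_stack(dict(fields.rasters))
    assert stack.kinds["lcover"] == "categorical"
    assert stack.kinds["rsf_s1"] == "ordinal"
    bad = fields["rsf_s1"].like(np.full(fields.template.shape, 11.0),
                                name="rsf_s1")
    rasters = dict(fields.rasters)
    rasters["rsf_s1"] = bad
    with pytest.raises(sc.ConfigurationError, match="0-10"):
        sc.assemble_stack(rasters)


def test_standard_stack_layers_and_grid_alignment(stack, fields):
    expected = {
        "cc", "pctcon", "lcover", "dhi_cum", "dhi_cv", "dhi_min", "elev",
        "tri", "cti", "rsf_s1", "rsf_s2", "rsf_s3", "rsf_max",
        "rd_dd", "rail_dd", "wl_dd", "ln_den", "cblk_l", "cblk_g", "pa",
    }
    assert set(stack.names) == expected
    template = fields.template
    for name in stack.names:
        assert stack[name].co_registered(template)  # no resampling drift
    assert stack["pa"].values.min() >= 0 and stack["pa"].values.max() <= 1
    assert stack["rd_dd"].values.min() >= 0 and stack["rd_dd"].values.max() <= 1
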