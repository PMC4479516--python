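import numpy as np
import pytest

from ibrscape.raster import (
    AGRICULTURAL,
    NATURAL,
    NODATA,
    GridFormatError,
    HabitatRaster,
    build_resistance_surface,
    habitat_proportion,
    read_ascii_grid,
    uniform_surface,
    write_ascii_grid,
)
from ibrscape.scan import IBRScenario
from ibrscape.sites import (
    PopulationSite,
    haversine_m,
    load_lamancha_sites,
    project_coordinates,
)


def _write(tmp_path, text, name="grid.asc"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 50\nNODATA_value -9999\n"


class TestAsciiGrid:
    def test_reads_classes_with_top_row_first(self, tmp_path):
        raster = read_ascii_grid(_write(tmp_path, HEADER + "1 1\n2 2\n"))
        assert (raster.classes[0] == NATURAL).all()
        assert (raster.classes[1] == AGRICULTURAL).all()
        assert raster.cellsize == 50

    def test_round_trip_preserves_cells_and_header(self, tmp_path, rng):
        classes = rng.choice([NATURAL, AGRICULTURAL, NODATA], size=(7, 5))
        raster = HabitatRaster(classes, cellsize=50.0, xll=123.5, yll=-7.25)
        path = tmp_path / "out.asc"
        write_ascii_grid(raster, path)
        back = read_ascii_grid(path)
        assert np.array_equal(back.classes, raster.classes)
        assert back.cellsize == raster.cellsize
        assert back.xll == raster.xll and back.yll == raster.yll

    def test_ragged_row_errors_with_line_number(self, tmp_path):
        bad = HEADER.replace("ncols 2", "ncols 3") + "1 1 1\n2 2\n"
        with pytest.raises(GridFormatError, match="line 8"):
            read_ascii_grid(_write(tmp_path, bad))

    def test_unknown_class_code_rejected(self, tmp_path):
        with pytest.raises(GridFormatError, match="unknown class code"):
            read_ascii_grid(_write(tmp_path, HEADER + "1 7\n2 2\n"))

    def test_missing_header_key_rejected(self, tmp_path):
        with pytest.raises(GridFormatError, match="missing header"):
            read_ascii_grid(_write(tmp_path, "ncols 2\nnrows 2\n1 1\n2 2\n"))

    def test_custom_class_codes(self, tmp_path):
        raster = read_ascii_grid(
            _write(tmp_path, HEADER + "5 5\n9 9\n"),
            class_codes={5: NATURAL, 9: AGRICULTURAL},
        )
        assert (raster.classes[0] == NATURAL).all()


class TestProjection:
    def test_identical_points_have_zero_separation(self):
        s = [
            PopulationSite("A", 40.0, -3.0, 2, 1, 1),
            PopulationSite("B", 40.0, -3.0, 2, 1, 1),
        ]
        xy = project_coordinates(s)
        assert np.hypot(*(xy.loc["A"] - xy.loc["B"])) == pytest.approx(0.0)

    def test_one_degree_latitude_is_111km(self):
        s = [
            PopulationSite("A", 39.5, -3.0, 2, 1, 1),
            PopulationSite("B", 40.5, -3.0, 2, 1, 1),
        ]
        xy = project_coordinates(s)
        d = np.hypot(*(xy.loc["A"] - xy.loc["B"]))
        assert d == pytest.approx(111_194.9, rel=1e-4)

    def test_matches_haversine_within_half_percent(self):
        sites = load_lamancha_sites()
        xy = project_coordinates(sites)
        by_id = {s.id: s for s in sites}
        for a, b in [("OCA", "ALC"), ("OCA", "PED"), ("HUE", "YEG")]:
            planar = float(np.hypot(*(xy.loc[a] - xy.loc[b])))
            great_circle = haversine_m(
                by_id[a].latitude, by_id[a].longitude,
                by_id[b].latitude, by_id[b].longitude,
            )
            assert planar == pytest.approx(great_circle, rel=0.005)

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValueError):
            project_coordinates([])

    def test_inconsistent_sex_totals_rejected(self):
        with pytest.raises(ValueError, match="n_total"):
            PopulationSite("A", 40.0, -3.0, 20, 12, 9)


class TestResistanceSurface:
    def test_substitution_per_class(self):
        classes = np.array([[NATURAL, AGRICULTURAL], [AGRICULTURAL, NATURAL]])
        raster = HabitatRaster(classes, cellsize=50.0)
        surf = build_resistance_surface(raster, IBRScenario("x", 1.0, 1000.0))
        assert surf.resistance[0, 0] == 1.0
        assert surf.resistance[0, 1] == 1000.0

    def test_equal_resistances_match_flat_landscape(self):
        classes = np.array([[NATURAL, AGRICULTURAL], [AGRICULTURAL, NATURAL]])
        raster = HabitatRaster(classes, cellsize=50.0)
        surf = build_resistance_surface(raster, IBRScenario("IBR-A", 1.0, 1.0))
        flat = uniform_surface(2, 2, 50.0)
        assert np.array_equal(surf.resistance, flat.resistance)

    def test_nodata_preserved_and_scaling(self):
        classes = np.array([[NATURAL, NODATA], [AGRICULTURAL, NATURAL]])
        raster = HabitatRaster(classes, cellsize=50.0)
        s1 = build_resistance_surface(raster, IBRScenario("a", 1.0, 7.0))
        s3 = build_resistance_surface(raster, IBRScenario("b", 3.0, 21.0))
        assert np.isnan(s1.resistance[0, 1])
        mask = np.isfinite(s1.resistance)
        assert np.allclose(s3.resistance[mask], 3.0 * s1.resistance[mask])

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            IBRScenario("bad", 0.0, 1.0)


class TestHabitatProportion:
    def test_saturated_landscapes(self):
        nat = HabitatRaster(np.full((10, 10), NATURAL), cellsize=10.0)
        agr = HabitatRaster(np.full((10, 10), AGRICULTURAL), cellsize=10.0)
        assert habitat_proportion(nat, (50.0, 50.0), 30.0) == 1.0
        assert habitat_proportion(agr, (50.0, 50.0), 30.0) == 0.0

    def test_half_plane_boundary_site_is_half(self):
        # left half natural, site on the dividing line, radius >> cellsize
        classes = np.full((100, 100), AGRICULTURAL)
        classes[:, :50] = NATURAL
        raster = HabitatRaster(classes, cellsize=1.0)
        frac = habitat_proportion(raster, (50.0, 50.0), 30.0)
        assert frac == pytest.approx(0.5, abs=0.02)  # one-cell-row discretization

    def test_nodata_excluded_from_denominator(self):
        classes = np.full((10, 10), NATURAL)
        classes[:, 5:] = NODATA
        raster = HabitatRaster(classes, cellsize=1.0)
        assert habitat_proportion(raster, (2.0, 5.0), 3.0) == 1.0

    def test_disc_outside_raster_errors(self):
        raster = HabitatRaster(np.full((5, 5), NATURAL), cellsize=1.0)
        with pytest.raises(ValueError, match="no usable cells"):
            habitat_proportion(raster, (100.0, 100.0), 2.0)

    def test_translation_invariance(self):
        classes = np.full((20, 20), AGRICULTURAL)
        classes[5:12, 5:12] = NATURAL
        a = HabitatRaster(classes, cellsize=1.0)
        b = HabitatRaster(classes, cellsize=1.0, xll=1000.0, yll=-500.0)
        fa = habitat_proportion(a, (8.0, 8.0), 5.0)
        fb = habitat_proportion(b, (1008.0, -492.0), 5.0)
        assert fa == fb
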