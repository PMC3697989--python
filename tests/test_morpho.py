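"""Stereology, vessel geometry and percent-change arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomet import morpho, synthio
from cardiomet.morpho import (
    count_lamellae,
    granule_stats,
    intima_media,
    lumen_diameter,
    numerical_density,
    overlay_grid,
    percent_change,
    volume_density,
    wall_tension,
)
from cardiomet.synthio import add_label_noise, gen_aorta_ring, gen_tissue_field


class TestPointCounting:
    def test_uniform_field_all_hits(self):
        fld = gen_tissue_field(200, 200, fractions={7: 100.0})
        grid = overlay_grid(fld, 82, seed=0)
        assert grid.hits(7) == 82
        assert volume_density(grid, 7) == 100.0

    def test_half_field_hits_binomially_distributed(self):
        fld = gen_tissue_field(500, 500, fractions={1: 50.0}, seed=1)
        hits = [overlay_grid(fld, 200, seed=s).hits(1) for s in range(40)]
        # Binomial(200, .5): mean 100, SD ~7.1
        assert abs(np.mean(hits) - 100.0) < 7.0
        assert np.std(hits, ddof=1) < 2 * 7.1
        assert sum(abs(h - 100) <= 14 for h in hits) >= 0.6 * len(hits)

    def test_same_seed_same_grid(self):
        fld = gen_tissue_field(100, 100, fractions={1: 30.0})
        a = overlay_grid(fld, 140, seed=5)
        b = overlay_grid(fld, 140, seed=5)
        np.testing.assert_array_equal(a.points, b.points)

    def test_vv_unbiased_with_binomial_standard_error(self):
        f = 0.137
        fld = gen_tissue_field(1000, 1000, fractions={5: 100 * f}, seed=0)
        vv = [volume_density(overlay_grid(fld, 140, seed=s), 5)
              for s in range(50)]
        assert abs(np.mean(vv) - 13.7) < 2.0
        theoretical_se = 100 * math.sqrt(f * (1 - f) / 140)
        assert np.std(vv, ddof=1) == pytest.approx(theoretical_se, rel=0.25)

    def test_zero_hits_zero_vv(self):
        fld = gen_tissue_field(100, 100)
        assert volume_density(overlay_grid(fld, 82, seed=0), 9) == 0.0

    def test_more_points_than_pixels_rejected(self):
        fld = gen_tissue_field(5, 5)
        with pytest.raises(ValueError):
            overlay_grid(fld, 82)


class TestDensities:
    def test_count_per_reference_area(self):
        assert numerical_density(10, 2.0)["density"] == 5.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            numerical_density(10, 0.0)

    def test_object_density_recovered_from_fields(self):
        densities = []
        for seed in range(20):
            fld = gen_tissue_field(1000, 1000, object_density_per_mm2=5.4,
                                   object_radius_um=5.0, px_per_um=1.0,
                                   seed=seed)
            n, _ = morpho.count_objects(fld)
            densities.append(numerical_density(n, fld.area_mm2)["density"])
        assert np.mean(densities) == pytest.approx(5.4, rel=0.1)


class TestGranules:
    def test_equivalent_circle_diameter_from_area(self):
        # a 1785 nm^2 profile has equivalent diameter 2*sqrt(a/pi) = 47.7 nm
        assert 2 * math.sqrt(1785 / math.pi) == pytest.approx(47.7, abs=0.05)

    def test_granule_count_density_and_diameter_recovered(self):
        fields = [gen_tissue_field(800, 800, object_density_per_mm2=18.7,
                                   object_radius_um=4.0, px_per_um=2.0, seed=s)
                  for s in range(10)]
        stats = granule_stats(fields)
        truth_density = np.mean([f.truth["object_density_per_mm2"] for f in fields])
        assert stats.density_per_mm2 == pytest.approx(truth_density, rel=0.1)
        # disks of radius 4 um -> diameter 8 um = 8000 nm
        assert stats.mean_diameter_nm == pytest.approx(8000, rel=0.1)
        assert stats.vv_pct > 0

    def test_empty_fields_zero_density(self):
        fields = [gen_tissue_field(200, 200)]
        stats = granule_stats(fields)
        assert stats.density_per_mm2 == 0.0
        assert stats.diameters_nm.size == 0


class TestVesselGeometry:
    def test_lumen_diameter_closed_form(self):
        assert lumen_diameter(math.pi) == pytest.approx(2.0)
        assert lumen_diameter(0.709) == pytest.approx(0.950, abs=0.001)
        assert lumen_diameter(0.0) == 0.0

    def test_diameter_area_round_trip(self):
        d = 1.15
        assert lumen_diameter(math.pi * (d / 2) ** 2) == pytest.approx(d)

    def test_intima_media_area_worked_example(self):
        imt, ima_raw, ima = intima_media(np.full(4, 177.3), 1.15)
        assert imt == pytest.approx(177.3)
        assert ima_raw == pytest.approx(0.739, abs=0.001)
        assert ima == pytest.approx(0.946, abs=0.002)

    def test_zero_thickness_zero_area(self):
        _, ima_raw, ima = intima_media(np.zeros(4), 1.0)
        assert ima_raw == 0.0 and ima == 0.0

    def test_unit_mismatch_rejected(self):
        # thickness passed in mm-sized numbers must be caught
        with pytest.raises(ValueError, match="units"):
            intima_media(np.full(4, 2000.0), 1.0)

    def test_ima_matches_pixel_counted_wall_area(self):
        ring = gen_aorta_ring(0.95, 158.0, 13, px_per_um=1.0)
        wall_mm2 = ring.truth["wall_area_px"] / (ring.px_per_um * 1e3) ** 2
        d = ring.truth["lumen_d_mm"]
        _, ima_raw, _ = intima_media(np.full(4, ring.truth["imt_um"]), d)
        assert ima_raw == pytest.approx(wall_mm2, rel=0.02)


class TestLamellae:
    @pytest.mark.parametrize("n", [1, 10, 13])
    def test_clean_ring_counted_exactly(self, n):
        ring = gen_aorta_ring(0.95, 158.0, n, seed=n)
        assert count_lamellae(ring) == n

    def test_count_robust_to_label_noise(self):
        ring = gen_aorta_ring(0.95, 158.0, 10, seed=3)
        noisy = add_label_noise(ring, 0.05, seed=4)
        assert count_lamellae(noisy) == 10

    def test_missing_wall_rejected(self):
        empty = synthio.TissueField(mask=np.zeros((50, 50), dtype=np.uint8),
                                    px_per_um=1.0)
        with pytest.raises(ValueError, match="wall"):
            count_lamellae(empty)


class TestWallTension:
    def test_trained_group_worked_example(self):
        cwt, _ = wall_tension(142.0, 0.86)
        assert round(cwt) == 61

    def test_zero_pressure_zero_tension(self):
        assert wall_tension(0.0, 1.0) == (0.0, 0.0)

    @given(p=st.floats(0, 300), d=st.floats(0, 3), s=st.floats(0.1, 4.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_bilinear_in_pressure_and_diameter(self, p, d, s):
        base = wall_tension(p, d)[0]
        assert wall_tension(s * p, d)[0] == pytest.approx(s * base, rel=1e-12)
        assert wall_tension(p, s * d)[0] == pytest.approx(s * base, rel=1e-12)

    def test_dyne_conversion_factor(self):
        cwt_mm, cwt_dyne = wall_tension(100.0, 1.0)
        assert cwt_mm == 50.0
        assert cwt_dyne == pytest.approx(50.0 * 133.322)


class TestPercentChange:
    def test_decrease_relative_to_reference(self):
        assert percent_change(240, 160, "reference") == pytest.approx(-33.3, abs=0.05)

    def test_increase_relative_to_value(self):
        assert percent_change(3.9, 5.2, "value") == pytest.approx(25.0, abs=0.05)

    def test_no_change_is_zero(self):
        assert percent_change(7.0, 7.0) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0, "reference")
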