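"""Metric definitions: radius, perimeter, compactness, occupancy, sectors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import eden3d as e
from eden3d.fixtures import (
    make_rasterized_disk,
    make_sector_series,
    make_sphere_shell,
    paint_sectors,
)
from eden3d.morphometrics import (
    ProjectionImage,
    default_fit_window,
    ensemble_occupancy,
    sector_density,
    sturges_bins,
)

from conftest import brute_force_surface, flood_fill_sectors


class TestExtractSurface:
    def test_single_voxel(self):
        vol = np.zeros((3, 3, 3), np.int32)
        vol[1, 1, 1] = 2
        mask = e.extract_surface(vol)
        assert mask.n_voxels == 1
        assert mask.colors[0] == 2

    def test_solid_cube_sheds_interior(self):
        vol = np.zeros((7, 7, 7), np.int32)
        vol[1:6, 1:6, 1:6] = 1
        mask = e.extract_surface(vol)
        assert mask.n_voxels == 5**3 - 3**3  # 98

    def test_empty_volume_gives_empty_mask(self):
        mask = e.extract_surface(np.zeros((4, 4, 4), np.int32))
        assert mask.n_voxels == 0

    def test_matches_brute_force_on_solid_sphere(self):
        solid = (make_sphere_shell(6, thickness=6) != 0).astype(np.int32)
        mask = e.extract_surface(solid)
        got = set(map(tuple, mask.coords))
        assert got == brute_force_surface(solid)

    def test_colors_preserved(self):
        shell = make_sphere_shell(5)
        mask = paint_sectors(shell, "hemispheres")
        surf = e.extract_surface(mask.to_volume())
        assert set(surf.palette) == {1, 2}


class TestProjection:
    def test_single_voxel_single_pixel(self):
        vol = np.zeros((4, 4, 4), np.int32)
        vol[1, 2, 3] = 1
        proj = e.project_z(vol)
        assert proj.pixels.sum() == 1
        assert proj.pixels[1, 2]

    def test_column_collapse(self):
        vol = np.zeros((4, 4, 4), np.int32)
        vol[1, 2, 0] = 1
        vol[1, 2, 3] = 1
        assert e.project_z(vol).pixels.sum() == 1

    def test_shell_projects_to_filled_disk(self):
        shell = make_sphere_shell(8)
        proj = e.project_z(shell)
        disk = make_rasterized_disk(8).pixels
        assert abs(proj.pixels.sum() - disk.sum()) <= disk.sum() * 0.15
        # no hole in the middle
        c = proj.pixels.shape[0] // 2
        assert proj.pixels[c, c]


class TestRadius:
    def test_mean_of_radii_not_radius_of_mean(self):
        # colonies with areas pi*100 and pi*400 um^2 -> <R> = (10+20)/2
        p1 = ProjectionImage(np.ones((10, 10), bool),
                             pixel_size=(math.sqrt(math.pi), math.sqrt(math.pi)))
        p2 = ProjectionImage(np.ones((20, 20), bool),
                             pixel_size=(math.sqrt(math.pi), math.sqrt(math.pi)))
        assert p1.area == pytest.approx(100 * math.pi)
        mean_r = e.estimate_radius([p1, p2])
        assert mean_r == pytest.approx(15.0)
        radius_of_mean_area = math.sqrt((p1.area + p2.area) / 2 / math.pi)
        assert mean_r != pytest.approx(radius_of_mean_area, rel=1e-3)

    def test_rasterized_disk_radius_recovered(self):
        proj = make_rasterized_disk(30)
        assert e.colony_radius(proj) == pytest.approx(30, abs=1)

    def test_empty_projection_warns_radius_zero(self):
        with pytest.warns(UserWarning):
            r = e.estimate_radius([ProjectionImage(np.zeros((3, 3), bool))])
        assert r == 0.0


class TestPerimeter:
    def test_single_pixel(self):
        assert e.measure_perimeter(ProjectionImage(np.ones((1, 1), bool))) == 4

    @pytest.mark.parametrize("s", [2, 5, 11])
    def test_square(self, s):
        img = np.zeros((s + 2, s + 2), bool)
        img[1:-1, 1:-1] = True
        assert e.measure_perimeter(ProjectionImage(img)) == 4 * s

    def test_city_block_bias_on_disk(self):
        # pixel-edge perimeter of a disk overshoots 2*pi*r by 4/pi
        proj = make_rasterized_disk(50)
        ratio = e.measure_perimeter(proj) / (2 * math.pi * 50)
        assert ratio == pytest.approx(4 / math.pi, rel=0.02)

    def test_anisotropic_pixels(self):
        img = ProjectionImage(np.ones((1, 1), bool), pixel_size=(2.0, 3.0))
        assert e.measure_perimeter(img) == pytest.approx(2 * (2.0 + 3.0))


class TestCompactness:
    def test_ideal_circle_quotient_is_one(self):
        r = 7.3
        assert e.isoperimetric_quotient(math.pi * r**2, 2 * math.pi * r) == (
            pytest.approx(1.0)
        )

    def test_square_quotient(self):
        assert e.isoperimetric_quotient(4.0, 8.0) == pytest.approx(math.pi / 4)

    def test_single_pixel_reference(self):
        assert e.reference_circle_quotient(1.0) == pytest.approx(math.pi / 4)

    def test_reference_asymptote(self):
        # large pixelated circles: rho' -> pi^2/16 from the 4/pi perimeter bias
        rho = e.reference_circle_quotient(math.pi * 200**2)
        assert rho == pytest.approx(math.pi**2 / 16, rel=0.02)

    @pytest.mark.parametrize("r", [5, 10, 30, 50])
    def test_self_normalization_exact(self, r):
        # the definitional anchor: a pixel-resolved circle has rho = 1
        assert e.normalized_compactness(make_rasterized_disk(r)) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_rough_shape_below_one(self):
        plus = np.zeros((5, 5), bool)
        plus[2, :] = True
        plus[:, 2] = True  # plus-sign pentomino-like cross
        assert e.normalized_compactness(ProjectionImage(plus)) < 1

    def test_zero_perimeter_rejected(self):
        with pytest.raises(ValueError):
            e.isoperimetric_quotient(1.0, 0.0)


class TestOccupancy:
    def test_monochrome_is_one(self):
        mask = paint_sectors(make_sphere_shell(5), "wedges", k=1)
        assert e.occupancy(mask, focal_color=1) == 1.0

    def test_hemispheres_half(self):
        mask = paint_sectors(make_sphere_shell(9), "hemispheres")
        occ = e.occupancy(mask, focal_color=1)
        # one equatorial voxel ring of allowance
        assert occ == pytest.approx(0.5, abs=0.1)
        assert e.occupancy(mask, focal_color=2) == pytest.approx(1 - occ)

    def test_colors_sum_to_one(self):
        mask = paint_sectors(make_sphere_shell(6), "random", seed=3)
        total = sum(e.occupancy(mask, focal_color=c) for c in mask.palette)
        assert total == pytest.approx(1.0)

    def test_absent_color_rejected(self):
        mask = paint_sectors(make_sphere_shell(5), "wedges", k=1)
        with pytest.raises(ValueError):
            e.occupancy(mask, focal_color=7)

    def test_ensemble_mean(self):
        masks = [paint_sectors(make_sphere_shell(7), "hemispheres")] * 3
        assert ensemble_occupancy(masks) == pytest.approx(
            e.occupancy(masks[0], 1)
        )


class TestLabelSectors:
    def test_monochrome_shell_single_sector(self):
        mask = paint_sectors(make_sphere_shell(6), "wedges", k=1)
        assert len(e.label_sectors(mask)) == 1

    def test_four_meridian_wedges(self):
        mask = paint_sectors(make_sphere_shell(8), "wedges", k=4)
        table = e.label_sectors(mask)
        assert len(table) == 4
        oracle = flood_fill_sectors(mask.to_volume())
        assert sorted(table.n_voxels) == sorted(s for _, s in oracle)

    def test_separated_same_color_clusters_are_distinct(self):
        a = make_sphere_shell(4)
        vol = np.zeros((40, 13, 13), np.int32)
        vol[: a.shape[0], :, :] = a[:, : 13, : 13]
        vol[40 - a.shape[0]:, :, :] = a[:, : 13, : 13]
        mask = e.extract_surface(vol)
        assert len(e.label_sectors(mask)) == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_flood_fill_oracle_random_masks(self, connectivity, seed):
        mask = paint_sectors(make_sphere_shell(6), "random", seed=seed)
        table = e.label_sectors(mask, connectivity=connectivity)
        oracle = flood_fill_sectors(mask.to_volume(), connectivity=connectivity)
        assert sorted(zip(table.color, table.n_voxels)) == sorted(oracle)

    def test_scipy_cross_check(self):
        # independent pooled count via per-color scipy labeling
        mask = paint_sectors(make_sphere_shell(7), "random", seed=9)
        vol = mask.to_volume()
        structure = ndimage.generate_binary_structure(3, 3)
        pooled = sum(
            ndimage.label(vol == c, structure=structure)[1]
            for c in mask.palette
        )
        assert len(e.label_sectors(mask)) == pooled

    def test_min_area_filters(self):
        mask = paint_sectors(make_sphere_shell(6), "random", seed=4)
        full = e.label_sectors(mask, min_area=1)
        filtered = e.label_sectors(mask, min_area=5)
        assert len(filtered) == (full.n_voxels >= 5).sum()

    def test_sector_areas_cover_surface(self):
        # at min_area=1 the sector areas partition the surface
        mask = paint_sectors(make_sphere_shell(8), "random", seed=5)
        table = e.label_sectors(mask, min_area=1)
        assert table.n_voxels.sum() == mask.n_voxels
        assert table.area.sum() == pytest.approx(mask.total_area)

    def test_invalid_min_area(self):
        mask = paint_sectors(make_sphere_shell(5), "wedges", k=1)
        with pytest.raises(ValueError):
            e.label_sectors(mask, min_area=0)


class TestSurvivalCurve:
    def test_printed_formula_on_three_sectors(self):
        a, s = e.survival_curve(np.array([1.0, 1.0, 2.0]))
        assert list(a) == [0.0, 1.0, 2.0]
        assert list(s) == [1.0, 0.5, 0.0]

    def test_single_sector(self):
        a, s = e.survival_curve(np.array([5.0]))
        assert list(a) == [0.0, 5.0]
        assert list(s) == [1.0, 0.0]

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.5, 100.0), min_size=1, max_size=30))
    def test_nonincreasing_from_one(self, areas):
        a, s = e.survival_curve(np.array(areas))
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            e.survival_curve(np.array([]))


class TestSectorDensity:
    def test_direct_values(self):
        d = sector_density(np.array([10.0]), np.array([1000.0]))
        assert d[0] == pytest.approx(0.01)

    def test_constant_sigma_growing_area_decreases(self):
        d = sector_density(np.full(5, 7.0), np.array([10, 20, 40, 80, 160.0]))
        assert (np.diff(d) < 0).all()

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            sector_density(np.array([1.0]), np.array([0.0]))


class TestSplittingRateFit:
    def test_exact_line(self):
        t = np.arange(0, 20.0)
        series = pd.DataFrame({"t": t, "sigma_mean": 2 * t + 3})
        fit = e.fit_splitting_rate(series, window=(5, 15))
        assert fit.slope == pytest.approx(2.0)
        assert fit.stderr == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept == pytest.approx(3.0)
        assert "splitting rate" in fit.summary()

    def test_default_window_isolates_increasing_branch(self):
        series = make_sector_series(sigma0=120, merge_rate=10, split_rate=2.0,
                                    floor=5, noise=0.0, t_max=40)
        fit = e.fit_splitting_rate(series)
        assert fit.window[0] >= 11.5  # crossover at t = 11.5
        assert fit.slope == pytest.approx(2.0, rel=1e-6)

    def test_noisy_slope_recovered_within_3_se(self):
        series = make_sector_series(sigma0=100, merge_rate=8, split_rate=1.0,
                                    floor=5, noise=1.5, t_max=50, seed=12)
        fit = e.fit_splitting_rate(series)
        assert abs(fit.slope - 1.0) < 3 * fit.stderr

    def test_zero_split_rate(self):
        series = make_sector_series(split_rate=0.0, noise=0.0)
        fit = e.fit_splitting_rate(series)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)

    def test_window_reported_and_validated(self):
        series = make_sector_series()
        fit = e.fit_splitting_rate(series)
        assert series.t.min() <= fit.window[0] < fit.window[1] <= series.t.max()
        with pytest.raises(ValueError):
            e.fit_splitting_rate(series, window=(30, 10))

    def test_sem_tolerant_start_skips_early_hump(self):
        # flat start, transient hump, then a linear rise from a level within
        # one SEM of the start: the window must begin after the hump
        t = np.arange(0, 41.0)
        sigma = np.full_like(t, 99.4)
        sigma[(t >= 4) & (t <= 8)] = 200.0
        late = t >= 9
        sigma[late] = 99.5 + 1.0 * (t[late] - 9)
        series = pd.DataFrame({"t": t, "sigma_mean": sigma, "sigma_sem": 2.0})
        fit = e.fit_splitting_rate(series)
        assert fit.window[0] > 8
        assert fit.slope == pytest.approx(1.0, abs=1e-9)


def test_sturges_bins():
    assert sturges_bins(1) == 1
    assert sturges_bins(100) == 8
    with pytest.raises(ValueError):
        sturges_bins(0)
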