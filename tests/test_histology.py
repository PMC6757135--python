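"""Slice quantification: thresholding, labeling, densities, NNDs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from skimage.filters import threshold_otsu

import taudamage as td
from taudamage.histology import RegionSet


def binary_image(mask, scale=0.1):
    return td.SliceImage(np.where(mask, 0, 255).astype(np.uint8), scale)


def region_set_from_centroids(pts, area=1.0, total=1000.0):
    df = pd.DataFrame({"label": range(1, len(pts) + 1),
                       "area_cm2": [area] * len(pts),
                       "centroid_x_cm": [p[0] for p in pts],
                       "centroid_y_cm": [p[1] for p in pts]})
    return RegionSet(regions=df, total_slice_area_cm2=total)


class TestThreshold:
    def test_fixed_midpoint_idempotent_on_binary(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        img = binary_image(m)
        cfg = td.ThresholdConfig(method="fixed", fixed_value=127.5)
        out = td.threshold_slice(img, cfg)
        np.testing.assert_array_equal(out.mask, m)
        # re-threshold the mask rendered back to an image: unchanged
        again = td.threshold_slice(binary_image(out.mask), cfg)
        np.testing.assert_array_equal(again.mask, m)

    def test_constant_image_is_all_background(self):
        img = td.SliceImage(np.full((8, 8), 77, np.uint8), 0.1)
        for cfg in (td.ThresholdConfig("otsu"), td.ThresholdConfig("fixed", 77)):
            assert not td.threshold_slice(img, cfg).mask.any()

    def test_otsu_matches_per_pixel_classification(self, rng):
        # two dark disks on a bright noisy field; oracle classifies each
        # pixel independently against the same computed threshold
        yy, xx = np.mgrid[:64, :64]
        img = rng.normal(220, 8, (64, 64))
        for cy, cx in ((16, 16), (45, 40)):
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= 36
            img[disk] = rng.normal(30, 8, disk.sum())
        img = np.clip(img, 0, 255).astype(np.uint8)
        out = td.threshold_slice(td.SliceImage(img, 0.1), td.ThresholdConfig("otsu"))
        thr = threshold_otsu(img)
        np.testing.assert_array_equal(out.mask, img <= thr)
        assert td.label_regions(out).regions.shape[0] == 2

    def test_fixed_value_outside_range_rejected(self):
        img = td.SliceImage(np.arange(100, dtype=np.uint8).reshape(10, 10), 0.1)
        with pytest.raises(ValueError, match="outside"):
            td.threshold_slice(img, td.ThresholdConfig("fixed", 200))


def flood_fill_count(mask, conn8=True):
    """Brute-force component counter (iterative flood fill), test-only oracle."""
    seen = np.zeros_like(mask, bool)
    if conn8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    H, W = mask.shape
    for i in range(H):
        for j in range(W):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


class TestLabelRegions:
    def test_two_squares_counts_and_areas(self):
        m = np.zeros((40, 40), bool)
        m[2:7, 2:7] = True       # 25 px
        m[20:25, 20:25] = True   # 25 px
        rs = td.label_regions(td.DamageMask(m, 0.1))
        assert len(rs) == 2
        np.testing.assert_allclose(rs.regions["area_cm2"], [0.25, 0.25])
        assert rs.total_slice_area_cm2 == pytest.approx(16.0)
        assert rs.damaged_area_cm2 == pytest.approx(0.5)

    def test_diagonal_pixels_connectivity(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert len(td.label_regions(td.DamageMask(m, 1.0), connectivity=8)) == 1
        assert len(td.label_regions(td.DamageMask(m, 1.0), connectivity=4)) == 2

    def test_random_masks_match_flood_fill_oracle(self, rng):
        for density in (0.2, 0.4, 0.6):
            m = rng.random((64, 64)) < density
            for conn in (4, 8):
                got = len(td.label_regions(td.DamageMask(m, 1.0), connectivity=conn))
                assert got == flood_fill_count(m, conn8=(conn == 8))

    def test_empty_mask(self):
        rs = td.label_regions(td.DamageMask(np.zeros((5, 5), bool), 1.0))
        assert len(rs) == 0 and rs.damaged_area_cm2 == 0.0

    def test_translation_invariance(self):
        m = np.zeros((50, 50), bool)
        m[5:12, 5:12] = True
        m[30:33, 8:15] = True
        shifted = np.roll(np.roll(m, 7, axis=0), 11, axis=1)
        a = td.label_regions(td.DamageMask(m, 0.1))
        b = td.label_regions(td.DamageMask(shifted, 0.1))
        assert len(a) == len(b)
        np.testing.assert_allclose(sorted(a.regions["area_cm2"]),
                                   sorted(b.regions["area_cm2"]))


class TestDensities:
    def test_nucleation_density(self):
        rs = region_set_from_centroids([(0, 0), (5, 5)], total=100.0)
        assert td.nucleation_density(rs) == pytest.approx(0.02)
        empty = td.label_regions(td.DamageMask(np.zeros((10, 10), bool), 1.0))
        assert td.nucleation_density(empty) == 0.0

    def test_damage_fraction(self):
        rs = region_set_from_centroids([(0, 0)], area=0.25, total=100.0)
        assert td.damage_fraction(rs) == pytest.approx(0.25)
        empty = td.label_regions(td.DamageMask(np.zeros((10, 10), bool), 1.0))
        assert td.damage_fraction(empty) == 0.0

    def test_zero_total_area_rejected(self):
        with pytest.raises(ValueError):
            region_set_from_centroids([(0, 0)], total=0.0)


class TestNND:
    def test_3_4_5_geometry(self):
        rs = region_set_from_centroids([(0, 0), (3, 0), (0, 4)])
        nnds, mean = td.nearest_neighbor_distances(rs)
        np.testing.assert_allclose(sorted(nnds), [3, 3, 4])
        assert mean == pytest.approx(10 / 3)

    def test_pair_symmetry(self):
        rs = region_set_from_centroids([(1, 1), (4, 5)])
        nnds, mean = td.nearest_neighbor_distances(rs)
        np.testing.assert_allclose(nnds, [5.0, 5.0])
        assert mean == 5.0

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        pts = rng.random((50, 2)) * 20
        rs = region_set_from_centroids([tuple(p) for p in pts])
        nnds, _ = td.nearest_neighbor_distances(rs)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        np.testing.assert_allclose(nnds, np.sqrt(d2.min(1)), rtol=1e-12)

    def test_undefined_below_two_regions(self):
        with pytest.raises(ValueError, match="undefined"):
            td.nearest_neighbor_distances(region_set_from_centroids([(0, 0)]))

    def test_rotation_invariance(self, rng):
        pts = rng.random((20, 2)) * 10
        theta = 0.83
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        a, _ = td.nearest_neighbor_distances(region_set_from_centroids([tuple(p) for p in pts]))
        b, _ = td.nearest_neighbor_distances(
            region_set_from_centroids([tuple(p) for p in pts @ R.T]))
        np.testing.assert_allclose(sorted(a), sorted(b), rtol=1e-10)


class TestQuantifySlice:
    @pytest.mark.parametrize("stage,count,pct", [(1, 2, 0.03), (4, 23, 20.85)])
    def test_stage_fixtures(self, stage, count, pct):
        img, _ = td.generate_slice_mask(td.stage_fixture_spec(stage))
        obs = td.quantify_slice(img)
        assert obs.n_regions == count
        assert round(obs.damage_fraction, 2) == pct

    def test_empty_image_gives_zeros_with_undefined_nnd(self):
        obs = td.quantify_slice(td.SliceImage(np.full((20, 20), 200, np.uint8), 0.1))
        assert obs.n_regions == 0
        assert obs.damage_fraction == 0.0
        assert obs.nucleation_density == 0.0
        assert math.isnan(obs.nnd)

    def test_observation_csv_units(self, tmp_path):
        img, _ = td.generate_slice_mask(td.stage_fixture_spec(2))
        obs = td.quantify_slice(img)
        from taudamage.histology import write_observations_csv

        write_observations_csv([obs], tmp_path / "cm.csv", area_units="cm2")
        write_observations_csv([obs], tmp_path / "mm.csv", area_units="mm2")
        cm = pd.read_csv(tmp_path / "cm.csv")["damaged_area_cm2"][0]
        mm = pd.read_csv(tmp_path / "mm.csv")["damaged_area_mm2"][0]
        assert mm == pytest.approx(100 * cm)

    def test_image_file_round_trip(self, tmp_path):
        img, gt = td.generate_slice_mask(td.stage_fixture_spec(3))
        mask = td.DamageMask(gt.mask, 0.1)
        mask.save(tmp_path / "m.png")
        back = td.SliceImage.from_file(tmp_path / "m.png", 0.1)
        obs = td.quantify_slice(back, td.ThresholdConfig("fixed", 127.5,
                                                         dark_damage=False))
        assert obs.n_regions == gt.n_regions


@given(st.integers(1, 6), st.floats(0.001, 0.05))
def test_quantification_bounds_property(n, frac):
    """Damage fraction in [0, 100] and nucleation density >= 0 always."""
    spec = td.SliceSpec(80, 80, 0.1, n, frac, seed=7)
    img, _ = td.generate_slice_mask(spec)
    obs = td.quantify_slice(img)
    assert 0.0 <= obs.damage_fraction <= 100.0
    assert obs.nucleation_density >= 0.0
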