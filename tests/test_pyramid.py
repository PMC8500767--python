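"""Pyramid construction, tissue masking, tiling, coordinates, preprocessing."""

import numpy as np
import pytest

from pyrascreen.pyramid import (Patch, augment_patch, build_pyramid,
                                contour_to_mask, downsample2_mask,
                                equalize_color, map_coords, otsu_tissue_mask,
                                read_pyramid, tile_level, write_pyramid)


class TestBuildPyramid:
    def test_halving_dims(self, rng):
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        pyr = build_pyramid(img, 3)
        assert [l.shape[:2] for l in pyr.levels] == [(64, 64), (32, 32), (16, 16)]
        np.testing.assert_array_equal(pyr.levels[0], img)

    def test_single_level_identity(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        pyr = build_pyramid(img, 1)
        assert len(pyr.levels) == 1

    def test_uniform_image_stays_uniform(self):
        img = np.full((32, 32, 3), 130, np.uint8)
        pyr = build_pyramid(img, 4)
        for lvl in pyr.levels:
            assert np.all(lvl == 130)

    def test_mean_conserved_within_one_gray_level(self, rng):
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        pyr = build_pyramid(img, 4)
        means = [l.mean() for l in pyr.levels]
        assert max(means) - min(means) < 1.0

    def test_too_many_levels_rejected(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            build_pyramid(img, 6)

    def test_odd_dims_ceil(self, rng):
        img = rng.integers(0, 256, (10, 14, 3), dtype=np.uint8)
        pyr = build_pyramid(img, 3)
        assert pyr.levels[1].shape[:2] == (5, 7)
        assert pyr.levels[2].shape[:2] == (3, 4)

    def test_pixel_size_doubles(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        pyr = build_pyramid(img, 3, pixel_size_um=0.25)
        assert pyr.level_pixel_size_um(2) == pytest.approx(1.0)


def test_mask_downsampling_any_positive():
    mask = np.zeros((8, 8), bool)
    mask[3, 5] = True
    small = downsample2_mask(mask)
    assert small.sum() == 1 and small[1, 2]


class TestOtsuTissueMask:
    def test_covers_planted_tissue(self, small_slide):
        mask = otsu_tissue_mask(small_slide.pyramid.levels[0])
        coverage = mask[small_slide.tissue_mask].mean()
        assert coverage >= 0.95

    def test_pure_white_empty(self):
        img = np.full((32, 32, 3), 255, np.uint8)
        with pytest.warns(UserWarning):
            mask = otsu_tissue_mask(img)
        assert not mask.any()

    def test_bimodal_threshold_between_modes(self):
        """Otsu on a 2-value saturation image splits the two modes exactly,
        matching a brute-force between-class-variance scan."""
        img = np.zeros((20, 20, 3), np.uint8)
        img[:, :] = (255, 255, 255)          # saturation 0
        img[:10] = (200, 100, 150)           # saturation 0.5
        mask = otsu_tissue_mask(img)
        assert mask[:10].mean() > 0.95 and mask[10:].mean() < 0.05


class TestContourToMask:
    def test_square_inclusive_centers(self):
        mask = contour_to_mask([[(0, 0), (0, 4), (4, 4), (4, 0)]], (8, 8))
        assert mask.sum() == 25
        assert mask[:5, :5].all()

    def test_empty_list(self):
        assert contour_to_mask([], (4, 4)).sum() == 0

    def test_nested_squares_even_odd_annulus(self):
        outer = [(0, 0), (0, 8), (8, 8), (8, 0)]
        inner = [(2, 2), (2, 6), (6, 6), (6, 2)]
        mask = contour_to_mask([outer, inner], (10, 10))
        assert mask[0, 0] and mask[1, 4]
        assert not mask[4, 4]  # inside both -> even -> off

    def test_matches_shapely_point_in_polygon_oracle(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point, Polygon

        verts = [(1, 1), (1, 10), (6, 12), (11, 7), (7, 1)]
        mask = contour_to_mask([verts], (14, 14))
        poly = Polygon(verts)
        for r in range(14):
            for c in range(14):
                assert mask[r, c] == poly.covers(Point(r, c)), (r, c)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            contour_to_mask([[(0, 0), (1, 1)]], (4, 4))


class TestTileLevel:
    def test_exact_partition(self, rng):
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        pyr = build_pyramid(img, 1)
        patches = tile_level(pyr, 0, 32, 32)
        assert len(patches) == 4
        # reassemble
        recon = np.zeros_like(img)
        for p in patches:
            r, c = p.origin
            recon[r:r + 32, c:c + 32] = p.image
        np.testing.assert_array_equal(recon, img)

    def test_overlapping_stride(self, rng):
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        pyr = build_pyramid(img, 1)
        assert len(tile_level(pyr, 0, 32, 16)) == 9

    def test_edge_padding(self, rng):
        img = rng.integers(0, 256, (70, 70, 3), dtype=np.uint8)
        pyr = build_pyramid(img, 1)
        patches = tile_level(pyr, 0, 32, 32)
        assert len(patches) == 9
        assert all(p.image.shape == (32, 32, 3) for p in patches)

    def test_all_white_tissue_only_empty(self):
        img = np.full((64, 64, 3), 255, np.uint8)
        pyr = build_pyramid(img, 1)
        with pytest.warns(UserWarning):
            assert tile_level(pyr, 0, 32, 32, tissue_only=True) == []

    def test_bad_stride(self, rng):
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        pyr = build_pyramid(img, 1)
        with pytest.raises(ValueError):
            tile_level(pyr, 0, 32, 0)


class TestMapCoords:
    def test_refine(self):
        assert map_coords((10, 10), 2, 0) == (40, 40)

    def test_coarsen_floor(self):
        assert map_coords((41, 41), 0, 2) == (10, 10)

    def test_roundtrip_quantization_bound(self, rng):
        for _ in range(50):
            r, c = int(rng.integers(0, 1000)), int(rng.integers(0, 1000))
            rc, cc = map_coords(map_coords((r, c), 0, 3), 3, 0)
            assert abs(rc - r) < 8 and abs(cc - c) < 8


class TestEqualizeColor:
    def test_self_matching_identity(self, rng):
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        out = equalize_color(img, img)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1

    def test_cdf_matches_reference(self, rng):
        a = rng.integers(0, 128, (64, 64, 3), dtype=np.uint8)
        ref = rng.integers(64, 256, (64, 64, 3), dtype=np.uint8)
        out = equalize_color(a, ref)
        for ch in range(3):
            q_out = np.percentile(out[:, :, ch], [25, 50, 75])
            q_ref = np.percentile(ref[:, :, ch], [25, 50, 75])
            assert np.abs(q_out - q_ref).max() <= 2.0


class TestAugmentPatch:
    def _patch(self, rng):
        return rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)

    def test_deterministic_under_seed(self, rng):
        img = self._patch(rng)
        a = augment_patch(img, ["crop", "rotate", "color_jitter"], seed=5)
        b = augment_patch(img, ["crop", "rotate", "color_jitter"], seed=5)
        np.testing.assert_array_equal(a, b)

    def test_rotation_90_matches_index_arithmetic(self, rng):
        img = self._patch(rng)
        # find a seed whose right-angle draw is 90 degrees (k=1)
        seed = next(s for s in range(50)
                    if np.random.default_rng(s).integers(0, 4) == 1)
        out = augment_patch(img, ["rotate"], seed=seed)
        np.testing.assert_array_equal(out, np.rot90(img, 1, axes=(0, 1)))

    def test_zero_rotation_identity(self, rng):
        img = self._patch(rng)
        seed = next(s for s in range(50)
                    if np.random.default_rng(s).integers(0, 4) == 0)
        np.testing.assert_array_equal(augment_patch(img, ["rotate"], seed=seed), img)

    def test_size_preserved(self, rng):
        img = self._patch(rng)
        out = augment_patch(img, ["crop", "scale"], seed=1)
        assert out.shape == img.shape

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_patch(self._patch(rng), ["sharpen"], seed=0)


def test_pyramid_roundtrip_on_disk(tmp_path, small_slide):
    write_pyramid(small_slide.pyramid, tmp_path / "pyr")
    back = read_pyramid(tmp_path / "pyr")
    assert back.n_levels == small_slide.pyramid.n_levels
    for a, b in zip(back.levels, small_slide.pyramid.levels):
        np.testing.assert_array_equal(a, b)
    for a, b in zip(back.masks, small_slide.pyramid.masks):
        np.testing.assert_array_equal(a, b)


def test_pyramidal_tiff_reader(tmp_path, rng):
    tifffile = pytest.importorskip("tifffile")
    from pyrascreen.pyramid import read_pyramid_tiff

    img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
    pyr = build_pyramid(img, 3)
    path = tmp_path / "pyr.tiff"
    with tifffile.TiffWriter(path) as tw:
        tw.write(pyr.levels[0], subifds=2, tile=(16, 16))
        for lvl in pyr.levels[1:]:
            tw.write(lvl, subfiletype=1, tile=(16, 16))
    back = read_pyramid_tiff(path)
    assert back.n_levels == 3
    np.testing.assert_array_equal(back.levels[0], img)
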