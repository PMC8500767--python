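"""Synthetic slide generator: determinism, labels, geometry, ground truth."""

import numpy as np
import pytest

from pyrascreen.staging import StagingThresholds, region_extent_mm
from pyrascreen.synthetic import (LesionSpec, SlideSpec, bbox_to_point,
                                  generate_nuclei_patches, generate_slide,
                                  generate_tissue_patches, read_slide,
                                  write_slide)


class TestBboxToPoint:
    @pytest.mark.parametrize("bbox,expected", [
        ((0, 0, 10, 10), (5, 5)),
        ((2, 4, 6, 8), (4, 6)),
        ((3, 3, 3, 3), (3, 3)),
    ])
    def test_center(self, bbox, expected):
        assert bbox_to_point(bbox) == expected

    def test_inverted_rejected(self):
        with pytest.raises(ValueError):
            bbox_to_point((5, 0, 3, 10))


class TestSlideSpecValidation:
    def test_indivisible_dims(self):
        with pytest.raises(ValueError):
            SlideSpec(base_height=100, base_width=128, n_levels=4)

    def test_pixel_size_range(self):
        with pytest.raises(ValueError):
            SlideSpec(base_height=128, base_width=128, n_levels=3,
                      pixel_size_um=2.0)

    def test_min_levels(self):
        with pytest.raises(ValueError):
            SlideSpec(base_height=128, base_width=128, n_levels=1)


class TestGenerateSlide:
    def test_no_lesions_negative(self, negative_slide):
        assert negative_slide.true_label == "negative"
        assert not any(m.any() for m in negative_slide.lesion_masks)
        assert not negative_slide.nuclei_tumor.any()

    def test_macro_label_from_staging_thresholds(self):
        spec = SlideSpec(base_height=512, base_width=512, n_levels=4,
                         pixel_size_um=0.1,
                         lesions=[LesionSpec(center=(256, 256), diameter_um=30)],
                         background_seed=2)
        # 30 um at 0.1 um/px = 300 px; 0.03 mm -> itc scale
        assert generate_slide(spec, seed=1).true_label == "itc"
        spec3mm = SlideSpec(base_height=4096, base_width=4096, n_levels=6,
                            pixel_size_um=1.0,
                            lesions=[LesionSpec(center=(2048, 2048),
                                                diameter_um=3000)],
                            background_seed=2)
        assert generate_slide(spec3mm, seed=1).true_label == "macro"

    def test_seed_determinism(self):
        spec = SlideSpec(base_height=256, base_width=256, n_levels=3,
                         pixel_size_um=1.0,
                         lesions=[LesionSpec(center=(128, 128), diameter_um=60)],
                         background_seed=9)
        a = generate_slide(spec, seed=7)
        b = generate_slide(spec, seed=7)
        for la, lb in zip(a.pyramid.levels, b.pyramid.levels):
            np.testing.assert_array_equal(la, lb)
        np.testing.assert_array_equal(a.nuclei_points, b.nuclei_points)

    def test_lesion_outside_canvas_rejected(self):
        spec = SlideSpec(base_height=256, base_width=256, n_levels=3,
                         pixel_size_um=1.0,
                         lesions=[LesionSpec(center=(5, 5), diameter_um=100)])
        with pytest.raises(ValueError, match="canvas|tissue"):
            generate_slide(spec, seed=0)

    def test_masks_coarsen_any_positive(self, small_slide):
        for l in range(small_slide.pyramid.n_levels - 1):
            fine = small_slide.lesion_masks[l]
            coarse = small_slide.lesion_masks[l + 1]
            h, w = fine.shape
            ph, pw = h % 2, w % 2
            if ph or pw:
                fine = np.pad(fine, ((0, ph), (0, pw)))
                h, w = fine.shape
            expect = fine.reshape(h // 2, 2, w // 2, 2).any(axis=(1, 3))
            np.testing.assert_array_equal(coarse, expect)

    def test_points_are_bbox_centers(self, small_slide):
        b = small_slide.nuclei_bboxes
        centers = np.column_stack([(b[:, 0] + b[:, 2]) / 2, (b[:, 1] + b[:, 3]) / 2])
        np.testing.assert_allclose(centers, small_slide.nuclei_points, atol=1e-9)

    def test_itc_cell_count_controls_tumor_cells(self):
        spec = SlideSpec(base_height=512, base_width=512, n_levels=4,
                         pixel_size_um=1.0,
                         lesions=[LesionSpec(center=(256, 256), diameter_um=100,
                                             cell_count=150)],
                         nuclei_density=200.0, background_seed=4)
        slide = generate_slide(spec, seed=2)
        n_tumor = int(slide.nuclei_tumor.sum())
        # planted count plus the few background nuclei that fall inside
        assert 150 <= n_tumor <= 170
        assert slide.true_label == "itc"

    def test_lesion_area_matches_disk(self):
        d_um = 200.0
        spec = SlideSpec(base_height=1024, base_width=1024, n_levels=4,
                         pixel_size_um=1.0,
                         lesions=[LesionSpec(center=(512, 512), diameter_um=d_um,
                                             shape_irregularity=0.0)],
                         background_seed=6)
        slide = generate_slide(spec, seed=1)
        area_mm2 = slide.lesion_masks[0].sum() * 1e-6
        expected = np.pi * (d_um / 2000.0) ** 2
        assert abs(area_mm2 - expected) / expected < 0.15

    def test_lesion_extent_matches_diameter(self):
        d_um = 300.0
        spec = SlideSpec(base_height=1024, base_width=1024, n_levels=4,
                         pixel_size_um=1.0,
                         lesions=[LesionSpec(center=(512, 512), diameter_um=d_um,
                                             shape_irregularity=0.0)],
                         background_seed=6)
        slide = generate_slide(spec, seed=1)
        extent = region_extent_mm(slide.lesion_masks[0], pixel_size_um=1.0)
        assert abs(extent - d_um / 1000.0) / (d_um / 1000.0) < 0.10

    def test_lesions_have_denser_nuclei(self, small_slide):
        mask = small_slide.lesion_masks[0]
        pts = small_slide.nuclei_points.astype(int)
        inside = small_slide.nuclei_tumor.sum() / mask.sum()
        outside_mask = small_slide.tissue_mask & ~mask
        outside = (len(pts) - small_slide.nuclei_tumor.sum()) / outside_mask.sum()
        assert inside > 1.5 * outside


def test_label_consistency_staging_oracle_on_masks():
    """The staging oracle applied to the planted ground truth reproduces
    true_label across all three lesion classes and the negative case."""
    thresholds = StagingThresholds()
    cases = [
        ([], "negative"),
        ([LesionSpec(center=(1536, 1536), diameter_um=100, cell_count=120)], "itc"),
        ([LesionSpec(center=(1536, 1536), diameter_um=600)], "micro"),
        ([LesionSpec(center=(1536, 1536), diameter_um=2400)], "macro"),
    ]
    for lesions, expected in cases:
        spec = SlideSpec(base_height=3072, base_width=3072, n_levels=6,
                         pixel_size_um=1.0, lesions=lesions, background_seed=8)
        slide = generate_slide(spec, seed=3)
        assert slide.true_label == expected
        if lesions:
            extent = region_extent_mm(slide.lesion_masks[0], pixel_size_um=1.0)
            cells = int(slide.nuclei_tumor.sum())
            if extent >= thresholds.macro_min_mm:
                oracle = "macro"
            elif (extent >= thresholds.micro_min_mm
                  or cells > thresholds.itc_max_cells):
                oracle = "micro"
            elif cells > 0:
                oracle = "itc"
            else:
                oracle = "negative"
            assert oracle == expected


class TestPatchDatasets:
    def test_tissue_patch_shapes_balance(self):
        X, y = generate_tissue_patches(20, size=32, seed=0)
        assert X.shape == (20, 32, 32, 3) and X.dtype == np.uint8
        assert y.sum() == 10

    def test_nuclei_patches_targets_integrate_to_counts(self):
        X, pts, Y = generate_nuclei_patches(6, size=64, seed=0)
        for p, dmap in zip(pts, Y):
            assert abs(dmap.sum() - len(p)) < 1e-6

    def test_nuclei_min_separation(self):
        from scipy.spatial.distance import pdist
        _X, pts, _Y = generate_nuclei_patches(6, size=64, seed=1, min_sep=14)
        for p in pts:
            if len(p) > 1:
                assert pdist(p).min() >= 14


def test_slide_roundtrip_on_disk(tmp_path, small_slide):
    write_slide(small_slide, tmp_path / "s")
    pyramid, nuclei, label = read_slide(tmp_path / "s")
    assert label == small_slide.true_label
    assert len(nuclei) == len(small_slide.nuclei_points)
    assert (tmp_path / "s" / "lesions.csv").exists()
    np.testing.assert_array_equal(pyramid.levels[0], small_slide.pyramid.levels[0])
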