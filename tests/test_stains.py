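"""Optical-density transform, pixel assignment and area quantification."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import eoquant as eq
from eoquant.stains import DAB_OD, OD_EPSILON


class TestOpticalDensity:
    def test_background_pixel_has_zero_od(self):
        img = np.full((2, 2, 3), 255.0)
        od = eq.to_optical_density(img, (255, 255, 255))
        assert np.allclose(od, 0.0, atol=5e-3)

    def test_tenth_of_background_gives_unit_od(self):
        img = np.full((1, 1, 3), 25.5)
        od = eq.to_optical_density(img, (255, 255, 255))
        assert np.allclose(od, 1.0, atol=0.02)

    def test_od_nonnegative_even_above_background(self):
        img = np.full((1, 1, 3), 300.0)
        od = eq.to_optical_density(img, (255, 255, 255))
        assert np.all(od >= 0)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            eq.to_optical_density(np.zeros((1, 1, 3)), (0, 255, 255))

    def test_pure_dab_pixel_collinear_with_dab_vector(self, stain_model):
        v = stain_model.stain_vectors["ins"]
        img = (255.0 * 10.0 ** (-1.0 * v)).reshape(1, 1, 3)
        od = eq.to_optical_density(img, (255, 255, 255))[0, 0]
        cos = od @ v / np.linalg.norm(od)
        assert cos > 0.999


class TestAssignPixels:
    def test_pure_background_gives_empty_masks(self, stain_model):
        img = np.full((8, 8, 3), 255, dtype=np.uint8)
        od = eq.to_optical_density(img, stain_model.background_intensity)
        masks = eq.assign_pixels(od, stain_model, microns_per_px=0.5)
        for m in masks.masks.values():
            assert not m.any()

    def test_rendered_pure_ins_eo_recovered_within_2pct(self, stain_model):
        spec = eq.SectionSpec(width_px=200, height_px=200, microns_per_px=0.5,
                              tissue_fraction=1.0, rng_seed=3,
                              eo_specs=[eq.EOSpec(center=(100, 100),
                                                  target_area=680.0)])
        img, truth = eq.render_section(spec, stain_model)
        od = eq.to_optical_density(img, stain_model.background_intensity)
        masks = eq.assign_pixels(od, stain_model, microns_per_px=0.5)
        ins_area = masks.masks["ins"].sum() * 0.25
        assert ins_area == pytest.approx(680.0, rel=0.02)
        assert ins_area == truth.loc[0, "ins_area_um2"]

    def test_chromogen_masks_mutually_exclusive(self, rendered_section,
                                                stain_model):
        _, img, _ = rendered_section
        od = eq.to_optical_density(img, stain_model.background_intensity)
        masks = eq.assign_pixels(od, stain_model, microns_per_px=0.5)
        assert not (masks.masks["ins"] & masks.masks["gluc"]).any()

    def test_saturated_dual_stain_pixel_goes_to_stronger_projection(
            self, stain_model):
        # both chromogens present, insulin slightly stronger: the pixel
        # is attributed once, to DAB — the documented under-count of
        # dual-positive pixels
        vi = stain_model.stain_vectors["ins"]
        vg = stain_model.stain_vectors["gluc"]
        od = (1.2 * vi + 1.0 * vg).reshape(1, 1, 3)
        masks = eq.assign_pixels(od, stain_model, microns_per_px=1.0)
        assert masks.masks["ins"][0, 0]
        assert not masks.masks["gluc"][0, 0]

    def test_raising_threshold_never_increases_positive_area(
            self, rendered_section, stain_model):
        _, img, _ = rendered_section
        od = eq.to_optical_density(img, stain_model.background_intensity)
        prev = np.inf
        for thr in (0.05, 0.3, 0.8, 1.2):
            model = eq.StainModel(
                stain_vectors=dict(stain_model.stain_vectors),
                od_threshold={"hematoxylin": 0.05, "ins": thr, "gluc": thr},
            )
            area = eq.assign_pixels(od, model).masks["ins"].sum()
            assert area <= prev
            prev = area

    def test_collinear_stain_vectors_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            eq.StainModel(stain_vectors={"hematoxylin": np.array(DAB_OD),
                                         "ins": np.array(DAB_OD)},
                          od_threshold={"ins": 0.1})


class TestQuantifyAreas:
    @pytest.fixture()
    def simple_masks(self):
        ins = np.zeros((40, 40), dtype=bool)
        ins[10:20, 10:20] = True  # 100 px
        gluc = np.zeros((40, 40), dtype=bool)
        return eq.StainMaskSet(masks={"ins": ins, "gluc": gluc},
                               microns_per_px=1.0)

    def test_annotation_with_no_positive_pixels(self, simple_masks):
        ring = [(25, 25), (35, 25), (35, 35), (25, 35)]
        (rec,) = eq.quantify_areas(simple_masks, [ring])
        assert rec["ins_area_um2"] == 0.0
        assert rec["gluc_area_um2"] == 0.0
        assert rec["total_area_um2"] == 100.0

    def test_annotation_covering_block_exactly(self, simple_masks):
        ring = [(10, 10), (20, 10), (20, 20), (10, 20)]
        (rec,) = eq.quantify_areas(simple_masks, [ring])
        assert rec["ins_area_um2"] == 100.0

    def test_disjoint_annotations_are_additive(self, simple_masks):
        left = [(10, 10), (15, 10), (15, 20), (10, 20)]
        right = [(15, 10), (20, 10), (20, 20), (15, 20)]
        whole = [(10, 10), (20, 10), (20, 20), (10, 20)]
        part = eq.quantify_areas(simple_masks, [left, right])
        (full,) = eq.quantify_areas(simple_masks, [whole])
        assert (part[0]["ins_area_um2"] + part[1]["ins_area_um2"]
                == full["ins_area_um2"])

    def test_empty_polygon_flagged(self, simple_masks):
        (rec,) = eq.quantify_areas(
            simple_masks, [Polygon([(0, 0), (0, 0), (0, 0)])])
        assert rec["empty"]
        assert rec["total_area_um2"] == 0.0

    def test_doubling_mpp_quadruples_areas(self):
        ins = np.zeros((20, 20), dtype=bool)
        ins[5:10, 5:10] = True
        ring = [(0, 0), (20, 0), (20, 20), (0, 20)]
        areas = {}
        for mpp in (1.0, 2.0):
            masks = eq.StainMaskSet(masks={"ins": ins.copy()},
                                    microns_per_px=mpp)
            (rec,) = eq.quantify_areas(masks, [ring])
            areas[mpp] = rec["ins_area_um2"]
        assert areas[2.0] == 4.0 * areas[1.0]
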