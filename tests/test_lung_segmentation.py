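"""Unit and property tests for the four-stage lung segmentation."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import circle_perimeter

from elvarkit import (
    CTVolume,
    DiseaseSpec,
    PhantomSpec,
    SegmentationParams,
    VesselTreeSpec,
    coarse_segment,
    detect_contours,
    eliminate_holes,
    fill_contours,
    generate_phantom,
    segment_lungs,
    shrink_contour,
)
from elvarkit.image_io import BinaryMask
from elvarkit.lung_segmentation import ContourField

from conftest import dice


def slice_mask(arr2d: np.ndarray) -> BinaryMask:
    return BinaryMask(arr2d[None, :, :], "test-grid", "coarse_air", (1.0, 1.0, 1.0))


def brute_force_zero_crossings(laplacian2d: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit per-pixel in-plane neighbour sign scan."""
    h, w = laplacian2d.shape
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    if laplacian2d[r, c] * laplacian2d[rr, cc] < 0:
                        out[r, c] = True
    return out


class TestCoarseSegment:
    def test_phantom_air_region_dice(self):
        # no vessels/disease: the coarse air mask should trace the lung cavity
        vol, truth = generate_phantom(
            PhantomSpec(seed=2, vessel_tree=VesselTreeSpec(n_branches=0))
        )
        mask = coarse_segment(vol, SegmentationParams())
        assert dice(mask.data, truth.lung_mask_true.data) >= 0.98

    def test_uniform_soft_tissue_is_empty(self):
        vol = CTVolume(data=np.full((5, 20, 20), 50.0, np.float32), spacing=(1, 1, 1))
        with pytest.warns(UserWarning):
            mask = coarse_segment(vol, SegmentationParams(min_lung_component_mm3=1))
        assert mask.popcount() == 0

    def test_border_connected_air_excluded(self, healthy_phantom, healthy_seg):
        vol, _ = healthy_phantom
        coarse = healthy_seg.stages["coarse_air"]
        border = np.zeros(vol.shape, bool)
        for axis in range(3):
            border[tuple(slice(None) if a != axis else 0 for a in range(3))] = True
            border[tuple(slice(None) if a != axis else -1 for a in range(3))] = True
        # the exterior -1000 HU air touches every border; none of it survives
        assert not (coarse.data & border).any()


class TestDetectContours:
    def test_matches_brute_force_oracle_on_disk(self):
        sl = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 20)
        sl[rr, cc] = True
        cf = detect_contours(slice_mask(sl), SegmentationParams(), (1, 1, 1))
        oracle = brute_force_zero_crossings(cf.laplacian[0])
        assert np.array_equal(cf.zero_crossings.data[0], oracle)
        # the ring is closed: filling it yields a disk-sized region
        filled = ndimage.binary_fill_holes(cf.outer_boundary.data[0])
        assert filled.sum() > sl.sum()

    def test_boundary_sets_partition_zero_crossings(self):
        sl = np.zeros((64, 64), bool)
        rr, cc = draw_disk((30, 28), 17)
        sl[rr, cc] = True
        cf = detect_contours(slice_mask(sl), SegmentationParams(), (1, 1, 1))
        assert not (cf.inner_boundary.data & cf.outer_boundary.data).any()
        assert np.array_equal(
            cf.inner_boundary.data | cf.outer_boundary.data, cf.zero_crossings.data
        )

    def test_all_true_slice_has_no_interior_crossings(self):
        cf = detect_contours(
            slice_mask(np.ones((32, 32), bool)), SegmentationParams(), (1, 1, 1)
        )
        assert cf.zero_crossings.popcount() == 0

    def test_two_disks_give_two_rings(self):
        sl = np.zeros((64, 64), bool)
        for center in ((18, 18), (46, 46)):
            rr, cc = draw_disk(center, 10)
            sl[rr, cc] = True
        cf = detect_contours(slice_mask(sl), SegmentationParams(), (1, 1, 1))
        _, n = ndimage.label(cf.outer_boundary.data[0], structure=np.ones((3, 3)))
        assert n == 2


class TestFillContours:
    def _cf_from_outer(self, outer2d: np.ndarray) -> ContourField:
        m = slice_mask(outer2d)
        empty = slice_mask(np.zeros_like(outer2d))
        return ContourField(
            smoothed=np.zeros(m.shape),
            laplacian=np.zeros(m.shape),
            zero_crossings=m,
            inner_boundary=empty,
            outer_boundary=m,
        )

    def test_closed_ring_fills_to_disk(self):
        outer = np.zeros((64, 64), bool)
        rr, cc = circle_perimeter(32, 32, 20)
        outer[rr, cc] = True
        filled = fill_contours(self._cf_from_outer(outer), SegmentationParams())
        # the filled set includes the one-pixel ring, whose outer envelope
        # lies at r + 0.5; compare against that discrete disk count
        yy, xx = np.mgrid[:64, :64]
        disk_count = int(((yy - 32) ** 2 + (xx - 32) ** 2 <= 20.5**2).sum())
        assert abs(filled.popcount() - disk_count) / disk_count <= 0.03

    def test_empty_contour_field_fills_nothing(self):
        filled = fill_contours(
            self._cf_from_outer(np.zeros((32, 32), bool)), SegmentationParams()
        )
        assert filled.popcount() == 0

    def test_open_contour_not_filled(self):
        outer = np.zeros((64, 64), bool)
        rr, cc = circle_perimeter(32, 32, 20)
        keep = cc < 40  # cut away one side: a C shape
        outer[rr[keep], cc[keep]] = True
        filled = fill_contours(self._cf_from_outer(outer), SegmentationParams())
        assert filled.popcount() == outer.sum()


class TestEliminateHoles:
    def test_organ_indentation_removed(self, indented_phantom, indented_seg):
        _, truth = indented_phantom
        quasi = indented_seg.stages["pre_shrink"]
        hole = indented_seg.stages["hole"]
        # the enclosed part of the organ bulge lands in the hole mask (at
        # basal slices the contour already routes around the bulge, so the
        # hole mask need not cover all of it) ...
        overlap = hole.data & truth.indentation_mask.data
        assert overlap.sum() >= 0.5 * truth.indentation_mask.popcount()
        # ... but no organ voxel may survive into the final lung
        assert not (indented_seg.lung_mask.data & truth.indentation_mask.data).any()
        assert not (quasi.data & hole.data).any()
        assert dice(indented_seg.lung_mask.data, truth.lung_mask_true.data) >= 0.95

    def test_vessels_not_treated_as_holes(self, healthy_phantom, healthy_seg):
        # vessels are enclosed by lung air: they stay inside the lung mask
        _, truth = healthy_phantom
        hole = healthy_seg.stages["hole"]
        assert not (hole.data & truth.vessel_mask_true.data).any()
        in_lung = truth.vessel_mask_true.data & healthy_seg.lung_mask.data
        assert in_lung.sum() >= 0.9 * truth.vessel_mask_true.popcount()

    def test_no_candidates_no_hole(self):
        m = np.zeros((2, 16, 16), bool)
        m[:, 4:12, 4:12] = True
        filled = BinaryMask(m, "g", "filled_contour")
        coarse = BinaryMask(m.copy(), "g", "coarse_air")
        quasi, hole = eliminate_holes(filled, coarse, SegmentationParams(), (1, 1, 1))
        assert hole.popcount() == 0
        assert np.array_equal(quasi.data, filled.data)


class TestShrinkContour:
    def _disk_setup(self, dilate=0):
        sl = np.zeros((64, 64), bool)
        rr, cc = draw_disk((32, 32), 20)
        sl[rr, cc] = True
        cf = detect_contours(slice_mask(sl), SegmentationParams(), (1, 1, 1))
        target = np.array(
            [ndimage.binary_fill_holes(cf.inner_boundary.data[0])]
        )
        quasi = target.copy()
        if dilate:
            quasi = ndimage.binary_dilation(quasi, iterations=dilate)
            quasi[0] = ndimage.binary_dilation(target[0], iterations=dilate)
        return cf, BinaryMask(quasi, "test-grid", "filled_contour"), target

    def test_fixed_point_when_already_on_ring(self):
        cf, quasi, _ = self._disk_setup(dilate=0)
        out = shrink_contour(quasi, cf, SegmentationParams())
        assert out.converged
        assert np.array_equal(out.mask.data, quasi.data)

    def test_dilated_disk_converges_to_ring_bounded_disk(self):
        cf, quasi, target = self._disk_setup(dilate=3)
        p = SegmentationParams()
        out = shrink_contour(quasi, cf, p)
        assert out.converged and out.iterations <= 4 + 1
        symdiff = np.logical_xor(out.mask.data, target).sum()
        assert symdiff <= p.shrink_tolerance_voxels

    def test_empty_stopping_set_is_flagged(self):
        _, quasi, _ = self._disk_setup()
        empty = slice_mask(np.zeros((64, 64), bool))
        cf = ContourField(
            smoothed=np.zeros(quasi.shape),
            laplacian=np.zeros(quasi.shape),
            zero_crossings=empty,
            inner_boundary=empty,
            outer_boundary=empty,
        )
        out = shrink_contour(quasi, cf, SegmentationParams())
        assert out.empty_stopping_set
        assert np.array_equal(out.mask.data, quasi.data)

    def test_popcount_monotone_nonincreasing(self):
        cf, quasi, _ = self._disk_setup(dilate=4)
        p = SegmentationParams()
        counts = [quasi.popcount()]
        mask = quasi
        for _ in range(6):
            out = shrink_contour(mask, cf, SegmentationParams(shrink_max_iters=1))
            counts.append(out.mask.popcount())
            mask = out.mask
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestFullPipeline:
    def test_healthy_phantom_dice(self, healthy_phantom, healthy_seg):
        _, truth = healthy_phantom
        assert dice(healthy_seg.lung_mask.data, truth.lung_mask_true.data) >= 0.95
        assert healthy_seg.L == healthy_seg.lung_mask.popcount()

    def test_dense_disease_not_carved_out(self):
        vol, truth = generate_phantom(
            PhantomSpec(
                seed=4,
                disease=DiseaseSpec(
                    target_fraction=0.25,
                    pattern_mix={"consolidation": 0.7, "septal_sheet": 0.2, "ggo": 0.1},
                ),
            )
        )
        seg = segment_lungs(vol)
        assert dice(seg.lung_mask.data, truth.lung_mask_true.data) >= 0.90
        # most of the consolidation volume must remain inside the lung mask
        cons = truth.disease_mask_true.data
        assert (cons & seg.lung_mask.data).sum() >= 0.8 * cons.sum()

    def test_containment_chain(self, diseased_seg):
        lung = diseased_seg.lung_mask.data
        filled = diseased_seg.stages["contour_filled"].data
        hole = diseased_seg.stages["hole"].data
        assert not (lung & ~(filled & ~hole)).any()

    def test_determinism(self, diseased_phantom, diseased_seg):
        vol, _ = diseased_phantom
        again = segment_lungs(vol)
        assert again.L == diseased_seg.L
        assert np.array_equal(again.lung_mask.data, diseased_seg.lung_mask.data)

    def test_L_invariant_under_inplane_rotation(self, healthy_phantom, healthy_seg):
        vol, _ = healthy_phantom
        rotated = CTVolume(
            data=np.ascontiguousarray(np.rot90(vol.data, k=1, axes=(1, 2))),
            spacing=vol.spacing,
        )
        seg_rot = segment_lungs(rotated)
        assert seg_rot.L == healthy_seg.L
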