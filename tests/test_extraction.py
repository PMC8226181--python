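"""Segmentation, component selection, skeletonization, electrode frame."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from dbsdeform import (
    AmbiguousOriginError,
    ComponentNotFoundError,
    DegenerateElectrodeError,
    ElectrodeMask,
    EmptySegmentationError,
    SkeletonPolyline,
    VoxelVolume,
    make_ground_truth_curve,
    rasterize_case,
    select_electrode_components,
    skeletonize,
    threshold_segment,
    to_electrode_frame,
)
from dbsdeform.synthetic import LABEL

from conftest import cumulative_chord


class TestThresholdSegment:
    def test_mask_contains_every_truth_electrode_voxel(self, bent_case):
        mask = threshold_segment(bent_case.volume, 2000.0)
        truth = bent_case.class_labels == LABEL["electrode"]
        assert np.all(mask.mask[truth])

    def test_idempotent(self, straight_case):
        m1 = threshold_segment(straight_case.volume, 2000.0)
        m2 = threshold_segment(straight_case.volume, 2000.0)
        assert np.array_equal(m1.mask, m2.mask)

    def test_threshold_above_max_raises(self, straight_case):
        with pytest.raises(EmptySegmentationError):
            threshold_segment(straight_case.volume, 1e9)

    def test_threshold_at_min_selects_full_grid(self, straight_case):
        data = np.asarray(straight_case.volume.data)
        mask = threshold_segment(straight_case.volume, float(data.min()))
        assert mask.mask.all()


class TestComponentSelection:
    def test_two_electrodes_selected_bone_rejected(self, two_electrode_case):
        # threshold below bone intensity so the skull shell enters the mask
        mask = threshold_segment(two_electrode_case.volume, 1000.0)
        comps = select_electrode_components(mask, n_electrodes=2)
        assert len(comps) == 2
        bone = two_electrode_case.class_labels == LABEL["bone"]
        for comp in comps:
            assert not np.any(comp.mask & bone)

    def test_small_artifact_blobs_do_not_change_selection(self):
        curve = make_ground_truth_curve("non_directional", "left", (0.4, 0.2, 0), 70.0, seed=6)
        clean = rasterize_case(curve, seed=6, artifact_level=0)
        noisy = rasterize_case(curve, seed=6, artifact_level=4)
        sel_clean = select_electrode_components(threshold_segment(clean.volume), n_electrodes=1)
        sel_noisy = select_electrode_components(threshold_segment(noisy.volume), n_electrodes=1)
        assert np.array_equal(sel_clean[0].mask, sel_noisy[0].mask)

    def test_requesting_more_electrodes_than_present_raises(self, two_electrode_case):
        mask = threshold_segment(two_electrode_case.volume, 2000.0)
        with pytest.raises(ComponentNotFoundError) as exc:
            select_electrode_components(mask, n_electrodes=3)
        assert exc.value.diagnostics  # diagnostics listed for the caller


class TestSkeletonize:
    def test_straight_cylinder_centerline_near_true_axis(self, straight_case):
        mask = select_electrode_components(
            threshold_segment(straight_case.volume), n_electrodes=1
        )[0]
        skel = skeletonize(mask)
        entry = straight_case.entry_point["left"]
        # true axis: entry + s * (0,0,-1) in scanner frame (left lead runs inferior)
        radial = np.linalg.norm(skel.points[:, :2] - entry[:2], axis=1)
        assert radial.max() < 0.25

    def test_helical_tube_rms_within_half_voxel(self):
        # analytic helix, radius 3 mm, pitch 40 mm, rasterized by hand
        a, pitch, turns = 3.0, 40.0, 1.5
        theta = np.linspace(0, 2 * np.pi * turns, 4001)
        pts = np.stack([a * np.cos(theta), a * np.sin(theta),
                        pitch * theta / (2 * np.pi)], axis=1)
        voxel = 0.5
        lo = pts.min(axis=0) - 3.0
        shape = np.ceil((pts.max(axis=0) - lo + 6.0) / voxel).astype(int)
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        centers = np.stack([g.ravel() for g in grids], axis=1) * voxel + lo
        d, _ = cKDTree(pts).query(centers)
        data = np.where(d <= 0.635, 3000.0, 40.0).reshape(tuple(shape)).astype(np.float32)
        affine = np.eye(4)
        affine[:3, :3] = np.diag([voxel] * 3)
        affine[:3, 3] = lo
        vol = VoxelVolume(data=data, affine=affine)
        mask = threshold_segment(vol, 2000.0)
        skel = skeletonize(ElectrodeMask(mask.mask, affine, weights=data))
        dist, _ = cKDTree(pts).query(skel.points)
        rms = np.sqrt(np.mean(dist**2))
        assert rms <= 0.5 * voxel

    def test_tiny_blob_raises_degenerate(self):
        data = np.full((8, 8, 8), 40.0, dtype=np.float32)
        data[3:5, 4, 4] = 3000.0
        vol = VoxelVolume(data=data, affine=np.eye(4))
        mask = threshold_segment(vol, 2000.0)
        with pytest.raises(DegenerateElectrodeError):
            skeletonize(mask)


class TestElectrodeFrame:
    def _polyline(self):
        z = np.linspace(0, 70, 80)
        pts = np.stack([10 + 0.01 * z, -5 + np.zeros_like(z), 40 - z], axis=1)
        return SkeletonPolyline(points=pts, cumulative_arc=cumulative_chord(pts))

    def test_identity_case_first_point_origin(self):
        skel = self._polyline()
        out = to_electrode_frame(skel, skel.points[0], "left")
        np.testing.assert_allclose(out.points[0], 0.0, atol=1e-12)
        assert out.frame == "electrode"
        # left map: x -> -x, y -> y, z -> -z of the translated points
        shifted = skel.points - skel.points[0]
        np.testing.assert_allclose(out.points, shifted * [-1, 1, -1], atol=1e-12)

    def test_right_vs_left_negates_x_only(self):
        skel = self._polyline()
        left = to_electrode_frame(skel, skel.points[0], "left")
        right = to_electrode_frame(skel, skel.points[0], "right")
        np.testing.assert_allclose(left.points[:, 0], -right.points[:, 0], atol=1e-12)
        np.testing.assert_allclose(left.points[:, 1:], right.points[:, 1:], atol=1e-12)

    def test_distal_first_input_is_reversed(self):
        skel = self._polyline()
        reversed_pts = skel.points[::-1]
        rev = SkeletonPolyline(points=reversed_pts, cumulative_arc=cumulative_chord(reversed_pts))
        out = to_electrode_frame(rev, skel.points[0], "left")
        ref = to_electrode_frame(skel, skel.points[0], "left")
        np.testing.assert_allclose(out.points, ref.points, atol=1e-12)
        assert np.all(np.diff(out.cumulative_arc) > 0)

    def test_mirror_property_through_full_frame_chain(self):
        """A mirrored scanner skeleton processed as the other hemisphere
        yields the identical electrode-frame polyline."""
        skel = self._polyline()
        mirrored_pts = skel.points * [-1, 1, 1]
        mirrored = SkeletonPolyline(
            points=mirrored_pts, cumulative_arc=cumulative_chord(mirrored_pts)
        )
        left = to_electrode_frame(skel, skel.points[0], "left")
        right = to_electrode_frame(mirrored, mirrored.points[0], "right")
        np.testing.assert_allclose(left.points, right.points, atol=1e-12)

    def test_far_proximal_point_raises(self):
        skel = self._polyline()
        with pytest.raises(AmbiguousOriginError):
            to_electrode_frame(skel, skel.points[0] + [0, 20.0, 30.0], "left")
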