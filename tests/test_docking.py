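"""ROI docking, leave-one-out accuracy, NIRB coarse alignment, and the
translation of predicted depths into section indices."""

import numpy as np
import pytest

from clemdock.docking import (
    RegionOfInterest,
    coarse_align_nirb,
    depth_to_sections,
    dock_roi,
)
from clemdock.errors import CoverageError, PairingError
from clemdock.geometry import FeatureClass, Point3
from clemdock.registration import (
    fit_rigid,
    fit_tps,
    loo_docking_error,
)
from clemdock.sectioning import alternating_series_scheme, uniform_scheme

from conftest import make_pairing, make_set, random_cloud, rotation_about_z


class TestLooDockingError:
    def test_exact_rigid_correspondence_gives_zero(self, geometry):
        rng = np.random.default_rng(30)
        src = random_cloud(rng, 8)
        tgt = src @ rotation_about_z(25.0).T + np.array([5.0, 5.0, 5.0])
        loo = loo_docking_error(make_pairing(src, tgt, geometry), "rigid")
        assert loo.errors.max() < 1e-9

    def test_affine_correspondence_reproduced_by_held_out_tps(self, geometry):
        rng = np.random.default_rng(31)
        src = random_cloud(rng, 10)
        tgt = src @ np.diag([0.95, 0.92, 0.9]) + 4.0
        loo = loo_docking_error(make_pairing(src, tgt, geometry), "tps")
        assert loo.errors.max() < 1e-6

    def test_too_few_pairs_is_an_error(self, geometry):
        rng = np.random.default_rng(32)
        src = random_cloud(rng, 5)
        with pytest.raises(PairingError):
            loo_docking_error(make_pairing(src, src, geometry), "tps")

    def test_errors_in_pairing_order_with_median_and_max(self, geometry):
        rng = np.random.default_rng(33)
        src = random_cloud(rng, 8)
        tgt = src + rng.normal(scale=3.0, size=src.shape)
        loo = loo_docking_error(make_pairing(src, tgt, geometry), "rigid")
        assert len(loo) == 8
        assert loo.median == pytest.approx(np.median(loo.errors))
        assert loo.max == pytest.approx(loo.errors.max())


class TestDockRoi:
    def test_control_point_roi_lands_on_paired_target(self, geometry):
        rng = np.random.default_rng(34)
        src = random_cloud(rng, 8)
        tgt = src + rng.normal(scale=5.0, size=src.shape)
        pairing = make_pairing(src, tgt, geometry)
        t = fit_tps(pairing, 0.0)
        roi = RegionOfInterest("cell", [Point3.from_array(src[2])])
        result = dock_roi(t, roi, pairing)
        assert np.allclose(
            result.predicted_points[0].as_array(), tgt[2], atol=1e-6
        )
        assert result.predicted_z_range[0] == pytest.approx(tgt[2][2], abs=1e-6)

    def test_pure_translation_docks_by_translation(self, geometry):
        rng = np.random.default_rng(35)
        src = random_cloud(rng, 7)
        shift = np.array([12.0, -7.0, 3.0])
        pairing = make_pairing(src, src + shift, geometry)
        t = fit_rigid(pairing)
        roi_pt = np.array([200.0, 200.0, 75.0])
        result = dock_roi(t, RegionOfInterest("roi", [Point3.from_array(roi_pt)]), pairing)
        assert np.allclose(result.predicted_points[0].as_array(), roi_pt + shift, atol=1e-9)
        assert result.accuracy_estimate < 1e-9
        assert result.within_claimed_accuracy

    def test_far_roi_sets_extrapolation_flag(self, geometry):
        rng = np.random.default_rng(36)
        src = rng.uniform(100, 200, (8, 3))
        pairing = make_pairing(src, src, geometry)
        t = fit_tps(pairing, 0.0)
        inside = dock_roi(t, RegionOfInterest("in", [Point3(150, 150, 150)]), pairing)
        far = dock_roi(t, RegionOfInterest("out", [Point3(490, 490, 10)]), pairing)
        assert not inside.extrapolation_warning
        assert far.extrapolation_warning

    def test_prediction_error_consistent_with_loo_estimate(self, default_scenarios):
        """Simulation self-consistency: the true docking error of the cell
        centroid stays within 3× the median LOO estimate in ≥ 90% of
        seeds."""
        hits = 0
        for scenario in default_scenarios.values():
            pairing = scenario.pairing
            t = fit_tps(pairing, 0.0)
            roi = RegionOfInterest(
                "cell", [Point3.from_array(scenario.roi_true_source)]
            )
            result = dock_roi(t, roi, pairing)
            err = np.linalg.norm(
                result.predicted_points[0].as_array() - scenario.roi_true_target
            )
            if err <= 3.0 * max(result.accuracy_estimate, 1e-9):
                hits += 1
        assert hits >= 18  # ≥ 90% of 20 seeds


class TestCoarseAlignNirb:
    def _frame(self, geometry, corners, jitter_z=0.0, prefix="N"):
        pts = np.array(corners, dtype=float)
        pts = np.column_stack([pts, np.full(len(pts), jitter_z)])
        return make_set(pts, geometry, [f"{prefix}{i}" for i in range(len(pts))],
                        feature_class=FeatureClass.NIRB_MARK)

    def test_identical_frames_give_identity(self, geometry):
        frame = self._frame(geometry, [[50, 50], [350, 50], [350, 350], [50, 350]])
        aligned = coarse_align_nirb(frame, frame)
        assert np.allclose(aligned.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(aligned.transform.translation, 0.0, atol=1e-9)

    def test_in_plane_rotation_and_shift_recovered(self, geometry):
        corners = np.array([[50, 50], [350, 50], [350, 350], [50, 350]], dtype=float)
        src = self._frame(geometry, corners)
        rot2 = rotation_about_z(15.0)[:2, :2]
        shifted = corners @ rot2.T + np.array([30.0, -10.0])
        tgt = self._frame(geometry, shifted)
        aligned = coarse_align_nirb(src, tgt)
        assert np.allclose(aligned.transform.rotation[:2, :2], rot2, atol=1e-6)
        assert np.allclose(aligned.transform.translation[:2], [30.0, -10.0], atol=1e-6)
        assert aligned.rms_xy < 1e-6

    def test_z_offset_reported_never_corrected(self, geometry):
        """NIRB marks are depth-blind: an 8 µm z offset between frames is
        reported but the fitted z translation stays 0."""
        corners = [[50, 50], [350, 50], [350, 350], [50, 350]]
        src = self._frame(geometry, corners, jitter_z=0.0)
        tgt = self._frame(geometry, corners, jitter_z=8.0)
        aligned = coarse_align_nirb(src, tgt)
        assert aligned.transform.translation[2] == 0.0
        assert aligned.residual_z_offset == pytest.approx(8.0)
        moved = aligned.apply(src.positions())
        assert np.allclose(moved[:, 2], src.positions()[:, 2])

    def test_fewer_than_two_marks_is_an_error(self, geometry):
        one = self._frame(geometry, [[50, 50]])
        with pytest.raises(PairingError):
            coarse_align_nirb(one, one)


def _docking_stub(z_lo, z_hi, accuracy=0.0):
    pts = [Point3(0.0, 0.0, z_lo), Point3(0.0, 1.0, z_hi)]
    if z_lo == z_hi:
        pts = [Point3(0.0, 0.0, z_lo)]
    from clemdock.docking import DockingResult

    return DockingResult(
        label="stub",
        predicted_points=pts,
        predicted_z_range=(z_lo, z_hi),
        accuracy_estimate=accuracy,
        within_claimed_accuracy=True,
        transform_kind="tps",
    )


class TestDepthToSections:
    def test_boundary_depth_goes_to_deeper_section(self):
        scheme = uniform_scheme(100, 500.0)
        window = depth_to_sections(_docking_stub(10.0, 10.0), scheme)
        assert (window.first_index, window.last_index) == (21, 21)
        assert scheme.depth_of(21) == (pytest.approx(10.0), pytest.approx(10.5))

    def test_deep_window_section_count(self):
        scheme = uniform_scheme(200, 300.0)
        window = depth_to_sections(_docking_stub(73.0, 123.0), scheme,
                                   approach_offset=73.0)
        assert window.first_index == 1
        assert window.n_sections == 167

    def test_margin_growth_never_shrinks_the_range(self):
        scheme = uniform_scheme(400, 300.0)
        counts = [
            depth_to_sections(_docking_stub(40.0, 60.0, accuracy=a), scheme).n_sections
            for a in [0.0, 2.0, 5.0, 10.0, 20.0]
        ]
        assert counts == sorted(counts)

    def test_too_shallow_scheme_reports_missing_depth(self):
        scheme = uniform_scheme(10, 500.0)  # 5 µm total
        with pytest.raises(CoverageError, match="missing"):
            depth_to_sections(_docking_stub(40.0, 60.0), scheme)

    def test_alternating_scheme_window(self):
        scheme = alternating_series_scheme(180)
        window = depth_to_sections(_docking_stub(90.01, 90.05), scheme)
        assert window.first_index == 181  # first thin section after approach
        assert window.last_index == 181
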