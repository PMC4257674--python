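"""Landmark-candidate detection: skeletons, bifurcations, fiber crossings,
and cross-modality pair suggestion."""

import numpy as np
import pytest

from clemdock.errors import ValidationError
from clemdock.features import (
    FiberSet,
    VesselSkeleton,
    detect_bifurcations,
    detect_fiber_crossings,
    skeletonize_mask,
    suggest_pairs,
)
from clemdock.geometry import FeatureClass, VolumeGeometry
from clemdock.registration import RigidTransform

from conftest import make_set


def paint_capsule(stack, p0, p1, radius, spacing=1.0):
    """Voxelize a capsule into a (z, y, x) stack at isotropic spacing."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    nz, ny, nx = stack.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * spacing, np.arange(ny) * spacing, np.arange(nx) * spacing,
        indexing="ij",
    )
    pts = np.stack([xx, yy, zz], axis=-1)
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / (d @ d), 0.0, 1.0)
    nearest = p0 + t[..., None] * d
    stack[np.linalg.norm(pts - nearest, axis=-1) <= radius] = 1


class TestSkeletonize:
    def test_straight_cylinder_yields_a_path(self):
        geo = VolumeGeometry((1.0, 1.0, 1.0), (60, 40, 40))
        stack = np.zeros((40, 40, 60), dtype=np.uint8)
        paint_capsule(stack, (5, 20, 20), (55, 20, 20), 3.5)
        skeleton = skeletonize_mask(stack, geo)
        assert (skeleton.degrees() >= 3).sum() == 0
        assert not skeleton.has_cycles
        assert len(detect_bifurcations(skeleton)) == 0

    def test_y_junction_branch_point_localised(self):
        geo = VolumeGeometry((1.0, 1.0, 1.0), (60, 60, 60))
        stack = np.zeros((60, 60, 60), dtype=np.uint8)
        paint_capsule(stack, (5, 30, 30), (30, 30, 30), 3.5)
        paint_capsule(stack, (30, 30, 30), (50, 45, 35), 3.0)
        paint_capsule(stack, (30, 30, 30), (50, 15, 25), 3.0)
        landmarks = detect_bifurcations(skeletonize_mask(stack, geo))
        assert len(landmarks) == 1
        lm = landmarks.landmarks[0]
        assert lm.feature_class is FeatureClass.VESSEL_BIFURCATION
        assert np.linalg.norm(lm.position.as_array() - [30, 30, 30]) <= 2.0

    def test_empty_mask_is_an_error(self):
        geo = VolumeGeometry((1.0, 1.0, 1.0), (10, 10, 10))
        with pytest.raises(ValidationError, match="empty"):
            skeletonize_mask(np.zeros((10, 10, 10), dtype=np.uint8), geo)

    def test_anisotropic_spacing_scales_node_coordinates(self):
        geo = VolumeGeometry((0.5, 0.5, 2.0), (40, 40, 20))
        stack = np.zeros((20, 40, 40), dtype=np.uint8)
        stack[10, 20, 5:35] = 1  # a 1-voxel line along x
        skeleton = skeletonize_mask(stack, geo)
        assert skeleton.nodes[:, 2].max() == pytest.approx(20.0)  # 10 × 2 µm
        assert skeleton.nodes[:, 1].max() == pytest.approx(10.0)  # 20 × 0.5 µm


class TestBifurcationMerging:
    def test_hand_built_path_graph_has_no_bifurcations(self):
        nodes = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0]], dtype=float)
        skeleton = VesselSkeleton(nodes, [(0, 1), (1, 2)])
        assert len(detect_bifurcations(skeleton, refine=False)) == 0

    def test_single_degree_three_node_detected(self):
        nodes = np.array(
            [[0, 0, 0], [10, 0, 0], [20, 5, 0], [20, -5, 0]], dtype=float
        )
        skeleton = VesselSkeleton(nodes, [(0, 1), (1, 2), (1, 3)])
        landmarks = detect_bifurcations(skeleton, refine=False)
        assert len(landmarks) == 1
        assert np.allclose(landmarks.positions()[0], [10, 0, 0])

    def test_close_junction_nodes_merge_to_midpoint(self):
        nodes = np.array(
            [
                [0, 0, 0], [10, 0, 0], [11, 0, 0], [21, 0, 0],
                [10, 5, 0], [10, -5, 0], [11, 5, 1], [11, -5, 1],
            ],
            dtype=float,
        )
        edges = [(0, 1), (1, 2), (2, 3), (1, 4), (1, 5), (2, 6), (2, 7)]
        skeleton = VesselSkeleton(nodes, edges)
        landmarks = detect_bifurcations(skeleton, merge_radius=3.0, refine=False)
        assert len(landmarks) == 1
        assert np.allclose(landmarks.positions()[0], [10.5, 0, 0])


def brute_force_crossings(polylines, gate):
    """Naive all-segment-pairs scan, kept deliberately independent of the
    implementation."""
    def seg_dist(p0, p1, q0, q1):
        best = np.inf
        for s in np.linspace(0, 1, 41):
            a = p0 + s * (p1 - p0)
            for t in np.linspace(0, 1, 41):
                b = q0 + t * (q1 - q0)
                best = min(best, float(np.linalg.norm(a - b)))
        return best

    count = 0
    for i in range(len(polylines)):
        for j in range(i + 1, len(polylines)):
            dmin = np.inf
            for a in range(len(polylines[i]) - 1):
                for b in range(len(polylines[j]) - 1):
                    dmin = min(
                        dmin,
                        seg_dist(
                            polylines[i][a], polylines[i][a + 1],
                            polylines[j][b], polylines[j][b + 1],
                        ),
                    )
            if dmin < gate:
                count += 1
    return count


class TestFiberCrossings:
    def test_orthogonal_segments_cross_once(self):
        fibers = FiberSet([
            np.array([[0.0, 10.0, 10.0], [20.0, 10.0, 10.0]]),
            np.array([[10.0, 0.0, 10.0], [10.0, 20.0, 10.0]]),
        ])
        landmarks = detect_fiber_crossings(fibers, gate=2.0)
        assert len(landmarks) == 1
        assert np.allclose(landmarks.positions()[0], [10.0, 10.0, 10.0])

    def test_distant_parallel_lines_do_not_cross(self):
        fibers = FiberSet([
            np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]),
            np.array([[0.0, 10.0, 0.0], [50.0, 10.0, 0.0]]),
        ])
        assert len(detect_fiber_crossings(fibers, gate=2.0)) == 0

    def test_count_matches_brute_force_oracle(self):
        rng = np.random.default_rng(40)
        polylines = []
        for _ in range(20):
            start = rng.uniform(0, 120, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            steps = rng.integers(3, 6)
            pts = [start]
            for _ in range(steps):
                d = d + rng.normal(scale=0.3, size=3)
                d /= np.linalg.norm(d)
                pts.append(pts[-1] + 25.0 * d)
            polylines.append(np.array(pts))
        gate = 2.0
        # disable merging so each crossing fiber pair stays one landmark
        detected = detect_fiber_crossings(FiberSet(polylines), gate=gate, merge_radius=0.0)
        assert len(detected) == brute_force_crossings(polylines, gate)


class TestSuggestPairs:
    def test_identical_sets_self_pair_under_identity(self, geometry):
        rng = np.random.default_rng(41)
        pts = rng.uniform(50, 350, (10, 3))
        lms = make_set(pts, geometry, feature_class=FeatureClass.FIBER_CROSSING)
        proposal = suggest_pairs(lms, lms, RigidTransform.identity(), gate=2.0)
        assert proposal.requires_review
        assert proposal.pairs == [(i, i) for i in lms.ids()]

    def test_known_translation_recovers_full_pairing(self, geometry):
        rng = np.random.default_rng(42)
        pts = rng.uniform(50, 350, (12, 3))
        shift = np.array([5.0, 0.0, 0.0])
        src = make_set(pts, geometry, [f"s{i}" for i in range(12)],
                       feature_class=FeatureClass.VESSEL_BIFURCATION)
        tgt = make_set(pts + shift, geometry, [f"t{i}" for i in range(12)],
                       feature_class=FeatureClass.VESSEL_BIFURCATION)
        coarse = RigidTransform(np.eye(3), shift)
        proposal = suggest_pairs(src, tgt, coarse, gate=2.0)
        assert len(proposal) == 12
        assert all(s[1:] == t[1:] for s, t in proposal.pairs)

    def test_mismatched_feature_classes_not_paired(self, geometry):
        src = make_set([[100, 100, 50]], geometry, ["a"],
                       feature_class=FeatureClass.VESSEL_BIFURCATION)
        tgt = make_set([[100, 100, 50]], geometry, ["b"],
                       feature_class=FeatureClass.FIBER_CROSSING)
        proposal = suggest_pairs(src, tgt, RigidTransform.identity(), gate=5.0)
        assert len(proposal) == 0

    def test_symmetric_under_swap_and_inverse(self, geometry):
        rng = np.random.default_rng(43)
        pts = rng.uniform(50, 350, (15, 3))
        coarse = RigidTransform(np.eye(3), np.array([4.0, -3.0, 2.0]))
        src = make_set(pts, geometry, [f"s{i}" for i in range(15)])
        tgt = make_set(coarse.apply(pts) + rng.normal(scale=1.0, size=pts.shape),
                       geometry, [f"t{i}" for i in range(15)])
        forward = suggest_pairs(src, tgt, coarse, gate=6.0)
        backward = suggest_pairs(tgt, src, coarse.inverse(), gate=6.0)
        assert set(forward.pairs) == {(s, t) for t, s in backward.pairs}

    def test_precision_with_spurious_detections(self, default_scenarios, geometry):
        """With 20% spurious candidates added per side, mutual-NN proposal
        precision stays ≥ 0.9 across the 20 standard seeds."""
        from clemdock.geometry import Landmark, LandmarkSet, Point3

        total_correct, total_proposed = 0, 0
        for seed, scenario in default_scenarios.items():
            rng = np.random.default_rng([seed, 99])
            sets = []
            for base, tag in ((scenario.observed_source, "s"), (scenario.observed_target, "t")):
                extra_n = max(1, int(0.2 * len(base)))
                extras = [
                    Landmark(
                        f"spur_{tag}{k}",
                        Point3.from_array(rng.uniform([0, 0, 0], [400, 400, 150])),
                        FeatureClass.FIBER_CROSSING,
                    )
                    for k in range(extra_n)
                ]
                sets.append(LandmarkSet(list(base.landmarks) + extras, base.geometry,
                                        min_separation=0.0))
            # coarse map: the global contraction the deformation applies
            centre = np.array(scenario.tissue.extent) / 2.0
            from clemdock.registration import SimilarityTransform

            coarse = SimilarityTransform(
                0.95, np.eye(3), centre - 0.95 * centre
            )
            proposal = suggest_pairs(sets[0], sets[1], coarse, gate=15.0)
            for s, t in proposal.pairs:
                total_proposed += 1
                if s == t:
                    total_correct += 1
        assert total_proposed > 0
        assert total_correct / total_proposed >= 0.9
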