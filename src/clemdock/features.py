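"""Landmark-candidate detection from anatomy.

Replaces interactive clicking with a reproducible procedure: vessel
bifurcations are the degree ≥ 3 nodes of a 3D-thinned centerline skeleton
of a tubular mask; collagen cross-points are closest-approach midpoints of
fiber polylines that pass within a distance gate of each other (fibers
rarely touch exactly in 3D, so true intersections are not required).
Cross-modality pairing proposals use mutual nearest neighbours under a
coarse alignment and are always marked as requiring review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .errors import ValidationError
from .geometry import (
    FeatureClass,
    Landmark,
    LandmarkPairing,
    LandmarkSet,
    Point3,
    VolumeGeometry,
)
from .registration import SpatialTransform

__all__ = [
    "VesselSkeleton",
    "FiberSet",
    "skeletonize_mask",
    "detect_bifurcations",
    "detect_fiber_crossings",
    "suggest_pairs",
    "MERGE_RADIUS_UM",
    "CROSSING_GATE_UM",
]

#: Default merge radius (µm) for clustering nearby candidate landmarks.
MERGE_RADIUS_UM = 3.0

#: Default gate (µm) below which two fibers count as crossing.
CROSSING_GATE_UM = 2.0


@dataclass
class VesselSkeleton:
    """Centerline graph of a vessel network: nodes in physical µm, edges as
    node-index pairs.  Cycles are allowed but flagged (anastomoses or
    thinning artefacts)."""

    nodes: np.ndarray
    edges: list[tuple[int, int]]
    geometry: VolumeGeometry | None = None
    has_cycles: bool = field(init=False, default=False)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        n = len(self.nodes)
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"edge ({i}, {j}) references a missing node")
        g = self.graph()
        self.has_cycles = len(g.edges) > len(g.nodes) - nx.number_connected_components(g)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(self.edges)
        return g

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class FiberSet:
    """Collagen fibers as ordered polylines in physical µm."""

    polylines: list[np.ndarray]

    def __post_init__(self):
        cleaned = []
        for k, poly in enumerate(self.polylines):
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 3 or len(poly) < 2:
                raise ValidationError(f"fiber {k} must be an (n≥2, 3) polyline")
            seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            if (seg <= 0).any():
                raise ValidationError(f"fiber {k} has a zero-length segment")
            cleaned.append(poly)
        self.polylines = cleaned

    def __len__(self):
        return len(self.polylines)


def skeletonize_mask(stack: np.ndarray, geometry: VolumeGeometry) -> VesselSkeleton:
    """3D topological thinning of a binary stack into a 1-voxel centerline
    graph in physical µm.

    ``stack`` is indexed (z, y, x) — one TIFF page per z slice — while
    ``geometry`` follows the package's (x, y, z) axis order.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValidationError("expected a 3D (z, y, x) stack")
    mask = stack > 0
    if not mask.any():
        raise ValidationError("empty mask: no foreground voxels to skeletonize")
    skel = skeletonize(mask)
    zz, yy, xx = np.nonzero(skel)
    voxels = np.column_stack([xx, yy, zz]).astype(float)
    sx, sy, sz = geometry.voxel_spacing
    nodes = voxels * np.array([sx, sy, sz])
    # 26-connectivity between skeleton voxels
    index = {tuple(v): i for i, v in enumerate(np.column_stack([zz, yy, xx]))}
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)  # half the neighbourhood; avoids duplicates
    ]
    edges = []
    for (z, y, x), i in index.items():
        for dz, dy, dx in offsets:
            j = index.get((z + dz, y + dy, x + dx))
            if j is not None:
                edges.append((i, j))
    return VesselSkeleton(nodes, edges, geometry=geometry)


def _merge_points(points: np.ndarray, merge_radius: float) -> np.ndarray:
    """Single-linkage clustering of points within ``merge_radius``; each
    cluster collapses to its centroid."""
    if len(points) == 0:
        return points.reshape(0, 3)
    g = nx.Graph()
    g.add_nodes_from(range(len(points)))
    if merge_radius > 0:
        g.add_edges_from(cKDTree(points).query_pairs(merge_radius))
    centroids = [points[list(comp)].mean(axis=0) for comp in nx.connected_components(g)]
    return np.array(centroids).reshape(-1, 3)


def _candidate_set(
    points: np.ndarray,
    feature_class: FeatureClass,
    prefix: str,
    geometry: VolumeGeometry | None,
    name: str,
) -> LandmarkSet:
    order = np.lexsort((points[:, 1], points[:, 0], points[:, 2])) if len(points) else []
    landmarks = [
        Landmark(f"{prefix}{k}", Point3.from_array(points[i]), feature_class)
        for k, i in enumerate(order, start=1)
    ]
    if geometry is None:
        geometry = VolumeGeometry.bounding(points if len(points) else np.zeros((1, 3)))
    # candidates were already merged; disable the 1 µm digitisation guard
    return LandmarkSet(landmarks, geometry, name=name, min_separation=0.0)


def _refine_junction(
    skeleton: VesselSkeleton,
    junction: np.ndarray,
    r_inner: float = 2.5,
    r_outer: float = 12.0,
    max_shift: float = 6.0,
) -> np.ndarray:
    """Correct the systematic thinning bias at a junction of thick tubes.

    Skeleton nodes in the annulus [r_inner, r_outer] around the raw junction
    are grouped into incident branches (connected components after removing
    the core); each branch is fitted as a ray by PCA and the branch point is
    re-estimated as the least-squares intersection of those rays.  Falls
    back to the raw position if fewer than 3 branches resolve or the
    solution drifts implausibly far."""
    d = np.linalg.norm(skeleton.nodes - junction, axis=1)
    annulus = np.where((d >= r_inner) & (d <= r_outer))[0]
    if len(annulus) < 6:
        return junction
    g = skeleton.graph().subgraph(annulus)
    rays = []
    for comp in nx.connected_components(g):
        pts = skeleton.nodes[list(comp)]
        if len(pts) < 3:
            continue
        mean = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - mean)
        rays.append((mean, vt[0]))
    if len(rays) < 3:
        return junction
    a = np.zeros((3, 3))
    b = np.zeros(3)
    for mean, direction in rays:
        proj = np.eye(3) - np.outer(direction, direction)
        a += proj
        b += proj @ mean
    try:
        refined = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        return junction
    if np.linalg.norm(refined - junction) > max_shift:
        return junction
    return refined


def detect_bifurcations(
    skeleton: VesselSkeleton,
    merge_radius: float = MERGE_RADIUS_UM,
    geometry: VolumeGeometry | None = None,
    refine: bool = True,
) -> LandmarkSet:
    """Vessel-fork landmarks: one per degree ≥ 3 skeleton node, with nearby
    junction nodes (thinning emits small clusters) merged to their centroid
    and, by default, refined to the least-squares intersection of the
    incident centerline rays (thinning displaces junctions of thick tubes
    toward the parent).  Ids are auto-assigned V1…Vn ordered by z then x."""
    deg = skeleton.degrees()
    junctions = skeleton.nodes[deg >= 3]
    merged = _merge_points(junctions, merge_radius)
    if refine and len(merged):
        merged = np.array([_refine_junction(skeleton, j) for j in merged])
    return _candidate_set(
        merged,
        FeatureClass.VESSEL_BIFURCATION,
        "V",
        geometry or skeleton.geometry,
        "vessel-bifurcation candidates",
    )


def _segment_pair_distance(p0, p1, q0, q1):
    """Minimum distance between segments [p0,p1] and [q0,q1] and the
    midpoint of the closest-approach segment (standard clamped solution)."""
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    c = float(d1 @ r)
    b = float(d1 @ d2)
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-12 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    pa = p0 + s * d1
    pb = q0 + t * d2
    return float(np.linalg.norm(pa - pb)), (pa + pb) / 2.0


def _fiber_pair_closest(poly_a: np.ndarray, poly_b: np.ndarray):
    """Global minimum distance between two polylines and its midpoint."""
    best = (np.inf, None)
    for i in range(len(poly_a) - 1):
        for j in range(len(poly_b) - 1):
            d, mid = _segment_pair_distance(
                poly_a[i], poly_a[i + 1], poly_b[j], poly_b[j + 1]
            )
            if d < best[0]:
                best = (d, mid)
    return best


def detect_fiber_crossings(
    fibers: FiberSet,
    gate: float = CROSSING_GATE_UM,
    merge_radius: float = MERGE_RADIUS_UM,
    geometry: VolumeGeometry | None = None,
) -> LandmarkSet:
    """Collagen cross-point landmarks.

    For every pair of distinct fibers whose minimum segment-to-segment
    distance is below ``gate``, a landmark is placed at the midpoint of the
    closest-approach segment; candidates within ``merge_radius`` are merged.
    Ids are C1…Cn ordered by z then x.
    """
    if len(fibers) < 2:
        raise ValidationError("fiber-crossing detection needs at least 2 fibers")
    if not gate > 0:
        raise ValidationError("gate must be > 0 µm")
    candidates = []
    polys = fibers.polylines
    for a in range(len(polys)):
        for b in range(a + 1, len(polys)):
            d, mid = _fiber_pair_closest(polys[a], polys[b])
            if d < gate:
                candidates.append(mid)
    merged = _merge_points(
        np.array(candidates).reshape(-1, 3), merge_radius
    )
    return _candidate_set(
        merged, FeatureClass.FIBER_CROSSING, "C", geometry, "fiber-crossing candidates"
    )


def suggest_pairs(
    source: LandmarkSet,
    target: LandmarkSet,
    coarse: SpatialTransform,
    gate: float,
) -> LandmarkPairing:
    """Propose cross-modality landmark pairs as mutual nearest neighbours
    under a coarse alignment.

    A pair (a, b) is proposed when b is the nearest target to coarse(a),
    a is reciprocally nearest among transformed sources, their distance is
    below ``gate`` and the feature classes match.  The proposal is marked
    ``requires_review`` — it automates the correlation step but is meant to
    be curated, not trusted blindly.
    """
    if not gate > 0:
        raise ValidationError("gate must be > 0 µm")
    src_pts = coarse.apply(source.positions())
    tgt_pts = target.positions()
    if len(src_pts) == 0 or len(tgt_pts) == 0:
        return LandmarkPairing(source, target, [], requires_review=True)
    tgt_tree = cKDTree(tgt_pts)
    src_tree = cKDTree(src_pts)
    d_st, nn_t = tgt_tree.query(src_pts)
    _, nn_s = src_tree.query(tgt_pts)
    src_lms = list(source)
    tgt_lms = list(target)
    pairs = []
    for i, (d, j) in enumerate(zip(d_st, nn_t)):
        if d < gate and nn_s[j] == i and (
            src_lms[i].feature_class is tgt_lms[j].feature_class
        ):
            pairs.append((src_lms[i].id, tgt_lms[j].id))
    return LandmarkPairing(source, target, pairs, requires_review=True)
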