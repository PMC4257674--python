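"""Synthetic ear-skin scenes and the EM-processing deformation.

The generator emulates the kind of volume the targeting workflow operates
on: a block 270–440 µm wide in xy and 60–200 µm deep containing a branching
vessel tree, a collagen-fiber meshwork, a handful of cells placed near the
vessels, and a branded (NIRB) square frame at the skin surface.  EM
processing is modelled as a global anisotropic scaling about the volume
centroid (chemical fixation causes roughly 5% shrinkage; osmium fixation
can swell) plus a small number of smooth Gaussian displacement bumps —
tissue distortion is never homogeneous, which is exactly why a rigid
overlay fails where a thin-plate-spline warp succeeds.

Everything is deterministic given (params, seed): the ground-truth
correspondence between the in-vivo and block frames is returned exactly
and serves as the oracle for every registration test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, ValidationError
from .features import FiberSet, detect_fiber_crossings
from .geometry import (
    FeatureClass,
    Landmark,
    LandmarkPairing,
    LandmarkSet,
    Point3,
    VolumeGeometry,
    pair_by_id,
)

__all__ = [
    "TissueParams",
    "VesselTree",
    "Cell",
    "SyntheticTissue",
    "DeformationModel",
    "generate_tissue",
    "apply_em_processing",
    "true_landmarks",
    "observe_landmarks",
    "rasterize",
    "default_deformation",
    "default_scenario",
    "ScenarioResult",
]


@dataclass(frozen=True)
class TissueParams:
    """Scene parameters; defaults describe the standard simulated volume."""

    extent: tuple[float, float, float] = (400.0, 400.0, 150.0)
    vessel_levels: int = 3              # L split levels -> 2^L - 1 bifurcations
    n_fibers: int = 30
    n_cells: int = 6
    root_radius: float = 4.0            # µm; child radii shrink by radius_decay
    radius_decay: float = 0.78
    segment_length: float = 60.0        # µm; first-generation branch length
    length_decay: float = 0.75
    fiber_step: float = 18.0            # µm between fiber polyline vertices
    fiber_points: int = 12
    fiber_radius: float = 0.6           # µm, for rasterization
    cell_semiaxes: tuple[float, float, float] = (8.0, 6.0, 5.0)
    nirb_inset: float = 0.15            # frame inset as fraction of xy extent

    def __post_init__(self):
        ex, ey, ez = self.extent
        if not (60.0 <= ez <= 200.0):
            raise ValidationError(
                f"depth extent must lie in [60, 200] µm, got {ez}"
            )
        if not (100.0 <= ex and 100.0 <= ey):
            raise ValidationError("xy extent too small to host the scene")
        if self.vessel_levels < 1:
            raise ValidationError("vessel_levels must be ≥ 1")


@dataclass
class VesselTree:
    """Centerline graph with per-node radii; bifurcation ground truth is
    exactly the set of degree-3 internal nodes."""

    nodes: np.ndarray                   # (n, 3) µm
    edges: list[tuple[int, int]]
    node_radii: np.ndarray              # (n,) µm
    bifurcation_indices: list[int]

    @property
    def bifurcations(self) -> np.ndarray:
        return self.nodes[self.bifurcation_indices].reshape(-1, 3)

    def segments(self):
        """Iterate (p0, p1, radius) tuples for rasterization."""
        for i, j in self.edges:
            yield self.nodes[i], self.nodes[j], float(
                min(self.node_radii[i], self.node_radii[j])
            )


@dataclass(frozen=True)
class Cell:
    centroid: np.ndarray
    semiaxes: tuple[float, float, float]


@dataclass
class SyntheticTissue:
    extent: tuple[float, float, float]
    vessel_tree: VesselTree
    fibers: FiberSet
    fiber_crossings: np.ndarray         # (k, 3) ground-truth cross-points
    cells: list[Cell]
    nirb_frame: np.ndarray              # (4, 3) corners at z ≈ 0
    seed: int
    params: TissueParams
    deformed: bool = False

    @property
    def bifurcations(self) -> np.ndarray:
        return self.vessel_tree.bifurcations


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _steer_inside(point, direction, length, lo, hi, rng, tries=60):
    """Pick a direction close to ``direction`` whose endpoint stays inside
    the box [lo, hi]; progressively steer toward the box centre."""
    centre = (lo + hi) / 2.0
    d = _unit(direction)
    for attempt in range(tries):
        end = point + length * d
        if np.all(end >= lo) and np.all(end <= hi):
            return d, end
        blend = min(1.0, 0.15 * (attempt + 1))
        jitter = rng.normal(scale=0.25, size=3)
        d = _unit((1 - blend) * d + blend * _unit(centre - point) + jitter * 0.1)
    raise GenerationError("could not keep a vessel branch inside the volume")


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r = rng.normal(size=3)
    p = r - (r @ v) * v
    return _unit(p)


def _grow_vessel_tree(params: TissueParams, rng: np.random.Generator) -> VesselTree:
    extent = np.array(params.extent)
    margin = 0.06 * extent
    lo, hi = margin, extent - margin
    start = np.array(
        [
            lo[0],
            rng.uniform(0.35, 0.65) * extent[1],
            rng.uniform(0.40, 0.60) * extent[2],
        ]
    )
    root_dir = _unit(np.array([1.0, rng.uniform(-0.2, 0.2), rng.uniform(-0.1, 0.1)]))

    nodes = [start]
    radii = [params.root_radius]
    edges: list[tuple[int, int]] = []
    bifurcations: list[int] = []

    def grow(node_idx: int, direction: np.ndarray, level: int) -> None:
        """Extend from nodes[node_idx] one segment; split until level runs out."""
        length = params.segment_length * (params.length_decay ** (params.vessel_levels - level)) \
            * rng.uniform(0.85, 1.15)
        d, end = _steer_inside(nodes[node_idx], direction, length, lo, hi, rng)
        radius = params.root_radius * (
            params.radius_decay ** (params.vessel_levels - level)
        )
        nodes.append(end)
        radii.append(radius)
        end_idx = len(nodes) - 1
        edges.append((node_idx, end_idx))
        if level > 0:
            bifurcations.append(end_idx)
            child_len = params.segment_length * (
                params.length_decay ** (params.vessel_levels - level + 1)
            )
            # the two daughter branches must actually diverge (≥ 30° after
            # boundary steering) or the fork is not a real bifurcation
            for _ in range(40):
                axis = _perpendicular(d, rng)
                children = []
                for sign in (+1.0, -1.0):
                    angle = np.deg2rad(rng.uniform(25.0, 40.0))
                    proposal = _unit(np.cos(angle) * d + sign * np.sin(angle) * axis)
                    steered, _ = _steer_inside(end, proposal, child_len, lo, hi, rng)
                    children.append(steered)
                if np.degrees(np.arccos(np.clip(children[0] @ children[1], -1, 1))) >= 30.0:
                    break
            else:
                raise GenerationError("could not place diverging daughter branches")
            for child in children:
                grow(end_idx, child, level - 1)

    grow(0, root_dir, params.vessel_levels)
    return VesselTree(
        nodes=np.array(nodes),
        edges=edges,
        node_radii=np.array(radii),
        bifurcation_indices=bifurcations,
    )


def _grow_fibers(params: TissueParams, rng: np.random.Generator) -> FiberSet:
    extent = np.array(params.extent)
    margin = 0.04 * extent
    lo, hi = margin, extent - margin
    polylines = []
    # collagen bundles concentrate in the upper dermis: confine fibers to a
    # band below the surface so the meshwork is dense enough to cross often
    band_lo, band_hi = max(lo[2], 5.0), min(hi[2], 0.45 * extent[2])
    for _ in range(params.n_fibers):
        p = rng.uniform(lo, hi)
        p[2] = rng.uniform(band_lo, band_hi)
        d = _unit(np.concatenate([rng.normal(size=2), rng.normal(scale=0.3, size=1)]))
        f_lo = np.array([lo[0], lo[1], band_lo])
        f_hi = np.array([hi[0], hi[1], band_hi])
        pts = [p.copy()]
        for _ in range(params.fiber_points - 1):
            d = _unit(d + rng.normal(scale=0.25, size=3))  # smooth random walk
            step = p + params.fiber_step * d
            # bounce off the fiber band boundary instead of clipping in place
            out = (step < f_lo) | (step > f_hi)
            d[out] *= -1.0
            step = np.clip(p + params.fiber_step * d, f_lo, f_hi)
            p = step
            pts.append(p.copy())
        polylines.append(np.array(pts))
    return FiberSet(polylines)


def _place_cells(
    params: TissueParams, tree: VesselTree, rng: np.random.Generator
) -> list[Cell]:
    extent = np.array(params.extent)
    anchors = tree.nodes
    cells = []
    for _ in range(params.n_cells):
        # invading cells cluster near the vasculature
        anchor = anchors[rng.integers(len(anchors))]
        offset = rng.normal(scale=12.0, size=3)
        centroid = np.clip(anchor + offset, 0.05 * extent, 0.95 * extent)
        cells.append(Cell(centroid=centroid, semiaxes=params.cell_semiaxes))
    return cells


def generate_tissue(params: TissueParams | None = None, seed: int = 0) -> SyntheticTissue:
    """Generate a ground-truth scene; bit-reproducible from (params, seed).

    The vessel tree is a recursive binary tree with ``vessel_levels`` split
    levels, hence exactly ``2**vessel_levels − 1`` bifurcations; fibers are
    smoothed random polylines; cells are placed near vessels; the NIRB
    frame sits at the surface (z = 0).
    """
    params = params or TissueParams()
    rng = np.random.default_rng([int(seed), 0xC1E])
    for attempt in range(8):
        try:
            tree = _grow_vessel_tree(params, rng)
            break
        except GenerationError:
            if attempt == 7:
                raise GenerationError(
                    "vessel tree generation failed: structures cannot fit the extent"
                )
    fibers = _grow_fibers(params, rng)
    crossings = detect_fiber_crossings(fibers).positions()
    cells = _place_cells(params, tree, rng)
    ex, ey, _ = params.extent
    inset = params.nirb_inset
    frame = np.array(
        [
            [inset * ex, inset * ey, 0.0],
            [(1 - inset) * ex, inset * ey, 0.0],
            [(1 - inset) * ex, (1 - inset) * ey, 0.0],
            [inset * ex, (1 - inset) * ey, 0.0],
        ]
    )
    return SyntheticTissue(
        extent=params.extent,
        vessel_tree=tree,
        fibers=fibers,
        fiber_crossings=crossings,
        cells=cells,
        nirb_frame=frame,
        seed=int(seed),
        params=params,
    )


@dataclass(frozen=True)
class DeformationModel:
    """The in-vivo → block-frame distortion introduced by EM processing.

    Displacement at p = centroid-anchored global scaling plus a sum of
    Gaussian bumps: Σ aₖ · exp(−‖p − cₖ‖² / (2 wₖ²)).  With unit scales and
    zero amplitudes the model is the identity; the non-affine displacement
    magnitude is bounded by Σ‖aₖ‖ everywhere.  ``detection_noise_sd`` and
    ``dropout_rate`` describe the imperfect landmark observation in each
    modality, not the tissue itself.
    """

    global_scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bump_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    bump_amplitudes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    bump_widths: np.ndarray = field(default_factory=lambda: np.zeros(0))
    detection_noise_sd: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "bump_centers",
                           np.asarray(self.bump_centers, dtype=float).reshape(-1, 3))
        object.__setattr__(self, "bump_amplitudes",
                           np.asarray(self.bump_amplitudes, dtype=float).reshape(-1, 3))
        object.__setattr__(self, "bump_widths",
                           np.asarray(self.bump_widths, dtype=float).reshape(-1))
        if not (len(self.bump_centers) == len(self.bump_amplitudes) == len(self.bump_widths)):
            raise ValidationError("bump arrays must have matching lengths")
        if (self.bump_widths <= 0).any():
            raise ValidationError("bump widths must be > 0")
        if any(s <= 0 for s in self.global_scales):
            raise ValidationError("global scales must be > 0")
        if self.detection_noise_sd < 0:
            raise ValidationError("detection noise sd must be ≥ 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout rate must be in [0, 1)")

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """Apply the deformation to (n, 3) µm points."""
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        c = np.asarray(self.center, dtype=float)
        out = c + (p - c) * np.asarray(self.global_scales)
        for centre, amp, width in zip(
            self.bump_centers, self.bump_amplitudes, self.bump_widths
        ):
            w = np.exp(-((p - centre) ** 2).sum(axis=1) / (2.0 * width**2))
            out = out + w[:, None] * amp
        return out


def apply_em_processing(
    tissue: SyntheticTissue, model: DeformationModel
) -> tuple[SyntheticTissue, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Map every ground-truth point through the deformation.

    Returns the deformed tissue and the exact point-to-point correspondence
    {landmark id: (in-vivo position, block-frame position)} over all named
    features — the oracle against which registrations are scored.
    """
    m = model.map_points
    tree = tissue.vessel_tree
    new_tree = VesselTree(
        nodes=m(tree.nodes),
        edges=list(tree.edges),
        node_radii=tree.node_radii.copy(),
        bifurcation_indices=list(tree.bifurcation_indices),
    )
    new_fibers = FiberSet([m(poly) for poly in tissue.fibers.polylines])
    deformed = SyntheticTissue(
        extent=tissue.extent,
        vessel_tree=new_tree,
        fibers=new_fibers,
        fiber_crossings=m(tissue.fiber_crossings),
        cells=[Cell(m(c.centroid)[0], c.semiaxes) for c in tissue.cells],
        nirb_frame=m(tissue.nirb_frame),
        seed=tissue.seed,
        params=tissue.params,
        deformed=True,
    )
    correspondence: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for lm_src, lm_tgt in zip(true_landmarks(tissue), true_landmarks(deformed)):
        correspondence[lm_src.id] = (
            lm_src.position.as_array(),
            lm_tgt.position.as_array(),
        )
    return deformed, correspondence


def _tissue_geometry(tissue: SyntheticTissue, modality: str) -> VolumeGeometry:
    dims = tuple(int(np.ceil(e)) + 1 for e in tissue.extent)
    return VolumeGeometry((1.0, 1.0, 1.0), dims, modality=modality)


def true_landmarks(
    tissue: SyntheticTissue,
    include: tuple[str, ...] = ("bifurcation", "crossing", "nirb", "cell"),
) -> LandmarkSet:
    """Ground-truth landmark set with stable ids (V*, C*, N*, CELL*) so the
    in-vivo and deformed frames pair exactly by id."""
    modality = "EM_SERIAL" if tissue.deformed else "LM_2PEM"
    landmarks: list[Landmark] = []
    if "bifurcation" in include:
        for k, p in enumerate(tissue.bifurcations, start=1):
            landmarks.append(
                Landmark(f"V{k}", Point3.from_array(p), FeatureClass.VESSEL_BIFURCATION)
            )
    if "crossing" in include:
        for k, p in enumerate(tissue.fiber_crossings, start=1):
            landmarks.append(
                Landmark(f"C{k}", Point3.from_array(p), FeatureClass.FIBER_CROSSING)
            )
    if "nirb" in include:
        for k, p in enumerate(tissue.nirb_frame, start=1):
            landmarks.append(
                Landmark(f"N{k}", Point3.from_array(p), FeatureClass.NIRB_MARK)
            )
    if "cell" in include:
        for k, c in enumerate(tissue.cells, start=1):
            landmarks.append(
                Landmark(f"CELL{k}", Point3.from_array(c.centroid), FeatureClass.CELL)
            )
    return LandmarkSet(
        landmarks,
        _tissue_geometry(tissue, modality),
        name=f"{'deformed' if tissue.deformed else 'in-vivo'} ground truth (seed {tissue.seed})",
        min_separation=0.0,
    )


def observe_landmarks(
    truth: LandmarkSet,
    model: DeformationModel,
    frame: str = "source",
) -> LandmarkSet:
    """Simulate imperfect landmark localisation: independent zero-mean
    Gaussian noise (sd per axis = ``detection_noise_sd``) on each kept
    landmark, each dropped independently with ``dropout_rate``.  Ids are
    preserved so the ground-truth pairing remains known."""
    tag = {"source": 1, "target": 2}.get(frame)
    if tag is None:
        raise ValidationError("frame must be 'source' or 'target'")
    rng = np.random.default_rng([int(model.seed), 0x0B5, tag])
    kept: list[Landmark] = []
    for lm in truth:
        if rng.random() < model.dropout_rate:
            continue
        noise = rng.normal(scale=model.detection_noise_sd, size=3) \
            if model.detection_noise_sd > 0 else np.zeros(3)
        pos = lm.position.as_array() + noise
        if lm.feature_class is FeatureClass.NIRB_MARK:
            pos[2] = max(pos[2], 0.0)  # a surface mark cannot be observed above z=0
        kept.append(Landmark(lm.id, Point3.from_array(pos), lm.feature_class, lm.confidence))
    return LandmarkSet(
        kept,
        truth.geometry,
        name=f"observed {frame} (sd {model.detection_noise_sd} µm)",
        min_separation=0.0,
    )


def rasterize(
    tissue: SyntheticTissue,
    geometry: VolumeGeometry,
    channel: str = "vessels",
) -> np.ndarray:
    """Rasterize one channel into a binary (z, y, x) stack.

    Voxels whose centres fall within a structure's radius (vessels, fibers)
    or ellipsoid semi-axes (cells) become foreground.  Deterministic.
    """
    import logging

    if channel not in ("vessels", "fibers", "cells"):
        raise ValidationError(f"unknown channel {channel!r}")
    for g_ext, t_ext in zip(geometry.extent, tissue.extent):
        if g_ext + 1e-6 < t_ext:
            raise ValidationError(
                "rasterization geometry extent is smaller than the tissue extent"
            )
    spacing = np.array(geometry.voxel_spacing)
    if channel == "vessels":
        min_radius = float(tissue.vessel_tree.node_radii.min())
    elif channel == "fibers":
        min_radius = tissue.params.fiber_radius
    else:
        min_radius = min(tissue.params.cell_semiaxes)
    if spacing.max() > min_radius:
        logging.getLogger("clemdock").warning(
            "voxel spacing %s µm is coarser than the smallest structure radius "
            "%.2f µm; thin structures may break up", tuple(spacing), min_radius
        )
    nx_, ny, nz = geometry.dimensions
    stack = np.zeros((nz, ny, nx_), dtype=np.uint8)

    def paint_ball_capsule(p0, p1, radius):
        lo = np.minimum(p0, p1) - radius
        hi = np.maximum(p0, p1) + radius
        i_lo = np.maximum(np.floor(lo / spacing).astype(int), 0)
        i_hi = np.minimum(np.ceil(hi / spacing).astype(int) + 1, [nx_, ny, nz])
        if np.any(i_lo >= i_hi):
            return
        xs = np.arange(i_lo[0], i_hi[0]) * spacing[0]
        ys = np.arange(i_lo[1], i_hi[1]) * spacing[1]
        zs = np.arange(i_lo[2], i_hi[2]) * spacing[2]
        gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1)
        d = p1 - p0
        len2 = float(d @ d)
        if len2 < 1e-12:
            dist = np.linalg.norm(pts - p0, axis=-1)
        else:
            t = np.clip(((pts - p0) @ d) / len2, 0.0, 1.0)
            nearest = p0 + t[..., None] * d
            dist = np.linalg.norm(pts - nearest, axis=-1)
        sub = stack[i_lo[2]:i_hi[2], i_lo[1]:i_hi[1], i_lo[0]:i_hi[0]]
        sub[dist <= radius] = 1

    if channel == "vessels":
        for p0, p1, radius in tissue.vessel_tree.segments():
            paint_ball_capsule(p0, p1, radius)
    elif channel == "fibers":
        for poly in tissue.fibers.polylines:
            for i in range(len(poly) - 1):
                paint_ball_capsule(poly[i], poly[i + 1], tissue.params.fiber_radius)
    else:
        for cell in tissue.cells:
            a = np.array(cell.semiaxes)
            lo = cell.centroid - a
            hi = cell.centroid + a
            i_lo = np.maximum(np.floor(lo / spacing).astype(int), 0)
            i_hi = np.minimum(np.ceil(hi / spacing).astype(int) + 1, [nx_, ny, nz])
            if np.any(i_lo >= i_hi):
                continue
            xs = np.arange(i_lo[0], i_hi[0]) * spacing[0]
            ys = np.arange(i_lo[1], i_hi[1]) * spacing[1]
            zs = np.arange(i_lo[2], i_hi[2]) * spacing[2]
            gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
            q = (
                ((gx - cell.centroid[0]) / a[0]) ** 2
                + ((gy - cell.centroid[1]) / a[1]) ** 2
                + ((gz - cell.centroid[2]) / a[2]) ** 2
            )
            sub = stack[i_lo[2]:i_hi[2], i_lo[1]:i_hi[1], i_lo[0]:i_hi[0]]
            sub[q <= 1.0] = 1
    return stack


# --- the default study scenario ----------------------------------------------

#: Global contraction from glutaraldehyde fixation: ~5% linear shrinkage.
GA_SHRINKAGE_SCALE = 0.95

#: Default non-homogeneous distortion: 3 smooth bumps, per-axis amplitude
#: up to 8 µm, width 120 µm.
DEFAULT_N_BUMPS = 3
DEFAULT_BUMP_AMPLITUDE = 8.0
DEFAULT_BUMP_WIDTH = 120.0

#: Default landmark observation: 2 µm isotropic localisation noise, 10%
#: dropout per modality, 12 bifurcation/crossing landmarks retained.
DEFAULT_NOISE_SD = 2.0
DEFAULT_DROPOUT = 0.1
DEFAULT_N_LANDMARKS = 12


def default_deformation(seed: int, extent: tuple[float, float, float],
                        noise_sd: float = DEFAULT_NOISE_SD,
                        dropout: float = DEFAULT_DROPOUT) -> DeformationModel:
    """The default EM-processing distortion for a given volume extent."""
    rng = np.random.default_rng([int(seed), 0xDEF])
    ext = np.array(extent)
    centers = rng.uniform(0.2, 0.8, size=(DEFAULT_N_BUMPS, 3)) * ext
    amplitudes = rng.uniform(
        -DEFAULT_BUMP_AMPLITUDE, DEFAULT_BUMP_AMPLITUDE, size=(DEFAULT_N_BUMPS, 3)
    )
    return DeformationModel(
        global_scales=(GA_SHRINKAGE_SCALE,) * 3,
        center=tuple(ext / 2.0),
        bump_centers=centers,
        bump_amplitudes=amplitudes,
        bump_widths=np.full(DEFAULT_N_BUMPS, DEFAULT_BUMP_WIDTH),
        detection_noise_sd=noise_sd,
        dropout_rate=dropout,
        seed=int(seed),
    )


@dataclass
class ScenarioResult:
    """One simulated study: ground truth, deformation, observed landmark
    sets in both frames, their id-based pairing, and the ROI with its true
    deformed position."""

    tissue: SyntheticTissue
    deformed: SyntheticTissue
    model: DeformationModel
    correspondence: dict[str, tuple[np.ndarray, np.ndarray]]
    observed_source: LandmarkSet
    observed_target: LandmarkSet
    pairing: LandmarkPairing
    roi_label: str
    roi_true_source: np.ndarray
    roi_true_target: np.ndarray


def _select_pairing_ids(tissue: SyntheticTissue, n_landmarks: int) -> list[str]:
    """All vessel bifurcations first, topped up with fiber crossings chosen
    evenly across the crossing list (already ordered by z then x)."""
    ids = [f"V{k}" for k in range(1, len(tissue.bifurcations) + 1)]
    n_cross = len(tissue.fiber_crossings)
    need = max(0, n_landmarks - len(ids))
    if need and n_cross:
        picks = np.unique(np.linspace(0, n_cross - 1, min(need, n_cross)).round().astype(int))
        ids.extend(f"C{k + 1}" for k in picks)
    return ids[:n_landmarks]


def default_scenario(
    seed: int,
    params: TissueParams | None = None,
    n_landmarks: int = DEFAULT_N_LANDMARKS,
    noise_sd: float = DEFAULT_NOISE_SD,
    dropout: float = DEFAULT_DROPOUT,
) -> ScenarioResult:
    """The package's standard simulated study ("s1-default").

    400×400×150 µm volume, 3-level vessel tree (7 bifurcations), 30 fibers,
    6 cells; 5% isotropic shrinkage about the centroid plus 3 smooth bumps
    (≤ 8 µm per axis, width 120 µm); 12 retained landmarks observed with
    2 µm noise and 10% dropout per frame; ROI = first cell centroid.
    """
    params = params or TissueParams()
    tissue = generate_tissue(params, seed)
    model = default_deformation(seed, params.extent, noise_sd=noise_sd, dropout=dropout)
    deformed, correspondence = apply_em_processing(tissue, model)

    keep_ids = _select_pairing_ids(tissue, n_landmarks)
    src_truth = true_landmarks(tissue, include=("bifurcation", "crossing"))
    tgt_truth = true_landmarks(deformed, include=("bifurcation", "crossing"))
    src_truth = src_truth.subset([i for i in keep_ids if i in src_truth.ids()])
    tgt_truth = tgt_truth.subset([i for i in keep_ids if i in tgt_truth.ids()])

    observed_source = observe_landmarks(src_truth, model, frame="source")
    observed_target = observe_landmarks(tgt_truth, model, frame="target")
    pairing = pair_by_id(observed_source, observed_target)

    roi_src = tissue.cells[0].centroid
    roi_tgt = deformed.cells[0].centroid
    return ScenarioResult(
        tissue=tissue,
        deformed=deformed,
        model=model,
        correspondence=correspondence,
        observed_source=observed_source,
        observed_target=observed_target,
        pairing=pairing,
        roi_label="CELL1",
        roi_true_source=np.asarray(roi_src, dtype=float),
        roi_true_target=np.asarray(roi_tgt, dtype=float),
    )
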