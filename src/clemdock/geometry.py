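"""Physical-coordinate conventions and landmark containers.

All positions live in micrometres (µm) in a right-handed frame whose origin
sits at the corner of the imaged stack at the skin surface; z increases with
depth into the tissue.  Voxel indices are 0-based and a voxel's physical
position is the centre of that voxel, with the origin placed at the centre
of voxel (0, 0, 0) — so physical = index × spacing.  Voxel coordinates never
leave the conversion routines in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import PairingError, RangeError, ValidationError

__all__ = [
    "FeatureClass",
    "Point3",
    "VolumeGeometry",
    "Landmark",
    "LandmarkSet",
    "LandmarkPairing",
    "to_physical",
    "to_voxel",
    "pair_by_id",
]

#: Default minimum landmark separation in µm; two landmarks closer than this
#: signal a digitisation error (below the optical resolution budget).
MIN_SEPARATION_UM = 1.0

#: Default surface band (µm) within which NIRB marks must lie.  Generous
#: because EM processing legitimately displaces the branded surface.
NIRB_SURFACE_BAND_UM = 20.0


class FeatureClass(str, Enum):
    """Kind of anatomical or artificial feature a landmark marks."""

    VESSEL_BIFURCATION = "VESSEL_BIFURCATION"
    FIBER_CROSSING = "FIBER_CROSSING"
    NIRB_MARK = "NIRB_MARK"
    CELL = "CELL"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Point3:
    """A 3D point in physical µm coordinates."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for axis in ("x", "y", "z"):
            v = getattr(self, axis)
            if not math.isfinite(v):
                raise ValidationError(f"non-finite {axis} coordinate: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "Point3":
        return cls(float(a[0]), float(a[1]), float(a[2]))


def points_to_array(points: Iterable[Point3]) -> np.ndarray:
    """Stack Point3 objects into an (n, 3) float array."""
    return np.array([[p.x, p.y, p.z] for p in points], dtype=float).reshape(-1, 3)


def array_to_points(a: np.ndarray) -> list[Point3]:
    return [Point3.from_array(row) for row in np.asarray(a, dtype=float).reshape(-1, 3)]


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid metadata for one acquired volume.

    Parameters
    ----------
    voxel_spacing : (sx, sy, sz)
        µm per voxel along x, y, z.  Anisotropy is expected: intravital
        two-photon stacks are typically stretched in z relative to the
        serial-section reconstruction, so spacing is always supplied
        per modality, never assumed shared.
    dimensions : (nx, ny, nz)
        Voxel counts per axis.
    modality : {"LM_2PEM", "EM_SERIAL"}
    """

    voxel_spacing: tuple[float, float, float]
    dimensions: tuple[int, int, int]
    modality: str = "LM_2PEM"

    _MODALITIES = ("LM_2PEM", "EM_SERIAL")

    def __post_init__(self) -> None:
        if len(self.voxel_spacing) != 3 or len(self.dimensions) != 3:
            raise ValidationError("voxel_spacing and dimensions must have 3 entries")
        if any(not (s > 0) for s in self.voxel_spacing):
            raise ValidationError(f"voxel spacings must be > 0, got {self.voxel_spacing}")
        if any(int(d) <= 0 for d in self.dimensions):
            raise ValidationError(f"dimensions must be positive, got {self.dimensions}")
        if self.modality not in self._MODALITIES:
            raise ValidationError(
                f"unknown modality {self.modality!r}; expected one of {self._MODALITIES}"
            )

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent (µm) per axis: spacing × dimensions."""
        return tuple(s * d for s, d in zip(self.voxel_spacing, self.dimensions))

    @classmethod
    def bounding(
        cls,
        coords: np.ndarray,
        voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
        modality: str = "LM_2PEM",
    ) -> "VolumeGeometry":
        """A loose geometry just large enough to contain ``coords`` (n×3 µm)."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        dims = tuple(
            max(1, int(math.ceil(m / s)) + 1)
            for m, s in zip(coords.max(axis=0), voxel_spacing)
        )
        return cls(voxel_spacing=tuple(voxel_spacing), dimensions=dims, modality=modality)


def to_physical(voxel_coords: Sequence[int], geometry: VolumeGeometry) -> Point3:
    """Convert a 0-based voxel index triple to physical µm coordinates."""
    axes = "xyz"
    out = []
    for i, (v, s, d) in enumerate(
        zip(voxel_coords, geometry.voxel_spacing, geometry.dimensions)
    ):
        if not (0 <= v < d):
            raise RangeError(
                f"voxel index {v} out of bounds on axis {axes[i]} (0..{d - 1})"
            )
        out.append(v * s)
    return Point3(*out)


def to_voxel(point: Point3, geometry: VolumeGeometry) -> tuple[int, int, int]:
    """Convert a physical point to the nearest voxel index (inverse of
    :func:`to_physical` on the voxel lattice)."""
    axes = "xyz"
    idx = []
    for i, (c, s, d) in enumerate(
        zip((point.x, point.y, point.z), geometry.voxel_spacing, geometry.dimensions)
    ):
        v = int(round(c / s))
        if not (0 <= v < d):
            raise RangeError(
                f"physical coordinate {c} µm maps outside the grid on axis "
                f"{axes[i]} (0..{d - 1})"
            )
        idx.append(v)
    return tuple(idx)


@dataclass(frozen=True)
class Landmark:
    """A single labelled reference point in one modality."""

    id: str
    position: Point3
    feature_class: FeatureClass = FeatureClass.OTHER
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("landmark id must be a non-empty string")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"confidence must be in [0, 1], got {self.confidence} for {self.id!r}"
            )


@dataclass
class LandmarkSet:
    """An ordered, validated collection of landmarks for one volume."""

    landmarks: list[Landmark]
    geometry: VolumeGeometry
    name: str = ""
    min_separation: float = MIN_SEPARATION_UM
    nirb_surface_band: float = NIRB_SURFACE_BAND_UM

    def __post_init__(self) -> None:
        ids = [lm.id for lm in self.landmarks]
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ValidationError(f"duplicate landmark id {i!r}")
            seen.add(i)
        for lm in self.landmarks:
            if lm.feature_class is FeatureClass.NIRB_MARK and (
                lm.position.z > self.nirb_surface_band
            ):
                raise ValidationError(
                    f"NIRB mark {lm.id!r} at z={lm.position.z:.3f} µm lies below "
                    f"the surface band ({self.nirb_surface_band} µm); NIRB marks "
                    "are surface features"
                )
        if len(self.landmarks) >= 2 and self.min_separation > 0:
            pts = self.positions()
            pairs = cKDTree(pts).query_pairs(self.min_separation)
            if pairs:
                i, j = sorted(pairs)[0]
                raise ValidationError(
                    f"landmarks {ids[i]!r} and {ids[j]!r} are closer than the "
                    f"minimum separation {self.min_separation} µm — likely a "
                    "digitisation error"
                )

    def __len__(self) -> int:
        return len(self.landmarks)

    def __iter__(self):
        return iter(self.landmarks)

    def ids(self) -> list[str]:
        return [lm.id for lm in self.landmarks]

    def positions(self) -> np.ndarray:
        """(n, 3) array of positions, µm, in set order."""
        return points_to_array(lm.position for lm in self.landmarks)

    def get(self, landmark_id: str) -> Landmark:
        for lm in self.landmarks:
            if lm.id == landmark_id:
                return lm
        raise KeyError(landmark_id)

    def subset(self, ids: Iterable[str], name: str | None = None) -> "LandmarkSet":
        wanted = list(ids)
        index = {lm.id: lm for lm in self.landmarks}
        missing = [i for i in wanted if i not in index]
        if missing:
            raise ValidationError(f"unknown landmark ids: {missing}")
        return LandmarkSet(
            [index[i] for i in wanted],
            self.geometry,
            name=name if name is not None else self.name,
            min_separation=self.min_separation,
            nirb_surface_band=self.nirb_surface_band,
        )


#: Minimum pair counts per transform family (rigid/similarity need 3
#: non-collinear pairs, affine 4 non-coplanar, thin-plate spline 5).
MIN_PAIRS = {"rigid": 3, "similarity": 3, "affine": 4, "tps": 5}


@dataclass
class LandmarkPairing:
    """Ordered correspondences between a source (LM-frame) and a target
    (EM-frame) landmark set — the paired landmark-sets on which every
    registration is fitted."""

    source: LandmarkSet
    target: LandmarkSet
    pairs: list[tuple[str, str]]
    requires_review: bool = False
    unmatched_source: list[str] = field(default_factory=list)
    unmatched_target: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        src_used: set[str] = set()
        tgt_used: set[str] = set()
        for s, t in self.pairs:
            if s in src_used or t in tgt_used:
                raise PairingError(
                    f"pairing is not injective: ({s!r}, {t!r}) reuses an id"
                )
            src_used.add(s)
            tgt_used.add(t)
            self.source.get(s)  # raises KeyError on unknown ids
            self.target.get(t)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n(self) -> int:
        return len(self.pairs)

    def source_points(self) -> np.ndarray:
        return points_to_array(self.source.get(s).position for s, _ in self.pairs)

    def target_points(self) -> np.ndarray:
        return points_to_array(self.target.get(t).position for _, t in self.pairs)

    def drop(self, index: int) -> "LandmarkPairing":
        """Pairing with pair ``index`` held out (for leave-one-out analysis)."""
        pairs = [p for k, p in enumerate(self.pairs) if k != index]
        return LandmarkPairing(self.source, self.target, pairs)

    def require_min_pairs(self, method: str, extra: int = 0) -> None:
        need = MIN_PAIRS[method] + extra
        if self.n < need:
            raise PairingError(
                f"{method} fit requires at least {need} pairs, got {self.n}"
            )


def pair_by_id(source: LandmarkSet, target: LandmarkSet) -> LandmarkPairing:
    """Pair landmarks sharing an id in both sets, ordered by the source set.

    Ids present on only one side are recorded on the pairing
    (``unmatched_source`` / ``unmatched_target``), not silently dropped.
    """
    if len(source) == 0 or len(target) == 0:
        raise PairingError("both landmark sets must be non-empty")
    target_ids = set(target.ids())
    shared = [i for i in source.ids() if i in target_ids]
    if not shared:
        raise PairingError("no shared landmark ids between the two sets")
    return LandmarkPairing(
        source,
        target,
        [(i, i) for i in shared],
        unmatched_source=[i for i in source.ids() if i not in target_ids],
        unmatched_target=[i for i in target.ids() if i not in set(source.ids())],
    )
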