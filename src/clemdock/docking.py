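"""ROI docking: projecting the region of interest from the in-vivo frame
into the EM block frame, with a quantified accuracy estimate and sectioning
guidance.

The accuracy attached to a docking is the median leave-one-out docking
error of the transform family actually used, compared against a fixed
20 µm reference line — the order of magnitude at which single-structure
prediction inside a chemically processed block is realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, PairingError, ValidationError
from .geometry import (
    FeatureClass,
    LandmarkPairing,
    LandmarkSet,
    Point3,
    array_to_points,
    points_to_array,
)
from .registration import (
    RigidTransform,
    SpatialTransform,
    loo_docking_error,
)
from .sectioning import SectioningScheme

__all__ = [
    "ACCURACY_REFERENCE_UM",
    "RegionOfInterest",
    "DockingResult",
    "InPlaneAlignment",
    "SectionWindow",
    "dock_roi",
    "coarse_align_nirb",
    "depth_to_sections",
]

#: Reference targeting accuracy (µm): order-of-magnitude limit for predicting
#: one structure's position inside the processed block.
ACCURACY_REFERENCE_UM = 20.0

#: Default extrapolation margin as a fraction of the landmark bounding-box
#: diagonal; beyond it a TPS prediction is flagged (splines extrapolate poorly).
EXTRAPOLATION_MARGIN = 0.25


@dataclass
class RegionOfInterest:
    """A labelled set of LM-frame points to dock (e.g. a cell centroid plus
    optional outline points), µm."""

    label: str
    points: list[Point3]

    def __post_init__(self):
        if not self.points:
            raise ValidationError(f"ROI {self.label!r} has no points")

    def as_array(self) -> np.ndarray:
        return points_to_array(self.points)


@dataclass
class DockingResult:
    """Predicted EM-frame ROI points plus the accuracy bookkeeping used to
    plan sectioning around them."""

    label: str
    predicted_points: list[Point3]
    predicted_z_range: tuple[float, float]
    accuracy_estimate: float
    within_claimed_accuracy: bool
    transform_kind: str
    extrapolation_warning: bool = False
    loo_errors: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        zs = [p.z for p in self.predicted_points]
        lo, hi = self.predicted_z_range
        if abs(lo - min(zs)) > 1e-9 or abs(hi - max(zs)) > 1e-9:
            raise ValidationError("predicted_z_range must span the predicted points")
        if self.accuracy_estimate < 0:
            raise ValidationError("accuracy estimate must be ≥ 0")

    def summary(self) -> str:
        lines = [
            f"docking of ROI {self.label!r} ({self.transform_kind} transform)",
            f"  predicted z range   : {self.predicted_z_range[0]:.3f} – "
            f"{self.predicted_z_range[1]:.3f} µm",
            f"  accuracy (median LOO): {self.accuracy_estimate:.3f} µm",
            f"  within {ACCURACY_REFERENCE_UM:.0f} µm reference : "
            f"{'yes' if self.within_claimed_accuracy else 'no'}",
        ]
        if self.extrapolation_warning:
            lines.append(
                "  WARNING: ROI lies outside the landmark hull margin; the "
                "warp extrapolates there and the accuracy estimate may not hold"
            )
        for p in self.predicted_points:
            lines.append(f"    predicted point ({p.x:9.3f}, {p.y:9.3f}, {p.z:9.3f}) µm")
        return "\n".join(lines)


def _outside_hull_margin(roi_pts: np.ndarray, landmark_pts: np.ndarray,
                         margin_fraction: float) -> bool:
    lo = landmark_pts.min(axis=0)
    hi = landmark_pts.max(axis=0)
    diag = float(np.linalg.norm(hi - lo))
    pad = margin_fraction * diag
    return bool(((roi_pts < lo - pad) | (roi_pts > hi + pad)).any())


def dock_roi(
    transform: SpatialTransform,
    roi: RegionOfInterest,
    pairing: LandmarkPairing,
    regularization: float | None = None,
    extrapolation_margin: float = EXTRAPOLATION_MARGIN,
) -> DockingResult:
    """Project ``roi`` through ``transform`` into the EM frame.

    The attached accuracy estimate is the median leave-one-out docking error
    of the same transform family refitted on ``pairing``; ROI points beyond
    ``extrapolation_margin`` × (landmark bounding-box diagonal) outside the
    landmark hull only raise a warning flag — docking still runs.
    """
    if regularization is None:
        regularization = float(getattr(transform, "regularization", 0.0))
    loo = loo_docking_error(pairing, method=transform.kind, regularization=regularization)
    roi_arr = roi.as_array()
    predicted = transform.apply(roi_arr)
    zs = predicted[:, 2]
    return DockingResult(
        label=roi.label,
        predicted_points=array_to_points(predicted),
        predicted_z_range=(float(zs.min()), float(zs.max())),
        accuracy_estimate=loo.median,
        within_claimed_accuracy=bool(loo.median <= ACCURACY_REFERENCE_UM),
        transform_kind=transform.kind,
        extrapolation_warning=_outside_hull_margin(
            roi_arr, pairing.source_points(), extrapolation_margin
        ),
        loo_errors=loo.errors,
    )


@dataclass(frozen=True)
class InPlaneAlignment:
    """Surface-frame alignment from NIRB marks: in-plane rotation +
    xy-translation only.  NIRB marks pin down xy with high precision but
    carry no depth information, so the fitted z translation is 0 by
    construction; any residual z offset is reported, never corrected."""

    transform: RigidTransform
    residual_z_offset: float
    rms_xy: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.transform.apply(points)


def coarse_align_nirb(
    source_marks: LandmarkSet, target_marks: LandmarkSet
) -> InPlaneAlignment:
    """Fit translation + rotation about z from paired NIRB surface marks.

    Marks are paired by shared id; at least 2 pairs of NIRB_MARK landmarks
    are required.  Used to initialise pair suggestion, never for final
    docking depth.
    """
    def nirb_only(s: LandmarkSet) -> list[str]:
        return [lm.id for lm in s if lm.feature_class is FeatureClass.NIRB_MARK]

    src_ids = nirb_only(source_marks)
    tgt_ids = set(nirb_only(target_marks))
    shared = [i for i in src_ids if i in tgt_ids]
    if len(shared) < 2:
        raise PairingError(
            f"coarse NIRB alignment needs ≥ 2 paired NIRB_MARK landmarks, got {len(shared)}"
        )
    src = points_to_array(source_marks.get(i).position for i in shared)
    tgt = points_to_array(target_marks.get(i).position for i in shared)
    s2, t2 = src[:, :2], tgt[:, :2]
    cs, ct = s2.mean(axis=0), t2.mean(axis=0)
    h = (s2 - cs).T @ (t2 - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r2 = vt.T @ np.diag([1.0, d]) @ u.T
    t_xy = ct - r2 @ cs
    rotation = np.eye(3)
    rotation[:2, :2] = r2
    transform = RigidTransform(rotation, np.array([t_xy[0], t_xy[1], 0.0]))
    residuals = t2 - (s2 @ r2.T + t_xy)
    return InPlaneAlignment(
        transform=transform,
        residual_z_offset=float(np.mean(tgt[:, 2] - src[:, 2])),
        rms_xy=float(np.sqrt((residuals**2).sum(axis=1).mean())),
    )


@dataclass(frozen=True)
class SectionWindow:
    """The contiguous 1-based section index range that must be collected to
    cover a docked ROI, with the safety margin applied on both sides."""

    first_index: int
    last_index: int
    z_window: tuple[float, float]
    n_sections: int

    def indices(self) -> range:
        return range(self.first_index, self.last_index + 1)


def _section_at(scheme: SectioningScheme, z: float) -> int:
    """1-based section containing block depth z, with a depth exactly on a
    section boundary assigned to the deeper section."""
    bounds = scheme.boundaries()
    total = float(bounds[-1])
    if z < 0:
        raise CoverageError(f"depth {z:.3f} µm lies above the block face")
    if z >= total - 1e-9:
        if z <= total + 1e-9:
            return len(bounds)  # window ends exactly at the last deep face
        raise CoverageError(
            f"scheme too shallow: reaches {total:.3f} µm but {z:.3f} µm needed "
            f"({z - total:.3f} µm missing)"
        )
    # first section whose deep face exceeds z -> boundary goes deeper
    return int(np.searchsorted(bounds, z, side="right")) + 1


def depth_to_sections(
    docking: DockingResult,
    scheme: SectioningScheme,
    approach_offset: float = 0.0,
) -> SectionWindow:
    """Translate a docked z range into the section indices to collect.

    The window is ``[z_min − accuracy, z_max + accuracy] − approach_offset``
    (clipped at the block face): the safety margin on each side equals the
    docking's accuracy estimate.
    """
    acc = docking.accuracy_estimate
    z_lo = docking.predicted_z_range[0] - acc - approach_offset
    z_hi = docking.predicted_z_range[1] + acc - approach_offset
    if z_hi < 0:
        raise CoverageError(
            "predicted window lies entirely above the block face after the "
            f"approach offset ({z_hi:.3f} µm)"
        )
    z_lo = max(z_lo, 0.0)
    first = _section_at(scheme, z_lo)
    last = _section_at(scheme, z_hi)
    return SectionWindow(
        first_index=first,
        last_index=last,
        z_window=(z_lo, z_hi),
        n_sections=last - first + 1,
    )
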