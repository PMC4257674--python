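"""Point-set registration between paired landmark sets.

Four nested transform families are provided, mirroring the comparison a
CLEM targeting workflow needs:

* rigid — translation + rotation only (no deformation);
* similarity — rigid plus one global scale (first-order shrinkage/swelling
  from chemical fixation, e.g. the ~5% glutaraldehyde contraction);
* affine — arbitrary invertible linear part (anisotropic stretch/shear);
* thin-plate spline (TPS, the Bookstein warp) — affine part plus a radial
  bending term that interpolates every landmark exactly at λ = 0.

Rigid and similarity fits use the SVD (Kabsch/Umeyama) solution of the
orthogonal Procrustes problem with reflection correction.  The 3D TPS uses
the biharmonic kernel U(r) = r (sign-positive convention), solving the
standard (n+4)×(n+4) bordered linear system per output axis; λ ≥ 0 adds
λ·I to the kernel block (smoothing instead of interpolation).

All fits are deterministic — no random initialisation anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateConfigurationError, ValidationError
from .geometry import LandmarkPairing, Point3, array_to_points, points_to_array

logger = logging.getLogger("clemdock")

__all__ = [
    "RigidTransform",
    "SimilarityTransform",
    "AffineTransform",
    "TPSTransform",
    "SpatialTransform",
    "RegistrationReport",
    "LooResult",
    "fit_rigid",
    "fit_similarity",
    "fit_affine",
    "fit_tps",
    "fit_transform",
    "apply_transform",
    "residual_report",
    "loo_docking_error",
]

_ORTHO_TOL = 1e-8
_DEGENERACY_SV_RATIO = 1e-8
_CONDITION_WARN = 1e12


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValidationError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=1e-10):
        raise ValidationError("rotation matrix is not orthonormal")
    if np.linalg.det(rotation) < 0:
        raise ValidationError("rotation matrix has determinant -1 (reflection)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """Translation + proper rotation, µm."""

    rotation: np.ndarray
    translation: np.ndarray
    kind = "rigid"

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T
        return RigidTransform(r_inv, -r_inv @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class SimilarityTransform:
    """Global scale + rotation + translation."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray
    kind = "similarity"

    def __post_init__(self):
        if not self.scale > 0:
            raise ValidationError(f"similarity scale must be > 0, got {self.scale}")
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, dtype=float) @ self.rotation.T) + self.translation

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        return SimilarityTransform(
            1.0 / self.scale, r_inv, -(r_inv @ self.translation) / self.scale
        )


@dataclass(frozen=True)
class AffineTransform:
    """General invertible linear map + translation."""

    linear: np.ndarray
    translation: np.ndarray
    kind = "affine"

    def __post_init__(self):
        linear = np.asarray(self.linear, dtype=float)
        if linear.shape != (3, 3):
            raise ValidationError("affine linear part must be 3x3")
        if abs(np.linalg.det(linear)) <= 1e-12:
            raise ValidationError("affine linear part is (near-)singular")
        object.__setattr__(self, "linear", linear)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        l_inv = np.linalg.inv(self.linear)
        return AffineTransform(l_inv, -l_inv @ self.translation)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class TPSTransform:
    """3D thin-plate spline: affine part + radial bending term.

    f(x) = A·x + t + Σᵢ wᵢ · U(‖x − cᵢ‖) with kernel U(r) = r.

    Side conditions Σ wᵢ = 0 and Σ wᵢ cᵢ = 0 (per output axis) keep the
    warp bounded at infinity; with λ = 0 every control point maps exactly
    onto its paired target.
    """

    control_points: np.ndarray
    affine_part: AffineTransform
    warp_coefficients: np.ndarray
    regularization: float = 0.0
    control_ids: tuple[str, ...] | None = None
    kind = "tps"

    def __post_init__(self):
        c = np.asarray(self.control_points, dtype=float)
        w = np.asarray(self.warp_coefficients, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or w.shape != c.shape:
            raise ValidationError(
                "control_points and warp_coefficients must both be (n, 3)"
            )
        if self.regularization < 0:
            raise ValidationError("regularization λ must be ≥ 0")
        # side conditions guarantee bounded behaviour at infinity
        if len(c) and (
            np.abs(w.sum(axis=0)).max() > 1e-8
            or np.abs(c.T @ w).max() > 1e-6 * max(1.0, np.abs(c).max())
        ):
            raise ValidationError("TPS side conditions violated")
        object.__setattr__(self, "control_points", c)
        object.__setattr__(self, "warp_coefficients", w)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        kernel = cdist(pts, self.control_points)  # U(r) = r
        return self.affine_part.apply(pts) + kernel @ self.warp_coefficients

    def bending_energy(self) -> float:
        """Total bending energy Σ_axis −wᵀKw (non-negative for the U(r)=r
        kernel under the side conditions)."""
        k = cdist(self.control_points, self.control_points)
        return float(sum(-self.warp_coefficients[:, a] @ k @ self.warp_coefficients[:, a]
                         for a in range(3)))


SpatialTransform = Union[RigidTransform, SimilarityTransform, AffineTransform, TPSTransform]


def _centered_rank_check(points: np.ndarray, min_rank: int, what: str) -> None:
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0 or sv[min_rank - 1] / sv[0] < _DEGENERACY_SV_RATIO:
        raise DegenerateConfigurationError(
            f"landmark configuration is degenerate ({what}); the fit is not unique"
        )


def _pairing_arrays(pairing: LandmarkPairing, method: str, extra: int = 0):
    pairing.require_min_pairs(method, extra)
    return pairing.source_points(), pairing.target_points()


def _kabsch(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation between centred clouds; returns (R, singular values,
    reflection sign)."""
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    h = (src - cs).T @ (tgt - ct)
    u, sv, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d < 0:
        logger.warning(
            "optimal Procrustes solution is a reflection; corrected to a proper "
            "rotation — check for an axis flip between the two modalities"
        )
    signs = np.array([1.0, 1.0, d])
    rotation = vt.T @ np.diag(signs) @ u.T
    return rotation, sv, signs


def fit_rigid(pairing: LandmarkPairing) -> RigidTransform:
    """Least-squares rigid (translation + rotation) map source → target."""
    src, tgt = _pairing_arrays(pairing, "rigid")
    _centered_rank_check(src, 2, "collinear points")
    rotation, _, _ = _kabsch(src, tgt)
    translation = tgt.mean(axis=0) - rotation @ src.mean(axis=0)
    return RigidTransform(rotation, translation)


def fit_similarity(pairing: LandmarkPairing) -> SimilarityTransform:
    """Least-squares similarity (scale + rotation + translation) map
    (Umeyama solution)."""
    src, tgt = _pairing_arrays(pairing, "similarity")
    _centered_rank_check(src, 2, "collinear points")
    rotation, sv, signs = _kabsch(src, tgt)
    var_src = ((src - src.mean(axis=0)) ** 2).sum()
    scale = float((sv * signs).sum() / var_src)
    if scale <= 0:
        raise DegenerateConfigurationError("similarity fit produced non-positive scale")
    translation = tgt.mean(axis=0) - scale * (rotation @ src.mean(axis=0))
    return SimilarityTransform(scale, rotation, translation)


def fit_affine(pairing: LandmarkPairing) -> AffineTransform:
    """Least-squares affine map source → target."""
    src, tgt = _pairing_arrays(pairing, "affine")
    _centered_rank_check(src, 3, "coplanar points")
    design = np.hstack([src, np.ones((len(src), 1))])
    sol, *_ = np.linalg.lstsq(design, tgt, rcond=None)
    return AffineTransform(sol[:3].T, sol[3])


def _tps_system(control: np.ndarray, lam: float) -> np.ndarray:
    # U(r) = r is of negative type on the side-condition subspace, so the
    # smoothing term enters as K − λI (equivalently, kernel −r with +λI);
    # with K + λI the system can turn singular at intermediate λ.
    n = len(control)
    kernel = cdist(control, control)
    poly = np.hstack([np.ones((n, 1)), control])
    system = np.zeros((n + 4, n + 4))
    system[:n, :n] = kernel - lam * np.eye(n)
    system[:n, n:] = poly
    system[n:, :n] = poly.T
    return system


def fit_tps(pairing: LandmarkPairing, regularization: float = 0.0) -> TPSTransform:
    """Fit a 3D thin-plate spline (Bookstein warp) source → target.

    With ``regularization`` λ = 0 the spline interpolates: every paired
    landmark is forced to overlap exactly, which is how the EM-frame warp
    is meant to behave on clean landmark sets.  λ > 0 trades control-point
    fidelity for smoothness on noisy pairings.
    """
    if regularization < 0:
        raise ValidationError("regularization λ must be ≥ 0")
    src, tgt = _pairing_arrays(pairing, "tps")
    _centered_rank_check(src, 3, "all points coplanar")
    n = len(src)
    dists = cdist(src, src)
    close = np.argwhere((dists < 1e-9) & ~np.eye(n, dtype=bool))
    if len(close):
        i, j = close[0]
        ids = [s for s, _ in pairing.pairs]
        raise DegenerateConfigurationError(
            f"coincident source control points {ids[i]!r} and {ids[j]!r} "
            "make the TPS system singular"
        )
    system = _tps_system(src, regularization)
    cond = np.linalg.cond(system)
    if cond > _CONDITION_WARN:
        logger.warning(
            "TPS system is near-singular (condition ≈ %.2e); consider raising λ",
            cond,
        )
    rhs = np.vstack([tgt, np.zeros((4, 3))])
    sol = np.linalg.solve(system, rhs)
    warp = sol[:n]
    affine = AffineTransform(sol[n + 1 :].T, sol[n])
    return TPSTransform(
        control_points=src,
        affine_part=affine,
        warp_coefficients=warp,
        regularization=regularization,
        control_ids=tuple(s for s, _ in pairing.pairs),
    )


_FITTERS = {
    "rigid": fit_rigid,
    "similarity": fit_similarity,
    "affine": fit_affine,
    "tps": fit_tps,
}


def fit_transform(
    pairing: LandmarkPairing, method: str, regularization: float = 0.0
) -> SpatialTransform:
    """Dispatch to the fitter for ``method`` in
    {"rigid", "similarity", "affine", "tps"}."""
    if method not in _FITTERS:
        raise ValidationError(
            f"unknown method {method!r}; expected one of {sorted(_FITTERS)}"
        )
    if method == "tps":
        return fit_tps(pairing, regularization)
    return _FITTERS[method](pairing)


def apply_transform(
    transform: SpatialTransform, points: Sequence[Point3] | np.ndarray
):
    """Apply any fitted transform to points (µm), preserving input type and
    order: a list of :class:`Point3` comes back as such, an array as an
    array."""
    if isinstance(points, np.ndarray):
        return transform.apply(points)
    arr = points_to_array(points)
    return array_to_points(transform.apply(arr))


@dataclass(frozen=True)
class RegistrationReport:
    """Per-landmark offset vectors target − transform(source), their
    magnitudes, and summary statistics (all µm)."""

    offsets: np.ndarray
    magnitudes: np.ndarray
    rms: float
    max: float
    transform_kind: str
    n_pairs: int
    pair_ids: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.rms > self.max + 1e-12:
            raise ValidationError("RMS residual cannot exceed the max residual")

    def summary(self) -> str:
        lines = [
            f"registration residuals ({self.transform_kind}, {self.n_pairs} pairs)",
            f"  RMS residual : {self.rms:10.4f} µm",
            f"  max residual : {self.max:10.4f} µm",
        ]
        for (s, t), off, mag in zip(
            self.pair_ids or [("?", "?")] * self.n_pairs, self.offsets, self.magnitudes
        ):
            lines.append(
                f"  {s:>8s} -> {t:<8s} offset ({off[0]:+8.3f}, {off[1]:+8.3f}, "
                f"{off[2]:+8.3f}) |{mag:8.3f}| µm"
            )
        return "\n".join(lines)


def residual_report(
    transform: SpatialTransform, pairing: LandmarkPairing
) -> RegistrationReport:
    """Quantify how well ``transform`` overlays the paired landmarks."""
    src, tgt = pairing.source_points(), pairing.target_points()
    offsets = tgt - transform.apply(src)
    magnitudes = np.linalg.norm(offsets, axis=1)
    rms = float(np.sqrt((magnitudes**2).mean())) if len(magnitudes) else 0.0
    return RegistrationReport(
        offsets=offsets,
        magnitudes=magnitudes,
        rms=rms,
        max=float(magnitudes.max()) if len(magnitudes) else 0.0,
        transform_kind=transform.kind,
        n_pairs=pairing.n,
        pair_ids=tuple(pairing.pairs),
    )


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out docking errors: for each pair the transform is refitted
    without it and the held-out source landmark is predicted; the error is
    the distance to its true target position.  This is the package's proxy
    for how accurately an unseen ROI can be targeted."""

    errors: np.ndarray
    median: float
    max: float
    method: str
    regularization: float = 0.0

    def __len__(self):
        return len(self.errors)


def loo_docking_error(
    pairing: LandmarkPairing, method: str = "tps", regularization: float = 0.0
) -> LooResult:
    """Leave-one-out cross-validated prediction error per landmark (µm)."""
    if method not in _FITTERS:
        raise ValidationError(f"unknown method {method!r}")
    pairing.require_min_pairs(method, extra=1)
    src, tgt = pairing.source_points(), pairing.target_points()
    errors = np.empty(pairing.n)
    for i in range(pairing.n):
        sub = pairing.drop(i)
        transform = fit_transform(sub, method, regularization)
        predicted = transform.apply(src[i : i + 1])[0]
        errors[i] = float(np.linalg.norm(predicted - tgt[i]))
    return LooResult(
        errors=errors,
        median=float(np.median(errors)),
        max=float(errors.max()),
        method=method,
        regularization=regularization,
    )
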