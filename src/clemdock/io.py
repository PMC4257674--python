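"""Tabular and structured-text I/O.

Landmark tables are UTF-8 comma- or tab-delimited text with header
``id,x_um,y_um,z_um,feature_class,confidence`` (confidence optional,
default 1.0); ``#``-prefixed lines are comments.  Fiber tables list
ordered polyline vertices as ``fiber_id,x_um,y_um,z_um`` rows.
Transforms and sectioning schemes serialize to small YAML documents.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError
from .geometry import (
    FeatureClass,
    Landmark,
    LandmarkSet,
    Point3,
    VolumeGeometry,
)

logger = logging.getLogger("clemdock")

_LANDMARK_COLUMNS = ("id", "x_um", "y_um", "z_um", "feature_class", "confidence")


def _split_table_line(line: str, delimiter: str) -> list[str]:
    return [c.strip() for c in line.rstrip("\n").split(delimiter)]


def _detect_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_landmarks(
    path: str | Path,
    geometry: VolumeGeometry | None = None,
    name: str | None = None,
) -> LandmarkSet:
    """Read a landmark table into a validated :class:`LandmarkSet`.

    Unknown feature classes are mapped to ``OTHER`` with a logged warning.
    If ``geometry`` is omitted a loose bounding geometry at 1 µm spacing is
    attached (the table already carries physical µm coordinates).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    header_idx = None
    for idx, line in enumerate(lines):
        if line.strip() and not line.lstrip().startswith("#"):
            header_idx = idx
            break
    if header_idx is None:
        raise FormatError(f"{path}: empty landmark table")
    delimiter = _detect_delimiter(lines[header_idx])
    header = _split_table_line(lines[header_idx], delimiter)
    if header[:4] != list(_LANDMARK_COLUMNS[:4]):
        raise FormatError(
            f"{path}: expected header starting with "
            f"{','.join(_LANDMARK_COLUMNS[:4])}, got {lines[header_idx]!r}"
        )
    col = {c: i for i, c in enumerate(header)}

    landmarks: list[Landmark] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = _split_table_line(line, delimiter)
        if len(cells) < 4:
            raise FormatError(f"{path}:{lineno}: expected at least 4 columns")
        lm_id = cells[col["id"]]
        if lm_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate landmark id {lm_id!r}")
        seen.add(lm_id)
        coords = []
        for axis in ("x_um", "y_um", "z_um"):
            raw = cells[col[axis]]
            try:
                coords.append(float(raw))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric {axis} value {raw!r}"
                ) from None
        fc = FeatureClass.OTHER
        if "feature_class" in col and len(cells) > col["feature_class"]:
            raw_fc = cells[col["feature_class"]]
            if raw_fc:
                try:
                    fc = FeatureClass(raw_fc)
                except ValueError:
                    logger.warning(
                        "%s:%d: unknown feature_class %r mapped to OTHER",
                        path,
                        lineno,
                        raw_fc,
                    )
        confidence = 1.0
        if "confidence" in col and len(cells) > col["confidence"] and cells[col["confidence"]]:
            raw_c = cells[col["confidence"]]
            try:
                confidence = float(raw_c)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric confidence {raw_c!r}"
                ) from None
        landmarks.append(Landmark(lm_id, Point3(*coords), fc, confidence))

    if geometry is None:
        coords_arr = (
            np.array([[lm.position.x, lm.position.y, lm.position.z] for lm in landmarks])
            if landmarks
            else np.zeros((1, 3))
        )
        geometry = VolumeGeometry.bounding(coords_arr)
    return LandmarkSet(landmarks, geometry, name=name if name is not None else path.stem)


def write_landmarks(path: str | Path, landmark_set: LandmarkSet, delimiter: str = ",") -> None:
    """Write a landmark table; float formatting round-trips exactly."""
    path = Path(path)
    rows = [delimiter.join(_LANDMARK_COLUMNS)]
    for lm in landmark_set:
        rows.append(
            delimiter.join(
                [
                    lm.id,
                    repr(lm.position.x),
                    repr(lm.position.y),
                    repr(lm.position.z),
                    lm.feature_class.value,
                    repr(lm.confidence),
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_fibers(path: str | Path) -> list[np.ndarray]:
    """Read a multi-polyline fiber table (``fiber_id,x_um,y_um,z_um`` rows)
    into a list of (k, 3) vertex arrays ordered by first appearance."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    chains: dict[str, list[list[float]]] = {}
    order: list[str] = []
    header_seen = False
    delimiter = ","
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if not header_seen:
            delimiter = _detect_delimiter(line)
            cells = _split_table_line(line, delimiter)
            if cells[:4] != ["fiber_id", "x_um", "y_um", "z_um"]:
                raise FormatError(
                    f"{path}:{lineno}: expected header fiber_id,x_um,y_um,z_um"
                )
            header_seen = True
            continue
        cells = _split_table_line(line, delimiter)
        if len(cells) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        fid = cells[0]
        try:
            vertex = [float(c) for c in cells[1:4]]
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
        if fid not in chains:
            chains[fid] = []
            order.append(fid)
        chains[fid].append(vertex)
    polylines = [np.array(chains[fid], dtype=float) for fid in order]
    for fid, poly in zip(order, polylines):
        if len(poly) < 2:
            raise FormatError(f"{path}: fiber {fid!r} has fewer than 2 vertices")
    return polylines


def write_fibers(path: str | Path, polylines: list[np.ndarray]) -> None:
    rows = ["fiber_id,x_um,y_um,z_um"]
    for k, poly in enumerate(polylines, start=1):
        for v in np.asarray(poly, dtype=float):
            rows.append(f"F{k},{float(v[0])!r},{float(v[1])!r},{float(v[2])!r}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


# --- transform serialization -------------------------------------------------

def save_transform(path: str | Path, transform, metadata: dict | None = None) -> None:
    """Serialize a fitted transform to a YAML file for reuse when docking."""
    from . import __version__
    from .registration import (
        AffineTransform,
        RigidTransform,
        SimilarityTransform,
        TPSTransform,
    )

    doc: dict = {"kind": transform.kind, "tool_version": __version__}
    if metadata:
        doc["metadata"] = metadata
    if isinstance(transform, RigidTransform):
        doc["rotation"] = transform.rotation.tolist()
        doc["translation"] = transform.translation.tolist()
    elif isinstance(transform, SimilarityTransform):
        doc["scale"] = float(transform.scale)
        doc["rotation"] = transform.rotation.tolist()
        doc["translation"] = transform.translation.tolist()
    elif isinstance(transform, AffineTransform):
        doc["linear"] = transform.linear.tolist()
        doc["translation"] = transform.translation.tolist()
    elif isinstance(transform, TPSTransform):
        doc["control_points"] = transform.control_points.tolist()
        doc["warp_coefficients"] = transform.warp_coefficients.tolist()
        doc["affine"] = {
            "linear": transform.affine_part.linear.tolist(),
            "translation": transform.affine_part.translation.tolist(),
        }
        doc["regularization"] = float(transform.regularization)
        doc["control_ids"] = list(transform.control_ids or [])
    else:  # pragma: no cover - defensive
        raise FormatError(f"cannot serialize transform of type {type(transform)!r}")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_transform(path: str | Path):
    from .registration import (
        AffineTransform,
        RigidTransform,
        SimilarityTransform,
        TPSTransform,
    )

    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    kind = doc.get("kind")
    if kind == "rigid":
        return RigidTransform(np.array(doc["rotation"]), np.array(doc["translation"]))
    if kind == "similarity":
        return SimilarityTransform(
            float(doc["scale"]), np.array(doc["rotation"]), np.array(doc["translation"])
        )
    if kind == "affine":
        return AffineTransform(np.array(doc["linear"]), np.array(doc["translation"]))
    if kind == "tps":
        affine = AffineTransform(
            np.array(doc["affine"]["linear"]), np.array(doc["affine"]["translation"])
        )
        return TPSTransform(
            control_points=np.array(doc["control_points"]),
            affine_part=affine,
            warp_coefficients=np.array(doc["warp_coefficients"]),
            regularization=float(doc.get("regularization", 0.0)),
            control_ids=tuple(doc.get("control_ids") or ()) or None,
        )
    raise FormatError(f"{path}: unknown transform kind {kind!r}")
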