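"""Serial-sectioning depth arithmetic.

A :class:`SectioningScheme` describes how a resin block is cut from the
block face downward: an ordered list of section blocks (count × thickness,
each of one of the three modes used in practice — 500 nm thick sections for
LM overview, 60 nm thin sections for TEM, ~240–300 nm semi-thick sections
for tomography) followed by an optional periodic unit repeated a fixed
number of times.  Depth intervals are half-open ``(z_start, z_end]`` µm
from the block face; consecutive sections abut exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError, RangeError, ValidationError

__all__ = [
    "SectionKind",
    "SchemeBlock",
    "SectioningScheme",
    "alternating_series_scheme",
    "uniform_scheme",
    "sections_covering",
    "save_scheme",
    "load_scheme",
]


class SectionKind(str, Enum):
    THICK_LM = "THICK_LM"          # ~500 nm, toluidine-blue stained, glass slide
    THIN_EM = "THIN_EM"            # ~60 nm, slot grid, TEM
    SEMITHICK_TOMO = "SEMITHICK_TOMO"  # ~240-300 nm, electron tomography


@dataclass(frozen=True)
class SchemeBlock:
    count: int
    thickness_nm: float
    kind: SectionKind

    def __post_init__(self):
        if int(self.count) < 1:
            raise ValidationError(f"block count must be ≥ 1, got {self.count}")
        if not self.thickness_nm > 0:
            raise ValidationError(f"thickness must be > 0 nm, got {self.thickness_nm}")


@dataclass
class SectioningScheme:
    """Ordered section blocks plus an optional trailing periodic unit.

    ``thickness_scale`` (default 1.0) uniformly rescales nominal thicknesses,
    exposed for calibration against measured cutting feed.
    """

    blocks: list[SchemeBlock]
    repeat_unit: list[SchemeBlock] = field(default_factory=list)
    repeat_count: int = 0
    thickness_scale: float = 1.0

    def __post_init__(self):
        if self.repeat_count < 0:
            raise ValidationError("repeat_count must be ≥ 0")
        if self.repeat_count > 0 and not self.repeat_unit:
            raise ValidationError("repeat_count > 0 requires a repeat unit")
        if not self.thickness_scale > 0:
            raise ValidationError("thickness_scale must be > 0")
        if not self.blocks and not (self.repeat_unit and self.repeat_count):
            raise ValidationError("scheme has no sections")

    def _expanded(self) -> tuple[np.ndarray, list[SectionKind]]:
        thick_um: list[float] = []
        kinds: list[SectionKind] = []
        series = list(self.blocks) + list(self.repeat_unit) * self.repeat_count
        for block in series:
            thick_um.extend([block.thickness_nm * self.thickness_scale / 1000.0] * int(block.count))
            kinds.extend([block.kind] * int(block.count))
        return np.array(thick_um), kinds

    @property
    def n_sections(self) -> int:
        return int(sum(int(b.count) for b in self.blocks)
                   + self.repeat_count * sum(int(b.count) for b in self.repeat_unit))

    @property
    def total_depth(self) -> float:
        """Cumulative depth of the whole scheme, µm."""
        thick, _ = self._expanded()
        return float(thick.sum())

    def boundaries(self) -> np.ndarray:
        """Cumulative deep-face depths, µm; boundaries[k] is the deep face of
        1-based section k+1... i.e. boundaries = cumsum(thicknesses)."""
        thick, _ = self._expanded()
        return np.cumsum(thick)

    def depth_of(self, section_index: int) -> tuple[float, float]:
        """Half-open physical interval ``(z_start, z_end]`` of a 1-based
        section index, µm from the block face."""
        n = self.n_sections
        if not (1 <= section_index <= n):
            raise RangeError(
                f"section index {section_index} out of range; scheme has {n} sections"
            )
        bounds = self.boundaries()
        z_end = float(bounds[section_index - 1])
        z_start = float(bounds[section_index - 2]) if section_index > 1 else 0.0
        return z_start, z_end

    def kind_of(self, section_index: int) -> SectionKind:
        _, kinds = self._expanded()
        if not (1 <= section_index <= len(kinds)):
            raise RangeError(
                f"section index {section_index} out of range; scheme has "
                f"{len(kinds)} sections"
            )
        return kinds[section_index - 1]

    def table(self) -> list[tuple[int, float, float, str]]:
        """Per-section (index, z_start, z_end, kind) rows."""
        thick, kinds = self._expanded()
        bounds = np.cumsum(thick)
        rows = []
        z0 = 0.0
        for i, (z1, kind) in enumerate(zip(bounds, kinds), start=1):
            rows.append((i, z0, float(z1), kind.value))
            z0 = float(z1)
        return rows


def uniform_scheme(count: int, thickness_nm: float,
                   kind: SectionKind = SectionKind.SEMITHICK_TOMO) -> SectioningScheme:
    return SectioningScheme([SchemeBlock(count, thickness_nm, kind)])


def alternating_series_scheme(
    approach_count: int,
    n_series: int = 10,
    thin_per_series: int = 10,
    thin_nm: float = 60.0,
    thick_per_series: int = 2,
    thick_nm: float = 500.0,
) -> SectioningScheme:
    """The alternating LM/EM strategy: an approach run of 500 nm thick
    sections, then periodic series of thin EM sections interleaved with
    thick LM correlation sections (defaults: 10 series of 10 × 60 nm thin
    + 2 × 500 nm thick)."""
    if approach_count < 0:
        raise ValidationError("approach_count must be ≥ 0")
    blocks = []
    if approach_count:
        blocks.append(SchemeBlock(approach_count, thick_nm, SectionKind.THICK_LM))
    repeat = [
        SchemeBlock(thin_per_series, thin_nm, SectionKind.THIN_EM),
        SchemeBlock(thick_per_series, thick_nm, SectionKind.THICK_LM),
    ]
    return SectioningScheme(blocks, repeat_unit=repeat, repeat_count=n_series)


def sections_covering(z_range: tuple[float, float], thickness_nm: float) -> int:
    """Minimum number of sections of the given nominal thickness needed to
    cover a depth window (µm): ceil(window length / thickness)."""
    z_lo, z_hi = z_range
    if not z_hi > z_lo:
        raise ValidationError(f"inverted or degenerate z range {z_range}")
    if not thickness_nm > 0:
        raise ValidationError("thickness must be > 0 nm")
    length_nm = (z_hi - z_lo) * 1000.0
    # tiny slack absorbs binary-float noise in exactly divisible windows
    return int(math.ceil(length_nm / thickness_nm - 1e-9))


def save_scheme(path: str | Path, scheme: SectioningScheme) -> None:
    def block_doc(b: SchemeBlock) -> dict:
        return {"count": int(b.count), "thickness_nm": float(b.thickness_nm),
                "kind": b.kind.value}

    doc = {
        "blocks": [block_doc(b) for b in scheme.blocks],
        "repeat_unit": [block_doc(b) for b in scheme.repeat_unit],
        "repeat_count": int(scheme.repeat_count),
        "thickness_scale": float(scheme.thickness_scale),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_scheme(path: str | Path) -> SectioningScheme:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        blocks = [
            SchemeBlock(int(b["count"]), float(b["thickness_nm"]), SectionKind(b["kind"]))
            for b in doc.get("blocks", [])
        ]
        repeat = [
            SchemeBlock(int(b["count"]), float(b["thickness_nm"]), SectionKind(b["kind"]))
            for b in doc.get("repeat_unit", [])
        ]
        return SectioningScheme(
            blocks,
            repeat_unit=repeat,
            repeat_count=int(doc.get("repeat_count", 0)),
            thickness_scale=float(doc.get("thickness_scale", 1.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed scheme file ({exc})") from exc
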