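"""Vessel segment identities for the circle of Willis and its major branches.

The unit of analysis throughout the package is one vessel segment of one
examination: the basilar artery (midline) plus the sided posterior cerebral
(P1+P2 pooled), internal carotid, M1, frontal and temporal M2 branches, and
the A1 and A2 anterior cerebral segments.  The vertebral artery is
deliberately not a valid segment: its caliber varies too much between sides
and individuals for a per-class severity threshold to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

SEGMENT_CLASSES: tuple[str, ...] = (
    "BA",
    "PCA",
    "ICA",
    "M1",
    "M2_frontal",
    "M2_temporal",
    "A1",
    "A2",
)

#: Classes the pipeline explicitly refuses (no threshold is ever calibrated).
REJECTED_CLASSES: frozenset[str] = frozenset({"VA", "vertebral", "vertebral_artery"})

SIDES: tuple[str, ...] = ("left", "right", "midline")

#: Classes that exist once per exam, on the midline.
MIDLINE_CLASSES: frozenset[str] = frozenset({"BA"})


class UnknownSegmentError(ValueError):
    """Raised for a segment class outside the supported vessel list."""


@dataclass(frozen=True, order=True)
class SegmentId:
    """One vessel segment slot: an anatomical class plus a side.

    ``BA`` is midline; every other class is ``left`` or ``right``.  Left and
    right slots of the same class are distinct segments (bilateral spasm of
    one class counts twice toward any multi-segment criterion).
    """

    seg_class: str
    side: str

    def __post_init__(self) -> None:
        if self.seg_class in REJECTED_CLASSES:
            raise UnknownSegmentError(
                f"segment class {self.seg_class!r} is not supported: no threshold "
                "is defined for the vertebral artery"
            )
        if self.seg_class not in SEGMENT_CLASSES:
            raise UnknownSegmentError(f"unknown segment class {self.seg_class!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.seg_class in MIDLINE_CLASSES and self.side != "midline":
            raise ValueError(f"{self.seg_class} is a midline vessel, got side {self.side!r}")
        if self.seg_class not in MIDLINE_CLASSES and self.side == "midline":
            raise ValueError(f"{self.seg_class} is a sided vessel, got side 'midline'")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.seg_class}/{self.side}"


def iter_segment_ids() -> Iterator[SegmentId]:
    """All 15 per-exam segment slots (1 midline BA + 7 sided classes x 2)."""
    for seg_class in SEGMENT_CLASSES:
        if seg_class in MIDLINE_CLASSES:
            yield SegmentId(seg_class, "midline")
        else:
            yield SegmentId(seg_class, "left")
            yield SegmentId(seg_class, "right")


ALL_SEGMENT_IDS: tuple[SegmentId, ...] = tuple(iter_segment_ids())
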