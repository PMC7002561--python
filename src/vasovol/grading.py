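"""Decision rules: per-segment severity, k-of-n CTA criteria, CTP flag.

The DSA grading scale is 0 (no vasospasm), 1 (<50% diameter change) and 2
(>50% narrowing); grade 2 is "severe".  On CTA a segment is called severe
when its volume/length ratio falls *strictly below* the class threshold
(boundary equality is not severe).  An examination's CTA is pathological
under the k-segment criterion when at least k measured segments (left and
right counted separately) are severe.  CTP is summarized by a hypoperfusion
flag: any graded region scoring other than 0.  The combined criterion
requires both a pathological CTA and the CTP flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime

from .calibration import SegmentThreshold
from .segments import SegmentId

DSA_GRADES = (0, 1, 2)
SEVERE_GRADE = 2

CTP_REGIONS: tuple[str, ...] = (
    "frontal",
    "temporal",
    "parietal",
    "occipital",
    "thalamus",
    "basal_ganglia",
    "insula",
)
CTP_SIDES = ("left", "right")


class GradingError(ValueError):
    pass


@dataclass(frozen=True)
class DsaGrade:
    """Catheter-angiography vasospasm grade for one segment."""

    segment: SegmentId
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in DSA_GRADES:
            raise GradingError(f"DSA grade must be in {DSA_GRADES}, got {self.grade}")

    @property
    def severe(self) -> bool:
        return self.grade == SEVERE_GRADE


@dataclass(frozen=True)
class RatioObservation:
    """A segment's volume/length ratio when volume and length are not kept."""

    segment: SegmentId
    ratio: float

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise GradingError(f"ratio must be > 0, got {self.ratio}")


@dataclass
class CtpAssessment:
    """Per-region perfusion grades: 0 normal, 1 abnormal.

    Regions are graded per side (14 gradeable slots over 7 anatomical
    regions); ``grades`` maps ``(region, side)`` to 0/1.  An ungraded slot is
    simply absent.
    """

    grades: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (region, side), grade in self.grades.items():
            if region not in CTP_REGIONS:
                raise GradingError(f"unknown CTP region {region!r}")
            if side not in CTP_SIDES:
                raise GradingError(f"CTP region side must be left/right, got {side!r}")
            if grade not in (0, 1):
                raise GradingError(f"CTP grade must be 0 or 1, got {grade}")


@dataclass
class ExaminationRecord:
    """One CTA examination: measured ratios plus optional DSA, CTP and outcome."""

    patient_id: str
    exam_id: str
    timestamp: str | None = None
    ratios: dict[SegmentId, float] = field(default_factory=dict)
    dsa_grades: dict[SegmentId, int] = field(default_factory=dict)
    ctp: CtpAssessment | None = None
    treated_within_24h: bool | None = None


def classify_segment(measurement, threshold: SegmentThreshold) -> bool:
    """True iff the segment is severe on CTA: ratio strictly below the cutoff.

    ``measurement`` needs ``.segment`` and ``.ratio`` attributes (a
    :class:`~vasovol.recon.SegmentMeasurement` or :class:`RatioObservation`);
    its class must match the threshold's.
    """
    if measurement.segment.seg_class != threshold.segment_class:
        raise GradingError(
            f"segment class mismatch: measurement {measurement.segment.seg_class} "
            f"vs threshold {threshold.segment_class}"
        )
    return measurement.ratio < threshold.threshold


def count_spastic_segments(
    exam: ExaminationRecord, thresholds: dict[str, SegmentThreshold]
) -> int:
    """Number of measured (class, side) slots classified severe on CTA.

    Left and right are counted separately.  Measurements of a class without
    a threshold do not contribute (warned once per call); unmeasured
    segments simply do not count.
    """
    count = 0
    missing: set[str] = set()
    for seg, ratio in exam.ratios.items():
        t = thresholds.get(seg.seg_class)
        if t is None:
            missing.add(seg.seg_class)
            continue
        if classify_segment(RatioObservation(seg, ratio), t):
            count += 1
    if missing:
        warnings.warn(
            f"exam {exam.exam_id}: no threshold for {sorted(missing)}; excluded",
            stacklevel=2,
        )
    return count


def cta_pathological(
    exam: ExaminationRecord, thresholds: dict[str, SegmentThreshold], k: int
) -> bool:
    """k-segment criterion: at least k segments below their thresholds."""
    if k not in (1, 2, 3):
        raise GradingError(f"k must be 1, 2 or 3, got {k}")
    return count_spastic_segments(exam, thresholds) >= k


def ctp_hypoperfusion(assessment: CtpAssessment) -> bool:
    """True iff any graded region scores other than 0 (cerebral hypoperfusion)."""
    if not assessment.grades:
        raise GradingError("no CTP regions graded")
    return any(g != 0 for g in assessment.grades.values())


def combined_positive(
    exam: ExaminationRecord, thresholds: dict[str, SegmentThreshold], k: int
) -> bool:
    """CTA-and-CTP criterion: pathological CTA (k segments) AND hypoperfusion."""
    if exam.ctp is None:
        raise GradingError(f"exam {exam.exam_id} has no CTP assessment")
    return cta_pathological(exam, thresholds, k) and ctp_hypoperfusion(exam.ctp)


def treated_within_24h(cta_time: datetime, treatment_start: datetime) -> bool:
    """Outcome gold standard: endovascular treatment started within the
    closed interval [0 h, 24 h] after the CTA acquisition."""
    delta = (treatment_start - cta_time).total_seconds()
    return 0.0 <= delta <= 24.0 * 3600.0
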