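"""Readers and writers for the pipeline's file formats.

Cohort tables are long-format CSV mixing two row kinds: segment rows
(``segment_class, side, ratio_uL_per_mm`` with an optional ``dsa_grade``)
and CTP-region rows (``ctp_region, side, ctp_grade``).  Thresholds travel
as JSON; volumes as NIfTI with the voxel spacing in the header; landmarks
as JSON.  All readers validate field-by-field and name the first offending
row.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .calibration import SegmentThreshold, threshold_to_dict
from .grading import CTP_REGIONS, CtpAssessment, ExaminationRecord
from .recon import ImageVolume, SegmentMeasurement
from .segments import SegmentId, UnknownSegmentError

COHORT_COLUMNS = (
    "patient_id",
    "exam_id",
    "timestamp",
    "segment_class",
    "side",
    "ratio_uL_per_mm",
    "dsa_grade",
    "ctp_region",
    "ctp_grade",
    "treated_within_24h",
)


class CohortFormatError(ValueError):
    """Raised with the row index and column of the first violation."""


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == ""


def _parse_bool(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise CohortFormatError(f"row {row}: treated_within_24h must be boolean, got {value!r}")


def read_cohort(path) -> list[ExaminationRecord]:
    """Parse and validate a cohort CSV into examination records."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(COHORT_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise CohortFormatError(f"cohort CSV missing columns: {sorted(missing)}")
    records: dict[tuple[str, str], ExaminationRecord] = {}
    for i, row in df.iterrows():
        key = (row["patient_id"], row["exam_id"])
        rec = records.get(key)
        if rec is None:
            rec = records[key] = ExaminationRecord(
                patient_id=row["patient_id"],
                exam_id=row["exam_id"],
                timestamp=row.get("timestamp") or None,
            )
        if "treated_within_24h" in df.columns and not _is_blank(row["treated_within_24h"]):
            rec.treated_within_24h = _parse_bool(row["treated_within_24h"], i)

        if not _is_blank(row.get("segment_class", "")):
            try:
                seg = SegmentId(row["segment_class"].strip(), row["side"].strip())
            except (UnknownSegmentError, ValueError) as err:
                raise CohortFormatError(f"row {i}, column segment_class/side: {err}") from None
            try:
                ratio = float(row["ratio_uL_per_mm"])
            except ValueError:
                raise CohortFormatError(
                    f"row {i}, column ratio_uL_per_mm: not a number "
                    f"({row['ratio_uL_per_mm']!r})"
                ) from None
            if not ratio > 0:
                raise CohortFormatError(
                    f"row {i}, column ratio_uL_per_mm: ratio must be > 0, got {ratio}"
                )
            if seg in rec.ratios:
                raise CohortFormatError(f"row {i}: duplicate segment {seg} in exam {rec.exam_id}")
            rec.ratios[seg] = ratio
            if not _is_blank(row.get("dsa_grade", "")):
                try:
                    grade = int(row["dsa_grade"])
                except ValueError:
                    grade = -1
                if grade not in (0, 1, 2):
                    raise CohortFormatError(
                        f"row {i}, column dsa_grade: must be 0, 1 or 2, got {row['dsa_grade']!r}"
                    )
                rec.dsa_grades[seg] = grade
        elif not _is_blank(row.get("ctp_region", "")):
            region = row["ctp_region"].strip()
            side = row["side"].strip()
            if region not in CTP_REGIONS:
                raise CohortFormatError(f"row {i}, column ctp_region: unknown region {region!r}")
            try:
                grade = int(row["ctp_grade"])
            except ValueError:
                grade = -1
            if grade not in (0, 1):
                raise CohortFormatError(
                    f"row {i}, column ctp_grade: must be 0 or 1, got {row['ctp_grade']!r}"
                )
            if rec.ctp is None:
                rec.ctp = CtpAssessment({})
            rec.ctp.grades[(region, side)] = grade
        else:
            raise CohortFormatError(
                f"row {i}: neither a segment row nor a CTP row (both class and region blank)"
            )
    return list(records.values())


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Thresholds


def write_thresholds(thresholds: list[SegmentThreshold], path) -> None:
    Path(path).write_text(
        json.dumps([threshold_to_dict(t) for t in thresholds], indent=2) + "\n"
    )


def read_thresholds(path) -> list[SegmentThreshold]:
    """Round-trip counterpart of :func:`write_thresholds`, with validation."""
    try:
        rows = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed thresholds JSON: {err}") from None
    if not isinstance(rows, list):
        raise ValueError("thresholds JSON must be a list of objects")
    return [SegmentThreshold(**row) for row in rows]


# ---------------------------------------------------------------------------
# Volumes (NIfTI)


def save_volume(volume: ImageVolume, path) -> None:
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine), str(path))


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(voxels=np.asarray(img.dataobj, dtype=np.float64), spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# Landmarks and measurements


@dataclass(frozen=True)
class LandmarkPair:
    """Start/end world coordinates (mm) bounding one vessel segment."""

    segment: SegmentId
    start_xyz_mm: tuple[float, float, float]
    end_xyz_mm: tuple[float, float, float]
    fetal_pca: bool = False


def read_landmarks(path) -> list[LandmarkPair]:
    rows = json.loads(Path(path).read_text())
    out = []
    for row in rows:
        out.append(
            LandmarkPair(
                segment=SegmentId(row["segment_class"], row["side"]),
                start_xyz_mm=tuple(float(v) for v in row["start_xyz_mm"]),
                end_xyz_mm=tuple(float(v) for v in row["end_xyz_mm"]),
                fetal_pca=bool(row.get("fetal_pca", False)),
            )
        )
    return out


def measurements_to_dataframe(
    measurements: list[SegmentMeasurement], patient_id: str = "", exam_id: str = ""
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": patient_id,
                "exam_id": exam_id,
                "segment_class": m.segment.seg_class,
                "side": m.segment.side,
                "volume_uL": m.volume,
                "length_mm": m.length,
                "ratio_uL_per_mm": m.ratio,
            }
            for m in measurements
        ]
    )
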