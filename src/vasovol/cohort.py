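"""Synthetic surveillance cohorts with known narrowing ground truth.

The simulator emulates the statistical structure of a post-SAH vasospasm
surveillance cohort: each examination carries 15 segment slots whose healthy
volume/length ratios are log-normal per class; a spastic segment's diameter
is reduced by a fraction d, scaling its observed ratio by (1-d)^2 (the
ratio is a mean cross-sectional area); the DSA grade is 2 iff d > 0.5 and 1
for milder narrowing; the CTP hypoperfusion flag and the
treatment-within-24-h outcome are drawn from configurable conditional
probabilities linked to the severity of narrowing.  Everything is
reproducible from a single seed, and a hidden-truth table in the same
schema as the consumable cohort CSV accompanies every draw.

``synthetic_cohort_from_cells`` builds a deterministic fixture cohort from a
joint count table over (severe-segment count, CTP flag, treated flag), used
to exercise the evaluation stack against known contingency tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import SegmentThreshold
from .grading import CTP_REGIONS, CTP_SIDES, CtpAssessment, ExaminationRecord
from .segments import ALL_SEGMENT_IDS, SEGMENT_CLASSES, SegmentId


class CohortSimError(ValueError):
    pass


#: Healthy per-class median ratios (uL/mm) used as simulator defaults.  They
#: sit roughly at twice the calibrated severity thresholds, i.e. plausible
#: unspastic calibers; they are placeholders with the right ordering and
#: scale, not estimates of any clinical cohort.
DEFAULT_BASELINE_MEDIANS: dict[str, float] = {
    "BA": 8.5,
    "PCA": 2.5,
    "ICA": 16.0,
    "M1": 9.0,
    "M2_frontal": 3.5,
    "M2_temporal": 5.5,
    "A1": 4.5,
    "A2": 3.5,
}


def _default_locations() -> dict[str, float]:
    return {c: math.log(m) for c, m in DEFAULT_BASELINE_MEDIANS.items()}


def _default_scales() -> dict[str, float]:
    return {c: 0.25 for c in SEGMENT_CLASSES}


def _default_p_hypo() -> dict[int, float]:
    p = {0: 0.10, 1: 0.35, 2: 0.55, 3: 0.75}
    p.update({k: 0.85 for k in range(4, len(ALL_SEGMENT_IDS) + 1)})
    return p


def _default_p_treat() -> dict[tuple[bool, bool], float]:
    return {
        (False, False): 0.02,
        (False, True): 0.30,
        (True, False): 0.15,
        (True, True): 0.70,
    }


@dataclass(frozen=True)
class CohortSimConfig:
    """Generative settings for a synthetic surveillance cohort.

    ``baseline_ratio_location``/``_scale`` are per-class log-scale
    parameters of the healthy ratio distribution (uL/mm).  A segment is
    spastic with probability ``spasm_prevalence``; its diameter reduction d
    is uniform on ``diameter_reduction_range``.  ``measurement_noise_cv`` is
    the coefficient of variation of mean-one multiplicative log-normal
    measurement noise.  The CTP flag is Bernoulli with probability keyed on
    the exam's count of truly severe (d > 0.5) segments; the treatment flag
    is keyed on (any-severe-segment, CTP flag).
    """

    n_patients: int = 20
    exams_per_patient: int = 3
    baseline_ratio_location: dict[str, float] = field(default_factory=_default_locations)
    baseline_ratio_scale: dict[str, float] = field(default_factory=_default_scales)
    spasm_prevalence: float = 0.15
    diameter_reduction_range: tuple[float, float] = (0.3, 0.7)
    measurement_noise_cv: float = 0.05
    p_hypoperfusion_given_k_spastic: dict[int, float] = field(default_factory=_default_p_hypo)
    p_treatment_given_cta_ctp: dict[tuple[bool, bool], float] = field(
        default_factory=_default_p_treat
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.exams_per_patient < 1:
            raise CohortSimError("n_patients and exams_per_patient must be >= 1")
        lo, hi = self.diameter_reduction_range
        if not (0 < lo <= hi < 1):
            raise CohortSimError("diameter_reduction_range must lie within (0, 1)")
        if not 0 <= self.spasm_prevalence <= 1:
            raise CohortSimError("spasm_prevalence must be in [0, 1]")
        if self.measurement_noise_cv < 0:
            raise CohortSimError("measurement_noise_cv must be >= 0")
        for p in self.p_hypoperfusion_given_k_spastic.values():
            if not 0 <= p <= 1:
                raise CohortSimError("hypoperfusion probabilities must be in [0, 1]")
        for p in self.p_treatment_given_cta_ctp.values():
            if not 0 <= p <= 1:
                raise CohortSimError("treatment probabilities must be in [0, 1]")
        for c in SEGMENT_CLASSES:
            if c not in self.baseline_ratio_location or c not in self.baseline_ratio_scale:
                raise CohortSimError(f"baseline parameters missing for class {c}")


def _dsa_grade(d: float) -> int:
    """Severity grade from the true diameter reduction: 2 iff d > 0.5."""
    if d > 0.5:
        return 2
    if d > 0.0:
        return 1
    return 0


def generate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns ``(cohort, truth)`` tables.

    ``cohort`` is the long-format CSV schema the pipeline consumes (segment
    rows and CTP-region rows).  ``truth`` repeats the segment rows with the
    hidden generative columns (baseline ratio, diameter reduction, severe
    flag, exam-level severe count).
    """
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log1p(config.measurement_noise_cv**2))
    cohort_rows: list[dict] = []
    truth_rows: list[dict] = []
    for p in range(config.n_patients):
        patient = f"P{p:03d}"
        for e in range(config.exams_per_patient):
            exam = f"{patient}E{e:02d}"
            ts = f"2024-01-{(e % 28) + 1:02d}T08:00:00"
            seg_draws = []
            for seg in ALL_SEGMENT_IDS:
                baseline = float(
                    rng.lognormal(
                        config.baseline_ratio_location[seg.seg_class],
                        config.baseline_ratio_scale[seg.seg_class],
                    )
                )
                spastic = rng.random() < config.spasm_prevalence
                d = float(rng.uniform(*config.diameter_reduction_range)) if spastic else 0.0
                noise = (
                    float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if sigma > 0 else 1.0
                )
                observed = baseline * (1.0 - d) ** 2 * noise
                seg_draws.append((seg, baseline, d, observed))
            n_severe = sum(1 for _, _, d, _ in seg_draws if d > 0.5)
            cta_pos = n_severe >= 1
            try:
                p_hypo = config.p_hypoperfusion_given_k_spastic[n_severe]
            except KeyError:
                raise CohortSimError(
                    f"no hypoperfusion probability configured for {n_severe} severe segments"
                ) from None
            ctp_pos = bool(rng.random() < p_hypo)
            try:
                p_treat = config.p_treatment_given_cta_ctp[(cta_pos, ctp_pos)]
            except KeyError:
                raise CohortSimError(
                    f"no treatment probability configured for condition "
                    f"(CTA+={cta_pos}, CTP+={ctp_pos})"
                ) from None
            treated = bool(rng.random() < p_treat)

            for seg, baseline, d, observed in seg_draws:
                base = {
                    "patient_id": patient,
                    "exam_id": exam,
                    "timestamp": ts,
                    "segment_class": seg.seg_class,
                    "side": seg.side,
                    "ratio_uL_per_mm": round(observed, 6),
                    "dsa_grade": _dsa_grade(d),
                    "ctp_region": "",
                    "ctp_grade": "",
                    "treated_within_24h": treated,
                }
                cohort_rows.append(base)
                truth_rows.append(
                    {
                        **base,
                        "true_baseline_ratio": round(baseline, 6),
                        "true_diameter_reduction": round(d, 6),
                        "true_severe": d > 0.5,
                        "exam_n_severe": n_severe,
                        "exam_ctp_positive": ctp_pos,
                    }
                )
            abnormal_slot = (
                int(rng.integers(len(CTP_REGIONS) * len(CTP_SIDES))) if ctp_pos else -1
            )
            for i, region in enumerate(CTP_REGIONS):
                for j, side in enumerate(CTP_SIDES):
                    slot = i * len(CTP_SIDES) + j
                    cohort_rows.append(
                        {
                            "patient_id": patient,
                            "exam_id": exam,
                            "timestamp": ts,
                            "segment_class": "",
                            "side": side,
                            "ratio_uL_per_mm": "",
                            "dsa_grade": "",
                            "ctp_region": region,
                            "ctp_grade": 1 if slot == abnormal_slot else 0,
                            "treated_within_24h": treated,
                        }
                    )
    return pd.DataFrame(cohort_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Deterministic fixture cohorts from joint count tables


def load_reference_cohort_cells() -> list[dict]:
    """Joint (severe-segment count, CTP flag, treated flag) cell counts of a
    96-examination synthetic fixture cohort consistent with the published
    contingency tables of the original clinical study (28 CTP-positive, 19
    treated).  Counts in the ``3`` category mean "three or more" and are
    realized with exactly three severe segments."""
    text = resources.files("vasovol.data").joinpath("reference_cohort_cells.json").read_text()
    return json.loads(text)


#: Fixed slot order used to realize n severe segments deterministically.
_SEVERE_SLOTS = (
    SegmentId("M1", "left"),
    SegmentId("M1", "right"),
    SegmentId("ICA", "left"),
)


def synthetic_cohort_from_cells(
    cells: list[dict], thresholds: dict[str, SegmentThreshold]
) -> list[ExaminationRecord]:
    """Deterministic cohort realizing given joint cell counts.

    Each cell dict has keys ``n_severe`` (0-3, realized exactly), ``ctp``,
    ``treated`` and ``count``.  Severe slots get a ratio at half their class
    threshold, all other slots at twice it; a positive CTP is one abnormal
    insula grade with every other region slot graded 0.
    """
    records: list[ExaminationRecord] = []
    idx = 0
    for cell in cells:
        n_severe = int(cell["n_severe"])
        if not 0 <= n_severe <= len(_SEVERE_SLOTS):
            raise CohortSimError(f"cannot realize {n_severe} severe segments")
        for _ in range(int(cell["count"])):
            pid = f"S{idx:03d}"
            ratios: dict[SegmentId, float] = {}
            severe_slots = _SEVERE_SLOTS[:n_severe]
            for seg in ALL_SEGMENT_IDS:
                t = thresholds[seg.seg_class].threshold
                ratios[seg] = 0.5 * t if seg in severe_slots else 2.0 * t
            grades = {(r, s): 0 for r in CTP_REGIONS for s in CTP_SIDES}
            if cell["ctp"]:
                grades[("insula", "left")] = 1
            records.append(
                ExaminationRecord(
                    patient_id=pid,
                    exam_id=f"{pid}E00",
                    timestamp="2024-01-01T08:00:00",
                    ratios=ratios,
                    ctp=CtpAssessment(grades),
                    treated_within_24h=bool(cell["treated"]),
                )
            )
            idx += 1
    return records
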