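"""Contingency tables and diagnostic metrics for the CTA/CTP criteria.

Two evaluations are supported on a cohort of examinations: the k-segment
CTA criteria against CTP hypoperfusion as the gold standard, and CTP, CTA
and their conjunction against endovascular vasospasm treatment within 24 h.
Metrics are kept as exact fractions; the whole-percent rendering rounds
half away from zero to one decimal and then to a whole percent, matching
how such tables are conventionally reported (a value first published to one
decimal and then rounded again).  Undefined metrics (zero denominators) are
reported as ``None``, never as 0 or 100.

Examinations are treated as independent observations; repeated exams of one
patient are not clustered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping

from .calibration import SegmentThreshold
from .grading import (
    ExaminationRecord,
    GradingError,
    cta_pathological,
    combined_positive,
    ctp_hypoperfusion,
)

METRIC_NAMES = ("sensitivity", "specificity", "npv", "ppv")


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts of a binary test against a gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DiagnosticsError("contingency counts must be non-negative")
        if self.n == 0:
            raise DiagnosticsError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def render_percent(value: Fraction | None) -> int | None:
    """Whole-percent rendering: half away from zero via one decimal place."""
    if value is None:
        return None
    d = (Decimal(value.numerator) / Decimal(value.denominator)) * 100
    one_decimal = d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return int(one_decimal.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, NPV, PPV as exact fractions.

    A metric is ``None`` when its denominator is zero (e.g. PPV of a test
    that never fires); ``percents`` renders the defined metrics to whole
    percent.
    """

    sensitivity: Fraction | None
    specificity: Fraction | None
    npv: Fraction | None
    ppv: Fraction | None

    @property
    def percents(self) -> dict[str, int | None]:
        return {name: render_percent(getattr(self, name)) for name in METRIC_NAMES}


def build_contingency(predicted: Iterable[bool], gold: Iterable[bool]) -> ContingencyTable:
    """Cross-tabulate a predicted flag against the gold standard."""
    predicted = list(predicted)
    gold = list(gold)
    if len(predicted) != len(gold):
        raise DiagnosticsError("predicted and gold must have equal length")
    if not predicted:
        raise DiagnosticsError("cannot build a contingency table from no observations")
    tp = sum(1 for p, g in zip(predicted, gold) if p and g)
    fp = sum(1 for p, g in zip(predicted, gold) if p and not g)
    fn = sum(1 for p, g in zip(predicted, gold) if not p and g)
    tn = len(predicted) - tp - fp - fn
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(ct: ContingencyTable) -> DiagnosticMetrics:
    """Exact diagnostic metrics; zero-denominator metrics are flagged None."""

    def frac(num: int, den: int) -> Fraction | None:
        return Fraction(num, den) if den > 0 else None

    return DiagnosticMetrics(
        sensitivity=frac(ct.tp, ct.tp + ct.fn),
        specificity=frac(ct.tn, ct.tn + ct.fp),
        npv=frac(ct.tn, ct.tn + ct.fn),
        ppv=frac(ct.tp, ct.tp + ct.fp),
    )


def _require_ctp(cohort: list[ExaminationRecord]) -> None:
    missing = [e.exam_id for e in cohort if e.ctp is None]
    if missing:
        raise GradingError(f"exams without CTP assessment: {missing[:5]}")


def evaluate_vs_ctp(
    cohort: list[ExaminationRecord], thresholds: Mapping[str, SegmentThreshold]
) -> dict[int, tuple[ContingencyTable, DiagnosticMetrics]]:
    """k-segment CTA criteria vs CTP hypoperfusion as gold standard."""
    if not cohort:
        raise DiagnosticsError("empty cohort")
    _require_ctp(cohort)
    gold = [ctp_hypoperfusion(e.ctp) for e in cohort]
    out = {}
    for k in (1, 2, 3):
        pred = [cta_pathological(e, thresholds, k) for e in cohort]
        ct = build_contingency(pred, gold)
        out[k] = (ct, metrics(ct))
    return out


def evaluate_vs_treatment(
    cohort: list[ExaminationRecord], thresholds: Mapping[str, SegmentThreshold]
) -> dict[str, tuple[ContingencyTable, DiagnosticMetrics]]:
    """CTP alone, CTA per k, and the CTA-and-CTP conjunction per k, each
    against treatment within 24 h as gold standard.

    Keys: ``"ctp"``, ``"cta_k1".."cta_k3"``, ``"combined_k1".."combined_k3"``.
    """
    if not cohort:
        raise DiagnosticsError("empty cohort")
    _require_ctp(cohort)
    missing = [e.exam_id for e in cohort if e.treated_within_24h is None]
    if missing:
        raise DiagnosticsError(f"exams without treatment flag: {missing[:5]}")
    gold = [bool(e.treated_within_24h) for e in cohort]

    predictors: dict[str, list[bool]] = {"ctp": [ctp_hypoperfusion(e.ctp) for e in cohort]}
    for k in (1, 2, 3):
        predictors[f"cta_k{k}"] = [cta_pathological(e, thresholds, k) for e in cohort]
        predictors[f"combined_k{k}"] = [combined_positive(e, thresholds, k) for e in cohort]

    out = {}
    for name, pred in predictors.items():
        ct = build_contingency(pred, gold)
        out[name] = (ct, metrics(ct))
    return out


def load_reference_tables() -> dict:
    """Published diagnostic tables of the original clinical cohort (96 CTA
    examinations with CTP; gold standards: CTP hypoperfusion and treatment
    within 24 h), as contingency counts plus the printed whole-percent
    metrics; shipped as package data."""
    text = resources.files("vasovol.data").joinpath("reference_tables.json").read_text()
    return json.loads(text)


# ---------------------------------------------------------------------------
# Report rendering

_ROW_ORDER = ("N", "FP", "FN", "TP", "TN", "Sensitivity", "Specificity", "NPV", "PPV")


def report_dict(
    results: Mapping[object, tuple[ContingencyTable, DiagnosticMetrics]]
) -> dict[str, dict[str, int | None]]:
    """JSON-ready report: per predictor, counts plus whole-percent metrics."""
    out: dict[str, dict[str, int | None]] = {}
    for key, (ct, m) in results.items():
        pct = m.percents
        out[str(key)] = {
            "N": ct.n,
            "FP": ct.fp,
            "FN": ct.fn,
            "TP": ct.tp,
            "TN": ct.tn,
            "Sensitivity": pct["sensitivity"],
            "Specificity": pct["specificity"],
            "NPV": pct["npv"],
            "PPV": pct["ppv"],
        }
    return out


def report_tsv(results: Mapping[object, tuple[ContingencyTable, DiagnosticMetrics]]) -> str:
    """TSV mirroring the standard layout: one column per predictor, rows
    N/FP/FN/TP/TN then the four metrics as whole percents."""
    cols = report_dict(results)
    lines = ["\t".join(["", *cols])]
    for row in _ROW_ORDER:
        cells = []
        for col in cols.values():
            v = col[row]
            if v is None:
                cells.append("n/a")
            elif row in ("Sensitivity", "Specificity", "NPV", "PPV"):
                cells.append(f"{v}%")
            else:
                cells.append(str(v))
        lines.append("\t".join([row, *cells]))
    return "\n".join(lines) + "\n"
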