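"""Per-segment severity thresholds from ROC analysis against DSA grades.

For each vessel segment class, the volume/length ratios of examinations with
a catheter-angiography (DSA) gold standard are split into severe (DSA grade
2, i.e. >50% diameter narrowing) and non-severe observations, pooling left
and right sides.  A spastic vessel is *narrow*, so the test is
"ratio strictly below the cutoff => severe".  The cutoff maximizing
sensitivity + specificity (the Youden criterion) is the point estimate; its
95% confidence interval comes from percentile bootstrap over stratified
replicates that resample severe and non-severe observations independently,
preserving both group sizes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .segments import REJECTED_CLASSES, SEGMENT_CLASSES


class DegenerateSampleError(ValueError):
    """Raised when a calibration sample contains only one class."""


@dataclass(frozen=True)
class CalibrationConfig:
    """Bootstrap settings: replicate count, CI level and seed."""

    n_bootstrap: int = 2000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class SegmentThreshold:
    """Severity cutoff for one segment class, with CI and sample counts.

    A measured ratio strictly below ``threshold`` indicates severe vasospasm.
    ``n_examinations``/``n_patients`` count only observations actually used.
    """

    segment_class: str
    threshold: float
    ci_low: float
    ci_high: float
    n_examinations: int
    n_patients: int

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must be <= ci_high")
        if not self.n_examinations >= self.n_patients >= 1:
            raise ValueError("need n_examinations >= n_patients >= 1")


def _candidate_cutoffs(ratios: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive distinct sorted ratios, plus one candidate
    below the minimum and one above the maximum (multiplicative offsets keep
    the candidate set scale-equivariant; ratios are strictly positive)."""
    u = np.unique(ratios)
    mids = 0.5 * (u[:-1] + u[1:])
    return np.concatenate(([0.5 * u[0]], mids, [2.0 * u[-1]]))


def youden_cutoff(ratios, severe) -> tuple[float, float, float]:
    """Cutoff maximizing sensitivity + specificity for "ratio < cutoff = severe".

    Returns ``(cutoff, sensitivity, specificity)`` at the optimum.  Among
    tied candidates the largest cutoff is chosen (the detection-oriented
    tie-break: it maximizes sensitivity).

    Raises
    ------
    DegenerateSampleError
        If all observations are severe or all are non-severe.
    ValueError
        If any ratio is not strictly positive.
    """
    r = np.asarray(ratios, dtype=float)
    s = np.asarray(severe, dtype=bool)
    if r.shape != s.shape or r.ndim != 1 or r.size == 0:
        raise ValueError("ratios and severe must be equal-length 1-D sequences")
    if not (r > 0).all():
        raise ValueError("ratios must be > 0")
    n_pos = int(s.sum())
    if n_pos == 0 or n_pos == r.size:
        raise DegenerateSampleError("degenerate calibration sample: only one class present")

    n_neg = r.size - n_pos
    cands = _candidate_cutoffs(r)
    pred = r[None, :] < cands[:, None]  # predicted severe
    tp = (pred & s).sum(axis=1)
    tn = (~pred & ~s).sum(axis=1)
    # integer objective proportional to sensitivity + specificity: exact ties
    j = tp * n_neg + tn * n_pos
    best = len(j) - 1 - int(np.argmax(j[::-1]))  # last argmax = largest cutoff
    return float(cands[best]), tp[best] / n_pos, tn[best] / n_neg


def bootstrap_cutoff_distribution(
    ratios: np.ndarray, severe: np.ndarray, config: CalibrationConfig
) -> np.ndarray:
    """Youden cutoffs from ``n_bootstrap`` stratified replicates.

    Severe and non-severe observations are resampled with replacement
    independently, so every replicate keeps both group sizes; a replicate can
    therefore never collapse to one class (the redraw guard is kept for
    safety).  Reproducible from ``config.seed``.
    """
    r = np.asarray(ratios, dtype=float)
    s = np.asarray(severe, dtype=bool)
    # strata are sorted so replicates depend only on the multiset of values
    # (and the seed), not on input row order
    pos, neg = np.sort(r[s]), np.sort(r[~s])
    rng = np.random.default_rng(config.seed)
    cutoffs = np.empty(config.n_bootstrap)
    lab = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
    for i in range(config.n_bootstrap):
        for _ in range(100):
            rep = np.concatenate(
                [
                    rng.choice(pos, size=pos.size, replace=True),
                    rng.choice(neg, size=neg.size, replace=True),
                ]
            )
            try:
                cutoffs[i], _, _ = youden_cutoff(rep, lab)
                break
            except DegenerateSampleError:  # pragma: no cover - unreachable when stratified
                continue
        else:  # pragma: no cover
            raise RuntimeError("bootstrap replicate kept collapsing to one class")
    return cutoffs


def bootstrap_threshold(
    ratios,
    severe,
    config: CalibrationConfig,
    *,
    segment_class: str = "M1",
    n_examinations: int | None = None,
    n_patients: int | None = None,
) -> SegmentThreshold:
    """Point estimate (full-sample Youden cutoff) + percentile bootstrap CI."""
    cutoff, _, _ = youden_cutoff(ratios, severe)
    dist = bootstrap_cutoff_distribution(np.asarray(ratios, float), np.asarray(severe, bool), config)
    alpha = 1.0 - config.ci_level
    ci_low, ci_high = np.quantile(dist, [alpha / 2.0, 1.0 - alpha / 2.0])
    n = len(np.asarray(ratios))
    return SegmentThreshold(
        segment_class=segment_class,
        threshold=cutoff,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_examinations=n if n_examinations is None else n_examinations,
        n_patients=n if n_patients is None else n_patients,
    )


def calibrate_all(
    sample: pd.DataFrame, config: CalibrationConfig
) -> tuple[list[SegmentThreshold], list[str]]:
    """Calibrate every segment class present in a long-format sample table.

    ``sample`` needs columns ``patient_id, exam_id, segment_class, side,
    ratio_uL_per_mm, dsa_grade``; severe means DSA grade 2.  Left and right
    observations of a class are pooled.  Vertebral-artery rows are rejected
    with a warning; classes whose sample is degenerate (a single class after
    pooling) are recorded as uncalibrated rather than failing the run.

    Returns ``(thresholds, uncalibrated_classes)``.  Each class gets its own
    bootstrap stream derived from ``config.seed``, so results do not depend
    on the order classes appear in the table.
    """
    required = {"patient_id", "exam_id", "segment_class", "side", "ratio_uL_per_mm", "dsa_grade"}
    missing = required - set(sample.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    sample = sample.dropna(subset=["dsa_grade"])
    if len(sample) == 0:
        warnings.warn("empty calibration table: no thresholds calibrated", stacklevel=2)
        return [], []

    rejected = sample["segment_class"].isin(REJECTED_CLASSES)
    if rejected.any():
        warnings.warn(
            "rejecting vertebral-artery observations: no threshold is calibrated "
            "for the vertebral artery",
            stacklevel=2,
        )
        sample = sample[~rejected]

    thresholds: list[SegmentThreshold] = []
    uncalibrated: list[str] = []
    # class-keyed child seeds: independent of table order
    root = np.random.SeedSequence(config.seed)
    streams = dict(zip(SEGMENT_CLASSES, root.spawn(len(SEGMENT_CLASSES))))
    for seg_class, grp in sample.groupby("segment_class", sort=True):
        if seg_class not in SEGMENT_CLASSES:
            warnings.warn(f"unknown segment class {seg_class!r} skipped", stacklevel=2)
            continue
        ratios = grp["ratio_uL_per_mm"].to_numpy(float)
        severe = grp["dsa_grade"].to_numpy(int) == 2
        cls_seed = int(streams[seg_class].generate_state(1)[0] % (2**31))
        cls_config = CalibrationConfig(config.n_bootstrap, config.ci_level, cls_seed)
        try:
            thresholds.append(
                bootstrap_threshold(
                    ratios,
                    severe,
                    cls_config,
                    segment_class=str(seg_class),
                    n_examinations=grp[["patient_id", "exam_id"]].drop_duplicates().shape[0],
                    n_patients=grp["patient_id"].nunique(),
                )
            )
        except DegenerateSampleError:
            warnings.warn(f"segment class {seg_class}: degenerate sample, uncalibrated", stacklevel=2)
            uncalibrated.append(str(seg_class))
    return thresholds, uncalibrated


def thresholds_by_class(thresholds) -> dict[str, SegmentThreshold]:
    """Index a threshold list by segment class."""
    return {t.segment_class: t for t in thresholds}


def load_reference_thresholds() -> list[SegmentThreshold]:
    """Severity thresholds calibrated on the original single-center clinical
    cohort (20 DSA examinations from 10 SAH patients), shipped as package
    data.  Units are uL/mm; CIs are stratified-bootstrap 95% intervals."""
    text = resources.files("vasovol.data").joinpath("reference_thresholds.json").read_text()
    return [SegmentThreshold(**row) for row in json.loads(text)]


def threshold_to_dict(t: SegmentThreshold) -> dict:
    return asdict(t)
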