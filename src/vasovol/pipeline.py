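"""End-to-end orchestration: simulate -> calibrate -> evaluate.

A single :class:`RunConfig` (one JSON file) drives a fully synthetic run:
draw a surveillance cohort, calibrate per-segment thresholds on the
DSA-graded observations, then evaluate the k-segment CTA criteria against
CTP hypoperfusion and the CTP/CTA/combined criteria against treatment
within 24 h.  All randomness flows from one seed, so identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibration import CalibrationConfig, calibrate_all, thresholds_by_class
from .cohort import CohortSimConfig, generate_cohort
from .diagnostics import evaluate_vs_ctp, evaluate_vs_treatment, report_dict, report_tsv
from .io import read_cohort, write_thresholds

log = logging.getLogger("vasovol")


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full synthetic run."""

    out_dir: str
    seed: int = 0
    n_patients: int = 24
    exams_per_patient: int = 3
    spasm_prevalence: float = 0.15
    measurement_noise_cv: float = 0.05
    n_bootstrap: int = 2000
    ci_level: float = 0.95
    k_values: tuple[int, ...] = (1, 2, 3)
    log_level: str = "INFO"
    sim_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(k not in (1, 2, 3) for k in self.k_values):
            raise ValueError("k_values must be within {1, 2, 3}")
        CalibrationConfig(self.n_bootstrap, self.ci_level, self.seed)  # validates

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "k_values" in data:
            data["k_values"] = tuple(data["k_values"])
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report bundle and writes artifacts."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        sim = CohortSimConfig(
            n_patients=config.n_patients,
            exams_per_patient=config.exams_per_patient,
            spasm_prevalence=config.spasm_prevalence,
            measurement_noise_cv=config.measurement_noise_cv,
            seed=config.seed,
            **config.sim_overrides,
        )
        log.info("simulate: %d patients x %d exams, seed %d", sim.n_patients,
                 sim.exams_per_patient, sim.seed)
        cohort_df, truth_df = generate_cohort(sim)
        cohort_df.to_csv(out / "cohort.csv", index=False)
        truth_df.to_csv(out / "truth.csv", index=False)
    except Exception as err:
        raise PipelineError(f"simulate stage failed: {err}") from err

    try:
        cal = CalibrationConfig(config.n_bootstrap, config.ci_level, config.seed)
        seg_rows = cohort_df[cohort_df["segment_class"] != ""].copy()
        seg_rows["ratio_uL_per_mm"] = seg_rows["ratio_uL_per_mm"].astype(float)
        seg_rows["dsa_grade"] = seg_rows["dsa_grade"].astype(int)
        log.info("calibrate: %d observations, %d bootstrap replicates",
                 len(seg_rows), cal.n_bootstrap)
        thresholds, uncalibrated = calibrate_all(seg_rows, cal)
        if uncalibrated:
            log.warning("uncalibrated classes: %s", uncalibrated)
        write_thresholds(thresholds, out / "thresholds.json")
        by_class = thresholds_by_class(thresholds)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"calibrate stage failed: {err}") from err

    try:
        records = read_cohort(out / "cohort.csv")
        log.info("evaluate: %d examinations", len(records))
        vs_ctp = evaluate_vs_ctp(records, by_class)
        vs_treatment = evaluate_vs_treatment(records, by_class)
        bundle = {
            "thresholds": [dataclasses.asdict(t) for t in thresholds],
            "uncalibrated": uncalibrated,
            "cta_vs_ctp": report_dict({f"k{k}": vs_ctp[k] for k in config.k_values}),
            "vs_treatment": report_dict(vs_treatment),
        }
        (out / "report_ctp.tsv").write_text(
            report_tsv({f">= {k} segment(s)": vs_ctp[k] for k in config.k_values})
        )
        (out / "report_treatment.tsv").write_text(report_tsv(vs_treatment))
        (out / "report.json").write_text(json.dumps(bundle, indent=2) + "\n")
    except Exception as err:
        raise PipelineError(f"evaluate stage failed: {err}") from err
    return bundle


def records_from_cohort_df(cohort_df: pd.DataFrame):
    """Convenience: parse an in-memory cohort table via the CSV reader."""
    import io as _io

    buf = _io.StringIO()
    cohort_df.to_csv(buf, index=False)
    buf.seek(0)
    return read_cohort(buf)
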