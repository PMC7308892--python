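"""End-to-end pipeline: simulate -> process -> calibrate -> evaluate.

Every stage is reproducible from (config, seed); any stage failure is
re-raised with the stage name attached. With an ``output_dir`` configured,
each stage's intermediates (recordings, references, windows, calibration,
report, plots) are written out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .calibration import CohortCalibration
from .config import PipelineConfig
from .dsp import WindowEstimate, process_recording
from .evaluation import (
    EvaluationReport,
    compute_accuracy_stats,
    filter_stable_reference,
    format_table,
    pair_with_reference,
    rejection_accounting,
    stratify,
)
from .model import OximeterCalibration, OximeterCalibrationResults
from .simulate import PpgRecording, ReferenceSeries, make_cohort

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]

log = logging.getLogger("pulsox")


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; ``stage`` names it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineResult:
    """Everything a pipeline run produces."""

    report: EvaluationReport  # continuous-reference comparison, stratified
    abga_report: Optional[EvaluationReport]  # blood-gas comparison
    calibration: CohortCalibration
    results: OximeterCalibrationResults
    windows: list[WindowEstimate]
    pairs_continuous: pd.DataFrame
    pairs_abga: pd.DataFrame
    subjects: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full chain on a synthetic cohort defined by ``config``."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(name, exc) from exc

    cohort = stage(
        "simulate", make_cohort, config.n_subjects, config.simulation,
        config.seed,
    )
    log.info("simulated %d subjects", len(cohort))
    if out:
        from . import io

        for rec, ref, truth in cohort:
            io.write_recording(rec, out / f"recording_{rec.subject_id}.csv")
            io.write_reference(
                ref,
                out / f"reference_{rec.subject_id}.csv",
                out / f"abga_{rec.subject_id}.csv",
            )
            io.write_truth(truth, out / f"truth_{rec.subject_id}.csv")

    all_windows: list[WindowEstimate] = []
    refs: dict[str, ReferenceSeries] = {}
    for rec, ref, _truth in cohort:
        wins = stage("process", process_recording, rec, config.processing)
        wins = stage(
            "stable_reference_filter",
            filter_stable_reference,
            wins,
            ref,
            config.evaluation.max_reference_range_pct,
        )
        refs[rec.subject_id] = ref
        all_windows.extend(wins)
        summ = rejection_accounting(wins)
        log.info(
            "subject %s: %d windows, %d retained (%s)",
            rec.subject_id,
            summ.n_total,
            summ.n_retained,
            summ.by_reason,
        )

    results = stage(
        "calibrate",
        lambda: OximeterCalibration.from_windows(all_windows).fit(),
    )
    stage("apply_calibration", results.apply_to_windows, all_windows)
    log.info(
        "leave-one-out calibration: a=%.3f+/-%.3f b=%.3f+/-%.3f",
        *(lambda s: (s["a_mean"], s["a_sd"], s["b_mean"], s["b_sd"]))(
            results.cohort.coefficient_summary
        ),
    )

    by_subject: dict[str, list[WindowEstimate]] = {}
    for w in all_windows:
        by_subject.setdefault(w.subject_id, []).append(w)
    pairs_cont = []
    pairs_abga = []
    for sid, wins in by_subject.items():
        ref = refs[sid]
        pairs_cont.append(
            stage("pair", pair_with_reference, wins, ref, "continuous")
        )
        pairs_abga.append(
            stage(
                "pair", pair_with_reference, wins, ref, "abga",
                config.evaluation.abga_max_gap_s,
            )
        )
    pairs_cont = pd.concat(pairs_cont, ignore_index=True)
    pairs_abga = pd.concat(pairs_abga, ignore_index=True)

    strata = stage("evaluate", stratify, pairs_cont, all_windows)
    report = strata.pop("overall")
    report.strata = strata
    abga_report = None
    if len(pairs_abga) >= 2:
        abga_report = stage("evaluate", compute_accuracy_stats, pairs_abga)

    if out:
        from . import io, plotting

        io.write_windows(all_windows, out / "windows.csv")
        (out / "calibration.txt").write_text(results.summary() + "\n")
        (out / "report.json").write_text(report.to_json() + "\n")
        table = format_table({"overall": report, **report.strata})
        (out / "report.txt").write_text(table + "\n")
        if abga_report is not None:
            (out / "report_abga.json").write_text(abga_report.to_json() + "\n")
        pairs_cont.to_csv(out / "pairs_continuous.csv", index=False)
        pairs_abga.to_csv(out / "pairs_abga.csv", index=False)
        if len(pairs_cont) >= 2:
            plotting.bland_altman_plot(
                pairs_cont, path=out / "bland_altman.png"
            )
            plotting.correlation_plot(pairs_cont, path=out / "correlation.png")

    return PipelineResult(
        report=report,
        abga_report=abga_report,
        calibration=results.cohort,
        results=results,
        windows=all_windows,
        pairs_continuous=pairs_cont,
        pairs_abga=pairs_abga,
        subjects=sorted(by_subject),
    )
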