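"""End-to-end orchestration: recording -> events -> trial outcomes ->
subject summaries -> statistics, deterministic under a fixed seed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .events import detect_events
from .preprocess import GazeRecording, angular_velocity, average_eyes, fill_gaps
from .stats import correlate_all, fit_late_error_regression, RegressionResult
from .trials import (RATE_COLUMNS, TrialOutcome, analyze_trial, outcomes_to_frame,
                     summarize_subject)

__all__ = ["process_recording", "summarize_recordings", "run_pipeline", "PipelineResult"]

log = logging.getLogger("mgst")


def process_recording(rec: GazeRecording, config: PipelineConfig = PipelineConfig()) -> list[TrialOutcome]:
    """Preprocess, detect events, and classify every trial of one session."""
    rec = fill_gaps(rec, config.preprocess.gap_fill_ms)
    trace = average_eyes(rec)
    trace = angular_velocity(trace, config.preprocess.velocity_window_ms)
    events = detect_events(
        trace, config.ivt.threshold_deg_s, config.ivt.merge_time_ms,
        config.ivt.merge_angle_deg, config.ivt.min_fixation_ms)
    return [analyze_trial(tpl, events, trace, config.trials) for tpl in rec.schedule]


def summarize_recordings(recordings: dict[str, GazeRecording],
                         config: PipelineConfig = PipelineConfig()
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Process a set of subject recordings into per-trial and per-subject
    tables plus a run log dictionary (rejection tally, exclusions)."""
    trial_frames, summary_rows = [], []
    rejections: dict[str, int] = {}
    excluded: list[str] = []
    for sid, rec in recordings.items():
        outcomes = process_recording(rec, config)
        trial_frames.append(outcomes_to_frame(outcomes, sid))
        summary = summarize_subject(outcomes, sid, config.trials)
        summary_rows.append(summary.to_row())
        for o in outcomes:
            if not o.valid:
                rejections[o.rejection_reason] = rejections.get(o.rejection_reason, 0) + 1
        if not summary.usable:
            excluded.append(sid)
            log.warning("subject %s excluded: %d valid trials (< %d)",
                        sid, summary.n_valid, config.trials.min_valid_trials)
    trials_df = pd.concat(trial_frames, ignore_index=True) if trial_frames else pd.DataFrame()
    summaries_df = pd.DataFrame(summary_rows)
    run_log = {
        "config_digest": config.digest(),
        "n_subjects": len(recordings),
        "n_samples": int(sum(r.n_samples for r in recordings.values())),
        "trial_rejections": rejections,
        "excluded_subjects": excluded,
    }
    return trials_df, summaries_df, run_log


@dataclass
class PipelineResult:
    trials: pd.DataFrame
    summaries: pd.DataFrame
    correlations: pd.DataFrame
    regression: RegressionResult | None
    run_log: dict = field(default_factory=dict)


def run_pipeline(recordings: dict[str, GazeRecording],
                 covariates: pd.DataFrame | None = None,
                 config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Full chain.  Only usable subjects (>= 7 valid trials) enter the
    statistics; the regression is attempted only when enough complete
    cases exist and is otherwise reported as absent."""
    trials_df, summaries_df, run_log = summarize_recordings(recordings, config)
    correlations = pd.DataFrame()
    regression = None
    if covariates is not None and not summaries_df.empty:
        usable = summaries_df[summaries_df["usable"]]
        stat_cols = ["subject_id", *RATE_COLUMNS]
        correlations = correlate_all(
            usable[stat_cols], covariates, method=config.stats.method,
            alpha=config.stats.alpha, fdr=config.stats.fdr)
        merged = covariates.merge(usable[stat_cols], on="subject_id")
        try:
            regression = fit_late_error_regression(merged, alpha=config.stats.alpha)
        except ValueError as err:
            log.warning("regression skipped: %s", err)
            run_log["regression_skipped"] = str(err)
    return PipelineResult(trials=trials_df, summaries=summaries_df,
                          correlations=correlations, regression=regression,
                          run_log=run_log)
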