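"""Trial validity, saccade selection, error taxonomy, and aggregation.

A trial enters the analysis only if, in the 60 ms window ending at target
flash onset, gaze is valid (no blink), saccade-free, and within +/-100 px
of screen center.  On valid trials the first saccade of the memorization
phase (>= 1 deg) is an error — early if it starts within 300 ms of flash
onset, late after.  Otherwise the first saccade of the reaction interval
is the candidate MGS; it must be >= 1 deg, start within the center band,
head toward the cued side, and have a clean 100 ms history (no saccade or
gap).  A corrective VGS is the first confirmation-interval saccade that
reduces the distance to the target under the same amplitude/history rules.
Per-subject summaries hold near/far means and SDs of the seven saccade
metrics for MGS and VGS plus the five session rates; subjects with fewer
than 7 valid trials are flagged unusable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import FIXATION, GAP, SACCADE, OculomotorEvent
from .paradigm import TrialTemplate, pixel_to_degree
from .preprocess import CyclopeanTrace

__all__ = [
    "TrialRules", "TrialOutcome", "SubjectSummary",
    "validate_trial", "classify_error", "extract_mgs", "extract_corrective_vgs",
    "saccade_metrics", "analyze_trial", "summarize_subject",
]

METRICS = ("latency", "amplitude", "duration", "mean_velocity",
           "peak_velocity", "time_to_peak", "gain")

RATE_COLUMNS = ("%MGS", "%CorrVGS", "%EarlyErrorRate", "%LateErrorRate", "%TotalErrorRate")


@dataclass(frozen=True)
class TrialRules:
    """Selection thresholds of the trial layer (defaults per protocol)."""

    center_band_px: float = 100.0
    preflash_window_ms: float = 60.0
    min_amplitude_deg: float = 1.0
    clean_history_ms: float = 100.0
    early_late_boundary_ms: float = 300.0
    min_valid_trials: int = 7
    require_direction: bool = True


@dataclass
class TrialOutcome:
    """Classification and metrics of one trial."""

    trial: TrialTemplate
    valid: bool
    rejection_reason: str | None  # blink | saccade | off-center
    outcome: str | None           # valid_mgs | early_error | late_error | omission
    mgs: dict | None = None       # seven metrics + gain
    vgs: dict | None = None
    error_onset_ms: float | None = None  # relative to flash onset


def _saccades(events: list[OculomotorEvent]) -> list[OculomotorEvent]:
    return [e for e in events if e.kind == SACCADE]


def validate_trial(trial: TrialTemplate, events: list[OculomotorEvent],
                   trace: CyclopeanTrace, rules: TrialRules = TrialRules()) -> tuple[bool, str | None]:
    """Pre-flash gating: over [flash - 60 ms, flash) every sample must be
    valid, no saccade may overlap, and |x| must stay inside the center
    band.  Returns (valid, rejection reason)."""
    t1 = trial.flash_onset_abs_ms
    t0 = t1 - rules.preflash_window_ms
    t_ms = trace.t_ms
    sel = (t_ms >= t0) & (t_ms < t1)
    if not np.all(trace.valid[sel]):
        return False, "blink"
    if any(e.kind in (SACCADE, GAP) and e.overlaps(t0, t1) for e in events):
        reason = "saccade" if any(
            e.kind == SACCADE and e.overlaps(t0, t1) for e in events) else "blink"
        return False, reason
    band_deg = pixel_to_degree(rules.center_band_px, trace.geometry)
    if np.any(np.abs(trace.x_deg[sel]) > band_deg):
        return False, "off-center"
    return True, None


def classify_error(trial: TrialTemplate, events: list[OculomotorEvent],
                   rules: TrialRules = TrialRules()) -> tuple[str | None, float | None]:
    """First >= 1 deg saccade during the memorization phase (flash onset to
    go signal), any direction: early if its onset is within 300 ms of flash
    onset, late after.  Returns (label or None, onset ms after flash)."""
    flash = trial.flash_onset_abs_ms
    end = trial.go_signal_abs_ms
    for sac in _saccades(events):
        if flash < sac.onset_ms <= end and sac.amplitude_deg >= rules.min_amplitude_deg:
            rel = sac.onset_ms - flash
            label = "early_error" if rel <= rules.early_late_boundary_ms else "late_error"
            return label, rel
    return None, None


def _clean_history(sac: OculomotorEvent, events: list[OculomotorEvent],
                   rules: TrialRules) -> bool:
    t0 = sac.onset_ms - rules.clean_history_ms
    return not any(
        e.kind in (SACCADE, GAP) and e is not sac and e.overlaps(t0, sac.onset_ms)
        for e in events
    )


def extract_mgs(trial: TrialTemplate, events: list[OculomotorEvent],
                trace: CyclopeanTrace, rules: TrialRules = TrialRules()) -> OculomotorEvent | None:
    """First-saccade rule for the memory-guided saccade.

    The first saccade with onset in the reaction interval is selected iff
    it is >= 1 deg, starts inside the center band, heads toward the cued
    side (configurable), and has a clean 100 ms pre-saccade window; if it
    fails any criterion the trial is an omission (no fallback).
    """
    go = trial.go_signal_abs_ms
    end = trial.confirmation_onset_abs_ms
    band_deg = pixel_to_degree(rules.center_band_px, trace.geometry)
    for sac in _saccades(events):
        if not go < sac.onset_ms <= end:
            continue
        if sac.amplitude_deg < rules.min_amplitude_deg:
            return None
        if abs(sac.start_x) > band_deg:
            return None
        if rules.require_direction:
            direction = np.sign(sac.end_x - sac.start_x)
            if direction != np.sign(trial.signed_eccentricity_deg):
                return None
        if not _clean_history(sac, events, rules):
            return None
        return sac
    return None


def extract_corrective_vgs(trial: TrialTemplate, events: list[OculomotorEvent],
                           rules: TrialRules = TrialRules()) -> OculomotorEvent | None:
    """First confirmation-interval saccade that moves gaze toward the
    confirmation target, >= 1 deg, with a clean 100 ms history."""
    t0 = trial.confirmation_onset_abs_ms
    t1 = trial.start_ms + trial.boundaries_ms[4]  # end of the confirmation interval
    target = trial.signed_eccentricity_deg
    for sac in _saccades(events):
        if not t0 < sac.onset_ms <= t1:
            continue
        if sac.amplitude_deg < rules.min_amplitude_deg:
            return None
        if abs(sac.end_x - target) >= abs(sac.start_x - target):
            return None
        if not _clean_history(sac, events, rules):
            return None
        return sac
    return None


def saccade_metrics(sac: OculomotorEvent, target_eccentricity_deg: float,
                    latency_ms: float) -> dict:
    """Seven saccade metrics plus gain = amplitude / |target| x 100."""
    if target_eccentricity_deg == 0:
        raise ValueError("target eccentricity must be nonzero")
    return {
        "latency": latency_ms,
        "amplitude": sac.amplitude_deg,
        "duration": sac.duration_ms,
        "mean_velocity": sac.mean_velocity_deg_s,
        "peak_velocity": sac.peak_velocity_deg_s,
        "time_to_peak": sac.time_to_peak_ms,
        "gain": sac.amplitude_deg / abs(target_eccentricity_deg) * 100.0,
    }


def analyze_trial(trial: TrialTemplate, events: list[OculomotorEvent],
                  trace: CyclopeanTrace, rules: TrialRules = TrialRules()) -> TrialOutcome:
    """Full per-trial pipeline: gate validity, classify errors, select the
    MGS and (when present) the corrective VGS, compute metrics."""
    valid, reason = validate_trial(trial, events, trace, rules)
    if not valid:
        return TrialOutcome(trial=trial, valid=False, rejection_reason=reason, outcome=None)
    err, err_onset = classify_error(trial, events, rules)
    if err is not None:
        return TrialOutcome(trial=trial, valid=True, rejection_reason=None,
                            outcome=err, error_onset_ms=err_onset)
    mgs = extract_mgs(trial, events, trace, rules)
    if mgs is None:
        return TrialOutcome(trial=trial, valid=True, rejection_reason=None, outcome="omission")
    mgs_metrics = saccade_metrics(mgs, trial.eccentricity_deg,
                                  mgs.onset_ms - trial.go_signal_abs_ms)
    out = TrialOutcome(trial=trial, valid=True, rejection_reason=None,
                       outcome="valid_mgs", mgs=mgs_metrics)
    vgs = extract_corrective_vgs(trial, events, rules)
    if vgs is not None:
        out.vgs = saccade_metrics(vgs, trial.eccentricity_deg,
                                  vgs.onset_ms - trial.confirmation_onset_abs_ms)
    return out


@dataclass
class SubjectSummary:
    """Per-subject aggregation: five session rates and near/far mean-SD of
    the seven metrics for MGS and corrective VGS.

    ``%MGS`` is referred to the total number of session trials; the other
    four rates to the number of valid trials (as the indicators are
    defined).  ``usable`` is False below 7 valid trials.
    """

    subject_id: str
    n_trials: int
    n_valid: int
    pct_mgs: float
    pct_corr_vgs: float
    pct_early_error: float
    pct_late_error: float
    pct_total_error: float
    usable: bool
    metrics: dict = field(default_factory=dict)  # (type, ecc, metric) -> (mean, sd)

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "n_trials": self.n_trials,
            "n_valid": self.n_valid,
            "usable": self.usable,
            "%MGS": self.pct_mgs,
            "%CorrVGS": self.pct_corr_vgs,
            "%EarlyErrorRate": self.pct_early_error,
            "%LateErrorRate": self.pct_late_error,
            "%TotalErrorRate": self.pct_total_error,
        }
        for typ in ("mgs", "vgs"):
            for ecc in ("near", "far"):
                for m in METRICS:
                    mean, sd = self.metrics.get((typ, ecc, m), (np.nan, np.nan))
                    row[f"{typ}_{ecc}_{m}_mean"] = mean
                    row[f"{typ}_{ecc}_{m}_sd"] = sd
        return row


def summarize_subject(outcomes: list[TrialOutcome], subject_id: str = "S000",
                      rules: TrialRules = TrialRules()) -> SubjectSummary:
    """Aggregate a session's trial outcomes into a SubjectSummary.

    Means use all contributing trials; SDs are sample SDs (n-1, NaN below
    two trials).  With zero valid trials all rates on the valid-trial
    denominator are NaN and the summary is flagged unusable.
    """
    n_total = len(outcomes)
    valid = [o for o in outcomes if o.valid]
    n_valid = len(valid)
    n_mgs = sum(1 for o in valid if o.outcome == "valid_mgs")
    n_vgs = sum(1 for o in valid if o.vgs is not None)
    n_early = sum(1 for o in valid if o.outcome == "early_error")
    n_late = sum(1 for o in valid if o.outcome == "late_error")

    pct_mgs = 100.0 * n_mgs / n_total if n_total else np.nan
    if n_valid:
        pct_vgs = 100.0 * n_vgs / n_valid
        pct_early = 100.0 * n_early / n_valid
        pct_late = 100.0 * n_late / n_valid
    else:
        pct_vgs = pct_early = pct_late = np.nan

    metrics: dict = {}
    for typ in ("mgs", "vgs"):
        for ecc in ("near", "far"):
            rows = [getattr(o, typ) for o in valid
                    if getattr(o, typ) is not None and o.trial.eccentricity_class == ecc]
            for m in METRICS:
                vals = np.array([r[m] for r in rows], dtype=float)
                if len(vals) == 0:
                    metrics[(typ, ecc, m)] = (np.nan, np.nan)
                else:
                    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
                    metrics[(typ, ecc, m)] = (float(np.mean(vals)), sd)

    return SubjectSummary(
        subject_id=subject_id, n_trials=n_total, n_valid=n_valid,
        pct_mgs=pct_mgs, pct_corr_vgs=pct_vgs,
        pct_early_error=pct_early, pct_late_error=pct_late,
        pct_total_error=pct_early + pct_late,
        usable=n_valid >= rules.min_valid_trials,
        metrics=metrics,
    )


def outcomes_to_frame(outcomes: list[TrialOutcome], subject_id: str = "S000") -> pd.DataFrame:
    """One row per trial: validity, outcome, and the 7+7 metrics + gains."""
    rows = []
    for o in outcomes:
        row = {
            "subject_id": subject_id,
            "trial": o.trial.index,
            "side": o.trial.side,
            "eccentricity_deg": o.trial.eccentricity_deg,
            "eccentricity_class": o.trial.eccentricity_class,
            "valid": o.valid,
            "rejection_reason": o.rejection_reason,
            "outcome": o.outcome,
        }
        for typ in ("mgs", "vgs"):
            d = getattr(o, typ)
            for m in METRICS:
                row[f"{typ}_{m}"] = d[m] if d else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
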