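"""Synthetic MGST gaze sessions and cohorts with known ground truth.

Saccades are minimum-jerk trajectories whose kinematics follow the main
sequence: the target peak velocity is Vmax*(1 - exp(-A/c)) and the
duration is max(2.2*A + 21 ms, the duration at which the minimum-jerk
peak 1.875*A/D equals that target), so at paradigm amplitudes the peak
velocity matches the main-sequence value exactly.  Fixation noise is
temporally correlated (AR(1), ~100 ms time constant) Gaussian noise per
eye, matching video-tracker behaviour where slow drift dominates the
marginal SD and sample-to-sample precision is far smaller.  Blinks are
runs of invalid samples in both eyes.  Cohorts couple subject covariates
(age, MoCA, HADS, Color Trails, digit span, processing speed) to the
subject-level generating parameters through a Gaussian copula, so that
statistical recovery is an end-to-end test of the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .paradigm import (
    ParadigmSpec, ScreenGeometry, TrialTemplate, build_trial_schedule, degree_to_pixel,
)
from .preprocess import GazeRecording

__all__ = [
    "SubjectProfile", "TrialTruth", "GroundTruth", "CohortSpec", "CohortSample",
    "saccade_waveform", "simulate_session", "simulate_cohort",
]

#: minimum physiological saccade latency (ms); Normal draws are truncated here
MIN_LATENCY_MS = 80.0


@dataclass(frozen=True)
class SubjectProfile:
    """Generating parameters of one simulated subject.

    Latencies in ms, amplitudes/noise in degrees, velocities in deg/s.
    ``mgs_gain_mean`` is the mean ratio of MGS amplitude to target
    eccentricity (memory-guided saccades are typically hypometric).
    ``early/late/omission`` probabilities are per-trial outcome rates;
    the remainder is the probability of a correctly executed MGS trial.
    """

    mgs_latency_mean: float = 400.0
    mgs_latency_sd: float = 80.0
    mgs_gain_mean: float = 0.9
    mgs_gain_sd: float = 0.08
    vgs_latency_mean: float = 250.0
    vgs_latency_sd: float = 50.0
    main_sequence_vmax: float = 500.0
    main_sequence_c: float = 14.0
    fixation_noise_sd: float = 0.15
    early_error_prob: float = 0.10
    late_error_prob: float = 0.15
    omission_prob: float = 0.05
    blink_rate_per_trial: float = 0.10
    blink_duration_mean_ms: float = 150.0
    blink_duration_sd_ms: float = 40.0
    interocular_offset_deg: float = 0.5

    def __post_init__(self) -> None:
        for name in ("early_error_prob", "late_error_prob", "omission_prob",
                     "blink_rate_per_trial"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.early_error_prob + self.late_error_prob + self.omission_prob > 1.0 + 1e-12:
            raise ValueError("outcome probabilities must sum to <= 1")
        for name in ("mgs_latency_sd", "mgs_gain_sd", "vgs_latency_sd",
                     "fixation_noise_sd", "blink_duration_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.main_sequence_vmax <= 0 or self.main_sequence_c <= 0:
            raise ValueError("main-sequence parameters must be > 0")


@dataclass
class TrialTruth:
    """Ground-truth outcome and kinematics of one simulated trial."""

    label: str                       # valid_mgs | early_error | late_error | omission
    mgs_onset_ms: float | None = None      # absolute session time
    mgs_offset_ms: float | None = None
    mgs_amplitude_deg: float | None = None
    mgs_peak_velocity_deg_s: float | None = None
    vgs_onset_ms: float | None = None
    error_onset_ms: float | None = None
    blinks_ms: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Per-trial truth for a session, serializable as a JSON sidecar."""

    trials: list[TrialTruth]

    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(t) for t in self.trials], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        trials = []
        for d in raw:
            d["blinks_ms"] = [tuple(b) for b in d.get("blinks_ms", [])]
            trials.append(TrialTruth(**d))
        return cls(trials)


# ---------------------------------------------------------------------------
# saccade kinematics
# ---------------------------------------------------------------------------

def _minjerk_s(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]; s(0)=0, s(1)=1."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def main_sequence_peak_velocity(amplitude_deg: float, vmax: float, c: float) -> float:
    """Saturating main-sequence peak velocity Vmax*(1 - exp(-A/c)), deg/s."""
    return vmax * (1.0 - np.exp(-amplitude_deg / c))


def saccade_duration_ms(amplitude_deg: float, vmax: float, c: float) -> float:
    """Duration reconciling the linear main-sequence duration rule with the
    minimum-jerk shape: max(2.2A + 21, 1875*A/Vpeak) ms, so the waveform's
    actual peak (1.875*A/D) never exceeds the main-sequence value."""
    vpeak = main_sequence_peak_velocity(amplitude_deg, vmax, c)
    return max(2.2 * amplitude_deg + 21.0, 1875.0 * amplitude_deg / vpeak)


def saccade_waveform(start_deg: float, end_deg: float,
                     profile: SubjectProfile = SubjectProfile(),
                     rate_hz: float = 250.0):
    """Sampled minimum-jerk saccade from ``start_deg`` to ``end_deg``.

    Returns ``(t_ms, pos_deg, kinematics)`` where ``t_ms`` are sample
    offsets from movement onset and ``kinematics`` holds the analytic
    amplitude, duration, peak velocity (= 1.875*A/D, the true peak of the
    generated waveform), and time to peak (= D/2, symmetric profile).
    Amplitudes below 0.1 deg are rejected as sub-resolution.
    """
    amp = abs(end_deg - start_deg)
    if not np.isfinite(amp) or amp < 0.1:
        raise ValueError("saccade amplitude must be >= 0.1 deg")
    dur_ms = saccade_duration_ms(amp, profile.main_sequence_vmax, profile.main_sequence_c)
    dt_ms = 1000.0 / rate_hz
    t_ms = np.arange(0.0, dur_ms + dt_ms, dt_ms)
    tau = np.clip(t_ms / dur_ms, 0.0, 1.0)
    pos = start_deg + (end_deg - start_deg) * _minjerk_s(tau)
    kin = {
        "amplitude_deg": amp,
        "duration_ms": dur_ms,
        "peak_velocity_deg_s": 1.875 * amp / (dur_ms / 1000.0),
        "time_to_peak_ms": dur_ms / 2.0,
    }
    return t_ms, pos, kin


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def _ar1_noise(rng: np.random.Generator, n: int, sd: float, dt_ms: float,
               tau_ms: float = 100.0) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` and time constant
    ``tau_ms`` (slow drift dominating, small sample-to-sample jitter)."""
    if sd == 0.0:
        return np.zeros(n)
    phi = np.exp(-dt_ms / tau_ms)
    w = rng.standard_normal(n) * sd * np.sqrt(1.0 - phi**2)
    w[0] = rng.standard_normal() * sd
    return _signal.lfilter([1.0], [1.0, -phi], w)


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


class _Session:
    """Accumulates piecewise-constant + minimum-jerk horizontal position."""

    def __init__(self, n: int, dt_ms: float, profile: SubjectProfile):
        self.x = np.zeros(n)
        self.dt_ms = dt_ms
        self.profile = profile
        self.moves: list[tuple[float, float, float, float]] = []  # onset, x0, x1, dur
        self.cur = 0.0

    def add_move(self, onset_ms: float, target_deg: float) -> dict:
        amp = abs(target_deg - self.cur)
        if amp < 1e-9:  # no-op move (already there)
            return {"onset_ms": onset_ms, "offset_ms": onset_ms, "amplitude_deg": 0.0,
                    "peak_velocity_deg_s": 0.0}
        dur = saccade_duration_ms(amp, self.profile.main_sequence_vmax,
                                  self.profile.main_sequence_c)
        self.moves.append((onset_ms, self.cur, target_deg, dur))
        kin = {
            "onset_ms": onset_ms, "offset_ms": onset_ms + dur, "amplitude_deg": amp,
            "peak_velocity_deg_s": 1.875 * amp / (dur / 1000.0),
        }
        self.cur = target_deg
        return kin

    def render(self) -> np.ndarray:
        n = len(self.x)
        t = np.arange(n) * self.dt_ms
        for onset, x0, x1, dur in sorted(self.moves):
            i0 = int(np.searchsorted(t, onset))
            i1 = int(np.searchsorted(t, onset + dur))
            tau = np.clip((t[i0:i1] - onset) / dur, 0.0, 1.0)
            self.x[i0:i1] = x0 + (x1 - x0) * _minjerk_s(tau)
            self.x[i1:] = x1
        return self.x


def simulate_session(schedule: list[TrialTemplate],
                     profile: SubjectProfile = SubjectProfile(),
                     geom: ScreenGeometry = ScreenGeometry(),
                     seed: int = 0,
                     paradigm: ParadigmSpec = ParadigmSpec()) -> tuple[GazeRecording, GroundTruth]:
    """Simulate one 250 Hz binocular MGST session with ground truth.

    Per trial the outcome is drawn from the profile's probabilities.  A
    correct trial holds fixation through the memorization phase, makes an
    MGS (truncated-Normal latency, amplitude = gain x eccentricity) in the
    reaction interval, a corrective VGS onto the target in the confirmation
    interval when the MGS under/overshoots by >= 0.1 deg, and a return
    saccade to center in the intertrial interval.  Error trials break
    fixation during the memorization phase (early: 90-270 ms after flash
    onset; late: 340-1250 ms) and return to center 500 ms later.  Omission
    trials hold fixation throughout.  Both eyes are the cyclopean signal
    displaced horizontally by +/- half the interocular offset, plus
    independent AR(1) noise per eye; blinks invalidate both eyes.
    """
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / paradigm.sample_rate_hz
    total_ms = len(schedule) * paradigm.trial_duration_ms
    n = int(round(total_ms / dt_ms))
    sess = _Session(n, dt_ms, profile)
    truths: list[TrialTruth] = []
    valid = np.ones(n, dtype=bool)

    pe, pl, po = profile.early_error_prob, profile.late_error_prob, profile.omission_prob
    for tpl in schedule:
        t0 = tpl.start_ms
        target = tpl.signed_eccentricity_deg
        u = rng.random()
        if u < pe:
            onset = tpl.flash_onset_abs_ms + rng.uniform(90.0, 270.0)
            amp = rng.uniform(3.0, 8.0) * rng.choice([-1.0, 1.0])
            sess.add_move(onset, amp)
            sess.add_move(onset + 500.0, 0.0)
            truth = TrialTruth(label="early_error", error_onset_ms=onset)
        elif u < pe + pl:
            onset = tpl.flash_onset_abs_ms + rng.uniform(340.0, 1250.0)
            amp = rng.uniform(3.0, 8.0) * rng.choice([-1.0, 1.0])
            sess.add_move(onset, amp)
            sess.add_move(onset + 500.0, 0.0)
            truth = TrialTruth(label="late_error", error_onset_ms=onset)
        elif u < pe + pl + po:
            truth = TrialTruth(label="omission")
        else:
            lat = _truncnorm(rng, profile.mgs_latency_mean, profile.mgs_latency_sd,
                             MIN_LATENCY_MS, 1200.0)
            gain = _truncnorm(rng, profile.mgs_gain_mean, profile.mgs_gain_sd, 0.2, 1.5)
            kin = sess.add_move(tpl.go_signal_abs_ms + lat, gain * target)
            truth = TrialTruth(
                label="valid_mgs",
                mgs_onset_ms=kin["onset_ms"], mgs_offset_ms=kin["offset_ms"],
                mgs_amplitude_deg=kin["amplitude_deg"],
                mgs_peak_velocity_deg_s=kin["peak_velocity_deg_s"],
            )
            if abs(target - gain * target) >= 0.1:
                vlat = _truncnorm(rng, profile.vgs_latency_mean, profile.vgs_latency_sd,
                                  MIN_LATENCY_MS, 2000.0)
                vkin = sess.add_move(tpl.confirmation_onset_abs_ms + vlat, target)
                truth.vgs_onset_ms = vkin["onset_ms"]
            sess.add_move(tpl.end_abs_ms - paradigm.intertrial_ms + 120.0, 0.0)
        # blinks: both eyes invalid for a truncated-Normal duration
        if rng.random() < profile.blink_rate_per_trial:
            dur = _truncnorm(rng, profile.blink_duration_mean_ms,
                             profile.blink_duration_sd_ms, 40.0, 500.0)
            b0 = t0 + rng.uniform(0.0, paradigm.trial_duration_ms - dur)
            i0, i1 = int(b0 / dt_ms), int((b0 + dur) / dt_ms)
            valid[i0:i1] = False
            truth.blinks_ms.append((b0, b0 + dur))
        truths.append(truth)

    x = sess.render()
    y = np.zeros(n)
    off = profile.interocular_offset_deg / 2.0
    lx = x - off + _ar1_noise(rng, n, profile.fixation_noise_sd, dt_ms)
    rx = x + off + _ar1_noise(rng, n, profile.fixation_noise_sd, dt_ms)
    ly = y + _ar1_noise(rng, n, profile.fixation_noise_sd, dt_ms)
    ry = y + _ar1_noise(rng, n, profile.fixation_noise_sd, dt_ms)

    cx, cy = geom.center_px
    rec = GazeRecording(
        t_us=np.arange(n, dtype=np.int64) * int(round(dt_ms * 1000)),
        left_x_px=cx + degree_to_pixel(lx, geom),
        left_y_px=cy + degree_to_pixel(ly, geom),
        right_x_px=cx + degree_to_pixel(rx, geom),
        right_y_px=cy + degree_to_pixel(ry, geom),
        left_valid=valid.copy(), right_valid=valid.copy(),
        geometry=geom, schedule=schedule,
    )
    rec.left_x_px[~valid] = np.nan
    rec.left_y_px[~valid] = np.nan
    rec.right_x_px[~valid] = np.nan
    rec.right_y_px[~valid] = np.nan
    return rec, GroundTruth(truths)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: subject-profile parameters the cohort copula can couple covariates to
MODELLED_PARAMS = (
    "early_error_prob", "late_error_prob", "omission_prob",
    "mgs_latency_mean", "mgs_gain_mean", "vgs_latency_mean",
)

COVARIATE_COLUMNS = (
    "age", "gender", "MOTS-1", "HDTSA-1", "HDTSD-1",
    "CLRES01-1", "CLRES02-1", "CLRES03-1", "CLRES04-1", "CLRES05-1",
    "CLRES06-1", "CLRES07-1", "CLRES08-1", "CLRES09-1",
    "DGFRES-1", "DGBRES-1", "PSCNUM-1", "PSSCNUM-1", "PSSINUM-1",
)

# marginal quantile functions (uniform -> value) for covariates and params
_AGE = _stats.truncnorm((18 - 59.94) / 10.88, (80 - 59.94) / 10.88, loc=59.94, scale=10.88)


def _round_clip_norm(u, mean, sd, lo, hi):
    return np.round(np.clip(_stats.norm.ppf(u, mean, sd), lo, hi))


_COVARIATE_PPF = {
    "age": lambda u: _AGE.ppf(u),
    "gender": lambda u: np.where(u < 0.774, "male", "female"),
    "MOTS-1": lambda u: _round_clip_norm(u, 24, 3, 0, 30),
    "HDTSA-1": lambda u: _round_clip_norm(u, 7, 3.5, 0, 21),
    "HDTSD-1": lambda u: _round_clip_norm(u, 6, 3, 0, 21),
    "CLRES01-1": lambda u: _stats.lognorm.ppf(u, 0.35, scale=60.0),
    "CLRES02-1": lambda u: _stats.poisson.ppf(u, 1.0),
    "CLRES03-1": lambda u: _stats.poisson.ppf(u, 1.0),
    "CLRES04-1": lambda u: _stats.poisson.ppf(u, 0.5),
    "CLRES05-1": lambda u: _stats.lognorm.ppf(u, 0.35, scale=120.0),
    "CLRES06-1": lambda u: _stats.poisson.ppf(u, 1.0),
    "CLRES07-1": lambda u: _stats.poisson.ppf(u, 1.0),
    "CLRES08-1": lambda u: _stats.poisson.ppf(u, 1.0),
    "CLRES09-1": lambda u: _stats.poisson.ppf(u, 0.5),
    "DGFRES-1": lambda u: _round_clip_norm(u, 9, 2, 0, 16),
    "DGBRES-1": lambda u: _round_clip_norm(u, 7, 2, 0, 14),
    "PSCNUM-1": lambda u: _round_clip_norm(u, 45, 12, 0, 135),
    "PSSCNUM-1": lambda u: _round_clip_norm(u, 24, 6, 0, 60),
    "PSSINUM-1": lambda u: _stats.poisson.ppf(u, 1.5),
}

_PARAM_PPF = {
    "early_error_prob": lambda u: _stats.beta.ppf(u, 2.0, 12.0),
    "late_error_prob": lambda u: _stats.beta.ppf(u, 2.5, 7.5),
    "omission_prob": lambda u: _stats.beta.ppf(u, 1.5, 13.5),
    "mgs_latency_mean": lambda u: _stats.truncnorm.ppf(u, (200 - 400) / 70, (800 - 400) / 70, loc=400, scale=70),
    "mgs_gain_mean": lambda u: _stats.truncnorm.ppf(u, (0.5 - 0.9) / 0.08, (1.2 - 0.9) / 0.08, loc=0.9, scale=0.08),
    "vgs_latency_mean": lambda u: _stats.truncnorm.ppf(u, (120 - 250) / 40, (500 - 250) / 40, loc=250, scale=40),
}

#: default covariate-parameter coupling: observed stroke-cohort associations
#: (age with late fixation-break errors and with failure to produce an MGS;
#: anxiety with early fixation-break errors)
DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("age", "late_error_prob"): 0.327,
    ("age", "omission_prob"): 0.274,
    ("HDTSA-1", "early_error_prob"): 0.325,
}


@dataclass
class CohortSpec:
    """Cohort-level generating conditions.

    ``correlations`` maps (covariate, profile parameter) to a target
    Spearman rank correlation, induced through a Gaussian copula on the
    subject-level generating parameters.  ``age_slope_late_pct`` switches
    the late-error channel to an explicit linear model: the subject's
    late-error probability (in percent) is
    ``late_base_pct + slope * (age - 60) + Normal(0, late_resid_sd_pct)``,
    clipped to [0.5, 70] — used for regression-recovery experiments.
    """

    base_profile: SubjectProfile = field(default_factory=SubjectProfile)
    correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    age_slope_late_pct: float | None = None
    late_base_pct: float = 30.0
    late_resid_sd_pct: float = 5.0
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)


@dataclass
class CohortSample:
    """Simulated cohort: covariates, per-subject profiles, recordings or
    outcome draws, and the latent correlation metadata."""

    covariates: pd.DataFrame
    profiles: list[SubjectProfile]
    recordings: list[tuple[GazeRecording, GroundTruth]] | None
    outcome_rates: pd.DataFrame | None
    latent_correlation: pd.DataFrame


def _copula_draw(n: int, spec: CohortSpec, rng: np.random.Generator):
    names = list(COVARIATE_COLUMNS) + list(MODELLED_PARAMS)
    idx = {v: i for i, v in enumerate(names)}
    corr = np.eye(len(names))
    for (cov, par), rho in spec.correlations.items():
        if cov not in _COVARIATE_PPF:
            raise ValueError(f"unknown covariate {cov!r}")
        if par not in MODELLED_PARAMS:
            raise ValueError(
                f"{par!r} is not a modelled profile parameter; choose from {MODELLED_PARAMS}")
        if not -1.0 < rho < 1.0:
            raise ValueError("target correlations must lie in (-1, 1)")
        r = 2.0 * np.sin(np.pi * rho / 6.0)  # Spearman -> Gaussian latent
        corr[idx[cov], idx[par]] = corr[idx[par], idx[cov]] = r
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError("requested correlation matrix is not positive semi-definite")
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((n, len(names))) @ chol.T
    u = _stats.norm.cdf(z)
    return names, u, pd.DataFrame(corr, index=names, columns=names)


def _rates_from_outcomes(labels: np.ndarray, corr_present: np.ndarray) -> dict:
    n = len(labels)
    n_mgs = int(np.sum(labels == 3))
    rates = {
        "n_trials": n, "n_valid": n,
        "%MGS": 100.0 * n_mgs / n,
        "%CorrVGS": 100.0 * int(corr_present.sum()) / n,
        "%EarlyErrorRate": 100.0 * int(np.sum(labels == 0)) / n,
        "%LateErrorRate": 100.0 * int(np.sum(labels == 1)) / n,
    }
    rates["%TotalErrorRate"] = rates["%EarlyErrorRate"] + rates["%LateErrorRate"]
    return rates


def simulate_cohort(n_subjects: int, cohort_spec: CohortSpec = CohortSpec(),
                    seed: int = 0, signals: bool = True) -> CohortSample:
    """Simulate a cohort of subjects with coupled covariates.

    With ``signals=True`` each subject gets a full simulated recording
    (plus ground truth); with ``signals=False`` only per-trial outcome
    draws are made and summarised into the five session rates — the
    behavioural level, sufficient and fast for statistical calibration.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    names, u, latent = _copula_draw(n_subjects, cohort_spec, rng)

    cov = {}
    for j, name in enumerate(COVARIATE_COLUMNS):
        cov[name] = _COVARIATE_PPF[name](u[:, j])
    covariates = pd.DataFrame(cov)
    covariates.insert(0, "subject_id", [f"S{i:03d}" for i in range(n_subjects)])

    off = len(COVARIATE_COLUMNS)
    params = {p: _PARAM_PPF[p](u[:, off + k]) for k, p in enumerate(MODELLED_PARAMS)}
    if cohort_spec.age_slope_late_pct is not None:
        pct = (cohort_spec.late_base_pct
               + cohort_spec.age_slope_late_pct * (covariates["age"].to_numpy() - 60.0)
               + rng.normal(0.0, cohort_spec.late_resid_sd_pct, n_subjects))
        params["late_error_prob"] = np.clip(pct, 0.5, 70.0) / 100.0

    base = cohort_spec.base_profile
    profiles = []
    for i in range(n_subjects):
        kw = {p: float(params[p][i]) for p in MODELLED_PARAMS}
        # keep the outcome simplex feasible
        total = kw["early_error_prob"] + kw["late_error_prob"] + kw["omission_prob"]
        if total > 0.95:
            for p in ("early_error_prob", "late_error_prob", "omission_prob"):
                kw[p] *= 0.95 / total
        profiles.append(SubjectProfile(
            **kw,
            mgs_latency_sd=base.mgs_latency_sd, mgs_gain_sd=base.mgs_gain_sd,
            vgs_latency_sd=base.vgs_latency_sd,
            main_sequence_vmax=base.main_sequence_vmax, main_sequence_c=base.main_sequence_c,
            fixation_noise_sd=base.fixation_noise_sd,
            blink_rate_per_trial=base.blink_rate_per_trial,
            blink_duration_mean_ms=base.blink_duration_mean_ms,
            blink_duration_sd_ms=base.blink_duration_sd_ms,
            interocular_offset_deg=base.interocular_offset_deg,
        ))

    recordings = None
    outcome_rates = None
    if signals:
        recordings = []
        for i, prof in enumerate(profiles):
            schedule = build_trial_schedule(cohort_spec.paradigm, seed=int(rng.integers(2**31)))
            recordings.append(simulate_session(
                schedule, prof, cohort_spec.geometry,
                seed=int(rng.integers(2**31)), paradigm=cohort_spec.paradigm))
    else:
        n_trials = cohort_spec.paradigm.n_trials
        rows = []
        for i, prof in enumerate(profiles):
            p = [prof.early_error_prob, prof.late_error_prob, prof.omission_prob]
            p.append(max(0.0, 1.0 - sum(p)))
            labels = rng.choice(4, size=n_trials, p=np.asarray(p) / np.sum(p))
            gains = rng.normal(prof.mgs_gain_mean, prof.mgs_gain_sd, n_trials)
            ecc = rng.choice([10.0, 18.0], size=n_trials)
            corr_present = (labels == 3) & (np.abs(1.0 - gains) * ecc >= 1.0)
            row = {"subject_id": f"S{i:03d}", **_rates_from_outcomes(labels, corr_present)}
            rows.append(row)
        outcome_rates = pd.DataFrame(rows)

    return CohortSample(covariates=covariates, profiles=profiles,
                       recordings=recordings, outcome_rates=outcome_rates,
                       latent_correlation=latent)
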