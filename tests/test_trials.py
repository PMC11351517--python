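"""Trial gating, saccade selection, error taxonomy, and aggregation."""

import numpy as np
import pytest

from mgst.events import SACCADE, GAP, OculomotorEvent
from mgst.paradigm import build_trial_schedule, pixel_to_degree
from mgst.pipeline import process_recording
from mgst.preprocess import angular_velocity, average_eyes
from mgst.synthgaze import SubjectProfile, simulate_session
from mgst.trials import (TrialRules, analyze_trial, classify_error, extract_mgs,
                         extract_corrective_vgs, saccade_metrics, summarize_subject,
                         validate_trial)

from conftest import recording_from_degrees


def _sac(onset, offset, x0, x1, peak=200.0):
    return OculomotorEvent(kind=SACCADE, onset_ms=onset, offset_ms=offset,
                           start_x=x0, start_y=0.0, end_x=x1, end_y=0.0,
                           amplitude_deg=abs(x1 - x0), mean_velocity_deg_s=peak / 2,
                           peak_velocity_deg_s=peak, time_to_peak_ms=(offset - onset) / 2)


@pytest.fixture()
def trial(schedule):
    return schedule[0]  # start_ms = 0: flash 1500, go 3000, confirmation 4500


@pytest.fixture()
def centered_trace(schedule):
    n = 2000  # 8 s at 250 Hz covers one trial
    return angular_velocity(average_eyes(recording_from_degrees(
        np.zeros(n), schedule=schedule)))


class TestValidateTrial:
    def test_centered_quiet_gaze_valid(self, trial, centered_trace):
        valid, reason = validate_trial(trial, [], centered_trace)
        assert valid and reason is None

    def test_off_center_rejected(self, trial, schedule):
        x = np.full(2000, pixel_to_degree(150.0))  # parked at +150 px
        trace = angular_velocity(average_eyes(recording_from_degrees(x, schedule=schedule)))
        valid, reason = validate_trial(trial, [], trace)
        assert not valid and reason == "off-center"

    def test_saccade_in_window_rejected(self, trial, centered_trace):
        ev = [_sac(1460, 1480, 0.0, 2.0)]
        valid, reason = validate_trial(trial, ev, centered_trace)
        assert not valid and reason == "saccade"

    def test_blink_in_window_rejected(self, trial, schedule):
        valid_mask = np.ones(2000, dtype=bool)
        valid_mask[365:370] = False  # 1460-1480 ms
        trace = angular_velocity(average_eyes(recording_from_degrees(
            np.zeros(2000), valid=valid_mask, schedule=schedule)))
        valid, reason = validate_trial(trial, [], trace)
        assert not valid and reason == "blink"

    def test_saccade_outside_window_ok(self, trial, centered_trace):
        ev = [_sac(1300, 1340, 0.0, 2.0)]
        valid, _ = validate_trial(trial, ev, centered_trace)
        assert valid


class TestClassifyError:
    def test_break_at_250ms_is_early(self, trial):
        label, onset = classify_error(trial, [_sac(1750, 1800, 0.0, 5.0)])
        assert label == "early_error" and onset == pytest.approx(250.0)

    def test_break_at_400ms_is_late(self, trial):
        label, _ = classify_error(trial, [_sac(1900, 1950, 0.0, 5.0)])
        assert label == "late_error"

    def test_boundary_300ms_is_early(self, trial):
        label, _ = classify_error(trial, [_sac(1800, 1850, 0.0, 5.0)])
        assert label == "early_error"

    def test_no_saccade_no_error(self, trial):
        assert classify_error(trial, []) == (None, None)

    def test_subamplitude_saccade_ignored(self, trial):
        label, _ = classify_error(trial, [_sac(1750, 1800, 0.0, 0.5)])
        assert label is None

    def test_saccade_after_memorization_not_error(self, trial):
        assert classify_error(trial, [_sac(3200, 3260, 0.0, 9.0)])[0] is None


class TestExtractMGS:
    def test_clean_first_saccade_selected(self, trial, centered_trace):
        target = trial.signed_eccentricity_deg
        sac = _sac(3250, 3320, 0.0, 0.9 * target)
        out = extract_mgs(trial, [sac], centered_trace)
        assert out is sac
        assert out.onset_ms - trial.go_signal_abs_ms == pytest.approx(250.0)

    def test_subamplitude_first_saccade_is_omission(self, trial, centered_trace):
        sign = np.sign(trial.signed_eccentricity_deg)
        out = extract_mgs(trial, [_sac(3250, 3300, 0.0, 0.8 * sign)], centered_trace)
        assert out is None

    def test_dirty_history_is_omission(self, trial, centered_trace):
        target = trial.signed_eccentricity_deg
        prior = _sac(3180, 3200, 0.0, 0.3)
        mgs = _sac(3250, 3320, 0.3, 0.9 * target)
        assert extract_mgs(trial, [prior, mgs], centered_trace) is None

    def test_gap_in_history_is_omission(self, trial, centered_trace):
        target = trial.signed_eccentricity_deg
        gap = OculomotorEvent(kind=GAP, onset_ms=3180, offset_ms=3220)
        mgs = _sac(3250, 3320, 0.0, 0.9 * target)
        assert extract_mgs(trial, [gap, mgs], centered_trace) is None

    def test_wrong_direction_is_omission(self, trial, centered_trace):
        target = trial.signed_eccentricity_deg
        out = extract_mgs(trial, [_sac(3250, 3320, 0.0, -0.9 * target)], centered_trace)
        assert out is None

    def test_wrong_direction_allowed_when_configured(self, trial, centered_trace):
        target = trial.signed_eccentricity_deg
        rules = TrialRules(require_direction=False)
        out = extract_mgs(trial, [_sac(3250, 3320, 0.0, -0.9 * target)],
                          centered_trace, rules)
        assert out is not None

    def test_off_center_start_is_omission(self, trial, centered_trace):
        target = trial.signed_eccentricity_deg
        start = 3.0 * np.sign(target)  # outside the ~2.34 deg band
        out = extract_mgs(trial, [_sac(3250, 3320, start, start + 0.9 * target)],
                          centered_trace)
        assert out is None


class TestCorrectiveVGS:
    def test_corrective_toward_target_selected(self, trial):
        target = trial.signed_eccentricity_deg
        vgs = _sac(4680, 4730, 0.8 * target, target)
        out = extract_corrective_vgs(trial, [vgs])
        assert out is vgs

    def test_saccade_away_from_target_rejected(self, trial):
        target = trial.signed_eccentricity_deg
        away = _sac(4680, 4730, 0.8 * target, 0.6 * target)
        assert extract_corrective_vgs(trial, [away]) is None

    def test_absent_when_no_confirmation_saccade(self, trial):
        assert extract_corrective_vgs(trial, []) is None


class TestSaccadeMetrics:
    def test_gain_formula(self):
        m = saccade_metrics(_sac(3250, 3320, 0.0, 9.0), 10.0, 250.0)
        assert m["gain"] == pytest.approx(90.0)
        m = saccade_metrics(_sac(3250, 3320, 0.0, 18.0), 18.0, 250.0)
        assert m["gain"] == pytest.approx(100.0)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            saccade_metrics(_sac(0, 50, 0.0, 9.0), 0.0, 100.0)

    def test_time_to_peak_of_symmetric_saccade(self, spec, geom, quiet_profile, schedule):
        # minimum-jerk saccades peak mid-flight: time-to-peak ~ duration/2
        rec, _ = simulate_session(schedule, quiet_profile, geom, seed=21)
        outcomes = process_recording(rec)
        for o in outcomes:
            if o.mgs is not None:
                assert abs(o.mgs["time_to_peak"] - o.mgs["duration"] / 2) <= 8.0 + 1e-9


class TestSummaries:
    def _outcomes(self, schedule, labels, vgs_on_valid=True):
        out = []
        from mgst.trials import TrialOutcome
        for tpl, lab in zip(schedule, labels):
            valid = lab != "invalid"
            oc = TrialOutcome(trial=tpl, valid=valid,
                              rejection_reason=None if valid else "blink",
                              outcome=None if not valid else lab)
            if lab == "valid_mgs":
                oc.mgs = saccade_metrics(_sac(3250, 3320, 0.0, 0.9 * tpl.signed_eccentricity_deg),
                                         tpl.eccentricity_deg, 250.0)
                if vgs_on_valid:
                    oc.vgs = saccade_metrics(
                        _sac(4680, 4730, 0.9 * tpl.signed_eccentricity_deg,
                             tpl.signed_eccentricity_deg),
                        tpl.eccentricity_deg, 180.0)
            out.append(oc)
        return out

    def test_rate_denominators(self, schedule):
        # 40 trials, all valid, 30 MGS -> %MGS = 75 (total-trial denominator)
        labels = ["valid_mgs"] * 30 + ["omission"] * 10
        s = summarize_subject(self._outcomes(schedule, labels))
        assert s.pct_mgs == pytest.approx(75.0)
        assert s.pct_corr_vgs == pytest.approx(75.0)

    def test_error_rates_sum(self, schedule):
        # 10 valid trials, 2 early + 3 late -> 20 / 30 / 50
        labels = (["early_error"] * 2 + ["late_error"] * 3 + ["valid_mgs"] * 5
                  + ["invalid"] * 30)
        s = summarize_subject(self._outcomes(schedule, labels))
        assert s.pct_early_error == pytest.approx(20.0)
        assert s.pct_late_error == pytest.approx(30.0)
        assert s.pct_total_error == pytest.approx(50.0)

    def test_below_7_valid_trials_flagged(self, schedule):
        labels = ["valid_mgs"] * 6 + ["invalid"] * 34
        s = summarize_subject(self._outcomes(schedule, labels))
        assert not s.usable
        labels = ["valid_mgs"] * 7 + ["invalid"] * 33
        assert summarize_subject(self._outcomes(schedule, labels)).usable

    def test_zero_valid_trials_rates_undefined(self, schedule):
        s = summarize_subject(self._outcomes(schedule, ["invalid"] * 40))
        assert not s.usable
        assert np.isnan(s.pct_early_error) and np.isnan(s.pct_total_error)
        assert s.pct_mgs == 0.0  # total-trial denominator stays defined

    def test_near_far_split(self, schedule):
        labels = ["valid_mgs"] * 40
        s = summarize_subject(self._outcomes(schedule, labels))
        assert s.metrics[("mgs", "near", "gain")][0] == pytest.approx(90.0)
        assert s.metrics[("mgs", "far", "gain")][0] == pytest.approx(90.0)
        assert s.metrics[("mgs", "near", "amplitude")][0] == pytest.approx(9.0)
        assert s.metrics[("mgs", "far", "amplitude")][0] == pytest.approx(16.2)


class TestEndToEndRecovery:
    def test_noise_free_outcomes_match_truth(self, spec, geom):
        # 5 sessions, mixed outcomes, zero noise: 100% label agreement
        prof = SubjectProfile(fixation_noise_sd=0.0, blink_rate_per_trial=0.0,
                              interocular_offset_deg=0.0,
                              early_error_prob=0.25, late_error_prob=0.25,
                              omission_prob=0.15)
        for s in range(5):
            sched = build_trial_schedule(spec, seed=40 + s)
            rec, truth = simulate_session(sched, prof, geom, seed=50 + s)
            outcomes = process_recording(rec)
            assert all(o.valid for o in outcomes)
            assert [o.outcome for o in outcomes] == truth.labels()

    def test_every_accepted_mgs_obeys_selection_rules(self, spec, geom):
        prof = SubjectProfile(fixation_noise_sd=0.3, early_error_prob=0.2,
                              late_error_prob=0.2, omission_prob=0.1)
        band = pixel_to_degree(100.0)
        sched = build_trial_schedule(spec, seed=60)
        rec, _ = simulate_session(sched, prof, geom, seed=61)
        for o in process_recording(rec):
            if o.mgs is not None:
                assert o.mgs["amplitude"] >= 1.0
                assert 0.0 < o.mgs["latency"] <= 1500.0

    def test_rate_recovery_within_binomial_band(self, spec, geom):
        # early-error probability 0.2 recovered over 1000 simulated trials
        p = 0.2
        prof = SubjectProfile(fixation_noise_sd=0.0, blink_rate_per_trial=0.0,
                              early_error_prob=p, late_error_prob=0.0, omission_prob=0.0)
        n_early = n_valid = 0
        for s in range(25):
            sched = build_trial_schedule(spec, seed=70 + s)
            rec, _ = simulate_session(sched, prof, geom, seed=80 + s)
            for o in process_recording(rec):
                if o.valid:
                    n_valid += 1
                    n_early += o.outcome == "early_error"
        half = 1.96 * np.sqrt(p * (1 - p) / n_valid)
        assert abs(n_early / n_valid - p) <= half

    def test_more_early_errors_with_higher_probability(self, spec, geom):
        # paired seeds: increasing the generating probability increases the rate
        rates = []
        for p in (0.1, 0.4):
            prof = SubjectProfile(fixation_noise_sd=0.0, blink_rate_per_trial=0.0,
                                  early_error_prob=p, late_error_prob=0.0,
                                  omission_prob=0.0)
            n_early = 0
            for s in range(5):
                sched = build_trial_schedule(spec, seed=90 + s)
                rec, _ = simulate_session(sched, prof, geom, seed=95 + s)
                n_early += sum(o.outcome == "early_error" for o in process_recording(rec))
            rates.append(n_early)
        assert rates[1] > rates[0]
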