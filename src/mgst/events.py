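"""I-VT event detection: fixations, saccades, gaps, and the post-filters.

Samples whose windowed angular speed reaches the velocity threshold
(default 30 deg/s, inclusive) are saccadic; defined samples below it are
fixational; invalid samples form gaps.  Valid samples with undefined
velocity (window touching a gap or the recording edge) terminate events
without belonging to any — conservative segmentation.  Post-filters merge
adjacent fixations (75 ms / 0.5 deg bounds) and discard fixations shorter
than the 60 ms minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import CyclopeanTrace

__all__ = ["OculomotorEvent", "ivt_classify", "merge_fixations", "enforce_min_fixation", "detect_events"]

FIXATION = "fixation"
SACCADE = "saccade"
GAP = "gap"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class OculomotorEvent:
    """One classified interval of the cyclopean trace.

    Kinematics are populated for saccades (amplitude = angular separation
    of start and end positions; velocities from the windowed speed signal);
    centroid for fixations.  Times in ms, positions/amplitudes in degrees,
    velocities in deg/s.
    """

    kind: str
    onset_ms: float
    offset_ms: float
    start_x: float = np.nan
    start_y: float = np.nan
    end_x: float = np.nan
    end_y: float = np.nan
    centroid_x: float = np.nan
    centroid_y: float = np.nan
    amplitude_deg: float = np.nan
    mean_velocity_deg_s: float = np.nan
    peak_velocity_deg_s: float = np.nan
    time_to_peak_ms: float = np.nan

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise ValueError("event offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    def overlaps(self, t0_ms: float, t1_ms: float) -> bool:
        """True if the event intersects the half-open window [t0, t1)."""
        return self.onset_ms < t1_ms and self.offset_ms > t0_ms


def _saccade_from_run(trace: CyclopeanTrace, i0: int, i1: int) -> OculomotorEvent:
    """Build a saccade event from the inclusive sample run [i0, i1]."""
    t_ms = trace.t_ms
    dt = trace.sample_period_ms
    vel = trace.velocity_deg_s
    # end position: the sample at offset time when available and valid
    j = i1 + 1 if i1 + 1 < len(t_ms) and trace.valid[i1 + 1] else i1
    run = slice(i0, i1 + 1)
    v = vel[run]
    ipeak = i0 + int(np.nanargmax(v))
    sx, sy = trace.x_deg[i0], trace.y_deg[i0]
    ex, ey = trace.x_deg[j], trace.y_deg[j]
    return OculomotorEvent(
        kind=SACCADE,
        onset_ms=float(t_ms[i0]),
        offset_ms=float(t_ms[i1] + dt),
        start_x=float(sx), start_y=float(sy), end_x=float(ex), end_y=float(ey),
        amplitude_deg=float(np.hypot(ex - sx, ey - sy)),
        mean_velocity_deg_s=float(np.nanmean(v)),
        peak_velocity_deg_s=float(np.nanmax(v)),
        time_to_peak_ms=float(t_ms[ipeak] - t_ms[i0]),
    )


def _fixation_from_run(trace: CyclopeanTrace, i0: int, i1: int) -> OculomotorEvent:
    run = slice(i0, i1 + 1)
    t_ms = trace.t_ms
    dt = trace.sample_period_ms
    return OculomotorEvent(
        kind=FIXATION,
        onset_ms=float(t_ms[i0]),
        offset_ms=float(t_ms[i1] + dt),
        start_x=float(trace.x_deg[i0]), start_y=float(trace.y_deg[i0]),
        end_x=float(trace.x_deg[i1]), end_y=float(trace.y_deg[i1]),
        centroid_x=float(np.mean(trace.x_deg[run])),
        centroid_y=float(np.mean(trace.y_deg[run])),
    )


def ivt_classify(trace: CyclopeanTrace, threshold_deg_s: float = 30.0) -> list[OculomotorEvent]:
    """Segment the trace into fixation/saccade/gap events by velocity.

    Maximal runs of samples with speed >= threshold become saccades
    (inclusive comparison), defined samples below threshold fixations, and
    invalid samples gaps.  A saccade's offset is one sample period after
    its last above-threshold sample.
    """
    if trace.velocity_deg_s is None:
        raise ValueError("compute angular_velocity before classification")
    vel = trace.velocity_deg_s
    n = len(vel)
    cls = np.full(n, 1, dtype=np.int8)  # 1 = unknown (valid, velocity undefined)
    cls[~trace.valid] = 0               # gap
    defined = trace.valid & np.isfinite(vel)
    cls[defined & (vel >= threshold_deg_s)] = 3
    cls[defined & (vel < threshold_deg_s)] = 2

    events: list[OculomotorEvent] = []
    t_ms = trace.t_ms
    dt = trace.sample_period_ms
    edges = np.flatnonzero(np.diff(cls)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [n]))
    for i0, i1 in zip(starts, ends - 1):
        c = cls[i0]
        if c == 3:
            events.append(_saccade_from_run(trace, i0, i1))
        elif c == 2:
            events.append(_fixation_from_run(trace, i0, i1))
        elif c == 0:
            events.append(OculomotorEvent(kind=GAP, onset_ms=float(t_ms[i0]),
                                          offset_ms=float(t_ms[i1] + dt)))
        # unknown runs emit no event
    return events


def _merge_pair(f1: OculomotorEvent, f2: OculomotorEvent) -> OculomotorEvent:
    w1, w2 = f1.duration_ms, f2.duration_ms
    cx = (f1.centroid_x * w1 + f2.centroid_x * w2) / (w1 + w2)
    cy = (f1.centroid_y * w1 + f2.centroid_y * w2) / (w1 + w2)
    return OculomotorEvent(
        kind=FIXATION, onset_ms=f1.onset_ms, offset_ms=f2.offset_ms,
        start_x=f1.start_x, start_y=f1.start_y, end_x=f2.end_x, end_y=f2.end_y,
        centroid_x=cx, centroid_y=cy,
    )


def merge_fixations(events: list[OculomotorEvent], max_time_ms: float = 75.0,
                    max_angle_deg: float = 0.5) -> list[OculomotorEvent]:
    """Merge adjacent fixations separated by <= 75 ms and <= 0.5 deg.

    The separation is measured offset-to-onset; intervening short saccades
    or gaps are absorbed into the merged fixation.  Applied iteratively
    left-to-right until no merge applies; merged centroids are
    duration-weighted.
    """
    out = list(events)
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(out):
            if out[i].kind != FIXATION:
                i += 1
                continue
            # next fixation after i
            j = i + 1
            while j < len(out) and out[j].kind != FIXATION:
                j += 1
            if j >= len(out):
                break
            f1, f2 = out[i], out[j]
            gap = f2.onset_ms - f1.offset_ms
            sep = float(np.hypot(f2.centroid_x - f1.centroid_x,
                                 f2.centroid_y - f1.centroid_y))
            if gap <= max_time_ms and sep <= max_angle_deg:
                out[i: j + 1] = [_merge_pair(f1, f2)]
                changed = True
            else:
                i = j
    return out


def enforce_min_fixation(events: list[OculomotorEvent], min_ms: float = 60.0) -> list[OculomotorEvent]:
    """Reclassify fixations shorter than ``min_ms`` as unknown (inclusive
    bound: exactly 60 ms is kept); other events pass through unchanged."""
    return [
        replace(ev, kind=UNKNOWN) if ev.kind == FIXATION and ev.duration_ms < min_ms else ev
        for ev in events
    ]


def detect_events(trace: CyclopeanTrace, threshold_deg_s: float = 30.0,
                  merge_time_ms: float = 75.0, merge_angle_deg: float = 0.5,
                  min_fixation_ms: float = 60.0) -> list[OculomotorEvent]:
    """Full I-VT chain: classify, merge adjacent fixations, enforce the
    minimum fixation duration."""
    ev = ivt_classify(trace, threshold_deg_s)
    ev = merge_fixations(ev, merge_time_ms, merge_angle_deg)
    return enforce_min_fixation(ev, min_fixation_ms)
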