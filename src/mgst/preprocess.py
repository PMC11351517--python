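"""Recording-level preprocessing: gap filling, eye averaging, velocity.

Mirrors the velocity-threshold (I-VT) filter front end of a screen-based
eye tracker: short dropouts are linearly interpolated per eye (gap fill),
the two eyes are averaged into a cyclopean signal expressed in degrees of
visual angle, and angular speed is computed over a centered window.  No
additional smoothing is applied (noise reduction disabled).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

from .paradigm import ScreenGeometry, TrialTemplate, pixel_to_degree

__all__ = ["GazeRecording", "CyclopeanTrace", "fill_gaps", "average_eyes", "angular_velocity"]


def _check_uniform(t_us: np.ndarray) -> int:
    if len(t_us) < 2:
        raise ValueError("recording needs at least 2 samples")
    d = np.diff(t_us)
    if np.any(d <= 0):
        raise ValueError("timestamps must be strictly increasing")
    period = int(d[0])
    if np.any(d != period):
        raise ValueError("sampling must be uniform")
    return period


@dataclass
class GazeRecording:
    """Timestamped binocular sample sequence with per-eye validity.

    Timestamps are integer microseconds internally (4000 us at 250 Hz) to
    avoid float drift; positions are screen pixels.  ``trial_index`` is -1
    outside any trial.  The attached schedule anchors trial timelines.
    """

    t_us: np.ndarray
    left_x_px: np.ndarray
    left_y_px: np.ndarray
    right_x_px: np.ndarray
    right_y_px: np.ndarray
    left_valid: np.ndarray
    right_valid: np.ndarray
    geometry: ScreenGeometry
    schedule: list[TrialTemplate]
    trial_index: np.ndarray | None = None
    interval_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=np.int64)
        self.sample_period_us = _check_uniform(self.t_us)
        for name in ("left_x_px", "left_y_px", "right_x_px", "right_y_px"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.left_valid = np.asarray(self.left_valid, dtype=bool)
        self.right_valid = np.asarray(self.right_valid, dtype=bool)
        n = len(self.t_us)
        for name in ("left_x_px", "left_y_px", "right_x_px", "right_y_px",
                     "left_valid", "right_valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.trial_index is None:
            self.trial_index = np.full(n, -1, dtype=int)
            starts = np.array([tpl.start_ms for tpl in self.schedule])
            ends = np.array([tpl.end_abs_ms for tpl in self.schedule])
            t_ms = self.t_ms
            for k in range(len(self.schedule)):
                self.trial_index[(t_ms >= starts[k]) & (t_ms < ends[k])] = k
        if self.interval_label is None:
            from .paradigm import INTERVALS
            names = np.array(list(INTERVALS) + ["none"], dtype=object)
            labels = np.full(n, "none", dtype=object)
            t_ms = self.t_ms
            for k, tpl in enumerate(self.schedule):
                sel = self.trial_index == k
                idx = np.searchsorted(tpl.boundaries_ms, t_ms[sel] - tpl.start_ms, side="right")
                labels[sel] = names[np.minimum(idx, len(INTERVALS) - 1)]
            self.interval_label = labels

    @property
    def t_ms(self) -> np.ndarray:
        return self.t_us / 1000.0

    @property
    def sample_period_ms(self) -> float:
        return self.sample_period_us / 1000.0

    @property
    def n_samples(self) -> int:
        return len(self.t_us)


@dataclass
class CyclopeanTrace:
    """Averaged-eye gaze in degrees of visual angle from screen center.

    ``velocity_deg_s`` is NaN wherever the velocity window is not fully
    valid (edges, and samples whose window touches a gap); the tracker's
    literal deg/ms figure is available as ``velocity_deg_ms``.
    """

    t_us: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    geometry: ScreenGeometry
    schedule: list[TrialTemplate]
    velocity_deg_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=np.int64)
        self.sample_period_us = _check_uniform(self.t_us)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def t_ms(self) -> np.ndarray:
        return self.t_us / 1000.0

    @property
    def sample_period_ms(self) -> float:
        return self.sample_period_us / 1000.0

    @property
    def velocity_deg_ms(self) -> np.ndarray:
        if self.velocity_deg_s is None:
            raise ValueError("velocity has not been computed")
        return self.velocity_deg_s / 1000.0


def _fill_eye(x: np.ndarray, y: np.ndarray, valid: np.ndarray,
              max_gap_samples: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x, y, valid = x.copy(), y.copy(), valid.copy()
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run = j - i
        # interior run with both flanks valid, short enough -> interpolate
        if 0 < i and j < n and run <= max_gap_samples:
            idx = np.arange(i, j)
            x[idx] = np.interp(idx, [i - 1, j], [x[i - 1], x[j]])
            y[idx] = np.interp(idx, [i - 1, j], [y[i - 1], y[j]])
            valid[idx] = True
        i = j
    return x, y, valid


def fill_gaps(rec: GazeRecording, max_gap_ms: float = 75.0) -> GazeRecording:
    """Linearly interpolate short per-eye dropouts (gap-fill, default 75 ms).

    A run of invalid samples is filled only if it is flanked by valid
    samples on both sides and its duration (run length x sample period)
    does not exceed ``max_gap_ms``; longer runs and edge runs remain gaps.
    Idempotent.
    """
    max_gap_samples = int(np.floor(max_gap_ms / rec.sample_period_ms))
    lx, ly, lv = _fill_eye(rec.left_x_px, rec.left_y_px, rec.left_valid, max_gap_samples)
    rx, ry, rv = _fill_eye(rec.right_x_px, rec.right_y_px, rec.right_valid, max_gap_samples)
    return GazeRecording(
        t_us=rec.t_us, left_x_px=lx, left_y_px=ly, right_x_px=rx, right_y_px=ry,
        left_valid=lv, right_valid=rv, geometry=rec.geometry, schedule=rec.schedule,
        trial_index=rec.trial_index, interval_label=rec.interval_label,
    )


def average_eyes(rec: GazeRecording) -> CyclopeanTrace:
    """Cyclopean trace: mean of both eyes where both are valid, else the
    valid eye, else invalid; positions converted to degrees from center."""
    both = rec.left_valid & rec.right_valid
    left_only = rec.left_valid & ~rec.right_valid
    right_only = rec.right_valid & ~rec.left_valid
    valid = rec.left_valid | rec.right_valid

    x_px = np.full(rec.n_samples, np.nan)
    y_px = np.full(rec.n_samples, np.nan)
    x_px[both] = 0.5 * (rec.left_x_px[both] + rec.right_x_px[both])
    y_px[both] = 0.5 * (rec.left_y_px[both] + rec.right_y_px[both])
    x_px[left_only] = rec.left_x_px[left_only]
    y_px[left_only] = rec.left_y_px[left_only]
    x_px[right_only] = rec.right_x_px[right_only]
    y_px[right_only] = rec.right_y_px[right_only]

    cx, cy = rec.geometry.center_px
    x_deg = pixel_to_degree(x_px - cx, rec.geometry)
    y_deg = pixel_to_degree(y_px - cy, rec.geometry)
    return CyclopeanTrace(
        t_us=rec.t_us, x_deg=np.asarray(x_deg), y_deg=np.asarray(y_deg),
        valid=valid, geometry=rec.geometry, schedule=rec.schedule,
    )


def angular_velocity(trace: CyclopeanTrace, window_ms: float = 20.0) -> CyclopeanTrace:
    """Windowed angular speed in deg/s (default 20 ms window).

    Speed at sample i is the angular separation between the gaze positions
    at i - floor(w/2) and i + ceil(w/2) (w = window in sample periods)
    divided by the window duration, so the span is exactly ``window_ms``.
    The angle between positions is the Euclidean distance in (x deg, y deg)
    space.  Velocity is NaN wherever any sample in the span is invalid or
    the span leaves the recording.
    """
    dt = trace.sample_period_ms
    w = int(round(window_ms / dt))
    if w < 2:
        raise ValueError("velocity window must span at least 2 sample periods")
    back, fwd = w // 2, w - w // 2
    n = len(trace.t_us)
    vel = np.full(n, np.nan)

    x, y = trace.x_deg, trace.y_deg
    core = slice(back, n - fwd)
    dx = x[back + fwd:] - x[: n - back - fwd]
    dy = y[back + fwd:] - y[: n - back - fwd]
    speed = np.hypot(dx, dy) / (w * dt / 1000.0)

    # window fully valid: running AND of validity over [i-back, i+fwd]
    ok = np.ones(n - back - fwd, dtype=bool)
    valid = trace.valid
    for k in range(w + 1):
        ok &= valid[k: k + n - back - fwd]
    vel[core] = np.where(ok, speed, np.nan)
    return CyclopeanTrace(
        t_us=trace.t_us, x_deg=x, y_deg=y, valid=trace.valid,
        geometry=trace.geometry, schedule=trace.schedule, velocity_deg_s=vel,
    )
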