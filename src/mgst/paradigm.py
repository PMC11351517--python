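"""Memory-guided saccade task (MGST) geometry and trial structure.

The paradigm presents, on each trial, a central fixation dot, a brief
lateral target flash at 10 deg or 18 deg eccentricity, a memory delay, a
"go" signal (fixation offset) cueing a memory-guided saccade (MGS), and a
confirmation dot at the target location eliciting a corrective visually
guided saccade (VGS).  This module owns the screen geometry (pixel <->
degree-of-visual-angle conversion for a flat panel viewed head-on) and the
per-trial interval timeline, and builds randomized 40-trial schedules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ScreenGeometry",
    "ParadigmSpec",
    "TrialTemplate",
    "INTERVALS",
    "pixel_to_degree",
    "degree_to_pixel",
    "build_trial_schedule",
]

#: Ordered interval names of one trial.
INTERVALS = (
    "fixation",
    "flash",
    "memory",
    "reaction",
    "confirmation",
    "intertrial",
)


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display and viewing distance; assumes square pixels.

    Defaults describe a 23-inch 16:9 1920x1080 panel viewed from 650 mm.
    """

    width_px: int = 1920
    height_px: int = 1080
    diagonal_mm: float = 584.2
    viewing_distance_mm: float = 650.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "diagonal_mm", "viewing_distance_mm"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")

    @property
    def pixel_pitch_mm(self) -> float:
        """Physical size of one (square) pixel in mm."""
        hyp_px = math.hypot(self.width_px, self.height_px)
        physical_width_mm = self.diagonal_mm * self.width_px / hyp_px
        return physical_width_mm / self.width_px

    @property
    def center_px(self) -> tuple[float, float]:
        return self.width_px / 2.0, self.height_px / 2.0


def pixel_to_degree(offset_px, geom: ScreenGeometry = ScreenGeometry()):
    """Signed pixel offset from screen center -> degrees of visual angle.

    Angles are measured from the line of sight through the screen center:
    angle = atan(offset * pitch / viewing_distance).  Accepts scalars or
    arrays; sign is preserved; non-finite input is rejected for scalars and
    propagated as NaN for arrays.
    """
    offset = np.asarray(offset_px, dtype=float)
    if offset.ndim == 0 and not np.isfinite(offset):
        raise ValueError("offset_px must be finite")
    angle = np.degrees(np.arctan(offset * geom.pixel_pitch_mm / geom.viewing_distance_mm))
    return float(angle) if np.isscalar(offset_px) or np.asarray(offset_px).ndim == 0 else angle


def degree_to_pixel(angle_deg, geom: ScreenGeometry = ScreenGeometry()):
    """Signed degrees of visual angle -> real-valued pixel offset from center.

    Exact inverse of :func:`pixel_to_degree`.  Requires |angle| < 90 deg;
    warns when the resulting position falls beyond the horizontal screen
    edge (target off-screen).
    """
    angle = np.asarray(angle_deg, dtype=float)
    if np.any(np.abs(angle) >= 90.0):
        raise ValueError("angle must satisfy |angle| < 90 deg")
    px = np.tan(np.radians(angle)) * geom.viewing_distance_mm / geom.pixel_pitch_mm
    if np.any(np.abs(px) > geom.width_px / 2.0):
        warnings.warn("target position lies beyond the horizontal screen edge", stacklevel=2)
    return float(px) if np.isscalar(angle_deg) or np.asarray(angle_deg).ndim == 0 else px


@dataclass(frozen=True)
class ParadigmSpec:
    """Durations and layout of the 40-trial MGST session.

    Interval durations in ms; the fixation-suppression span (fixation +
    flash + memory) totals 3000 ms and each trial lasts 7700 ms.
    """

    central_fixation_ms: float = 1500.0
    target_flash_ms: float = 200.0
    memory_ms: float = 1300.0
    reaction_ms: float = 1500.0
    confirmation_ms: float = 2500.0
    intertrial_ms: float = 700.0
    eccentricities_deg: tuple[float, ...] = (10.0, 18.0)
    sides: tuple[str, ...] = ("left", "right")
    trials_per_position: int = 10
    sample_rate_hz: float = 250.0

    def __post_init__(self) -> None:
        durations = (
            self.central_fixation_ms, self.target_flash_ms, self.memory_ms,
            self.reaction_ms, self.confirmation_ms, self.intertrial_ms,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("all interval durations must be > 0")
        if self.trials_per_position <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("trials_per_position and sample_rate_hz must be > 0")
        for side in self.sides:
            if side not in ("left", "right"):
                raise ValueError(f"unknown side {side!r}")

    @property
    def interval_durations_ms(self) -> tuple[float, ...]:
        return (
            self.central_fixation_ms, self.target_flash_ms, self.memory_ms,
            self.reaction_ms, self.confirmation_ms, self.intertrial_ms,
        )

    @property
    def trial_duration_ms(self) -> float:
        return float(sum(self.interval_durations_ms))

    @property
    def n_trials(self) -> int:
        return len(self.eccentricities_deg) * len(self.sides) * self.trials_per_position

    @property
    def boundaries_ms(self) -> tuple[float, ...]:
        """Cumulative interval end times relative to trial start."""
        return tuple(np.cumsum(self.interval_durations_ms))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eccentricities_deg"] = list(self.eccentricities_deg)
        d["sides"] = list(self.sides)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmSpec":
        d = dict(d)
        if "eccentricities_deg" in d:
            d["eccentricities_deg"] = tuple(d["eccentricities_deg"])
        if "sides" in d:
            d["sides"] = tuple(d["sides"])
        return cls(**d)


@dataclass(frozen=True)
class TrialTemplate:
    """One scheduled trial: target position plus its interval timeline.

    Boundary times are in ms from trial start; ``start_ms`` anchors the
    trial in session time (trials are contiguous 7700 ms slots).
    """

    index: int
    side: str
    eccentricity_deg: float
    start_ms: float
    boundaries_ms: tuple[float, ...] = field(default=(1500.0, 1700.0, 3000.0, 4500.0, 7000.0, 7700.0))

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        b = self.boundaries_ms
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("interval boundaries must be strictly increasing")

    @property
    def eccentricity_class(self) -> str:
        """'near' for the smaller eccentricity (10 deg), 'far' for 18 deg."""
        return "near" if self.eccentricity_deg <= 14.0 else "far"

    @property
    def signed_eccentricity_deg(self) -> float:
        return -self.eccentricity_deg if self.side == "left" else self.eccentricity_deg

    # -- timeline, relative to trial start ------------------------------
    @property
    def flash_onset_ms(self) -> float:
        return self.boundaries_ms[0]

    @property
    def go_signal_ms(self) -> float:
        return self.boundaries_ms[2]

    @property
    def confirmation_onset_ms(self) -> float:
        return self.boundaries_ms[3]

    @property
    def end_ms(self) -> float:
        return self.boundaries_ms[5]

    # -- absolute session times -----------------------------------------
    @property
    def flash_onset_abs_ms(self) -> float:
        return self.start_ms + self.flash_onset_ms

    @property
    def go_signal_abs_ms(self) -> float:
        return self.start_ms + self.go_signal_ms

    @property
    def confirmation_onset_abs_ms(self) -> float:
        return self.start_ms + self.confirmation_onset_ms

    @property
    def end_abs_ms(self) -> float:
        return self.start_ms + self.end_ms

    def interval_at(self, t_rel_ms: float) -> str:
        """Interval label for a time within the trial (relative ms)."""
        i = int(np.searchsorted(self.boundaries_ms, t_rel_ms, side="right"))
        return INTERVALS[min(i, len(INTERVALS) - 1)]


def build_trial_schedule(spec: ParadigmSpec = ParadigmSpec(), seed: int = 0) -> list[TrialTemplate]:
    """Seeded random ordering of the trial multiset.

    Exactly ``trials_per_position`` trials per (side, eccentricity) pair,
    shuffled uniformly; the same seed reproduces the same order.
    """
    rng = np.random.default_rng(seed)
    positions = [
        (side, ecc)
        for side in spec.sides
        for ecc in spec.eccentricities_deg
        for _ in range(spec.trials_per_position)
    ]
    order = rng.permutation(len(positions))
    bounds = tuple(float(b) for b in spec.boundaries_ms)
    return [
        TrialTemplate(
            index=i,
            side=positions[j][0],
            eccentricity_deg=positions[j][1],
            start_ms=i * spec.trial_duration_ms,
            boundaries_ms=bounds,
        )
        for i, j in enumerate(order)
    ]
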