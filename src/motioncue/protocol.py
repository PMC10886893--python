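"""Experimental protocol: geometry, timing, and class definitions.

A single object moves from the center of a 25 cm circle on a monitor 50 cm
from the observer, in a uniformly random direction, at one of 11 speeds whose
traverse durations span 0.5 s (slowest) down to 0.1 s (fastest).  Directions
are binned into 11 classes to match the number of speeds.  Every other module
reads its constants and unit conversions from here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import List, Tuple

__all__ = [
    "ProtocolConfig",
    "visual_angle_deg",
    "traverse_durations_s",
    "speed_schedule",
    "mean_angular_speed_deg_s",
    "direction_to_class",
    "trial_counts",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Geometry, timing, and counting constants of the experiment.

    Defaults encode the study protocol: 15 sessions per gaze condition, each
    with 33 motion trials (3 per speed class), speeds covering mean screen
    velocities of 25-125 cm/s, EEG sampled at 500 Hz from 31 signal
    electrodes, and a 0.5 s post-onset analysis window downsampled to 25 Hz.
    """

    screen_distance_cm: float = 50.0
    traverse_radius_cm: float = 12.5  # half of the 25 cm circle diameter
    n_speeds: int = 11
    n_directions: int = 11
    slowest_duration_s: float = 0.5
    fastest_duration_s: float = 0.1
    fixation_s: float = 2.0
    cue_green_s: float = 0.3
    hold_s: float = 1.0
    intertrial_s: float = 3.0
    sessions_per_condition: int = 15
    trials_per_speed_per_session: int = 3
    sample_rate_hz: float = 500.0
    analysis_window_s: float = 0.5
    downsample_rate_hz: float = 25.0
    n_signal_electrodes: int = 31

    def __post_init__(self) -> None:
        durations = (
            self.slowest_duration_s,
            self.fastest_duration_s,
            self.fixation_s,
            self.cue_green_s,
            self.hold_s,
            self.intertrial_s,
            self.analysis_window_s,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("all protocol durations must be positive")
        if self.fastest_duration_s >= self.slowest_duration_s:
            raise ValueError("fastest traverse must be shorter than slowest")
        if self.n_speeds != self.n_directions:
            # The task matches class counts so the two cues are comparable.
            raise ValueError("n_speeds must equal n_directions")
        if self.screen_distance_cm <= 0 or self.traverse_radius_cm <= 0:
            raise ValueError("geometry lengths must be positive")
        if self.sample_rate_hz <= 0 or self.downsample_rate_hz <= 0:
            raise ValueError("sample rates must be positive")

    @property
    def trials_per_session(self) -> int:
        return self.n_speeds * self.trials_per_speed_per_session

    def with_overrides(self, **kwargs) -> "ProtocolConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> List[str]:
        return [f.name for f in fields(cls)]


def visual_angle_deg(extent_cm: float, distance_cm: float) -> float:
    """Visual angle (degrees) subtended by ``extent_cm`` at ``distance_cm``.

    For the default geometry (12.5 cm at 50 cm) this is the 14 degree end
    angle of the gaze traverse.

    Raises
    ------
    ValueError
        If ``distance_cm`` is not positive or ``extent_cm`` is negative.
    """
    if distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    if extent_cm < 0:
        raise ValueError("extent must be non-negative")
    return math.degrees(math.atan2(extent_cm, distance_cm))


def traverse_durations_s(config: ProtocolConfig | None = None) -> List[float]:
    """Traverse duration of each speed class, slowest (index 0) to fastest.

    Durations are geometrically spaced between the measured endpoints
    (0.5 s down to 0.1 s by default): each speed is a constant factor faster
    than the previous, which preserves the protocol's multiplicative speed
    ladder within the measured range.
    """
    config = config or ProtocolConfig()
    n = config.n_speeds
    if n == 1:
        return [config.slowest_duration_s]
    ratio = (config.fastest_duration_s / config.slowest_duration_s) ** (1.0 / (n - 1))
    return [config.slowest_duration_s * ratio**k for k in range(n)]


def speed_schedule(
    config: ProtocolConfig | None = None,
) -> List[Tuple[int, float, float]]:
    """Per speed class: ``(speed_index, traverse_duration_s, screen_speed_cm_s)``.

    Speed indices run 1 (slowest, 25 cm/s under defaults) to ``n_speeds``
    (fastest, 125 cm/s).  Screen speed is the mean over the traverse:
    radius / duration.
    """
    config = config or ProtocolConfig()
    return [
        (k + 1, dur, config.traverse_radius_cm / dur)
        for k, dur in enumerate(traverse_durations_s(config))
    ]


def mean_angular_speed_deg_s(
    speed_index: int, config: ProtocolConfig | None = None
) -> float:
    """Mean angular speed of the gaze traverse for one speed class (deg/s).

    Defined as the end visual angle of the traverse divided by the traverse
    duration; for the slowest class this is ~28 deg/s.  Using the mean rate
    (rather than the instantaneous small-angle rate at center) matches the
    protocol's printed gaze speed.
    """
    config = config or ProtocolConfig()
    if not 1 <= speed_index <= config.n_speeds:
        raise ValueError(
            f"speed_index must be in 1..{config.n_speeds}, got {speed_index}"
        )
    end_angle = visual_angle_deg(config.traverse_radius_cm, config.screen_distance_cm)
    duration = traverse_durations_s(config)[speed_index - 1]
    return end_angle / duration


def direction_to_class(direction_deg: float, n_directions: int = 11) -> int:
    """Map a motion direction to its class, 1..n_directions.

    Bins partition [0, 360) with no gaps or overlaps; bin 1 starts at 0
    degrees (rightward on screen, counter-clockwise positive) and boundaries
    fall at k*360/n.  Angles must already be normalized to [0, 360).
    """
    if not 0.0 <= direction_deg < 360.0:
        raise ValueError("direction must be normalized to [0, 360)")
    if n_directions < 1:
        raise ValueError("need at least one direction bin")
    cls = 1 + int(direction_deg / (360.0 / n_directions))
    return min(cls, n_directions)  # guard float roundoff at the top edge


def trial_counts(config: ProtocolConfig | None = None) -> Tuple[int, int, int]:
    """``(trials_per_session, trials_per_class_per_condition, total_motion_trials)``.

    Under the default protocol: 33 trials per session, 45 trials per speed
    (or direction) class per condition, 495 motion trials per condition.
    """
    config = config or ProtocolConfig()
    per_session = config.trials_per_session
    per_class = config.sessions_per_condition * config.trials_per_speed_per_session
    total = per_class * config.n_speeds
    return per_session, per_class, total
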