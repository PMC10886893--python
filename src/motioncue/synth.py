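"""Protocol-faithful synthetic EEG sessions with known cue encoding.

The study's recordings are not publicly deposited, so this module generates
sessions with the same structure — 33 motion trials per session (3 per speed
class, uniformly random directions), the 2 s fixation / motion / 1 s hold /
3 s intertrial timeline, 31 signal channels at 500 Hz, and a 2-D gaze trace —
with a controllable ground-truth mapping from speed and direction class to
the evoked response at each electrode.

Signal model, per channel, in microvolts:

* 1/f-shaped background noise plus a white floor (``noise_sd_uv`` total SD);
* an 8-12 Hz alpha oscillation, posterior-weighted, with a slow random
  amplitude envelope;
* blink artifacts: large, slow, frontally weighted biphasic waves occurring
  as a Poisson process confined (by default) to intertrial intervals;
* during each motion window, a biphasic visual evoked component whose
  amplitude and latency follow the electrode's :class:`EncodingProfile` as a
  function of the trial's speed and direction classes;
* under the eye-tracking condition, an ocular (EOG) component proportional
  to the gaze's displacement from screen center, anterior-weighted and
  signed by direction, which starts after a sampled pursuit latency and
  returns to baseline (with the gaze) after the hold period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import fft as sfft

from . import montage
from .protocol import ProtocolConfig, direction_to_class, traverse_durations_s

__all__ = [
    "EncodingProfile",
    "SynthConfig",
    "SessionRecording",
    "default_profiles",
    "null_profiles",
    "generate_session",
    "generate_subject",
    "generate_gaze",
    "make_trial_table",
]

Condition = Literal["eye_fixed", "eye_tracking"]
CONDITIONS: Tuple[Condition, Condition] = ("eye_fixed", "eye_tracking")

#: Trial-table columns, in order.
TRIAL_COLUMNS = [
    "trial_id",
    "speed_class",
    "direction_deg",
    "direction_class",
    "motion_onset_sample",
    "traverse_duration_s",
    "condition",
]

EVENT_KINDS = ("fixation_on", "cue_green", "motion_on", "motion_off", "hold_off")


@dataclass(frozen=True)
class EncodingProfile:
    """How one electrode's evoked response depends on the two motion cues.

    The evoked component's peak amplitude for a trial with speed class ``s``
    and direction class ``d`` (both 1-based, out of ``K``) is::

        base_amp_uv + speed_gain * (s - 1)
                    + direction_gain * cos(2*pi*(d - direction_phase) / K)

    and its latency is shifted by ``speed_latency_shift_ms * (s - 1)``.
    ``eog_gain`` scales the pursuit-locked ocular component (eye-tracking
    condition only); it is weighted by the electrode's frontality, so it
    matters mainly for anterior sites.
    """

    electrode_label: str
    base_amp_uv: float = 0.0
    speed_gain: float = 0.0
    speed_latency_shift_ms: float = 0.0
    direction_gain: float = 0.0
    direction_phase: float = 1.0
    eog_gain: float = 0.0

    def __post_init__(self) -> None:
        vals = (
            self.base_amp_uv,
            self.speed_gain,
            self.speed_latency_shift_ms,
            self.direction_gain,
            self.eog_gain,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("encoding gains must be finite")

    def amplitude_uv(self, speed_class: int, direction_class: int, n_classes: int) -> float:
        return (
            self.base_amp_uv
            + self.speed_gain * (speed_class - 1)
            + self.direction_gain
            * np.cos(2.0 * np.pi * (direction_class - self.direction_phase) / n_classes)
        )


def default_profiles(protocol: ProtocolConfig | None = None) -> Dict[str, EncodingProfile]:
    """Encoding profiles emulating the empirical topographies.

    Posterior (visual) electrodes carry speed-dependent amplitude/latency and
    cosine direction tuning with preferred directions spread across sites;
    anterior electrodes carry the ocular gain that dominates direction
    decoding under the eye-tracking condition.  Central sites are unselective.
    """
    protocol = protocol or ProtocolConfig()
    k = protocol.n_speeds
    profiles: Dict[str, EncodingProfile] = {}
    posterior = montage.POSTERIOR_CHANNELS
    for i, lab in enumerate(montage.CHANNEL_LABELS):
        if lab in posterior:
            j = posterior.index(lab)
            profiles[lab] = EncodingProfile(
                electrode_label=lab,
                base_amp_uv=3.0,
                speed_gain=0.35,
                speed_latency_shift_ms=-4.0,
                direction_gain=2.0,
                # spread preferred direction classes over posterior sites
                direction_phase=1.0 + (j * k) / len(posterior),
                eog_gain=2.0,
            )
        elif lab in montage.FRONTAL_CHANNELS:
            profiles[lab] = EncodingProfile(
                electrode_label=lab, base_amp_uv=1.0, eog_gain=15.0
            )
        else:
            profiles[lab] = EncodingProfile(
                electrode_label=lab, base_amp_uv=1.0, eog_gain=4.0
            )
    return profiles


def null_profiles() -> Dict[str, EncodingProfile]:
    """Profiles with every gain zero: no cue information in any channel."""
    return {
        lab: EncodingProfile(electrode_label=lab) for lab in montage.CHANNEL_LABELS
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings: protocol, per-electrode encoding, and nuisance terms.

    Amplitudes are free parameters of the simulation (the study reports no
    microvolt scales); defaults give single-trial evoked responses well below
    the background SD, so that decoding rests on trial averaging, as in the
    study's analysis.
    """

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    profiles: Optional[Dict[str, EncodingProfile]] = None  # None -> default_profiles
    noise_sd_uv: float = 8.0
    noise_exponent: float = 1.0  # power ~ 1/f**exponent
    white_fraction: float = 0.3  # fraction of noise variance that is white
    alpha_amp_uv: float = 4.0
    blink_rate_hz: float = 0.2
    blink_amp_uv: float = 80.0
    blinks_in_trials: bool = False
    pursuit_latency_ms: Tuple[float, float] = (100.0, 300.0)
    fixation_jitter: float = 0.008  # gaze jitter SD, normalized screen units
    screen_width_cm: float = 59.8  # 27-inch 16:9 monitor
    screen_height_cm: float = 33.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        if self.blink_rate_hz < 0:
            raise ValueError("blink_rate_hz must be non-negative")
        lo, hi = self.pursuit_latency_ms
        if not (50.0 <= lo <= hi <= 400.0):
            raise ValueError("pursuit_latency_ms range must lie within [50, 400] ms")
        if not 0.0 <= self.white_fraction <= 1.0:
            raise ValueError("white_fraction must be in [0, 1]")

    def resolved_profiles(self) -> Dict[str, EncodingProfile]:
        return self.profiles if self.profiles is not None else default_profiles(self.protocol)

    def with_overrides(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class SessionRecording:
    """One session: multichannel EEG, event markers, gaze trace, condition."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    channel_labels: List[str]
    events: pd.DataFrame  # columns: sample, trial_id, kind
    gaze: np.ndarray  # (n_samples, 2), normalized screen coords in [0, 1]
    condition: str
    sample_rate_hz: float = 500.0
    #: generator ground truth (e.g. 'blink_onsets' sample indices); not an
    #: input to any analysis stage, only for validation.
    annotations: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "SessionRecording":
        return SessionRecording(
            data=data,
            channel_labels=list(self.channel_labels),
            events=self.events,
            gaze=self.gaze,
            condition=self.condition,
            sample_rate_hz=self.sample_rate_hz,
            annotations=self.annotations,
        )


# ---------------------------------------------------------------------------
# timeline


def _trial_sample_layout(protocol: ProtocolConfig, durations: List[float]):
    """Per-trial event sample offsets and the total session length."""
    fs = protocol.sample_rate_hz
    layouts = []
    t0 = 0
    for dur in durations:
        fix_on = t0
        cue = t0 + int(round((protocol.fixation_s - protocol.cue_green_s) * fs))
        mot_on = t0 + int(round(protocol.fixation_s * fs))
        mot_off = mot_on + int(round(dur * fs))
        hold_off = mot_off + int(round(protocol.hold_s * fs))
        t_next = hold_off + int(round(protocol.intertrial_s * fs))
        layouts.append((fix_on, cue, mot_on, mot_off, hold_off, t_next))
        t0 = t_next
    return layouts, t0


def make_trial_table(
    protocol: ProtocolConfig, condition: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomize one session's trial order: 3 trials per speed, uniform directions."""
    durations = traverse_durations_s(protocol)
    speed_classes = np.repeat(
        np.arange(1, protocol.n_speeds + 1), protocol.trials_per_speed_per_session
    )
    rng.shuffle(speed_classes)
    direction_deg = rng.uniform(0.0, 360.0, size=speed_classes.size)
    trial_durs = [durations[s - 1] for s in speed_classes]
    layouts, _ = _trial_sample_layout(protocol, trial_durs)
    rows = []
    for i, (s, ang) in enumerate(zip(speed_classes, direction_deg)):
        rows.append(
            {
                "trial_id": i,
                "speed_class": int(s),
                "direction_deg": float(ang),
                "direction_class": direction_to_class(float(ang), protocol.n_directions),
                "motion_onset_sample": layouts[i][2],
                "traverse_duration_s": durations[s - 1],
                "condition": condition,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _events_frame(layouts) -> pd.DataFrame:
    rows = []
    for trial_id, (fix_on, cue, mot_on, mot_off, hold_off, _) in enumerate(layouts):
        for sample, kind in zip(
            (fix_on, cue, mot_on, mot_off, hold_off), EVENT_KINDS
        ):
            rows.append({"sample": sample, "trial_id": trial_id, "kind": kind})
    return pd.DataFrame(rows, columns=["sample", "trial_id", "kind"])


# ---------------------------------------------------------------------------
# signal components


def _one_over_f_noise(
    n_channels: int, n_samples: int, fs: float, exponent: float,
    white_fraction: float, rng: np.random.Generator,
) -> np.ndarray:
    """(n_channels, n_samples) unit-SD noise, power ~ (1-w)/f**exponent + w.

    Channels are independent.  The FFT is padded to a fast length for speed;
    the trailing pad is discarded.
    """
    if white_fraction >= 1.0:
        return rng.standard_normal((n_channels, n_samples))
    n_fast = sfft.next_fast_len(n_samples)
    spec = sfft.rfft(rng.standard_normal((n_channels, n_fast)), axis=1)
    freqs = np.fft.rfftfreq(n_fast, d=1.0 / fs)
    power = np.full_like(freqs, white_fraction)
    power[1:] += (1.0 - white_fraction) * freqs[1:] ** (-exponent)
    power[0] = 0.0  # remove DC
    colored = sfft.irfft(spec * np.sqrt(power), axis=1)[:, :n_samples]
    sd = colored.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return colored / sd


def _alpha_oscillations(
    n_channels: int, n_samples: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_channels, n_samples) unit-amplitude alpha waves, slow random envelopes."""
    t = np.arange(n_samples) / fs
    f_alpha = rng.uniform(8.0, 12.0, size=(n_channels, 1))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, 1))
    f_env = rng.uniform(0.05, 0.15, size=(n_channels, 1))
    phase_env = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, 1))
    env = 1.0 + 0.5 * np.sin(2.0 * np.pi * f_env * t + phase_env)
    return env * np.sin(2.0 * np.pi * f_alpha * t + phase)


def _blink_kernel(fs: float) -> np.ndarray:
    """Slow biphasic blink waveform, ~0.5 s, unit peak amplitude."""
    t = np.arange(int(round(0.5 * fs))) / fs
    wave = np.exp(-((t - 0.15) / 0.08) ** 2) - 0.35 * np.exp(-((t - 0.32) / 0.12) ** 2)
    return wave / np.abs(wave).max()


def _evoked_kernel(fs: float, window_s: float, latency_shift_ms: float) -> np.ndarray:
    """Biphasic visual evoked waveform over the motion window, unit positive peak.

    Positive peak near 120 ms and negative trough near 250 ms after motion
    onset; the whole kernel shifts by ``latency_shift_ms``.
    """
    t = np.arange(int(round(window_s * fs))) / fs
    shift = latency_shift_ms / 1000.0
    pos = np.exp(-((t - (0.12 + shift)) / 0.035) ** 2)
    neg = -0.7 * np.exp(-((t - (0.25 + shift)) / 0.055) ** 2)
    return pos + neg


def _poisson_event_times(
    windows: List[Tuple[int, int]], rate_hz: float, fs: float, rng: np.random.Generator
) -> List[int]:
    """Poisson event onset samples within the given sample windows."""
    times: List[int] = []
    for start, stop in windows:
        dur_s = (stop - start) / fs
        n = rng.poisson(rate_hz * dur_s)
        if n:
            times.extend(int(u) for u in rng.uniform(start, stop, size=n))
    return sorted(times)


# ---------------------------------------------------------------------------
# gaze


def generate_gaze(
    trial: pd.Series | dict,
    condition: str,
    config: SynthConfig,
    rng: np.random.Generator,
    n_samples: int,
    trial_start_sample: int,
) -> np.ndarray:
    """Gaze trace segment (normalized screen coords) for one trial.

    Eye-fixed: jitter around screen center.  Eye-tracking: after a sampled
    pursuit latency the gaze ramps from center to the circle rim along the
    trial's direction, holds there through the 1 s hold, then returns
    smoothly to center early in the intertrial interval.  The vertical
    excursion is larger in normalized units (the screen is wider than tall),
    so tracking endpoints form an ellipse with a vertical long axis.
    """
    protocol = config.protocol
    fs = protocol.sample_rate_hz
    center = np.array([0.5, 0.5])
    gaze = np.tile(center, (n_samples, 1))
    if condition == "eye_tracking":
        theta = np.deg2rad(trial["direction_deg"])
        rx = protocol.traverse_radius_cm / config.screen_width_cm
        ry = protocol.traverse_radius_cm / config.screen_height_cm
        rim = np.array([rx * np.cos(theta), ry * np.sin(theta)])
        onset = int(trial["motion_onset_sample"]) - trial_start_sample
        dur = float(trial["traverse_duration_s"])
        latency_s = rng.uniform(*config.pursuit_latency_ms) / 1000.0
        t = (np.arange(n_samples) - onset) / fs  # time from motion onset
        # pursuit progress: 0 before latency, ramps to 1 over the traverse
        progress = np.clip((t - latency_s) / dur, 0.0, 1.0)
        # return to center over 0.4 s starting shortly after hold ends
        t_hold_off = dur + protocol.hold_s
        ret = np.clip((t - t_hold_off - 0.1) / 0.4, 0.0, 1.0)
        excursion = progress * (1.0 - ret)
        gaze = center + excursion[:, None] * rim[None, :]
    gaze = gaze + rng.normal(0.0, config.fixation_jitter, size=gaze.shape)
    return np.clip(gaze, 0.0, 1.0)


# ---------------------------------------------------------------------------
# session / subject generation


def generate_session(
    config: SynthConfig, condition: str, session_seed: int
) -> Tuple[SessionRecording, pd.DataFrame]:
    """Generate one session's recording and trial table.

    Fully deterministic in ``(config, condition, session_seed)``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    protocol = config.protocol
    fs = protocol.sample_rate_hz
    rng = np.random.default_rng(session_seed)
    profiles = config.resolved_profiles()
    labels = [lab for lab in montage.CHANNEL_LABELS if lab in profiles]
    if set(labels) != set(profiles):
        # keep montage order but accept custom (e.g. reduced) label sets
        labels = list(profiles)

    trials = make_trial_table(protocol, condition, rng)
    layouts, n_samples = _trial_sample_layout(
        protocol, list(trials["traverse_duration_s"])
    )
    events = _events_frame(layouts)

    n_ch = len(labels)
    data = np.zeros((n_ch, n_samples), dtype=np.float64)

    # background noise + posterior-weighted alpha
    if config.noise_sd_uv > 0:
        data += config.noise_sd_uv * _one_over_f_noise(
            n_ch, n_samples, fs, config.noise_exponent, config.white_fraction, rng
        )
    if config.alpha_amp_uv > 0:
        alpha_w = np.array([0.4 + 0.6 * montage.posteriority(lab) for lab in labels])
        data += (
            config.alpha_amp_uv
            * alpha_w[:, None]
            * _alpha_oscillations(n_ch, n_samples, fs, rng)
        )

    # blink artifacts (frontally weighted), by default intertrial-only
    blink_onsets: List[int] = []
    if config.blink_rate_hz > 0 and config.blink_amp_uv != 0:
        if config.blinks_in_trials:
            windows = [(0, n_samples)]
        else:
            windows = [(hold_off, t_next) for *_, hold_off, t_next in layouts]
        kernel = _blink_kernel(fs)
        blink_w = np.array([montage.frontality(lab) for lab in labels])
        for onset in _poisson_event_times(windows, config.blink_rate_hz, fs, rng):
            stop = min(onset + kernel.size, n_samples)
            seg = kernel[: stop - onset]
            amp = config.blink_amp_uv * rng.uniform(0.7, 1.3)
            data[:, onset:stop] += amp * np.outer(blink_w, seg)
            blink_onsets.append(onset)

    # evoked components in each motion window
    k_classes = protocol.n_speeds
    win_s = protocol.analysis_window_s
    for _, trial in trials.iterrows():
        onset = int(trial["motion_onset_sample"])
        s, d = int(trial["speed_class"]), int(trial["direction_class"])
        for ci, lab in enumerate(labels):
            prof = profiles[lab]
            amp = prof.amplitude_uv(s, d, k_classes)
            if amp == 0.0 and prof.speed_latency_shift_ms == 0.0:
                continue
            kernel = _evoked_kernel(fs, win_s, prof.speed_latency_shift_ms * (s - 1))
            stop = min(onset + kernel.size, n_samples)
            data[ci, onset:stop] += amp * kernel[: stop - onset]

    # gaze trace, assembled per trial; EOG follows gaze displacement
    gaze = np.empty((n_samples, 2))
    for (fix_on, *_rest, t_next), (_, trial) in zip(layouts, trials.iterrows()):
        seg = generate_gaze(
            trial, condition, config, rng, n_samples=t_next - fix_on,
            trial_start_sample=fix_on,
        )
        gaze[fix_on:t_next] = seg

    if condition == "eye_tracking":
        rx = protocol.traverse_radius_cm / config.screen_width_cm
        ry = protocol.traverse_radius_cm / config.screen_height_cm
        ex = (gaze[:, 0] - 0.5) / rx  # horizontal displacement, ~[-1, 1]
        ey = (gaze[:, 1] - 0.5) / ry
        for ci, lab in enumerate(labels):
            g = profiles[lab].eog_gain * montage.frontality(lab)
            if g == 0.0:
                continue
            lat = montage.laterality(lab)
            data[ci] += g * (lat * ex + ey)

    recording = SessionRecording(
        data=data.astype(np.float32),
        channel_labels=labels,
        events=events,
        gaze=gaze,
        condition=condition,
        sample_rate_hz=fs,
        annotations={"blink_onsets": np.array(blink_onsets, dtype=int)},
    )
    return recording, trials


def session_seed_for(master_seed: int, condition: str, session_index: int) -> int:
    """Deterministic per-session seed derived from the master seed."""
    cond_idx = CONDITIONS.index(condition)
    ss = np.random.SeedSequence((int(master_seed), cond_idx, int(session_index)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_subject(
    config: SynthConfig,
    conditions: Tuple[str, ...] = CONDITIONS,
    sessions_per_condition: Optional[int] = None,
) -> Iterator[Tuple[SessionRecording, pd.DataFrame]]:
    """Yield every session of one synthetic subject, eye-fixed then eye-tracking.

    Session seeds derive deterministically from ``config.seed`` via a
    (seed, condition, session) counter scheme, so any single session can be
    regenerated independently.  With default settings this yields 15 sessions
    per condition, i.e. 45 trials per class and 495 motion trials per
    condition.
    """
    n_sessions = (
        sessions_per_condition
        if sessions_per_condition is not None
        else config.protocol.sessions_per_condition
    )
    for condition in conditions:
        for i in range(n_sessions):
            yield generate_session(
                config, condition, session_seed_for(config.seed, condition, i)
            )
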