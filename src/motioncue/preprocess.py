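"""EEG signal chain: re-reference, ICA blink removal, bandpass, epoching.

The fixed pipeline order is common-average reference -> ICA artifact
removal -> 50th-order FIR bandpass (0.1-13 Hz; the linear-phase filter is
applied once and its exact 25-sample group delay removed, giving zero phase
without squaring the magnitude response) -> motion-window epoch extraction
with downsampling to 25 Hz.  Gaze-based condition verification is a
screening report only; it never gates the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from . import montage
from .synth import SessionRecording

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "EpochFeatures",
    "EpochStack",
    "common_average_reference",
    "remove_blink_artifacts",
    "design_bandpass",
    "bandpass_filter",
    "extract_motion_epochs",
    "gaze_std_from_center",
    "verify_condition",
    "preprocess_session",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Signal-chain settings.

    The 51-tap (50th-order) Hamming-window FIR at 500 Hz cannot realize a
    sharp 0.1 Hz high-pass; the filter is implemented exactly as configured
    and its measured response is what the test suite checks, so the effective
    band is the designed filter's, not the nominal corner frequencies.
    """

    bandpass_low_hz: float = 0.1
    bandpass_high_hz: float = 13.0
    fir_order: int = 50
    ica_components: int = 31  # capped at the data's numerical rank (30 after CAR)
    blink_detect_threshold: float = 0.8  # |r| with the frontal proxy
    kurtosis_fallback: float = 5.0
    epoch_start_s_after_motion_on: float = 0.0
    epoch_len_s: float = 0.5
    downsample_hz: float = 25.0
    gaze_std_criterion: float = 0.030
    ica_algorithm: str = "deflation"  # extracts the non-Gaussian (blink) source first
    ica_max_iter: int = 500
    ica_tol: float = 1e-3
    ica_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low_hz < self.bandpass_high_hz:
            raise ValueError("need 0 < bandpass_low_hz < bandpass_high_hz")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")

    def n_features(self, sample_rate_hz: float) -> int:
        """Features per electrode per trial: window-start sample plus every
        stride-th sample through the window end (13 under defaults)."""
        stride = int(round(sample_rate_hz / self.downsample_hz))
        win = int(round(self.epoch_len_s * sample_rate_hz))
        return win // stride + 1

    def with_overrides(self, **kwargs) -> "PreprocessConfig":
        return replace(self, **kwargs)


@dataclass
class EpochFeatures:
    """Per-electrode classifier input: one row of downsampled waveform per trial."""

    electrode_label: str
    data: np.ndarray  # (n_trials, n_features), microvolts
    labels: pd.DataFrame  # aligned with rows: speed_class, direction_class, ...


@dataclass
class EpochStack:
    """All electrodes' epochs for a pooled set of trials, row-aligned."""

    data: np.ndarray  # (n_electrodes, n_trials, n_features)
    channel_labels: List[str]
    labels: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def electrode(self, label: str) -> EpochFeatures:
        idx = self.channel_labels.index(label)
        return EpochFeatures(label, self.data[idx], self.labels)

    def subset_channels(self, labels: List[str]) -> "EpochStack":
        idx = [self.channel_labels.index(lab) for lab in labels]
        return EpochStack(self.data[idx], list(labels), self.labels)

    @classmethod
    def concatenate(cls, stacks: List["EpochStack"]) -> "EpochStack":
        if not stacks:
            raise ValueError("no epoch stacks to concatenate")
        labels0 = stacks[0].channel_labels
        for s in stacks[1:]:
            if s.channel_labels != labels0:
                raise ValueError("cannot pool epochs with mismatched channels")
        return cls(
            data=np.concatenate([s.data for s in stacks], axis=1),
            channel_labels=list(labels0),
            labels=pd.concat([s.labels for s in stacks], ignore_index=True),
        )


# ---------------------------------------------------------------------------
# referencing and artifact removal


def common_average_reference(recording: SessionRecording) -> SessionRecording:
    """Subtract the instantaneous mean of all signal electrodes from each channel."""
    n_expected = 31
    if recording.n_channels != n_expected and recording.n_channels < 2:
        raise ValueError(
            f"common average reference needs multiple channels, got {recording.n_channels}"
        )
    data = np.asarray(recording.data, dtype=np.float64)
    return recording.copy_with(data - data.mean(axis=0, keepdims=True))


def remove_blink_artifacts(
    recording: SessionRecording, config: PreprocessConfig | None = None
) -> Tuple[SessionRecording, Dict]:
    """ICA decomposition; zero components tracking the frontal blink proxy.

    The proxy is the mean of the two most anterior electrodes.  Components
    whose time course correlates with it (|r| above the threshold) are
    removed; if none qualifies, the highest-kurtosis component is removed
    instead, provided its kurtosis exceeds the fallback threshold (blinks
    are sparse, hence heavy-tailed).  If ICA fails to converge the input is
    returned unchanged with ``info['converged'] = False``.
    """
    config = config or PreprocessConfig()
    X = np.asarray(recording.data, dtype=np.float64).T  # (samples, channels)
    # common-average-referenced data has rank n_channels - 1; whitening a
    # rank-deficient direction would make the reconstruction ill-conditioned
    eigvals = np.linalg.eigvalsh(np.cov(X, rowvar=False))
    rank = int((eigvals > eigvals.max() * 1e-10).sum())
    n_comp = min(config.ica_components, rank)
    ica = FastICA(
        n_components=n_comp,
        algorithm=config.ica_algorithm,
        whiten="unit-variance",
        max_iter=config.ica_max_iter,
        tol=config.ica_tol,
        random_state=config.ica_seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            sources = ica.fit_transform(X)
        except Exception as exc:  # non-convergence or numerical failure
            logger.warning("ICA failed (%s); returning input unchanged", exc)
            return recording, {"converged": False, "removed_components": []}
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False

    proxy_labels = montage.most_anterior(recording.channel_labels, k=2)
    proxy_idx = [recording.channel_labels.index(lab) for lab in proxy_labels]
    proxy = X[:, proxy_idx].mean(axis=1)

    corr = np.zeros(n_comp)
    proxy_c = proxy - proxy.mean()
    pnorm = np.linalg.norm(proxy_c)
    for k in range(n_comp):
        s = sources[:, k] - sources[:, k].mean()
        denom = pnorm * np.linalg.norm(s)
        corr[k] = (proxy_c @ s) / denom if denom > 0 else 0.0

    removed = [k for k in range(n_comp) if abs(corr[k]) > config.blink_detect_threshold]
    if not removed:
        kurt = kurtosis(sources, axis=0, fisher=True)
        top = int(np.argmax(kurt))
        if kurt[top] > config.kurtosis_fallback:
            removed = [top]

    info = {
        "converged": converged,
        "removed_components": removed,
        "proxy_correlations": corr,
    }
    if not converged:
        logger.warning("ICA did not converge; returning input unchanged")
        return recording, {**info, "removed_components": []}
    if not removed:
        return recording, info

    artifact = sources[:, removed] @ ica.mixing_[:, removed].T
    cleaned = (X - artifact).T
    logger.info(
        "removed %d ICA component(s) %s (proxy |r| max %.2f)",
        len(removed), removed, np.abs(corr).max(),
    )
    return recording.copy_with(cleaned), info


# ---------------------------------------------------------------------------
# filtering


def design_bandpass(
    config: PreprocessConfig | None = None, sample_rate_hz: float = 500.0
) -> np.ndarray:
    """Hamming-window FIR taps (order + 1 of them) for the configured band."""
    config = config or PreprocessConfig()
    nyq = sample_rate_hz / 2.0
    if not config.bandpass_high_hz < nyq:
        raise ValueError("bandpass_high_hz must be below Nyquist")
    return sps.firwin(
        config.fir_order + 1,
        [config.bandpass_low_hz, config.bandpass_high_hz],
        fs=sample_rate_hz,
        pass_zero=False,
        window="hamming",
    )


def bandpass_filter(
    recording: SessionRecording, config: PreprocessConfig | None = None
) -> SessionRecording:
    """Zero-phase application of the designed FIR filter.

    The even-order linear-phase FIR is applied once and its exact
    ``order/2``-sample group delay removed, so the output is time-aligned
    with the input and the magnitude response is that of the designed filter
    (a forward-backward pass would square it, pushing the ~6 % passband
    ripple of the 51-tap design outside its stated tolerance).
    """
    config = config or PreprocessConfig()
    taps = design_bandpass(config, recording.sample_rate_hz)
    data = np.asarray(recording.data, dtype=np.float64)
    delay = config.fir_order // 2
    padded = np.concatenate([data, np.zeros((data.shape[0], delay))], axis=1)
    filtered = sps.lfilter(taps, [1.0], padded, axis=1)[:, delay:]
    return recording.copy_with(filtered)


# ---------------------------------------------------------------------------
# epoching


def extract_motion_epochs(
    recording: SessionRecording,
    trials: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> EpochStack:
    """Cut the motion-onset window per trial and downsample by striding.

    Each trial contributes the samples at offsets 0, stride, 2*stride, ...
    through the end of the window (13 features under defaults: stride 20
    through a 250-sample window).  Trials whose window would run past the
    end of the recording are dropped with a logged warning.
    """
    config = config or PreprocessConfig()
    fs = recording.sample_rate_hz
    stride = int(round(fs / config.downsample_hz))
    start_off = int(round(config.epoch_start_s_after_motion_on * fs))
    win = int(round(config.epoch_len_s * fs))
    offsets = np.arange(0, win + 1, stride)

    keep_rows, slices = [], []
    for _, trial in trials.iterrows():
        t0 = int(trial["motion_onset_sample"]) + start_off
        if t0 < 0 or t0 + offsets[-1] >= recording.n_samples:
            logger.warning(
                "dropping trial %s: window [%d, %d] exceeds recording of %d samples",
                trial["trial_id"], t0, t0 + offsets[-1], recording.n_samples,
            )
            continue
        keep_rows.append(trial)
        slices.append(t0 + offsets)

    if not slices:
        raise ValueError("no trials with a complete motion window")
    index = np.stack(slices)  # (n_trials, n_features)
    data = np.asarray(recording.data, dtype=np.float64)[:, index]
    labels = pd.DataFrame(keep_rows).reset_index(drop=True)
    return EpochStack(data=data, channel_labels=list(recording.channel_labels), labels=labels)


# ---------------------------------------------------------------------------
# gaze screening


def gaze_std_from_center(gaze: np.ndarray) -> float:
    """Dispersion of a 2-D gaze trace: RMS Euclidean distance from its centroid.

    Units are normalized screen coordinates; the eye-fixed/eye-tracking
    screening threshold on this quantity is 0.030.
    """
    gaze = np.asarray(gaze, dtype=float)
    if gaze.size == 0:
        raise ValueError("empty gaze trace")
    center = gaze.mean(axis=0)
    return float(np.sqrt(((gaze - center) ** 2).sum(axis=1).mean()))


def verify_condition(dispersion: float, criterion: float = 0.030) -> str:
    """Classify a session's gaze dispersion against the screening criterion."""
    return "eye_tracking" if dispersion > criterion else "eye_fixed"


# ---------------------------------------------------------------------------
# pipeline


def preprocess_session(
    recording: SessionRecording,
    config: PreprocessConfig | None = None,
    skip_ica: bool = False,
) -> Tuple[SessionRecording, Dict]:
    """Full chain in fixed order: reference -> ICA removal -> bandpass."""
    config = config or PreprocessConfig()
    rec = common_average_reference(recording)
    info: Dict = {"ica": None}
    if not skip_ica:
        rec, ica_info = remove_blink_artifacts(rec, config)
        info["ica"] = ica_info
    rec = bandpass_filter(rec, config)
    info["gaze_dispersion"] = gaze_std_from_center(recording.gaze)
    info["verified_condition"] = verify_condition(
        info["gaze_dispersion"], config.gaze_std_criterion
    )
    return rec, info
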