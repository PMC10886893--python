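"""Session container on disk, run manifests, and optional EDF ingest.

A subject is a directory; each session stores its data matrix, channel
labels, events, and gaze in a compressed ``.npz``, with the trial table as a
TSV (columns documented in :data:`motioncue.synth.TRIAL_COLUMNS`) and a
subject-level ``manifest.json`` echoing the configuration and seeds and
hashing every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .synth import SessionRecording, TRIAL_COLUMNS

__all__ = [
    "save_session",
    "load_session",
    "sha256_file",
    "write_manifest",
    "read_manifest",
    "session_name",
    "list_sessions",
    "load_edf_session",
]


def session_name(condition: str, index: int) -> str:
    return f"{condition}_{index:02d}"


def save_session(
    subject_dir: str | Path,
    recording: SessionRecording,
    trials: pd.DataFrame,
    name: str,
) -> List[Path]:
    """Write one session's files; returns the paths written."""
    subject_dir = Path(subject_dir)
    subject_dir.mkdir(parents=True, exist_ok=True)
    npz_path = subject_dir / f"{name}.npz"
    np.savez_compressed(
        npz_path,
        data=recording.data.astype(np.float32),
        gaze=recording.gaze.astype(np.float32),
        channel_labels=np.array(recording.channel_labels),
        condition=np.array(recording.condition),
        sample_rate_hz=np.array(recording.sample_rate_hz),
        event_sample=recording.events["sample"].to_numpy(),
        event_trial=recording.events["trial_id"].to_numpy(),
        event_kind=recording.events["kind"].to_numpy().astype("U16"),
    )
    tsv_path = subject_dir / f"{name}_trials.tsv"
    trials.to_csv(tsv_path, sep="\t", index=False)
    return [npz_path, tsv_path]


def load_session(
    subject_dir: str | Path, name: str
) -> Tuple[SessionRecording, pd.DataFrame]:
    subject_dir = Path(subject_dir)
    with np.load(subject_dir / f"{name}.npz", allow_pickle=False) as z:
        events = pd.DataFrame(
            {
                "sample": z["event_sample"],
                "trial_id": z["event_trial"],
                "kind": z["event_kind"],
            }
        )
        recording = SessionRecording(
            data=z["data"],
            channel_labels=[str(lab) for lab in z["channel_labels"]],
            events=events,
            gaze=z["gaze"],
            condition=str(z["condition"]),
            sample_rate_hz=float(z["sample_rate_hz"]),
        )
    trials = pd.read_csv(subject_dir / f"{name}_trials.tsv", sep="\t")
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return recording, trials


def list_sessions(subject_dir: str | Path) -> List[str]:
    """Session names present in a subject directory, sorted."""
    return sorted(p.stem for p in Path(subject_dir).glob("*.npz"))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_manifest(
    out_dir: str | Path,
    config_snapshot: Dict,
    seeds: Dict,
    files: List[Path],
    warnings: Optional[List[str]] = None,
) -> Path:
    """Write ``manifest.json``: config echo, seeds, per-file hashes, warnings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": _jsonable(config_snapshot),
        "seeds": _jsonable(seeds),
        "files": {str(Path(f).name): sha256_file(f) for f in files},
        "warnings": warnings or [],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(out_dir: str | Path) -> Dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())


def load_edf_session(
    edf_path: str | Path,
    trials_tsv: str | Path,
    channel_map: Optional[Dict[str, str]] = None,
    condition: str = "eye_fixed",
) -> Tuple[SessionRecording, pd.DataFrame]:
    """Ingest a real recording from EDF plus a sidecar trial table.

    The sidecar TSV must provide the documented trial columns
    (:data:`motioncue.synth.TRIAL_COLUMNS`).  ``channel_map`` renames EDF
    channels to montage labels.  Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF ingest requires the optional 'mne' dependency "
            "(pip install motioncue[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    if channel_map:
        raw.rename_channels(channel_map)
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    trials = pd.read_csv(trials_tsv, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"sidecar trial table missing columns: {sorted(missing)}")
    n_samples = data_uv.shape[1]
    events = pd.DataFrame(
        {
            "sample": trials["motion_onset_sample"],
            "trial_id": trials["trial_id"],
            "kind": "motion_on",
        }
    )
    recording = SessionRecording(
        data=data_uv.astype(np.float32),
        channel_labels=list(raw.ch_names),
        events=events,
        gaze=np.full((n_samples, 2), 0.5, dtype=np.float32),  # no gaze in EDF
        condition=condition,
        sample_rate_hz=float(raw.info["sfreq"]),
    )
    return recording, trials
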