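"""End-to-end orchestration: simulate -> preprocess -> decode -> stats -> report.

A run is configured by a single flat key/value mapping (YAML file and/or CLI
overrides); keys are routed to the protocol, synthesis, preprocessing, and
cross-validation configs by field name.  Outputs are schema-stable TSV/JSON
tables plus a manifest hashing every file, so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import io as mcio
from .decode import AccuracyMap, CVConfig, classify_all_electrodes, nested_speed_analysis
from .preprocess import (
    EpochStack,
    PreprocessConfig,
    extract_motion_epochs,
    gaze_std_from_center,
    preprocess_session,
    verify_condition,
)
from .protocol import ProtocolConfig
from .stats import compare_cues, electrode_significance
from .synth import (
    CONDITIONS,
    SynthConfig,
    default_profiles,
    generate_session,
    null_profiles,
    session_seed_for,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "build_subject_epochs", "run_pipeline"]

#: Electrode subset used by the reduced demo preset.
DEMO_ELECTRODES = ["Fp1", "Fp2", "Cz", "P4", "POz"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; constructed from a flat mapping."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    subject: str = "S1"
    conditions: Tuple[str, ...] = CONDITIONS
    electrodes: Optional[Tuple[str, ...]] = None  # None -> all 31
    skip_ica: bool = False
    nested: bool = False
    profile_set: str = "default"  # 'default' or 'null'
    alpha: float = 0.01
    seed: int = 0

    def resolved(self) -> "PipelineConfig":
        """Propagate the master seed and protocol into the sub-configs."""
        synth = replace(self.synth, protocol=self.protocol, seed=self.seed)
        if self.profile_set == "null":
            synth = replace(synth, profiles=null_profiles())
        elif self.profile_set == "default" and synth.profiles is None:
            synth = replace(synth, profiles=default_profiles(self.protocol))
        cv = replace(self.cv, seed=self.seed, n_classes=self.protocol.n_speeds)
        return replace(self, synth=synth, cv=cv)


def demo_preset(**overrides) -> PipelineConfig:
    """Reduced configuration for smoke runs: 3 sessions per condition,
    20 CV repetitions, 20 training averages per class, 5 electrodes,
    no blink simulation (so ICA is skipped).

    Demo sessions carry 5 trials per speed class (instead of 3) so that the
    randomly drawn direction classes almost surely retain the six trials per
    class that the hold-3-out scheme needs even at this reduced scale.
    """
    protocol = ProtocolConfig(sessions_per_condition=3, trials_per_speed_per_session=5)
    cfg = PipelineConfig(
        protocol=protocol,
        synth=SynthConfig(protocol=protocol, blink_rate_hz=0.0),
        cv=CVConfig(n_repetitions=20, n_train_veps_per_class=20),
        electrodes=tuple(DEMO_ELECTRODES),
        skip_ica=True,
    )
    return replace(cfg, **overrides) if overrides else cfg


_PIPELINE_KEYS = {
    "subject", "conditions", "electrodes", "skip_ica", "nested",
    "profile_set", "alpha", "seed",
}


def load_config(
    path: Optional[str | Path] = None,
    overrides: Optional[Dict] = None,
    demo: bool = False,
) -> PipelineConfig:
    """Build a run config from a flat YAML file plus override mapping.

    Keys are routed by name: protocol fields (e.g. ``sessions_per_condition``),
    synthesis fields (``noise_sd_uv``), preprocessing fields
    (``bandpass_high_hz``), cross-validation fields (``n_repetitions``), and
    pipeline-level keys (``seed``, ``electrodes``, ...).  Unknown keys raise.
    """
    flat: Dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must be a flat key/value mapping")
        flat.update(loaded)
    if overrides:
        flat.update({k: v for k, v in overrides.items() if v is not None})

    base = demo_preset() if demo else PipelineConfig()
    proto_fields = {f.name for f in dataclasses.fields(ProtocolConfig)}
    synth_fields = {f.name for f in dataclasses.fields(SynthConfig)} - {"protocol", "seed"}
    prep_fields = {f.name for f in dataclasses.fields(PreprocessConfig)}
    cv_fields = {f.name for f in dataclasses.fields(CVConfig)} - {"seed"}

    proto_kw, synth_kw, prep_kw, cv_kw, pipe_kw = {}, {}, {}, {}, {}
    for key, val in flat.items():
        if key in proto_fields:
            proto_kw[key] = val
        elif key in synth_fields:
            synth_kw[key] = val
        elif key in prep_fields:
            prep_kw[key] = val
        elif key in cv_fields:
            cv_kw[key] = val
        elif key in _PIPELINE_KEYS:
            if key in ("conditions", "electrodes") and isinstance(val, str):
                val = tuple(v.strip() for v in val.split(","))
            pipe_kw[key] = val
        else:
            raise ValueError(f"unknown configuration key: {key!r}")

    protocol = replace(base.protocol, **proto_kw)
    return replace(
        base,
        protocol=protocol,
        synth=replace(base.synth, protocol=protocol, **synth_kw),
        preprocess=replace(base.preprocess, **prep_kw),
        cv=replace(base.cv, **cv_kw),
        **pipe_kw,
    )


def build_subject_epochs(
    cfg: PipelineConfig,
    condition: str,
    save_dir: Optional[Path] = None,
) -> Tuple[EpochStack, pd.DataFrame, List[str]]:
    """Generate, preprocess, and epoch every session of one condition.

    Sessions are streamed (generated, reduced to epochs, discarded) to bound
    memory.  Returns the pooled epoch stack, a per-session gaze screening
    table, and accumulated warnings.
    """
    cfg = cfg.resolved()
    stacks, screening, warnings_log = [], [], []
    for i in range(cfg.protocol.sessions_per_condition):
        seed = session_seed_for(cfg.seed, condition, i)
        recording, trials = generate_session(cfg.synth, condition, seed)
        if save_dir is not None:
            mcio.save_session(save_dir, recording, trials, mcio.session_name(condition, i))
        dispersion = gaze_std_from_center(recording.gaze)
        screening.append(
            {
                "session": mcio.session_name(condition, i),
                "condition": condition,
                "gaze_dispersion": dispersion,
                "verified_condition": verify_condition(
                    dispersion, cfg.preprocess.gaze_std_criterion
                ),
                "session_seed": seed,
            }
        )
        rec, info = preprocess_session(recording, cfg.preprocess, skip_ica=cfg.skip_ica)
        if info.get("ica") and not info["ica"]["converged"]:
            warnings_log.append(f"{mcio.session_name(condition, i)}: ICA did not converge")
        stacks.append(extract_motion_epochs(rec, trials, cfg.preprocess))
    stack = EpochStack.concatenate(stacks)
    return stack, pd.DataFrame(screening), warnings_log


def _write_confusions(acc_map: AccuracyMap, out_dir: Path) -> List[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for lab, entry in acc_map.entries.items():
        df = pd.DataFrame(
            entry.confusion,
            index=[f"classified_{c}" for c in entry.classes],
            columns=[f"true_{c}" for c in entry.classes],
        )
        p = out_dir / f"confusion_{lab}.tsv"
        df.to_csv(p, sep="\t")
        paths.append(p)
    return paths


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Dict:
    """Execute all stages and write the report bundle.

    Emits, per condition: a significance table per cue (TSV), confusion
    matrices (TSV per electrode), a gaze screening table, and a
    cue-comparison summary across conditions, plus ``manifest.json``.
    Returns a dict with the in-memory results.
    """
    cfg = cfg.resolved()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    electrodes = list(cfg.electrodes) if cfg.electrodes else None

    files: List[Path] = []
    warnings_log: List[str] = []
    screening_tables = []
    comparisons = []
    results: Dict = {"accuracy_maps": {}, "significance": {}, "nested": {}}

    for condition in cfg.conditions:
        stack, screening, warns = build_subject_epochs(cfg, condition)
        screening_tables.append(screening)
        warnings_log.extend(warns)

        maps = {}
        for cue in ("speed", "direction"):
            amap = classify_all_electrodes(
                stack, cue=cue, config=cfg.cv, electrodes=electrodes,
                condition=condition,
            )
            maps[cue] = amap
            results["accuracy_maps"][(condition, cue)] = amap
            sig = electrode_significance(amap, alpha=cfg.alpha)
            sig.insert(0, "subject", cfg.subject)
            results["significance"][(condition, cue)] = sig
            p = out_dir / f"significance_{condition}_{cue}.tsv"
            sig.to_csv(p, sep="\t", index=False)
            files.append(p)
            files.extend(
                _write_confusions(amap, out_dir / f"confusion_{condition}_{cue}")
            )

        comparison = compare_cues(
            maps["speed"], maps["direction"], alpha=cfg.alpha, subject=cfg.subject
        )
        comparisons.append(comparison)
        results.setdefault("comparisons", {})[condition] = comparison

        if cfg.nested:
            nested = nested_speed_analysis(
                stack, config=cfg.cv, electrodes=electrodes, condition=condition
            )
            results["nested"][condition] = nested
            rows = [
                {
                    "condition": condition,
                    "n_classes": n,
                    "electrode": lab,
                    "gamma_hat": amap_n.gamma(lab),
                    "chance": 1.0 / n,
                }
                for n, amap_n in nested.items()
                for lab in amap_n.electrodes
            ]
            p = out_dir / f"nested_speed_{condition}.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            files.append(p)

    screening_df = pd.concat(screening_tables, ignore_index=True)
    p = out_dir / "gaze_screening.tsv"
    screening_df.to_csv(p, sep="\t", index=False)
    files.append(p)
    results["gaze_screening"] = screening_df

    cmp_df = pd.concat([c.to_frame() for c in comparisons], ignore_index=True)
    p = out_dir / "cue_comparison.tsv"
    cmp_df.to_csv(p, sep="\t", index=False)
    files.append(p)
    results["cue_comparison"] = cmp_df

    seeds = {
        "master": cfg.seed,
        "sessions": {
            cond: [
                session_seed_for(cfg.seed, cond, i)
                for i in range(cfg.protocol.sessions_per_condition)
            ]
            for cond in cfg.conditions
        },
    }
    manifest_path = mcio.write_manifest(
        out_dir,
        config_snapshot={
            "protocol": cfg.protocol,
            "preprocess": cfg.preprocess,
            "cv": cfg.cv,
            "subject": cfg.subject,
            "conditions": list(cfg.conditions),
            "electrodes": electrodes,
            "profile_set": cfg.profile_set,
            "alpha": cfg.alpha,
            "skip_ica": cfg.skip_ica,
            "noise_sd_uv": cfg.synth.noise_sd_uv,
            "alpha_amp_uv": cfg.synth.alpha_amp_uv,
            "blink_rate_hz": cfg.synth.blink_rate_hz,
        },
        seeds=seeds,
        files=files,
        warnings=warnings_log,
    )
    results["manifest"] = manifest_path
    results["files"] = files
    return results
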