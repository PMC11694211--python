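"""End-to-end orchestration: raw trial -> features; manifest -> study."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .features import PhaseEvents, SnatchFeatures, extract_features
from .io import (
    AxisMap,
    CohortIndex,
    PipelineConfig,
    RawTrial,
    StaticRecord,
    SubjectInfo,
    load_manifest,
    load_trial,
    read_force_file,
)
from .preprocess import TrialSignals, body_weight_from_static, normalize_trial
from .stats import ConditionStudy, StudyResults

__all__ = ["process_trial", "run_study"]

log = logging.getLogger("snatchlab")


def process_trial(
    raw: RawTrial,
    subject: SubjectInfo,
    body_weight: float | None = None,
    cfg: PipelineConfig | None = None,
) -> tuple[TrialSignals, PhaseEvents, SnatchFeatures]:
    """Condition one trial, segment it and compute the 23 parameters."""
    cfg = cfg or PipelineConfig()
    signals = normalize_trial(raw, subject, body_weight, cfg)
    events, feats = extract_features(signals, cfg)
    return signals, events, feats


def run_study(
    manifest: str | Path | CohortIndex,
    cfg: PipelineConfig | None = None,
    axis_map: AxisMap | None = None,
) -> tuple[pd.DataFrame, StudyResults]:
    """Process every trial of a cohort and run the statistical battery.

    Returns the per-trial feature table (published column names) and the
    fitted :class:`~snatchlab.stats.StudyResults`.
    """
    cfg = cfg or PipelineConfig()
    index = manifest if isinstance(manifest, CohortIndex) else load_manifest(manifest)
    weights: dict[str, float] = {}
    for sid, fname in index.static_files.items():
        p1, p2, f_force = read_force_file(index.root / fname, axis_map)
        static = StaticRecord(subject_id=sid, plate1=p1, plate2=p2, f_force=f_force)
        weights[sid], _ = body_weight_from_static(static)
    rows = []
    for entry in index.trials:
        raw = load_trial(entry, index, axis_map)
        subject = index.subjects[entry.subject_id]
        _, _, feats = process_trial(
            raw, subject, body_weight=weights.get(entry.subject_id), cfg=cfg)
        rows.append(feats.to_row())
        log.info("processed %s %s trial %d", entry.subject_id, entry.condition,
                 entry.trial_index)
    features = pd.DataFrame(rows)
    study = ConditionStudy.from_features(features, cfg=cfg)
    return features, study.fit()
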