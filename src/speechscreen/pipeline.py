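"""Feature-table assembly: transcripts + audio -> one wide row per
participant.

Column layout: per-task verbal features prefixed ``svf_``, ``alt_``,
``pvf_``, ``pdt_``; acoustic features prefixed ``speech_`` (one recording
per task, averaged across the four tasks into a single per-participant
vector); then the participant metadata columns (diagnosis, mmse,
demographics) carried through for labeling and benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioSignal, preprocess_audio, read_wav
from .audio_features import (
    ACOUSTIC_FEATURE_NAMES,
    extract_acoustic_features,
    silence_stats_from_audio,
)
from .lexicon import Lexicon, default_lexicon
from .models import TASK_PREFIXES
from .synthetic import Cohort, synthesize_task_audio
from .transcript_features import FEATURE_SCHEMAS, extract_task_features
from .transcripts import TASKS, Transcript, read_transcript_json


@dataclass(frozen=True)
class FeatureExtractionConfig:
    """Tunables of the feature-extraction stage."""

    spurt_gap_s: float = 1.0
    min_gap_s: float = 0.25
    butter_cutoff_hz: float = 7000.0
    butter_order: int = 4
    silence_source: str = "tokens"  # or "audio"
    include_audio: bool = True


def feature_columns(include_audio: bool = True) -> list[str]:
    """Deterministic column order of the wide feature table."""
    cols = []
    for task in TASKS:
        cols += [TASK_PREFIXES[task] + name for name in FEATURE_SCHEMAS[task]]
    if include_audio:
        cols += ["speech_" + name for name in ACOUSTIC_FEATURE_NAMES]
    return cols


def transcript_feature_row(
    transcripts: dict[str, Transcript],
    lexicon: Lexicon,
    cfg: FeatureExtractionConfig = FeatureExtractionConfig(),
) -> dict[str, float]:
    """Prefixed verbal-task features for one participant (all four tasks)."""
    missing = [t for t in TASKS if t not in transcripts]
    if missing:
        raise ValueError(f"missing transcripts for tasks: {missing}")
    row: dict[str, float] = {}
    for task in TASKS:
        fv = extract_task_features(
            transcripts[task], lexicon,
            spurt_gap_s=cfg.spurt_gap_s, min_gap_s=cfg.min_gap_s,
        )
        for name, val in fv.features.items():
            row[TASK_PREFIXES[task] + name] = val
    return row


def speech_feature_row(
    signals: dict[str, AudioSignal],
    cfg: FeatureExtractionConfig = FeatureExtractionConfig(),
) -> dict[str, float]:
    """Acoustic features per task recording, averaged into one vector."""
    vecs = []
    for task in TASKS:
        sig = preprocess_audio(signals[task], cfg.butter_cutoff_hz, cfg.butter_order)
        vecs.append(extract_acoustic_features(sig).as_array())
    mean_vec = np.mean(vecs, axis=0)
    return {
        "speech_" + name: float(v)
        for name, v in zip(ACOUSTIC_FEATURE_NAMES, mean_vec)
    }


def _override_silence_from_audio(
    row: dict[str, float],
    signals: dict[str, AudioSignal],
    cfg: FeatureExtractionConfig,
) -> None:
    for task in TASKS:
        stats = silence_stats_from_audio(signals[task], min_silence_s=cfg.min_gap_s)
        row[TASK_PREFIXES[task] + "mean_silence_s"] = stats.mean_silence_s
        row[TASK_PREFIXES[task] + "std_silence_s"] = stats.std_silence_s


def cohort_features(
    cohort: Cohort,
    lexicon: Lexicon | None = None,
    cfg: FeatureExtractionConfig = FeatureExtractionConfig(),
) -> pd.DataFrame:
    """Wide feature table for a synthetic cohort.

    Audio is synthesized per participant-task on the fly (tone bursts at
    the transcript timestamps), so memory stays flat in cohort size.
    """
    lex = lexicon if lexicon is not None else default_lexicon()
    rows = []
    for p in cohort:
        row: dict[str, object] = {"participant_id": p.id}
        row.update(transcript_feature_row(p.transcripts, lex, cfg))
        if cfg.include_audio or cfg.silence_source == "audio":
            signals = {
                task: synthesize_task_audio(p.transcripts[task], p.audio_seeds[task])
                for task in TASKS
            }
            if cfg.include_audio:
                row.update(speech_feature_row(signals, cfg))
            if cfg.silence_source == "audio":
                _override_silence_from_audio(row, signals, cfg)
        row.update(
            {
                "diagnosis": p.diagnosis,
                "mmse": p.mmse,
                "age": p.age,
                "sex": p.sex,
                "education": p.education,
                "center": p.center,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def features_from_files(
    data_dir,
    lexicon: Lexicon | None = None,
    cfg: FeatureExtractionConfig = FeatureExtractionConfig(),
) -> tuple[pd.DataFrame, list[str]]:
    """Feature table from the on-disk layout (participants.csv,
    transcripts/<id>_<task>.json, audio/<id>_<task>.wav).

    Participants with missing or unreadable inputs are skipped and
    reported in the returned problem list.
    """
    lex = lexicon if lexicon is not None else default_lexicon()
    data = Path(data_dir)
    participants = pd.read_csv(data / "participants.csv", index_col="participant_id")
    audio_dir = data / "audio"
    rows, problems = [], []
    for pid, meta in participants.iterrows():
        try:
            transcripts = {}
            for task in TASKS:
                path = data / "transcripts" / f"{pid}_{task}.json"
                if not path.exists():
                    raise FileNotFoundError(f"{pid}: missing transcript {path.name}")
                transcripts[task] = read_transcript_json(path)
            row: dict[str, object] = {"participant_id": pid}
            row.update(transcript_feature_row(transcripts, lex, cfg))
            if cfg.include_audio or cfg.silence_source == "audio":
                signals = {}
                for task in TASKS:
                    wav = audio_dir / f"{pid}_{task}.wav"
                    if not wav.exists():
                        raise FileNotFoundError(f"{pid}: missing audio {wav.name}")
                    signals[task] = read_wav(wav)
                if cfg.include_audio:
                    row.update(speech_feature_row(signals, cfg))
                if cfg.silence_source == "audio":
                    _override_silence_from_audio(row, signals, cfg)
            row.update(meta.to_dict())
            rows.append(row)
        except (FileNotFoundError, ValueError) as exc:
            problems.append(str(exc))
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("participant_id")
    return df, problems


def labels_for_contrast(features: pd.DataFrame, contrast: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Subset a feature table and build binary labels from its diagnosis
    column for one diagnostic contrast."""
    if "diagnosis" not in features.columns:
        raise ValueError("feature table has no 'diagnosis' column")
    if contrast == "cn_vs_mci":
        features = features[features["diagnosis"] != "DEM"]
    elif contrast != "cn_vs_impaired":
        raise ValueError("contrast must be 'cn_vs_impaired' or 'cn_vs_mci'")
    y = (features["diagnosis"] != "CN").astype(int).to_numpy()
    return features, y
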