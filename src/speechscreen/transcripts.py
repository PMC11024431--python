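"""Timestamped transcripts of the four verbal tasks.

A transcript is the word-level output of speech-to-text transcription for one
participant performing one task: an ordered, non-overlapping sequence of
words, each with onset/offset times in seconds.  The three fluency tasks
(semantic, alternating, phonemic) are administered with a 1-minute limit;
the picture-description task (PDT) runs until the examiner stops it.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

#: Canonical task identifiers.
TASKS = ("SVF", "SVF_ALT", "PVF", "PDT")

#: Tasks administered under the 1-minute limit.
TIMED_TASKS = ("SVF", "SVF_ALT", "PVF")

#: Maximum duration (s) accepted for the timed fluency tasks.
MAX_TIMED_DURATION_S = 61.0


class TranscriptError(ValueError):
    """Raised when a transcript violates its structural invariants."""


def normalize_word(text: str) -> str:
    """Normalize a word for lexicon lookup.

    Lowercases, applies Unicode NFC normalization and strips punctuation.
    Accents are preserved: Spanish orthography distinguishes e.g. ``papa``
    from ``papá``.
    """
    text = unicodedata.normalize("NFC", text).lower().strip()
    return "".join(c for c in text if c.isalpha() or c in "ñü'-")


@dataclass(frozen=True)
class WordToken:
    """One transcribed word with its time span in seconds."""

    text: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        norm = normalize_word(self.text)
        if not norm:
            raise TranscriptError(f"token text {self.text!r} empty after normalization")
        object.__setattr__(self, "text", norm)
        if self.onset_s < 0:
            raise TranscriptError(f"token {norm!r}: onset {self.onset_s} < 0")
        if self.offset_s < self.onset_s:
            raise TranscriptError(
                f"token {norm!r}: offset {self.offset_s} < onset {self.onset_s}"
            )


@dataclass(frozen=True)
class Transcript:
    """Ordered, non-overlapping word tokens for one participant-task."""

    participant_id: str
    task: str
    tokens: tuple[WordToken, ...]
    duration_s: float

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise TranscriptError(f"unknown task {self.task!r}; expected one of {TASKS}")
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if self.duration_s <= 0:
            raise TranscriptError(f"duration_s must be > 0, got {self.duration_s}")
        if self.task in TIMED_TASKS and self.duration_s > MAX_TIMED_DURATION_S:
            raise TranscriptError(
                f"{self.task} duration {self.duration_s} s exceeds the "
                f"{MAX_TIMED_DURATION_S} s task limit"
            )
        prev_offset = 0.0
        prev_onset = -1.0
        for tok in self.tokens:
            if tok.onset_s < prev_onset:
                raise TranscriptError("tokens not sorted by onset")
            if tok.onset_s < prev_offset - 1e-9:
                raise TranscriptError(
                    f"token {tok.text!r} at {tok.onset_s} s overlaps previous token"
                )
            prev_onset, prev_offset = tok.onset_s, tok.offset_s
        if self.tokens and self.tokens[-1].offset_s > self.duration_s + 1e-9:
            raise TranscriptError("last token ends after duration_s")

    @property
    def words(self) -> list[str]:
        return [tok.text for tok in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


class SilenceStats(NamedTuple):
    mean_silence_s: float
    std_silence_s: float
    n_silences: int


def silence_durations_from_tokens(t: Transcript, min_gap_s: float = 0.25) -> np.ndarray:
    """Durations of all inter-token gaps of at least ``min_gap_s`` seconds.

    The leading gap (before the first word) and the trailing gap (after the
    last word, up to ``duration_s``) count as silences when long enough.
    """
    if not t.tokens:
        # degenerate transcript: no speech means no measurable pauses
        return np.array([])
    gaps = [t.tokens[0].onset_s]
    for prev, cur in zip(t.tokens, t.tokens[1:]):
        gaps.append(cur.onset_s - prev.offset_s)
    gaps.append(t.duration_s - t.tokens[-1].offset_s)
    arr = np.asarray(gaps, dtype=float)
    return arr[arr >= min_gap_s]


def silence_stats_from_tokens(t: Transcript, min_gap_s: float = 0.25) -> SilenceStats:
    """Mean and population std of silence durations derived from timestamps.

    A silence is any inter-token gap >= ``min_gap_s``, including leading and
    trailing gaps.  With zero qualifying silences both statistics are 0.
    """
    durs = silence_durations_from_tokens(t, min_gap_s)
    if durs.size == 0:
        return SilenceStats(0.0, 0.0, 0)
    return SilenceStats(float(durs.mean()), float(durs.std()), int(durs.size))


# ---------------------------------------------------------------------------
# serialization

def transcript_to_dict(t: Transcript) -> dict:
    return {
        "participant_id": t.participant_id,
        "task": t.task,
        "duration_s": t.duration_s,
        "tokens": [
            {"text": tok.text, "onset_s": tok.onset_s, "offset_s": tok.offset_s}
            for tok in t.tokens
        ],
    }


def transcript_from_dict(d: dict) -> Transcript:
    try:
        tokens = tuple(
            WordToken(tok["text"], float(tok["onset_s"]), float(tok["offset_s"]))
            for tok in d["tokens"]
        )
        return Transcript(
            participant_id=str(d["participant_id"]),
            task=d["task"],
            tokens=tokens,
            duration_s=float(d["duration_s"]),
        )
    except KeyError as exc:
        raise TranscriptError(f"transcript record missing field {exc}") from exc


def write_transcript_json(t: Transcript, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(transcript_to_dict(t), fh, ensure_ascii=False, indent=1)


def read_transcript_json(path) -> Transcript:
    with open(path, encoding="utf-8") as fh:
        return transcript_from_dict(json.load(fh))


def read_transcripts_csv(path) -> list[Transcript]:
    """Read transcripts from long-format CSV.

    Expected columns: participant_id, task, duration_s, text, onset_s,
    offset_s — one row per word token.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "task", "duration_s", "text", "onset_s", "offset_s"}
    missing = required - set(df.columns)
    if missing:
        raise TranscriptError(f"transcript CSV missing columns: {sorted(missing)}")
    out = []
    for (pid, task), grp in df.groupby(["participant_id", "task"], sort=False):
        grp = grp.sort_values("onset_s")
        tokens = tuple(
            WordToken(str(r.text), float(r.onset_s), float(r.offset_s))
            for r in grp.itertuples()
        )
        out.append(
            Transcript(str(pid), str(task), tokens, float(grp["duration_s"].iloc[0]))
        )
    return out


def transcripts_to_csv(transcripts: Iterable[Transcript], path) -> None:
    rows = []
    for t in transcripts:
        for tok in t.tokens:
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "task": t.task,
                    "duration_s": t.duration_s,
                    "text": tok.text,
                    "onset_s": tok.onset_s,
                    "offset_s": tok.offset_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
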