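"""Synthetic speech cohorts for end-to-end exercise of the screening
pipeline.

Each synthetic participant gets a clinical label (CN, MCI or all-cause
dementia), demographics and an MMSE score drawn from distributions shaped
like an elderly Spanish clinical sample, plus four task transcripts with
word timestamps.  Group differences are injected through interpretable
generator parameters: impaired groups produce fewer words, longer pauses,
more repetitions and intrusions, more frequent semantic switches, more
alternation violations and poorer picture-keyword coverage; the dementia
group inherits the MCI shifts scaled up (x1.8 by default), giving the
monotone CN < MCI < dementia severity ordering.

Audio is synthesized on demand as one 200-400 Hz tone burst per word at
the word's exact timestamps over digital silence, so token-derived and
energy-derived silence statistics agree by construction.  Tone bursts
exercise framing, RMS, ZCR and silence detection deterministically but are
not speech-realistic spectrally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .audio import DEFAULT_SAMPLE_RATE, AudioSignal
from .lexicon import Lexicon, default_lexicon
from .transcripts import Transcript, WordToken, write_transcript_json

DIAGNOSES = ("CN", "MCI", "DEM")
CONTRASTS = ("cn_vs_impaired", "cn_vs_mci")

#: Group MMSE (mean, sd): CN, MCI, dementia.
MMSE_PARAMS = {"CN": (28.58, 1.32), "MCI": (25.78, 3.17), "DEM": (23.33, 1.97)}

#: Common non-list intrusion words for the fluency tasks.
_INTRUSIONS = ("mesa", "silla", "coche", "casa", "puerta", "cosa", "persona")


@dataclass(frozen=True)
class EffectSizes:
    """Per-feature group shifts applied to the MCI group (dementia gets the
    same shifts scaled by ``SyntheticCohortConfig.dementia_scale``)."""

    word_rate_drop: float = 0.0  # words per SVF minute
    pause_increase_s: float = 0.0  # mean inter-word gap increment
    repetition_increase: float = 0.0  # probability increment
    switch_increase: float = 0.0  # semantic switch probability increment
    violation_increase: float = 0.0  # alternation violation increment
    intrusion_increase: float = 0.0  # out-of-list word increment
    keyword_coverage_drop: float = 0.0  # PDT keyword coverage decrement


EFFECT_PRESETS: dict[str, EffectSizes] = {
    "null": EffectSizes(),
    "moderate": EffectSizes(
        word_rate_drop=3.0,
        pause_increase_s=0.35,
        repetition_increase=0.04,
        switch_increase=0.10,
        violation_increase=0.08,
        intrusion_increase=0.02,
        keyword_coverage_drop=0.15,
    ),
    "strong": EffectSizes(
        word_rate_drop=6.0,
        pause_increase_s=0.80,
        repetition_increase=0.10,
        switch_increase=0.22,
        violation_increase=0.18,
        intrusion_increase=0.05,
        keyword_coverage_drop=0.30,
    ),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort composition and effect-size control.

    Defaults mirror the study cohort: 87 CN, 63 MCI, 24 dementia.
    ``effect`` is a preset name or an explicit :class:`EffectSizes`;
    ``noise_sd`` scales within-group timing dispersion.
    """

    n_cn: int = 87
    n_mci: int = 63
    n_dem: int = 24
    seed: int = 0
    effect: str | EffectSizes = "moderate"
    noise_sd: float = 1.0
    dementia_scale: float = 1.8
    audio: bool = False

    def resolved_effect(self) -> EffectSizes:
        if isinstance(self.effect, EffectSizes):
            return self.effect
        try:
            return EFFECT_PRESETS[self.effect]
        except KeyError:
            raise ValueError(
                f"unknown effect preset {self.effect!r}; "
                f"available presets: {sorted(EFFECT_PRESETS)}"
            ) from None


@dataclass(frozen=True)
class SyntheticParticipant:
    id: str
    diagnosis: str
    age: float
    sex: str  # "F" / "M"
    education: float
    center: int
    mmse: int
    transcripts: dict[str, Transcript]
    audio_seeds: dict[str, int]


@dataclass(frozen=True)
class Cohort:
    participants: tuple[SyntheticParticipant, ...]

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "participant_id": p.id,
                    "diagnosis": p.diagnosis,
                    "age": p.age,
                    "sex": p.sex,
                    "education": p.education,
                    "center": p.center,
                    "mmse": p.mmse,
                }
                for p in self.participants
            ]
        ).set_index("participant_id")

    def for_contrast(self, contrast: str) -> tuple["Cohort", np.ndarray]:
        """Subset and binary labels for a diagnostic contrast.

        ``cn_vs_impaired`` keeps everyone (MCI and dementia are positive);
        ``cn_vs_mci`` drops the dementia group.
        """
        if contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}")
        if contrast == "cn_vs_mci":
            kept = tuple(p for p in self.participants if p.diagnosis != "DEM")
        else:
            kept = self.participants
        y = np.array([int(p.diagnosis != "CN") for p in kept])
        return Cohort(kept), y


# ---------------------------------------------------------------------------
# group parameterization

@dataclass(frozen=True)
class _TaskParams:
    svf_rate: float
    alt_rate: float
    pvf_rate: float
    pdt_rate: float
    p_switch: float
    p_rep: float
    p_intrusion: float
    p_violation: float
    keyword_coverage: float
    pause_shift_s: float  # added to every mean inter-word gap


_CN_PARAMS = _TaskParams(
    svf_rate=18.0,
    alt_rate=14.0,
    pvf_rate=12.0,
    pdt_rate=85.0,
    p_switch=0.35,
    p_rep=0.02,
    p_intrusion=0.02,
    p_violation=0.05,
    keyword_coverage=0.85,
    pause_shift_s=0.0,
)


def _group_params(diagnosis: str, eff: EffectSizes, dem_scale: float) -> _TaskParams:
    if diagnosis == "CN":
        return _CN_PARAMS
    s = 1.0 if diagnosis == "MCI" else dem_scale
    b = _CN_PARAMS
    return _TaskParams(
        svf_rate=max(2.0, b.svf_rate - s * eff.word_rate_drop),
        alt_rate=max(2.0, b.alt_rate - s * 0.7 * eff.word_rate_drop),
        pvf_rate=max(2.0, b.pvf_rate - s * 0.6 * eff.word_rate_drop),
        pdt_rate=max(10.0, b.pdt_rate - s * 2.5 * eff.word_rate_drop),
        p_switch=min(0.95, b.p_switch + s * eff.switch_increase),
        p_rep=min(0.6, b.p_rep + s * eff.repetition_increase),
        p_intrusion=min(0.5, b.p_intrusion + s * eff.intrusion_increase),
        p_violation=min(0.9, b.p_violation + s * eff.violation_increase),
        keyword_coverage=max(0.05, b.keyword_coverage - s * eff.keyword_coverage_drop),
        pause_shift_s=s * eff.pause_increase_s,
    )


def _fluency_gap_mean_s(n_words: int, pause_shift_s: float) -> float:
    """Mean inter-word gap that spreads ``n_words`` across the 1-minute
    fluency window (word production slows as retrieval gets harder), plus
    the group pause shift.  Keeps the trailing silence realistic instead of
    leaving half the minute empty."""
    base = max(0.4, (57.0 - 0.5 * n_words) / max(n_words, 1))
    return base + pause_shift_s


# ---------------------------------------------------------------------------
# word-sequence generators

def _svf_words(rng: np.random.Generator, n: int, p: _TaskParams, lex: Lexicon) -> list[str]:
    by_subcat: dict[str, list[str]] = {}
    for w, subs in sorted(lex.animals.items()):
        for s in subs:
            by_subcat.setdefault(s, []).append(w)
    subcats = sorted(by_subcat)
    current = str(rng.choice(subcats))
    said: list[str] = []
    for _ in range(n):
        r = rng.random()
        if said and r < p.p_rep:
            said.append(str(rng.choice(said)))
            continue
        if r < p.p_rep + p.p_intrusion:
            said.append(str(rng.choice(_INTRUSIONS)))
            continue
        if rng.random() < p.p_switch:
            current = str(rng.choice([s for s in subcats if s != current]))
        pool = [w for w in by_subcat[current] if w not in said]
        if not pool:
            current = str(rng.choice(subcats))
            pool = [w for w in by_subcat[current] if w not in said] or by_subcat[current]
        said.append(str(rng.choice(pool)))
    return said


def _alt_words(rng, n: int, p: _TaskParams, lex: Lexicon) -> list[str]:
    pools = {"fruit": sorted(lex.fruits), "sport": sorted(lex.sports)}
    expected = "fruit"
    out: list[str] = []
    prev_cat: str | None = None
    for _ in range(n):
        if rng.random() < p.p_intrusion:
            out.append(str(rng.choice(_INTRUSIONS)))
            continue
        cat = expected
        if prev_cat is not None and rng.random() < p.p_violation:
            cat = prev_cat  # perseverate on the previous category
        out.append(str(rng.choice(pools[cat])))
        prev_cat = cat
        expected = "sport" if cat == "fruit" else "fruit"
    return out


def _pvf_words(rng, n: int, p: _TaskParams, lex: Lexicon) -> list[str]:
    pool = list(lex.f_words)
    said: list[str] = []
    for _ in range(n):
        if said and rng.random() < p.p_rep:
            said.append(str(rng.choice(said)))
            continue
        fresh = [w for w in pool if w not in said] or pool
        said.append(str(rng.choice(fresh)))
    return said


def _pdt_words(rng, n: int, p: _TaskParams, lex: Lexicon) -> list[str]:
    keywords = sorted(lex.pdt_keywords)
    covered = [k for k in keywords if rng.random() < p.keyword_coverage]
    filler = [
        w for w, lm in sorted(lex.lemma_map.items()) if lm not in lex.pdt_keywords
    ]
    words = [str(rng.choice(filler)) for _ in range(max(n, len(covered)))]
    # splice each covered keyword in once (plus occasional extra mentions)
    positions = rng.choice(len(words), size=len(covered), replace=False)
    for pos, kw in zip(positions, covered):
        words[pos] = kw
    for kw in covered:
        if rng.random() < 0.3 and len(words) > 1:
            words[int(rng.integers(len(words)))] = kw
    return words


# ---------------------------------------------------------------------------
# timing

def _timed_transcript(
    rng,
    pid: str,
    task: str,
    words: list[str],
    gap_mean_s: float,
    noise_sd: float,
    limit_s: float | None,
    long_pause_prob: float = 0.0,
    long_gap_mean_s: float = 0.0,
) -> Transcript:
    sigma = 0.5 * noise_sd
    tokens: list[WordToken] = []
    t = 0.0
    for i, w in enumerate(words):
        mean_gap = gap_mean_s
        if long_pause_prob and rng.random() < long_pause_prob:
            mean_gap = long_gap_mean_s
        mu = math.log(max(mean_gap, 1e-3)) - sigma**2 / 2
        gap = float(rng.lognormal(mu, sigma))
        dur = float(rng.uniform(0.35, 0.65))
        onset = t + gap
        offset = onset + dur
        if limit_s is not None and offset > limit_s:
            break
        tokens.append(WordToken(w, onset, offset))
        t = offset
    duration = limit_s if limit_s is not None else (t + 0.5 if tokens else 5.0)
    return Transcript(pid, task, tuple(tokens), duration)


def _make_transcripts(
    rng, pid: str, p: _TaskParams, lex: Lexicon, noise_sd: float
) -> dict[str, Transcript]:
    out = {}
    for task, rate, maker in (
        ("SVF", p.svf_rate, _svf_words),
        ("SVF_ALT", p.alt_rate, _alt_words),
        ("PVF", p.pvf_rate, _pvf_words),
    ):
        n = int(rng.poisson(rate))
        out[task] = _timed_transcript(
            rng, pid, task, maker(rng, n, p, lex),
            _fluency_gap_mean_s(n, p.pause_shift_s), noise_sd, 60.0,
        )
    n_pdt = int(rng.poisson(p.pdt_rate))
    out["PDT"] = _timed_transcript(
        rng,
        pid,
        "PDT",
        _pdt_words(rng, n_pdt, p, lex),
        0.15 + 0.25 * p.pause_shift_s,
        noise_sd,
        None,
        long_pause_prob=0.12,
        long_gap_mean_s=1.2 + p.pause_shift_s,
    )
    return out


# ---------------------------------------------------------------------------
# cohort-level API

def simulate_cohort(cfg: SyntheticCohortConfig, lexicon: Lexicon | None = None) -> Cohort:
    """Generate a labeled cohort, fully reproducible from ``cfg.seed``."""
    eff = cfg.resolved_effect()
    lex = lexicon if lexicon is not None else default_lexicon()
    participants = []
    plan = (
        [("CN", i) for i in range(cfg.n_cn)]
        + [("MCI", i) for i in range(cfg.n_mci)]
        + [("DEM", i) for i in range(cfg.n_dem)]
    )
    for idx, (diagnosis, _) in enumerate(plan):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, idx)))
        pid = f"P{idx:04d}"
        params = _group_params(diagnosis, eff, cfg.dementia_scale)
        age = float(np.clip(rng.normal(75.0, 8.0), 50, 95))
        education = float(np.clip(rng.normal(12.5, 5.0), 0, 25))
        sex = "F" if rng.random() < 0.56 else "M"
        center = int(rng.choice([1, 2, 3], p=[0.47, 0.36, 0.17]))
        mu, sd = MMSE_PARAMS[diagnosis]
        mmse = int(np.clip(round(rng.normal(mu, sd)), 0, 30))
        transcripts = _make_transcripts(rng, pid, params, lex, cfg.noise_sd)
        audio_seeds = {
            task: int(
                np.random.SeedSequence((cfg.seed, idx, ti, 7)).generate_state(1)[0]
                % (2**31)
            )
            for ti, task in enumerate(transcripts)
        }
        participants.append(
            SyntheticParticipant(
                pid, diagnosis, age, sex, education, center, mmse,
                transcripts, audio_seeds,
            )
        )
    return Cohort(tuple(participants))


def synthesize_task_audio(
    transcript: Transcript, seed: int, sample_rate: int = DEFAULT_SAMPLE_RATE
) -> AudioSignal:
    """Tone-burst audio matching a transcript's word timestamps.

    Each word becomes a sine burst at a per-word frequency drawn uniformly
    from 200-400 Hz, with 5 ms raised-cosine ramps to avoid clicks; the
    rest of the recording is digital silence.
    """
    rng = np.random.default_rng(seed)
    n = max(1, int(round(transcript.duration_s * sample_rate)))
    x = np.zeros(n)
    ramp_n = int(0.005 * sample_rate)
    for tok in transcript.tokens:
        i0 = int(round(tok.onset_s * sample_rate))
        i1 = min(n, int(round(tok.offset_s * sample_rate)))
        if i1 <= i0:
            continue
        f = rng.uniform(200.0, 400.0)
        t = np.arange(i1 - i0) / sample_rate
        seg = 0.8 * np.sin(2 * np.pi * f * t)
        m = min(ramp_n, seg.size // 2)
        if m > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
            seg[:m] *= ramp
            seg[-m:] *= ramp[::-1]
        x[i0:i1] = seg
    return AudioSignal(x, sample_rate)


@dataclass(frozen=True)
class SplitResult:
    train: Cohort
    test: Cohort
    balance: pd.DataFrame


def split_cohort(cohort: Cohort, train_frac: float = 0.70, seed: int | None = None) -> SplitResult:
    """Stratified train/test split by diagnosis with a covariate balance
    report (mean age/education/MMSE and percent female per split)."""
    diags = [p.diagnosis for p in cohort]
    counts = pd.Series(diags).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"diagnosis groups with < 2 members cannot be split: {small}")
    idx = np.arange(len(cohort))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, stratify=diags, random_state=seed
    )
    train = Cohort(tuple(cohort.participants[i] for i in sorted(train_idx)))
    test = Cohort(tuple(cohort.participants[i] for i in sorted(test_idx)))
    rows = []
    for name, c in (("train", train), ("test", test)):
        df = c.to_frame()
        rows.append(
            {
                "split": name,
                "n": len(c),
                "age_mean": df["age"].mean(),
                "education_mean": df["education"].mean(),
                "mmse_mean": df["mmse"].mean(),
                "pct_female": (df["sex"] == "F").mean() * 100,
            }
        )
    return SplitResult(train, test, pd.DataFrame(rows).set_index("split"))


# ---------------------------------------------------------------------------
# disk layout shared with the CLI

def write_cohort(cohort: Cohort, out_dir, audio: bool = False) -> None:
    """Write participants.csv, transcript JSON files and (optionally) WAVs
    in the directory layout the ``extract`` command consumes."""
    from .audio import write_wav  # local import to keep module load light

    out = Path(out_dir)
    (out / "transcripts").mkdir(parents=True, exist_ok=True)
    cohort.to_frame().to_csv(out / "participants.csv")
    if audio:
        (out / "audio").mkdir(exist_ok=True)
    for p in cohort:
        for task, t in p.transcripts.items():
            write_transcript_json(t, out / "transcripts" / f"{p.id}_{task}.json")
            if audio:
                sig = synthesize_task_audio(t, p.audio_seeds[task])
                write_wav(out / "audio" / f"{p.id}_{task}.wav", sig)
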