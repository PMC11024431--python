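"""Verbal-task features from timestamped transcripts.

Each of the four tasks yields a fixed, named feature vector used as
classifier input:

* **SVF** (semantic fluency, animals): production, repetition, semantic
  cluster/switch and temporal-cluster ("spurt") measures plus pause
  statistics.  A semantic cluster is a maximal run of two or more
  successively produced animal words in which every adjacent pair shares at
  least one subcategory; a switch is an adjacent animal pair sharing none.
  Cluster size counts the words in the run.  Non-animal intrusions are
  ignored when forming clusters and switches (they are scored separately as
  ``not_animals_ratio``).
* **SVF_ALT** (alternating fruits/sports): category counts, alternation
  violations, out-of-list intrusions, pauses.
* **PVF** (phonemic fluency, letter F): F-word count, repetitions, pooled
  consonant proportion of F-words, pauses.
* **PDT** (picture description): lexical diversity, part-of-speech rates,
  early word count, scene-keyword coverage, pauses.

Degenerate (empty) transcripts yield all-zero vectors so downstream models
never receive non-finite values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lexicon import Lexicon
from .transcripts import Transcript, silence_stats_from_tokens

#: Feature schema per task, in output column order.
FEATURE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "SVF": (
        "n_words",
        "mean_repetitions",
        "consecutive_repetitions",
        "n_semantic_clusters",
        "avg_semantic_cluster_size",
        "avg_switches",
        "not_animals_ratio",
        "n_temporal_clusters",
        "avg_temporal_cluster_size",
        "mean_silence_s",
        "std_silence_s",
    ),
    "SVF_ALT": (
        "count_fruits",
        "count_sports",
        "not_alternate",
        "not_in_list",
        "mean_silence_s",
        "std_silence_s",
    ),
    "PVF": (
        "n_f_words",
        "total_repetitions",
        "consonant_proportion",
        "mean_silence_s",
        "std_silence_s",
    ),
    "PDT": (
        "vocabulary_size",
        "pct_verbs",
        "pct_nouns",
        "pct_pronouns",
        "pct_determinants",
        "pct_adjectives",
        "n_words_30s",
        "n_keywords",
        "mean_silence_s",
        "std_silence_s",
    ),
}

#: Spanish vowels (accented forms included); every other letter is a consonant.
VOWELS = frozenset("aeiouáéíóúü")


@dataclass(frozen=True)
class TaskFeatureVector:
    """Named features for one participant-task, in schema order."""

    task: str
    features: dict[str, float]

    def __post_init__(self) -> None:
        schema = FEATURE_SCHEMAS[self.task]
        if tuple(self.features) != schema:
            raise ValueError(
                f"{self.task} features {tuple(self.features)} do not match "
                f"schema {schema}"
            )
        bad = [k for k, v in self.features.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features: {bad}")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.features.values()), dtype=float)


def _check_task(t: Transcript, task: str) -> None:
    if t.task != task:
        raise ValueError(f"expected a {task} transcript, got {t.task}")


def _zero_vector(task: str) -> TaskFeatureVector:
    return TaskFeatureVector(task, {k: 0.0 for k in FEATURE_SCHEMAS[task]})


# ---------------------------------------------------------------------------
# semantic fluency (animals)

def semantic_clusters(words: list[str], lex: Lexicon) -> tuple[list[int], int]:
    """Cluster sizes and switch count over the animal-word subsequence.

    Non-animal words are dropped first.  Adjacent animals sharing at least
    one subcategory stay in the same run; a pair sharing none is a switch.
    Runs of length >= 2 count as clusters; their size is the run length.
    """
    animals = [w for w in words if lex.is_animal(w)]
    if not animals:
        return [], 0
    runs = [1]
    switches = 0
    for prev, cur in zip(animals, animals[1:]):
        if lex.subcategories(prev) & lex.subcategories(cur):
            runs[-1] += 1
        else:
            switches += 1
            runs.append(1)
    return [r for r in runs if r >= 2], switches


def temporal_clusters(t: Transcript, spurt_gap_s: float = 1.0) -> list[int]:
    """Sizes of temporal clusters: maximal runs of >= 2 tokens whose
    inter-token gap is below ``spurt_gap_s`` seconds."""
    if len(t.tokens) < 2:
        return []
    runs = [1]
    for prev, cur in zip(t.tokens, t.tokens[1:]):
        if cur.onset_s - prev.offset_s < spurt_gap_s:
            runs[-1] += 1
        else:
            runs.append(1)
    return [r for r in runs if r >= 2]


def extract_svf_features(
    t: Transcript,
    lex: Lexicon,
    spurt_gap_s: float = 1.0,
    min_gap_s: float = 0.25,
) -> TaskFeatureVector:
    """Semantic-fluency features: production, repetitions, clusters, pauses.

    ``mean_repetitions`` is the ratio of repeated animal tokens (an animal
    already produced earlier in the transcript) to all listed tokens;
    ``consecutive_repetitions`` counts only immediate (token *i* == token
    *i*−1) animal repeats, over the same denominator.
    """
    _check_task(t, "SVF")
    if not t.tokens:
        return _zero_vector("SVF")
    words = t.words
    n = len(words)

    seen: set[str] = set()
    total_rep = 0
    consec_rep = 0
    for i, w in enumerate(words):
        if not lex.is_animal(w):
            continue
        if w in seen:
            total_rep += 1
            if i > 0 and words[i - 1] == w:
                consec_rep += 1
        seen.add(w)

    cluster_sizes, switches = semantic_clusters(words, lex)
    n_animals = sum(lex.is_animal(w) for w in words)
    spurts = temporal_clusters(t, spurt_gap_s)
    sil = silence_stats_from_tokens(t, min_gap_s)

    feats = {
        "n_words": float(n),
        "mean_repetitions": total_rep / n,
        "consecutive_repetitions": consec_rep / n,
        "n_semantic_clusters": float(len(cluster_sizes)),
        "avg_semantic_cluster_size": float(np.mean(cluster_sizes)) if cluster_sizes else 0.0,
        "avg_switches": switches / n_animals if n_animals else 0.0,
        "not_animals_ratio": (n - n_animals) / n,
        "n_temporal_clusters": float(len(spurts)),
        "avg_temporal_cluster_size": float(np.mean(spurts)) if spurts else 0.0,
        "mean_silence_s": sil.mean_silence_s,
        "std_silence_s": sil.std_silence_s,
    }
    return TaskFeatureVector("SVF", feats)


# ---------------------------------------------------------------------------
# alternating fluency (fruits / sports)

def extract_alt_features(
    t: Transcript, lex: Lexicon, min_gap_s: float = 0.25
) -> TaskFeatureVector:
    """Alternating-fluency features.

    ``not_alternate`` counts in-list tokens whose category (fruit or sport)
    equals the category of the previous in-list token — the expected
    sequence alternates, so the first in-list token can never violate.
    """
    _check_task(t, "SVF_ALT")
    if not t.tokens:
        return _zero_vector("SVF_ALT")
    n_fruits = n_sports = not_alt = not_in_list = 0
    prev_cat: str | None = None
    for w in t.words:
        cat = lex.alt_category(w)
        if cat is None:
            not_in_list += 1
            continue
        if cat == "fruit":
            n_fruits += 1
        else:
            n_sports += 1
        if cat == prev_cat:
            not_alt += 1
        prev_cat = cat
    sil = silence_stats_from_tokens(t, min_gap_s)
    feats = {
        "count_fruits": float(n_fruits),
        "count_sports": float(n_sports),
        "not_alternate": float(not_alt),
        "not_in_list": float(not_in_list),
        "mean_silence_s": sil.mean_silence_s,
        "std_silence_s": sil.std_silence_s,
    }
    return TaskFeatureVector("SVF_ALT", feats)


# ---------------------------------------------------------------------------
# phonemic fluency (letter F)

def extract_pvf_features(t: Transcript, min_gap_s: float = 0.25) -> TaskFeatureVector:
    """Phonemic-fluency features; needs no lexicon.

    ``consonant_proportion`` pools consonant and total letter counts over
    all F-words (letters outside the Spanish vowel set are consonants).
    """
    _check_task(t, "PVF")
    if not t.tokens:
        return _zero_vector("PVF")
    words = t.words
    f_words = [w for w in words if w.startswith("f")]
    seen: set[str] = set()
    reps = 0
    for w in words:
        if w in seen:
            reps += 1
        seen.add(w)
    letters = sum(len(w) for w in f_words)
    consonants = sum(1 for w in f_words for c in w if c not in VOWELS)
    sil = silence_stats_from_tokens(t, min_gap_s)
    feats = {
        "n_f_words": float(len(f_words)),
        "total_repetitions": float(reps),
        "consonant_proportion": consonants / letters if letters else 0.0,
        "mean_silence_s": sil.mean_silence_s,
        "std_silence_s": sil.std_silence_s,
    }
    return TaskFeatureVector("PVF", feats)


# ---------------------------------------------------------------------------
# picture description

def extract_pdt_features(
    t: Transcript, lex: Lexicon, min_gap_s: float = 0.25
) -> TaskFeatureVector:
    """Picture-description features via the pluggable lookup tagger.

    Words missing from the lemma map lemmatize to themselves; words missing
    from the POS map fall in no part-of-speech bucket, so the five POS
    percentages need not sum to one.  A keyword counts when any produced
    word lemmatizes to it; each keyword is counted once.  Words are counted
    toward ``n_words_30s`` when their onset is strictly before 30 s.
    """
    _check_task(t, "PDT")
    if not t.tokens:
        return _zero_vector("PDT")
    words = t.words
    n = len(words)
    lemmas = [lex.lemma(w) for w in words]
    pos_counts: dict[str, int] = {}
    for w in words:
        tag = lex.pos(w)
        if tag is not None:
            pos_counts[tag] = pos_counts.get(tag, 0) + 1
    keywords_hit = {lm for lm in lemmas if lm in lex.pdt_keywords}
    sil = silence_stats_from_tokens(t, min_gap_s)
    feats = {
        "vocabulary_size": float(len(set(lemmas))),
        "pct_verbs": pos_counts.get("VERB", 0) / n,
        "pct_nouns": pos_counts.get("NOUN", 0) / n,
        "pct_pronouns": pos_counts.get("PRON", 0) / n,
        "pct_determinants": pos_counts.get("DET", 0) / n,
        "pct_adjectives": pos_counts.get("ADJ", 0) / n,
        "n_words_30s": float(sum(tok.onset_s < 30.0 for tok in t.tokens)),
        "n_keywords": float(len(keywords_hit)),
        "mean_silence_s": sil.mean_silence_s,
        "std_silence_s": sil.std_silence_s,
    }
    return TaskFeatureVector("PDT", feats)


_EXTRACTORS = {
    "SVF": lambda t, lex, **kw: extract_svf_features(t, lex, **kw),
    "SVF_ALT": lambda t, lex, **kw: extract_alt_features(t, lex, **{k: v for k, v in kw.items() if k != "spurt_gap_s"}),
    "PVF": lambda t, lex, **kw: extract_pvf_features(t, **{k: v for k, v in kw.items() if k != "spurt_gap_s"}),
    "PDT": lambda t, lex, **kw: extract_pdt_features(t, lex, **{k: v for k, v in kw.items() if k != "spurt_gap_s"}),
}


def extract_task_features(
    t: Transcript,
    lex: Lexicon,
    spurt_gap_s: float = 1.0,
    min_gap_s: float = 0.25,
) -> TaskFeatureVector:
    """Dispatch to the task-specific extractor for ``t.task``."""
    return _EXTRACTORS[t.task](t, lex, spurt_gap_s=spurt_gap_s, min_gap_s=min_gap_s)
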