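"""Task lexicons: animal subcategories, fruits, sports, PDT keywords and a
lookup lemmatizer/POS tagger for the picture-description task.

The animal subcategory taxonomy used for semantic clustering is not
standardized; the one shipped here groups common Spanish animal names into
six semantic subcategories (pets, farm, wild, birds, fish-and-sea, insects),
with a handful of words legitimately belonging to more than one (e.g.
``gallina`` is both farm and bird).  All lexicon files are plain UTF-8 CSV
and can be replaced by the user.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .transcripts import normalize_word


def _read_rows(path_or_trav) -> list[list[str]]:
    if hasattr(path_or_trav, "open"):
        fh = path_or_trav.open(encoding="utf-8")
    else:
        fh = open(path_or_trav, encoding="utf-8")
    with fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    return rows[1:] if rows and rows[0][0] in ("word", "palabra") else rows


@dataclass(frozen=True)
class Lexicon:
    """Word lists backing Table-style verbal-task feature extraction."""

    animals: dict[str, frozenset[str]]  # word -> set of subcategories
    fruits: frozenset[str]
    sports: frozenset[str]
    pdt_keywords: frozenset[str]  # keyword lemmas for the picture scene
    lemma_map: dict[str, str] = field(default_factory=dict)
    pos_map: dict[str, str] = field(default_factory=dict)
    f_words: tuple[str, ...] = ()  # sample vocabulary for phonemic fluency

    # --- lookups (all accent-preserving, case-normalized) -----------------
    def subcategories(self, word: str) -> frozenset[str]:
        return self.animals.get(normalize_word(word), frozenset())

    def is_animal(self, word: str) -> bool:
        return normalize_word(word) in self.animals

    def alt_category(self, word: str) -> str | None:
        """Category of a word in the alternating fruits/sports task."""
        w = normalize_word(word)
        if w in self.fruits:
            return "fruit"
        if w in self.sports:
            return "sport"
        return None

    def lemma(self, word: str) -> str:
        """Lookup lemmatizer; unknown words lemmatize to themselves."""
        w = normalize_word(word)
        return self.lemma_map.get(w, w)

    def pos(self, word: str) -> str | None:
        """Lookup POS tagger; unknown words get no part-of-speech bucket."""
        return self.pos_map.get(normalize_word(word))


def load_lexicon(
    animals_csv,
    fruits_csv,
    sports_csv,
    pdt_keywords_csv,
    pdt_lexicon_csv=None,
    f_words_csv=None,
) -> Lexicon:
    """Build a :class:`Lexicon` from CSV files.

    ``animals_csv`` has columns (word, subcategory), one row per membership;
    ``fruits``/``sports``/``pdt_keywords``/``f_words`` are single-column word
    lists; ``pdt_lexicon_csv`` has columns (word, lemma, pos).
    """
    animals: dict[str, set[str]] = {}
    for row in _read_rows(animals_csv):
        w = normalize_word(row[0])
        animals.setdefault(w, set()).add(row[1].strip())
    lemma_map: dict[str, str] = {}
    pos_map: dict[str, str] = {}
    if pdt_lexicon_csv is not None:
        for row in _read_rows(pdt_lexicon_csv):
            w = normalize_word(row[0])
            lemma_map[w] = normalize_word(row[1])
            pos_map[w] = row[2].strip().upper()
    return Lexicon(
        animals={w: frozenset(s) for w, s in animals.items()},
        fruits=frozenset(normalize_word(r[0]) for r in _read_rows(fruits_csv)),
        sports=frozenset(normalize_word(r[0]) for r in _read_rows(sports_csv)),
        pdt_keywords=frozenset(
            normalize_word(r[0]) for r in _read_rows(pdt_keywords_csv)
        ),
        lemma_map=lemma_map,
        pos_map=pos_map,
        f_words=tuple(normalize_word(r[0]) for r in _read_rows(f_words_csv))
        if f_words_csv is not None
        else (),
    )


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    """The Spanish lexicon shipped with the package."""
    data = resources.files("speechscreen") / "data"
    return load_lexicon(
        data / "animals.csv",
        data / "fruits.csv",
        data / "sports.csv",
        data / "pdt_keywords.csv",
        data / "pdt_lexicon.csv",
        data / "f_words.csv",
    )


def load_lexicon_dir(directory) -> Lexicon:
    """Load a lexicon from a directory following the shipped file layout."""
    d = Path(directory)
    return load_lexicon(
        d / "animals.csv",
        d / "fruits.csv",
        d / "sports.csv",
        d / "pdt_keywords.csv",
        d / "pdt_lexicon.csv" if (d / "pdt_lexicon.csv").exists() else None,
        d / "f_words.csv" if (d / "f_words.csv").exists() else None,
    )
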