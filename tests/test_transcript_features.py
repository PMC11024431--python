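"""Verbal-task feature extraction: hand-computed examples, brute-force
cluster oracle, and structural invariants."""

import numpy as np
import pytest

from speechscreen import (
    FEATURE_SCHEMAS,
    Lexicon,
    Transcript,
    extract_alt_features,
    extract_pdt_features,
    extract_pvf_features,
    extract_svf_features,
    extract_task_features,
    WordToken,
)
from speechscreen.transcript_features import semantic_clusters, temporal_clusters

from conftest import make_transcript


@pytest.fixture(scope="module")
def toy_lexicon():
    """Tiny controlled lexicon: two animal subcategories plus alternating
    and PDT material."""
    return Lexicon(
        animals={
            "perro": frozenset({"pets"}),
            "gato": frozenset({"pets"}),
            "león": frozenset({"wild"}),
            "tigre": frozenset({"wild"}),
            "loro": frozenset({"pets", "birds"}),
            "águila": frozenset({"birds"}),
        },
        fruits=frozenset({"manzana", "pera"}),
        sports=frozenset({"fútbol", "tenis"}),
        pdt_keywords=frozenset({"niño", "galleta"}),
        lemma_map={"galletas": "galleta"},
        pos_map={"el": "DET", "niño": "NOUN", "roba": "VERB", "galletas": "NOUN"},
    )


class TestSVF:
    def test_two_cluster_example(self, toy_lexicon):
        fv = extract_svf_features(
            make_transcript(["perro", "gato", "león", "tigre"]), toy_lexicon
        )
        f = fv.features
        assert f["n_semantic_clusters"] == 2
        assert f["avg_semantic_cluster_size"] == 2.0
        assert f["avg_switches"] == 0.25
        assert f["n_words"] == 4
        assert f["not_animals_ratio"] == 0.0

    def test_repetition_ratios(self, toy_lexicon):
        fv = extract_svf_features(
            make_transcript(["perro", "perro", "perro"]), toy_lexicon
        )
        assert fv.features["mean_repetitions"] == pytest.approx(2 / 3)
        assert fv.features["consecutive_repetitions"] == pytest.approx(2 / 3)

    def test_empty_transcript_all_zero(self, toy_lexicon):
        fv = extract_svf_features(Transcript("p1", "SVF", (), 60.0), toy_lexicon)
        assert all(v == 0.0 for v in fv.features.values())

    def test_non_consecutive_repetition_counts_once(self, toy_lexicon):
        fv = extract_svf_features(
            make_transcript(["perro", "león", "perro"]), toy_lexicon
        )
        assert fv.features["mean_repetitions"] == pytest.approx(1 / 3)
        assert fv.features["consecutive_repetitions"] == 0.0

    def test_shared_subcategory_words_bridge_clusters(self, toy_lexicon):
        # loro belongs to pets and birds, linking both neighbours
        fv = extract_svf_features(
            make_transcript(["gato", "loro", "águila"]), toy_lexicon
        )
        assert fv.features["n_semantic_clusters"] == 1
        assert fv.features["avg_semantic_cluster_size"] == 3.0
        assert fv.features["avg_switches"] == 0.0

    def test_unknown_words_counted_not_raised(self, toy_lexicon):
        fv = extract_svf_features(
            make_transcript(["perro", "mesa", "gato"]), toy_lexicon
        )
        assert fv.features["not_animals_ratio"] == pytest.approx(1 / 3)

    def test_deleting_non_lexicon_words_preserves_clusters(self, toy_lexicon):
        with_noise = make_transcript(["perro", "mesa", "gato", "silla", "león", "tigre"])
        clean = make_transcript(["perro", "gato", "león", "tigre"])
        fa = extract_svf_features(with_noise, toy_lexicon).features
        fb = extract_svf_features(clean, toy_lexicon).features
        for key in ("n_semantic_clusters", "avg_semantic_cluster_size"):
            assert fa[key] == fb[key]
        assert fb["not_animals_ratio"] == 0.0

    def test_temporal_clusters_split_at_long_gaps(self, toy_lexicon):
        toks = (
            WordToken("perro", 0.0, 0.3),
            WordToken("gato", 0.5, 0.8),  # gap 0.2 < 1.0: same spurt
            WordToken("león", 3.0, 3.3),  # gap 2.2: new run (singleton)
            WordToken("tigre", 3.5, 3.8),
        )
        t = Transcript("p1", "SVF", toks, 60.0)
        fv = extract_svf_features(t, toy_lexicon, spurt_gap_s=1.0)
        assert fv.features["n_temporal_clusters"] == 2
        assert fv.features["avg_temporal_cluster_size"] == 2.0


def _oracle_runs(words, subcats):
    """Independent scan: maximal runs of adjacent animals sharing a
    subcategory, over the animal subsequence."""
    animals = [w for w in words if w in subcats]
    sizes, switches, i = [], 0, 0
    while i < len(animals):
        j = i
        while j + 1 < len(animals) and subcats[animals[j]] & subcats[animals[j + 1]]:
            j += 1
        if j > i:
            sizes.append(j - i + 1)
        if j + 1 < len(animals):
            switches += 1
        i = j + 1
    return sizes, switches


def test_semantic_clusters_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    subcats = {
        "dog": frozenset({"s1"}),
        "cat": frozenset({"s1"}),
        "cow": frozenset({"s2"}),
        "hen": frozenset({"s2"}),
        "fly": frozenset({"s3"}),
        "bat": frozenset({"s1", "s2"}),
    }
    lex = Lexicon(
        animals=subcats,
        fruits=frozenset(),
        sports=frozenset(),
        pdt_keywords=frozenset(),
    )
    vocab = list(subcats) + ["xx", "yy"]  # include non-animal intrusions
    for _ in range(1000):
        n = int(rng.integers(0, 13))
        words = [vocab[i] for i in rng.integers(0, len(vocab), n)]
        got_sizes, got_switches = semantic_clusters(words, lex)
        exp_sizes, exp_switches = _oracle_runs(words, subcats)
        assert got_sizes == exp_sizes
        assert got_switches == exp_switches


def test_svf_invariants_on_random_transcripts(lexicon, rng):
    animals = sorted(lexicon.animals)
    for _ in range(200):
        n = int(rng.integers(1, 15))
        words = [animals[i] for i in rng.integers(0, len(animals), n)]
        f = extract_svf_features(make_transcript(words), lexicon).features
        assert 0.0 <= f["avg_switches"] <= 1.0
        assert (
            f["n_semantic_clusters"] * f["avg_semantic_cluster_size"] <= f["n_words"]
        )


class TestAlternating:
    def test_perfect_alternation(self, toy_lexicon):
        fv = extract_alt_features(
            make_transcript(["manzana", "fútbol", "pera", "tenis"], task="SVF_ALT"),
            toy_lexicon,
        )
        f = fv.features
        assert (f["count_fruits"], f["count_sports"]) == (2, 2)
        assert (f["not_alternate"], f["not_in_list"]) == (0, 0)

    def test_violation_and_intrusion(self, toy_lexicon):
        fv = extract_alt_features(
            make_transcript(["manzana", "pera", "fútbol", "mesa"], task="SVF_ALT"),
            toy_lexicon,
        )
        f = fv.features
        assert f["not_alternate"] == 1  # pera repeats the fruit category
        assert f["not_in_list"] == 1  # mesa
        assert (f["count_fruits"], f["count_sports"]) == (2, 1)

    def test_single_token_cannot_violate(self, toy_lexicon):
        fv = extract_alt_features(
            make_transcript(["fútbol"], task="SVF_ALT"), toy_lexicon
        )
        assert fv.features["count_sports"] == 1
        assert fv.features["not_alternate"] == 0

    def test_empty_all_zero(self, toy_lexicon):
        fv = extract_alt_features(Transcript("p1", "SVF_ALT", (), 60.0), toy_lexicon)
        assert all(v == 0.0 for v in fv.features.values())


class TestPVF:
    def test_single_word_consonant_count(self):
        fv = extract_pvf_features(make_transcript(["foca"], task="PVF"))
        assert fv.features["n_f_words"] == 1
        assert fv.features["consonant_proportion"] == pytest.approx(0.5)

    def test_pooled_proportion_with_repetition(self):
        fv = extract_pvf_features(make_transcript(["foca", "foca", "flor"], task="PVF"))
        f = fv.features
        assert f["n_f_words"] == 3
        assert f["total_repetitions"] == 1
        assert f["consonant_proportion"] == pytest.approx(7 / 12)

    def test_no_f_words_zero_proportion(self):
        fv = extract_pvf_features(make_transcript(["mesa"], task="PVF"))
        assert fv.features["n_f_words"] == 0
        assert fv.features["consonant_proportion"] == 0.0

    def test_accented_vowels_not_consonants(self):
        # fácil: consonants f, c, l of 5 letters
        fv = extract_pvf_features(make_transcript(["fácil"], task="PVF"))
        assert fv.features["consonant_proportion"] == pytest.approx(3 / 5)


class TestPDT:
    def test_pos_percentages_and_keywords(self, toy_lexicon):
        fv = extract_pdt_features(
            make_transcript(["el", "niño", "roba", "galletas"], task="PDT"),
            toy_lexicon,
        )
        f = fv.features
        assert f["pct_nouns"] == 0.5
        assert f["pct_verbs"] == 0.25
        assert f["pct_determinants"] == 0.25
        assert f["n_keywords"] == 2  # niño + galletas->galleta
        assert f["vocabulary_size"] == 4

    def test_30s_boundary_half_open(self, toy_lexicon):
        toks = (
            WordToken("el", 5.0, 5.4),
            WordToken("niño", 29.9, 30.3),
            WordToken("roba", 31.0, 31.4),
        )
        t = Transcript("p1", "PDT", toks, 40.0)
        fv = extract_pdt_features(t, toy_lexicon)
        assert fv.features["n_words_30s"] == 2

    def test_unknown_words_self_lemmatize_no_pos(self, toy_lexicon):
        fv = extract_pdt_features(
            make_transcript(["zzz", "zzz", "niño"], task="PDT"), toy_lexicon
        )
        f = fv.features
        assert f["vocabulary_size"] == 2  # zzz and niño
        pos_sum = (
            f["pct_verbs"] + f["pct_nouns"] + f["pct_pronouns"]
            + f["pct_determinants"] + f["pct_adjectives"]
        )
        assert pos_sum == pytest.approx(1 / 3)  # only niño is tagged

    def test_empty_all_zero(self, toy_lexicon):
        fv = extract_pdt_features(Transcript("p1", "PDT", (), 10.0), toy_lexicon)
        assert all(v == 0.0 for v in fv.features.values())


def test_dispatch_matches_schemas(lexicon):
    cases = {
        "SVF": ["perro", "gato"],
        "SVF_ALT": ["manzana", "tenis"],
        "PVF": ["foca"],
        "PDT": ["el", "niño"],
    }
    for task, words in cases.items():
        fv = extract_task_features(make_transcript(words, task=task), lexicon)
        assert tuple(fv.features) == FEATURE_SCHEMAS[task]
        assert np.isfinite(fv.as_array()).all()
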