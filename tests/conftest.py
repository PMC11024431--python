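"""Shared fixtures: transcript builders, lexicons, and a small trained
screening model reused by the model/CLI tests."""

from __future__ import annotations

import numpy as np
import pytest

from speechscreen import (
    ModelSpec,
    ScreeningModel,
    SyntheticCohortConfig,
    Transcript,
    WordToken,
    cohort_features,
    default_lexicon,
    simulate_cohort,
)
from speechscreen.pipeline import labels_for_contrast


def make_transcript(
    words,
    task: str = "SVF",
    gap_s: float = 0.2,
    word_dur_s: float = 0.4,
    start_s: float = 0.5,
    duration_s: float = 60.0,
    participant_id: str = "p1",
) -> Transcript:
    """Evenly timed transcript helper."""
    tokens, t = [], start_s
    for w in words:
        tokens.append(WordToken(w, t, t + word_dur_s))
        t += word_dur_s + gap_s
    return Transcript(participant_id, task, tuple(tokens), duration_s)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate-effect cohort large enough to train on, small enough to be
    quick; audio synthesized on demand from stored seeds."""
    cfg = SyntheticCohortConfig(n_cn=24, n_mci=14, n_dem=6, seed=5, effect="strong")
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return cohort_features(small_cohort)


CHEAP_SPECS = (ModelSpec("logistic_regression", {"C": (0.1, 1.0)}),)


@pytest.fixture(scope="session")
def small_model(small_features):
    """Screening model trained with a reduced search (logistic-only task
    candidates, 5x1 CV) to keep the suite fast."""
    df, y = labels_for_contrast(small_features, "cn_vs_impaired")
    specs = {t: CHEAP_SPECS for t in ("SVF", "SVF_ALT", "PVF", "PDT")}
    model = ScreeningModel(
        specs_by_task=specs, n_splits=5, n_repeats=1, random_state=3
    ).fit(df, y)
    return model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
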