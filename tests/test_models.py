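"""Model pipeline: ANOVA-F selection against a textbook oracle, logit
transform, grid-search CV properties (signal recovery, null behaviour,
determinism), fold-internal fitting, stacking and deployment scoring."""

import numpy as np
import pytest

from speechscreen import (
    EnsembleScreener,
    ModelSpec,
    TaskScoreClassifier,
    logit_transform,
    select_features_f_stat,
    train_ensemble,
    train_task_model,
)
from speechscreen.models import FStatSelector, _make_pipeline, anova_f_scores

LOGISTIC_ONLY = (ModelSpec("logistic_regression", {"C": (0.1, 1.0)}),)


def textbook_f(x, y):
    """One-way ANOVA F from group means and variances (independent oracle)."""
    groups = [x[y == g] for g in np.unique(y)]
    k = len(groups)
    n = len(x)
    grand = x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        return 0.0
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestFStatSelection:
    def test_k_equals_n_features_returns_all(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        assert list(select_features_f_stat(X, y, 4)) == [0, 1, 2, 3]

    def test_perfect_separator_beats_constant(self):
        y = np.array([0, 1] * 10)
        X = np.column_stack([y.astype(float), np.ones(20)])
        assert list(select_features_f_stat(X, y, 1)) == [0]

    def test_matches_textbook_oracle(self, rng):
        for _ in range(50):
            X = rng.normal(size=(40, 6))
            y = rng.integers(0, 2, 40)
            y[:2] = [0, 1]
            expected = np.array([textbook_f(X[:, j], y) for j in range(6)])
            np.testing.assert_allclose(anova_f_scores(X, y), expected, rtol=1e-8)

    def test_tie_break_prefers_lower_index(self):
        y = np.array([0, 1] * 8)
        base = y.astype(float)
        X = np.column_stack([base, base, base])  # identical F values
        assert list(select_features_f_stat(X, y, 2)) == [0, 1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_features_f_stat(np.ones((10, 2)), np.zeros(10), 1)

    def test_selector_transformer_round_trip(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        sel = FStatSelector(k=3).fit(X, y)
        assert sel.transform(X).shape == (40, 3)


class TestLogit:
    def test_symmetry_point(self):
        assert logit_transform(0.5) == 0.0

    def test_closed_form_value(self):
        assert logit_transform(0.731) == pytest.approx(np.log(0.731 / 0.269), abs=1e-9)
        assert logit_transform(0.731) == pytest.approx(0.9996, abs=1e-3)

    def test_endpoint_clamped_finite(self):
        assert logit_transform(1.0, eps=1e-6) == pytest.approx(13.8155, abs=1e-3)
        assert np.isfinite(logit_transform(0.0))

    def test_vectorized(self):
        out = logit_transform(np.array([0.0, 0.5, 1.0]))
        assert out[0] == pytest.approx(-out[2])
        assert out[1] == 0.0


def two_gaussians(n, sep_sigma, seed, d=3):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, d))
    X[y == 1, 0] += sep_sigma
    return X, y


class TestTaskScoreClassifier:
    def test_separable_data_high_cv_auc(self):
        X, y = two_gaussians(100, 3.0, seed=0)
        model = TaskScoreClassifier(specs=LOGISTIC_ONLY, n_repeats=2, random_state=0)
        model.fit(X, y)
        assert model.cv_report_["auc"]["mean"] >= 0.95
        assert np.all((model.decision_scores(X) >= 0) & (model.decision_scores(X) <= 1))

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 5))
        y = rng.permutation(np.repeat([0, 1], 100))
        model = TaskScoreClassifier(specs=LOGISTIC_ONLY, n_repeats=2, random_state=1)
        model.fit(X, y)
        assert 0.40 <= model.cv_report_["auc"]["mean"] <= 0.60

    def test_identical_seed_identical_report(self):
        X, y = two_gaussians(80, 1.0, seed=5)
        specs = LOGISTIC_ONLY + (ModelSpec("knn", {"n_neighbors": (3, 5)}),)
        a = TaskScoreClassifier(specs=specs, n_repeats=2, random_state=7).fit(X, y)
        b = TaskScoreClassifier(specs=specs, n_repeats=2, random_state=7).fit(X, y)
        assert a.cv_report_ == b.cv_report_
        assert a.best_family_ == b.best_family_
        np.testing.assert_array_equal(a.decision_scores(X), b.decision_scores(X))

    def test_speech_task_selects_k_from_grid(self):
        X, y = two_gaussians(80, 2.5, seed=2, d=30)
        model = TaskScoreClassifier(
            task_id="SPEECH", n_splits=5, n_repeats=1, random_state=0
        ).fit(X, y)
        assert model.best_k_ in (5, 10, 15, 20)
        assert model.selected_features_.size == model.best_k_
        assert 0 in model.selected_features_  # the informative feature survives

    def test_small_class_reduces_folds_with_warning(self):
        X, y = two_gaussians(12, 3.0, seed=1)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            TaskScoreClassifier(specs=LOGISTIC_ONLY, n_repeats=1,
                                random_state=0).fit(X, y)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        with pytest.raises(ValueError):
            TaskScoreClassifier(specs=LOGISTIC_ONLY).fit(X, np.zeros(30))


def test_fold_internal_fitting_ignores_validation_rows(rng):
    """Corrupting (or shuffling) the validation rows must not change the
    scaler statistics or the selected features fitted on a training fold."""
    from sklearn.model_selection import StratifiedKFold

    X = rng.normal(size=(60, 20))
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    X[y == 1, 2] += 2.0
    for train_idx, val_idx in StratifiedKFold(5).split(X, y):
        corrupted = X.copy()
        corrupted[val_idx] = rng.normal(size=(len(val_idx), 20)) * 100 + 57
        pipe_a = _make_pipeline("logistic_regression", {"C": 1.0}, 10, 0)
        pipe_b = _make_pipeline("logistic_regression", {"C": 1.0}, 10, 0)
        pipe_a.fit(X[train_idx], y[train_idx])
        pipe_b.fit(corrupted[train_idx], y[train_idx])
        np.testing.assert_array_equal(
            pipe_a.named_steps["scale"].mean_, pipe_b.named_steps["scale"].mean_
        )
        np.testing.assert_array_equal(
            pipe_a.named_steps["select"].selected_,
            pipe_b.named_steps["select"].selected_,
        )


class TestEnsembleScreener:
    @staticmethod
    def _score_matrix(n, informative, seed):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        S = np.clip(rng.random((n, 5)), 0.01, 0.99)
        if informative:
            S[:, 1] = np.clip(y + rng.normal(0, 0.15, n), 0.01, 0.99)
        return S, y

    def test_informative_column_recovered(self):
        S, y = self._score_matrix(100, True, 0)
        ens = EnsembleScreener(specs=LOGISTIC_ONLY, n_repeats=2, random_state=0).fit(S, y)
        assert ens.cv_report_["auc"]["mean"] >= 0.95
        assert 0.0 <= ens.threshold_ <= 1.0
        assert len(ens.sweep_) == 101

    def test_constant_scores_near_chance(self):
        rng = np.random.default_rng(1)
        y = rng.permutation(np.repeat([0, 1], 50))
        S = np.full((100, 5), 0.5)
        ens = EnsembleScreener(specs=LOGISTIC_ONLY, n_repeats=2, random_state=0).fit(S, y)
        assert 0.4 <= ens.cv_report_["auc"]["mean"] <= 0.6

    def test_wrong_column_count_rejected(self):
        S, y = self._score_matrix(40, True, 2)
        with pytest.raises(ValueError, match="5 task-score columns"):
            EnsembleScreener(specs=LOGISTIC_ONLY).fit(S[:, :4], y)

    def test_monotone_score_transform_preserves_forest_cv_auc(self):
        # axis-aligned trees depend only on within-column ranks, which a
        # strictly monotone transform preserves
        S, y = self._score_matrix(80, True, 3)
        rf = (ModelSpec("random_forest", {"n_estimators": (50,), "max_depth": (3,)}),)
        a = EnsembleScreener(specs=rf, n_repeats=1, n_splits=5, random_state=0).fit(S, y)
        b = EnsembleScreener(specs=rf, n_repeats=1, n_splits=5, random_state=0).fit(S**2, y)
        assert a.cv_report_["auc"]["mean"] == pytest.approx(
            b.cv_report_["auc"]["mean"], abs=1e-9
        )


class TestScreeningModelDeployment:
    def test_boundary_score_decides_positive(self, small_model, small_features):
        from speechscreen.pipeline import labels_for_contrast

        df, _ = labels_for_contrast(small_features, "cn_vs_impaired")
        pred = small_model.predict_participant(df.iloc[[0]])
        assert pred.decision == int(pred.final_score >= small_model.threshold_)
        assert set(pred.task_scores) == {"SVF", "SVF_ALT", "PVF", "PDT", "SPEECH"}

    def test_missing_task_block_listed(self, small_model, small_features):
        dropped = small_features.drop(
            columns=[c for c in small_features.columns if c.startswith("pdt_")]
        )
        with pytest.raises(ValueError, match="PDT"):
            small_model.task_scores(dropped.iloc[[0]])

    def test_all_zero_features_do_not_crash(self, small_model, small_features):
        row = small_features.iloc[[0]].copy()
        num_cols = [c for c in row.columns if row[c].dtype.kind in "fi"]
        row[num_cols] = 0.0
        pred = small_model.predict_participant(row)
        assert pred.decision in (0, 1)
        assert 0.0 <= pred.final_score <= 1.0

    def test_scores_match_refit_pipeline(self, small_model, small_features):
        # the deployment path reuses the stored full-data pipelines
        task = "SVF"
        cols = small_model.feature_columns_[task]
        X = small_features[cols].to_numpy(dtype=float)
        direct = small_model.task_models_[task].decision_scores(X)
        via_matrix = small_model.task_scores(small_features)[:, 0]
        np.testing.assert_allclose(direct, via_matrix, atol=1e-12)


def test_functional_wrappers_return_fitted_estimators():
    X, y = two_gaussians(60, 2.0, seed=9)
    tm = train_task_model(X, y, "SVF", specs=LOGISTIC_ONLY, seed=0)
    assert hasattr(tm, "pipeline_")
    S = np.clip(np.random.default_rng(0).random((60, 5)), 0.01, 0.99)
    S[:, 0] = np.clip(y + 0.1, 0.01, 0.99)
    ens = train_ensemble(S, y, specs=LOGISTIC_ONLY, seed=0)
    assert 0.0 <= ens.threshold_ <= 1.0
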