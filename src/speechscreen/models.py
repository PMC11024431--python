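"""Per-task classifiers and the logit-stacked screening ensemble.

Five binary classifiers are trained — one per verbal task on its
transcript features and one on the acoustic ("speech") features — each by
exhaustive grid search over a list of candidate model families, evaluated
with stratified 10-fold cross-validation repeated 10 times and selected by
mean AUC.  Standardization (and, for the speech model, ANOVA-F feature
selection with the number of kept features ``k`` as a grid hyperparameter)
is refit inside every training fold, so no information from a validation
fold leaks into preprocessing.

The five per-participant scores (each in [0, 1]) are logit-transformed and
fed to a stacking classifier chosen by the same search procedure; the final
decision threshold is picked on cross-validated scores by a constrained
Youden rule (maximize sensitivity + specificity - 1 subject to
sensitivity > specificity, smallest threshold on ties).

Everything is expressed as scikit-learn estimators (``fit`` /
``predict_proba`` / ``get_params``), so the pieces compose with sklearn
model-selection utilities; the module-level ``train_*`` functions are thin
wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import make_scorer, recall_score
from sklearn.model_selection import (
    ParameterGrid,
    RepeatedStratifiedKFold,
    StratifiedKFold,
    cross_val_predict,
    cross_validate,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from .evaluation import auc as _auc
from .evaluation import select_threshold, threshold_sweep

#: The five model inputs, in canonical order.
TASK_ORDER = ("SVF", "SVF_ALT", "PVF", "PDT", "SPEECH")

#: Feature-column prefix per task in the wide feature table.
TASK_PREFIXES = {
    "SVF": "svf_",
    "SVF_ALT": "alt_",
    "PVF": "pvf_",
    "PDT": "pdt_",
    "SPEECH": "speech_",
}

#: Grid of candidate counts of selected acoustic features.
SPEECH_K_GRID = (5, 10, 15, 20)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate classifier family with its hyperparameter grid."""

    family: str
    grid: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _BUILDERS:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {sorted(_BUILDERS)}"
            )


def _build_logistic(params, rs):
    return LogisticRegression(max_iter=2000, random_state=rs, **params)


def _build_svm(params, rs):
    # sigmoid (Platt) calibration fitted on internal folds of the training
    # data maps the SVM margin to a probability in [0, 1]
    return CalibratedClassifierCV(
        SVC(kernel="linear", random_state=rs, **params),
        method="sigmoid",
        cv=5,
        ensemble=False,
    )


def _build_knn(params, rs):
    return KNeighborsClassifier(**params)


def _build_rf(params, rs):
    return RandomForestClassifier(random_state=rs, **params)


def _build_gb(params, rs):
    return GradientBoostingClassifier(random_state=rs, **params)


_BUILDERS = {
    "logistic_regression": _build_logistic,
    "svm": _build_svm,
    "knn": _build_knn,
    "random_forest": _build_rf,
    "gradient_boosting": _build_gb,
}

#: Default candidate lists.  Family order is the tie-break order.
DEFAULT_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec("logistic_regression", {"C": (0.01, 0.1, 1.0, 10.0)}),
    ModelSpec("svm", {"C": (0.1, 1.0, 10.0)}),
    ModelSpec("knn", {"n_neighbors": (3, 5, 7, 11)}),
    ModelSpec("random_forest", {"n_estimators": (100,), "max_depth": (3, None)}),
    ModelSpec("gradient_boosting", {"learning_rate": (0.05, 0.1), "n_estimators": (100,)}),
)

#: Default speech-model candidates: linear SVM, the family used for the
#: acoustic model, with regularization strength searched over the grid.
SPEECH_SPECS: tuple[ModelSpec, ...] = (ModelSpec("svm", {"C": (0.1, 1.0, 10.0)}),)


# ---------------------------------------------------------------------------
# ANOVA-F feature selection

def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic of each feature between the two classes.

    Zero-variance features get F = 0 (rather than NaN) so they are never
    selected ahead of informative ones.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("ANOVA F requires both classes present")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_vals, _ = f_classif(X, y)
    return np.nan_to_num(f_vals, nan=0.0, posinf=np.finfo(float).max)


def select_features_f_stat(X, y, k: int) -> np.ndarray:
    """Indices (ascending) of the ``k`` features with largest ANOVA F.

    Ties are broken deterministically toward the lower feature index.
    """
    X = np.asarray(X, dtype=float)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k={k} outside [1, {X.shape[1]}]")
    f_vals = anova_f_scores(X, y)
    top = np.argsort(-f_vals, kind="stable")[:k]
    return np.sort(top)


class FStatSelector(TransformerMixin, BaseEstimator):
    """Keep the ``k`` features with the largest between-class ANOVA F."""

    def __init__(self, k: int = 15):
        self.k = k

    def fit(self, X, y):
        self.selected_ = select_features_f_stat(X, y, self.k)
        return self

    def transform(self, X):
        check_is_fitted(self)
        return np.asarray(X)[:, self.selected_]


# ---------------------------------------------------------------------------
# logit stacking input

def logit_transform(p, eps: float = 1e-6):
    """Map a probability score to the real line: ln(p/(1-p)) after clamping
    into [eps, 1-eps] so endpoint scores stay finite."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# repeated-CV grid search shared by task models and the stacker

def _mse_scorer_func(y_true, proba):
    p = proba[:, 1] if getattr(proba, "ndim", 1) == 2 else np.asarray(proba)
    return float(np.mean((p - np.asarray(y_true)) ** 2))


_SCORERS = {
    "auc": "roc_auc",
    "accuracy": "accuracy",
    "sensitivity": make_scorer(recall_score, pos_label=1),
    "specificity": make_scorer(recall_score, pos_label=0),
    "mse": make_scorer(
        _mse_scorer_func, response_method="predict_proba", greater_is_better=False
    ),
}

_METRICS = ("auc", "accuracy", "sensitivity", "specificity", "mse")


def _expand_candidates(specs, k_grid):
    """Yield (family, params, k) in deterministic tie-break order."""
    for spec in specs:
        grid = ParameterGrid(dict(spec.grid)) if spec.grid else [{}]
        for params in grid:
            for k in k_grid if k_grid else (None,):
                yield spec.family, dict(params), k


def _summarize(res) -> dict:
    out = {}
    for m in _METRICS:
        vals = np.asarray(res[f"test_{m}"], dtype=float)
        if m == "mse":
            vals = -vals  # scorer is negated (greater_is_better=False)
        out[m] = {"mean": float(vals.mean()), "var": float(vals.var())}
    return out


def _grid_search_repeated_cv(X, y, specs, k_grid, n_splits, n_repeats, random_state):
    """Evaluate every candidate with repeated stratified k-fold CV.

    Returns (winner dict, report dict, effective n_splits).  The winner
    maximizes mean AUC; exact ties go to the lower mean MSE, then to the
    earlier candidate (family order as listed, then grid order).
    """
    class_counts = np.bincount(y)
    min_class = int(class_counts[class_counts > 0].min())
    eff_splits = n_splits
    if min_class < n_splits:
        eff_splits = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} members; reducing CV folds "
            f"from {n_splits} to {eff_splits}",
            stacklevel=3,
        )
    cv = RepeatedStratifiedKFold(
        n_splits=eff_splits, n_repeats=n_repeats, random_state=random_state
    )
    best = None
    for family, params, k in _expand_candidates(specs, k_grid):
        pipe = _make_pipeline(family, params, k, random_state)
        res = cross_validate(pipe, X, y, cv=cv, scoring=_SCORERS, error_score="raise")
        summary = _summarize(res)
        key = (summary["auc"]["mean"], -summary["mse"]["mean"])
        if best is None or key > best["key"]:
            best = {
                "key": key,
                "family": family,
                "params": params,
                "k": k,
                "report": summary,
            }
    return best


def _make_pipeline(family, params, k, random_state) -> Pipeline:
    steps = [("scale", StandardScaler())]
    if k is not None:
        steps.append(("select", FStatSelector(k=k)))
    steps.append(("clf", _BUILDERS[family](params, random_state)))
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# estimators

class TaskScoreClassifier(ClassifierMixin, BaseEstimator):
    """One task's screening classifier, selected by repeated-CV grid search.

    Parameters
    ----------
    task_id:
        One of ``SVF, SVF_ALT, PVF, PDT, SPEECH``.  For ``SPEECH`` the
        ANOVA-F feature-selection step is enabled with ``k`` searched over
        :data:`SPEECH_K_GRID`, and the default candidate list is the linear
        SVM family.
    specs:
        Candidate :class:`ModelSpec` list; the listed order is the tie-break
        order.  ``None`` uses the package defaults.
    n_splits, n_repeats:
        Stratified ``n_splits``-fold CV repeated ``n_repeats`` times; 10 x 10
        by default.  The fold count drops automatically (with a warning)
        when the smallest class is too small.
    random_state:
        Master seed for fold assignment and stochastic classifiers.

    Attributes
    ----------
    pipeline_ : fitted sklearn Pipeline (scaler [, selector], classifier)
    best_family_, best_params_, best_k_ : winning candidate
    cv_report_ : per-metric mean/variance over all CV evaluations
    selected_features_ : ndarray of kept feature indices (SPEECH only)
    """

    def __init__(
        self,
        task_id: str = "SVF",
        specs: tuple[ModelSpec, ...] | None = None,
        n_splits: int = 10,
        n_repeats: int = 10,
        random_state: int | None = None,
    ):
        self.task_id = task_id
        self.specs = specs
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.random_state = random_state

    def _resolved_specs(self):
        if self.specs is not None:
            return tuple(self.specs)
        return SPEECH_SPECS if self.task_id == "SPEECH" else DEFAULT_SPECS

    def fit(self, X, y):
        if self.task_id not in TASK_ORDER:
            raise ValueError(f"task_id must be one of {TASK_ORDER}")
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("need exactly two classes to train a screener")
        y = (y == self.classes_[1]).astype(int)
        k_grid = SPEECH_K_GRID if self.task_id == "SPEECH" else None
        if k_grid is not None:
            k_grid = tuple(k for k in k_grid if k <= X.shape[1]) or (X.shape[1],)
        best = _grid_search_repeated_cv(
            X, y, self._resolved_specs(), k_grid,
            self.n_splits, self.n_repeats, self.random_state,
        )
        self.best_family_ = best["family"]
        self.best_params_ = best["params"]
        self.best_k_ = best["k"]
        self.cv_report_ = {
            **best["report"],
            "chosen": {
                "family": best["family"],
                "params": best["params"],
                "k": best["k"],
            },
        }
        self.pipeline_ = _make_pipeline(
            best["family"], best["params"], best["k"], self.random_state
        ).fit(X, y)
        if self.best_k_ is not None:
            self.selected_features_ = self.pipeline_.named_steps["select"].selected_
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        return self.pipeline_.predict_proba(X)

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the impaired class, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        check_is_fitted(self)
        return self.classes_[self.pipeline_.predict(X)]


class EnsembleScreener(ClassifierMixin, BaseEstimator):
    """Stacking classifier over the five logit-transformed task scores.

    ``fit`` expects an (n, 5) matrix of *out-of-fold* task-model scores so
    the stacker never sees optimistically biased inputs.  After selecting
    the stacking family by the same repeated-CV grid search, the decision
    threshold is chosen on 10-fold cross-validated final scores by the
    constrained Youden rule.

    Attributes
    ----------
    stacker_ : fitted Pipeline over the logit score matrix
    threshold_ : decision cut in [0, 1] (final score >= threshold -> 1)
    sweep_ : CV-mean metric table over thresholds 0.00..1.00
    cv_report_, best_family_, best_params_ : as for TaskScoreClassifier
    """

    N_INPUTS = 5

    def __init__(
        self,
        specs: tuple[ModelSpec, ...] | None = None,
        logit_eps: float = 1e-6,
        n_splits: int = 10,
        n_repeats: int = 10,
        random_state: int | None = None,
    ):
        self.specs = specs
        self.logit_eps = logit_eps
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.random_state = random_state

    def fit(self, S, y):
        S, y = check_X_y(S, y)
        if S.shape[1] != self.N_INPUTS:
            raise ValueError(
                f"expected {self.N_INPUTS} task-score columns, got {S.shape[1]}"
            )
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("need exactly two classes to train the ensemble")
        y = (y == self.classes_[1]).astype(int)
        Z = logit_transform(S, self.logit_eps)
        specs = tuple(self.specs) if self.specs is not None else DEFAULT_SPECS
        best = _grid_search_repeated_cv(
            Z, y, specs, None, self.n_splits, self.n_repeats, self.random_state
        )
        self.best_family_ = best["family"]
        self.best_params_ = best["params"]
        self.cv_report_ = {
            **best["report"],
            "chosen": {"family": best["family"], "params": best["params"]},
        }
        self.stacker_ = _make_pipeline(
            best["family"], best["params"], None, self.random_state
        ).fit(Z, y)
        self.sweep_ = self._cv_sweep(Z, y, best)
        self.threshold_, self.threshold_constrained_ = select_threshold(self.sweep_)
        return self

    def _cv_sweep(self, Z, y, best) -> pd.DataFrame:
        """Mean per-threshold metrics over stratified 10-fold held-out scores."""
        class_counts = np.bincount(y)
        eff = min(self.n_splits, int(class_counts[class_counts > 0].min()))
        skf = StratifiedKFold(n_splits=max(2, eff), shuffle=True,
                              random_state=self.random_state)
        tables = []
        heldout_scores = np.empty(len(y))
        for train_idx, val_idx in skf.split(Z, y):
            pipe = _make_pipeline(
                best["family"], best["params"], None, self.random_state
            ).fit(Z[train_idx], y[train_idx])
            scores = pipe.predict_proba(Z[val_idx])[:, 1]
            heldout_scores[val_idx] = scores
            tables.append(threshold_sweep(scores, y[val_idx]))
        # AUC of pooled held-out scores: far less selection-optimistic than
        # the grid-search maximum, useful as a no-signal diagnostic
        self.cv_heldout_auc_ = _auc(heldout_scores, y)
        mean = tables[0].copy()
        for col in mean.columns:
            if col != "threshold":
                mean[col] = np.mean([t[col].to_numpy() for t in tables], axis=0)
        return mean

    def decision_scores(self, S) -> np.ndarray:
        check_is_fitted(self)
        Z = logit_transform(np.asarray(S, dtype=float), self.logit_eps)
        return self.stacker_.predict_proba(Z)[:, 1]

    def predict_proba(self, S):
        p = self.decision_scores(S)
        return np.column_stack([1.0 - p, p])

    def predict(self, S):
        return self.classes_[(self.decision_scores(S) >= self.threshold_).astype(int)]


@dataclass(frozen=True)
class ParticipantPrediction:
    """Deployment output for one participant."""

    task_scores: dict[str, float]
    final_score: float
    decision: int


class ScreeningModel(BaseEstimator):
    """The full deployable screener: five task models plus the ensemble.

    ``fit`` consumes the wide feature table produced by
    :func:`speechscreen.pipeline.cohort_features` (columns prefixed
    ``svf_``, ``alt_``, ``pvf_``, ``pdt_``, ``speech_``) and a binary label
    vector.  Stacker training inputs are out-of-fold scores: each
    participant's five scores come from task models fitted without that
    participant.
    """

    def __init__(
        self,
        specs_by_task: dict[str, tuple[ModelSpec, ...]] | None = None,
        n_splits: int = 10,
        n_repeats: int = 10,
        logit_eps: float = 1e-6,
        random_state: int | None = None,
    ):
        self.specs_by_task = specs_by_task
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.logit_eps = logit_eps
        self.random_state = random_state

    # -- column handling ----------------------------------------------------
    @staticmethod
    def _task_columns(features: pd.DataFrame, task: str) -> list[str]:
        return [c for c in features.columns if c.startswith(TASK_PREFIXES[task])]

    def _check_columns(self, features: pd.DataFrame) -> None:
        missing = [
            task for task in TASK_ORDER if not self._task_columns(features, task)
        ]
        if missing:
            raise ValueError(f"feature table missing task blocks: {missing}")

    def fit(self, features: pd.DataFrame, y):
        self._check_columns(features)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("need exactly two classes")
        ybin = (y == self.classes_[1]).astype(int)
        self.feature_columns_ = {
            task: self._task_columns(features, task) for task in TASK_ORDER
        }
        self.task_models_ = {}
        oof_scores = np.empty((len(features), len(TASK_ORDER)))
        class_counts = np.bincount(ybin)
        eff = max(2, min(self.n_splits, int(class_counts.min())))
        oof_cv = StratifiedKFold(n_splits=eff, shuffle=True, random_state=self.random_state)
        for j, task in enumerate(TASK_ORDER):
            X = features[self.feature_columns_[task]].to_numpy(dtype=float)
            specs = (self.specs_by_task or {}).get(task)
            model = TaskScoreClassifier(
                task_id=task,
                specs=specs,
                n_splits=self.n_splits,
                n_repeats=self.n_repeats,
                random_state=self.random_state,
            ).fit(X, ybin)
            self.task_models_[task] = model
            oof = cross_val_predict(
                clone(model.pipeline_), X, ybin, cv=oof_cv, method="predict_proba"
            )[:, 1]
            oof_scores[:, j] = oof
        self.oof_scores_ = oof_scores
        self.ensemble_ = EnsembleScreener(
            logit_eps=self.logit_eps,
            n_splits=self.n_splits,
            n_repeats=self.n_repeats,
            random_state=self.random_state,
        ).fit(oof_scores, ybin)
        self.threshold_ = self.ensemble_.threshold_
        return self

    def task_scores(self, features: pd.DataFrame) -> np.ndarray:
        """(n, 5) matrix of per-task impairment scores."""
        check_is_fitted(self)
        missing = [
            t for t in TASK_ORDER
            if any(c not in features.columns for c in self.feature_columns_[t])
        ]
        if missing:
            raise ValueError(f"missing features for tasks: {missing}")
        cols = []
        for task in TASK_ORDER:
            X = features[self.feature_columns_[task]].to_numpy(dtype=float)
            cols.append(self.task_models_[task].decision_scores(X))
        return np.column_stack(cols)

    def decision_scores(self, features: pd.DataFrame) -> np.ndarray:
        return self.ensemble_.decision_scores(self.task_scores(features))

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        p = self.decision_scores(features)
        return np.column_stack([1.0 - p, p])

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        p = self.decision_scores(features)
        return self.classes_[(p >= self.threshold_).astype(int)]

    def predict_participant(self, features: pd.DataFrame) -> ParticipantPrediction:
        """Score a single participant (one-row feature table)."""
        if len(features) != 1:
            raise ValueError("predict_participant expects exactly one row")
        scores = self.task_scores(features)[0]
        final = float(self.ensemble_.decision_scores(scores[None, :])[0])
        return ParticipantPrediction(
            task_scores={t: float(s) for t, s in zip(TASK_ORDER, scores)},
            final_score=final,
            decision=int(final >= self.threshold_),
        )


# ---------------------------------------------------------------------------
# thin functional wrappers

def train_task_model(X, y, task_id, specs=None, seed=None) -> TaskScoreClassifier:
    return TaskScoreClassifier(
        task_id=task_id, specs=specs, random_state=seed
    ).fit(X, y)


def train_ensemble(task_scores, y, specs=None, seed=None) -> EnsembleScreener:
    return EnsembleScreener(specs=specs, random_state=seed).fit(task_scores, y)


def predict_participant(model: ScreeningModel, features) -> ParticipantPrediction:
    return model.predict_participant(features)
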