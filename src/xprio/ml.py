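"""Classifier tournament and FDR-calibrated ensemble prediction.

Workflow: features are min-max normalized to [0,1] (statistics from the
training genes only, missing values imputed with the training median);
a registry of model families is evaluated by nested cross-validation
(outer 10-fold, inner 5-fold hyperparameter search, grid search when the
grid has at most 100 combinations, random search with 100 draws otherwise)
scored by the Matthews correlation coefficient; the top five families by
mean outer MCC are refit on all training data, probability-calibrated
where the family emits decision scores rather than probabilities, and
averaged into an ensemble.  A probability threshold t is then chosen so
that the running fraction of known-negative genes among genes scoring at
or above t stays below the target false discovery rate d; the default
prediction rule requires per-classifier probability > 0.5 in all five
families *and* mean probability > t.

The default registry ships the five tournament winners (adaptive boosting,
bootstrap-aggregated trees, linear max-margin, multilayer perceptron,
random forest) plus a constant-baseline control; the tournament structure
accepts any registry.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              RandomForestClassifier)
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import make_scorer, matthews_corrcoef
from sklearn.model_selection import (GridSearchCV, RandomizedSearchCV,
                                     StratifiedKFold)
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MinMaxImputeScaler", "normalize_features", "ClassifierSpec",
    "default_registry", "CVResult", "nested_cv", "build_ensemble",
    "ensemble_probabilities", "FdrThreshold", "estimate_fdr_threshold",
    "final_prediction", "permutation_importance", "DisorderGeneEnsemble",
]

_MCC = make_scorer(matthews_corrcoef)


@contextmanager
def _quiet():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*invalid value encountered.*")
        warnings.filterwarnings("ignore", message=".*single class.*")
        yield


# ---------------------------------------------------------------------------
# preprocessing

class MinMaxImputeScaler(BaseEstimator, TransformerMixin):
    """Min-max scaling to [0,1] with training-median imputation.

    Statistics (min, max, median) come from the reference (training) rows
    passed to ``fit``; transformed values outside the reference range clip
    to [0,1].  A feature constant on the reference maps to 0.5 everywhere
    (with a warning at fit time).  Missing cells are imputed with the
    reference median before scaling; :meth:`imputed_mask` reports them.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.empty:
            raise ValueError("reference rows must be non-empty")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.data_min_ = X.min(axis=0, skipna=True)
        self.data_max_ = X.max(axis=0, skipna=True)
        self.medians_ = X.median(axis=0, skipna=True)
        # all-missing reference column: pin to the midpoint
        allnan = self.medians_.isna()
        self.medians_[allnan] = 0.5
        self.data_min_[allnan], self.data_max_[allnan] = 0.0, 1.0
        self.constant_features_ = (self.data_max_ == self.data_min_)
        if self.constant_features_.any():
            warnings.warn(
                "constant feature(s) on the reference set mapped to 0.5: "
                f"{list(self.constant_features_[self.constant_features_].index)[:5]}",
                stacklevel=2)
        return self

    def imputed_mask(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X).isna()

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "data_min_")
        X = pd.DataFrame(X).copy()
        X = X.fillna(self.medians_)
        span = (self.data_max_ - self.data_min_).replace(0, np.nan)
        out = (X - self.data_min_) / span
        out[self.constant_features_[self.constant_features_].index] = 0.5
        return out.clip(0.0, 1.0)


def normalize_features(table: pd.DataFrame, reference_index) -> tuple[pd.DataFrame, MinMaxImputeScaler]:
    """Normalize all genes using statistics from the reference genes only."""
    scaler = MinMaxImputeScaler().fit(table.loc[reference_index])
    return scaler.transform(table), scaler


# ---------------------------------------------------------------------------
# classifier registry

@dataclass
class ClassifierSpec:
    """One model family: factory, hyperparameter space, calibration flag.

    The search strategy resolves to grid search when the finite grid has at
    most ``max_grid`` combinations, otherwise random search with
    ``max_grid`` draws.
    """

    name: str
    factory: object                      # callable(random_state) -> estimator
    param_grid: dict = field(default_factory=dict)
    calibrate: bool = False              # family emits scores, not probabilities
    max_grid: int = 100

    @property
    def n_combinations(self) -> int:
        n = 1
        for v in self.param_grid.values():
            n *= len(v)
        return n

    def make_search(self, inner_cv, random_state: int):
        est = self.factory(random_state)
        if not self.param_grid:
            return GridSearchCV(est, {}, scoring=_MCC, cv=inner_cv)
        if self.n_combinations <= self.max_grid:
            return GridSearchCV(est, self.param_grid, scoring=_MCC, cv=inner_cv)
        return RandomizedSearchCV(est, self.param_grid, n_iter=self.max_grid,
                                  scoring=_MCC, cv=inner_cv,
                                  random_state=random_state)


def default_registry(light: bool = False) -> list[ClassifierSpec]:
    """The five tournament winners plus a constant-baseline control.

    ``light=True`` shrinks grids and model sizes for quick runs.
    """
    mlp_hidden = [(16,)] if light else [(16,), (32,)]
    return [
        ClassifierSpec("adaboost",
                       lambda rs: AdaBoostClassifier(random_state=rs),
                       {"n_estimators": [25] if light else [25, 50]}),
        ClassifierSpec("bagging",
                       lambda rs: BaggingClassifier(random_state=rs),
                       {"n_estimators": [10] if light else [10, 20]}),
        ClassifierSpec("linear_svc",
                       lambda rs: LinearSVC(random_state=rs),
                       {"C": [1.0] if light else [0.1, 1.0, 10.0]},
                       calibrate=True),
        ClassifierSpec("mlp",
                       lambda rs, it=(200 if light else 300):
                       MLPClassifier(random_state=rs, max_iter=it),
                       {"hidden_layer_sizes": mlp_hidden}),
        ClassifierSpec("random_forest",
                       lambda rs: RandomForestClassifier(random_state=rs),
                       {"n_estimators": [50], "max_depth": [None] if light else [None, 8]}),
        ClassifierSpec("dummy",
                       lambda rs: DummyClassifier(strategy="most_frequent",
                                                  random_state=rs),
                       {"strategy": ["most_frequent", "stratified"]}),
    ]


def dummy_registry() -> list[ClassifierSpec]:
    """Constant/stratified-random baseline only (chance-level control)."""
    return [ClassifierSpec("dummy",
                           lambda rs: DummyClassifier(strategy="most_frequent",
                                                      random_state=rs),
                           {"strategy": ["most_frequent", "stratified"]})]


# ---------------------------------------------------------------------------
# nested cross-validation

@dataclass
class CVResult:
    name: str
    fold_mccs: list[float]
    mcc_mean: float
    mcc_std: float
    best_params: dict

    def to_dict(self) -> dict:
        return {"name": self.name, "fold_mccs": self.fold_mccs,
                "mcc_mean": self.mcc_mean, "mcc_std": self.mcc_std,
                "best_params": {k: repr(v) for k, v in self.best_params.items()}}


def nested_cv(X, y, registry: list[ClassifierSpec], outer_folds: int = 10,
              inner_folds: int = 5, seed: int = 0) -> list[CVResult]:
    """Nested cross-validation of every family in the registry.

    Outer folds are stratified by class; the inner search selects
    hyperparameters by mean inner MCC; outer MCC is computed on the
    held-out folds.  Reproducible from the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if outer_folds > counts.min():
        raise ValueError(
            f"outer_folds={outer_folds} exceeds minority class size {counts.min()}")
    outer = StratifiedKFold(outer_folds, shuffle=True, random_state=seed)
    inner = StratifiedKFold(inner_folds, shuffle=True, random_state=seed + 1)
    results = []
    with _quiet():
        for spec in registry:
            fold_mccs = []
            for tr, te in outer.split(X, y):
                search = spec.make_search(inner, seed)
                search.fit(X[tr], y[tr])
                fold_mccs.append(float(matthews_corrcoef(
                    y[te], search.best_estimator_.predict(X[te]))))
            final = spec.make_search(inner, seed).fit(X, y)
            results.append(CVResult(
                name=spec.name, fold_mccs=fold_mccs,
                mcc_mean=float(np.mean(fold_mccs)),
                mcc_std=float(np.std(fold_mccs)),
                best_params=dict(final.best_params_)))
    return results


# ---------------------------------------------------------------------------
# ensemble

def _can_score(est) -> bool:
    return hasattr(est, "predict_proba") or hasattr(est, "decision_function")


def build_ensemble(cv_results: list[CVResult], registry: list[ClassifierSpec],
                   X, y, top_k: int = 5, seed: int = 0,
                   calibration_folds: int = 5):
    """Refit the top-k families on all training data, calibrated.

    Families are ranked by mean MCC, ties broken by lower MCC standard
    deviation then by name.  Families flagged ``calibrate`` (scores, not
    probabilities) are wrapped in cross-validated sigmoid calibration; a
    family that can emit neither probabilities nor calibratable scores is
    excluded with a warning and the next-ranked family promoted.
    """
    by_name = {s.name: s for s in registry}
    ranked = sorted(cv_results,
                    key=lambda r: (-r.mcc_mean, r.mcc_std, r.name))
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    fitted = []
    for res in ranked:
        if len(fitted) == top_k:
            break
        spec = by_name[res.name]
        est = spec.factory(seed)
        est.set_params(**res.best_params)
        if not _can_score(est):
            warnings.warn(f"family {spec.name!r} cannot emit probabilities "
                          "or scores; excluded", stacklevel=2)
            continue
        if spec.calibrate or not hasattr(est, "predict_proba"):
            cv = StratifiedKFold(calibration_folds, shuffle=True,
                                 random_state=seed + 7)
            est = CalibratedClassifierCV(est, cv=cv, method="sigmoid")
        with _quiet():
            est.fit(X, y)
        fitted.append((spec.name, est))
    if len(fitted) < top_k:
        raise ValueError(f"only {len(fitted)} usable families, need {top_k}")
    return fitted


def ensemble_probabilities(fitted, X) -> pd.DataFrame:
    """Per-classifier calibrated probabilities of the positive class + mean."""
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
    Xa = np.asarray(X, dtype=float)
    cols = {}
    for name, est in fitted:
        pos = list(est.classes_).index(1)
        cols[name] = est.predict_proba(Xa)[:, pos]
    df = pd.DataFrame(cols, index=index)
    df["mean_probability"] = df.mean(axis=1)
    df["all_above_half"] = (df[[n for n, _ in fitted]] > 0.5).all(axis=1)
    return df


# ---------------------------------------------------------------------------
# FDR threshold

@dataclass
class FdrThreshold:
    """Result of the decreasing-threshold FDR scan.

    ``ok`` is False when even the top score violates the bound, in which
    case ``threshold`` is None.
    """

    threshold: float | None
    realized_fdr: float | None
    d: float
    ok: bool
    n_b: int
    n_d: int


def estimate_fdr_threshold(scores_b, scores_d, d: float = 0.05) -> FdrThreshold:
    """Scan candidate thresholds downward, keeping the running FDR below d.

    Candidates are the distinct observed scores of the positive class B in
    decreasing order (a threshold strictly between two B scores would only
    admit extra known-negative genes without gaining sensitivity);
    positives are genes scoring at or above the candidate.  Returns the
    smallest candidate t such that for it and every larger candidate
    ``|D >= t| / (|B >= t| + |D >= t|) < d`` — the maximal-sensitivity
    threshold whose running false-discovery proportion (known-negative
    genes D among positives) stays below d.
    """
    b = np.asarray(scores_b, dtype=float)
    dd = np.asarray(scores_d, dtype=float)
    if len(b) == 0 or len(dd) == 0:
        raise ValueError("both known classes must be present among scores")
    if not 0 < d < 1:
        raise ValueError("d must be in (0, 1)")
    candidates = np.unique(b)[::-1]
    best, best_fdr = None, None
    for t in candidates:
        n_b = int((b >= t).sum())
        n_d = int((dd >= t).sum())
        fdr = n_d / (n_b + n_d)
        if fdr < d:
            best, best_fdr = float(t), fdr
        else:
            break
    return FdrThreshold(threshold=best, realized_fdr=best_fdr, d=d,
                        ok=best is not None, n_b=len(b), n_d=len(dd))


def final_prediction(probabilities: pd.DataFrame, t: float | None,
                     rule: str = "conjunction") -> pd.Series:
    """Apply the prediction rule to ensemble probabilities.

    conjunction (default): all per-classifier probabilities > 0.5 AND mean
    probability > t.  disjunction: either condition.  With no valid FDR
    threshold the mean-probability condition is unsatisfiable.
    """
    if rule not in ("conjunction", "disjunction"):
        raise ValueError(f"unknown rule {rule!r}")
    mean_ok = (probabilities["mean_probability"] > t) if t is not None else \
        pd.Series(False, index=probabilities.index)
    allhalf = probabilities["all_above_half"]
    return (allhalf & mean_ok) if rule == "conjunction" else (allhalf | mean_ok)


# ---------------------------------------------------------------------------
# feature importance

def permutation_importance(fitted, X: pd.DataFrame, y, n_repeats: int = 5,
                           seed: int = 0) -> pd.Series:
    """Mean MCC drop when permuting each feature column.

    The score is the MCC of ``mean ensemble probability > 0.5`` against the
    known labels; importance of a feature is the average decrease over
    ``n_repeats`` random permutations of its column.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y).astype(int)
    base = matthews_corrcoef(
        y, ensemble_probabilities(fitted, X)["mean_probability"] > 0.5)
    drops = {}
    for col in X.columns:
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            mcc = matthews_corrcoef(
                y, ensemble_probabilities(fitted, Xp)["mean_probability"] > 0.5)
            deltas.append(base - mcc)
        drops[col] = float(np.mean(deltas))
    return pd.Series(drops, name="mcc_drop")


# ---------------------------------------------------------------------------
# the estimator

class DisorderGeneEnsemble(BaseEstimator, ClassifierMixin):
    """Nested-CV tournament + calibrated top-k ensemble + FDR threshold.

    ``fit(X, y)`` expects the raw (unnormalized) feature frame restricted
    to training genes with binary labels (1 = positive class, e.g. Cbi;
    0 = negative, e.g. NDt).  Normalization statistics, the tournament, the
    refit and the FDR threshold all derive from the training genes only.
    Per-gene probabilities for the training genes come from the refit on
    all training data (not from held-out folds).

    Parameters
    ----------
    registry : list of ClassifierSpec or None (default registry)
    top_k : families in the ensemble (default 5)
    outer_folds, inner_folds : nested CV structure (default 10 / 5)
    d : target false discovery rate (default 0.05)
    rule : "conjunction" (default) or "disjunction"
    select : run the nested-CV tournament; False refits the first top_k
        registry families with default hyperparameters (no tournament)
    random_state : seed for folds, models and calibration
    """

    def __init__(self, registry=None, top_k: int = 5, outer_folds: int = 10,
                 inner_folds: int = 5, d: float = 0.05,
                 rule: str = "conjunction", select: bool = True,
                 random_state: int = 0):
        self.registry = registry
        self.top_k = top_k
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.d = d
        self.rule = rule
        self.select = select
        self.random_state = random_state

    def _registry(self):
        return self.registry if self.registry is not None else default_registry()

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        registry = self._registry()
        self.scaler_ = MinMaxImputeScaler().fit(X)
        Xn = self.scaler_.transform(X)
        if self.select:
            self.cv_results_ = nested_cv(Xn, y, registry, self.outer_folds,
                                         self.inner_folds, self.random_state)
        else:
            usable = [s for s in registry if s.name != "dummy"][:self.top_k]
            self.cv_results_ = [
                CVResult(s.name, [], float("nan"), float("nan"),
                         {k: v[0] for k, v in s.param_grid.items()})
                for s in usable]
        self.estimators_ = build_ensemble(self.cv_results_, registry, Xn, y,
                                          self.top_k, self.random_state)
        train_probs = ensemble_probabilities(self.estimators_, Xn)
        scores = train_probs["mean_probability"].to_numpy()
        self.fdr_ = estimate_fdr_threshold(scores[y == 1], scores[y == 0], self.d)
        self.train_probabilities_ = train_probs
        self.classes_ = np.array([0, 1])
        return self

    def member_probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "estimators_")
        return ensemble_probabilities(self.estimators_,
                                      self.scaler_.transform(pd.DataFrame(X)))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.member_probabilities(X)["mean_probability"].to_numpy()
        return np.column_stack([1 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        probs = self.member_probabilities(X)
        return final_prediction(probs, self.fdr_.threshold, self.rule).to_numpy()

    def prediction_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-gene probabilities, flags, threshold and rule (one frame)."""
        probs = self.member_probabilities(X)
        probs["fdr_threshold"] = self.fdr_.threshold
        probs["rule"] = self.rule
        probs["predicted"] = final_prediction(probs, self.fdr_.threshold, self.rule)
        return probs
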