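"""Imbalance-aware wrapper feature selection and random-search tuning.

Stage 1 (normovolemia vs. hypovolemia) is heavily imbalanced (~10x more
hypovolemia beats), so hypovolemia rows are undersampled to a 1:1 ratio per
subject before feature selection, and the F1 score is the optimized metric.
Stage 2 (relative vs. absolute hypovolemia, ~3:1) uses no resampling and
optimizes accuracy.

Selection is sequential forward selection scored by inner leave-one-subject-
out cross-validation of the candidate classifier itself (a wrapper method);
hyper-parameters are then tuned by random search, scored the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import ParameterSampler
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: Metric optimized per stage.
STAGE_METRICS = {1: "f1", 2: "accuracy"}


def make_candidate(name: str, random_state=None):
    """Candidate classifier with its initial (pre-search) hyper-parameters.

    The initial random forest uses 100 estimators, maximum depth 12, and
    minimum samples of 2 at split nodes and 1 at leaf nodes, minimizing the
    Gini impurity; logistic regression uses L2 regularization; the SVM uses
    an RBF kernel with unity regularization and the 'scale' kernel
    coefficient (1 / (n_features * training variance)).
    """
    if name == "logistic_regression":
        return LogisticRegression(C=1.0, max_iter=2000)
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, max_depth=12, min_samples_split=2,
            min_samples_leaf=1, criterion="gini", random_state=random_state,
        )
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    raise ValueError(f"unknown candidate model '{name}'")


def default_search_space(name: str) -> dict:
    """Random-search ranges; they contain both the initial and the final
    reference settings (e.g. 672 estimators, depth 10, split 10, leaf 2 for
    the stage-1 random forest)."""
    if name == "random_forest":
        return {
            "n_estimators": randint(50, 801),
            "max_depth": randint(4, 17),
            "min_samples_split": randint(2, 17),
            "min_samples_leaf": randint(1, 6),
        }
    if name == "logistic_regression":
        return {"C": loguniform(1e-3, 1e3)}
    if name == "svm_rbf":
        return {"C": loguniform(1e-2, 1e2), "gamma": loguniform(1e-4, 1e1)}
    raise ValueError(f"unknown candidate model '{name}'")


def _metric_fn(metric: str):
    if metric == "f1":
        return lambda yt, yp: f1_score(yt, yp, zero_division=0)
    if metric == "accuracy":
        return accuracy_score
    raise ValueError(f"unknown metric '{metric}'")


def undersample(matrix: pd.DataFrame, labels, subjects, seed: int):
    """Randomly undersample majority (label 1) rows to a 1:1 ratio per subject.

    Stage-1 remedy: hypovolemia rows are subsampled without replacement to
    the normovolemia count within each subject; normovolemia rows are kept
    untouched. Deterministic for a given seed. Returns a boolean keep-mask
    aligned with ``matrix``.
    """
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    if not np.any(labels == 0):
        raise ValueError("undersampling requires at least one minority (0) row")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(labels), dtype=bool)
    for subject in pd.unique(subjects):
        sel = subjects == subject
        minority = np.flatnonzero(sel & (labels == 0))
        majority = np.flatnonzero(sel & (labels == 1))
        keep[minority] = True
        if len(majority) > len(minority):
            chosen = rng.choice(majority, size=len(minority), replace=False)
            keep[chosen] = True
        else:
            keep[majority] = True
    return keep


def loso_score(estimator, X, y, groups, metric: str) -> float:
    """Mean inner leave-one-subject-out score of an estimator.

    Each inner fold standard-scales on its own training rows before fitting.
    A fold whose metric is undefined (e.g. no predicted positives) scores 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    score = _metric_fn(metric)
    scores = []
    for g in pd.unique(groups):
        test = groups == g
        train = ~test
        if len(np.unique(y[train])) < 2:
            scores.append(0.0)
            continue
        pipe = make_pipeline(StandardScaler(), clone(estimator))
        pipe.fit(X[train], y[train])
        scores.append(score(y[test], pipe.predict(X[test])))
    return float(np.mean(scores))


@dataclass
class SelectionResult:
    features: list
    trace: list = field(default_factory=list)  # (feature, cumulative score)


def wrapper_select(X: pd.DataFrame, y, groups, estimator, metric: str,
                   tol: float = 0.002, max_features: int = 15,
                   candidates=None) -> SelectionResult:
    """Sequential forward selection under inner LOSO (wrapper method).

    At each step the feature whose addition maximizes the metric under inner
    leave-one-subject-out cross-validation is added; the loop stops when the
    improvement falls below ``tol`` or ``max_features`` is reached. The score
    trace is non-decreasing by construction.
    """
    if len(pd.unique(np.asarray(groups))) < 2:
        raise ValueError("wrapper selection needs >= 2 training subjects")
    candidates = list(candidates if candidates is not None else X.columns)
    selected, trace = [], []
    current = -np.inf
    while len(selected) < max_features and candidates:
        best_feat, best_score = None, -np.inf
        for feat in candidates:
            s = loso_score(estimator, X[selected + [feat]], y, groups, metric)
            if s > best_score:
                best_feat, best_score = feat, s
        if selected and best_score - current < tol:
            break
        selected.append(best_feat)
        candidates.remove(best_feat)
        trace.append((best_feat, best_score))
        current = best_score
    return SelectionResult(features=selected, trace=trace)


@dataclass
class SearchResult:
    best_params: dict
    best_score: float
    log: list = field(default_factory=list)  # (params, score)


def _tie_key(params: dict):
    # prefer fewer estimators / stronger regularization (smaller C) on ties
    return (-params.get("n_estimators", 0), -params.get("C", 0.0))


def random_search(X: pd.DataFrame, y, groups, estimator, space: dict,
                  metric: str, n_iter: int = 60, seed: int = 0
                  ) -> SearchResult:
    """Random-search hyper-parameter optimization scored by inner LOSO.

    ``n_iter`` parameter settings are drawn deterministically from ``space``
    (scipy distributions or value lists); each is scored by the mean inner
    leave-one-subject-out metric, and the arg-max is returned. Ties prefer
    fewer estimators / stronger regularization.
    """
    if not space:
        raise ValueError("empty search space")
    if not len(X.columns):
        raise ValueError("no features supplied to random search")
    sampler = ParameterSampler(space, n_iter=n_iter, random_state=seed)
    log = []
    best = None
    for params in sampler:
        est = clone(estimator).set_params(**params)
        s = loso_score(est, X, y, groups, metric)
        log.append((params, s))
        key = (s,) + _tie_key(params)
        if best is None or key > best[0]:
            best = (key, params, s)
    return SearchResult(best_params=best[1], best_score=best[2], log=log)
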