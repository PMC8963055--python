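"""Two-stage cascade classifier with temporal moving-average smoothing.

Stage 1 (default: random forest) scores each beat for hypovolemia
(NV = 0, HV = 1); stage 2 (default: L2 logistic regression) scores
hypovolemic beats for absolute vs. relative hypovolemia (RH = 0, AH = 1).
Each stage's continuous score sequence is smoothed with a causal trailing
moving average (500 beats for stage 1, 50 for stage 2) before thresholding
at 0.5:

* smoothed stage-1 score < 0.5  -> NV
* else smoothed stage-2 score < 0.5 -> RH, otherwise AH

Features are standard-scaled with statistics computed from the training
rows only. Stage 2 is trained on ground-truth hypovolemia rows, but its
score is computed and smoothed over every beat so the smoothing window has
no gaps; its value is only read where stage 1 says hypovolemia.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, META_COLUMNS
from .io import STATE_TO_CODE

#: Final (post random-search) stage-1 random-forest hyper-parameters.
STAGE1_FINAL_PARAMS = {
    "n_estimators": 672,
    "max_depth": 10,
    "min_samples_split": 10,
    "min_samples_leaf": 2,
    "criterion": "gini",
}
#: Initial stage-1 random-forest hyper-parameters (pre-search).
STAGE1_INITIAL_PARAMS = {
    "n_estimators": 100,
    "max_depth": 12,
    "min_samples_split": 2,
    "min_samples_leaf": 1,
    "criterion": "gini",
}

DEFAULT_SMOOTHING_WINDOWS = (500, 50)
DEFAULT_THRESHOLD = 0.5


def moving_average(scores, window: int) -> np.ndarray:
    """Causal trailing moving average with a shrinking warm-up window.

    ``out[i]`` is the mean of the last ``min(window, i + 1)`` values; output
    length equals input length, so isolated misclassification instances are
    removed as outliers without using future beats.
    """
    if not isinstance(window, (int, np.integer)) or window < 1:
        raise ValueError(f"window must be a positive integer, got {window!r}")
    x = np.asarray(scores, dtype=float)
    if len(x) == 0 or window == 1:
        return x.copy()
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(1, len(x) + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def fit_scaler(train) -> StandardScaler:
    """Fit a standard scaler on training rows only.

    A zero-variance feature would divide by zero; its spread is clamped to 1
    (the scaler's safe behaviour) and a warning is emitted.
    """
    X = np.asarray(train, dtype=float)
    scaler = StandardScaler().fit(X)
    if np.any(np.isclose(scaler.var_, 0.0)):
        warnings.warn("zero-variance feature(s): spread clamped to 1",
                      stacklevel=2)
    return scaler


def apply_scaler(matrix, scaler: StandardScaler) -> np.ndarray:
    return scaler.transform(np.asarray(matrix, dtype=float))


def _score_of(estimator, X) -> np.ndarray:
    """Continuous class-1 score: predicted probability, or a sigmoid-
    calibrated decision function for margin classifiers."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return expit(estimator.decision_function(X))


class CascadeClassifier(ClassifierMixin, BaseEstimator):
    """Two-stage blood-volume decompensation state classifier.

    Parameters
    ----------
    stage1, stage2 : estimator or None
        Binary classifiers for NV-vs-HV and RH-vs-AH. Defaults are the final
        reference configuration: a 672-tree random forest (max depth 10,
        min split 10, min leaf 2, Gini) and an L2 logistic regression.
    stage1_features, stage2_features : sequence of str or None
        Selected feature names per stage; ``None`` uses every feature column.
    smoothing_windows : (int, int)
        Causal moving-average windows in beats for the two stages.
    threshold : float
        Decision threshold on the smoothed scores (fixed at 0.5 by design).
    random_state : int or None
        Seed for the default stage-1 random forest.

    Attributes (after :meth:`fit`)
    ------------------------------
    scaler_ : fitted StandardScaler (training rows only)
    stage1_, stage2_ : fitted stage classifiers
    stage1_features_, stage2_features_ : resolved feature name lists
    feature_names_ : all feature columns seen at fit time
    classes_ : ``array([0, 1, 2])`` (NV, RH, AH)
    """

    def __init__(self, stage1=None, stage2=None,
                 stage1_features=None, stage2_features=None,
                 smoothing_windows=DEFAULT_SMOOTHING_WINDOWS,
                 threshold=DEFAULT_THRESHOLD, random_state=None):
        self.stage1 = stage1
        self.stage2 = stage2
        self.stage1_features = stage1_features
        self.stage2_features = stage2_features
        self.smoothing_windows = smoothing_windows
        self.threshold = threshold
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _feature_frame(self, X):
        """Feature columns (DataFrame) and optional subject grouping."""
        if isinstance(X, pd.DataFrame):
            feats = [c for c in X.columns if c not in META_COLUMNS]
            subjects = (X["subject_id"].to_numpy()
                        if "subject_id" in X.columns else None)
            return X[feats], subjects
        X = np.asarray(X, dtype=float)
        cols = [f"f{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X, columns=cols), None

    def _resolve_y(self, X, y):
        if y is not None:
            return np.asarray(y)
        if isinstance(X, pd.DataFrame) and "state" in X.columns:
            return X["state"].map(STATE_TO_CODE).to_numpy()
        raise ValueError("y is required when X carries no 'state' column")

    def _default_stage(self, which):
        if which == 1:
            return RandomForestClassifier(random_state=self.random_state,
                                          **STAGE1_FINAL_PARAMS)
        return LogisticRegression(C=1.0, max_iter=2000)

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the scaler and both stages on training rows.

        ``y`` holds 3-class codes (0 NV, 1 RH, 2 AH); it may be omitted when
        ``X`` is a feature table with a ``state`` column. Stage 1 is fitted
        on all training rows (NV=0 / HV=1); stage 2 on the ground-truth
        hypovolemia rows only (RH=0 / AH=1).
        """
        F, _ = self._feature_frame(X)
        y = self._resolve_y(X, y)
        if len(F) == 0:
            raise ValueError("empty training set")
        self.feature_names_ = list(F.columns)
        self.stage1_features_ = list(self.stage1_features or F.columns)
        self.stage2_features_ = list(self.stage2_features or F.columns)
        for f in self.stage1_features_ + self.stage2_features_:
            if f not in F.columns:
                raise ValueError(f"selected feature '{f}' not in matrix")
        self.scaler_ = fit_scaler(F.to_numpy(dtype=float))
        Z = pd.DataFrame(apply_scaler(F, self.scaler_), columns=F.columns,
                         index=F.index)
        y1 = (y > 0).astype(int)
        if len(np.unique(y1)) < 2:
            missing = "HV" if np.all(y1 == 0) else "NV"
            raise ValueError(f"stage 1 training data lacks class {missing}")
        est1 = self.stage1 if self.stage1 is not None else self._default_stage(1)
        self.stage1_ = clone(est1).fit(Z[self.stage1_features_], y1)
        hv = y > 0
        y2 = (y[hv] == 2).astype(int)
        if len(np.unique(y2)) < 2:
            missing = "AH" if np.all(y2 == 0) else "RH"
            raise ValueError(f"stage 2 training data lacks class {missing}")
        est2 = self.stage2 if self.stage2 is not None else self._default_stage(2)
        self.stage2_ = clone(est2).fit(Z.loc[hv, self.stage2_features_], y2)
        self.classes_ = np.array([0, 1, 2])
        return self

    def predict_trace(self, X) -> pd.DataFrame:
        """Per-beat raw and smoothed stage scores plus labels.

        Rows must be in temporal order within each subject (checked against
        ``beat_index`` when present); smoothing is applied per subject when a
        ``subject_id`` column is present, else over the whole sequence.
        """
        check_is_fitted(self, "stage1_")
        F, subjects = self._feature_frame(X)
        if (isinstance(X, pd.DataFrame) and "beat_index" in X.columns):
            bi = X["beat_index"].to_numpy()
            groups = subjects if subjects is not None else np.zeros(len(X))
            for g in pd.unique(groups):
                b = bi[groups == g]
                if len(b) > 1 and np.any(np.diff(b) <= 0):
                    raise ValueError(
                        "beats must be in temporal order within subject "
                        f"{g!r} (smoothing is temporal)")
        Z = pd.DataFrame(apply_scaler(F[self.feature_names_], self.scaler_),
                         columns=self.feature_names_, index=F.index)
        raw1 = _score_of(self.stage1_, Z[self.stage1_features_])
        raw2 = _score_of(self.stage2_, Z[self.stage2_features_])
        w1, w2 = self.smoothing_windows
        smooth1 = np.empty_like(raw1)
        smooth2 = np.empty_like(raw2)
        groups = subjects if subjects is not None else np.zeros(len(F))
        for g in pd.unique(groups):
            sel = groups == g
            smooth1[sel] = moving_average(raw1[sel], int(w1))
            smooth2[sel] = moving_average(raw2[sel], int(w2))
        stage1_label = (smooth1 >= self.threshold).astype(int)
        stage2_label = (smooth2 >= self.threshold).astype(int)
        final = np.where(stage1_label == 0, 0, np.where(stage2_label == 0, 1, 2))
        return pd.DataFrame({
            "raw_stage1": raw1, "smooth_stage1": smooth1,
            "stage1_label": stage1_label,
            "raw_stage2": raw2, "smooth_stage2": smooth2,
            "stage2_label": stage2_label,
            "label": final,
        })

    def predict(self, X) -> np.ndarray:
        """Final 3-class labels (0 NV, 1 RH, 2 AH) for an ordered sequence."""
        return self.predict_trace(X)["label"].to_numpy()


def train_cascade(train: pd.DataFrame, selections=None, params=None,
                  random_state=None, **kwargs) -> CascadeClassifier:
    """Thin wrapper: build and fit a :class:`CascadeClassifier`.

    ``selections`` maps stage (1, 2) to feature-name lists; ``params`` maps
    stage to hyper-parameter dicts applied to the default stage estimators.
    """
    selections = selections or {}
    params = params or {}
    stage1 = RandomForestClassifier(
        random_state=random_state, **{**STAGE1_FINAL_PARAMS, **params.get(1, {})}
    )
    stage2 = LogisticRegression(C=1.0, max_iter=2000,
                                **params.get(2, {}))
    model = CascadeClassifier(
        stage1=stage1, stage2=stage2,
        stage1_features=selections.get(1), stage2_features=selections.get(2),
        random_state=random_state, **kwargs,
    )
    return model.fit(train)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: CascadeClassifier, path):
    """Serialize a fitted cascade to a directory with a JSON manifest."""
    check_is_fitted(model, "stage1_")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path / "model.joblib")
    manifest = {
        "feature_names": model.feature_names_,
        "stage1_features": model.stage1_features_,
        "stage2_features": model.stage2_features_,
        "stage1_params": model.stage1_.get_params(),
        "stage2_params": model.stage2_.get_params(),
        "smoothing_windows": list(model.smoothing_windows),
        "threshold": model.threshold,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                   default=str))


def load_model(path) -> CascadeClassifier:
    return joblib.load(Path(path) / "model.joblib")
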