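"""Leave-one-subject-out evaluation, metrics, ablations, and importances.

For each held-out subject a cascade is developed on the remaining subjects
(optionally re-running feature selection and random search inside the fold,
so no held-out rows ever influence development) and the subject's full beat
sequence is classified in temporal order. Metrics:

* stage 1: accuracy/precision/recall/F1 with hypovolemia positive;
* stage 2: the same with absolute hypovolemia positive, scored on
  ground-truth hypovolemia beats;
* multi-class: overall accuracy, macro precision/recall/F1, and the 3x3
  confusion matrix (counts and percent of total).

Aggregation over subjects reports mean and sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)

from .cascade import CascadeClassifier
from .features import CHANNEL_MASKS, FEATURE_NAMES
from .io import STATE_TO_CODE
from . import select as sel


def binary_metrics(y_true, y_pred, positive: int = 1) -> dict:
    """Accuracy, precision, recall, F1 for one stage.

    When no positives are predicted, precision is undefined and reported as
    0 with ``flags`` noting the condition.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    flags = []
    if not np.any(y_pred == positive):
        flags.append("no_predicted_positives")
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[positive], average=None, zero_division=0)
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": float(p[0]), "recall": float(r[0]), "f1": float(f1[0]),
        "flags": flags,
    }


def multiclass_metrics(y_true, y_pred) -> dict:
    """Overall accuracy, macro one-vs-rest precision/recall/F1, confusion.

    Macro averages are unweighted means over the classes present in the
    truth; an absent class is excluded with a flag. The confusion matrix has
    truth on rows and prediction on columns, over labels (0, 1, 2).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = [0, 1, 2]
    present = [c for c in labels if np.any(y_true == c)]
    flags = [] if len(present) == 3 else [
        f"class_absent_from_truth:{sorted(set(labels) - set(present))}"]
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average=None, zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision_macro": float(np.mean(p)),
        "recall_macro": float(np.mean(r)),
        "f1_macro": float(np.mean(f1)),
        "confusion": cm,
        "confusion_percent": cm / max(cm.sum(), 1) * 100.0,
        "flags": flags,
    }


def naive_baseline_metrics(y_true_codes) -> dict:
    """Metrics of naive predictors: always-hypovolemia (stage 1) and
    always-absolute-hypovolemia (stage 2)."""
    y = np.asarray(y_true_codes)
    y1 = (y > 0).astype(int)
    hv = y > 0
    y2 = (y[hv] == 2).astype(int)
    return {
        "stage1": binary_metrics(y1, np.ones_like(y1)),
        "stage2": binary_metrics(y2, np.ones_like(y2)),
    }


@dataclass
class EvalReport:
    """Per-subject and aggregated LOSO results."""

    per_subject: pd.DataFrame
    aggregated: dict                      # metric -> (mean, sd)
    confusion: np.ndarray                 # summed 3x3 counts
    confusion_percent: np.ndarray
    importances: dict                     # stage -> DataFrame (fold x feature)
    selections: dict = field(default_factory=dict)   # subject -> per-stage features
    audit: list = field(default_factory=list)        # per-fold leakage audit
    baselines: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["LOSO evaluation (mean +/- sd over subjects)"]
        for k, (m, s) in self.aggregated.items():
            lines.append(f"  {k}: {m:.3f} +/- {s:.3f}")
        return "\n".join(lines)


@dataclass
class LosoConfig:
    """Per-fold development configuration.

    When ``select``/``search`` are enabled, wrapper feature selection and
    random-search tuning are re-run inside every fold on the training
    subjects only. Defaults keep them off and use the final reference
    hyper-parameters with all supplied features.
    """

    select: bool = False
    search: bool = False
    stage1_model: str = "random_forest"
    stage2_model: str = "logistic_regression"
    n_iter: int = 20
    tol: float = 0.002
    max_features: int = 15
    seed: int = 0


def _stage_frames(matrix, features):
    y3 = matrix["state"].map(STATE_TO_CODE).to_numpy()
    subjects = matrix["subject_id"].to_numpy()
    return matrix[list(features)], y3, subjects


def _develop_fold(train, features, config: LosoConfig, fold_seed: int):
    """Feature selection + hyper-parameter search on the training subjects."""
    X, y3, subjects = _stage_frames(train, features)
    y1 = (y3 > 0).astype(int)
    hv = y3 > 0
    selections, params = {}, {}
    audit = {"selection_subjects": set(), "search_subjects": set()}
    if config.select:
        keep = sel.undersample(X, y1, subjects, seed=fold_seed)
        est1 = sel.make_candidate(config.stage1_model, random_state=fold_seed)
        res1 = sel.wrapper_select(
            X[keep], y1[keep], subjects[keep], est1, metric="f1",
            tol=config.tol, max_features=config.max_features)
        est2 = sel.make_candidate(config.stage2_model, random_state=fold_seed)
        res2 = sel.wrapper_select(
            X[hv], (y3[hv] == 2).astype(int), subjects[hv], est2,
            metric="accuracy", tol=config.tol,
            max_features=config.max_features)
        selections = {1: res1.features, 2: res2.features}
        audit["selection_subjects"] = set(np.unique(subjects))
    if config.search:
        feats1 = selections.get(1) or list(features)
        feats2 = selections.get(2) or list(features)
        keep = sel.undersample(X, y1, subjects, seed=fold_seed)
        est1 = sel.make_candidate(config.stage1_model, random_state=fold_seed)
        sr1 = sel.random_search(
            X.loc[keep, feats1], y1[keep], subjects[keep], est1,
            sel.default_search_space(config.stage1_model), metric="f1",
            n_iter=config.n_iter, seed=fold_seed)
        est2 = sel.make_candidate(config.stage2_model, random_state=fold_seed)
        sr2 = sel.random_search(
            X.loc[hv, feats2], (y3[hv] == 2).astype(int), subjects[hv], est2,
            sel.default_search_space(config.stage2_model), metric="accuracy",
            n_iter=config.n_iter, seed=fold_seed)
        params = {1: sr1.best_params, 2: sr2.best_params}
        audit["search_subjects"] = set(np.unique(subjects))
    return selections, params, audit


def loso_evaluate(matrix: pd.DataFrame, features=None,
                  config: LosoConfig | None = None,
                  cascade_kwargs: dict | None = None) -> EvalReport:
    """Leave-one-subject-out evaluation of the cascade.

    ``matrix`` is a baseline-normalized feature table with meta columns;
    ``features`` restricts the usable feature set (ablation mask). Each fold
    trains on the other subjects only; a leakage audit records the subjects
    seen by scaler fitting, selection, and search, and asserts the held-out
    subject is never among them.
    """
    config = config or LosoConfig()
    features = list(features if features is not None
                    else [c for c in FEATURE_NAMES if c in matrix.columns])
    subjects = pd.unique(matrix["subject_id"])
    if len(subjects) < 3:
        raise ValueError("LOSO evaluation needs >= 3 subjects")
    rows, audits, selections_by_subject = [], [], {}
    confusion = np.zeros((3, 3), dtype=int)
    imp1, imp2 = [], []
    for fold, held_out in enumerate(subjects):
        train = matrix[matrix["subject_id"] != held_out]
        test = matrix[matrix["subject_id"] == held_out]
        fold_seed = int(config.seed) * 1009 + fold
        fold_sel, fold_params, audit = _develop_fold(
            train, features, config, fold_seed)
        selections_by_subject[held_out] = fold_sel
        est1 = est2 = None  # None -> final reference defaults
        if config.search or config.stage1_model != "random_forest":
            est1 = sel.make_candidate(config.stage1_model,
                                      random_state=fold_seed)
            est1.set_params(**fold_params.get(1, {}))
        if config.search or config.stage2_model != "logistic_regression":
            est2 = sel.make_candidate(config.stage2_model)
            est2.set_params(**fold_params.get(2, {}))
        model = CascadeClassifier(
            stage1=est1, stage2=est2,
            stage1_features=fold_sel.get(1, features),
            stage2_features=fold_sel.get(2, features),
            random_state=fold_seed, **(cascade_kwargs or {}),
        ).fit(train[["beat_index", "subject_id", "state"] + features])
        train_subjects = set(np.unique(train["subject_id"]))
        audit.update({
            "test_subject": held_out,
            "train_subjects": train_subjects,
            "scaler_subjects": train_subjects,
        })
        for key in ("scaler_subjects", "selection_subjects",
                    "search_subjects"):
            assert held_out not in audit[key], (
                f"leakage: held-out subject {held_out} reached {key}")
        audits.append(audit)

        trace = model.predict_trace(
            test[["beat_index", "subject_id"] + features])
        y3 = test["state"].map(STATE_TO_CODE).to_numpy()
        y1_true = (y3 > 0).astype(int)
        m1 = binary_metrics(y1_true, trace["stage1_label"].to_numpy())
        hv = y3 > 0
        m2 = binary_metrics((y3[hv] == 2).astype(int),
                            trace.loc[hv, "stage2_label"].to_numpy())
        mm = multiclass_metrics(y3, trace["label"].to_numpy())
        confusion += mm["confusion"]
        rows.append({
            "subject_id": held_out, "n_beats": len(test),
            **{f"stage1_{k}": v for k, v in m1.items() if k != "flags"},
            **{f"stage2_{k}": v for k, v in m2.items() if k != "flags"},
            "multi_accuracy": mm["accuracy"],
            "multi_precision_macro": mm["precision_macro"],
            "multi_recall_macro": mm["recall_macro"],
            "multi_f1_macro": mm["f1_macro"],
        })
        fi = feature_importance(model)
        imp1.append(fi["stage1"])
        imp2.append(fi["stage2"])
    per_subject = pd.DataFrame(rows)
    metric_cols = [c for c in per_subject.columns
                   if c not in ("subject_id", "n_beats")]
    aggregated = {
        c: (float(per_subject[c].mean()), float(per_subject[c].std(ddof=1)))
        for c in metric_cols
    }
    y_all = matrix["state"].map(STATE_TO_CODE).to_numpy()
    return EvalReport(
        per_subject=per_subject,
        aggregated=aggregated,
        confusion=confusion,
        confusion_percent=confusion / max(confusion.sum(), 1) * 100.0,
        importances={"stage1": pd.DataFrame(imp1).fillna(0.0),
                     "stage2": pd.DataFrame(imp2).fillna(0.0)},
        selections=selections_by_subject,
        audit=audits,
        baselines=naive_baseline_metrics(y_all),
    )


def feature_importance(model: CascadeClassifier) -> dict:
    """Per-stage importance tables of a fitted cascade.

    Stage 1 (random forest): mean impurity-decrease importances, summing to
    1 over the selected features. Stage 2 (logistic regression): signed
    coefficients on the standard-scaled features.
    """
    from sklearn.utils.validation import check_is_fitted

    check_is_fitted(model, "stage1_")
    out = {}
    for stage, est, feats in ((1, model.stage1_, model.stage1_features_),
                              (2, model.stage2_, model.stage2_features_)):
        if hasattr(est, "feature_importances_"):
            vals = pd.Series(est.feature_importances_, index=feats)
        elif hasattr(est, "coef_"):
            vals = pd.Series(np.ravel(est.coef_), index=feats)
        else:
            raise ValueError(f"stage {stage} estimator exposes no importances")
        out[f"stage{stage}"] = vals
    return out


@dataclass
class AblationResult:
    scores: pd.DataFrame                  # mask x (metric mean, sd)
    per_subject: pd.DataFrame             # subject x (mask, metric)
    ttests: pd.DataFrame                  # full vs mask paired t-tests
    reports: dict


def ablation_compare(matrix: pd.DataFrame, masks: dict | None = None,
                     config: LosoConfig | None = None,
                     cascade_kwargs: dict | None = None) -> AblationResult:
    """LOSO scores per feature mask, with paired t-tests against 'full'.

    Default masks: full, no_scg, no_bcg, vitals_only (HR + HRV). The t-test
    is two-sided and paired across per-subject scores; identical score
    vectors give t = 0, p = 1, and a zero-variance non-zero difference is
    flagged degenerate.
    """
    masks = masks or {k: [f for f in v if f in matrix.columns]
                      for k, v in CHANNEL_MASKS.items()}
    if any(len(v) == 0 for v in masks.values()):
        raise ValueError("empty feature mask")
    if "full" not in masks:
        raise ValueError("masks must include 'full' as the comparison base")
    reports = {name: loso_evaluate(matrix, features=feats, config=config,
                                   cascade_kwargs=cascade_kwargs)
               for name, feats in masks.items()}
    score_rows, subject_rows = [], []
    for name, rep in reports.items():
        for metric in ("multi_accuracy", "multi_f1_macro"):
            m, s = rep.aggregated[metric]
            score_rows.append({"mask": name, "metric": metric,
                               "mean": m, "sd": s})
        for _, row in rep.per_subject.iterrows():
            subject_rows.append({"mask": name, "subject_id": row["subject_id"],
                                 "multi_accuracy": row["multi_accuracy"],
                                 "multi_f1_macro": row["multi_f1_macro"]})
    per_subject = pd.DataFrame(subject_rows)
    ttest_rows = []
    full = reports["full"].per_subject.set_index("subject_id")
    for name, rep in reports.items():
        if name == "full":
            continue
        other = rep.per_subject.set_index("subject_id")
        for metric in ("multi_accuracy", "multi_f1_macro"):
            a = full[metric].to_numpy()
            b = other.loc[full.index, metric].to_numpy()
            ttest_rows.append({"mask": name, "metric": metric,
                               **paired_ttest(a, b)})
    return AblationResult(
        scores=pd.DataFrame(score_rows),
        per_subject=per_subject,
        ttests=pd.DataFrame(ttest_rows),
        reports=reports,
    )


def paired_ttest(a, b) -> dict:
    """Two-sided paired t-test with explicit degenerate handling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    if np.allclose(d, 0):
        return {"t": 0.0, "p": 1.0, "flag": "identical"}
    if np.isclose(np.std(d, ddof=1), 0):
        return {"t": np.inf if d.mean() > 0 else -np.inf, "p": 0.0,
                "flag": "degenerate_zero_variance"}
    t, p = sp_stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "flag": ""}
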