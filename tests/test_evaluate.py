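"""Metrics, LOSO structure, leakage audit, ablations, importances."""

import numpy as np
import pandas as pd
import pytest

from volstate import evaluate as ev
from volstate import (CascadeClassifier, GeneratorConfig, LosoConfig,
                      baseline_normalize, generate_feature_matrix)
from volstate.features import CHANNEL_MASKS


def brute_binary(y_true, y_pred, positive=1):
    tp = np.sum((y_true == positive) & (y_pred == positive))
    fp = np.sum((y_true != positive) & (y_pred == positive))
    fn = np.sum((y_true == positive) & (y_pred != positive))
    acc = np.mean(y_true == y_pred)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


class TestBinaryMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        m = ev.binary_metrics(y, y)
        assert (m["accuracy"], m["precision"], m["recall"], m["f1"]) == (
            1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_example(self):
        # TP=2, FP=1, FN=1, TN=6
        y_true = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
        m = ev.binary_metrics(y_true, y_pred)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_always_positive_naive_predictor(self, rng):
        y_true = (rng.random(200) < 0.8).astype(int)
        m = ev.binary_metrics(y_true, np.ones(200, dtype=int))
        assert m["recall"] == 1.0
        assert m["precision"] == pytest.approx(y_true.mean())

    def test_no_predicted_positives_flagged(self):
        m = ev.binary_metrics(np.array([1, 0]), np.array([0, 0]))
        assert m["precision"] == 0.0
        assert "no_predicted_positives" in m["flags"]

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            y_true = rng.integers(0, 2, 50)
            y_pred = rng.integers(0, 2, 50)
            m = ev.binary_metrics(y_true, y_pred)
            acc, prec, rec, f1 = brute_binary(y_true, y_pred)
            assert m["accuracy"] == pytest.approx(acc, abs=1e-12)
            assert m["precision"] == pytest.approx(prec, abs=1e-12)
            assert m["recall"] == pytest.approx(rec, abs=1e-12)
            assert m["f1"] == pytest.approx(f1, abs=1e-12)


class TestMulticlassMetrics:
    def test_identity_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        m = ev.multiclass_metrics(y, y)
        assert m["accuracy"] == 1.0 and m["f1_macro"] == 1.0
        assert np.all(m["confusion"] == np.eye(3) * 2)

    def test_cyclic_shift_is_fully_off_diagonal(self):
        y = np.array([0, 1, 2] * 10)
        pred = (y + 1) % 3
        m = ev.multiclass_metrics(y, pred)
        assert m["accuracy"] == 0.0 and m["f1_macro"] == 0.0
        assert np.trace(m["confusion"]) == 0

    def test_matches_brute_force_one_vs_rest(self, rng):
        for _ in range(100):
            y_true = rng.integers(0, 3, 60)
            y_pred = rng.integers(0, 3, 60)
            m = ev.multiclass_metrics(y_true, y_pred)
            per_class = [brute_binary((y_true == c).astype(int),
                                      (y_pred == c).astype(int))
                         for c in np.unique(y_true)]
            assert m["precision_macro"] == pytest.approx(
                np.mean([p for _, p, _, _ in per_class]), abs=1e-12)
            assert m["f1_macro"] == pytest.approx(
                np.mean([f for _, _, _, f in per_class]), abs=1e-12)

    def test_confusion_marginals(self, rng):
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        m = ev.multiclass_metrics(y_true, y_pred)
        cm = m["confusion"]
        assert cm.sum() == 200
        for c in range(3):
            assert cm[c].sum() == np.sum(y_true == c)
            assert cm[:, c].sum() == np.sum(y_pred == c)
        assert m["confusion_percent"].sum() == pytest.approx(100.0)

    def test_absent_class_flagged(self):
        m = ev.multiclass_metrics(np.array([0, 1, 0, 1]),
                                  np.array([0, 1, 2, 1]))
        assert any("class_absent" in f for f in m["flags"])


class TestPairedTtest:
    def test_identical_vectors(self):
        out = ev.paired_ttest([0.8, 0.9, 0.85], [0.8, 0.9, 0.85])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_nonzero_difference_flagged(self):
        out = ev.paired_ttest([0.8, 0.9, 0.85], [0.6, 0.7, 0.65])
        assert out["flag"] == "degenerate_zero_variance"

    def test_ordinary_case_matches_scipy(self, rng):
        from scipy import stats
        a = rng.normal(0.8, 0.05, 6)
        b = rng.normal(0.7, 0.05, 6)
        out = ev.paired_ttest(a, b)
        t, p = stats.ttest_rel(a, b)
        assert out["t"] == pytest.approx(t) and out["p"] == pytest.approx(p)


class TestLoso:
    def test_fold_structure_and_leakage_audit(self, tiny_matrix):
        norm = baseline_normalize(tiny_matrix)
        rep = ev.loso_evaluate(
            norm, config=LosoConfig(seed=1),
            cascade_kwargs={"smoothing_windows": (50, 10)})
        assert len(rep.per_subject) == 4
        for audit in rep.audit:
            assert audit["test_subject"] not in audit["train_subjects"]
            assert len(audit["train_subjects"]) == 3
        assert rep.confusion.sum() == len(norm)

    def test_selection_and_search_exclude_held_out_subject(self, tiny_matrix):
        norm = baseline_normalize(tiny_matrix)
        config = LosoConfig(select=True, search=True, n_iter=2,
                            max_features=2, stage1_model="logistic_regression",
                            seed=0)
        rep = ev.loso_evaluate(
            norm, features=["pep_ao", "ratio_ao", "hr", "a_ppg"],
            config=config, cascade_kwargs={"smoothing_windows": (50, 10)})
        for audit in rep.audit:
            assert audit["selection_subjects"], "selection ran"
            assert audit["test_subject"] not in audit["selection_subjects"]
            assert audit["test_subject"] not in audit["search_subjects"]
        for fold_sel in rep.selections.values():
            assert 1 in fold_sel and len(fold_sel[1]) >= 1

    def test_strong_separation_high_accuracy(self):
        cfg = GeneratorConfig(n_subjects=4, beats_per_state=(60, 80, 120),
                              feature_noise_frac=0.02, latency_jitter_s=0.001,
                              amp_jitter_frac=0.01)
        norm = baseline_normalize(generate_feature_matrix(cfg, seed=3))
        rep = ev.loso_evaluate(
            norm, config=LosoConfig(seed=0),
            cascade_kwargs={"smoothing_windows": (1, 1)})
        for _, row in rep.per_subject.iterrows():
            assert row["multi_accuracy"] >= 0.95

    def test_too_few_subjects_errors(self, tiny_matrix):
        two = tiny_matrix[tiny_matrix.subject_id.isin(["S0", "S1"])]
        with pytest.raises(ValueError, match="subjects"):
            ev.loso_evaluate(baseline_normalize(two))


class TestImportance:
    def test_importances(self, rng):
        n = 600
        df = pd.DataFrame({
            "beat_index": np.arange(n),
            "subject_id": "S0",
            "state": ["NV"] * 200 + ["RH"] * 200 + ["AH"] * 200,
            "informative": np.r_[np.zeros(200), np.ones(400)]
            + rng.normal(0, 0.1, n),
            "noise": rng.normal(size=n),
            "ah_marker": np.r_[np.zeros(400), np.ones(200)]
            + rng.normal(0, 0.1, n),
        })
        model = CascadeClassifier(random_state=0,
                                  smoothing_windows=(1, 1)).fit(df)
        imp = ev.feature_importance(model)
        assert imp["stage1"].sum() == pytest.approx(1.0, abs=1e-9)
        assert imp["stage1"].idxmax() == "informative"
        # LR coefficient for a feature positively associated with AH
        assert imp["stage2"]["ah_marker"] > 0

    def test_unfitted_model_errors(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            ev.feature_importance(CascadeClassifier())


class TestAblation:
    def test_masks_and_bcg_signal_placement(self, rng):
        """When only BCG features separate RH from AH, removing them hurts
        every fold."""
        frames = []
        for s in range(3):
            n = 450
            state = ["NV"] * 150 + ["RH"] * 150 + ["AH"] * 150
            code = np.r_[np.zeros(150), np.ones(150), np.full(150, 2)]
            df = pd.DataFrame({
                "beat_index": np.arange(n), "subject_id": f"S{s}",
                "state": state,
                "hr": (code > 0) + rng.normal(0, 0.1, n),      # stage-1 signal
                "amp_k": (code == 2) + rng.normal(0, 0.1, n),  # stage-2 in BCG
            })
            frames.append(df)
        mat = pd.concat(frames, ignore_index=True)
        masks = {"full": ["hr", "amp_k"], "no_bcg": ["hr"]}
        res = ev.ablation_compare(
            mat, masks=masks, config=LosoConfig(seed=0),
            cascade_kwargs={"smoothing_windows": (5, 5)})
        full = res.reports["full"].per_subject["multi_accuracy"]
        nobcg = res.reports["no_bcg"].per_subject["multi_accuracy"]
        assert (full.to_numpy() > nobcg.to_numpy()).all()
        assert {"mask", "metric", "t", "p"} <= set(res.ttests.columns)

    def test_empty_mask_errors(self, tiny_matrix):
        with pytest.raises(ValueError, match="empty"):
            ev.ablation_compare(baseline_normalize(tiny_matrix),
                                masks={"full": ["hr"], "none": []})

    def test_default_masks_cover_modalities(self):
        assert set(CHANNEL_MASKS) == {"full", "no_scg", "no_bcg",
                                      "vitals_only"}


class TestNaiveBaselines:
    def test_always_hypovolemia_and_always_ah(self):
        y = np.array([0] * 20 + [1] * 60 + [2] * 120)
        base = ev.naive_baseline_metrics(y)
        assert base["stage1"]["recall"] == 1.0
        assert base["stage1"]["precision"] == pytest.approx(180 / 200)
        assert base["stage2"]["accuracy"] == pytest.approx(120 / 180)
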