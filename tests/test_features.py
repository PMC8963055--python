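"""Feature definitions, HRV estimators, windowing, and normalization."""

import numpy as np
import pandas as pd
import pytest

from volstate import features as ft
from volstate.fiducials import BeatFiducials


class TestManifest:
    def test_partition_counts(self):
        assert len(ft.FEATURE_NAMES) == 46
        assert len(ft.RATE_FEATURES) == 4
        assert len(ft.TIMING_FEATURES) == 13
        assert len(ft.PPG_FEATURES) == 1
        assert len(ft.BCG_FEATURES) == 28
        assert len(set(ft.FEATURE_NAMES)) == 46

    def test_ik_exclusion_applies_to_variability_only(self):
        assert "int_ik" in ft.FEATURE_NAMES
        assert "w2w_ik" in ft.FEATURE_NAMES
        assert "var_int_ik" not in ft.FEATURE_NAMES
        assert "var_w2w_ik" not in ft.FEATURE_NAMES

    def test_masks_are_subsets(self):
        for name, mask in ft.CHANNEL_MASKS.items():
            assert set(mask) <= set(ft.FEATURE_NAMES), name
        assert set(ft.CHANNEL_MASKS["vitals_only"]) == set(ft.RATE_FEATURES)
        assert not set(ft.CHANNEL_MASKS["no_bcg"]) & {"pep_h", "amp_j"}
        assert not set(ft.CHANNEL_MASKS["no_scg"]) & {"pep_ao", "lvet",
                                                      "ratio_h"}


def _fiducials(r=0, ao=100, ac=700, h=160, i=300, j=460, k=560, l=660,
               trough=240, peak=600, amps=None):
    amps = amps or {"h": 1.0, "i": -2.0, "j": 3.0, "k": -1.0, "l": 0.5}
    return BeatFiducials(r=r, ao=ao, ac=ac, h=h, i=i, j=j, k=k, l=l,
                         ppg_trough=trough, ppg_peak=peak,
                         bcg_amplitudes=amps)


class TestBeatFeatures:
    FS = 2000.0

    def _segments(self, n=1600):
        ppg = np.zeros(n)
        ppg[240] = 0.2
        ppg[600] = 1.2
        return {"ppg": ppg}

    def test_timing_arithmetic(self):
        out = ft.compute_beat_features(_fiducials(), self._segments(),
                                       self.FS, rr_s=0.8)
        assert out["pep_ao"] == pytest.approx(0.05)
        assert out["lvet"] == pytest.approx(0.30)
        assert out["ratio_ao"] == pytest.approx(0.05 / 0.30)
        assert out["hr"] == pytest.approx(75.0)

    def test_ppg_amplitude_is_vertical_difference(self):
        out = ft.compute_beat_features(_fiducials(), self._segments(),
                                       self.FS, rr_s=0.8)
        assert out["a_ppg"] == pytest.approx(1.0)

    def test_bcg_wave_arithmetic(self):
        out = ft.compute_beat_features(_fiducials(), self._segments(),
                                       self.FS, rr_s=0.8)
        assert out["amp_j"] == pytest.approx(3.0)
        assert out["w2w_ij"] == pytest.approx(5.0)
        assert out["w2w_jk"] == pytest.approx(-4.0)
        assert out["int_hi"] == pytest.approx(140 / 2000)
        assert out["int_ik"] == pytest.approx(260 / 2000)

    def test_ratio_identity(self):
        out = ft.compute_beat_features(_fiducials(), self._segments(),
                                       self.FS, rr_s=0.8)
        for w in ("ao", "h", "i", "j", "k", "l"):
            assert out[f"ratio_{w}"] == out[f"pep_{w}"] / out["lvet"]

    def test_nonpositive_lvet_rejected(self):
        bad = _fiducials(ao=700, ac=700)
        assert ft.compute_beat_features(bad, self._segments(), self.FS,
                                        rr_s=0.8) is None

    def test_incomplete_fiducials_rejected(self):
        f = _fiducials()
        f.k = None
        assert ft.compute_beat_features(f, self._segments(), self.FS,
                                        rr_s=0.8) is None


class TestHrvEstimators:
    def test_constant_rr_zero_variance(self):
        rr = np.full(100, 0.8)
        assert ft.sdnn(rr) == pytest.approx(0.0, abs=1e-12)
        assert ft.poincare_sd1(rr) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_rr_sd1_closed_form(self):
        # brute-force oracle: SD1 = std(successive differences)/sqrt(2);
        # for +/-100 ms alternation this is 100/sqrt(2) ~ 70.7 ms
        rr = np.tile([0.750, 0.850], 50)
        diffs = np.diff(rr)
        oracle = np.std(diffs) / np.sqrt(2.0)
        assert oracle == pytest.approx(0.100 / np.sqrt(2.0), rel=1e-3)
        assert ft.poincare_sd1(rr) == pytest.approx(oracle, abs=1e-15)

    def test_sdnn_matches_brute_force(self, rng):
        rr = rng.normal(0.8, 0.05, 100)
        assert ft.sdnn(rr) == pytest.approx(
            np.sqrt(np.mean((rr - rr.mean()) ** 2)), abs=1e-15)

    def test_pure_hf_modulation_gives_low_lf_hf(self):
        # RR = 800 + 25 sin(2*pi*0.25*t) ms: all power in the HF band
        t = np.cumsum(np.full(100, 0.8))
        rr = 0.8 + 0.025 * np.sin(2 * np.pi * 0.25 * t)
        assert ft.lf_hf_ratio(t, rr) < 0.2

    def test_pure_lf_modulation_gives_high_lf_hf(self):
        t = np.cumsum(np.full(100, 0.8))
        rr = 0.8 + 0.025 * np.sin(2 * np.pi * 0.08 * t)
        assert ft.lf_hf_ratio(t, rr) > 5.0


class TestWindowed:
    def test_first_window_beats_undefined_and_causal(self, rng):
        n = 140
        rr = rng.normal(0.8, 0.02, n)
        t = np.cumsum(rr)
        bcg = pd.DataFrame({c: rng.normal(size=n)
                            for c in ["amp_h", "amp_i", "amp_j", "amp_k",
                                      "amp_l", "int_hi", "int_ij", "int_jk",
                                      "int_kl", "w2w_hi", "w2w_ij", "w2w_jk",
                                      "w2w_kl"]})
        full = ft.compute_windowed_features(rr, t, bcg)
        assert full.iloc[:100].isna().all().all()
        assert not full.iloc[100:].isna().any().any()
        # causality: truncating the future leaves past rows unchanged
        cut = 120
        trunc = ft.compute_windowed_features(rr[:cut], t[:cut],
                                             bcg.iloc[:cut])
        pd.testing.assert_frame_equal(full.iloc[:cut], trunc)

    def test_variability_is_window_std(self, rng):
        n = 110
        rr = np.full(n, 0.8)
        t = np.cumsum(rr)
        cols = ["amp_h", "amp_i", "amp_j", "amp_k", "amp_l", "int_hi",
                "int_ij", "int_jk", "int_kl", "w2w_hi", "w2w_ij", "w2w_jk",
                "w2w_kl"]
        bcg = pd.DataFrame({c: rng.normal(size=n) for c in cols})
        out = ft.compute_windowed_features(rr, t, bcg)
        i = 105
        for c in cols:
            assert out.loc[i, f"var_{c}"] == pytest.approx(
                np.std(bcg[c].to_numpy()[i - 100:i]), abs=1e-12)


class TestBaselineNormalize:
    def test_simple_ratio(self, tiny_matrix):
        norm = ft.baseline_normalize(tiny_matrix)
        sub = tiny_matrix[tiny_matrix.subject_id == "S0"]
        nv_mean = sub[sub.state == "NV"]["pep_ao"].mean()
        expected = sub["pep_ao"].iloc[5] / nv_mean
        got = norm[norm.subject_id == "S0"]["pep_ao"].iloc[5]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_baseline_beats_self_normalize_to_one(self, tiny_matrix):
        norm = ft.baseline_normalize(tiny_matrix)
        for _, sub in norm.groupby("subject_id"):
            nv = sub[sub.state == "NV"]
            means = nv[list(ft.FEATURE_NAMES)].mean()
            np.testing.assert_allclose(means.to_numpy(), 1.0, atol=1e-12)

    def test_scale_invariance_across_subjects(self, tiny_matrix):
        """Two subjects with identical relative trajectories but different
        baselines normalize to identical matrices."""
        a = tiny_matrix[tiny_matrix.subject_id == "S0"].reset_index(drop=True)
        b = a.copy()
        b["subject_id"] = "S1"
        b[list(ft.FEATURE_NAMES)] = b[list(ft.FEATURE_NAMES)] * 3.7
        pair = pd.concat([a, b], ignore_index=True)
        norm = ft.baseline_normalize(pair)
        na = norm[norm.subject_id == "S0"][list(ft.FEATURE_NAMES)]
        nb = norm[norm.subject_id == "S1"][list(ft.FEATURE_NAMES)]
        np.testing.assert_allclose(na.to_numpy(), nb.to_numpy(), rtol=1e-10)

    def test_missing_baseline_errors(self, tiny_matrix):
        no_nv = tiny_matrix[tiny_matrix.state != "NV"]
        with pytest.raises(ValueError, match="baseline"):
            ft.baseline_normalize(no_nv)

    def test_zero_baseline_mean_warns(self, tiny_matrix):
        mat = tiny_matrix.copy()
        mat.loc[mat.subject_id == "S0", "w2w_hi"] = np.where(
            mat.loc[mat.subject_id == "S0", "state"] == "NV", 0.0, 1.0)
        with pytest.warns(UserWarning, match="zero baseline"):
            norm = ft.baseline_normalize(mat)
        assert norm[norm.subject_id == "S0"]["w2w_hi"].isna().all()


class TestEndToEnd:
    def test_extracted_matrix_shape_and_labels(self, small_recording):
        rec, gt = small_recording
        mat = ft.extract_features(rec)
        assert list(mat.columns) == list(ft.META_COLUMNS) + list(ft.FEATURE_NAMES)
        assert mat[list(ft.FEATURE_NAMES)].notna().all().all()
        assert set(mat["state"]) <= {"NV", "RH", "AH"}
        # first 100 beats carry no windowed features and are excluded
        assert mat["beat_index"].min() >= 100
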