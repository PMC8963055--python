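"""The 46 beat-level features and their extraction pipeline.

Feature groups (46 total):

* 4 rate features: instantaneous heart rate plus heart-rate variability by a
  time-domain estimator (SDNN), the Poincaré estimator (SD1), and a
  frequency-domain estimator (LF/HF power ratio), each over the 100 causal
  beats preceding the beat of interest.
* 13 cardiac timing features: pre-ejection period from the ECG R wave to the
  SCG AO point and to each BCG wave (6), left ventricular ejection time
  (SCG AO to AC, 1), and the six PEP/LVET ratios.
* 1 PPG feature: pulse amplitude, diastolic trough to systolic peak.
* 28 BCG features: the five wave amplitudes, five wave-to-wave intervals and
  five wave-to-wave amplitudes (H-I, I-J, J-K, I-K, K-L), and the causal
  100-beat standard deviation of the amplitudes and of the wave-to-wave
  intervals/amplitudes except I-K (whose amplitude has a very large
  coefficient of variation) — 13 variability features.

Features are normalized per subject by their mean over that subject's
normovolemic (baseline) beats before any cross-subject modelling.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .fiducials import FiducialWindows, detect_beat_fiducials
from .io import Recording

_BCG_WAVES = ("h", "i", "j", "k", "l")
_BCG_PAIRS = (("h", "i"), ("i", "j"), ("j", "k"), ("i", "k"), ("k", "l"))
#: I-K is excluded from the variability features only.
_VAR_PAIRS = (("h", "i"), ("i", "j"), ("j", "k"), ("k", "l"))

RATE_FEATURES = ("hr", "hrv_t", "hrv_p", "hrv_f")
TIMING_FEATURES = (
    "pep_ao", "pep_h", "pep_i", "pep_j", "pep_k", "pep_l", "lvet",
    "ratio_ao", "ratio_h", "ratio_i", "ratio_j", "ratio_k", "ratio_l",
)
PPG_FEATURES = ("a_ppg",)
BCG_FEATURES = tuple(
    [f"amp_{w}" for w in _BCG_WAVES]
    + [f"int_{a}{b}" for a, b in _BCG_PAIRS]
    + [f"w2w_{a}{b}" for a, b in _BCG_PAIRS]
    + [f"var_amp_{w}" for w in _BCG_WAVES]
    + [f"var_int_{a}{b}" for a, b in _VAR_PAIRS]
    + [f"var_w2w_{a}{b}" for a, b in _VAR_PAIRS]
)

FEATURE_GROUPS = {
    "rate": RATE_FEATURES,
    "timing": TIMING_FEATURES,
    "ppg": PPG_FEATURES,
    "bcg": BCG_FEATURES,
}
FEATURE_NAMES = RATE_FEATURES + TIMING_FEATURES + PPG_FEATURES + BCG_FEATURES
META_COLUMNS = ("beat_index", "subject_id", "state")

#: Features requiring each signal modality, for ablation masks.
_SCG_DERIVED = ("pep_ao", "lvet", "ratio_ao", "ratio_h", "ratio_i",
                "ratio_j", "ratio_k", "ratio_l")
_BCG_DERIVED = ("pep_h", "pep_i", "pep_j", "pep_k", "pep_l") + BCG_FEATURES

CHANNEL_MASKS = {
    "full": FEATURE_NAMES,
    "no_scg": tuple(f for f in FEATURE_NAMES if f not in _SCG_DERIVED),
    "no_bcg": tuple(f for f in FEATURE_NAMES if f not in _BCG_DERIVED),
    "vitals_only": RATE_FEATURES,
}

#: Spectral bands (Hz) for the frequency-domain HRV estimator.
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
#: Causal window (beats) shared by HRV and BCG variability features.
VARIABILITY_WINDOW = 100


def manifest() -> dict:
    """Machine-readable feature manifest (names, groups, ablation masks)."""
    return {
        "n_features": len(FEATURE_NAMES),
        "features": list(FEATURE_NAMES),
        "groups": {k: list(v) for k, v in FEATURE_GROUPS.items()},
        "masks": {k: list(v) for k, v in CHANNEL_MASKS.items()},
        "meta_columns": list(META_COLUMNS),
    }


def write_manifest(path):
    with open(path, "w") as fh:
        json.dump(manifest(), fh, indent=1)


# ---------------------------------------------------------------------------
# instantaneous (per-beat) features
# ---------------------------------------------------------------------------

def compute_beat_features(fid, segments: dict, fs: float, rr_s: float) -> dict:
    """Instantaneous features of one beat from its fiducials.

    ``pep_x = (x - r)/fs``, ``lvet = (ac - ao)/fs``, ``ratio_x = pep_x/lvet``,
    ``a_ppg`` is the trough-to-peak vertical difference, BCG amplitudes are
    the filtered-signal values at each wave, and wave-to-wave intervals and
    amplitudes are pairwise differences. Beats with ``lvet <= 0`` are
    rejected (returns ``None``).
    """
    if not fid.complete:
        return None
    out = {"hr": 60.0 / rr_s}
    lvet = (fid.ac - fid.ao) / fs
    if lvet <= 0:
        return None
    out["lvet"] = lvet
    waves = {"ao": fid.ao, **{w: getattr(fid, w) for w in _BCG_WAVES}}
    for name, idx in waves.items():
        pep = (idx - fid.r) / fs
        out[f"pep_{name}"] = pep
        out[f"ratio_{name}"] = pep / lvet
    ppg = segments["ppg"]
    out["a_ppg"] = float(ppg[fid.ppg_peak - fid.r] - ppg[fid.ppg_trough - fid.r])
    amps = fid.bcg_amplitudes
    for w in _BCG_WAVES:
        out[f"amp_{w}"] = amps[w]
    for a, b in _BCG_PAIRS:
        out[f"int_{a}{b}"] = (getattr(fid, b) - getattr(fid, a)) / fs
        out[f"w2w_{a}{b}"] = amps[b] - amps[a]
    return out


# ---------------------------------------------------------------------------
# windowed (causal 100-beat) features
# ---------------------------------------------------------------------------

def sdnn(rr_s) -> float:
    """Time-domain HRV: standard deviation of the RR intervals (population)."""
    return float(np.std(np.asarray(rr_s, dtype=float)))


def poincare_sd1(rr_s) -> float:
    """Poincaré HRV: SD1 = std of successive RR differences / sqrt(2)."""
    rr = np.asarray(rr_s, dtype=float)
    if len(rr) < 2:
        return np.nan
    return float(np.std(np.diff(rr)) / np.sqrt(2.0))


def lf_hf_ratio(beat_times_s, rr_s,
                lf_band=LF_BAND, hf_band=HF_BAND, df: float = 0.005) -> float:
    """Frequency-domain HRV: LF/HF power ratio of the RR tachogram.

    The RR series is unevenly sampled (one value per beat), so band powers
    are integrated from a least-squares (Lomb-Scargle) spectrum evaluated on
    a uniform frequency grid of step ``df`` Hz.
    """
    t = np.asarray(beat_times_s, dtype=float)
    rr = np.asarray(rr_s, dtype=float)
    rr = rr - rr.mean()
    if np.allclose(rr, 0):
        return np.nan
    freqs = np.arange(lf_band[0], hf_band[1] + df / 2, df)
    pgram = lombscargle(t, rr, 2 * np.pi * freqs)
    lf_mask = (freqs >= lf_band[0]) & (freqs < lf_band[1])
    hf_mask = (freqs >= hf_band[0]) & (freqs <= hf_band[1])
    lf = np.trapezoid(pgram[lf_mask], freqs[lf_mask])
    hf = np.trapezoid(pgram[hf_mask], freqs[hf_mask])
    if hf <= 0:
        return np.nan
    return float(lf / hf)


def compute_windowed_features(rr_s, beat_times_s, bcg_values: pd.DataFrame,
                              window: int = VARIABILITY_WINDOW,
                              min_valid: int = 50) -> pd.DataFrame:
    """HRV triplet and the 13 BCG variability features, per beat.

    All features are causal: beat ``n`` uses the ``window`` beats strictly
    preceding it, so the first ``window`` beats of a subject are undefined
    (NaN) and excluded downstream. BCG variability tolerates gaps (beats with
    missing fiducials) provided at least ``min_valid`` of the window's values
    are present.
    """
    rr = np.asarray(rr_s, dtype=float)
    t = np.asarray(beat_times_s, dtype=float)
    n = len(rr)
    var_cols = [c for c in BCG_FEATURES if c.startswith("var_")]
    out = pd.DataFrame(
        np.nan, index=range(n), columns=["hrv_t", "hrv_p", "hrv_f"] + var_cols
    )
    for i in range(window, n):
        sl = slice(i - window, i)
        out.iat[i, 0] = sdnn(rr[sl])
        out.iat[i, 1] = poincare_sd1(rr[sl])
        out.iat[i, 2] = lf_hf_ratio(t[sl], rr[sl])
    for col in var_cols:
        base = col[len("var_"):]
        series = bcg_values[base].to_numpy(dtype=float)
        for i in range(window, n):
            vals = series[i - window:i]
            vals = vals[~np.isnan(vals)]
            out.loc[i, col] = np.std(vals) if len(vals) >= min_valid else np.nan
    return out


# ---------------------------------------------------------------------------
# pipeline: recording -> feature matrix
# ---------------------------------------------------------------------------

def extract_features(rec: Recording, windows: FiducialWindows | None = None,
                     variability_window: int = VARIABILITY_WINDOW,
                     rr_bounds_s=(0.25, 2.0)) -> pd.DataFrame:
    """Extract the full beat-level feature matrix from one recording.

    Runs filtering, BCG rotation, R detection, beat gating, fiducial
    detection and feature computation; returns one row per beat with
    complete features and a state label (unlabeled or incomplete beats are
    dropped, as are the first ``variability_window`` beats, whose windowed
    features are undefined).
    """
    from .preprocess import preprocess_recording

    _, _, beats = preprocess_recording(rec, rr_bounds_s=rr_bounds_s)
    fs = rec.fs
    rows, rr, times, states, indices = [], [], [], [], []
    for beat in beats:
        fid = detect_beat_fiducials(beat, fs, windows)
        inst = compute_beat_features(fid, beat.segments, fs, beat.rr_s)
        rows.append(inst)
        rr.append(beat.rr_s)
        times.append(beat.start / fs)
        states.append(beat.state)
        indices.append(beat.index)
    inst_cols = [c for c in FEATURE_NAMES
                 if not c.startswith(("hrv", "var_"))]
    inst_df = pd.DataFrame(
        [r if r is not None else {c: np.nan for c in inst_cols}
         for r in rows],
        columns=inst_cols,
    )
    bcg_values = inst_df[[f"int_{a}{b}" for a, b in _VAR_PAIRS]
                         + [f"w2w_{a}{b}" for a, b in _VAR_PAIRS]].copy()
    bcg_values.columns = ([f"int_{a}{b}" for a, b in _VAR_PAIRS]
                          + [f"w2w_{a}{b}" for a, b in _VAR_PAIRS])
    for w in _BCG_WAVES:
        bcg_values[f"amp_{w}"] = inst_df[f"amp_{w}"]
    windowed = compute_windowed_features(rr, times, bcg_values,
                                         window=variability_window)
    df = pd.concat([inst_df, windowed], axis=1)
    df["beat_index"] = indices
    df["subject_id"] = rec.subject_id
    df["state"] = states
    df = df.dropna(subset=list(FEATURE_NAMES) + ["state"])
    return df[list(META_COLUMNS) + list(FEATURE_NAMES)].reset_index(drop=True)


def baseline_normalize(matrix: pd.DataFrame, baseline_state: str = "NV"
                       ) -> pd.DataFrame:
    """Normalize every feature by its subject's mean over baseline beats.

    Each subject must have at least one baseline (normovolemia) beat with
    complete features; a feature whose baseline mean is zero for a subject
    is set to NaN for that subject with a warning (downstream consumers drop
    such rows). Normalization is strictly per subject, so no cross-subject
    information leaks.
    """
    out = matrix.copy()
    feats = [c for c in FEATURE_NAMES if c in out.columns]
    for subject, idx in out.groupby("subject_id").groups.items():
        sub = out.loc[idx]
        nv = sub[sub["state"] == baseline_state]
        if len(nv) == 0:
            raise ValueError(
                f"subject '{subject}' has no {baseline_state} baseline beats"
            )
        means = nv[feats].mean()
        zero = means.index[np.isclose(means.to_numpy(dtype=float), 0.0)]
        if len(zero):
            warnings.warn(
                f"subject '{subject}': zero baseline mean for {list(zero)}; "
                "feature(s) excluded for this subject", stacklevel=2)
            means[zero] = np.nan
        out.loc[idx, feats] = sub[feats] / means
    return out
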