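"""Synthetic multi-subject recordings and feature matrices with ground truth.

The generator emulates the study protocol: each subject passes through a
normovolemic baseline (NV), a relative hypovolemia period (RH), and an
absolute hypovolemia period (AH), with hypovolemic beats roughly ten times
more numerous than baseline beats and AH:RH near 3:1.

State-dependent structure follows the known effect directions:

* hypovolemia (RH and AH): pre-ejection period lengthens (reduced preload),
  heart rate rises, the BCG K wave and K-L amplitude shrink, the K-L
  interval lengthens, and BCG feature variability increases;
* absolute vs. relative hypovolemia: LVET shortens (reduced stroke volume),
  so PEP/LVET rises further; PPG amplitude falls with hemorrhagic
  vasoconstriction but rises under vasodilatory relative hypovolemia;
* heart-rate-variability differences across states are mild.

Two paths are provided: :func:`generate_subject` renders full waveforms
(Gaussian-lobe beat templates embedded in a gravity-tilted accelerometer
frame) with per-beat ground-truth fiducials, and
:func:`generate_feature_matrix` draws the 46 features directly from the same
per-state parameter distributions for fast classifier tests. Waveform
templates are deliberately simple morphologies, not physiological
simulators: the detectors operate on extrema, not fine morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, META_COLUMNS, _BCG_PAIRS, _BCG_WAVES
from .io import Recording

STATE_SEQUENCE = ("NV", "RH", "AH")


def _d(**kwargs):
    return field(default_factory=lambda: dict(kwargs))


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Per-state multipliers scale the NV means; all timing values are seconds.
    ``beats_per_state`` defaults give ~10:1 hypovolemia:normovolemia and
    3:1 AH:RH, matching the protocol imbalance.
    """

    n_subjects: int = 4
    beats_per_state: tuple = (280, 680, 2040)
    fs: float = 2000.0
    state_sequence: tuple = STATE_SEQUENCE

    # RR interval and its modulation
    rr_mean_s: float = 0.80
    rr_jitter_s: float = 0.012
    rr_state_scale: dict = _d(NV=1.0, RH=0.90, AH=0.85)
    rr_jitter_state_scale: dict = _d(NV=1.0, RH=1.1, AH=1.1)
    lf_amp: float = 0.012
    lf_freq_hz: float = 0.095
    hf_amp: float = 0.018
    hf_freq_hz: float = 0.25

    # systolic timing
    pep_ao_s: float = 0.060
    pep_state_scale: dict = _d(NV=1.0, RH=1.15, AH=1.30)
    lvet_s: float = 0.300
    lvet_state_scale: dict = _d(NV=1.0, RH=1.0, AH=0.85)

    # BCG morphology
    bcg_latencies_s: dict = _d(h=0.080, i=0.150, j=0.230, k=0.280, l=0.330)
    bcg_amps: dict = _d(h=0.40, i=-0.80, j=1.50, k=-1.00, l=0.60)
    #: K and L amplitudes shrink with hypovolemia (K and K-L amplitude down).
    bcg_kl_amp_state_scale: dict = _d(NV=1.0, RH=0.75, AH=0.60)
    #: L latency stretches with hypovolemia (K-L interval up).
    bcg_l_latency_state_scale: dict = _d(NV=1.0, RH=1.10, AH=1.20)
    bcg_variability_state_scale: dict = _d(NV=1.0, RH=1.3, AH=1.3)

    # PPG
    ppg_amp: float = 1.0
    ppg_state_scale: dict = _d(NV=1.0, RH=1.30, AH=0.60)
    ppg_trough_s: float = 0.120
    ppg_peak_s: float = 0.300

    # noise / nuisance structure
    subject_sd: float = 0.08          # lognormal per-subject scale spread
    latency_jitter_s: float = 0.0025  # beat-to-beat fiducial latency sd
    amp_jitter_frac: float = 0.05     # beat-to-beat amplitude sd (fraction)
    feature_noise_frac: float = 0.08  # direct-draw path relative noise
    noise_sd: dict = _d(ecg=0.01, scg_ap=0.02, acc=0.02, ppg=0.01)
    wander_amp: float = 0.05
    wander_freq_hz: float = 0.2
    gravity_tilt_deg: float = 10.0
    gravity_g: float = 9.81

    def state_counts(self) -> dict:
        return dict(zip(self.state_sequence, self.beats_per_state))


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """The no-signal null: identical per-state distributions, same labels."""
    neutral = {s: 1.0 for s in config.state_sequence}
    return replace(
        config,
        rr_state_scale=dict(neutral), rr_jitter_state_scale=dict(neutral),
        pep_state_scale=dict(neutral), lvet_state_scale=dict(neutral),
        bcg_kl_amp_state_scale=dict(neutral),
        bcg_l_latency_state_scale=dict(neutral),
        bcg_variability_state_scale=dict(neutral),
        ppg_state_scale=dict(neutral),
    )


def _rng_for(seed: int, subject_index: int, stream: int = 0):
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(subject_index), int(stream)]))


def _subject_factors(config: GeneratorConfig, rng) -> dict:
    """Per-subject constant multiplicative baseline offsets.

    Timing intervals vary less across subjects than amplitudes, so they use
    half the configured spread; this also keeps fiducials inside their
    physiologic search windows.
    """
    sd = config.subject_sd
    sds = {"rr": sd, "pep": sd / 2, "lvet": sd / 2,
           "bcg_amp": sd, "bcg_lat": sd / 2, "ppg": sd}
    return {k: float(rng.lognormal(0.0, s)) for k, s in sds.items()}


def _draw_beat_params(config: GeneratorConfig, state: str, factors: dict,
                      t: float, rng) -> dict:
    """Underlying per-beat physiological parameters for one beat."""
    c = config
    rr = (c.rr_mean_s * c.rr_state_scale[state] * factors["rr"]
          * (1.0 + c.lf_amp * np.sin(2 * np.pi * c.lf_freq_hz * t)
             + c.hf_amp * np.sin(2 * np.pi * c.hf_freq_hz * t))
          + rng.normal(0.0, c.rr_jitter_s * c.rr_jitter_state_scale[state]))
    pep = (c.pep_ao_s * c.pep_state_scale[state] * factors["pep"]
           + rng.normal(0.0, c.latency_jitter_s))
    lvet = (c.lvet_s * c.lvet_state_scale[state] * factors["lvet"]
            + rng.normal(0.0, c.latency_jitter_s))
    lats, amps = {}, {}
    for w in _BCG_WAVES:
        lat = c.bcg_latencies_s[w] * factors["bcg_lat"]
        if w == "l":
            lat *= c.bcg_l_latency_state_scale[state]
        lats[w] = lat + rng.normal(0.0, c.latency_jitter_s)
        amp = c.bcg_amps[w] * factors["bcg_amp"]
        if w in ("k", "l"):
            amp *= c.bcg_kl_amp_state_scale[state]
        amps[w] = amp * (1.0 + rng.normal(0.0, c.amp_jitter_frac)
                         * c.bcg_variability_state_scale[state])
    a_ppg = (c.ppg_amp * c.ppg_state_scale[state] * factors["ppg"]
             * (1.0 + rng.normal(0.0, c.amp_jitter_frac)))
    return {"rr": max(rr, 0.3), "pep": pep, "lvet": lvet,
            "bcg_lat": lats, "bcg_amp": amps, "a_ppg": a_ppg}


def _min_rr(config: GeneratorConfig) -> float:
    tail = max(
        config.pep_ao_s * max(config.pep_state_scale.values())
        + config.lvet_s * max(config.lvet_state_scale.values()),
        config.bcg_latencies_s["l"]
        * max(config.bcg_l_latency_state_scale.values()),
        config.ppg_peak_s,
    )
    return tail * max(1.0 + 3 * config.subject_sd, 1.0) + 0.08


def _gauss(t_axis, center, sd):
    return np.exp(-0.5 * ((t_axis - center) / sd) ** 2)


def generate_subject(config: GeneratorConfig, subject_index: int,
                     seed: int = 0):
    """Render one subject's multi-channel recording with ground truth.

    Fully deterministic for a given ``(seed, subject_index)``. Returns
    ``(Recording, GroundTruth DataFrame)``; the ground truth holds, per
    beat, the true state, fiducial sample indices and BCG amplitudes, and
    the true RR interval.
    """
    c = config
    rng = _rng_for(seed, subject_index, stream=0)
    factors = _subject_factors(c, rng)
    min_rr = _min_rr(c)
    if c.rr_mean_s * min(c.rr_state_scale.values()) < min_rr:
        raise ValueError(
            f"configured RR mean too short for beat templates "
            f"(needs >= {min_rr:.3f} s)")
    fs = c.fs
    beats = []
    t = 0.5  # lead-in so the first R wave is an interior local peak
    for state in c.state_sequence:
        for _ in range(c.state_counts()[state]):
            p = _draw_beat_params(c, state, factors, t, rng)
            p["rr"] = max(p["rr"], min_rr)
            beats.append((state, t, p))
            t += p["rr"]
    total_s = t + 1.0
    n = int(np.ceil(total_s * fs))
    t_axis = np.arange(n) / fs
    ecg = np.zeros(n)
    scg = np.zeros(n)
    bcg = np.zeros(n)
    ppg = np.zeros(n)

    def add(channel, center_s, amp, sd_s):
        lo = max(int((center_s - 5 * sd_s) * fs), 0)
        hi = min(int((center_s + 5 * sd_s) * fs) + 1, n)
        channel[lo:hi] += amp * _gauss(t_axis[lo:hi], center_s, sd_s)

    gt_rows = []
    beat_params = []
    for idx, (state, t0, p) in enumerate(beats):
        rr = p["rr"]
        add(ecg, t0, 1.0, 0.008)                     # R spike
        add(ecg, t0 + 0.25 * rr, 0.15, 0.040)        # T bump
        add(ecg, t0 + 0.80 * rr, 0.10, 0.025)        # next-beat P bump
        ao_t = t0 + p["pep"]
        ac_t = ao_t + p["lvet"]
        add(scg, ao_t, 1.0, 0.010)
        add(scg, ac_t, 0.7, 0.010)
        for w in _BCG_WAVES:
            add(bcg, t0 + p["bcg_lat"][w], p["bcg_amp"][w], 0.010)
        trough_t = t0 + c.ppg_trough_s
        peak_t = t0 + c.ppg_peak_s
        add(ppg, peak_t, p["a_ppg"], 0.060)
        add(ppg, trough_t, -0.4 * p["a_ppg"], 0.035)
        row = {
            "beat_index": idx, "state": state,
            "r_sample": int(round(t0 * fs)),
            "rr_s": rr,
            "ao_sample": int(round(ao_t * fs)),
            "ac_sample": int(round(ac_t * fs)),
        }
        for w in _BCG_WAVES:
            row[f"{w}_sample"] = int(round((t0 + p["bcg_lat"][w]) * fs))
            row[f"amp_{w}"] = p["bcg_amp"][w]
        gt_rows.append(row)
        beat_params.append((t0, rr))
    # the PPG trough/peak ground truth is read off the composed clean
    # waveform: the dip and peak lobes overlap, so the composite extremum is
    # not exactly at either lobe center
    for row, (t0, rr) in zip(gt_rows, beat_params):
        r = row["r_sample"]
        lo = r + int(0.02 * fs)
        mid = r + int((c.ppg_trough_s + c.ppg_peak_s) / 2 * fs)
        hi = min(r + int(0.45 * fs), n)
        row["ppg_trough_sample"] = lo + int(np.argmin(ppg[lo:mid]))
        row["ppg_peak_sample"] = mid + int(np.argmax(ppg[mid:hi]))
    ground_truth = pd.DataFrame(gt_rows)

    # accelerometer frame: gravity tilted from x toward z; the true SI axis
    # is z projected orthogonal to gravity.
    theta = np.deg2rad(c.gravity_tilt_deg)
    g_hat = np.array([np.cos(theta), 0.0, np.sin(theta)])
    z = np.array([0.0, 0.0, 1.0])
    v = z - np.dot(z, g_hat) * g_hat
    v_hat = v / np.linalg.norm(v)
    noise = _rng_for(seed, subject_index, stream=1)
    acc = (c.gravity_g * g_hat[None, :]
           + bcg[:, None] * v_hat[None, :]
           + noise.normal(0.0, c.noise_sd["acc"], size=(n, 3)))
    wander = c.wander_amp * np.sin(2 * np.pi * c.wander_freq_hz * t_axis)
    channels = {
        "ecg": ecg + noise.normal(0.0, c.noise_sd["ecg"], n),
        "scg_ap": scg + wander + noise.normal(0.0, c.noise_sd["scg_ap"], n),
        "acc_x": acc[:, 0], "acc_y": acc[:, 1], "acc_z": acc[:, 2],
        "ppg": ppg + wander + noise.normal(0.0, c.noise_sd["ppg"], n),
    }
    annotations = []
    start_beat = 0
    for state in c.state_sequence:
        count = c.state_counts()[state]
        if count == 0:
            continue
        s0 = gt_rows[start_beat]["r_sample"]
        last = start_beat + count - 1
        if last + 1 < len(gt_rows):
            s1 = gt_rows[last + 1]["r_sample"]
        else:
            s1 = n
        annotations.append((s0, s1, state))
        start_beat += count
    rec = Recording(subject_id=f"S{subject_index}", fs=fs, channels=channels,
                    annotations=annotations)
    return rec, ground_truth


def generate_dataset(config: GeneratorConfig, seed: int = 0):
    """All subjects' (Recording, GroundTruth) pairs."""
    return [generate_subject(config, i, seed=seed)
            for i in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# direct feature-matrix path
# ---------------------------------------------------------------------------

def generate_feature_matrix(config: GeneratorConfig, seed: int = 0
                            ) -> pd.DataFrame:
    """Draw the 46-feature beat table directly from per-state distributions.

    Per beat the underlying parameters (RR, PEP, LVET, BCG latencies and
    amplitudes, PPG amplitude) are drawn with the same state effects as the
    waveform path and the features derived from them, so internal identities
    (ratio = PEP/LVET, wave-to-wave amplitude = amplitude difference) hold
    exactly. Beats are emitted in protocol order per subject. Noise is
    ``feature_noise_frac`` relative on the windowed (HRV and variability)
    features, which are drawn rather than accumulated.
    """
    c = config
    frames = []
    for s in range(c.n_subjects):
        rng = _rng_for(seed, s, stream=2)
        factors = _subject_factors(c, rng)
        rows = []
        t = 0.0
        beat_idx = 0
        for state in c.state_sequence:
            jit = c.rr_jitter_s * c.rr_jitter_state_scale[state]
            var_scale = c.bcg_variability_state_scale[state]
            for _ in range(c.state_counts()[state]):
                p = _draw_beat_params(c, state, factors, t, rng)
                t += p["rr"]
                row = {"beat_index": beat_idx, "subject_id": f"S{s}",
                       "state": state, "hr": 60.0 / p["rr"],
                       "lvet": p["lvet"], "a_ppg": p["a_ppg"]}
                row["pep_ao"] = p["pep"]
                row["ratio_ao"] = p["pep"] / p["lvet"]
                shift = p["pep"] - c.pep_ao_s * factors["pep"]
                for w in _BCG_WAVES:
                    # BCG waves ride on ejection onset: share the PEP shift
                    pep_w = p["bcg_lat"][w] + shift
                    row[f"pep_{w}"] = pep_w
                    row[f"ratio_{w}"] = pep_w / p["lvet"]
                    row[f"amp_{w}"] = p["bcg_amp"][w]
                for a, b in _BCG_PAIRS:
                    row[f"int_{a}{b}"] = p["bcg_lat"][b] - p["bcg_lat"][a]
                    row[f"w2w_{a}{b}"] = p["bcg_amp"][b] - p["bcg_amp"][a]
                # windowed features drawn around their state-scaled means
                row["hrv_t"] = abs(jit * (1 + rng.normal(0, c.feature_noise_frac)))
                row["hrv_p"] = abs(jit * 0.8
                                   * (1 + rng.normal(0, c.feature_noise_frac)))
                row["hrv_f"] = abs(1.0 + rng.normal(0, c.feature_noise_frac))
                for col in FEATURE_NAMES:
                    if not col.startswith("var_"):
                        continue
                    base = col[len("var_"):]
                    ref = abs(row[base]) if base in row else 0.01
                    row[col] = abs(0.05 * ref * var_scale
                                   * (1 + rng.normal(0, c.feature_noise_frac)))
                rows.append(row)
                beat_idx += 1
        frames.append(pd.DataFrame(rows))
    df = pd.concat(frames, ignore_index=True)
    return df[list(META_COLUMNS) + list(FEATURE_NAMES)]
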