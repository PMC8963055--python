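"""Band-pass filtering, R-wave detection, beat gating, and BCG rotation.

Each channel is filtered with a zero-phase FIR band-pass designed with a
Kaiser window; per-channel passbands are 0.5–40 Hz (ECG), 1.0–40 Hz (SCG and
BCG), and 0.5–10 Hz (PPG). Cardiac beats are gated on the ECG R wave, with
each beat spanning ``[R_i, R_{i+1})``. The superior–inferior BCG is obtained
by rotating the raw 3-axis accelerometer frame so that the output axis is
orthogonal to the estimated gravity vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import maximum_filter1d

from .io import Recording


@dataclass(frozen=True)
class FilterSpec:
    """Kaiser-window FIR band-pass specification.

    ``attenuation_db`` is the stop-band attenuation and ``transition_hz`` the
    transition-band width; together with the passband they fix the Kaiser
    design (length and beta) via ``scipy.signal.kaiserord``.
    """

    passband: tuple
    attenuation_db: float = 60.0
    transition_hz: float = 0.5


#: Per-channel passbands.
FILTER_SPECS = {
    "ecg": FilterSpec((0.5, 40.0)),
    "scg": FilterSpec((1.0, 40.0)),
    "bcg": FilterSpec((1.0, 40.0)),
    "ppg": FilterSpec((0.5, 10.0)),
}


def design_bandpass(fs: float, spec: FilterSpec) -> np.ndarray:
    """Design the (odd-length, symmetric) Kaiser FIR band-pass taps."""
    low, high = spec.passband
    if not (0 < low < high):
        raise ValueError(f"invalid passband {spec.passband}")
    if high >= fs / 2:
        raise ValueError(
            f"upper cutoff {high} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    numtaps, beta = sp_signal.kaiserord(
        spec.attenuation_db, spec.transition_hz / (0.5 * fs)
    )
    numtaps |= 1  # odd length -> integer group delay, exact zero phase
    return sp_signal.firwin(
        numtaps, list(spec.passband), window=("kaiser", beta),
        pass_zero=False, fs=fs,
    )


def bandpass(x, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase band-pass filter a signal.

    The symmetric (linear-phase) FIR is applied once by centered FFT
    convolution on a reflect-padded signal, so the net phase shift is zero
    and feature latencies are unbiased. Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    taps = design_bandpass(fs, spec)
    if len(x) <= 3 * len(taps):
        raise ValueError(
            f"signal length {len(x)} must exceed 3x filter length {len(taps)}"
        )
    # DC lies outside every passband; removing the mean up front makes the
    # rejection exact instead of bounded by the stop-band ripple
    x = x - x.mean()
    half = len(taps) // 2
    padded = np.pad(x, half, mode="reflect")
    y = sp_signal.fftconvolve(padded, taps, mode="same")
    return y[half:half + len(x)]


@dataclass
class BeatIndex:
    """Ordered ECG R-wave sample indices; beat ``i`` spans ``[r_i, r_{i+1})``."""

    r_samples: np.ndarray

    def __post_init__(self):
        self.r_samples = np.asarray(self.r_samples, dtype=int)
        if len(self.r_samples) > 1 and np.any(np.diff(self.r_samples) <= 0):
            raise ValueError("R-wave indices must be strictly increasing")

    def __len__(self):
        return len(self.r_samples)


def detect_r_waves(ecg, fs: float, threshold_frac: float = 0.5,
                   refractory_s: float = 0.25,
                   window_s: float = 5.0) -> BeatIndex:
    """Detect ECG R waves as local peaks.

    A candidate local maximum is kept when it exceeds ``threshold_frac``
    times the rolling ``window_s``-second maximum of the filtered ECG, with a
    ``refractory_s`` minimum spacing between accepted peaks.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) == 0 or np.max(np.abs(ecg)) == 0:
        warnings.warn("no R waves found: flat or empty ECG", stacklevel=2)
        return BeatIndex(np.array([], dtype=int))
    local_max = maximum_filter1d(ecg, size=max(int(window_s * fs), 1),
                                 mode="nearest")
    peaks, _ = sp_signal.find_peaks(ecg, distance=max(int(refractory_s * fs), 1))
    peaks = peaks[ecg[peaks] >= threshold_frac * local_max[peaks]]
    if len(peaks) == 0:
        warnings.warn("no R waves found above threshold", stacklevel=2)
    return BeatIndex(peaks)


@dataclass
class Beat:
    """One gated cardiac beat.

    ``state`` is the annotation state at the R sample, or ``None`` when the
    beat is unlabeled or spans two different states. ``segments`` maps channel
    name to the samples over ``[start, end)``.
    """

    index: int
    start: int
    end: int
    rr_s: float
    state: str | None
    segments: dict


def gate_beats(channels: dict, beats: BeatIndex, fs: float,
               state_codes=None, rr_bounds_s=(0.25, 2.0)) -> list:
    """Gate filtered channels into per-beat segments ``[r_i, r_{i+1})``.

    The last R wave begins no beat. Beats with an RR interval outside
    ``rr_bounds_s`` (physiologically implausible: missed or double
    detections) are discarded. A beat whose span covers two different
    annotation states is marked unlabeled.
    """
    from .io import CODE_TO_STATE

    if len(beats) < 2:
        return []
    out = []
    r = beats.r_samples
    for i in range(len(r) - 1):
        start, end = int(r[i]), int(r[i + 1])
        rr = (end - start) / fs
        if not (rr_bounds_s[0] <= rr <= rr_bounds_s[1]):
            continue
        state = None
        if state_codes is not None:
            span = state_codes[start:end]
            code = state_codes[start]
            if code >= 0 and np.all(span == code):
                state = CODE_TO_STATE[int(code)]
        out.append(Beat(
            index=i, start=start, end=end, rr_s=rr, state=state,
            segments={name: np.asarray(x)[start:end]
                      for name, x in channels.items()},
        ))
    return out


# ---------------------------------------------------------------------------
# accelerometer rotation
# ---------------------------------------------------------------------------

def rotation_matrix_from_vectors(a, b) -> np.ndarray:
    """Minimal (Rodrigues) rotation taking unit vector ``a`` onto ``b``."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def rotate_bcg(acc_x, acc_y, acc_z, fs: float,
               nominal_si_axis=(0.0, 0.0, 1.0),
               gravity_window_s: float = 10.0):
    """Rotate the raw accelerometer frame to the superior–inferior BCG axis.

    The gravity direction is estimated as the mean of the raw 3-axis signal
    over the leading ``gravity_window_s`` seconds; the output axis is the
    nominal SI axis minimally rotated into the plane orthogonal to gravity,
    so the returned series is maximally aligned with the superior–inferior
    direction. The raw (unfiltered) signal must be supplied so the gravity
    DC component is present.

    Returns ``(bcg_si, rotation_matrix)``; band-pass the series with the BCG
    spec afterwards.
    """
    acc = np.column_stack([np.asarray(acc_x, float),
                           np.asarray(acc_y, float),
                           np.asarray(acc_z, float)])
    n_win = max(int(gravity_window_s * fs), 1)
    g = acc[:n_win].mean(axis=0)
    g_norm = np.linalg.norm(g)
    if g_norm < 1e-6:
        raise ValueError("near-zero gravity estimate; rotation undefined")
    g_hat = g / g_norm
    u = np.asarray(nominal_si_axis, float)
    u = u / np.linalg.norm(u)
    v = u - np.dot(u, g_hat) * g_hat
    v_norm = np.linalg.norm(v)
    if v_norm < 1e-9:
        raise ValueError(
            "nominal SI axis is parallel to gravity; rotation undefined"
        )
    v_hat = v / v_norm
    rot = rotation_matrix_from_vectors(u, v_hat)
    bcg_si = acc @ v_hat
    return bcg_si, rot


def preprocess_recording(rec: Recording, specs: dict | None = None,
                         detector_kwargs: dict | None = None,
                         rr_bounds_s=(0.25, 2.0)):
    """Filter all channels, derive the SI BCG, detect R waves, gate beats.

    Returns ``(filtered_channels, beat_index, beats)`` where
    ``filtered_channels`` includes the rotated-then-filtered ``bcg_si``.
    """
    specs = {**FILTER_SPECS, **(specs or {})}
    fs = rec.fs
    bcg_si, _ = rotate_bcg(rec.channels["acc_x"], rec.channels["acc_y"],
                           rec.channels["acc_z"], fs)
    filtered = {
        "ecg": bandpass(rec.channels["ecg"], fs, specs["ecg"]),
        "scg_ap": bandpass(rec.channels["scg_ap"], fs, specs["scg"]),
        "bcg_si": bandpass(bcg_si, fs, specs["bcg"]),
        "ppg": bandpass(rec.channels["ppg"], fs, specs["ppg"]),
    }
    beat_index = detect_r_waves(filtered["ecg"], fs, **(detector_kwargs or {}))
    beats = gate_beats(filtered, beat_index, fs,
                       state_codes=rec.state_codes(), rr_bounds_s=rr_bounds_s)
    return filtered, beat_index, beats
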