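"""Per-beat fiducial point detection on SCG, BCG, and PPG segments.

Fiducials, all located within a beat gated at the ECG R wave:

* SCG: AO (aortic valve opening) and AC (aortic valve closure), each the
  maximal positive peak inside a configurable post-R latency window.
* BCG: the H, I, J, K, L waves — alternating extrema (H max, I min, J max,
  K min, L max), each constrained to follow the previous wave.
* PPG: the diastolic trough (minimum preceding the steepest upstroke) and
  the systolic peak (first maximum after the trough).

A fiducial that cannot be resolved is flagged missing (``None``); beats with
missing required fiducials contribute no feature row downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal


@dataclass(frozen=True)
class FiducialWindows:
    """Post-R search windows in seconds (start, end) or max offsets.

    ``i_after_h`` etc. bound each BCG wave's search window relative to the
    previously located wave.
    """

    ao: tuple = (0.010, 0.160)
    ac: tuple = (0.200, 0.450)
    h: tuple = (0.030, 0.200)
    i_after_h: float = 0.120
    j_after_i: float = 0.120
    k_after_j: float = 0.120
    l_after_k: float = 0.150


@dataclass
class BeatFiducials:
    """Fiducial sample indices for one beat, absolute within the recording.

    Missing fiducials are ``None``; ``bcg_amplitudes`` holds the filtered
    BCG values at H..L (undefined, not zero, when a wave is missing).
    """

    r: int
    ao: int | None = None
    ac: int | None = None
    h: int | None = None
    i: int | None = None
    j: int | None = None
    k: int | None = None
    l: int | None = None
    ppg_trough: int | None = None
    ppg_peak: int | None = None
    bcg_amplitudes: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(
            getattr(self, name) is not None
            for name in ("ao", "ac", "h", "i", "j", "k", "l",
                         "ppg_trough", "ppg_peak")
        )


def _window_peak(seg, fs, start_s, end_s, mode="max"):
    """Extremum index inside ``[start_s, end_s)`` of a segment, or None."""
    lo = int(np.ceil(start_s * fs))
    hi = min(int(np.floor(end_s * fs)), len(seg))
    if hi - lo < 3:
        return None
    window = seg[lo:hi]
    if np.ptp(window) == 0:
        return None
    idx = int(np.argmax(window)) if mode == "max" else int(np.argmin(window))
    return lo + idx


def detect_scg_fiducials(scg_segment, fs, windows: FiducialWindows | None = None):
    """Locate SCG AO and AC as maximal positive peaks in their windows."""
    windows = windows or FiducialWindows()
    seg = np.asarray(scg_segment, dtype=float)
    ao = _window_peak(seg, fs, *windows.ao, mode="max")
    ac = _window_peak(seg, fs, *windows.ac, mode="max")
    if ao is not None and seg[ao] <= 0:
        ao = None
    if ac is not None and seg[ac] <= 0:
        ac = None
    if ao is not None and ac is not None and ac <= ao:
        ao = ac = None
    return ao, ac


def detect_bcg_fiducials(bcg_segment, fs, windows: FiducialWindows | None = None):
    """Locate the BCG H, I, J, K, L waves as ordered alternating extrema.

    Each wave is the extremal point of its window, constrained to follow the
    previous wave; the alternation (H > I < J > K < L in amplitude) is
    verified and the whole beat is flagged when the geometry does not
    alternate (e.g. a monotone segment).
    """
    windows = windows or FiducialWindows()
    seg = np.asarray(bcg_segment, dtype=float)
    missing = (None,) * 5

    h = _window_peak(seg, fs, *windows.h, mode="max")
    if h is None:
        return missing
    chain = [h]
    for offset, mode in ((windows.i_after_h, "min"),
                         (windows.j_after_i, "max"),
                         (windows.k_after_j, "min"),
                         (windows.l_after_k, "max")):
        prev = chain[-1]
        nxt = _window_peak(seg, fs, (prev + 1) / fs, prev / fs + offset,
                           mode=mode)
        if nxt is None:
            return missing
        chain.append(nxt)
    h, i, j, k, l = chain
    alternating = (seg[h] > seg[i] and seg[j] > seg[i]
                   and seg[j] > seg[k] and seg[l] > seg[k])
    if not alternating:
        return missing
    return h, i, j, k, l


def detect_ppg_fiducials(ppg_segment, fs):
    """Locate the PPG diastolic trough and systolic peak.

    The trough is the minimum preceding the steepest upstroke; the peak is
    the first local maximum after the trough (falling back to the overall
    maximum when no interior peak exists).
    """
    seg = np.asarray(ppg_segment, dtype=float)
    if len(seg) < 4 or np.ptp(seg) == 0:
        return None, None
    slope = np.diff(seg)
    if np.max(slope) <= 0:
        return None, None
    upstroke = int(np.argmax(slope))
    trough = int(np.argmin(seg[:upstroke + 1]))
    after = seg[upstroke:]
    peaks, _ = sp_signal.find_peaks(after)
    if len(peaks):
        peak = upstroke + int(peaks[0])
    else:
        peak = upstroke + int(np.argmax(after))
    if peak <= trough or seg[peak] <= seg[trough]:
        return None, None
    return trough, peak


def detect_beat_fiducials(beat, fs, windows: FiducialWindows | None = None
                          ) -> BeatFiducials:
    """Detect all fiducials on one gated beat (absolute sample indices)."""
    windows = windows or FiducialWindows()
    scg = beat.segments["scg_ap"]
    bcg = beat.segments["bcg_si"]
    ppg = beat.segments["ppg"]
    ao, ac = detect_scg_fiducials(scg, fs, windows)
    h, i, j, k, l = detect_bcg_fiducials(bcg, fs, windows)
    pt, pp = detect_ppg_fiducials(ppg, fs)

    def absolute(rel):
        return None if rel is None else beat.start + rel

    amps = {}
    if h is not None:
        amps = {"h": float(bcg[h]), "i": float(bcg[i]), "j": float(bcg[j]),
                "k": float(bcg[k]), "l": float(bcg[l])}
    return BeatFiducials(
        r=beat.start,
        ao=absolute(ao), ac=absolute(ac),
        h=absolute(h), i=absolute(i), j=absolute(j), k=absolute(k),
        l=absolute(l),
        ppg_trough=absolute(pt), ppg_peak=absolute(pp),
        bcg_amplitudes=amps,
    )
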