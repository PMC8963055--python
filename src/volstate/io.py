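"""Recording and feature-table I/O.

A :class:`Recording` bundles the simultaneously acquired waveform channels
(ECG lead II, anterior–posterior SCG, raw 3-axis accelerometer, PPG) with the
sampling rate, a subject identifier, and blood-volume state annotations
(NV = normovolemia, RH = relative hypovolemia, AH = absolute hypovolemia).

Two on-disk dialects are supported:

``csv``
    ``<base>.csv`` with one sample per row and a header of channel names,
    plus a ``<base>.json`` sidecar carrying ``fs``, ``subject_id`` and the
    annotation intervals.
``wfdb``
    A minimal subset of the PhysioNet waveform-database format:
    ``<base>.hea`` text header and ``<base>.dat`` (format 32, little-endian
    int32, interleaved), plus the same JSON sidecar for annotations.

All sample indices are 0-based; annotation intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STATES = ("NV", "RH", "AH")
STATE_TO_CODE = {"NV": 0, "RH": 1, "AH": 2}
CODE_TO_STATE = {v: k for k, v in STATE_TO_CODE.items()}

REQUIRED_CHANNELS = ("ecg", "scg_ap", "acc_x", "acc_y", "acc_z", "ppg")

#: Full-scale int32 head-room used by the wfdb dialect writer.
_WFDB_FULL_SCALE = 2 ** 28


class SchemaError(ValueError):
    """A table or file does not match the expected column/signal schema."""


def stage1_label(code):
    """Stage-1 encoding: NV -> 0, any hypovolemia (RH or AH) -> 1."""
    code = np.asarray(code)
    return (code > 0).astype(int)


def stage2_label(code):
    """Stage-2 encoding: RH -> 0, AH -> 1 (defined on hypovolemia rows)."""
    code = np.asarray(code)
    return (code == 2).astype(int)


@dataclass
class Recording:
    """Multi-channel physiological recording with state annotations.

    Parameters
    ----------
    subject_id : str
        Identifier used for leave-one-subject-out grouping.
    fs : float
        Sampling rate in Hz (all channels share it).
    channels : dict[str, numpy.ndarray]
        Equal-length 1-D sample arrays. The required names are
        ``ecg, scg_ap, acc_x, acc_y, acc_z, ppg``; ``bcg_si`` may be present
        after accelerometer rotation.
    annotations : list[tuple[int, int, str]]
        Half-open ``(start_sample, end_sample, state)`` intervals,
        non-overlapping, with state in ``{"NV", "RH", "AH"}``. Samples outside
        every interval are unlabeled.
    """

    subject_id: str
    fs: float
    channels: dict = field(default_factory=dict)
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        for name in REQUIRED_CHANNELS:
            if name not in self.channels:
                raise ValueError(f"missing required channel '{name}'")
        lengths = {name: len(np.asarray(x)) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel arrays have mismatched lengths: {lengths}")
        self.channels = {
            name: np.asarray(x, dtype=float) for name, x in self.channels.items()
        }
        n = self.n_samples
        prev_end = None
        for start, end, state in sorted(self.annotations, key=lambda a: a[0]):
            if state not in STATES:
                raise ValueError(f"unknown state '{state}'")
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"annotation [{start}, {end}) outside signal length {n}"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError("overlapping state annotations")
            prev_end = end

    @property
    def n_samples(self):
        return len(next(iter(self.channels.values())))

    def state_codes(self):
        """Per-sample state codes; -1 marks unlabeled samples."""
        codes = np.full(self.n_samples, -1, dtype=int)
        for start, end, state in self.annotations:
            codes[start:end] = STATE_TO_CODE[state]
        return codes


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def _sidecar(base: Path) -> Path:
    return base.with_suffix(".json")


def _write_sidecar(rec: Recording, base: Path):
    meta = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "annotations": [[int(s), int(e), st] for s, e, st in rec.annotations],
    }
    _sidecar(base).write_text(json.dumps(meta, indent=1))


def _read_sidecar(base: Path):
    path = _sidecar(base)
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {path}")
    meta = json.loads(path.read_text())
    annotations = [tuple(a) for a in meta.get("annotations", [])]
    return meta["subject_id"], float(meta["fs"]), annotations


def write_recording(rec: Recording, path, dialect: str = "csv"):
    """Write a recording under ``path`` (extension stripped) in a dialect."""
    base = Path(path).with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "csv":
        df = pd.DataFrame(rec.channels)
        df.to_csv(base.with_suffix(".csv"), index=False, float_format="%.17g")
    elif dialect == "wfdb":
        _write_wfdb_signals(rec, base)
    else:
        raise ValueError(f"unknown dialect '{dialect}'")
    _write_sidecar(rec, base)


def read_recording(path, dialect: str = "csv") -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises a load error naming the first missing required channel, a
    structural error on mismatched channel lengths, and a value error on a
    non-positive sampling rate.
    """
    base = Path(path).with_suffix("")
    subject_id, fs, annotations = _read_sidecar(base)
    if dialect == "csv":
        csv_path = base.with_suffix(".csv")
        if not csv_path.exists():
            raise FileNotFoundError(csv_path)
        df = pd.read_csv(csv_path, float_precision="round_trip")
        channels = {name: df[name].to_numpy() for name in df.columns}
    elif dialect == "wfdb":
        channels = _read_wfdb_signals(base)
    else:
        raise ValueError(f"unknown dialect '{dialect}'")
    for name in REQUIRED_CHANNELS:
        if name not in channels:
            raise ValueError(f"missing required channel '{name}' in {base}")
    return Recording(subject_id=subject_id, fs=fs, channels=channels,
                     annotations=annotations)


# -- minimal WFDB subset (format 32) ----------------------------------------

def _write_wfdb_signals(rec: Recording, base: Path):
    names = list(rec.channels)
    data = np.column_stack([rec.channels[n] for n in names])
    n_samples, n_sig = data.shape
    gains, baselines = [], []
    digital = np.empty_like(data, dtype=np.int32)
    for j in range(n_sig):
        span = np.max(np.abs(data[:, j])) if n_samples else 0.0
        gain = _WFDB_FULL_SCALE / span if span > 0 else 1.0
        digital[:, j] = np.round(data[:, j] * gain).astype(np.int64)
        gains.append(gain)
        baselines.append(0)
    record = base.name
    lines = [f"{record} {n_sig} {rec.fs:g} {n_samples}"]
    for name, gain, baseline in zip(names, gains, baselines):
        lines.append(
            f"{record}.dat 32 {gain:.12g}({baseline})/adu 32 0 0 0 0 {name}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    digital.astype("<i4").tofile(base.with_suffix(".dat"))


def _read_wfdb_signals(base: Path):
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    _, n_sig, _fs, n_samples = lines[0].split()[:4]
    n_sig, n_samples = int(n_sig), int(n_samples)
    names, gains, baselines = [], [], []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        fmt = parts[1]
        if fmt != "32":
            raise SchemaError(f"unsupported WFDB signal format '{fmt}'")
        spec = parts[2].split("/")[0]
        if "(" in spec:
            gain_s, base_s = spec.rstrip(")").split("(")
        else:
            gain_s, base_s = spec, "0"
        gains.append(float(gain_s))
        baselines.append(float(base_s))
        names.append(parts[-1])
    raw = np.fromfile(base.with_suffix(".dat"), dtype="<i4")
    raw = raw.reshape(n_samples, n_sig)
    return {
        name: (raw[:, j] - baselines[j]) / gains[j]
        for j, name in enumerate(names)
    }


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

def write_feature_table(matrix: pd.DataFrame, path):
    """Write a beat-level feature table as CSV (canonical column order)."""
    from .features import FEATURE_NAMES, META_COLUMNS

    expected = list(META_COLUMNS) + list(FEATURE_NAMES)
    unknown = [c for c in matrix.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown feature-table column(s): {unknown}")
    missing = [c for c in expected if c not in matrix.columns]
    if missing:
        raise SchemaError(f"missing feature-table column(s): {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix[expected].to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    from .features import FEATURE_NAMES, META_COLUMNS

    expected = list(META_COLUMNS) + list(FEATURE_NAMES)
    df = pd.read_csv(Path(path), float_precision="round_trip")
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown feature-table column(s): {unknown}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"missing feature-table column(s): {missing}")
    if len(df):
        df["subject_id"] = df["subject_id"].astype(str)
    else:
        df = df.astype({c: float for c in FEATURE_NAMES})
    return df[expected]
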