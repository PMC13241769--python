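"""Recording I/O and deterministic preprocessing.

Covers reading multichannel scalp EEG from EDF or plain numeric matrices,
common-average re-referencing, zero-phase FIR band-pass + notch filtering,
and selection of artifact-free analysis epochs of a target total duration.

Units: signal data are microvolts (µV) throughout; sample intervals are
0-based and half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import firwin, fftconvolve

from netsig.errors import (
    FormatError,
    InsufficientDataError,
    ParameterError,
    UnsupportedInputError,
)

#: Standard 19-channel 10-20 montage order used by the synthetic generator.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]


@dataclass
class Recording:
    """A multichannel EEG recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel names, one per row of ``data``, unique.
    meta : dict
        Free-form provenance (source file, preprocessing applied, ...).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 2:
            raise ParameterError("a Recording needs at least 2 channels")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("all samples must be finite")
        if len(self.labels) != self.data.shape[0]:
            raise ParameterError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Contiguous 0-based half-open sample intervals selected for analysis."""

    epochs: list[tuple[int, int]]
    fs: float
    warn_duration: bool = False

    def __post_init__(self):
        prev_end = -1
        for a, b in self.epochs:
            if not (0 <= a < b):
                raise ParameterError(f"invalid interval ({a}, {b})")
            if a < prev_end:
                raise ParameterError("intervals must be non-overlapping and ordered")
            prev_end = b

    @property
    def total_samples(self) -> int:
        return sum(b - a for a, b in self.epochs)

    @property
    def total_duration(self) -> float:
        return self.total_samples / self.fs


# ---------------------------------------------------------------------------
# EDF reading / minimal writing
# ---------------------------------------------------------------------------

def _read_edf_header(path: Path) -> dict:
    """Parse the fixed-size EDF header (validation only; data read via mne)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except (ValueError, UnicodeDecodeError) as exc:
            raise FormatError(f"{path}: malformed EDF header: {exc}") from exc
        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise FormatError(f"{path}: truncated EDF signal header")
        labels = [sig_head[16 * i:16 * (i + 1)].decode("ascii", "replace").strip()
                  for i in range(ns)]
        off = ns * 216  # labels+transducer+dim+phys/dig ranges+prefilter
        try:
            spr = [int(sig_head[off + 8 * i:off + 8 * (i + 1)].decode("ascii").strip())
                   for i in range(ns)]
        except ValueError as exc:
            raise FormatError(f"{path}: malformed samples-per-record field") from exc
    return {"n_records": n_records, "record_dur": record_dur,
            "ns": ns, "labels": labels, "samples_per_record": spr}


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (µV).

    Annotation channels are dropped. All retained signals must share one
    sampling rate; heterogeneous rates raise :class:`UnsupportedInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    hdr = _read_edf_header(path)
    expected = 256 * (1 + hdr["ns"]) + hdr["n_records"] * 2 * sum(hdr["samples_per_record"])
    if hdr["n_records"] >= 0 and path.stat().st_size < expected:
        raise FormatError(f"{path}: file shorter than header declares")
    signal_spr = {spr for lab, spr in zip(hdr["labels"], hdr["samples_per_record"])
                  if "annotation" not in lab.lower()}
    if len(signal_spr) > 1:
        raise UnsupportedInputError(
            f"{path}: signals have heterogeneous sampling rates {sorted(signal_spr)}")

    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad files
        raise FormatError(f"{path}: failed to parse as EDF: {exc}") from exc
    picks = [i for i, ch in enumerate(raw.ch_names) if "annotation" not in ch.lower()]
    data = raw.get_data(picks=picks) * 1e6  # mne returns volts
    labels = [raw.ch_names[i] for i in picks]
    return Recording(data=data, fs=float(raw.info["sfreq"]), labels=labels,
                     meta={"source": str(path), "format": "edf"})


def write_edf(rec: Recording, path) -> None:
    """Write a Recording as a minimal EDF file (16-bit quantization).

    Intended for fixtures and cohort export. Data are trimmed to an
    integer number of 1-second records.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ParameterError("recording shorter than one EDF record (1 s)")
    if n_records * spr != rec.n_samples:
        warnings.warn("trimming recording to a whole number of EDF records")
    data = rec.data[:, : n_records * spr]
    ns = rec.n_channels

    pmin = float(np.floor(data.min())) - 1.0
    pmax = float(np.ceil(data.max())) + 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin) / scale + dmin).astype("<i2")

    def pad(text, n):
        b = str(text).encode("ascii")[:n]
        return b + b" " * (n - len(b))

    head = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(ns), 4),
    ])
    sig = b"".join(pad(lab, 16) for lab in rec.labels)
    sig += b"".join(pad("", 80) for _ in range(ns))
    sig += b"".join(pad("uV", 8) for _ in range(ns))
    sig += b"".join(pad(f"{pmin:.1f}", 8) for _ in range(ns))
    sig += b"".join(pad(f"{pmax:.1f}", 8) for _ in range(ns))
    sig += b"".join(pad(str(dmin), 8) for _ in range(ns))
    sig += b"".join(pad(str(dmax), 8) for _ in range(ns))
    sig += b"".join(pad("", 80) for _ in range(ns))
    sig += b"".join(pad(str(spr), 8) for _ in range(ns))
    sig += b"".join(pad("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# CSV matrices and clinical tables
# ---------------------------------------------------------------------------

def read_matrix_csv(path, fs: float, labels: list[str] | None = None,
                    channels_in_columns: bool = False) -> Recording:
    """Read a rectangular numeric CSV as a Recording.

    Rows are channels unless ``channels_in_columns`` is set.
    """
    import pandas as pd

    try:
        df = pd.read_csv(path, header=None)
        mat = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a rectangular numeric table: {exc}") from exc
    if not np.all(np.isfinite(mat)):
        raise FormatError(f"{path}: non-numeric or missing cells")
    if channels_in_columns:
        mat = mat.T
    if labels is None:
        labels = [f"ch{i}" for i in range(mat.shape[0])]
    if len(labels) != mat.shape[0]:
        raise ParameterError(
            f"{len(labels)} labels for {mat.shape[0]} channels")
    return Recording(data=mat, fs=fs, labels=list(labels),
                     meta={"source": str(path), "format": "csv"})


def read_clinical_csv(path):
    """Read the per-subject clinical covariate table.

    Requires ``subject_id`` and a binary ``outcome`` column (1 = DRE-like)
    with no missing values.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "outcome" not in df.columns:
        raise FormatError(f"{path}: needs subject_id and outcome columns")
    if df["outcome"].isna().any():
        raise FormatError(f"{path}: missing outcome values")
    if not set(df["outcome"].unique()) <= {0, 1}:
        raise FormatError(f"{path}: outcome must be coded 0/1")
    return df


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def rereference_average(rec: Recording) -> Recording:
    """Re-reference to the common average: subtract the across-channel mean
    at every sample. Idempotent."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    meta = dict(rec.meta, rereference="common_average")
    return replace(rec, data=data, meta=meta)


def _design_bandpass(fs: float, band: tuple[float, float],
                     transition: float = 0.25) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ParameterError(f"band {band} outside (0, {nyq}) Hz")
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += (numtaps + 1) % 2  # odd -> type-I linear phase
    return firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")


def _design_notch(fs: float, notch: float, half_width: float = 2.0) -> np.ndarray:
    nyq = fs / 2.0
    lo, hi = notch - half_width, notch + half_width
    if not (0 < lo < hi < nyq):
        raise ParameterError(f"notch band ({lo}, {hi}) outside (0, {nyq}) Hz")
    numtaps = int(np.ceil(3.3 * fs / 1.0))
    numtaps += (numtaps + 1) % 2
    return firwin(numtaps, [lo, hi], pass_zero=True, fs=fs, window="hamming")


def filter_recording(rec: Recording, band: tuple[float, float] = (0.5, 70.0),
                     notch: float | None = 50.0) -> Recording:
    """Apply the zero-phase FIR band-pass and (optionally) notch filter.

    Windowed-sinc (Hamming) linear-phase kernels applied centred
    (forward convolution with the group delay compensated), so the
    filtered signal has no phase distortion. A pure in-band sinusoid
    passes within ~1 dB; the notch frequency is attenuated by >= 30 dB.
    """
    kernel = _design_bandpass(rec.fs, band)
    if notch is not None:
        if not (band[0] < notch < band[1]):
            raise ParameterError("notch frequency must lie inside the passband")
        kernel = fftconvolve(kernel, _design_notch(rec.fs, notch))
    data = fftconvolve(rec.data, kernel[None, :], mode="same", axes=1)
    meta = dict(rec.meta, filter={"band": band, "notch": notch,
                                  "numtaps": len(kernel)})
    return replace(rec, data=data, meta=meta)


def select_epochs(rec: Recording, keep_mask: np.ndarray | None = None,
                  intervals: list[tuple[int, int]] | None = None,
                  target: float = 180.0, tol: float = 25.0,
                  min_epoch: float = 2.0, strict: bool = False) -> EpochSet:
    """Select analysis epochs totalling ``target`` +/- ``tol`` seconds.

    With no mask/intervals the earliest contiguous samples are taken
    (deterministic default policy). A boolean ``keep_mask`` over samples
    excludes artifactual stretches; candidate epochs shorter than
    ``min_epoch`` seconds (one Welch window) are dropped. Epochs are
    accumulated in temporal order and the last is trimmed so the total
    equals ``target`` exactly when enough data exist.
    """
    n = rec.n_samples
    fs = rec.fs
    if intervals is not None and keep_mask is not None:
        raise ParameterError("pass either keep_mask or intervals, not both")
    if intervals is None:
        if keep_mask is None:
            candidates = [(0, n)]
        else:
            keep_mask = np.asarray(keep_mask, dtype=bool)
            if keep_mask.shape != (n,):
                raise ParameterError("keep_mask must have one entry per sample")
            candidates = _mask_to_intervals(keep_mask)
    else:
        for a, b in intervals:
            if not (0 <= a < b <= n):
                raise ParameterError(f"interval ({a}, {b}) outside recording")
        candidates = sorted(intervals)

    min_len = int(round(min_epoch * fs))
    candidates = [(a, b) for a, b in candidates if b - a >= min_len]

    target_n = int(round(target * fs))
    chosen: list[tuple[int, int]] = []
    acc = 0
    for a, b in candidates:
        if acc >= target_n:
            break
        take = min(b - a, target_n - acc)
        if take < min_len:
            break
        chosen.append((a, a + take))
        acc += take

    total = acc / fs
    warn = not (target - tol <= total <= target + tol)
    if warn and total < target - tol and strict:
        raise InsufficientDataError(
            f"only {total:.1f} s usable; need >= {target - tol:.1f} s")
    if warn:
        warnings.warn(f"selected {total:.1f} s outside target band "
                      f"[{target - tol:.0f}, {target + tol:.0f}] s")
    return EpochSet(epochs=chosen, fs=fs, warn_duration=warn)


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as half-open intervals."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]
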