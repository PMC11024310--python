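"""Deterministic signal conditioning: average reference, band-pass, windowing.

Operates on cleaned resting-state EEG (artifact rejection and ICA are
upstream responsibilities; the loader only validates finiteness).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

GROUPS = ("HC", "SCZ", "unknown")


@dataclass
class EEGRecord:
    """A channels x samples potential matrix (microvolts) with metadata."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains NaN or Inf")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EEGSegment(EEGRecord):
    """A non-overlapping window cut from a parent record."""

    window_index: int = 0
    window_length_s: float = 0.0
    parent_record: str = ""


def average_reference(record: EEGRecord) -> EEGRecord:
    """Re-reference every sample to the instantaneous channel mean.

    Idempotent; output channel means are < 1e-10 in magnitude at every
    sample.
    """
    if record.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = record.data - record.data.mean(axis=0, keepdims=True)
    return replace(record, data=data)


def _fir_taps(fs: float, low_hz: float, high_hz: float,
              n_samples: int) -> np.ndarray:
    # Window-method FIR; order ~ 3 x fs / low edge, capped so the
    # forward-backward pass has room to pad.
    numtaps = int(round(3.0 * fs / low_hz))
    numtaps = min(numtaps, 32769, max(3, (n_samples - 1) // 3))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs)


def bandpass(record: EEGRecord, low_hz: float = 0.1,
             high_hz: float = 40.0) -> EEGRecord:
    """Zero-phase FIR band-pass (default 0.1-40 Hz).

    Linear-phase FIR applied forward-backward (filtfilt), so the effective
    magnitude response is squared and the phase is exactly zero.
    """
    if not (0.0 < low_hz < high_hz < record.fs / 2.0):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy "
            f"0 < low < high < fs/2 = {record.fs / 2}"
        )
    taps = _fir_taps(record.fs, low_hz, high_hz, record.n_samples)
    padlen = min(record.n_samples - 1, 3 * len(taps))
    data = sps.filtfilt(taps, [1.0], record.data, axis=1, padlen=padlen)
    return replace(record, data=data)


def segment(record: EEGRecord, window_s: float,
            overlap_s: float = 0.0) -> list[EEGSegment]:
    """Cut a record into floor(T/window) non-overlapping windows.

    The trailing remainder is discarded; each segment inherits the
    record's group label and subject id.  A window longer than the record
    yields an empty list (logged), not an error.  ``overlap_s`` is exposed
    for completeness but defaults to 0 (non-overlapping), the convention
    used throughout.
    """
    win = int(round(window_s * record.fs))
    if win < 2:
        raise ValueError("window must span at least 2 samples")
    hop = win - int(round(overlap_s * record.fs))
    if hop < 1:
        raise ValueError("overlap must be smaller than the window")
    out: list[EEGSegment] = []
    start, k = 0, 0
    while start + win <= record.n_samples:
        out.append(EEGSegment(
            data=record.data[:, start:start + win].copy(),
            fs=record.fs,
            channel_names=list(record.channel_names),
            subject_id=record.subject_id,
            group=record.group,
            window_index=k,
            window_length_s=window_s,
            parent_record=record.subject_id,
        ))
        start += hop
        k += 1
    if not out:
        logger.info("window (%.3g s) longer than record (%.3g s); no segments",
                    window_s, record.duration_s)
    return out
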