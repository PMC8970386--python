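"""Band-pass filtering, epoch selection and overlapping segmentation.

The analysis pipeline filters the whole record once (0.1-70 Hz
Butterworth), selects a 150-s eyes-closed epoch and cuts it into 2-s
segments stepped by 1 s, so a 150-s epoch yields 149 segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import EpochLengthError, NyquistError
from .io_eeg import EEGRecord

#: Pipeline defaults (band edges in Hz, durations in seconds).
DEFAULT_LOW_HZ = 0.1
DEFAULT_HIGH_HZ = 70.0
DEFAULT_ORDER = 8
DEFAULT_EPOCH_S = 150.0
DEFAULT_SEGMENT_S = 2.0
DEFAULT_STEP_S = 1.0


@dataclass
class Epoch:
    """A contiguous analysis window of an :class:`EEGRecord`."""

    record: EEGRecord
    start_time: float
    duration: float


@dataclass
class SegmentSet:
    """Overlapping segments cut from an epoch.

    ``segments`` is shaped ``(count, n_channels, samples_per_segment)``.
    """

    segments: np.ndarray
    sampling_rate: float
    segment_length: float
    step: float

    @property
    def count(self) -> int:
        return self.segments.shape[0]


def butter_bandpass_sos(
    low: float, high: float, order: int, fs: float
) -> np.ndarray:
    """Design the band-pass as second-order sections.

    ``order`` follows the Butterworth prototype order, i.e. ``order=8``
    gives 8 poles per band edge (a 16th-order band-pass transfer
    function); applied forward-backward this yields the effective
    magnitude response used throughout.
    """
    if fs <= 2 * high:
        raise NyquistError(
            f"sampling rate {fs} Hz too low for a {high} Hz band edge"
        )
    return signal.butter(order, [low, high], btype="bandpass", output="sos", fs=fs)


def bandpass_filter(
    record: EEGRecord,
    low: float = DEFAULT_LOW_HZ,
    high: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_ORDER,
    zero_phase: bool = True,
) -> EEGRecord:
    """Band-pass every channel with a Butterworth filter.

    Zero-phase (forward-backward) application is the default: it removes
    the filter's group delay and preserves the cross-channel phase
    relations on which the covariance features depend.  DC is removed by
    the 0.1 Hz high-pass edge.
    """
    sos = butter_bandpass_sos(low, high, order, record.sampling_rate)
    if zero_phase:
        data = signal.sosfiltfilt(sos, record.data, axis=1)
    else:
        data = signal.sosfilt(sos, record.data, axis=1)
    rec = replace(record, data=data)
    rec.meta = dict(record.meta, filtered=(low, high, order, zero_phase))
    return rec


def extract_epoch(
    record: EEGRecord,
    duration: float = DEFAULT_EPOCH_S,
    start: float = 0.0,
) -> Epoch:
    """Slice a contiguous epoch of exactly ``duration`` seconds.

    Raises :class:`EpochLengthError` when the record cannot supply the
    window: the classifier is undefined below 150 s of artefact-free EEG.
    """
    fs = record.sampling_rate
    i0 = int(round(start * fs))
    i1 = i0 + int(round(duration * fs))
    if i1 > record.n_samples or i0 < 0:
        raise EpochLengthError(
            f"record of {record.duration:.1f} s cannot supply a "
            f"{duration:g}-s epoch starting at {start:g} s"
        )
    sliced = replace(record, data=record.data[:, i0:i1])
    return Epoch(record=sliced, start_time=start, duration=duration)


def segment_epoch(
    epoch: Epoch,
    length: float = DEFAULT_SEGMENT_S,
    step: float = DEFAULT_STEP_S,
) -> SegmentSet:
    """Cut the epoch into windows of ``length`` seconds stepped by ``step``.

    Window starts are 0, step, 2*step, ...; the count is
    ``floor((duration - length)/step) + 1`` (149 for the default 150-s
    epoch with 2-s windows stepped by 1 s).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if epoch.duration < length:
        raise ValueError("epoch shorter than one segment")
    fs = epoch.record.sampling_rate
    n_len = int(round(length * fs))
    n_step = int(round(step * fs))
    count = int(np.floor((epoch.duration - length) / step + 1e-9)) + 1
    data = epoch.record.data
    idx = np.arange(count)[:, None] * n_step + np.arange(n_len)[None, :]
    segments = data[:, idx].transpose(1, 0, 2)
    return SegmentSet(
        segments=segments,
        sampling_rate=fs,
        segment_length=length,
        step=step,
    )


def segment_count(duration: float, length: float, step: float) -> int:
    """Number of windows of ``length`` stepped by ``step`` in ``duration``."""
    if duration < length:
        return 0
    return int(np.floor((duration - length) / step + 1e-9)) + 1
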