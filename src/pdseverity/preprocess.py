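"""Filtering, per-recording normalization, and fixed-window segmentation.

Pipeline order is filter -> z-score -> segment.  Windows are 300 samples
(1.5 s at 200 Hz) with 50% overlap; the trailing partial window is
discarded so every instance has identical length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import signal as sps

from pdseverity.simulate import SignalRecording

DEFAULT_WINDOW_SAMPLES = 300
DEFAULT_OVERLAP = 0.5


@dataclass
class WindowSegment:
    """One fixed-length analysis window — the MIL instance's raw material.

    ``samples`` is (window, 6); ``start_sample`` indexes 0-based into the
    filtered recording, covering the half-open range
    [start_sample, start_sample + window).
    """

    subject_id: str
    activity_id: int
    window_index: int
    start_sample: int
    samples: np.ndarray
    sample_rate: float

    @property
    def duration(self) -> float:
        """Window length in seconds (samples / sampling frequency)."""
        return self.samples.shape[0] / self.sample_rate


def bandpass_filter(
    recording: SignalRecording,
    low: float = 0.3,
    high: float = 20.0,
    order: int = 4,
) -> SignalRecording:
    """Causal Butterworth bandpass applied per channel.

    Single-pass (not forward-backward), so the realized order is exactly
    ``order``; removes DC/gravity via the low edge.
    """
    nyquist = recording.sample_rate / 2.0
    if high >= nyquist:
        raise ValueError(
            f"high cutoff {high} Hz must be below Nyquist {nyquist} Hz"
        )
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if not np.all(np.isfinite(recording.data)):
        raise ValueError("recording contains non-finite samples")
    if recording.n_samples <= 3 * order:
        raise ValueError(
            f"recording too short ({recording.n_samples} samples) for an "
            f"order-{order} filter"
        )
    sos = sps.butter(
        order, [low, high], btype="bandpass", fs=recording.sample_rate, output="sos"
    )
    filtered = sps.sosfilt(sos, recording.data, axis=0)
    return SignalRecording(
        subject_id=recording.subject_id,
        activity_id=recording.activity_id,
        sample_rate=recording.sample_rate,
        data=filtered,
    )


def zscore_normalize(recording: SignalRecording) -> SignalRecording:
    """Per-channel, per-recording z-score.

    Zero-variance channels are mapped to all zeros with a warning rather
    than failing — degenerate synthetic inputs are legal.
    """
    data = recording.data
    mean = data.mean(axis=0)
    std = data.std(axis=0)
    out = np.zeros_like(data)
    for c in range(data.shape[1]):
        if std[c] == 0.0:
            warnings.warn(
                f"channel {c} of {recording.subject_id}/{recording.activity_id} "
                "has zero variance; normalized to zeros",
                stacklevel=2,
            )
        else:
            out[:, c] = (data[:, c] - mean[c]) / std[c]
    return SignalRecording(
        subject_id=recording.subject_id,
        activity_id=recording.activity_id,
        sample_rate=recording.sample_rate,
        data=out,
    )


def segment_windows(
    recording: SignalRecording,
    window: int = DEFAULT_WINDOW_SAMPLES,
    overlap: float = DEFAULT_OVERLAP,
) -> List[WindowSegment]:
    """Slice into fixed windows with the given fractional overlap.

    Step S = round(window * (1 - overlap)); count = floor((N - W)/S) + 1;
    the trailing partial window is discarded.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    n = recording.n_samples
    if n < window:
        raise ValueError(
            f"recording has {n} samples; at least {window} required for one window"
        )
    step = int(round(window * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large: step would be < 1 sample")
    count = (n - window) // step + 1
    return [
        WindowSegment(
            subject_id=recording.subject_id,
            activity_id=recording.activity_id,
            window_index=i,
            start_sample=i * step,
            samples=recording.data[i * step : i * step + window],
            sample_rate=recording.sample_rate,
        )
        for i in range(count)
    ]


def preprocess_recording(
    recording: SignalRecording,
    low: float = 0.3,
    high: float = 20.0,
    order: int = 4,
    window: int = DEFAULT_WINDOW_SAMPLES,
    overlap: float = DEFAULT_OVERLAP,
) -> List[WindowSegment]:
    """filter -> z-score -> segment, the canonical preprocessing chain."""
    filtered = bandpass_filter(recording, low=low, high=high, order=order)
    normalized = zscore_normalize(filtered)
    return segment_windows(normalized, window=window, overlap=overlap)
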