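"""Per-window statistical descriptors — the MIL instance feature vector.

Eight statistics per channel (std, variance, skewness, kurtosis, RMS,
energy, median, range) plus Pearson correlations within the accelerometer
and gyroscope triads: 8 x 6 + 6 = 54 values per window.  All moments use
population (n) normalization and kurtosis is Fisher excess, so a constant
channel yields exactly zero for the shape statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from pdseverity.preprocess import WindowSegment
from pdseverity.simulate import CHANNEL_NAMES

CHANNEL_STATS: Tuple[str, ...] = (
    "std",
    "var",
    "skew",
    "kurt",
    "rms",
    "energy",
    "median",
    "range",
)

TRIAD_PAIRS: Tuple[Tuple[int, int], ...] = (
    (0, 1), (0, 2), (1, 2),  # accelerometer triad
    (3, 4), (3, 5), (4, 5),  # gyroscope triad
)
ALL_PAIRS: Tuple[Tuple[int, int], ...] = tuple(
    (i, j) for i in range(6) for j in range(i + 1, 6)
)


def correlation_pairs(scope: str = "triad") -> Tuple[Tuple[int, int], ...]:
    if scope == "triad":
        return TRIAD_PAIRS
    if scope == "all_pairs":
        return ALL_PAIRS
    raise ValueError(f"correlation_scope must be 'triad' or 'all_pairs', got {scope!r}")


def feature_names(correlation_scope: str = "triad") -> Tuple[str, ...]:
    """Ordered feature names, fixed for the whole cohort."""
    names = [
        f"{ch}_{stat}" for ch in CHANNEL_NAMES for stat in CHANNEL_STATS
    ]
    names += [
        f"corr_{CHANNEL_NAMES[i]}_{CHANNEL_NAMES[j]}"
        for i, j in correlation_pairs(correlation_scope)
    ]
    return tuple(names)


@dataclass
class WindowFeature:
    """Fixed-length numeric descriptor of one window (a MIL instance)."""

    subject_id: str
    activity_id: int
    window_index: int
    vector: np.ndarray
    feature_names: Tuple[str, ...]


def _batch_matrix(stack: np.ndarray, pairs: Sequence[Tuple[int, int]]) -> np.ndarray:
    """Feature matrix for a (n_windows, window, 6) stack."""
    n_win, w, n_ch = stack.shape
    mean = stack.mean(axis=1)
    centered = stack - mean[:, None, :]
    var = (centered**2).mean(axis=1)
    std = np.sqrt(var)
    m3 = (centered**3).mean(axis=1)
    m4 = (centered**4).mean(axis=1)
    nonzero = std > 0.0
    skew = np.zeros_like(var)
    kurt = np.zeros_like(var)
    np.divide(m3, std**3, out=skew, where=nonzero)
    np.divide(m4, var**2, out=kurt, where=nonzero)
    kurt = np.where(nonzero, kurt - 3.0, 0.0)  # Fisher excess; degenerate -> 0
    sq = stack**2
    rms = np.sqrt(sq.mean(axis=1))
    energy = sq.sum(axis=1)
    median = np.median(stack, axis=1)
    rng = stack.max(axis=1) - stack.min(axis=1)

    per_channel = np.stack(
        [std, var, skew, kurt, rms, energy, median, rng], axis=2
    )  # (n_win, 6, 8)
    per_channel = per_channel.reshape(n_win, n_ch * len(CHANNEL_STATS))

    cov = np.einsum("nwi,nwj->nij", centered, centered) / w
    corrs = np.zeros((n_win, len(pairs)))
    for p, (i, j) in enumerate(pairs):
        ok = nonzero[:, i] & nonzero[:, j]
        np.divide(cov[:, i, j], std[:, i] * std[:, j], out=corrs[:, p], where=ok)
    corrs = np.clip(corrs, -1.0, 1.0)
    return np.concatenate([per_channel, corrs], axis=1)


def extract_window_features(
    segment: WindowSegment, correlation_scope: str = "triad"
) -> WindowFeature:
    """Compute the 54-value descriptor of one window.

    Zero-variance channels get skewness/kurtosis/correlations of 0 with a
    warning; everything else is well defined.
    """
    samples = np.asarray(segment.samples, dtype=float)
    if not np.all(np.isfinite(samples)):
        raise ValueError("window contains non-finite samples")
    if samples.ndim != 2 or samples.shape[1] != len(CHANNEL_NAMES):
        raise ValueError(f"expected (window, 6) samples, got {samples.shape}")
    if np.any(samples.std(axis=0) == 0.0):
        warnings.warn(
            "zero-variance channel in window; shape statistics set to 0",
            stacklevel=2,
        )
    pairs = correlation_pairs(correlation_scope)
    vector = _batch_matrix(samples[None], pairs)[0]
    return WindowFeature(
        subject_id=segment.subject_id,
        activity_id=segment.activity_id,
        window_index=segment.window_index,
        vector=vector,
        feature_names=feature_names(correlation_scope),
    )


def extract_cohort_features(
    segments: Iterable[WindowSegment], correlation_scope: str = "triad"
) -> List[WindowFeature]:
    """Vectorized feature extraction for many equal-length windows."""
    segments = list(segments)
    if not segments:
        return []
    stack = np.stack([np.asarray(s.samples, dtype=float) for s in segments])
    if not np.all(np.isfinite(stack)):
        raise ValueError("windows contain non-finite samples")
    pairs = correlation_pairs(correlation_scope)
    matrix = _batch_matrix(stack, pairs)
    names = feature_names(correlation_scope)
    return [
        WindowFeature(
            subject_id=s.subject_id,
            activity_id=s.activity_id,
            window_index=s.window_index,
            vector=matrix[i],
            feature_names=names,
        )
        for i, s in enumerate(segments)
    ]


def features_to_frame(features: Sequence[WindowFeature]) -> pd.DataFrame:
    """Feature table with identity columns plus one column per feature."""
    if not features:
        return pd.DataFrame()
    names = features[0].feature_names
    rows = np.stack([f.vector for f in features])
    frame = pd.DataFrame(rows, columns=list(names))
    frame.insert(0, "window_index", [f.window_index for f in features])
    frame.insert(0, "activity_id", [f.activity_id for f in features])
    frame.insert(0, "subject_id", [f.subject_id for f in features])
    return frame
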