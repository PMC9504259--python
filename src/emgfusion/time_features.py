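"""Overlapping segmentation and the five time-domain EMG features.

For each channel the signal is cut into ``S = ceil(N / (L - V))`` windows
of length ``L`` with nominal overlap ``V`` (buffer semantics: window ``j``
starts at ``j * (L - V)``; the trailing window is zero-padded).  Per
window five features are computed:

MAV
    mean absolute value, ``(1/L) * sum |x_k|``.
MAVS
    mean-absolute-value slope, the forward difference of consecutive
    segment MAVs (the last segment's slot is padded with 0 so the matrix
    stays rectangular).
ZC
    thresholded zero-crossing count — sign flips between consecutive
    samples whose amplitude step ``|x_k - x_{k+1}|`` is at least the
    threshold (default 0.01 V).
SSC
    thresholded slope-sign-change count — strict interior extrema with
    ``|x_k - x_{k+1}|`` at least the threshold.
WL
    waveform length, ``sum |x_k - x_{k-1}|`` (total variation).

Stacking the features of all segments of all channels channel-major gives
the ``5 x (S * m)`` sequence consumed by the recurrent stream — e.g.
5 x 72 for 8 channels of 640 samples framed at (L=85, V=12), or 5 x 18
for 2 channels of 1500 samples framed at (L=200, V=30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from emgfusion.data_model import MultichannelEmgRecord

__all__ = [
    "FramingScheme",
    "FeatureSequence",
    "FEATURE_ORDER",
    "frame_signal",
    "feat_mav",
    "feat_mavs",
    "feat_zc",
    "feat_ssc",
    "feat_wl",
    "build_feature_sequence",
]

FEATURE_ORDER = ("MAV", "MAVS", "ZC", "SSC", "WL")

DEFAULT_THRESHOLD = 0.01  # volts, for both ZC and SSC


@dataclass(frozen=True)
class FramingScheme:
    """Fixed-interval framing with overlap.

    ``window_len`` is L, ``nominal_overlap`` is V; the hop between window
    starts is ``stride = L - V`` and a signal of length N yields
    ``ceil(N / stride)`` windows.
    """

    window_len: int
    nominal_overlap: int = 0

    def __post_init__(self) -> None:
        L, V = int(self.window_len), int(self.nominal_overlap)
        if L < 1:
            raise ValueError(f"window_len must be >= 1, got {L}")
        if not 0 <= V < L:
            raise ValueError(f"need 0 <= overlap < window_len, got overlap={V}, window={L}")

    @property
    def stride(self) -> int:
        return self.window_len - self.nominal_overlap

    def frame_count(self, n_samples: int) -> int:
        """Number of windows S = ceil(N / stride)."""
        if n_samples < self.window_len:
            raise ValueError(
                f"signal length {n_samples} shorter than window {self.window_len}"
            )
        return math.ceil(n_samples / self.stride)


def frame_signal(signal: np.ndarray, scheme: FramingScheme) -> np.ndarray:
    """Cut a 1-D signal into ``S x L`` overlapping windows (buffer semantics).

    Window ``j`` (0-based) covers samples ``[j*stride, j*stride + L)``;
    positions beyond the end of the signal are zero-filled.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    S = scheme.frame_count(x.size)
    L = scheme.window_len
    out = np.zeros((S, L))
    for j in range(S):
        start = j * scheme.stride
        chunk = x[start : start + L]
        out[j, : chunk.size] = chunk
    return out


def feat_mav(window: np.ndarray) -> float:
    """Mean absolute value of a window."""
    w = np.asarray(window, dtype=float)
    if w.size < 1:
        raise ValueError("empty window")
    return float(np.mean(np.abs(w)))


def feat_mavs(mav_per_segment: np.ndarray) -> np.ndarray:
    """Forward differences of segment MAVs, zero-padded to the input length."""
    m = np.asarray(mav_per_segment, dtype=float)
    if m.size < 1:
        raise ValueError("need at least one segment MAV")
    out = np.zeros_like(m)
    out[:-1] = np.diff(m)
    return out

def feat_zc(window: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> int:
    """Thresholded zero-crossing count.

    Counts sample pairs with a strict sign flip whose amplitude step
    exceeds the threshold; a sample sitting exactly at zero never starts
    or ends a crossing.
    """
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise ValueError("ZC needs at least 2 samples")
    a, b = w[:-1], w[1:]
    flip = ((a > 0) & (b < 0)) | ((a < 0) & (b > 0))
    big = np.abs(a - b) >= threshold
    return int(np.count_nonzero(flip & big))


def feat_ssc(window: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> int:
    """Thresholded slope-sign-change count (strict interior extrema)."""
    w = np.asarray(window, dtype=float)
    if w.size < 3:
        raise ValueError("SSC needs at least 3 samples")
    prev, cur, nxt = w[:-2], w[1:-1], w[2:]
    extremum = ((cur > prev) & (cur > nxt)) | ((cur < prev) & (cur < nxt))
    big = np.abs(cur - nxt) >= threshold
    return int(np.count_nonzero(extremum & big))


def feat_wl(window: np.ndarray) -> float:
    """Waveform length: cumulative absolute first difference."""
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise ValueError("WL needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(w))))


@dataclass(frozen=True)
class FeatureSequence:
    """The ``5 x (S * m)`` feature matrix for one record.

    Rows follow :data:`FEATURE_ORDER`; columns are channel-major (all S
    segments of channel 1, then channel 2, ...).  ZC and SSC rows are
    nonnegative integers; MAV and WL rows are nonnegative reals.
    """

    values: np.ndarray
    n_segments: int
    n_channels: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(FEATURE_ORDER):
            raise ValueError(f"values must be 5 x (S*m), got shape {v.shape}")
        if v.shape[1] != self.n_segments * self.n_channels:
            raise ValueError(
                f"column count {v.shape[1]} != S*m = {self.n_segments * self.n_channels}"
            )
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_labels(self) -> list[str]:
        return [
            f"ch{c + 1}_seg{s + 1}"
            for c in range(self.n_channels)
            for s in range(self.n_segments)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(FEATURE_ORDER), columns=self.column_labels())

    def write_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "FeatureSequence":
        df = pd.read_csv(path, index_col=0)
        ch, seg = df.columns[-1].split("_")  # "ch{m}_seg{S}"
        m, s = int(ch.removeprefix("ch")), int(seg.removeprefix("seg"))
        return cls(values=df.to_numpy(dtype=float), n_segments=s, n_channels=m)


def build_feature_sequence(
    record: MultichannelEmgRecord,
    scheme: FramingScheme,
    threshold: float = DEFAULT_THRESHOLD,
) -> FeatureSequence:
    """Frame every channel and assemble the 5-feature sequence matrix.

    MAVS is differenced within each channel over that channel's own
    segment MAVs.
    """
    blocks = []
    S = scheme.frame_count(record.n_samples)
    for ch in record.signal:
        windows = frame_signal(ch, scheme)
        mav = np.array([feat_mav(w) for w in windows])
        block = np.vstack(
            [
                mav,
                feat_mavs(mav),
                np.array([feat_zc(w, threshold) for w in windows], dtype=float),
                np.array([feat_ssc(w, threshold) for w in windows], dtype=float),
                np.array([feat_wl(w) for w in windows]),
            ]
        )
        blocks.append(block)
    return FeatureSequence(
        values=np.hstack(blocks), n_segments=S, n_channels=record.n_channels
    )
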