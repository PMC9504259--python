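"""Continuous wavelet transform scalograms and CNN input images.

The CWT is computed as an FFT-domain analytic-wavelet filter bank

    W(a, b) = ifft( fft(f) * psi_hat(a * omega) ),

with ``psi_hat`` supported on positive frequencies only and peak
response normalized to 2, over a logarithmic grid of center frequencies
(``voices_per_octave`` voices) from the Nyquist frequency downward.
Three mother wavelets are available:

* ``morse``  — generalized Morse, ``psi_hat(w) = U(w) * a * w^(P2/gamma) * exp(-w^gamma)``
  with symmetry ``gamma`` and time-bandwidth product ``P2`` (default 3, 60);
* ``gabor``  — analytic Morlet-type window with equal time/frequency variance;
* ``bump``   — compactly supported bump window in frequency (wide in time,
  narrow in frequency).

The scalogram magnitude is min-max normalized per image, mapped through
a colormap to three planes and bilinearly resized (no crops, no aspect
preservation) to the CNN input size, 224 x 224 by default.  In
*concatenated* mode a single scalogram of the channel-concatenated
signal yields an ``H x W x 3`` image (Case 1); in *per-channel* mode the
per-channel images are stacked depthwise into ``H x W x 3m`` (Case 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from emgfusion.data_model import MultichannelEmgRecord, concat_channels, resample_to_length

__all__ = [
    "WaveletSpec",
    "ScalogramMatrix",
    "ScalogramImage",
    "cwt_scalogram",
    "scalogram_to_image",
    "make_stream1_input",
]

_FAMILIES = ("morse", "gabor", "bump")

MIN_SIGNAL_LEN = 16


@dataclass(frozen=True)
class WaveletSpec:
    """Analytic mother-wavelet family and its parameters.

    ``morse_gamma`` (symmetry) and ``morse_time_bandwidth`` (P^2) apply to
    the Morse family; admissibility requires ``P^2 > gamma``.
    ``gabor_center`` and ``bump_center`` / ``bump_width`` are the standard
    dimensionless window parameters (radians per sample at unit scale).
    """

    family: str = "morse"
    morse_gamma: float = 3.0
    morse_time_bandwidth: float = 60.0
    voices_per_octave: int = 10
    gabor_center: float = 6.0
    bump_center: float = 5.0
    bump_width: float = 0.6

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown wavelet family {self.family!r}; choose from {_FAMILIES}")
        if not self.morse_gamma > 0:
            raise ValueError("morse_gamma must be > 0")
        if not self.morse_time_bandwidth > self.morse_gamma:
            raise ValueError("morse time-bandwidth product must exceed gamma")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")

    @property
    def peak_omega(self) -> float:
        """Peak angular frequency of the mother wavelet (rad/sample at scale 1)."""
        if self.family == "morse":
            beta = self.morse_time_bandwidth / self.morse_gamma
            return (beta / self.morse_gamma) ** (1.0 / self.morse_gamma)
        if self.family == "gabor":
            return self.gabor_center
        return self.bump_center

    def freq_response(self, omega: np.ndarray) -> np.ndarray:
        """Evaluate ``psi_hat`` on angular frequencies, peak normalized to 2."""
        w = np.asarray(omega, dtype=float)
        out = np.zeros_like(w)
        pos = w > 0
        if self.family == "morse":
            gamma = self.morse_gamma
            beta = self.morse_time_bandwidth / gamma
            wp = self.peak_omega
            lw = np.log(w[pos])
            out[pos] = 2.0 * np.exp(
                beta * (lw - math.log(wp)) - (w[pos] ** gamma - wp**gamma)
            )
        elif self.family == "gabor":
            out[pos] = 2.0 * np.exp(-0.5 * (w[pos] - self.gabor_center) ** 2)
        else:  # bump
            u = (w - self.bump_center) / self.bump_width
            inside = pos & (np.abs(u) < 1)
            out[inside] = 2.0 * np.exp(1.0 - 1.0 / (1.0 - u[inside] ** 2))
        return out


@dataclass(frozen=True)
class ScalogramMatrix:
    """CWT magnitude over a scales x time grid.

    ``freq_axis`` gives the center frequency (Hz) of each row, strictly
    descending (high frequencies on top); ``time_axis`` is in seconds.
    """

    magnitude: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=float)
        fa = np.asarray(self.freq_axis, dtype=float)
        ta = np.asarray(self.time_axis, dtype=float)
        if mag.ndim != 2 or mag.shape != (fa.size, ta.size):
            raise ValueError("magnitude shape must be (len(freq_axis), len(time_axis))")
        if np.any(mag < 0):
            raise ValueError("magnitude must be nonnegative")
        if not np.all(np.diff(fa) < 0):
            raise ValueError("freq_axis must be strictly decreasing")
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "freq_axis", fa)
        object.__setattr__(self, "time_axis", ta)

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


@dataclass(frozen=True)
class ScalogramImage:
    """Fixed-size image for the CNN stream: ``H x W x planes`` in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 3 or p.shape[2] % 3 != 0:
            raise ValueError(f"pixels must be H x W x 3k, got shape {p.shape}")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


def _frequency_grid(n_samples: int, rate: float, voices: int) -> np.ndarray:
    """Descending log-spaced center frequencies from Nyquist, one voice apart."""
    n_octaves = max(1, int(math.floor(math.log2(n_samples))) - 3)
    k = np.arange(n_octaves * voices + 1)
    return (rate / 2.0) * 2.0 ** (-k / voices)


def cwt_scalogram(
    signal: np.ndarray, rate: float, spec: WaveletSpec = WaveletSpec()
) -> ScalogramMatrix:
    """Magnitude CWT of a 1-D signal with an analytic wavelet filter bank.

    Rows are ordered high to low frequency.  The number of octaves grows
    with the signal length; signals shorter than 16 samples are rejected
    as too short to span one octave cleanly.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < MIN_SIGNAL_LEN:
        raise ValueError(f"signal too short for CWT: {x.size} < {MIN_SIGNAL_LEN}")
    if not rate > 0:
        raise ValueError("sampling rate must be > 0")
    n = x.size
    freqs = _frequency_grid(n, rate, spec.voices_per_octave)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample, negative half included
    X = np.fft.fft(x)
    wp = spec.peak_omega
    scales = wp / (2.0 * np.pi * freqs / rate)  # samples
    mag = np.empty((freqs.size, n))
    for i, s in enumerate(scales):
        psi = spec.freq_response(s * omega)
        mag[i] = np.abs(np.fft.ifft(X * psi))
    return ScalogramMatrix(
        magnitude=mag, freq_axis=freqs, time_axis=np.arange(n) / rate
    )


def scalogram_to_image(
    scalogram: ScalogramMatrix,
    size: tuple[int, int] = (224, 224),
    colormap: str = "viridis",
) -> ScalogramImage:
    """Render a scalogram to a fixed-size 3-plane image.

    The magnitude is min-max normalized per image to [0, 1] (a constant
    magnitude maps to all-zeros), pushed through the named colormap, and
    bilinearly resized to ``size`` without crops.
    """
    mag = scalogram.magnitude
    if mag.shape[0] < 2 or mag.shape[1] < 2:
        raise ValueError("scalogram must have at least 2 rows and 2 columns")
    lo, hi = float(mag.min()), float(mag.max())
    norm = (mag - lo) / (hi - lo) if hi > lo else np.zeros_like(mag)
    rgb = np.asarray(colormaps[colormap](norm))[..., :3]
    out = _sk_resize(rgb, size, order=1, anti_aliasing=False, preserve_range=True)
    return ScalogramImage(pixels=np.clip(out, 0.0, 1.0))


def make_stream1_input(
    record: MultichannelEmgRecord,
    mode: str = "concatenated",
    spec: WaveletSpec = WaveletSpec(),
    size: tuple[int, int] = (224, 224),
    target_len: int | None = None,
    colormap: str = "viridis",
) -> ScalogramImage:
    """Build the CNN-stream input image for one record.

    ``concatenated`` (Case 1): each channel is optionally length-normalized,
    channels are concatenated into one long vector, and a single CWT yields
    an ``H x W x 3`` image.  ``per_channel`` (Case 2): one CWT per channel,
    each rendered separately and stacked depthwise into ``H x W x 3m``.
    """
    if mode not in ("concatenated", "per_channel"):
        raise ValueError(f"unknown mode {mode!r}")
    channels = record.signal
    if target_len is not None:
        channels = np.vstack([resample_to_length(ch, target_len) for ch in channels])
    if mode == "concatenated":
        sig = channels.reshape(-1)
        return scalogram_to_image(cwt_scalogram(sig, record.sampling_rate, spec), size, colormap)
    planes = [
        scalogram_to_image(cwt_scalogram(ch, record.sampling_rate, spec), size, colormap).pixels
        for ch in channels
    ]
    return ScalogramImage(pixels=np.concatenate(planes, axis=2))
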