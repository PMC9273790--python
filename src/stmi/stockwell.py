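"""Discrete Stockwell (S-) transform and time-frequency map preparation.

The S-transform decomposes a signal with a frequency-scaled Gaussian
window: wide at low frequencies (good frequency resolution), narrow at
high frequencies (good time resolution).  For a length-N sampled signal
x(nT) with DFT

    X[k/(NT)] = (1/N) sum_n x(nT) exp(-2j pi k n / N),

the discrete transform at time index m and voice n >= 1 is

    S[m, n/(NT)] = sum_k X[(k+n)/(NT)] G(n, k) exp(-2j pi k m / N),
    G(n, k) = exp(-2 pi^2 k^2 / n^2),

with the k+n index taken modulo N.  Each voice is therefore one FFT of
the Gaussian-windowed, circularly shifted spectrum, giving an
O(N^2 log N) transform overall.  The Gaussian is undefined at the zero
voice; the standard convention S[m, 0] = mean(x) is adopted (the row is
discarded by the 7-30 Hz crop anyway).

Downstream, the magnitude maps of channels C3 and C4 are cropped to the
mu/beta range, stacked vertically into one image and resized to the CNN
input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage.transform import resize as _sk_resize

from .errors import DataError, ParameterError

__all__ = [
    "ComplexTFM",
    "TFM",
    "StackedTFM",
    "discrete_stockwell",
    "tfm_magnitude",
    "band_crop",
    "bandpass",
    "stack_and_resize",
]


@dataclass
class ComplexTFM:
    """Complex voices x times S-transform matrix with coordinate vectors."""

    values: np.ndarray  # (voices, times) complex, values[n, m] = S[m, n/(NT)]
    freqs_hz: np.ndarray
    times_s: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.freqs_hz), len(self.times_s)):
            raise DataError("values shape must match coordinate vectors")
        if np.any(np.diff(self.freqs_hz) <= 0) or self.freqs_hz[0] < 0:
            raise DataError("freqs_hz must be non-negative and strictly increasing")


@dataclass
class TFM:
    """Non-negative magnitude time-frequency map."""

    values: np.ndarray  # (voices, times) real, >= 0
    freqs_hz: np.ndarray
    times_s: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.freqs_hz), len(self.times_s)):
            raise DataError("values shape must match coordinate vectors")


@dataclass
class StackedTFM:
    """Single square image: C3 magnitude map stacked above C4, resized."""

    image: np.ndarray  # (out, out), min-max normalized to [0, 1]
    source_window: tuple[float, float] = (0.0, 0.0)


def discrete_stockwell(x: np.ndarray, fs: float) -> ComplexTFM:
    """Compute the discrete S-transform of a real signal.

    Returns the full set of N voices n = 0..N-1 at frequencies n/(NT);
    rows above the Nyquist voice mirror the conjugate spectrum and are
    normally removed by :func:`band_crop`.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise DataError(f"expected a 1-D signal, got shape {x.shape}")
    n_pts = x.size
    if n_pts < 4:
        raise ParameterError(f"need at least 4 samples, got {n_pts}")
    if not np.all(np.isfinite(x)):
        raise DataError("signal contains non-finite samples")

    X = np.fft.fft(x) / n_pts  # DFT with 1/N normalization
    k = np.arange(n_pts)
    voices = np.arange(1, n_pts)
    # shifted spectrum X[(k+n) mod N] windowed by the voice Gaussian
    shifted = X[(k[None, :] + voices[:, None]) % n_pts]
    gauss = np.exp(-2.0 * np.pi**2 * k[None, :] ** 2 / voices[:, None].astype(float) ** 2)
    S = np.empty((n_pts, n_pts), dtype=np.complex128)
    S[1:] = np.fft.fft(shifted * gauss, axis=1)
    S[0] = x.mean()  # zero-voice convention

    T = 1.0 / fs
    freqs = np.arange(n_pts) / (n_pts * T)
    times = np.arange(n_pts) * T
    return ComplexTFM(values=S, freqs_hz=freqs, times_s=times, fs=fs)


def tfm_magnitude(ctfm: ComplexTFM) -> TFM:
    """|S| = sqrt(Re^2 + Im^2), elementwise."""
    return TFM(
        values=np.abs(ctfm.values),
        freqs_hz=ctfm.freqs_hz.copy(),
        times_s=ctfm.times_s.copy(),
    )


def band_crop(tfm: TFM, f_lo: float = 7.0, f_hi: float = 30.0) -> TFM:
    """Retain exactly the voices with f_lo <= n/(NT) <= f_hi (inclusive)."""
    if not f_lo < f_hi:
        raise ParameterError(f"need f_lo < f_hi, got [{f_lo}, {f_hi}]")
    mask = (tfm.freqs_hz >= f_lo) & (tfm.freqs_hz <= f_hi)
    if not mask.any():
        raise ParameterError(f"no voices inside [{f_lo}, {f_hi}] Hz")
    return TFM(
        values=tfm.values[mask],
        freqs_hz=tfm.freqs_hz[mask],
        times_s=tfm.times_s.copy(),
    )


def bandpass(
    data: np.ndarray, fs: float, f_lo: float = 7.0, f_hi: float = 30.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass applied along the last axis.

    Mirrors the raw-signal 7-30 Hz filter applied before the transform to
    isolate the mu/beta range where ERD/ERS expresses.
    """
    if not 0 < f_lo < f_hi < fs / 2:
        raise ParameterError(f"invalid band [{f_lo}, {f_hi}] Hz at fs={fs}")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def stack_and_resize(tfm_c3: TFM, tfm_c4: TFM, out: int = 220) -> StackedTFM:
    """Stack the C3 map vertically above the C4 map and resize to out x out.

    Bilinear interpolation, then per-image min-max normalization to
    [0, 1].  A constant stacked map yields the all-zero image.  The
    default 220 makes the two-layer CNN's flattened feature
    16 * 55 * 55 = 48,400-dimensional.
    """
    if tfm_c3.values.shape != tfm_c4.values.shape or not (
        np.allclose(tfm_c3.freqs_hz, tfm_c4.freqs_hz)
        and np.allclose(tfm_c3.times_s, tfm_c4.times_s)
    ):
        raise DataError("C3 and C4 maps must share frequency and time coordinates")
    stacked = np.vstack([tfm_c3.values, tfm_c4.values])
    img = _sk_resize(
        stacked, (out, out), order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    t = tfm_c3.times_s
    return StackedTFM(image=img, source_window=(float(t[0]), float(t[-1])))
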