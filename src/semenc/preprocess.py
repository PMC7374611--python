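"""Raw voltage traces -> HFB amplitude at the film frame rate.

Pipeline: notch out line noise (50/100 Hz), common average reference per
grid, complex Morlet wavelet amplitudes in 1-Hz bins, average over the
60-120 Hz high-frequency band, anti-alias resample to the 25 Hz frame rate.

The wavelet envelope is parameterized by its temporal full width at half
maximum, fixed to four wavelengths of the center frequency, so temporal
resolution scales with frequency.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .datatypes import ElectrodeGeometry, NeuralRecording, RawRecording

__all__ = ["common_average_reference", "hfb_amplitude", "notch_filter"]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def common_average_reference(
    raw: RawRecording, groups: list[np.ndarray] | None = None
) -> RawRecording:
    """Subtract the instantaneous mean across channels within each grid group.

    ``groups`` partitions the good channels (e.g. clinical grid vs
    high-density grid referenced independently); default is a single group of
    all good channels.  Bad channels pass through untouched and never enter a
    group mean.
    """
    n_ch = raw.signal.shape[0]
    good = np.setdiff1d(np.arange(n_ch), np.fromiter(raw.bad_channels, dtype=int, count=len(raw.bad_channels)))
    if groups is None:
        groups = [good]
    seen: set[int] = set()
    for g in groups:
        g = np.asarray(g)
        if g.size == 0:
            raise ValueError("empty referencing group")
        if seen.intersection(g.tolist()):
            raise ValueError("groups must be disjoint")
        if np.intersect1d(g, np.fromiter(raw.bad_channels, dtype=int, count=len(raw.bad_channels))).size:
            raise ValueError("bad channels cannot be referenced")
        seen.update(g.tolist())
    if seen != set(good.tolist()):
        raise ValueError("groups must partition the good channels")
    out = raw.signal.copy()
    for g in groups:
        g = np.asarray(g)
        out[g] -= out[g].mean(axis=0, keepdims=True)
    return RawRecording(signal=out, fs=raw.fs, bad_channels=raw.bad_channels)


def notch_filter(
    x: np.ndarray, fs: float, freqs: tuple[float, ...] = (50.0, 100.0), q: float = 35.0
) -> np.ndarray:
    """Zero-phase IIR notch at each line-noise frequency."""
    out = np.asarray(x, dtype=float)
    for f0 in freqs:
        b, a = sps.iirnotch(f0, Q=q, fs=fs)
        out = sps.filtfilt(b, a, out, axis=-1)
    return out


def _morlet_amplitude(x: np.ndarray, fs: float, freq: float, fwhm_cycles: float) -> np.ndarray:
    """Amplitude of the complex Morlet transform at one center frequency.

    The Gaussian envelope has temporal FWHM ``fwhm_cycles / freq`` seconds.
    Convolution uses reflect padding so edges are defined (first/last second
    should still be treated with caution by callers).
    """
    sigma_t = (fwhm_cycles / freq) / _FWHM_TO_SIGMA
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    wavelet = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    wavelet /= np.abs(wavelet).sum() / 2.0  # unit gain for a matched sinusoid
    pad = half
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    conv = sps.oaconvolve(xp, wavelet[None, :] if x.ndim == 2 else wavelet, mode="same", axes=-1)
    sl = [slice(None)] * x.ndim
    sl[-1] = slice(pad, pad + x.shape[-1])
    return np.abs(conv[tuple(sl)])


def hfb_amplitude(
    raw: RawRecording,
    notch_hz: tuple[float, ...] = (50.0, 100.0),
    band: tuple[float, float] = (60.0, 120.0),
    step: float = 1.0,
    wavelet_fwhm_cycles: float = 4.0,
    out_rate: float = 25.0,
    geometry: ElectrodeGeometry | None = None,
) -> NeuralRecording:
    """High-frequency-band amplitude at the stimulus frame rate.

    Computes complex Morlet amplitudes in ``step``-Hz bins across ``band``
    (inclusive), averages them, then anti-alias resamples each electrode's
    amplitude series to ``out_rate``.
    """
    lo, hi = band
    if hi >= raw.fs / 2:
        raise ValueError("band upper edge must be below Nyquist")
    if lo <= 0 or hi <= lo:
        raise ValueError("invalid band")
    x = notch_filter(raw.signal, raw.fs, freqs=notch_hz) if notch_hz else raw.signal
    freqs = np.arange(lo, hi + step / 2, step)
    acc = np.zeros_like(x)
    for f0 in freqs:
        acc += _morlet_amplitude(x, raw.fs, f0, wavelet_fwhm_cycles)
    acc /= len(freqs)
    # low-pass anti-alias + polyphase decimation to the frame rate
    from fractions import Fraction

    frac = Fraction(out_rate / raw.fs).limit_denominator(10000)
    hfb = sps.resample_poly(acc, frac.numerator, frac.denominator, axis=-1)
    hfb = np.clip(hfb, 0.0, None)  # resampling ripple can dip below zero
    return NeuralRecording(hfb=hfb, frame_rate=out_rate, geometry=geometry)
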