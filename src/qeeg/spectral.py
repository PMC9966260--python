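"""Welch spectral estimation, dyadic wavelet band segmentation, relative power.

The classical EEG bands are obtained by a 5-level discrete wavelet transform
(Daubechies-2) of the signal resampled to 240 Hz, so that the dyadic band
edges coincide with the clinical boundaries:

    A5 0-3.75 Hz  delta | D5 3.75-7.5 theta | D4 7.5-15 alpha
    D3 15-30 beta       | D2 30-60 gamma

Band power is the integral of the Welch power spectral density of each
band-reconstructed series over the band's nominal interval; relative power
normalizes these over the included bands, giving a scale-free composition
vector per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .montage import EEGRecording
from .preprocess import FS_ANALYSIS

#: Welch defaults: 2-second Hamming windows with 75% overlap.
WELCH_WINDOW_S = 2.0
WELCH_OVERLAP = 0.75
WELCH_WINDOW = "hamming"

#: Decomposition depth of the dyadic band split.
WAVELET = "db2"
WAVELET_LEVEL = 5

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")
#: Bands used for the relative-power feature set (signals are band-limited
#: to 30 Hz, so gamma is excluded by default).
DEFAULT_RP_BANDS = ("delta", "theta", "alpha", "beta")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float
    wavelet_node: str


def band_definitions(fs: float = FS_ANALYSIS) -> list[BandDefinition]:
    """Dyadic band edges for a 5-level decomposition at rate ``fs``.

    The level-k detail spans [fs / 2**(k+1), fs / 2**k]; the level-5
    approximation spans [0, fs / 2**6].  At fs = 240 these are exactly the
    clinical delta/theta/alpha/beta/gamma boundaries.
    """
    nodes = ["A5", "D5", "D4", "D3", "D2"]
    levels = [6, 5, 4, 3, 2]  # divisor exponents: A5 top edge = fs/2**6
    defs = []
    lo = 0.0
    for name, node, k in zip(BAND_NAMES, nodes, levels):
        hi = fs / 2**k if node != "A5" else fs / 2**6
        defs.append(BandDefinition(name, lo, hi, node))
        lo = hi
    return defs


def band_interval(name: str, fs: float = FS_ANALYSIS) -> tuple[float, float]:
    for b in band_definitions(fs):
        if b.name == name:
            return (b.f_lo, b.f_hi)
    raise ValueError(f"unknown band {name!r}")


@dataclass
class PSDEstimate:
    """One-sided Welch PSD: frequency grid and power density per channel."""

    freqs: np.ndarray
    power: np.ndarray
    window_s: float
    overlap_frac: float


def welch_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = WELCH_WINDOW_S,
    overlap: float = WELCH_OVERLAP,
) -> PSDEstimate:
    """Welch PSD of a single-channel series (Hamming window, mean-detrended).

    With L = window_s * fs samples per segment and 75% overlap, the number
    of averaged segments is floor((N - L) / (0.25 L)) + 1.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"series of length {x.shape[-1]} is shorter than one "
            f"{window_s} s window ({nperseg} samples)"
        )
    noverlap = int(round(overlap * nperseg))
    freqs, power = signal.welch(
        x,
        fs=fs,
        window=WELCH_WINDOW,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    return PSDEstimate(freqs, power, window_s, overlap)


def wavelet_band_split(x: np.ndarray, fs: float = FS_ANALYSIS) -> dict[str, np.ndarray]:
    """Split a 240 Hz series into the five clinical bands by 5-level db2 DWT.

    Each band is the inverse transform of one coefficient branch, so the
    returned series have the original length and sum exactly back to the
    input (the 60-120 Hz level-1 detail is folded into gamma to keep the
    partition complete; it is numerically empty for 30 Hz band-limited
    input).
    """
    if abs(fs - FS_ANALYSIS) > 1e-9:
        raise ValueError(
            f"wavelet band split requires fs = {FS_ANALYSIS} Hz "
            f"(got {fs}); resample first"
        )
    x = np.asarray(x, dtype=float)
    coeffs = pywt.wavedec(x, WAVELET, mode="symmetric", level=WAVELET_LEVEL)
    # coeffs = [cA5, cD5, cD4, cD3, cD2, cD1]
    n = x.shape[-1]

    def recon(keep: list[int]) -> np.ndarray:
        cs = [c if i in keep else np.zeros_like(c) for i, c in enumerate(coeffs)]
        return pywt.waverec(cs, WAVELET, mode="symmetric")[..., :n]

    return {
        "delta": recon([0]),
        "theta": recon([1]),
        "alpha": recon([2]),
        "beta": recon([3]),
        "gamma": recon([4, 5]),
    }


def band_power(
    x: np.ndarray, fs: float, band: tuple[float, float],
    window_s: float = WELCH_WINDOW_S, overlap: float = WELCH_OVERLAP,
) -> float:
    """Integral of the Welch PSD of ``x`` over ``band`` (trapezoid-free sum)."""
    psd = welch_psd(x, fs, window_s, overlap)
    df = psd.freqs[1] - psd.freqs[0]
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    return float(psd.power[mask].sum() * df)


def relative_power(
    rec: EEGRecording,
    bands: tuple[str, ...] = DEFAULT_RP_BANDS,
) -> pd.DataFrame:
    """Relative band power per channel (rows sum to 1 over ``bands``).

    Each channel is wavelet-split, the Welch PSD of each band reconstruction
    is integrated over the band's nominal interval, and the resulting
    absolute powers are normalized across the included bands.
    """
    vals = np.empty((rec.n_channels, len(bands)))
    for i in range(rec.n_channels):
        x = rec.samples[i]
        if not np.any(x):
            raise ValueError(
                f"channel {rec.channel_names[i]} is all zero; "
                "relative power is undefined"
            )
        split = wavelet_band_split(x, rec.fs)
        for j, b in enumerate(bands):
            vals[i, j] = band_power(split[b], rec.fs, band_interval(b, rec.fs))
    total = vals.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total band power; relative power is undefined")
    return pd.DataFrame(vals / total, index=list(rec.channel_names), columns=list(bands))


def relative_power_features(
    rec: EEGRecording, bands: tuple[str, ...] = DEFAULT_RP_BANDS
) -> pd.Series:
    """Flatten relative power into named features "RP_<band>_<channel>"."""
    rp = relative_power(rec, bands)
    out = {}
    for b in bands:
        for ch in rec.channel_names:
            out[f"RP_{b}_{ch}"] = rp.loc[ch, b]
    return pd.Series(out, name=rec.subject_id)
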