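"""Magnitude-squared coherence between electrode pairs.

MSC at frequency f is |P_ab(f)|^2 / (P_aa(f) P_bb(f)) estimated by Welch
averaging; each electrode pair is summarized by the unweighted mean of the
MSC bins across the 1-30 Hz analysis band, giving one functional-connectivity
scalar per pair (8 interhemispheric + 28 left + 28 right = 64 features).

Note that with U averaged segments the MSC of two independent signals has a
positive bias floor of about 1/U, and a single segment gives identically 1 —
hence the two-window minimum length requirement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .montage import EEGRecording, PairScheme, SCHEME_TAGS, all_pair_schemes
from .spectral import WELCH_OVERLAP, WELCH_WINDOW, WELCH_WINDOW_S

#: Analysis band for the per-pair coherence scalar, Hz.
COH_F_LO = 1.0
COH_F_HI = 30.0


def msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = WELCH_WINDOW_S,
    overlap: float = WELCH_OVERLAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence of two equal-length series.

    Returns ``(freqs, coherence)`` with coherence in [0, 1] at every bin.
    Requires at least two Welch segments: single-segment coherence is
    identically 1 regardless of the signals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap * nperseg))
    step = nperseg - noverlap
    if x.shape[-1] < nperseg + step:
        raise ValueError(
            "coherence needs at least two Welch segments "
            f"({nperseg + step} samples at these settings); a single segment "
            "is degenerate (identically 1)"
        )
    freqs, cxy = signal.coherence(
        x, y, fs=fs, window=WELCH_WINDOW, nperseg=nperseg,
        noverlap=noverlap, detrend="constant",
    )
    return freqs, np.clip(cxy, 0.0, 1.0)


def band_mean_msc(
    x: np.ndarray, y: np.ndarray, fs: float,
    f_lo: float = COH_F_LO, f_hi: float = COH_F_HI,
) -> float:
    """Unweighted mean of MSC bins with f_lo <= f <= f_hi."""
    freqs, c = msc(x, y, fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise ValueError("no frequency bins inside the requested band")
    return float(c[mask].mean())


def coherence_features(
    rec: EEGRecording,
    schemes: list[PairScheme] | None = None,
    f_lo: float = COH_F_LO,
    f_hi: float = COH_F_HI,
) -> pd.Series:
    """Band-mean MSC for every pair of every scheme.

    Feature names follow "COH_<scheme>_<a>-<b>" with scheme tags
    inter/left/right; the default scheme list yields 64 features.
    """
    if schemes is None:
        schemes = all_pair_schemes()
    out: dict[str, float] = {}
    for scheme in schemes:
        tag = SCHEME_TAGS[scheme.name]
        for a, b in scheme.pairs:
            out[f"COH_{tag}_{a}-{b}"] = band_mean_msc(
                rec.channel(a), rec.channel(b), rec.fs, f_lo, f_hi
            )
    return pd.Series(out, name=rec.subject_id)
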