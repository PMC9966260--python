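"""Signal-complexity features: spectral entropy, dispersion entropy, and
spectral dispersion entropy.

Spectral entropy (SpecEn) is the Shannon entropy (base 2, in bits) of the
Welch power spectral density normalized over the 1-30 Hz analysis band: low
when power concentrates in few bins, at most log2(#bins) for a flat spectrum.

Dispersion entropy (DisEn) quantizes a series into c classes through the
normal cumulative distribution function, forms m-length embedding vectors at
delay d ("dispersion patterns"), and takes the Shannon entropy (natural log,
in nats) of the pattern distribution; its range is [0, m ln c].

Spectral dispersion entropy (SpecDE) applies DisEn to the frequency-ordered
PSD bin sequence instead of the time series, measuring the irregularity of
the spectral profile itself.  Defaults: m = 2, c = 6, d = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .montage import EEGRecording
from .spectral import welch_psd

#: Analysis band for the spectral-entropy family, Hz.
SPEC_F_LO = 1.0
SPEC_F_HI = 30.0


@dataclass(frozen=True)
class DispersionConfig:
    """Dispersion-entropy parameters: template length m, classes c, delay d."""

    m: int = 2
    c: int = 6
    d: int = 1

    def __post_init__(self) -> None:
        if self.m < 2 or self.c < 2 or self.d < 1:
            raise ValueError("need m >= 2, c >= 2, d >= 1")

    @property
    def max_entropy(self) -> float:
        """Upper bound m ln c, attained when all c**m patterns are equiprobable."""
        return self.m * float(np.log(self.c))


def ncdf_map(x: np.ndarray, c: int) -> np.ndarray:
    """Quantize a series into integer classes 1..c via the normal CDF.

    y_j = Phi((x_j - mean) / std), then z_j = round_half_up(c*y_j + 0.5)
    clipped to [1, c].  A constant series (std = 0) degenerates to all
    class 1, which downstream entropy treats as a single pattern.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    sigma = x.std()
    if sigma == 0:
        return np.ones(x.shape, dtype=np.int64)
    y = norm.cdf((x - x.mean()) / sigma)
    z = np.floor(c * y + 1.0).astype(np.int64)  # round-half-up of c*y + 0.5
    return np.clip(z, 1, c)


def dispersion_patterns(
    z: np.ndarray, cfg: DispersionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Count dispersion patterns in an integer class series.

    Returns ``(patterns, probabilities)`` where each pattern is an m-tuple
    row and probabilities are counts over N - (m-1)d embedding vectors;
    probabilities sum to exactly 1.
    """
    z = np.asarray(z)
    n_vec = z.shape[-1] - (cfg.m - 1) * cfg.d
    if n_vec < 1:
        raise ValueError(
            f"series of length {z.shape[-1]} too short for m={cfg.m}, d={cfg.d}"
        )
    emb = np.stack([z[i * cfg.d : i * cfg.d + n_vec] for i in range(cfg.m)], axis=1)
    patterns, counts = np.unique(emb, axis=0, return_counts=True)
    return patterns, counts / n_vec


def dispersion_entropy(
    x: np.ndarray, cfg: DispersionConfig = DispersionConfig(), premapped: bool = False
) -> float:
    """Dispersion entropy in nats.

    ``x`` is NCDF-quantized into ``cfg.c`` classes unless ``premapped`` is
    True (then it must already be an integer class series).  Returns the
    Shannon entropy of the dispersion-pattern distribution; 0 iff a single
    pattern occurs, at most m ln c.
    """
    z = np.asarray(x) if premapped else ncdf_map(x, cfg.c)
    _, probs = dispersion_patterns(z, cfg)
    return float(-(probs * np.log(probs)).sum())


def _band_psd(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> np.ndarray:
    psd = welch_psd(x, fs)
    mask = (psd.freqs >= f_lo) & (psd.freqs <= f_hi)
    return psd.power[mask]


def spectral_entropy(
    x: np.ndarray, fs: float, f_lo: float = SPEC_F_LO, f_hi: float = SPEC_F_HI
) -> float:
    """Shannon entropy (bits) of the Welch PSD normalized over [f_lo, f_hi]."""
    p = _band_psd(x, fs, f_lo, f_hi)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero power inside the analysis band")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def spectral_entropy_of_psd(power: np.ndarray) -> float:
    """Spectral entropy (bits) of an already-restricted PSD vector."""
    p = np.asarray(power, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total power")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def spectral_dispersion_entropy(
    x: np.ndarray,
    fs: float,
    cfg: DispersionConfig = DispersionConfig(),
    f_lo: float = SPEC_F_LO,
    f_hi: float = SPEC_F_HI,
) -> float:
    """Dispersion entropy (nats) of the frequency-ordered PSD bin series.

    The Welch PSD over [f_lo, f_hi] is treated as the input series to the
    NCDF quantizer and pattern counter.  A flat spectrum (std = 0) has a
    single pattern and entropy 0.
    """
    p = _band_psd(x, fs, f_lo, f_hi)
    if p.size - (cfg.m - 1) * cfg.d < 1:
        raise ValueError(
            f"only {p.size} spectral bins in band; need more than (m-1)*d"
        )
    if p.std() == 0:
        return 0.0
    return dispersion_entropy(p, cfg)


def complexity_features(
    rec: EEGRecording,
    cfg: DispersionConfig = DispersionConfig(),
    f_lo: float = SPEC_F_LO,
    f_hi: float = SPEC_F_HI,
) -> pd.Series:
    """SpecEn and SpecDE per channel, named "SPECEN_<ch>" / "SPECDE_<ch>"."""
    out: dict[str, float] = {}
    for i, ch in enumerate(rec.channel_names):
        x = rec.samples[i]
        out[f"SPECEN_{ch}"] = spectral_entropy(x, rec.fs, f_lo, f_hi)
    for i, ch in enumerate(rec.channel_names):
        x = rec.samples[i]
        out[f"SPECDE_{ch}"] = spectral_dispersion_entropy(x, rec.fs, cfg, f_lo, f_hi)
    return pd.Series(out, name=rec.subject_id)
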