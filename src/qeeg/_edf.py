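"""Minimal EDF (European Data Format) writer.

Covers exactly what this package needs: continuous multichannel signals at a
single integer sampling rate, 16-bit samples, 1-second data records.  Reading
is delegated to mne; this writer exists for round-trip tests and for
exporting synthetic cohorts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    labels: list[str],
    fs: float,
    patient_id: str = "X X X X",
) -> None:
    """Write ``data_uv`` (channels x time, microvolts) as an EDF file.

    The record length is padded to a whole number of 1-second data records;
    sampling rate must be a positive integer.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    if data_uv.ndim != 2:
        raise ValueError("data must be 2-D [channels x time]")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires a positive integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record, per signal
    nsig, n = data_uv.shape
    if len(labels) != nsig:
        raise ValueError("one label per channel required")
    nrec = int(np.ceil(n / spr))
    padded = np.pad(data_uv, ((0, 0), (0, nrec * spr - n)), mode="edge")

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    pmax = np.where(pmax - pmin < 1e-9, pmin + 1.0, pmax)  # avoid zero span
    # quantize the physical range to what the 8-char header field can hold,
    # so the scaling used for encoding matches what a reader recovers
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((padded - pmin[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field("X X X X", 80),
            _field("01.01.20", 8),
            _field("00.00.00", 8),
            _field(256 * (nsig + 1), 8),
            _field("", 44),
            _field(nrec, 8),
            _field(1, 8),  # record duration, seconds
            _field(nsig, 4),
        ]
    )
    header += b"".join(_field(lab, 16) for lab in labels)
    header += b"".join(_field("", 80) for _ in labels)  # transducer
    header += b"".join(_field("uV", 8) for _ in labels)
    header += b"".join(_field(f"{v:.6g}"[:8], 8) for v in pmin)
    header += b"".join(_field(f"{v:.6g}"[:8], 8) for v in pmax)
    header += b"".join(_field(_DIG_MIN, 8) for _ in labels)
    header += b"".join(_field(_DIG_MAX, 8) for _ in labels)
    header += b"".join(_field("", 80) for _ in labels)  # prefiltering
    header += b"".join(_field(spr, 8) for _ in labels)
    header += b"".join(_field("", 32) for _ in labels)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(nrec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
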