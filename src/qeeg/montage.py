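"""Recording data model, the 10-20 montage, and coherence electrode-pair schemes.

The 19-channel clinical montage (10-20 system) is the universal coordinate
system of this package: every reader maps its input onto the canonical
channel order below, and every electrode-pair scheme is defined against it.
Odd-numbered electrodes sit over the left hemisphere, even-numbered over the
right, and a trailing "z" marks the midline.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical 19-channel 10-20 montage, in recording order.
CHANNELS_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Lateral (non-midline) electrodes per hemisphere, in canonical order.
LEFT_LATERAL: tuple[str, ...] = ("Fp1", "F7", "F3", "T3", "C3", "T5", "P3", "O1")
RIGHT_LATERAL: tuple[str, ...] = ("Fp2", "F8", "F4", "T4", "C4", "T6", "P4", "O2")
MIDLINE: tuple[str, ...] = ("Fz", "Cz", "Pz")


class Group(str, enum.Enum):
    """Diagnostic group labels: normal elderly, post-stroke MCI, post-stroke dementia."""

    NORMAL = "normal"
    STROKE_MCI = "stroke_mci"
    STROKE_DEMENTIA = "stroke_dementia"


#: Fixed group order used for confusion matrices and reports.
GROUP_ORDER: tuple[Group, ...] = (Group.NORMAL, Group.STROKE_MCI, Group.STROKE_DEMENTIA)


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal amplitudes, conventionally in microvolts.
    channel_names : list of str
        One unique name per row of ``samples``.
    fs : float
        Sampling rate in Hz, > 0.
    subject_id : str
        Identifier used to align feature rows across extraction stages.
    group : Group or None
        Diagnostic label, if known.
    """

    samples: np.ndarray
    channel_names: list[str]
    fs: float
    subject_id: str = ""
    group: Group | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D array [channels x time]")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_times / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return the sample row for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None
        return self.samples[idx]

    def copy_with(self, samples: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Clone metadata onto new sample data (same channel set)."""
        return EEGRecording(
            samples=samples,
            channel_names=list(self.channel_names),
            fs=self.fs if fs is None else fs,
            subject_id=self.subject_id,
            group=self.group,
        )


class SchemeName(str, enum.Enum):
    INTERHEMISPHERIC = "interhemispheric"
    LEFT_INTRA = "left_intra"
    RIGHT_INTRA = "right_intra"


@dataclass(frozen=True)
class PairScheme:
    """A named, ordered list of electrode pairs for coherence features."""

    name: SchemeName
    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)


# Homologous left-right pairs, frontal to occipital.
_INTER_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("F7", "F8"), ("C3", "C4"),
    ("T3", "T4"), ("P3", "P4"), ("T5", "T6"), ("O1", "O2"),
)

# All 28 unordered pairs among the 8 left lateral electrodes, in the
# conventional anterior-to-posterior listing order.
_LEFT_INTRA_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "F3"), ("Fp1", "F7"), ("Fp1", "C3"), ("Fp1", "T3"),
    ("Fp1", "P3"), ("Fp1", "T5"), ("Fp1", "O1"),
    ("F3", "F7"), ("F3", "C3"), ("F3", "T3"), ("F3", "P3"),
    ("F3", "T5"), ("F3", "O1"),
    ("F7", "C3"), ("F7", "T3"), ("F7", "P3"), ("F7", "T5"), ("F7", "O1"),
    ("C3", "T3"), ("C3", "P3"), ("C3", "T5"), ("C3", "O1"),
    ("T3", "P3"), ("T3", "T5"), ("T3", "O1"),
    ("P3", "T5"), ("P3", "O1"),
    ("T5", "O1"),
)

#: Left -> right homologue substitution (odd index -> even index).
LEFT_TO_RIGHT: dict[str, str] = {
    "Fp1": "Fp2", "F7": "F8", "F3": "F4", "T3": "T4",
    "C3": "C4", "T5": "T6", "P3": "P4", "O1": "O2",
}

_RIGHT_INTRA_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (LEFT_TO_RIGHT[a], LEFT_TO_RIGHT[b]) for a, b in _LEFT_INTRA_PAIRS
)

_SCHEMES: dict[SchemeName, tuple[tuple[str, str], ...]] = {
    SchemeName.INTERHEMISPHERIC: _INTER_PAIRS,
    SchemeName.LEFT_INTRA: _LEFT_INTRA_PAIRS,
    SchemeName.RIGHT_INTRA: _RIGHT_INTRA_PAIRS,
}

#: Short scheme tags used in feature names ("COH_<tag>_<a>-<b>").
SCHEME_TAGS: dict[SchemeName, str] = {
    SchemeName.INTERHEMISPHERIC: "inter",
    SchemeName.LEFT_INTRA: "left",
    SchemeName.RIGHT_INTRA: "right",
}


def build_pair_scheme(name: SchemeName | str) -> PairScheme:
    """Return the electrode-pair scheme for coherence analysis.

    ``interhemispheric`` contains the 8 homologous left-right pairs;
    ``left_intra`` / ``right_intra`` contain all 28 pairs among the 8
    lateral electrodes of one hemisphere.  Midline electrodes never
    appear in any scheme.
    """
    try:
        name = SchemeName(name)
    except ValueError:
        raise ValueError(
            f"unknown scheme {name!r}; expected one of "
            f"{[s.value for s in SchemeName]}"
        ) from None
    return PairScheme(name=name, pairs=_SCHEMES[name])


def all_pair_schemes() -> list[PairScheme]:
    """All three schemes in report order: inter, left, right (8+28+28 pairs)."""
    return [build_pair_scheme(n) for n in SchemeName]


# ---------------------------------------------------------------------------
# channel-name normalization and I/O
# ---------------------------------------------------------------------------

_CANONICAL_BY_KEY = {c.upper(): c for c in CHANNELS_19}
# T3/T4/T5/T6 appear as T7/T8/P7/P8 in modern nomenclature.
_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def normalize_channel_name(label: str) -> str | None:
    """Map a clinical channel label onto the canonical montage, or None.

    Strips whitespace, an "EEG" prefix, and reference suffixes such as
    "-Ref" or "-A1A2"; comparison is case-insensitive.
    """
    s = label.strip()
    s = re.sub(r"^EEG[\s_:]*", "", s, flags=re.IGNORECASE)
    s = re.split(r"[-\s]", s, maxsplit=1)[0].strip()
    key = s.upper()
    key = _ALIASES.get(key, key)
    return _CANONICAL_BY_KEY.get(key)


def _reorder_to_canonical(
    samples: np.ndarray, labels: list[str]
) -> tuple[np.ndarray, list[str]]:
    mapped: dict[str, int] = {}
    for i, lab in enumerate(labels):
        canon = normalize_channel_name(lab)
        if canon is not None and canon not in mapped:
            mapped[canon] = i
    missing = [c for c in CHANNELS_19 if c not in mapped]
    if missing:
        raise ValueError(
            f"recording is missing canonical channel(s): {', '.join(missing)}"
        )
    idx = [mapped[c] for c in CHANNELS_19]
    return samples[idx], list(CHANNELS_19)


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    subject_id: str | None = None,
    group: Group | str | None = None,
) -> EEGRecording:
    """Read an EDF or delimited-text recording onto the canonical montage.

    Parameters
    ----------
    path : path
        Input file. ``format`` defaults to the file extension
        (``.edf`` -> EDF, anything else -> delimited text).
    fs : float, optional
        Sampling rate; required for text input, ignored for EDF
        (taken from the header).
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if subject_id is None:
        subject_id = path.stem
    if group is not None:
        group = Group(group)

    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        rates = {len(np.atleast_1d(raw.info["sfreq"]))}  # mne enforces one rate
        del rates
        data_uv = raw.get_data() * 1e6  # mne loads EEG in volts
        samples, names = _reorder_to_canonical(data_uv, list(raw.ch_names))
        return EEGRecording(samples, names, float(raw.info["sfreq"]), subject_id, group)

    if format == "csv":
        if fs is None:
            raise ValueError("fs must be provided for delimited-text input")
        df = pd.read_csv(path)
        header_canon = [normalize_channel_name(str(c)) for c in df.columns]
        if sum(c is not None for c in header_canon) >= 10:
            # channels are columns
            samples = df.to_numpy(dtype=float).T
            labels = [str(c) for c in df.columns]
        else:
            # channels are rows, first column holds labels
            df = pd.read_csv(path, header=None)
            labels = [str(v) for v in df.iloc[:, 0]]
            samples = df.iloc[:, 1:].to_numpy(dtype=float)
        samples, names = _reorder_to_canonical(samples, labels)
        return EEGRecording(samples, names, float(fs), subject_id, group)

    raise ValueError(f"unknown format {format!r}")


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording as EDF or as delimited text (channels as columns)."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        from ._edf import write_edf

        write_edf(path, rec.samples, rec.channel_names, rec.fs)
    elif format == "csv":
        pd.DataFrame(rec.samples.T, columns=rec.channel_names).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_cohort_manifest(manifest_path: str | Path) -> list[EEGRecording]:
    """Load a cohort from a JSON manifest.

    The manifest maps subject ids to ``{"path": ..., "group": ..., "fs": ...}``
    entries; relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    recs = []
    for sid, entry in spec.items():
        p = Path(entry["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        recs.append(
            read_recording(
                p,
                fs=entry.get("fs"),
                subject_id=sid,
                group=entry.get("group"),
            )
        )
    return recs
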