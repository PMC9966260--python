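"""Synthetic 19-channel EEG cohorts with the group structure of post-stroke
cognitive decline.

Each subject's channels are mixtures of band-limited noise sources:

    channel = coupling * shared + (1 - coupling) * private

where ``shared`` is one source per frequency band common to all channels
(controlling inter-channel coherence through the mixing weight) and
``private`` is an independent source per channel.  Per-band source standard
deviations follow a group band profile, giving direct control of relative
power; a spectral-concentration knob narrows each band's occupied width
around its centre, lowering spectral entropy with severity.

Severity encodings (normal -> MCI -> dementia) follow the qualitative
clinical signatures: delta relative power rises (0.25 -> 0.40 -> 0.55), beta
falls (0.25 -> 0.15 -> 0.08), channel coupling falls (0.7 -> 0.5 -> 0.35)
and the occupied bandwidth narrows (1.0 -> 0.7 -> 0.45).  The magnitudes are
synthetic free parameters, not measured patient values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import CHANNELS_19, EEGRecording, Group
from .spectral import band_interval

#: Default per-group cohort sizes (normal, MCI, dementia).
DEFAULT_N_PER_GROUP: dict[Group, int] = {
    Group.NORMAL: 18,
    Group.STROKE_MCI: 19,
    Group.STROKE_DEMENTIA: 13,
}

#: Overall signal scale, microvolts RMS per channel.
AMPLITUDE_UV = 30.0


@dataclass(frozen=True)
class GroupProfile:
    """Ground-truth generating parameters for one diagnostic group."""

    band_profile: dict[str, float]  # target relative power, sums to 1
    coupling: float                 # shared-source amplitude weight in [0, 1]
    bandwidth_frac: float           # occupied fraction of each band's width

    def __post_init__(self) -> None:
        s = sum(self.band_profile.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"band profile sums to {s}, expected 1")
        if not (0 <= self.coupling <= 1):
            raise ValueError("coupling must lie in [0, 1]")
        if not (0 < self.bandwidth_frac <= 1):
            raise ValueError("bandwidth_frac must lie in (0, 1]")


DEFAULT_PROFILES: dict[Group, GroupProfile] = {
    Group.NORMAL: GroupProfile(
        band_profile={"delta": 0.25, "theta": 0.20, "alpha": 0.30, "beta": 0.25},
        coupling=0.7,
        bandwidth_frac=1.0,
    ),
    Group.STROKE_MCI: GroupProfile(
        band_profile={"delta": 0.40, "theta": 0.22, "alpha": 0.23, "beta": 0.15},
        coupling=0.5,
        bandwidth_frac=0.7,
    ),
    Group.STROKE_DEMENTIA: GroupProfile(
        band_profile={"delta": 0.55, "theta": 0.22, "alpha": 0.15, "beta": 0.08},
        coupling=0.35,
        bandwidth_frac=0.45,
    ),
}


@dataclass
class SyntheticCohortConfig:
    """Cohort layout and generating parameters."""

    n_per_group: dict[Group, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    fs: float = 250.0
    duration_s: float = 40.0
    profiles: dict[Group, GroupProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g} needs at least 2 subjects")


@dataclass
class SyntheticCohort:
    """Generated recordings plus the ground truth that produced them."""

    recordings: list[EEGRecording]
    config: SyntheticCohortConfig

    def groups(self) -> list[Group]:
        return [r.group for r in self.recordings]


def _band_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    bandwidth_frac: float,
) -> np.ndarray:
    """Unit-variance noise confined to the centre fraction of a band."""
    lo, hi = band
    lo = max(lo, 1.0)  # the pipeline's high-pass removes sub-1 Hz content
    centre = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo) * bandwidth_frac
    f1, f2 = centre - half, centre + half
    sos = signal.butter(4, [f1, f2], btype="bandpass", output="sos", fs=fs)
    # pad to absorb the filter transient
    pad = int(2 * fs)
    x = signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_subject(
    group: Group,
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
    subject_id: str = "",
) -> EEGRecording:
    """One subject: per-band shared + private band-limited noise mixtures."""
    profile = cfg.profiles[group]
    n = int(round(cfg.duration_s * cfg.fs))
    w = profile.coupling
    data = np.zeros((len(CHANNELS_19), n))
    for band, target in profile.band_profile.items():
        if target <= 0:
            continue
        interval = band_interval(band, 240.0)
        shared = _band_noise(rng, n, cfg.fs, interval, profile.bandwidth_frac)
        sd = np.sqrt(target)
        for ch in range(len(CHANNELS_19)):
            private = _band_noise(rng, n, cfg.fs, interval, profile.bandwidth_frac)
            mix = w * shared + (1 - w) * private
            msd = mix.std()
            data[ch] += sd * (mix / msd if msd > 0 else mix)
    return EEGRecording(
        samples=AMPLITUDE_UV * data,
        channel_names=list(CHANNELS_19),
        fs=cfg.fs,
        subject_id=subject_id,
        group=group,
    )


def generate_cohort(
    cfg: SyntheticCohortConfig | None = None, seed: int | None = None
) -> SyntheticCohort:
    """Generate a labelled cohort, bit-for-bit reproducible from (config, seed)."""
    cfg = cfg or SyntheticCohortConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    recs = []
    for group in Group:
        if group not in cfg.n_per_group:
            continue
        for i in range(cfg.n_per_group[group]):
            sid = f"{group.value}_{i:02d}"
            recs.append(generate_subject(group, cfg, rng, subject_id=sid))
    return SyntheticCohort(recordings=recs, config=cfg)


def write_cohort(
    cohort: SyntheticCohort, out_dir: str | Path, format: str = "csv"
) -> Path:
    """Write one file per subject plus a JSON labels manifest; returns its path."""
    from .montage import write_recording

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for rec in cohort.recordings:
        fname = f"{rec.subject_id}.{format}"
        write_recording(rec, out_dir / fname, format=format)
        manifest[rec.subject_id] = {
            "path": fname,
            "group": rec.group.value,
            "fs": rec.fs,
        }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
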