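"""Cohort-level pipeline stages as scikit-learn style transformers.

The stages operate on lists of :class:`~qeeg.montage.EEGRecording` and
produce pandas feature frames indexed by subject id, so they compose with
sklearn pipelines and with :func:`qeeg.classify.crossval_classify`.  All
transformers are stateless (``fit`` only validates), because every feature
here is a fixed signal functional, not a learned mapping.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .coherence import COH_F_HI, COH_F_LO, coherence_features
from .complexity import DispersionConfig, complexity_features
from .montage import EEGRecording
from .preprocess import FS_ANALYSIS, FilterSpec, preprocess
from .spectral import DEFAULT_RP_BANDS, relative_power_features

#: Names of the four predictor groups, as used by scenario assembly.
FEATURE_SET_NAMES = ("relative_power", "coherence", "spec_en", "spec_de")


def _check_recordings(X) -> list[EEGRecording]:
    recs = list(X)
    if not recs:
        raise ValueError("no recordings given")
    for r in recs:
        if not isinstance(r, EEGRecording):
            raise TypeError(f"expected EEGRecording, got {type(r).__name__}")
    ids = [r.subject_id for r in recs]
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique across the cohort")
    return recs


class Preprocessor(BaseEstimator, TransformerMixin):
    """Band-pass (1-30 Hz, zero-phase Butterworth) then resample to 240 Hz."""

    def __init__(self, filter_spec: FilterSpec | None = None,
                 fs_out: float = FS_ANALYSIS):
        self.filter_spec = filter_spec
        self.fs_out = fs_out

    def fit(self, X, y=None):
        _check_recordings(X)
        return self

    def transform(self, X) -> list[EEGRecording]:
        return [
            preprocess(r, spec=self.filter_spec, fs_out=self.fs_out)
            for r in _check_recordings(X)
        ]


class _RecordingFeatureExtractor(BaseEstimator, TransformerMixin):
    """Base: map each recording to a named feature row."""

    def fit(self, X, y=None):
        _check_recordings(X)
        return self

    def _extract(self, rec: EEGRecording) -> pd.Series:  # pragma: no cover
        raise NotImplementedError

    def transform(self, X) -> pd.DataFrame:
        rows = [self._extract(r) for r in _check_recordings(X)]
        df = pd.DataFrame(rows)
        df.index.name = "subject_id"
        return df

    def get_feature_names_out(self, input_features=None):
        raise RuntimeError("feature names depend on the montage; call transform")


class RelativePowerExtractor(_RecordingFeatureExtractor):
    """Relative band power per channel ("RP_<band>_<channel>", 76 features)."""

    def __init__(self, bands: tuple[str, ...] = DEFAULT_RP_BANDS):
        self.bands = bands

    def _extract(self, rec: EEGRecording) -> pd.Series:
        return relative_power_features(rec, self.bands)


class CoherenceExtractor(_RecordingFeatureExtractor):
    """Band-mean MSC per electrode pair ("COH_<scheme>_<a>-<b>", 64 features)."""

    def __init__(self, f_lo: float = COH_F_LO, f_hi: float = COH_F_HI):
        self.f_lo = f_lo
        self.f_hi = f_hi

    def _extract(self, rec: EEGRecording) -> pd.Series:
        return coherence_features(rec, f_lo=self.f_lo, f_hi=self.f_hi)


class ComplexityExtractor(_RecordingFeatureExtractor):
    """SpecEn and SpecDE per channel (38 features)."""

    def __init__(self, cfg: DispersionConfig = DispersionConfig()):
        self.cfg = cfg

    def _extract(self, rec: EEGRecording) -> pd.Series:
        return complexity_features(rec, self.cfg)


def extract_feature_sets(
    recordings: list[EEGRecording],
    preprocessed: bool = False,
    rp_bands: tuple[str, ...] = DEFAULT_RP_BANDS,
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Run the full extraction chain on a cohort.

    Returns ``(feature_sets, groups)`` where ``feature_sets`` maps the four
    predictor-group names to subjects x features frames and ``groups`` holds
    the diagnostic label per subject (NaN-free only if every recording is
    labelled).
    """
    recs = _check_recordings(recordings)
    if not preprocessed:
        recs = Preprocessor().transform(recs)
    rp = RelativePowerExtractor(bands=rp_bands).transform(recs)
    coh = CoherenceExtractor().transform(recs)
    cx = ComplexityExtractor().transform(recs)
    spec_en = cx[[c for c in cx.columns if c.startswith("SPECEN_")]]
    spec_de = cx[[c for c in cx.columns if c.startswith("SPECDE_")]]
    groups = pd.Series(
        {r.subject_id: (r.group.value if r.group else None) for r in recs},
        name="group",
    )
    return (
        {
            "relative_power": rp,
            "coherence": coh,
            "spec_en": spec_en,
            "spec_de": spec_de,
        },
        groups,
    )
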