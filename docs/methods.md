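# Methods

This note records the models, parameter choices and numerical conventions
behind `qeeg`, and what the synthetic-cohort tests do and do not establish
about real clinical data.

## Signal model and preprocessing

Input is a 19-channel scalp EEG on the 10–20 montage (Fp1 … O2), nominally
sampled at 250 Hz, assumed already cleaned of ocular/muscle artifacts
(artifact removal by ICA is interactive and out of scope; the pipeline
consumes pre-cleaned signals).  The recording reference is assumed common
across channels; coherence values are reference-dependent, and no
re-referencing is applied.

The canonical preparation is: band-pass 1–30 Hz at the native rate, then
polyphase resampling to 240 Hz.  The band-pass is a cascade of Butterworth
high-pass (1 Hz) and low-pass (30 Hz) sections with design targets of 1 dB
maximum passband droop and 80 dB stopband attenuation at 0.5 and 35 Hz.
Because the filter is applied forward–backward (zero phase — coherence
depends on relative phase, and a causal filter would inject its group delay
into every channel), each pass is designed at half the dB specification;
the effective two-pass response then meets the full specification by
construction.  Resampling 250 → 240 Hz is the exact rational ratio 24/25
via `scipy.signal.resample_poly`, with its built-in anti-alias filter.  The
240 Hz rate makes the dyadic wavelet edges line up with the clinical band
boundaries (below).  Epoch selection is a half-open time slice
`[t_start, t_end)`; task-phase durations are configuration, not constants.

## Spectral features

Welch PSD estimation uses 2 s Hamming windows with 75% overlap and
constant detrending throughout the package (one parameter set shared by
power, coherence and entropy features).  With these settings a 40 s record
averages ~77 segments.

Band segmentation follows a 5-level discrete wavelet transform with the
Daubechies-2 mother wavelet at 240 Hz, symmetric signal extension.  The
level-k detail spans `[240/2^(k+1), 240/2^k]` Hz, so:

| branch | band | interval (Hz) |
| --- | --- | --- |
| A5 | delta | 0–3.75 |
| D5 | theta | 3.75–7.5 |
| D4 | alpha | 7.5–15 |
| D3 | beta | 15–30 |
| D2 | gamma | 30–60 |

The level-1 detail (60–120 Hz) has no clinical name; its reconstruction is
folded into gamma so the five returned series partition the signal exactly
(their sum reconstructs the input to machine precision).  Band power is the
integral of the Welch PSD of each band-reconstructed series over the band's
nominal interval; relative power normalizes these across the included
bands.  Gamma is excluded from the default relative-power feature set
(4 bands × 19 channels = 76 features) because the signal is band-limited to
30 Hz upstream; a 5-band option exists.

A practical limit worth knowing: db2 analysis filters are short, and the
decimation inside the DWT aliases out-of-band leakage *into* the
neighbouring bands' nominal intervals.  A pure 10 Hz tone ends up with
roughly 70% of its energy in the alpha branch (about 11% appears at 5 Hz in
the theta branch and 15% at 20 Hz in the beta branch).  Broadband signals
are much less affected because leakage flows both ways; the synthetic
cohort recovers its configured band profiles within ±0.05.

## Coherence features

Magnitude-squared coherence
`C_ab(f) = |P_ab(f)|² / (P_aa(f) P_bb(f))` is estimated with the shared
Welch settings.  MSC from a single segment is identically 1, so at least
two segments are required; with U segments the expected bias floor for
independent signals is ≈ 1/U.  Each electrode pair is reduced to the
unweighted mean of MSC bins over 1–30 Hz (per-band means are available
through the band arguments).  The pair schemes are fixed: 8 homologous
interhemispheric pairs and the complete graph on the 8 lateral electrodes
of each hemisphere (28 + 28); midline electrodes (Fz/Cz/Pz) appear in no
pair.  Total: 64 features named `COH_<inter|left|right>_<a>-<b>`.

## Complexity features

**Spectral entropy** is the Shannon entropy, base 2, of the Welch PSD
restricted to 1–30 Hz and normalized to sum 1; range `[0, log2 B]` for B
bins (58 bins at the default settings).

**Dispersion entropy** quantizes a series through the normal CDF
(`y = Φ((x − μ)/σ)`, classes `z = round_half_up(c·y + 0.5)` clipped to
`[1, c]` — the original convention of the method), forms embedding vectors
`(z_i, z_{i+d}, …, z_{i+(m−1)d})`, and takes the Shannon entropy, natural
log, of the pattern distribution over the `N − (m−1)d` vectors.  Range
`[0, m·ln c]`.  No normalization by the maximum is applied; SpecEn is
reported in bits and dispersion entropies in nats, deliberately following
the two formulas' respective logarithms.

**Spectral dispersion entropy** applies dispersion entropy (defaults
m = 2, c = 6, d = 1) to the frequency-ordered PSD bin sequence over
1–30 Hz, i.e. it measures the irregularity of the spectral profile rather
than of the time series.  The PSD *power* values are used directly (not
their square roots); a constant spectrum has σ = 0 under the quantizer and
is defined to have entropy 0 (single pattern) rather than raise, because
flat spectra are legal inputs.  A series shorter than `(m−1)d + 1` bins is
an error.

## Group statistics

Each feature is tested with classic one-way ANOVA across the three groups
and Tukey HSD pairwise post-hoc tests; unequal group sizes (the reference
cohort layout is 18/19/13) use the Tukey–Kramer form.  P-values are
reported raw per feature — **no correction across the feature family is
applied by default**, which matches the conventional per-channel reporting
style of this literature but inflates family-wise error; a
Benjamini–Hochberg option (`fdr=True`) is provided.  Both the omnibus p and
all three pairwise p-values are emitted, since either may be the quantity
of interest.

## Classification

Scenarios assemble feature blocks deterministically: A relative power (76),
B coherence (64), C SpecEn (19), D SpecDE (19), E = B + D (83).
Cross-validation is stratified by class (with 13 subjects in the smallest
group, unstratified 5-fold can starve folds), shuffled with a caller seed;
rows are sorted by subject id first so fold assignment is invariant to
input order.  Features are z-scored with training-fold statistics only —
necessary for distance-based k-NN across heterogeneous units (coherence in
[0,1] vs entropy in nats) and to avoid test-fold leakage.  Each subject is
predicted exactly once; the reported accuracy is the mean of per-fold
accuracies, and the confusion matrix is aggregated over folds.
Sensitivity/specificity/precision/F1 are computed from that aggregate
matrix as macro (unweighted) means of per-class one-vs-rest values;
fold-averaged variants of these can differ in the second decimal.

Classifier conventions: SVMs are one-vs-one with penalty C = 1; the
polynomial kernels use `(x·x′ + 1)^degree`; the Gaussian kernel is
`exp(−‖x−x′‖²/s²)` with scale `s = √p` for p predictors.  k-NN uses k = 1
(fine) or k = 10 (medium/cubic); "cubic" is Minkowski distance of order 3.
Vote ties are broken by the nearest neighbour among the tied classes, which
makes predictions deterministic.  A class never predicted gets precision 0
(with its F1 then 0) rather than NaN.

## Synthetic cohort generator

The generator exists because clinical recordings of this kind are shared
only on request; it emulates the three groups' published *directional*
signatures with controllable ground truth:

    channel = w·shared + (1−w)·private

per frequency band, where all sources are unit-variance band-limited
Gaussian noise (4th-order Butterworth band-pass of white noise), the
per-band standard deviations follow the group's target relative-power
profile, `w` is the coupling weight shared by all channels of a subject,
and a spectral-concentration knob narrows each band's occupied width around
its centre.  Channels are scaled to ~30 µV RMS.  Defaults
(normal → MCI → dementia):

| parameter | normal | MCI | dementia | emulates |
| --- | --- | --- | --- | --- |
| delta RP | 0.25 | 0.40 | 0.55 | slow-wave increase |
| theta RP | 0.20 | 0.22 | 0.22 | (fills remainder) |
| alpha RP | 0.30 | 0.23 | 0.15 | alpha decrease |
| beta RP | 0.25 | 0.15 | 0.08 | beta decrease |
| coupling w | 0.7 | 0.5 | 0.35 | coherence loss |
| bandwidth fraction | 1.0 | 0.7 | 0.45 | complexity loss |

Cohort layout defaults to 18/19/13 subjects at 250 Hz, 40 s per subject,
fully reproducible from (config, seed).  Delta sources are generated from
1 Hz up (not 0 Hz) so the pipeline's high-pass does not remove configured
power.  The MSC between two channels implied by amplitude weight w is
`w²/(w² + (1−w)²)` for unit-variance sources, monotone in w.

What the generator does **not** emulate: dipolar scalp topography and
volume conduction, 1/f background structure, nonstationarity, artifacts,
inter-subject variability beyond sampling noise, and realistic
class overlap — the default effect sizes separate the groups much more
cleanly than patients do.  Passing end-to-end tests therefore demonstrates
that the pipeline *recovers known ground truth and preserves orderings*,
not that clinical accuracy figures would be reproduced on real data.

## Numerical conventions and degenerate inputs

- Welch: 2 s Hamming, 75% overlap, constant detrend, one-sided density.
- Filter design at half-dB specs for zero-phase two-pass application.
- Wavelet boundary handling: symmetric extension; reconstructions trimmed
  to the input length.
- `round_half_up` (not banker's rounding) in the NCDF class map.
- σ = 0 series: class map degenerates to all-1, dispersion entropy 0.
- All-zero channels are an error for relative power (undefined ratio);
  zero in-band power is an error for spectral entropy.
- Coherence requires ≥ 2 Welch segments; shorter input is an error, not 1.
- Problem sizes in the test-suite and acceptance runs (40 s records,
  50-subject cohorts, 1000-replicate null calibrations) were chosen as the
  package's own defaults to keep estimator variance low while remaining
  quick to run.

## Known limitations

- The wavelet/Welch composition double-smooths band power; with db2 the
  effective band selectivity is ≈ 0.7 for narrowband signals (see above).
- Coherence is sensitive to the recording reference, which is assumed
  common and is not modelled.
- Raw per-feature p-values; see the multiplicity note above.
- The EDF writer covers continuous 16-bit single-rate signals only (it
  exists for round-tripping and synthetic export, not as a general
  clinical exporter).
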