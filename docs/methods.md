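# Methods

`apnea_mer` detects obstructive sleep apnea (OSA) events from five
polysomnography (PSG) channels — oxygen saturation (SaO2, 1 Hz), nasal-oral
airflow (10 Hz), thoracic and abdominal respiratory effort (10 Hz), and a
single-lead ECG (125 Hz). The method is a classical feature-engineering
pipeline: per-channel preprocessing, segmentation into labelled windows, a
66-feature multi-domain battery, a two-stage feature selection, and a
stacked ensemble ("multi-error-reduction", MER) classifier. This note
documents the model, its assumptions, the tunable parameters and the design
choices made where the procedure was genuinely open.

## Signal model and preprocessing

**SaO2.** Oximeter dropouts are treated as non-physiological whenever a
sample differs from its predecessor by strictly more than 8 percentage
points; such samples are replaced by the median of the first 10 s of the
raw trace. The scan compares each sample against the *cleaned* predecessor,
which makes the operation idempotent — a second pass changes nothing. The
8-point threshold and the 10-s reference window are configurable
(`PreprocessConfig.sao2_jump_pts`, fixed 10-sample reference).

**Airflow.** Baseline drift is removed by subtracting a 10-s running median
(edge values replicated over the first/last half window), followed by a
zero-phase 3rd-order Butterworth low-pass at 3 Hz and decimation to 1 Hz.
Note a structural property of the running median: a periodic signal whose
period does not divide the window length picks up a correlated baseline
component, so the composite chain attenuates e.g. a 0.25 Hz sine (period
4 s against a 10 s window) by roughly 30% while passing a 0.2 Hz sine
essentially unchanged. The filter stage itself is verified against the
analytic Butterworth magnitude response; the composite is tested with
integer-period probes.

**Respiratory effort.** 60-s running-median baseline subtraction and a
zero-phase 3rd-order Butterworth band-pass 0.05–4 Hz at the native 10 Hz.

**ECG.** Zero-phase 3rd-order Butterworth band-pass 0.05–40 Hz. All filters
in the package are applied forward–backward (`sosfiltfilt`): the phase
response is identically zero, so apnea-event boundaries are not shifted by
group delay; the effective magnitude response is the squared Butterworth
magnitude. Running medians use pandas' rolling median over an
edge-replicated padded array (O(n log w)), which keeps the 40-patient,
1-hour default cohort cheap.

**R-peak detection** is a Pan–Tompkins detector: 5–15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration, adaptive
signal/noise thresholds (THR = NPKI + 0.25·(SPKI − NPKI), exponential
updates 0.125/0.875), a 200 ms refractory period, search-back at half
threshold when the gap since the last beat exceeds 1.66× the running RR
average, and a 2-s learning phase for threshold initialization. Detected
integration peaks are refined to the local maximum of the band-passed ECG
within ±100 ms. On the synthetic generator's ECG at default noise the
detector recovers ≥ 99% of ground-truth beats within ±40 ms.

**RR correction.** Intervals outside 0.3–2.0 s, or deviating more than 20%
from the median of their five nearest neighbouring intervals, are replaced
by that local median clipped into the physiological range. The published
description names a correction method whose reference is not retrievable;
this concrete rule (range clamp + 5-neighbour median) is this package's
own rendering, with both thresholds configurable.

**EDR.** ECG-derived respiration uses the R-wave-area reading: per beat, a
symmetric 120 ms window (15 samples at 125 Hz) around the R peak has the
straight line through its first and last samples subtracted and the
residual averaged; the beat series is linearly interpolated to 1 Hz.
Respiration modulates QRS morphology, so the dominant EDR frequency tracks
the breathing rate (recovered to < 0.001 Hz on the generator).

## The 66-feature battery

Features are computed per segment with one code path for both segmentation
protocols (event-duration and fixed 60-s windows). Families: 12 SaO2
features (median, MM2, kurtosis, variance, min, mean, zero crossings,
Lempel–Ziv complexity, Poincaré SD1, Bel98/Abo98, and the mean 5th-order
Yule–Walker PSD over 0.016–0.05 Hz), 10 airflow features (moments, Welch
band means over 0–0.1 and 0.4–0.5 Hz with 5-sample Hann segments and
2-sample overlap, db3 level-3 wavelet means, complexity), 6 abdominal and 6
thoracic features (absolute-sum/moment statistics, db2 level-2 wavelet
means, and Yule–Walker band statistics averaged over 40-sample segments),
and 32 ECG features (RR statistics incl. one-sided NN50 and SDSD, ECG
moments, CV of EDR, spectral spread/decrease, sym3 level-7 entropy and
variance per detail level, RR wavelet spectral density, RR dominant
frequency in 0.03–0.5 Hz, ECG band means, serial correlations at lags 3 and
4, and two kernel-PCA summaries of the QRS matrix).

Decisions worth calling out:

- **MM2** counts adjacent pairs in the alternating local-extrema sequence
  (plateaus compressed, endpoints included) whose absolute difference
  exceeds 2 percentage points.
- **Bel98/Abo98** are in seconds (sample counts at 1 Hz); the threshold is
  0.98 × the window maximum, "below" strict.
- **SDSD_RR** is the standard deviation of successive RR differences (the
  standard meaning of the acronym); **tSD_RR** is the absolute difference
  of the RR standard deviations in the two halves of the segment, intervals
  assigned to halves by midpoint time.
- **WSD_RR** is the total sym3 detail-coefficient energy of the RR window
  divided by the window's interval count; the decomposition depth is
  min(7, dyadic maximum) for short RR windows.
- **var/kur** in the ECG block act on the ECG samples, not the RR series.
- **Normalized-band convention:** printed bands whose edges lie entirely
  above a channel's Nyquist frequency (the "80–100 Hz" bands on 10 Hz
  effort channels and on 125 Hz ECG Welch spectra) are read as percentages
  of Nyquist, i.e. the uppermost fifth of the spectrum; a band merely
  straddling Nyquist is clipped. This is configurable in spirit — the band
  statistic takes arbitrary edges — and is the only physically consistent
  reading of those band labels at the stated rates.
- **Lempel–Ziv complexity** binarizes at the window median (≥ median → 1),
  parses with LZ76 (self-overlap allowed), and normalizes the phrase count
  as c(n)·log2(n)/n. A trailing phrase still reproducible from the past
  when the window ends does not increment the count, so a constant window
  has c = 1. The implementation is verified against an exhaustive
  substring-set parser on all 4096 binary strings of length ≤ 12.
- **Kernel PCA on QRS matrices** uses an RBF kernel with the median
  pairwise distance as bandwidth (deterministic, no free parameter), a
  double-centred kernel matrix, and eigenvalues clipped at zero; reported
  are λ1 and λ2/Σλ. Fewer than 3 beats, or identical beats, degrade to
  (0, 0) with a warning rather than failing a whole window.
- **Kurtosis** is Pearson (normal → 3); constant windows return 0.
- Wavelet decompositions use periodization padding, which is exactly
  orthogonal (Parseval to machine precision) when the length divides
  2^level; odd-length halving introduces a boundary sample and a relative
  energy error of order 1e-4 on arbitrary lengths, which is irrelevant for
  the features but is why Parseval identities are asserted on
  dyadic-compatible lengths.

## Segmentation and labels

Intervals are half-open `[start, end)`, times in seconds from record start,
sample index = floor(t·fs), 0-based. Event-duration segmentation emits one
segment per annotation. Window segmentation tiles the record with 60-s
windows (trailing partial window dropped) and labels a window apnea iff its
total overlap with apnea annotations is at least 10 s — the clinical
minimum event duration — with the threshold configurable. The overlap rule
is monotone: more apnea overlap can never turn an apnea window normal.

## Two-stage feature selection

**Stage 1 (λ-counting).** Per patient with at least two segments of each
class, every feature is tested apnea-vs-normal with a one-way ANOVA
(positive iff p < 0.05) and a Wilcoxon rank-sum test (positive iff rejected
at 0.05; the rejection indicator, not a literal p-value, is the criterion).
A feature's λ is the number of patients where both tests are positive, so
λ is bounded by the processed patient count and, for the rank-sum
component, invariant under strictly monotone feature transforms. Features
survive iff λ strictly exceeds half the processed patients. No
multiple-testing correction is applied within Stage 1: counting across
patients is itself the aggregation device. Survivors are grouped into (by
default) four ordered classes by splitting the λ-sorted list at its three
largest consecutive gaps.

**Stage 2 (SVM hill climb).** Candidates are the cumulative class unions
(A, AB, ABC, ABCD) plus the all-feature baseline. Each candidate is scored
on a held-out split by a 21-configuration SVM grid — RBF widths σ ∈ {1, 5,
25}, polynomial degrees d ∈ {2, 3, 4} with kernel (x·y + 1)^d, and linear,
each crossed with regularization R ∈ {0.2, 1, 10}; features are
standardized on the training split. The chosen candidate is the one with
the highest mean AUC among those whose best accuracy is within 1 percentage
point of the overall best (accuracy adjudicates first, AUC breaks
near-ties). A λ-ordered prefix variant (`hill_climb_features`) starts from
the single best feature and accepts the shortest prefix matching the
all-feature gold standard. Splits are always at patient level; before
selection the training table is cleaned (any |z| > 3 feature drops the row)
and the majority class undersampled to the minority count.

## The MER stacked classifier

Level 0 holds four gradient-boosted tree families: sklearn
GradientBoosting (150 trees, depth 3), sklearn HistGradientBoosting (200
iterations, depth 6), XGBoost and LightGBM (200 trees, depth 6, learning
rate 0.1 throughout) — modest fixed settings, no hyperparameter search.
Base learners are pluggable: anything with `fit`/`predict_proba` can stand
in (the tests exercise an oracle stand-in). Meta-features are out-of-fold
apnea probabilities from a stratified, patient-grouped k-fold (default
k = 5): every row is scored by models that never saw it, and the fold
assignment verifiably changes the meta table (a leakage canary in the test
suite). The meta-learner is a feed-forward network with 4 inputs, one
hidden layer of 4 logistic units and a single sigmoid output, trained on
the cross-entropy loss with full-batch L-BFGS (α = 0.01, ≤ 500 iterations)
— at this size full-batch second-order optimization converges
deterministically where stochastic updates stall on the initial plateau.
Deployment refits the bases on the whole training table; prediction feeds
the 4 base probabilities through the meta-network and thresholds at 0.5.

Evaluation uses sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/(P+N) with apnea positive, and trapezoidal ROC AUC (equal to the
Mann–Whitney statistic, which the tests assert). Zero-denominator ratios
return 0 with a warning. The standard ROC ideal — sensitivity and
specificity both 1 giving AUC 1 — is implemented.

## Synthetic cohorts

The generator emulates exactly the signatures the battery targets, per
patient and fully seeded (per-patient child seeds derive from the cohort
seed, so cohorts are bitwise reproducible):

- airflow: breathing sinusoid (0.25 Hz nominal, ±10% per patient) whose
  envelope collapses to 10% of basal during events with 2-s cosine ramps;
- effort: attenuated during obstructive events with the abdomen
  counter-phased (paradoxical breathing); an optional central mode
  collapses effort together with airflow;
- SaO2: per-patient baseline 96–98%, a desaturation ramp of 3–10 points
  starting 15 s after event onset with exponential resaturation (τ = 8 s),
  quantized to 0.1 point, plus occasional single-sample dropout spikes
  (> 8 points) so the artifact cleaner is exercised;
- RR: respiratory sinus arrhythmia (4%), progressive lengthening up to 15%
  during events, 10% shortening in the 5 s after, 1% beat jitter;
- ECG: a fixed QRS-T template placed at the cumulative RR times, its
  amplitude modulated by respiration (which makes EDR recoverable),
  plus 0.15 Hz baseline wander and white noise.

Defaults are one hour per record, 40 patients, 15 events/hour (a
moderate-to-severe OSA clinic population), event durations 10–60 s, and
noise levels (SaO2 0.15 pts, airflow/effort 0.03 a.u., ECG 0.02 mV) at
which the channels look clean but not sterile. What the generator does
*not* model: hypopneas and arousals, sleep-stage structure, movement and
electrode artifacts beyond SaO2 spikes, realistic HRV spectra, or
inter-channel delays other than the fixed desaturation lag. Passing tests
therefore demonstrate that the pipeline recovers the signatures it claims
to exploit under controlled conditions — not clinical performance on real
polysomnography, which depends on exactly the artifact structure the
generator idealizes away.

A second generator (`synthetic_feature_table`) produces feature tables with
known structure — 10 features whose within-patient class means differ by
1.5 SD and 56 pure-noise features — used to measure Stage-1 recovery
(retention of informative features, rejection of noise).

## Problem sizes and numerical choices

The default study conditions (40 patients × 1 h, 60-s windows → 2400
segments) run end-to-end in about a minute on one CPU; ground-truth R-peak
recovery uses 3 one-hour records (~11k beats) and Stage-1 recovery uses 20
independent 40-patient tables. PSDs use nfft = 256 so the narrow 1-Hz-rate
bands contain multiple grid points; Welch overlap "2.5 samples" is floored
to 2; the Yule–Walker order is 5 everywhere. Degenerate inputs (constant
windows, too few beats/intervals) produce defined zero values with logged
warnings rather than NaNs — a fuzz test asserts the full battery is finite
on generator output.

## Known limitations

- The event-duration protocol depends on explicit normal annotations (or
  gap inference, which the reader supports); the generator marks normal
  stretches only after a 30-s post-event recovery exclusion.
- The hill climb explores only cumulative class unions or λ-ordered
  prefixes, as specified — it is not a general subset search.
- With strongly separated synthetic classes the base learners approach
  ceiling accuracy and share their few errors (desaturation-recovery
  windows adjacent to events), so the stacked model's margin over the best
  single base is small and can be slightly negative on some patient splits;
  the combiner's value shows when base errors are complementary.
- EDF export is not implemented (reading is, via the optional `mne`
  extra); the reference record dialect is per-channel CSV + JSON layout.
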