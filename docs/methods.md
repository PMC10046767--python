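# Methods

## Detector model

The voice-activity detector is a per-frame likelihood-ratio test over six
spectral sub-bands (80–250, 250–500, 500–1000, 1000–2000, 2000–3000,
3000–4000 Hz). Frames are 0.03 s, non-overlapping; each frame is
Hann-windowed and its band energy is the sum of squared rfft magnitudes
over the band's bins (half-open intervals `[low, high)`), floored at
`1e-12` and expressed in dB. Energies are kept on the log scale because
two-component Gaussian mixtures over raw linear energy are pathologically
scaled; log-energy is the standard domain for energy-based VAD.

Per band, log-energy is scored under a silent-state and a voiced-state
two-component 1-D Gaussian mixture. The per-band ratio uses the base-2
logarithm; both densities are floored at `1e-12` so ratios stay bounded
without branching. The voiced decision is
`E_t > Tm` **and** (`any L_i > T_τ` **or** `L_t > T_a`). The per-band
condition is interpreted as *any band exceeding* `T_τ`: a per-band
threshold over six values is otherwise ill-defined, and the any-band
reading makes the two branches complementary (narrowband evidence vs
broadband aggregate). No hangover smoothing is applied by default: the
encoded sequence should reflect raw frame decisions.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| frame duration | analysis step | 0.03 s | matches the sequence resolution used throughout |
| `K_i` | band weights of `L_t` | 1/6 each | no prior reason to favour a band |
| `T_τ` | per-band ratio threshold | 1.0 | one bit of evidence in a single band |
| `T_a` | total ratio threshold | 0.5 | half a bit averaged across bands |
| `Tm` | energy gate (dB) | 5th pct of `E_t` + 6 dB | sits just above the recording's noise floor |

### Fitting

No published parameter values exist for the mixtures, so the model is fit
on calibration audio (≥ 10 s): per band, pooled frame log-energies are
modelled with a four-component EM fit initialised at the 10/30/70/90th
percentiles; the two lowest-mean components become the silent mixture and
the two highest the voiced mixture. Forcing the state assignment by energy
ordering removes label switching and makes the fit deterministic (fixed
initialisation, no random restarts). Constant-energy calibration is
rejected explicitly.

## Pause encoding and classification

Frame decisions become a binary sequence (1 = voiced), segmented into
`floor(4.0/0.03) = 133`-frame segments with the trailing remainder
dropped — fixed-length inputs are required by the classifiers and padding
would fabricate silent frames. Each segment inherits its subject's
diagnosis label (the usual multiple-instance assumption). Subject labels
are the majority over segment predictions; exact ties resolve to AD,
because in a screening context a false positive is cheaper than a miss.
The cross-stream ensemble pools *segment-level* votes from all streams
before taking the majority: fusing at the subject level with two streams
would guarantee frequent ties, while pooled votes weight each stream by
its segment count.

Classifier defaults: LDA (with automatic covariance shrinkage once the
feature dimension exceeds 500, as needed for the 6373-dimensional set),
Gini decision tree, 5-nearest-neighbours (Euclidean), linear-kernel SVM
with C = 1, and 100 bagged decision trees. Distance/margin-based models
(LDA, KNN, SVM) see z-scored features with statistics from the training
split only; trees see raw features. Train/test splits are always
subject-disjoint (no subject contributes segments to both sides) and
stratified by class; each run reshuffles with a seed derived as
`(seed * 1000003 + run) mod 2^31`.

## Feature sets

ComParE 2013 (6373 features) and eGeMAPS (88) are extracted through the
openSMILE toolkit when it is installed. Because many deployment
environments lack the toolkit, a **surrogate** backend is provided: 11
spectral low-level descriptors per 25 ms/10 ms frame (log energy,
zero-crossing rate, spectral centroid/bandwidth/rolloff/flux/flatness and
four mel-cepstral coefficients) summarised by 8 functionals (mean, sd,
skewness, kurtosis, min, max, median, slope) give an 88-vector; the
ComParE-sized vector appends a fixed seeded linear expansion of those 88
to reach 6373. Surrogate vectors preserve the published cardinalities and
carry real spectral information, but they are *not* openSMILE features:
results on the surrogate characterise the pipeline, not the reference
feature sets. The expansion seed is a constant — it is part of the
surrogate format, not an experiment parameter.

## Evaluation

Metrics follow the confusion-matrix definitions with AD as the positive
class. Precision, recall and F1 are reported as missing (NaN, with a
warning) when their denominator is zero; coercing them to 0 would bias
averages across runs. The two-way ANOVA uses type-II sums of squares
(identical to type-I/III on the balanced designs it requires) on run-level
accuracies with feature and classifier as factors; a significant
interaction triggers an all-pairs Tukey HSD over the cells, and the cells
not significantly below the best cell form the reported best group. An
all-constant table yields 0/0 F ratios, reported as F = 0, p = 1 (no
evidence of any effect).

## Synthetic corpus generator

Recordings alternate voiced intervals and silent pauses with exponential
(memoryless) durations; defaults are 20 subjects per group, 120 s per
recording, voiced intervals averaging 1.5 s in both groups, pauses
averaging 0.5 s for controls and 1.5 s for the AD group (a 3× contrast),
voiced amplitude 0.3 with a noise floor of 0.003 (−40 dB relative).
Voiced intervals are harmonic complexes (fundamental uniform in
100–220 Hz, 1/k partial amplitudes up to 4 kHz, random phases, 10 ms
cosine ramps) synthesised by wavetable lookup with linear phase
interpolation — the interpolation error is ≈ −68 dB, below the noise
floor. The noise floor is band-limited to 80–4000 Hz, the detector's
analysis range. Ground-truth labels live on the 0.03 s frame grid: a
frame is voiced when more than half of it overlaps a voiced interval,
which makes detector accuracy exactly scorable. All randomness derives
from one corpus seed through per-recording spawned seeds.

The generator emulates only the pause *structure* of the two groups. It
does not model linguistic content, speaker identity, channel effects,
filled pauses ("uh"/"um"), or demographic structure — a green end-to-end
test therefore establishes that the pipeline recovers group differences
in pause timing from raw audio, not that it detects AD in real speech.

## Numerical and design notes

- Stereo is downmixed by the arithmetic channel mean; resampling is
  polyphase and band-limited; preprocessing is idempotent bit-for-bit.
- A 1.00 s signal at 44,100 Hz framed at 0.03 s yields 33 frames with 441
  trailing samples dropped (`44100 − 33·1323`).
- The batched VAD path is algebraically identical to per-frame
  classification; FFT batching can differ from the scalar path by ~1 ulp.
- Static mixture parameters by default. Adaptation (e.g. exponential
  moving averages of silent means) and median-filter label smoothing are
  deliberately not enabled anywhere in the shipped defaults.

## Known limitations

- The surrogate feature backend makes feature-set *cardinality* and
  pipeline behaviour testable offline but cannot reproduce reference
  openSMILE feature values.
- The detector's fitted mixtures are corpus-specific; a model fitted on
  one acoustic environment does not transfer to a very different one (see
  the self-calibration used in the tone test).
- Exponential interval durations are a modelling convenience; real pause
  duration distributions are heavier-tailed.
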