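# Methods

This note documents the models and procedures implemented in `cohorttrf`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## The cohort model and its information-theoretic quantities

A pronunciation lexicon assigns each wordform `w` a phoneme sequence and a
positive frequency count. Hearing a word phoneme by phoneme, the *cohort*
at position `i` is the set of wordforms whose pronunciations begin with the
phonemes heard so far, `k_1 .. k_i`, with posterior probabilities obtained
by renormalizing the frequencies of the surviving entries. Two quantities
follow, both in bits (log base 2 throughout):

- **phoneme surprisal**  `s_i = -log2 p(k_i | k_1 .. k_{i-1})`, where the
  conditional probability is the summed posterior mass of the previous
  cohort's members whose next phoneme is `k_i`. For `i = 1` the "previous
  cohort" is the whole-lexicon prior.
- **cohort entropy**  `H_i = -sum_w p(w | k_1 .. k_i) log2 p(w | ...)`,
  the Shannon entropy of the posterior over wordforms after `k_i`.

Design choices where the procedure is underdetermined:

- **Homophones** remain distinct wordforms (the entropy sum runs over
  wordforms); `Lexicon.merge_homophones()` provides the alternative.
- **Frequency floor**: zero or missing counts are replaced by 1 (counts
  must be positive for the probabilities to exist).
- **Out-of-lexicon prefixes** are a hard error by default; a lenient mode
  backs off to the previous distribution with `epsilon = 1/total_frequency`
  and flags the affected positions.
- **Words that are prefixes of longer words**: no end-of-word symbol is
  added; the cohort at a word's last phoneme legitimately retains longer
  competitors.
- Raw counts weight the cohort probabilities; a `frequency_transform` hook
  accepts alternatives (e.g. log counts). There is no solid ground for a
  transform, so identity is the default.

## Predictor time series

All predictors live on a 100 Hz master clock. Event times map to the
nearest sample with round-half-up; coincident events sum.

- **Envelope spectrogram**: a 256-channel fourth-order gammatone filterbank
  with center frequencies equally spaced on the ERB-number scale between
  20 and 5000 Hz; rectified filter outputs are averaged within 10 ms output
  frames and binned into 8 contiguous ERB bands (mean over the 32
  constituent channels, keeping band magnitudes comparable).
- **Onset spectrogram**: per band, the half-wave-rectified first difference
  of the floored log envelope after a 3-sample moving average. This is a
  transparent stand-in for neural acoustic-edge models; it shares the
  properties that matter for a control predictor (silence on steady state
  and decay, localized peaks at energy onsets) and sits behind a named
  interface so a different edge extractor can be swapped in.
- **Impulse predictors**: `word_onset` (unit impulse at each word onset),
  `phoneme_onset` (unit impulses at non-initial phoneme onsets), and
  surprisal/entropy channels carrying the cohort quantities at *all*
  phoneme onsets, including the first (the default, joint model). Optional
  splits produce initial/non-initial variants or per-word-class variants
  (e.g. mono- vs multisyllabic words). Note that a phoneme whose surprisal
  or entropy is exactly zero leaves its sample at zero — the number of
  nonzero samples equals the number of *nonzero values*, not the phoneme
  count.
- **Standardization**: channels are centered and then divided by the mean
  absolute value of the centered signal, in that order; responses are
  treated the same way. All boosting step sizes are in these standardized
  units.

## TRF estimation by l1 boosting

The response is modelled as `yhat_t = sum_i sum_tau h[i,tau] x[i,t-tau]`
with delays spanning [-100, 1000) ms. Kernels are expressed in a basis of
50 ms wide Hamming windows, one centered at every 10 ms delay sample (110
elements), truncated at the window edges.

Boosting proposes `+step` and `-step` for every (channel, basis element)
coefficient, applies the proposal with the greatest reduction in training
l1 error, and uses a held-out validation segment for early stopping: if the
selected proposal would increase validation error, its entire predictor
channel is frozen instead (no further updates to any of its coefficients).
Estimation stops when every channel is frozen, no proposal reduces training
error, or `max_iter` is reached; the returned weights are the snapshot with
minimal validation error. Ties between equal-error proposals resolve to the
lowest (channel, basis element) index with `+` before `-`, making the
procedure fully deterministic.

- **Default step**: 0.005 standardized units; the scaled-down simulations
  in the test-suite use 0.02 (sessions are short, kernels must be reachable
  in few iterations). Step size trades resolution for iterations; recovery
  correlations above 0.99 are reached at either setting on clean data.
- **Nested cross-validation**: `k` contiguous near-equal partitions; each
  serves as test data once; within the remaining `k-1`, each serves as
  validation once, so `k*(k-1)` models are trained. The `k-1` models per
  test fold are averaged before predicting the test partition; the final
  kernel is the mean of all `k*(k-1)` estimates. `k >= 3` is required
  (train/validation/test must be distinct).
- **Predictive power**: `1 - sum|y - yhat| / sum|y - mean(y)|` on the
  concatenated held-out predictions (an l1 analogue of R^2, consistent with
  the training loss; may be negative). The squared-error variant and the
  held-out Pearson r are also computed.
- **Unique predictive power** of a predictor is the drop in held-out power
  when the model is *refit from scratch* without it — never by zeroing the
  full model's weights.

### Identifiability caveat

Binary onset covariates share their event times with the value-scaled
surprisal/entropy channels. Greedy l1 boosting assigns shared variance to
whichever channel reduces error fastest, so the *individual kernels* of
such collinear channel sets are not identifiable at finite data, even at
high SNR — only the value-scaled channels' kernels (identified by their
value variation) and the *model comparison* quantities are. The kernel
recovery experiment therefore scores the surprisal/entropy kernels in a
two-channel design; the model-comparison pipeline keeps the covariates,
whose role is to absorb onset-locked response components, not to be
interpreted.

## Group statistics

- **Smoothing**: Gaussian kernel over inter-source distance (default
  SD 5 mm), truncated at 3 SD, weights normalized per source.
- **TFCE**: `sum_h extent(h)^E * h^H * dh` with `E = 0.5`, `H = 2` (the
  method's standard defaults) and `dh = max|stat|/100` unless given.
  Negative values are enhanced on the negated map and negated, giving an
  odd (sign-symmetric) transform.
- **Permutation tests**: paired condition-label tests are implemented as
  sign flips of within-subject differences (equivalent for two
  conditions); one-sample tests flip subject signs directly. The null is
  the maximum (|TFCE| for two-tailed) over sources per permutation;
  `p = (1 + #{null >= obs}) / (n_perm + 1)`. When the full sign-flip orbit
  `2^n` is no larger than `n_perm` the test enumerates it exactly instead
  of sampling (smaller, deterministic p-values; with fewer than 6 subjects
  a two-tailed max-statistic test cannot reach p <= 0.05 at all).
  Model-improvement comparisons in the pipeline are one-tailed: the
  question is whether adding a predictor *improves* held-out power.
- **ROI summary**: per-subject ROI mean; Cohen's d = mean/SD (ddof 1).
  Optionally the two hemispheres are tested against each other first and
  averaged only when not significantly different.
- **Ratio interaction test**: per subject, the ratio of unique entropy
  power to unique surprisal power; groups compared by pooled-variance
  two-sample t (`df = n1 + n2 - 2`; Welch variant available). The ratio is
  undefined when a surprisal delta is exactly zero (error naming the
  subject).
- **TRF PCA**: per subject, the first SVD component of the sources-by-time
  kernel, sign-aligned so the orientation-weighted mean current vector
  points upward. The upward rule pins the spatial map's sign; the time
  course then necessarily carries the data's sign (map x course
  reconstructs the kernel), so negating a subject's kernel leaves the map
  invariant and flips the course.

## The synthetic-study generator

The generator emulates the structure of a two-group listening study:
isolated words with a 267 ms interstimulus interval versus pause-free
continuous speech.

- **Lexicon**: random unique pronunciations over a deliberately small
  10-symbol inventory with word lengths 2–5. The small inventory produces
  the heavy prefix-sharing that real phonotactics gives a natural lexicon;
  with a large inventory cohorts collapse to singletons after one or two
  phonemes and entropy carries almost no variance. Frequencies follow
  `f(rank) = N / rank^s` exactly (Zipf exponent `s = 1` by default), with
  ranks assigned in random order. At these settings the surprisal/entropy
  value correlation comes out near 0.55; it is controllable through the
  lexicon shape, not hard-coded.
- **Sessions**: words sampled by frequency; phoneme onsets spaced by
  1/speech-rate (default 8 phonemes/s, between typical isolated-word and
  audiobook rates); single-word mode inserts the 267 ms ISI after each
  word. Defaults are 1,000 words per session and groups of 18 (single-word)
  and 12 (continuous) subjects, mirroring the study structure the generator
  emulates.
- **Ground-truth kernels**: a positive Gaussian lobe at 100 ms and a
  negative lobe (x -0.7) at 350 ms, each with 50 ms FWHM, projected into
  the Hamming basis so the truth lies exactly in the estimator's span.
  Gains are per channel and per group; the default study gives entropy
  gain 0 in the single-word group and 1 in the continuous group, with
  surprisal gain 1 in both — the built-in dissociation.
- **Recordings**: sources inside a configurable ROI of a 2-D source grid
  carry the summed convolution of predictors with kernels (spatial
  weight 1); all sources receive white Gaussian noise with
  SD = RMS(signal)/SNR (default SNR 2). Per-subject lognormal gain jitter
  (sigma 0.2) is applied jointly to all channels, so within-subject gain
  ratios — the quantity the interaction test uses — are preserved.

What the generator does *not* emulate: correlated (1/f, physiological)
noise, forward-model leakage between sources, head geometry, coarticulation
and variable phoneme durations, or behavioral attention effects. Passing
the validation suite therefore demonstrates the correctness and
calibration of the *analysis chain*, not robustness to every property of
real neural recordings.

## Validation problem sizes

The validation experiments run at reduced sizes chosen once as a balance
between statistical resolution and a single-CPU workflow:

- kernel recovery: one 5-minute continuous session (~685 words), SNR 10,
  two ROI sources, single train/validation split;
- permutation calibration: 200 null replicates per test, 500 permutations,
  10 subjects, 16-source grid / 30-point time axis;
- dissociation power: 20 replicates of a 6+6-subject study, 80 words per
  session, SNR 2, k = 3, one ROI source;
- interaction null calibration: 100 replicates at 5+5 subjects, 40 words;
- event-permutation control: 40 replicates, 60 words, k = 3.

`scripts/acceptance.py` re-runs all of the above from scratch and writes
the measured quantities to JSON; every number in it is computed at run
time.

## Known limitations

- The acoustic edge extractor is a documented stand-in, not a fit to any
  published neural model.
- The boosting freeze rule operates on whole channels; a per-coefficient
  variant would stop less aggressively but is not what the estimator
  specifies.
- Real-data mode expects forced alignments and source-localized responses
  produced elsewhere; no preprocessing (filtering, artifact rejection,
  source localization) is included.
- With very small groups the exact sign-flip orbit bounds attainable
  p-values; the pipeline reports them as computed rather than refusing.
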