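# Methods

`f0track` analyzes how the early EEG response at the fundamental
frequency (f0) of continuous speech is modulated, word by word, by
acoustic and linguistic properties of the words.  This note documents
the models, the choices behind them, and what the synthetic experiments
do and do not establish.

## Stimulus features

Two one-dimensional features summarize the speech signal at the EEG
sampling rate (1 kHz):

* **Fundamental waveform (f1).**  The speech recording band-pass
  filtered to the speaker's pitch range.  The band is the 5th..95th
  percentile of the voiced frames of a pitch track (linear interpolation
  between order statistics, rounded to the nearest Hz; a typical male
  narrator gives roughly 75–150 Hz).  The filter is a linear-phase
  Hamming-window FIR applied forward once with group-delay compensation
  (zero-phase).  The filter length follows the Hamming transition rule
  `numtaps ≈ 3.3 fs / Δf` using the narrower (lower) transition band —
  18.7 Hz at audio rates, 12.5 Hz for the 50–280 Hz EEG filter — which
  reproduces the reference designs of roughly 7.8 k taps at 44.1 kHz and
  265 taps at 1 kHz.  The upper transition bandwidths carried in
  `BandSpec` (38.12 / 70 Hz) are recorded metadata; the exact design
  heuristic that produced them upstream is not fully specified, so we do
  not reverse-engineer it.
* **High-frequency envelope modulation (f2).**  The audio is passed
  through an auditory-periphery approximation — a log-spaced filterbank
  (128 channels, 180–7000 Hz default) of 4th-order Butterworth bands
  with ERB-scale bandwidths, half-wave rectification, 8 ms leaky
  integration and cube-root compression, sampled at 1 ms steps.
  ERB-scale bandwidths matter: they leave neighboring harmonics
  unresolved in high-frequency channels, so their beating at f0 — the
  quantity of interest — survives.  Channels with center frequency above
  300 Hz are band-pass filtered in the pitch band (same FIR design) and
  averaged.  Channels are demeaned before this filter because the FIR's
  residual DC gain would otherwise leak the large rectified-energy
  offset.  Any cochlear model producing a (time × channel) energy array
  can be substituted through the `AuditorySpectrogram` container.

Pitch tracking is a plain normalized-autocorrelation tracker (40 ms
frames, 10 ms steps, parabolic peak refinement, voicing by a 0.45
autocorrelation threshold); precomputed tracks in CSV are accepted
everywhere a `PitchTrack` is.

## Forward model: complex TRF

The EEG at channel c is modeled as a lagged linear response to both
features and their Hilbert transforms,

    r(t, c) = Σ_j Σ_τ [ α_re(τ,c,j) f_j(t−τ) + α_im(τ,c,j) f_j^h(t−τ) ],

with α = α_re + i·α_im read as one complex kernel per (lag, channel,
feature).  Lags span −250..499 ms (750 lags at 1 kHz); τ > 0 means the
stimulus precedes the EEG.  Designs use valid samples only (no zero
padding), which avoids edge artifacts that would bias short-latency
estimates.  The Hilbert transform is computed once per recording part
before lagging.  Inputs are standardized per recording part.  The ridge
penalty is expressed in units of the mean eigenvalue of the design
covariance, λ = λ_n · e_m with e_m = trace(X'X/n)/p; the forward model
uses λ_n = 1.

Normal equations are accumulated from the raw series by an exact
shifted-window recursion (one small matrix product per lag for the first
row of each series-pair block, then O(T²) diagonal updates), verified
against the explicit design matrix to 1e-10 relative error in the test
suite.  This keeps the 3000-column forward design tractable on long
recordings without materializing it.

**Lag significance.**  Null TRFs are fitted with per-part time-reversed
features.  Population null models are bootstrapped by resampling
subjects with replacement (10,000 draws by default), and per-lag
empirical p-values use the add-one estimator with non-strict exceedance,
p = (1 + #{draws ≥ observed}) / (1 + n_boot), then Benjamini–Yekutieli
correction across lags per feature.

**Peak latency at finite SNR.**  Narrowband regressors load noise onto
the lag-window edges of a ridge solution; at low SNR this can exceed the
true response peak in the plain channel-averaged magnitude profile.  The
null models share exactly this stimulus-statistics-driven structure, so
`population_peak_lags` subtracts the mean null profile before taking the
argmax.  Noiseless recovery needs no correction.

## Backward model: stimulus reconstruction

Each feature is reconstructed from lagged EEG with real-valued
coefficients.  A decoder lag τ ∈ [−5, 49] ms means the EEG sample at
t + τ contributes to the feature estimate at t: the decoder reads the
EEG window *following* each stimulus sample, where the causal 11–18 ms
response lives.  Decoders are fitted for 51 log-spaced λ_n between
1e−10 and 1e10, both features simultaneously, and evaluated by
contiguous five-fold cross-validation over the recording parts
(near-equal durations).  Reconstruction quality is Pearson's r within
test segments — fixed-duration windows or word spans; segments shorter
than 20 samples are skipped and counted, zero-variance segments are
skipped with a log entry.  Segment scores are aggregated by arithmetic
mean (a Fisher-z switch exists).  The segment-duration comparison runs
Friedman tests across durations, pairwise Wilcoxon signed-rank tests
(exact for n ≤ 25, zeros dropped; identical columns report statistic 0,
p = 1 by the average-rank tie convention) and per-duration
feature-vs-feature tests, each family BY-corrected.

## Word-level features

Seven standardized predictors per word.  Acoustic, from the pitch track
over the word's voiced part (half-open intervals, frames assigned by
center time): mean f0; rate of f0 change (mean |Δf0/Δt| within voiced
intervals, never across gaps); voiced duration.  Linguistic, in nats
from a pluggable probability source: inverted word frequency −ln P(w);
surprisal −ln P(w_n | context); precision 1/E(w_n) where E is the
conditional next-word entropy (clamped at 1e-6 nats with a flag when the
context is deterministic); and precision × surprisal.  Words without a
voiced part are flagged and excluded from scoring.  Out-of-vocabulary
handling and the vocabulary over which entropies were computed are the
probability source's business and recorded as metadata.

## Per-word response strength

For each retained word, the held-out decoders of its cross-validation
fold reconstruct the features; Pearson's r over the word's voiced
samples (≥ 20, shorter flagged) is the raw score, per λ_n, for the
actual decoders and for null decoders trained on time-reversed features.
A word's null score is the score the time-reversed pipeline assigns to
it: the null reconstruction is evaluated on the word's mirrored window
(equivalently, flipped in time and scored on the word's own samples
against the actual features), so the voicing composition and length of
the scored segment match between model and null.  The null-corrected
score takes independent maxima over λ,

    r(i) = max_λ r_model(i) − max_λ r_null(i),

and may be negative.  Corrected scores are averaged (unweighted) over
subjects and standardized over words, per feature.

Two properties of this correction are worth knowing, both measured with
the synthetic generator and invisible at real-data noise levels:

* The null-side maximum inflates by roughly c·σ(n_word) — null scores
  across λ behave like more nearly independent draws than model scores,
  which share their noise.  When per-word model scores are reliable the
  inflations no longer cancel: the corrected score acquires a spurious
  positive dependence on word duration, and even under an exact global
  null the corrected mean is slightly negative (≈ 0.07 word-level SD in
  our conditions).  At fixed λ the null-score mean is exactly zero.
* Pearson's r over short autocorrelated windows has the usual
  small-sample attenuation, E[r̂] ≈ ρ(1 − (1−ρ²)/(2 n_eff)) with n_eff
  the number of effective cycles, which gives reliable per-word model
  scores a small positive duration slope (~0.003 SD/SD at our default
  conditions).  This scales with ρ exactly as the transmission of
  planted gain effects does, so no SNR makes the scores sensitive and
  duration-unbiased at once.

The package therefore exposes both procedures; the synthetic end-to-end
study uses the fixed λ_n = 1 control variant, which the real study
validated against the per-word maxima on its own data.

## Outlier screening and stepwise hierarchical regression

Words are screened with an isolation forest (1000 trees, subsample 256)
over the eight standardized descriptors (seven features + score); the
anomaly score 2^(−E[h]/c(n)) with c(n) = 2H(n−1) − 2(n−1)/n is
thresholded at the automatic 0.5.  The regression then fits the features
in a fixed hierarchy — mean f0, f0 rate, voiced duration, inverted
frequency, precision, surprisal, interaction — one at a time: each step
is a single-predictor, no-intercept Huber regression (IRLS, tuning
constant 1.345, MAD scale re-estimated per iteration, convergence 1e-8,
at most 200 iterations) on the running residuals, whose fitted values
are subtracted before the next step.  Shared variance is thereby
assigned conservatively to the earlier (acoustic) features; for
correlated predictors the result is order-dependent by design.  The
seven p-values (two-sided normal on z = coeff/SE) are BY-corrected as
one family per response feature.  The standard error is the
x²-weighted sandwich estimate — per-word score noise scales with word
length, and the unweighted form under-covers.  Huber reweighting makes
the step fits only approximately orthogonal projections; with orthogonal
predictors the stepwise coefficients match simple-regression slopes to
about 1e-2 under Gaussian noise, not machine precision.

## Synthetic data

The generator emulates the study conditions end to end with exact
ground truth.

* **Words.**  Lognormal voiced durations (mean 0.19 s; with unvoiced
  padding the mean word length is ≈ 0.26 s), lognormal gaps (60 ms),
  words split into 5 equal recording parts.
* **Correlated features.**  A Gaussian copula whose score correlation is
  forced to the target by empirical whitening/recoloring, with
  analytically Pearson-corrected marginal transforms (normal and
  lognormal).  The default 7×7 target reproduces the correlation
  structure of natural story material (surprisal strongly correlated
  with its interaction term, with inverted frequency and with voiced
  duration; the f0 rate nearly uncorrelated with everything).  The
  interaction column is the product of the sampled precision and
  surprisal, as its definition requires; a full 7-dimensional copula
  mode exists for correlation-structure checks.
* **Stimulus.**  Voiced spans carry sin(2π∫f0 dt) with per-word mean f0
  (normal, 107.2 ± 24.8 Hz, clipped to 60–180) and a linear drift of
  slope ±f0_rate; f2 is the same oscillation at an independent random
  phase per word (this alone decorrelates the features).  10 ms
  onset/offset ramps; unvoiced stretches carry 5%-RMS band-limited
  background, as band-passing real recordings leaves — exact digital
  silence would make time-reversed null scoring degenerate over mirrored
  gaps.  An audio-rate harmonic-complex renderer (`synthesize_stimulus`)
  feeds the full front end at small scale; large studies generate the
  two features directly at 1 kHz.
* **EEG.**  channel = Σ_j w_c · conv(gain_i·f_j, k_j) + noise.  Kernels
  are Gaussian-windowed band-limited pulses (peaks 11 and 18 ms,
  envelope σ 6 ms, amplitudes 1 and 2, pulse band 10–480 Hz): the wide
  flat band keeps the response gain independent of a word's pitch —
  a fixed-carrier kernel would plant a spurious mean-f0 effect under the
  zero-modulation null.  Channel weights are a fixed zero-sum pattern
  (8 channels by default).  Per-word gain is 1 + x_i·β with standardized
  features and the planted β vector (clipped at 0.1 with a warning).
  Noise is Gaussian filtered to the 50–280 Hz analysis band, scaled per
  channel to `snr_db`; the default −20 dB puts per-word reconstruction
  scores at r ≈ 0.15–0.4, the noise-influenced regime matching the small
  single-word scores of real recordings (at 0 dB the fixed-λ scores
  saturate near 0.9 and gain modulation cannot transmit).
* **Toy language model.**  A first-order Markov chain with closed-form
  per-position surprisal and entropy; the first word uses the stationary
  distribution.

What passing synthetic tests do *not* show: robustness to real EEG
artifacts (blinks, line noise), realistic head-model topographies,
non-stationary speech statistics, or forced-alignment errors.  One known
benign effect remains in the generator: decoders trained on the whole
pitch distribution decode typical pitches best, giving the per-word
scores a symmetric (quadratic) dependence on mean f0 that does not
project onto the linear regression terms.

## Problem sizes and calibration of the bundled experiments

The bundled acceptance experiments use 190-word single-part recordings
(~60 s) for latency recovery, 20 × 8-subject null replicates (400
bootstrap draws each) for lag calibration, a 400-word, 3-subject global
null for the score-correction checks, and ten 5000-word, 5-subject
replicates per arm for the end-to-end recovery study at β =
(−0.17, −0.07, 0, −0.04, 0, 0, 0).  In the null arm the per-replicate
false-flag probability combines the nominal BY family rate with the
small duration and pitch-selectivity effects described above, so an
occasional flagged replicate among ten is expected and documented rather
than tuned away.

## Numerical conventions

Seconds for times, 0-based sample indices, half-open intervals
everywhere.  Natural logarithms (nats) for all information measures.
All stochastic steps take explicit seeds and are bit-reproducible.
Pearson r over segments needs ≥ 20 samples; entropies are clamped at
1e-6 nats before inversion; empirical bootstrap p-values can never be 0
by the add-one rule.
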