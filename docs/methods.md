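# Methods

This note documents the models and procedures `lfpbeta` implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical decisions behind the defaults.

## Signal model and preprocessing

A recording is a channels × samples matrix of extracellular voltages in
microvolts with a single sampling rate.  Acquisition-rate data (typically
4 kHz) are brought to a 400 Hz analysis rate — beta activity lives far
below the new 200 Hz Nyquist — by a polyphase rational resampler with
Kaiser-window anti-alias design (`scipy.signal.resample_poly`).  Mains
interference is removed with one second-order IIR notch per harmonic of the
line frequency (default 50 Hz) up to 200 Hz, each with a 1 Hz −3 dB
bandwidth and applied forward–backward, so the comb is zero-phase and burst
timing is unshifted.  The notch bandwidth and order are package decisions;
the narrow 1 Hz width keeps broadband power loss below a few percent while
suppressing a pure line by more than 40 dB.  Event masks (categorical
per-sample flags) are resampled by nearest neighbour.

## Spectral estimation and beta-peak identification

PSDs use Welch's method with 4 s Hann windows and 50% overlap: 0.25 Hz
resolution at 400 Hz, enough to resolve a 1 Hz shift of an 18–19 Hz peak,
with density normalisation (integral ≈ variance for inputs whose power
lies on the grid; a 1/f background hides power below the grid's first
bin, so Parseval checks use spectrally flat inputs).

The beta peak is the strongest local maximum of the PSD inside 13–30 Hz
(the conventional beta band) that exceeds a locally detrended background
by at least 20%.  The background is a least-squares line in
log10(power) vs log10(frequency) fitted over the band — a 1/f-type trend —
so a monotone aperiodic spectrum yields "no peak" rather than reporting
its low-frequency shoulder.  The 20% prominence ratio is a package
decision: small enough to keep genuine peaks a few grid steps wide, large
enough to reject background curvature.

Amplitude noise density at the mains harmonics is √PSD interpolated at
{50, 100, 150, 200} Hz (µV/√Hz), the standard way to characterise
line-frequency pickup of a recording interface.

## Burst detection

The band 13–30 Hz peak frequency f_p defines a ±3 Hz pass-band (4th-order
Butterworth, zero-phase).  The Hilbert-transform analytic signal's
magnitude gives the instantaneous beta amplitude.  A burst is a maximal
run of envelope samples **strictly above** the channel's 80th envelope
percentile lasting at least 0.1 s.  Details:

- The percentile is computed per channel over the full analysed segment
  (assumed artifact-free).  This makes detection scale-invariant:
  rescaling the envelope rescales the threshold and leaves every burst
  statistic unchanged.
- Runs touching the first or last sample are discarded — their duration is
  censored by the recording edge and would bias duration statistics.
- No merging across sub-threshold gaps.
- `normalized_amp` = mean intra-burst envelope ÷ detection threshold,
  which is dimensionless and comparable across channels and sessions.
- Durations are histogrammed into seven bins with edges
  {0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.5, ∞} s; the two interior edges at
  0.2–0.25 and 0.25–0.3 s complete a contiguous monotone partition around
  the conventionally reported bins.

**Cross-condition rate comparisons.**  A per-recording percentile pins the
above-threshold time fraction at 20% in *every* recording, so it cannot
express a difference in burst probability between conditions; that is a
property of the estimator, not of the data.  `detect_bursts` therefore
accepts an explicit threshold, and comparisons between states (e.g.
Parkinsonian vs post-levodopa) should compute one threshold on a common
reference — the package's tests pool the two conditions' envelopes — and
apply it to both.  Within-condition statistics use the per-recording
percentile default.

The Spearman duration–amplitude correlation uses average ranks for ties
and requires ≥ 3 bursts.

## State discrimination (SVD–LDA)

Beta-envelope series are cut into non-overlapping 1 s epochs (the trailing
partial window dropped); 1 s is long relative to the 0.1 s minimum burst
and yields ~600 epochs from 10 min of three-state data.  Features are the
raw envelope samples of the epoch.  Epochs are column-centred and
projected onto the top-2 right singular directions of the **training**
matrix; centring and projection are frozen and applied to held-out data,
so no test information reaches the feature space.  Classification is a
pooled-covariance Gaussian linear discriminant with empirical priors; a
singular pooled covariance receives a fixed ridge of 1e-6 × mean diagonal.
Component signs and score ties are fixed deterministically.

Evaluation: per repetition, a stratified random 60/40 train/test split;
10-fold cross-validated accuracy on the training portion (SVD and LDA
refit per fold) recorded as the model-quality estimate; the final model
refit on the full training set and scored on the test set.  The mean test
accuracy over 30 repetitions is the headline number.  Because `evaluate`
operates on an already-built epoch matrix, hyperparameter selection by CV
lives in a separate helper, `select_epoch_length`, which picks the epoch
length among {0.5, 1, 2} s by training-set CV; `evaluate` itself sweeps
nothing.

Significance against chance (1/3 for three balanced states) is the exact
binomial upper-tail probability of the pooled test-set correct count, with
a Bonferroni factor when several channels are tested together.

Signal quality is summarised by `snr_db` = 20·log10(RMS of event samples /
RMS of baseline samples): RMS is an amplitude quantity, so the 20× decibel
convention applies (the 10× power convention is obtainable by halving).

## Synthetic generator

Each channel is generated independently (matching the largely
uncorrelated channels of a ventricular surface array) as the sum of

- 1/f^α Gaussian background, α default 1, synthesised by FFT spectral
  shaping and scaled to a target RMS (default 10 µV);
- white sensor noise (default 1 µV RMS);
- mains interference: sinusoids at k·50 Hz with per-harmonic amplitudes
  (default 2, 0.8, 0.4, 0.2 µV) and random phases;
- beta bursts: sinusoids at the state's centre frequency under a
  raised-cosine (Tukey) envelope whose ramps occupy 20% of the burst at
  each end — tight spectral footprint, no splatter into the PSD peak.
  Onsets are Poisson with overlap-resampling (non-overlapping intervals);
  durations are log-normal (positive, right-skewed, reproducing the
  > 0.5 s tail of Parkinsonian burst-duration distributions); burst peak
  amplitude is `amplitude_gain` × the mean beta-band Hilbert envelope of
  that channel's own background, so gain is dimensionless and
  noise-referenced.

State presets (chosen once to reproduce the qualitative state contrast —
long-duration-dominated, stronger, more frequent bursts in the
Parkinsonian state; short-duration-dominated after levodopa — since
numerical burst-rate/duration laws are not available for the recordings
being emulated):

| preset | rate (burst/s) | duration law (log-normal) | gain | f (Hz) |
|---|---|---|---|---|
| intraop-beforeLD (P1) | 0.5 | median 0.35 s, σ=0.55 | 4.0 | 19 |
| intraop-afterLD | 0.3 | median 0.15 s, σ=0.45 | 2.5 | 19 |
| parkinsonian (P2) | 0.5 | median 0.35 s, σ=0.55 | 4.0 | 18 |
| after-ld | 0.3 | median 0.15 s, σ=0.45 | 2.5 | 18 |
| postop | 0.15 | median 0.15 s, σ=0.45 | 2.0 | 18 |

`inject_events` scales randomly scheduled non-overlapping segments by a
gain, emulating high-amplitude episodes against a stationary background
for validating the RMS SNR metric (expected SNR = 20·log10(gain)).

Everything is reproducible bit-for-bit from (parameters, seed) via
`numpy.random.SeedSequence` spawning.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no biophysics (purely phenomenological
synthesis); no movement or electrode artifacts (analysis segments are
assumed artifact-free, as in curated recordings); no cross-channel
correlation or volume conduction by default; no non-stationarity of the
background within a recording; burst waveforms are pure tones rather than
wideband oscillation epochs.  Classifier results on synthetic states
therefore bound the pipeline's correctness, not real-world accuracy.

## Validation conditions and problem sizes

The test-suite study conditions are sized for precision per CPU-minute:

- Beta-peak recovery: 300 s single-channel recordings, 20 independent
  seeds per preset; the detected peak must match the configured centre
  frequency within one 0.25 Hz grid step in ≥ 18/20.
- Chance-level null: three states from one identical preset, 210 s each
  (210 one-second epochs per class), full 60/40 × 10-fold × 30-repetition
  protocol; mean accuracy must lie within 5 points of 33.3%.
- Detector validation uses a dedicated high-SNR preset (gain 6, rate
  0.35/s, log-normal median 0.7 s): its burst duty cycle sits slightly
  above the 20% the percentile threshold marks, so the threshold falls at
  the burst fringe rather than in the noise tail — the regime where
  recovering the injected rate and modal duration bin is well-posed.  The
  duration law is concentrated in the top (> 0.5 s) bin because the
  raised-cosine ramps shrink detected durations by roughly their ramp
  fraction, which would flip an interior-bin mode.
- Burst-detector correctness is checked exactly against a brute-force
  run-length enumeration on random envelopes, and SVD singular values
  against a Gram-matrix eigenvalue oracle at 1e-8.

## Known limitations

- EDF files are read (via MNE) but not written; CSV is the round-trip
  format.
- The multi-channel classifier variant concatenates per-channel epoch
  features (`combine_channels`); more elaborate fusion rules are out of
  scope.
- `find_beta_peak` assumes a single dominant beta oscillation; two peaks
  of near-equal prominence return only the stronger.
- The exact binomial significance treats pooled test classifications as
  independent trials; epochs reused across repetitions make this
  anti-conservative, so p-values are comparative rather than inferential.
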