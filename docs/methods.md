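# Methods

## The model

The package treats the auditory pathway, from eardrum to scalp electrode, as
a linear time-invariant system.  The input is not the raw audio but a
*regressor* derived from it, because the auditory system responds with the
same sign to compression and rarefaction: for continuous speech the regressor
is the half-wave rectified audio, kept in two branches (positive peaks, and
inverted negative peaks); for click stimuli it is a train of unit-height
single-sample impulses at the click times.  The recorded EEG `y` is modelled
per epoch as

    y(t) = sum_tau  h(tau) x(t - tau)  +  noise(t)

and the response `h` — amplitude per unit regressor as a function of lag —
is the least-squares solution over lags from −150 to 350 ms.  It is computed
in the frequency domain: cross-spectra `conj(X)·Y` and regressor power
spectra `|X|²` are summed over all usable epochs and then divided, which is
the joint (variance-optimal) regression over the whole session.  No
regularization is applied; the rectified-speech regressor is broadband, and
bins whose summed power falls below 1e−12 of the maximum are excluded
outright instead.  Each epoch is zero-padded by the lag span before the FFT
so the correlation is linear, not circular (wrap-around with 64-s epochs and
0.35-s lags would be negligible anyway; the padding makes it exact).

For an impulse-train regressor, the train is white by construction, so the
autocorrelation is treated as diagonal and the division reduces to a scalar
(the summed regressor energy, i.e. the click count for unit impulses).  This
makes the deconvolved response *exactly* the click-triggered average — the
classic ABR computation — and the package asserts that identity to 1e−9 µV.
Energy (not count) normalization is used so that scaling the regressor by c
scales the response by 1/c, the same covariance the spectral division has.

### Polarity handling and its bias

The two rectified branches are solved as independent single-regressor
problems and averaged (the standard procedure for this method); a joint
two-column solve over both branches is available as
`polarity_mode="joint"`.  These are not equivalent.  In the simulation the
EEG is generated from the *mean* of the two branches, so the joint solve
recovers the generating kernel exactly (noise-free r > 0.999).  The
branch-averaged estimate equals the kernel convolved with a zero-phase
smearing filter `1 + Re S_pn / S_pp` (with `S_pn` the pos–neg
cross-spectrum); for pitch-pulse-driven audio that cross-spectrum is large
and structured, and the noiseless branch-averaged recovery drops to
r ≈ 0.75–0.85 over 0–20 ms.  Because the smearing filter is zero-phase, peak
*latencies* are preserved (measured Wave V latency bias 0.075 ms, SD 0.089 ms
over 20 noisy 10-epoch sessions) — morphology smears, peaks stay put, which
is also the behaviour reported for real speech-evoked recordings (waves I–IV
merge while wave V remains distinct).  The joint solve needs at least two
epochs; with one, the per-frequency 2×2 system is exactly rank-deficient.

### Filtering contracts

Latency is the evidence that a response component is subcortical, so no
filter in the pipeline is allowed to move energy backwards in time on the
EEG side:

- stimulus audio: first-order Butterworth high-pass at 1 kHz, applied
  *anti-causally* (reverse, filter, reverse) — any smearing goes toward
  negative lags, away from the response;
- EEG: causal first-order 1-Hz high-pass, then causal second-order IIR
  notches at 60/180/300 Hz with a 5-Hz −3 dB bandwidth (Q = f0/5);
- derived response: causal first-order low-pass at 2 kHz (200 Hz or 20 Hz
  produce middle- and late-latency views of the same waveform); a
  zero-phase option exists behind a flag;
- traditional averaged ABR: causal second-order 150-Hz high-pass (the
  canonical display filter);
- Wave V picking: zero-phase 1-kHz low-pass — here zero-phase is safe
  because only the location of a local maximum is read off.

## Preprocessing

Epochs run from stimulus onset to 100 ms after stimulus end (64.1 s for
64-s speech, 30.1 s for 30-s clicks), cut sample-exactly at the markers; a
final epoch that would run past the record is an error, never padded.
Instead of rejecting minute-long epochs, every crossing of ±100 µV zeroes a
1-s segment centred on the offending sample (window `[i−w//2, i−w//2+w)`
with `w = round(fs)`, clipped at epoch edges).  Zeroing removes energy, so
each epoch carries the corrective gain `g_r = N/(N−N_r)`; the gain is stored
on the epochs and applied when the data enter a regression, which keeps the
zeroing operation idempotent (scaling the stored samples would push
sub-threshold samples over threshold on a second pass).  A fully zeroed
epoch is flagged unusable and excluded.  NaN in a recording is a hard error
at load time; zeroing is the only rejection mechanism.

## Leakage artifact removal

Headphone drivers couple electromagnetically into the electrode leads,
placing a filtered copy of the audio in the EEG at ≈ −0.9 ms lag (the
artifact is instantaneous while the sound arrives through a ~1-ms tube
delay).  Per epoch, the artifact system is estimated by direct spectral
division of the EEG DFT by the *signed* (un-rectified) audio DFT, inverse
transformed, cropped to a 10-ms lag window centred at −0.9 ms
(−5.9 to +4.1 ms), and detrended with a sixth-order polynomial — the speech
has almost no energy below ~100 Hz, so the division is noise-dominated
there.  The per-epoch kernels are averaged, tapered with a 10-ms Hann
window, convolved with the audio and subtracted.  Stimulus-DFT bins below
1e−8 of the spectral maximum are excluded from the division.

Artifact-energy accounting in the validation study: the kernel is estimated
under realistic noise, but raw/cleaned/background energies at negative lags
are measured on paired noise-free derivations of the same stimulus, since
for weak artifacts the negative-lag energy sits far below the response
noise floor.  Measured reductions: ≈ 99% for artifact-to-response ratios of
1 and 10 (4 × 16-s epochs suffice); a 0.1× artifact needs session-scale
data for its kernel to be estimable (92% reduction at 12 × 64 s).

## The synthetic-data generator

The generator realizes exactly the linear model above, plus controlled
violations, so every estimator property is testable without recordings.

**Evoked kernel** — a sum of Gabor-like damped oscillatory bumps
`a·exp(−(t−t0)²/2σ²)·cos(2πf(t−t0))` at (latency ms, amplitude, freq Hz,
width ms): (2, 0.08, 600, 0.6), (4, 0.10, 500, 0.8), (6.5, 0.25, 350, 1.2)
— the dominant Wave V — plus slow middle/late components (30, 0.35, 45, 6)
and (100, 0.50, 9, 20); support 0–250 ms.  Cohorts jitter the Wave V
latency (SD 0.25 ms, the across-subject spread of real click-evoked
latencies) and scale amplitudes lognormally.

**Speech stand-in** — source-filter synthesis at 24,414 Hz: glottal pulses
with a drifting fundamental (100–250 Hz geometric-centred random walk),
1.5% cycle jitter and lognormal shimmer; voicing gated off ~25% of the time
with aspiration noise taking over (voiceless stretches); four wandering
formant resonators (500/1500/2500/3600 Hz, ±¼ octave drift, 50-ms update);
broadband frication bypassing the resonators at 5% of signal RMS;
~4-Hz syllabic amplitude modulation; optional silent pauses (0.2–1.5 s,
~4/min) with 20-ms cosine ramps; first-order 80-Hz high-pass; RMS
normalized to the calibrated digital level 0.01 (≡ 75 dB SPL).  Third-octave
band power is flat to within ~31 dB from 0.2 to 8 kHz.  What it does *not*
emulate: phonotactics, formant transitions tied to articulation, narrator
identity beyond the f0 range, room acoustics — so passing tests demonstrate
estimator correctness under speech-like statistics, not performance on any
particular talker.

**EEG noise** — 1/f background (exponent 1, frequencies below 1 Hz held at
the 1-Hz level), line harmonics at 60/180/300 Hz (amplitudes 2/0.5/0.3 in
kernel units, random phase), and Poisson-timed high-amplitude excursions
(100-ms, 8-Hz Hann-windowed bursts of 300 units at 0.2/min) that exercise
the ±100 µV zeroing.  The background RMS default of 0.7 (in the same
arbitrary units as the kernel) was set so the simulated evoked-SNR
trajectory matches a typical single-channel recording — median ≈ 1.3 dB
after ten 64-s epochs, 5.8 after twenty, 8.8 after forty — and all
validation studies run at that operating point.  At that SNR the expected
correlation between a 10-epoch recovered kernel and the truth is bounded
near √(S/(S+N)) ≈ 0.78; high-fidelity morphology (r > 0.95) requires
roughly four times the data, which is why the kernel-recovery study reports
both the correlation and the (far more robust) Wave V latency.

**Leakage** — a damped 2-kHz burst at −0.9 ms convolved with the signed
audio; scaled so `leakage_gain` reads as artifact-to-neural amplitude ratio.

**Controlled violations** — a compressive exponent on the rectified drive
(recovery degrades monotonically with compression), polarity-specific
kernels (`neg_kernel_scale`), and narrator-specific kernels for split
studies.

## Measurements

- **Wave V**: zero-phase 1-kHz low-pass, maximum in 5–7 ms, ties to the
  earliest lag; amplitude is the smoothed value at the peak
  (baseline-to-peak; a peak-to-trough option is off by default).
- **Morphology**: Pearson r over 0–20 ms; scale- and offset-invariant.
- **Evoked SNR**: `10·log10[(σ²_ABR − σ²_noise)/σ²_noise]` with variances
  (mean removed) over 0–20 ms and −125 to −10 ms; undefined (NaN, never
  clamped) when the signal window carries no excess variance.  The
  cumulative SNR curve recomputes the response for every epoch prefix in one
  streaming pass over the spectra.
- **Split halves**: responses from even/odd epochs, session halves, or
  narrator subsets, correlated over 0–20 ms; medians and IQRs across
  subjects.
- **g_n**: cohort normalization `mean_i(σ_click,i)/mean_i(σ_speech,i)` over
  0–20 ms, computed after the 2-kHz response low-pass; applying it marks a
  speech response as being on the click µV scale.

## Numerical and design choices

- Periodic click trains place `floor(rate·duration)` clicks at `k/rate`.
- Click impulses round to EEG samples with banker's rounding; colliding
  clicks keep a single unit impulse (with a warning).
- Rectified-speech branches are polyphase-resampled to 10 kHz; tiny
  negative resampling ripple is clipped to zero (logged).  Impulse trains
  are never resampled through a low-pass — that would ring.
- Silence detection for pause truncation: 10-ms non-overlapping frames,
  silent below −40 dB relative to whole-signal RMS; runs are truncated to
  0.5 s with content order preserved.
- Fades are applied after RMS normalization (both orders are available by
  composing the operations; levels differ immeasurably for 64-s epochs).
- The ±100 µV scan runs after all filtering (a flag allows scanning first).
- The traditional-ABR window ends at `−3 ms + 1/rate` = 19.675 ms for
  44.1 clicks/s; the discrete lag grid realizes it at the nearest sample.
- Default problem sizes in the validation studies: 10-epoch sessions for
  kernel recovery (20 noise seeds), 20-vs-40 epochs for the SNR-doubling
  law (4 independent stimulus sessions × 8 noise seeds, since a single
  session leaves a stimulus-specific component in the estimate), 4 × 16-s
  epochs for leakage at gains ≥ 1 and 12 × 64 s at gain 0.1.  The full
  40 × 64-s session and 20 × 30-s click runs remain the generator defaults.

## Known limitations

- No biophysical cochlear/auditory-nerve front end: the generator is the
  estimator's own linear assumption plus controlled violations, by design.
- The branch-averaged estimator's morphology smearing (above) is inherent
  to half-wave-rectified regressors on pitch-driven audio; improving the
  regressor, not the solver, is the likely remedy.
- Single differential channel only; no montage handling, re-referencing or
  source analysis.
- Group statistics are descriptive (medians, IQRs); no inferential
  human-subject statistics are reproduced, as those require the original
  recordings.
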