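# Methods

`swdkit` detects spike-wave discharges (SWDs) — the EEG hallmark of absence
epilepsy — in chronic single-channel rodent recordings, summarizes them per
session, classifies their interruption by acoustic stimuli, and compares
groups nonparametrically.  Because chronic rodent EEG datasets are rarely
shareable, the package also ships a synthetic-session generator with exact
ground truth, so every stage of the pipeline is quantitatively verifiable.

## Detection model

1. **Conditioning.**  The raw trace (µV, nominally 1 kHz) is high-pass
   filtered with a zero-phase 4th-order Butterworth at 0.9 Hz.  Zero-phase
   (forward–backward) filtering was chosen because event boundary timing
   feeds the downstream duration statistics; order 4 balances rolloff
   against edge transients.  The trace is then resampled (polyphase,
   anti-aliased) to an internal analysis rate of 200 Hz — the analysis grid
   tops out at ~83 Hz, so 200 Hz keeps everything below Nyquist while
   making hour-scale wavelet transforms cheap.

2. **Time–frequency power.**  Continuous Morlet wavelet transform
   (ω₀ = 6), on a log-spaced grid at 8 voices/octave from 2 Hz up to just
   past the 80 Hz artifact-band top.  Morlet is the standard choice for
   oscillatory EEG; the grid brackets the 5–32 Hz analysis band with
   margin.  Coefficients are normalized so a unit-amplitude sinusoid at a
   grid frequency yields power ≈ 1 there, making the band-power trace read
   in µV².

3. **Band power and threshold.**  Power is integrated (trapezoid) over
   5–32 Hz — the interval that holds most of the SWD oscillation power
   (the ~8 Hz fundamental plus harmonics at 16 and 24 Hz) — giving a trace
   P(t).  The event threshold is robust:
   θ = median(P) + k · 1.4826 · MAD(P), default k = 6.  A median/MAD rule
   keeps θ stable even when discharges occupy several percent of the
   session, and makes detection exactly invariant under amplitude
   rescaling of the input (power scales multiplicatively; the comparison
   P > θ is unchanged).

4. **Segmentation.**  Maximal supra-threshold runs become candidates;
   candidates separated by gaps < 0.3 s are merged (one waxing–waning
   discharge should not split), and candidates shorter than 1 s are
   discarded — sub-second spike trains are not counted as SWDs.  The merge
   gap is deliberately shorter than the 1 s minimum so that merging alone
   cannot promote two sub-threshold fragments into an event.  Boundaries
   sit at threshold crossings; no half-height extension is applied.

5. **Artifact rejection.**  Mechanical noise (cable taps, chewing) is
   broadband, while SWD harmonics stay below 32 Hz.  A candidate is
   rejected when its power integrated over 40–80 Hz exceeds
   `artifact_power_ratio` (default 1.0) times its 5–32 Hz power.  This
   automates what is usually a manual visual screen; it is a declared,
   configurable criterion, not a reproduction of any particular lab's
   screening.

6. **Characterization.**  Each kept event gets a Welch PSD (1 s Hann
   segments, 50% overlap, ≤ 1 Hz resolution) on the full-rate filtered
   trace, its dominant frequency in 5–32 Hz, a harmonic ratio (power in
   2f₀ ± 1 Hz over power in f₀ ± 1 Hz), and its mean band power.

All intervals everywhere are half-open `[start, end)` in seconds from
recording start; sample *i* covers `[i/rate, (i+1)/rate)`.

## Synthetic sessions

The generator emulates the features of chronic rodent EEG that the
detector relies on, with exact ground truth:

- **Vigilance states.**  Semi-Markov chain over awake/NREM/REM; dwell
  times exponential (means 120/180/60 s) rounded up to whole 10 s epochs;
  REM is entered only from NREM (probability 0.5 per NREM exit, giving a
  physiologically sensible ~14% REM share of sleep); sessions start awake.
- **Backgrounds.**  Per state, a narrowband oscillator with slow Wiener
  phase drift at 30 Hz/30 µV (awake), 3 Hz/120 µV (NREM), 7 Hz/40 µV
  (REM), cross-faded over 1 s at state boundaries, plus 15 µV RMS pink
  (1/f) noise.  The peak frequencies mirror the spectral signatures of the
  three states and of SWDs in rat EEG.
- **SWDs.**  `A·w(t)·Σ_k decay^(k−1) cos(2π k f₀ t)` with f₀ = 8 Hz,
  3 harmonics, amplitude decay 0.5 (so the 16 Hz first harmonic carries
  ~0.25 of the fundamental's power), amplitude 250 µV, 0.25 s raised-cosine
  tapers.  Crest phase-locking of the harmonics produces the sharp spike
  riding each cycle of the slow wave.  Durations follow 1 + LogNormal(µ, σ)
  seconds — a floor of 1 s with a long right tail.  Events are injected
  only into awake epochs (discharges occur during quiet wakefulness),
  placed uniformly within awake time, non-overlapping by
  rejection-resampling (truncation would distort the duration law).
- **Artifacts.**  Poisson (6/h) broadband white-noise bursts of 0.3 s at
  5 × the SWD amplitude, anywhere in the session — true positives for the
  artifact-rejection stage.
- **Determinism.**  One integer seed drives a `SeedSequence`; identical
  (config, duration, seed) gives bit-identical sessions.

Provenance of the defaults: no µV amplitudes are published for
these signals, so amplitudes were chosen once for a clearly detectable but
non-saturating SNR and are all exposed in `GeneratorConfig`.  What the
generator does **not** emulate: EMG, real sleep architecture (circadian
structure, state fragmentation), amplitude nonstationarity, electrode
drift, or any behavioural coupling of stimuli to events.  Passing tests
therefore demonstrate the *pipeline's* correctness under the stated
statistical structure, not detector performance on any real recording.

## Preset calibration

`calibrate_preset` solves the generator's (rate, µ, σ) so that the
*detected* statistics of simulated sessions match group-level targets
(median duration, events/h, accumulated s/h — per total recording hour).
Registered targets: wt 2.1 s / 39 / 102; het 2.0 / 28 / 86; ko 2.3 / 61 /
155; wt_vpa 1.9 / 51 / 127; ko_vpa 3.0 / 91 / 307.  The treated-knockout
events/h was not published; 91/h is implied by 307 s/h and the duration
law's mean with σ carried over from the untreated knockout group.

The solve is analytic with simulation-estimated corrections: the median
pins `1 + e^µ`, the mean (accumulated/rate) pins `1 + e^(µ+σ²/2)`, and the
rate divides out the stationary awake fraction (computed in closed form
from the epoch-rounded exponential dwells).  A small pilot
(2 × 1 h simulate-and-detect) estimates the detection transfer factor
(misses, merges, false positives; typically ≈ 0.99) and the matched-pair
duration bias (boundary widening; |bias| < 0.05 s), and the parameters are
re-solved; two iterations suffice.  Verification runs 6 fresh 1 h
sessions.  Reported rate and accumulated-time figures use expectation
estimators (configured Poisson mean × measured transfer; transfer ×
measured mean duration): conditioning on the known generator mean removes
awake-time and Poisson counting noise that a 6-hour pool cannot average
away, leaving the low-variance transfer ratio as the only measured factor.
Raw pooled per-hour statistics are reported alongside.

A caveat that follows from the generator's own structure: the awake-time
fraction of a single 2 h session has a coefficient of variation around
15–20% (≈ 21 awake visits with exponential dwells), and the SWD count is
Poisson on top of that.  Calibration makes the *expectation* match the
targets; any single short session still scatters around them with roughly
that spread.

## Interruption classification

An event is *stimulated* iff a stimulus onset falls inside `[start, end)` —
tones were triggered on live detection of an ongoing discharge, so an
onset merely near an event does not count.  With t* the first in-event
onset, the event is Case 1 (interrupted) if it ends within `window_s` of
t*, else Case 2 (resistant).  The literature gives no latency criterion
for "readily interrupted", so `window_s` is a first-class parameter
(default 1.5 s: shorter than the median event, generous for a prompt
response).  The Case 2 ratio is n₂/(n₁+n₂), `None` (not 0) when nothing
was stimulated.  Half-session splits assign events by start time relative
to the session midpoint.

## Group statistics

Rank-sum (Mann–Whitney), signed-rank (Wilcoxon) and Kruskal–Wallis tests,
with mid-ranks and tie-corrected variances throughout (sampling-grid
quantization makes ties common).  Exact enumeration is used for small
samples without ties (rank-sum: combined n ≤ 12; signed-rank: n ≤ 15),
normal approximation with continuity correction otherwise.  The pairwise
follow-up is a Dunn-type z test on joint mean ranks with tie-corrected
pooled variance; in the Fisher's-LSD spirit the pairwise p values are
unadjusted and are reported only together with the omnibus H test.
Comparisons pool events within a group by default (per-event, not
per-animal, mirroring how such figures are usually reported); per-session
values can be passed instead where a paired design applies.  Degenerate
inputs are explicit: identical pooled samples give p = 1 with a flag;
all-zero paired differences are an error.

## Numerical choices and edge cases

- EDF files are standard 16-bit EDF, one channel, physical dimension µV;
  the last record is zero-padded, so read-back length is rounded up to a
  whole record.  Reading goes through `mne`; writing is a minimal writer
  in `swdkit._edf` (no EDF writer exists in the dependency set), and the
  round-trip is tested against `mne`'s independent decoder.
- CSV floats are parsed with round-trip precision so event tables
  round-trip exactly.
- A constant band-power trace has MAD 0: the threshold degenerates to the
  median, with a warning.
- `detection_metrics` matches greedily, one-to-one, accepting a pair when
  midpoints are within 0.5 s or overlap covers ≥ 50% of the shorter
  interval; empty predictions give precision 0 with an explicit flag.
- Problem sizes in the test suite and acceptance script (15 min–2 h
  sessions, 6–8 calibration hours, 1000-rep null Monte-Carlo) were chosen
  so the full pipeline, including calibration, runs in a few minutes on
  one CPU while keeping counting noise within the asserted tolerances.

## Known limitations

- The detector is offline and single-channel; no causal detection, no
  montage fusion, no template matching of the spike component.
- The artifact criterion targets broadband transients only; narrowband
  artifacts inside 5–32 Hz (e.g. mains hum harmonics after resampling)
  would not be rejected.
- Calibration assumes the detector's transfer factor and duration bias
  are locally constant in the parameters — true near the published target
  ranges, untested far outside them.
- The generator's vigilance dynamics are memoryless by design; real rat
  sleep has ultradian structure the chain does not reproduce.
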