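# Methods

`gliderpam` implements the acoustic-analysis chain of a glider-based
passive acoustic survey for odontocetes: synthetic data generation,
click detection, feature measurement, rule-based species
classification, mission-level statistics, and satellite-tag track
matching.  This note documents the models, conventions, and numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Click waveform model

No waveform model is prescribed by the feature tables the presets
emulate — they give aggregate quantities (duration, sweep band,
spectral peak, −20 dB low-frequency roll-off, ICI statistics).  The
generator therefore uses the simplest waveform reproducing all of
them: a linear FM chirp under an asymmetric Gaussian envelope,

    x(t) = a(t) · sin(2π (f0 t + ½ k t²)),   k = (f1 − f0)/T,

with independent rise and fall time constants.  By stationary phase,
the spectral magnitude of a linear chirp tracks the envelope, so:

* the envelope maximum is placed where the instantaneous frequency
  equals the target **peak frequency**;
* the rise-side σ is set so the spectrum first comes within 20 dB of
  its peak near the target **roll-off** (amplitude −20 dB at
  √(2 ln 10) σ).  A lower bound σ ≥ √(1/(2π|k|)) keeps the rise from
  entering the regime where window smearing, not the chirp-rate
  mapping, controls the spectral edge;
* zero-phase Butterworth confinement filters (high-pass 2 kHz below
  the band, low-pass 3 kHz above) remove residual leakage, giving
  ≥ 40 dB suppression outside the sweep band.

Because measured duration, peak and roll-off are nonlinear functions
of (T, envelope shape), the generator calibrates itself: an
eight-step fixed-point loop synthesises the click, measures duration /
peak / roll-off with the *feature module's own conventions*, and
adjusts the nominal sweep length, envelope-peak position and internal
roll-off target until the measurements match the spec.  Calibration is
cached per (spec, sample rate).

The wide-band unknown-species click (15–80 kHz sweep, 30 kHz peak) is
the one preset whose −20 dB roll-off cannot be pushed all the way to
20 kHz: at its chirp rate the smearing floor limits the achievable
edge sharpness, and the clean waveform measures ≈ 17 kHz.  This is a
physical property of short wide-band chirps, not a calibration bug.

The 'double click' structure (an attenuated replica of each click at a
fixed lag, of unexplained physical origin) is available as a separate
preset; the replica lag is a free parameter.  The default
unknown-species preset is single-pulse so that the 95 %-energy
duration convention measures the primary pulse.  The sperm-whale
preset is likewise a single low-frequency pulse rather than the real
multi-pulse structure, keeping one duration convention valid for every
preset.

### Presets

Blainville's and Cuvier's beaked whale values follow the published
feature table (250 µs / 25 kHz roll-off / ICI 0.2–0.4 s with upsweep;
175 µs / 20 kHz / 0.4 s).  ICI standard deviations (0.05 s and
0.04 s) treat the printed ranges as ≈ ±2 SD.  Delphinid, sperm-whale
and echosounder presets are literature-informed stand-ins (the survey
reported those classes without printing click parameters): delphinid —
50 µs broadband downsweep 80→25 kHz, lognormal ICI with 0.1 s median
(capped below the recorder's Nyquist of 97 kHz); sperm whale — 500 µs
low-frequency pulse 15→5 kHz, ICI 0.75 ± 0.12 s; echosounder — 1 ms
50 kHz tone pings at a metronomic 0.8 s interval.  Default SNRs
(delphinid 25 dB, sperm 22, echosounder 20, beaked whales 15 dB)
reflect that delphinids and sperm whales dominate such recordings at
high level.

### SNR calibration

Train amplitudes are scaled so the band-limited zero-to-peak SNR
(peak of the band-passed clean click over the band-passed RMS of the
*realised* noise) hits the target.  The convention band is 15–90 kHz;
for click types whose energy lies mostly below it (sperm whale) the
click's own band is used instead, since the convention band would
contain almost no click energy and the calibration would diverge.
Noise is Gaussian, white by default, with an optional dB/octave
spectral tilt.

## Detection

Recordings are high-pass filtered (5 kHz default) and framed into
128-sample Hamming windows (0.66 ms) with 75 % overlap and a 256-point
FFT — frames comparable to a click's length maximise the per-frame
energy contrast.  Two per-frame statistics are provided:

* **band mode** (onboard screening): 10 log10 of mean power in a
  beaked-whale signal band (24–48 kHz) over mean power in a guard band
  (5–20 kHz), threshold 10 dB.  All four values are configuration.
* **baseline mode** (full pipeline): the maximum over three sub-bands
  (10–20, 20–40, 40–92 kHz) of frame power relative to that sub-band's
  file-median power, threshold 4.5 dB.  Sub-bands are kept ≥ ~13 FFT
  bins wide so the mean-power ratio is chi-square concentrated: at the
  default threshold the per-frame false-alarm probability is < 1e−5,
  and residual false events are removed by the minimum-train-length
  rule (5 clicks).

Contiguous above-threshold frames form one candidate; the event onset
is the centre of the run's peak-ratio frame, events closer than 3 ms
are merged.  On synthetic trains this recovers every click at SNR
≥ 10 dB with onset error below one frame hop (0.165 ms); recall decays
to zero by 5 dB, which is the expected behaviour of energy detection —
a 0-to-peak SNR of 5.7 dB is below the amplitude of routine noise
envelope excursions.

Train grouping joins events separated by ≤ 2 s (so that one missed
click cannot split a slow sperm-whale or echosounder train below the
minimum length) and discards trains with fewer than 5 clicks.

Spectrogram display bandwidth is reported as the Hamming main-lobe
(null-to-null) width, 4·fs/frame, the one convention under which the
2048-sample and 32-sample analyst framings differ by exactly their
frame-size ratio of 64.

## Feature measurement

* **Duration** — the interval containing the central 95 % of the
  energy of the 10 kHz-high-passed click.  On noisy windows the
  measurement is restricted to an envelope-gated region (smoothed
  Hilbert envelope above max(10 % of peak, 1.8× the noise envelope),
  padded by 250 µs) and the expected noise-energy ramp is subtracted
  from the cumulative energy before the quantile scan.  Without
  gating, the cumulative noise random walk is comparable to the 2.5 %
  energy quantile and inflates durations systematically.
* **Spectra** — direct zero-padded FFTs of the click region (the fine
  spectrogram's 24 kHz display bandwidth cannot resolve a 20 vs
  25 kHz roll-off).  A noise power spectrum estimated from the
  adjacent click-free window *with the same window length* is
  subtracted, and the corrected spectrum is smoothed over about two
  independent spectral widths so residuals average out.
* **Roll-off** — scanning upward from 10 kHz, the lowest frequency at
  which the corrected spectrum first comes within 20 dB of its peak.
  The scan is floor-aware: where the −20 dB level lies below the
  measurable noise floor the spectrum must instead rise 2× above the
  local floor, i.e. the scan reports where the click emerges from the
  noise.  On clean spectra this reduces exactly to the −20 dB
  convention.
* **Upsweep** — least-squares slope of the per-frame argmax-frequency
  ridge on the fine (32-sample frame, 128-point FFT, 94 % overlap)
  spectrogram across the frames covering the click, energy-weighted so
  noise-dominated edge frames contribute little.  Positive slope
  (beyond a 1 kHz/ms quantisation deadband) over ≥ 3 frames counts as
  an upsweep; fewer frames is indeterminate.
* **SNR_0-p** — 20 log10 of the band-limited (15–90 kHz) peak
  amplitude over the adjacent noise window's RMS, the peak taken
  inside the envelope-gated region.  Note that on noisy data this
  plain convention is biased upward once the true SNR approaches the
  noise envelope's own excursions (~9 dB for millisecond windows);
  generator calibration is therefore verified against the clean click
  scaling.
* **Train-level stacking** — per-train duration, peak frequency and
  roll-off are measured on the *coherently stacked* click: equal-length
  segments centred on each click's envelope peak, aligned by
  cross-correlation and averaged, reducing noise power by 1/n.  A
  single click at 15 dB SNR has an in-band noise floor only ~9–12 dB
  below its spectral peak, which makes −20 dB roll-offs unobservable
  per click; stacking an 8-click train lowers the floor by another
  9 dB.  For real animals successive clicks vary more than the
  synthetic replicas do, so stacked estimates on field data would be
  slightly blurred; the per-click measurements remain available.

ICI series are successive differences of sorted onsets; mean and
sample SD (ddof = 1); fewer than two clicks give an empty series with
NaN statistics.

## Classification

Explicit, serialisable rules replace the analyst's judgement:

1. **echosounder** — ≥ 4 clicks, ICI coefficient of variation ≤ 0.02
   (metronomic), and a tone-like spectrum (peak − roll-off ≤ 8 kHz).
2. **beaked-whale gate** — upsweep with slope ≥ 10 kHz/ms, roll-off
   ≥ 18 kHz, duration 100–900 µs.  Within the gate, species windows:
   duration and roll-off within ±30 % of the species point values
   (250 µs / 25 kHz Blainville's, 175 µs / 20 kHz Cuvier's), ICI in
   [0.2, 0.4] s (Blainville's) or [0.3, 0.5] s (Cuvier's — the
   published table prints a point value of 0.4 s with no range, so the
   window width is a configuration guess).  Both windows accepting is
   resolved by nearest window centre in normalised
   (duration, roll-off, ICI) space; neither accepting yields
   `unidentified_beaked_whale`.
3. **sperm whale** — spectral peak ≤ 20 kHz and ICI ≥ 0.5 s.  Duration
   is deliberately not gated: the 10 kHz-high-pass duration convention
   is unreliable for clicks whose energy sits mostly below the cutoff.
4. **delphinid** — duration ≤ 120 µs and no upsweep.
5. otherwise **unknown**.

All windows, tolerances and precedence live in a `RuleSet` dataclass
(YAML-serialisable).  Gap-grouped trains that mix sources (a delphinid
train over echosounder pings) are additionally split into coarse
per-click spectral cells — low-frequency (< 20 kHz peak), narrowband
(peak − roll-off ≤ 8 kHz), broadband — and each sufficiently large
cell is classified on its own; a file's class flags are the union over
its (sub-)trains.

On the generator's study conditions the confusion structure is: both
beaked-whale species ≥ 95 % correct at 15 dB SNR with zero
beaked/sperm confusion; the unknown click type lands in
`unidentified_beaked_whale` or `unknown` depending on whether its
noise-limited roll-off clears the 18 kHz gate — appropriately, since
its real-world counterpart was not classifiable either.

## Mission statistics

Per-file flags aggregate into: per-class file percentages (reported to
1 decimal), per-dive summaries, local-hour diel profiles (UTC offset
−10 h for Hawai'i, no DST), encounter counting (maximal runs of
positive files with gaps ≤ 1 h), encounter rate (recording hours per
encounter), and detector performance (file-level recall, dive-level
true/false detections).  The one-way ANOVA is implemented from the
sum-of-squares definitions (only the F survival function comes from
scipy) and is checked against the t² = F identity and scipy's
reference implementation; the day/night grouping (day 07–18 h, night
19–06 h local, observations = per-dive-hour positive percentages) is
configuration, since the original grouping was not specified, and is
echoed in the output.

## Tag matching

Great-circle distances use the haversine formula with R = 6371 km.  A
tag fix marks a potential encounter when its ARGOS accuracy radius is
≤ 1.5 km and the glider — linearly interpolated between track samples,
or nearest-sample as an alternative mode, since the original
convention is not stated — is within 6 km at the fix time.  The
hypothetical whale dive profile places a surface interval centred on
each fix and one u-shaped deep dive between consecutive surfacings
(descent 1.1 m/s, ascent 0.8 m/s, ~58 min dives, 2 min surfacings,
vocal below 400 m — published Cuvier's-beaked-whale means, carried as
configuration), with optional flanking dives; vocal intervals are the
portions below the vocal-onset depth, and standard interval
intersection with the glider's recording intervals (recording only
below 500 m) quantifies simultaneous whale-vocal/glider-recording
time.

## Problem sizes and runtimes

The synthetic benchmarks are sized for a single CPU: parameter
recovery uses 100 seeded 11-click trains (~2.2 s of audio each);
classifier fidelity uses 200 trains; the end-to-end prevalence
benchmark uses a 1,000-file mission with 6 s per "minute file" —
presence statistics are per-file and do not depend on file length once
one train fits, so shorter files change nothing but cost.  The full
test suite runs in ~9 minutes and the acceptance script in ~8.

## What the synthetic benchmarks show — and don't

Passing parameter recovery shows the generator and measurement
conventions are mutually consistent and noise-robust at the stated
SNRs; passing prevalence recovery shows the detection–classification
chain has high per-file recall and a negligible false-flag rate under
the generator's conditions.  They do not demonstrate field
performance: real clicks vary within trains (direction-dependent
spectra, amplitude fades), propagation imposes frequency-dependent
loss and multipath, noise is non-Gaussian (snapping shrimp, vehicle
self-noise), and delphinid repertoires include whistles and
burst-pulses that this generator deliberately omits.  The rule windows
were chosen from published point values, not fitted to data.

## Known limitations

* Streaming/embedded operation is out of scope; files are processed
  whole.
* Trains spanning file boundaries are not stitched across files.
* ARGOS error is a scalar radius, not an error ellipse.
* The SNR_0-p plain convention is upward-biased at low SNR (see
  above).
* FLAC I/O is not provided; minute files are PCM-16 WAV.
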