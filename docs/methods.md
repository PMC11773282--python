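# Methods

This note records the models, numerical choices, and open design decisions
behind `pedscreen`, and what the simulation-based tests do and do not
establish about real screening data.

## Stimulus synthesis

**Band-limited surrogates.** The screener's non-tonal stimuli (noisemaker,
environmental, and animal sounds) are characterized entirely by their
band-pass specification: 500-Hz-wide bands at 250–750, 750–1250, 1750–2250,
and 3750–4250 Hz with a filter slope of at least 24 dB/octave and durations
of 2–3 s. Because the original field recordings are not redistributable,
the package synthesizes Gaussian-noise surrogates shaped to the same
specification; `filter_to_spec` applies the identical filter to imported
WAV recordings. The filter is a 4th-order Butterworth band-pass applied
forward-backward (`sosfiltfilt`), which is zero-phase and has an asymptotic
slope of 12 × order = 48 dB/octave per side — comfortably above the
24 dB/octave floor, which `measure_band_profile` verifies empirically
(measured roll-off on the shipped bands is ≈ 65–70 dB between the band edge
and one octave beyond, because the measurement window sits well into the
asymptotic region). The catalog's 500-Hz band, specified as "18 or 24
dB/octave", is built at 24 for uniformity.

**Conformance measurement.** `measure_band_profile` uses a Welch spectrum
(4096-point segments at 44.1 kHz). Passband level is the mean PSD (in dB)
across the band; stop-band level is the mean in a ±5% window centered one
octave beyond each edge; roll-off is their difference per octave. The
in-band energy fraction integrates the same spectrum. White noise measures
≈ 0 dB/octave, as it should.

**Warble tone.** The calibration tone is a 1000 Hz carrier with sinusoidal
frequency modulation. Modulation depth and rate are not dictated by the
screening design, so the package uses the common audiometric convention of
±5% deviation at 5 Hz, both configurable. Note a physical subtlety: for
sinusoidal FM with modulation index β = Δf/f_m, a few percent of power sits
in Bessel sidebands just beyond ±Δf (measured: ~10% outside the nominal
band at β = 5, ~4% at β = 10). Energy-confinement checks therefore use the
Carson band ±(Δf + 2 f_m), which captures > 99% of power; asserting > 99%
inside ±Δf would fail for any realistic warble.

**Gating and normalization.** All synthesized stimuli get 10-ms
raised-cosine on/off ramps to avoid spectral splatter. Word sessions
peak-normalize every word to −3 dBFS and insert exactly 5 s of silence
between word offset and the next onset; the verification oracle
re-measures the gaps by thresholding at −60 dBFS, ignoring sub-threshold
dips shorter than 50 ms (noise-like stimuli dip below any fixed threshold
for a sample or two). Audio exports as 44.1 kHz mono 16-bit PCM WAV; all
internal processing is float.

## Calibration

**Volume ↔ SPL.** Device calibration is a per-frequency table of measured
(volume %, dB SPL) points. Interpolation is piecewise linear through the
knots and never extrapolates — a screening level outside the measured range
is an error, not a guess. The inverse map is the same table read backwards
and round-trips to 1e−6 on strictly increasing segments.

**RETSPL.** dB HL → dB SPL is an exact per-frequency translation:
SPL = HL + RETSPL(f). The shipped headphone table is {500: 11, 1000: 1,
2000: 3, 4000: −2} dB; the sound-field table uses free-field 0°-azimuth
reference values rounded to integer dB ({500: 4, 1000: 2, 2000: −1,
4000: −5}), both overridable by user TSVs. The Wilber derivation is
implemented as the panel mean of (device SPL at threshold − audiometric
threshold in dB HL) per frequency, rounded half-away-from-zero for table
export with unrounded means retained. The derivation is unbiased by
construction and its panel-mean SD shrinks as 1/√n under additive
measurement noise, which the tests check empirically.

**dBA metering.** A-weighting uses the standard analog transfer function
(poles at 20.599, 107.653, 737.862, and 12194.217 Hz, normalized to 0 dB
at 1 kHz) discretized by bilinear transform at the signal's sample rate;
at 44.1 kHz the discretization error at the audiometric frequencies is
far below the ±0.3 dB test tolerance (measured −19.14 dB at 100 Hz vs the
−19.1 dB table value). The meter reports
20·log₁₀(RMS of the A-weighted signal) + cal_offset over a 1-s window
(the most recent window of the supplied signal), with digital silence
mapped to a −120 dBA floor. The calibration offset convention is
dB SPL = dBFS_RMS + cal_offset, so synthetic fixtures with a known offset
make the meter testable without hardware. The access gate is strict:
screening is allowed iff the measured level is *below* the threshold
(50.0 dBA exactly is denied), and a 0.1-dB sweep flips exactly once.

**Harmonic distortion.** THD is the RMS ratio of harmonics 2–5 to the
fundamental, each integrated from a Welch spectrum in a narrow window
around the harmonic. A square wave therefore measures
√(1/9 + 1/25) ≈ 38.9%, the Fourier-series value for odd harmonics through
the 5th (the familiar 48.3% figure includes all harmonics).

## Screening protocols

**Module selection.** Half-open age bins: [0, 12) months → behavioral
observation audiometry, [12, 36) → speech-spectrum awareness, [36, 72) →
speech recognition. Boundary ages take the older module. Ages outside
[0, 72) are out of scope. Chronological age drives selection; a hearing-age
override is the caller's choice of input.

**Ascending tracking.** Presentation starts at 20 dB HL. One presentation
per level; a response triggers up to two confirmations at the same level,
and the level is the minimum response level when ≥ 2 of the 3 draw
responses (early-stopped once decided). Otherwise the level rises 5 dB, to
a 90 dB HL ceiling with a distinct no-response code.

**Hughson–Westlake.** Descend 10 dB after each response, ascend 5 dB after
each miss; threshold is the lowest level collecting ≥ 2 responses among up
to 3 ascending-run presentations (a level that reaches 3 ascending
presentations with < 2 responses has its tally cleared). The initial run
from the start level is a familiarization descent. Descent clips at the
−10 dB HL grid floor, where two responses accept the floor; three misses
at the ceiling return the no-response code. Both trackers keep every
presentation on the 5-dB grid and log the complete trial history.

**Tracking accuracy.** For deterministic responders both procedures
reproduce hand-simulated walks exactly. For steep probabilistic listeners
(logistic scale 1 dB), 200-run Monte Carlo recovers the true threshold to
within one 5-dB step ≥ 95% of the time. The ascending-with-confirmation
rule is biased upward by about half a step near threshold (a level at
p = 0.5 is confirmed with probability 0.375), which is inherent to
confirmation rules, not a defect.

**Screening sessions.** A session first checks the noise gate, then
presents each frequency at the screening level (default 60 dB HL) up to
three times; a frequency passes with ≥ 2 responses — mirroring the
thrice-at-level confirmation of the ascending procedure, since the
single-level response rule is otherwise unspecified. Overall result is
pass iff every frequency passes (configurable). The speech module instead
runs one six-word closed-set block at the screening level with the 5-of-6
rule; its single outcome stands for all frequencies in per-frequency
cross-tabulations. Reinforcement events may be logged as annotations but
never alter state.

## Simulated listeners

**Psychometric model.** Detection:
p = fa + (1 − fa − lapse) · logistic((L − threshold − midpoint)/scale).
Word recognition (4-alternative closed set):
p = guess + (1 − guess − word_lapse) · logistic((SL − midpoint)/scale),
with SL the presentation level re the listener's own better-ear pure-tone
average. This is the simplest form supporting both tasks; every parameter
is per-profile.

**Detection defaults** — midpoint 0 dB, scale 1.5 dB, false-alarm 0.001,
lapse 0.001 — model a *reliable, trained observer* scoring unambiguous
behavioral responses. This is a deliberate idealization: the package's
separability guarantee (a cohort of normals at ≤ 15 dB HL and impaired at
≥ 71 dB HL yields perfect pooled agreement with ≥ 99% probability) is
arithmetically impossible at casual observer error rates — a 5%
false-alarm rate alone produces a spurious 2-of-3 "response" on ~0.8% of
impaired trials, i.e. roughly one false pass per 96-trial cohort. Raising
`false_alarm`/`lapse` models noisier field observers and degrades
agreement accordingly; the defaults define the engine's intended operating
regime, not a claim about untrained screeners.

**Word-task defaults** — guess 0.25 (four pictures), word_lapse 0.005,
midpoint 3 dB SL, scale 1.5 dB — are a calibration placing the 80%-correct
point between 0 and 5 dB SL: P(correct) ≈ 0.34 at 0 dB SL and ≈ 0.84 at
5 dB SL, so 5 dB SL is the smallest tested level {0, 5, 10, 20} reaching
criterion. This is a documented calibration to the intended operating
point, not an independent estimate of child word-recognition slopes.
Note the structural consequence of the closed set: a listener at chance
passes a 6-word block (≥ 5/6) with probability ≈ 0.5%, an irreducible
guessing floor. Perfect-agreement properties are therefore evaluated on
detection-module cohorts; mixed-age cohorts including the speech module
are held to the κ ≥ 0.8 standard instead.

**Cohorts.** Normal-hearing profiles draw integer thresholds uniformly in
[0, 15] dB HL per ear and frequency; impaired profiles draw from disjoint
severity bands — moderately severe [56, 70], severe [71, 90], profound
[91, 100] — chosen to match the conventional grade terminology (the exact
band edges are a package decision). The gold-standard table is exactly the
drawn truth, so agreement statistics measure the screener alone. The gold
label refers iff the better-ear threshold exceeds the 60 dB HL cutoff;
exactly 60 counts as pass (the cutoff wording is ambiguous; the boundary
convention is documented here and configurable).

## Agreement statistics

Cohen's κ from the 2×2 pass/refer table, with the large-sample standard
error √(po(1−po)/(n(1−pe)²)) and a 95% Wald interval clipped to [−1, 1];
the Fleiss–Cohen–Everitt variance is available behind `se_method="fleiss"`.
Degenerate margins (pe = 1) raise rather than return a number. Qualitative
labels follow the conventional bands (≥ 0.81 very good, ≥ 0.61 good,
≥ 0.41 moderate, ≥ 0.21 fair, else poor), with exact κ = 1 reported as
perfect. The overall table pools the per-frequency tables cell-wise
(unit of analysis: child × frequency); a per-subject alternative
(all-frequency concordance) is provided since the right pooling for an
overall κ is genuinely open. p-values are deliberately not reported; the
CI carries the same information without the degenerate-null baggage.
The word-familiarity filter keeps words identified by ≥ 85% of children
(inclusive boundary), preserving input order.

## Problem sizes and determinism

Monte-Carlo checks use 200 seeded runs for threshold recovery, 2,000
six-word blocks per sensation level for the operating point, 10,000 draws
for psychometric-rate convergence (3-SE tolerance), and 100 seeded
cohorts for the pipeline property — sizes at which the binomial standard
errors are several times smaller than the margins being asserted. All
stochastic paths take explicit seeds (`numpy.random.default_rng`);
identical seeds are bit-reproducible, and CLI outputs embed the seed and
a configuration hash.

## Known limitations

* Surrogate stimuli share the band spectrum of the originals but not their
  temporal envelopes or ecological familiarity; simulated pass rates say
  nothing about children's differential attention to real sounds.
* The listener model has no attention drift, habituation, middle-ear
  pathology, or aided-hearing simulation; lapse is a constant rate.
* Calibration tables are treated as opaque ground truth — transducer
  nonlinearity between measured points, coupler vs free-field geometry,
  and Bluetooth transport latency are out of scope.
* The agreement pipeline validates internal consistency (screener vs the
  simulator's own truth); it is not evidence of field sensitivity or
  specificity, which require real cohorts and an objective gold standard.
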