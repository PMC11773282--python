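# pedscreen

A desk-scale pediatric hearing-screening engine. Low-cost screeners built
from off-the-shelf transducers can identify moderately severe and higher
degrees of childhood hearing loss (better-ear thresholds above 60 dB HL)
in settings where objective audiometry is unaffordable — but the software
behind such a device must get several things exactly right: calibrated
stimulus synthesis, conversion between device volume, dB SPL, and dB HL,
ambient-noise gating, age-appropriate behavioral protocols, and the
agreement statistics that validate the screener against gold-standard
audiometry. `pedscreen` implements that whole chain as a tested Python
library plus CLI, with a simulated-listener harness so every protocol and
the validation pipeline run end to end without hardware or participants.

It is aimed at audiology researchers and device developers prototyping
screening logic, and at anyone who needs reference implementations of the
underlying pieces.

## What's inside

* **`stimuli`** — warble (FM) tone synthesis; band-limited Gaussian-noise
  surrogates of non-tonal screening stimuli on four 500-Hz-wide bands
  centered at 500, 1000, 2000, and 4000 Hz (zero-phase Butterworth
  band-pass, ≥ 24 dB/octave); peak normalization; six-word
  speech-recognition sessions with 5-s inter-stimulus intervals and
  −3 dBFS word peaks; spectral conformance measurement.
* **`calibration`** — piecewise-linear volume % ↔ dB SPL calibration
  tables; dB HL ↔ dB SPL via RETSPL tables, including the Wilber
  derivation, RETSPL(f) = mean over a normal-hearing panel of
  (device SPL at threshold − audiometric threshold); A-weighted (dBA)
  noise metering (IEC 61672 analog network, bilinear-discretized) and the
  strict `< 50 dBA` access gate; harmonic-distortion measurement.
* **`protocols`** — module selection by age (behavioral observation
  audiometry 0–12 months, speech-spectrum awareness 12–36 months, speech
  recognition 36–72 months); ascending 5-dB minimum-response-level
  tracking with thrice-at-level confirmation; Hughson–Westlake
  (down-10/up-5) threshold search; 5-of-6 word-block scoring; single-level
  screening sessions at 60 dB HL with automatic pass/refer.
* **`listener_sim`** — simulated children with per-ear true thresholds and
  logistic psychometric functions for detection and 4-alternative
  closed-set word recognition; cohort generation with a gold-standard
  threshold table.
* **`validation`** — 2×2 screener-vs-gold cross-tabulation per frequency,
  Cohen's κ with large-sample standard error, 95% CI and qualitative
  labels, and the 85%-familiarity word filter.

The central statistic: for a 2×2 table with concordant counts a, d and
discordant b, c (n = a+b+c+d),

    po = (a + d) / n
    pe = ((a+b)(a+c) + (c+d)(b+d)) / n²
    κ  = (po − pe) / (1 − pe),   SE = √( po(1−po) / (n(1−pe)²) )

## Worked example

Simulate a 55-child validation cohort (31 normal-hearing, 24 hearing-
impaired), screen every child at 60 dB HL with the age-appropriate module,
and compare against the cohort's gold-standard thresholds:

```
$ pedscreen screen-sim --seed 7 --out demo_run
frequency  kappa  ci_low  ci_high     label   n
      500  0.962   0.888    1.000 very good  55
     1000  0.923   0.818    1.000 very good  55
     2000  0.807   0.646    0.968      good  55
     4000  0.886   0.760    1.000 very good  55
  overall  0.895   0.834    0.955 very good 220
wrote 55 sessions to demo_run (seed 7, config 88261630af04)
```

Each row is the chance-corrected agreement between the screener's
pass/refer call and the gold label (refer iff the better-ear threshold at
that frequency exceeds 60 dB HL); the overall row pools the four
per-frequency tables (n = 55 children × 4 frequencies). Disagreement comes
almost entirely from moderately severe listeners whose true thresholds
straddle the 60 dB HL cutoff — exactly the children a single-level
screen is expected to classify least reliably. The run also writes
`trials.tsv` (every presentation), `sessions.json` (per-child summaries,
each embedding the seed and config hash), and `gold_thresholds.tsv`.

Other subcommands: `pedscreen synth` (write the stimulus catalog and
calibration warble as WAV), `pedscreen retspl` (derive a RETSPL table from
paired-threshold measurements), `pedscreen agreement` (κ report from
exported files), `pedscreen noise-check` (meter a WAV against the gate).

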