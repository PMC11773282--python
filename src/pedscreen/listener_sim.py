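"""Simulated child listeners with known thresholds and psychometric behavior.

Each listener carries per-frequency, per-ear true thresholds (dB HL) and a
logistic psychometric model for two tasks:

* detection (the behavioral responses an observer scores — eyeblink,
  head turn, sound search):
  p(respond) = fa + (1 - fa - lapse) * logistic((L - threshold - mid) / scale)
* closed-set word recognition (picture pointing, 4 alternatives):
  p(correct) = guess + (1 - guess - word_lapse)
               * logistic((SL - word_mid) / word_scale)

Default detection parameters model a reliable, trained observer (very low
false-positive and lapse rates); the word-task defaults place the 80%-correct
point just under 5 dB sensation level, matching the module's intended
operating point.  Cohorts pair each generated profile with a gold-standard
threshold table for downstream agreement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import MissingFrequencyError, SCREEN_FREQUENCIES

__all__ = [
    "ListenerProfile",
    "CohortSpec",
    "SEVERITY_RANGES",
    "respond_detection",
    "respond_word",
    "make_cohort",
    "gold_label",
    "better_ear_threshold",
    "pta",
]

# better-ear threshold bands (dB HL) by impairment grade; the device targets
# moderately severe and higher
SEVERITY_RANGES: dict[str, tuple[int, int]] = {
    "moderately_severe": (56, 70),
    "severe": (71, 90),
    "profound": (91, 100),
}
NORMAL_RANGE = (0, 15)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ListenerProfile:
    """One simulated child: true thresholds plus psychometric parameters."""

    subject: str
    thresholds: dict[float, tuple[float, float]]  # freq -> (left, right) dB HL
    age_months: float = 24.0
    psychometric_scale: float = 1.5       # dB, detection slope parameter
    detection_midpoint_offset: float = 0.0  # dB above threshold at 50% detection
    false_alarm: float = 0.001
    lapse: float = 0.001
    word_guess: float = 0.25              # 4-alternative closed set
    word_lapse: float = 0.005
    word_midpoint_offset: float = 3.0     # dB SL at 50% (above guessing)
    word_scale: float = 1.5               # dB

    def __post_init__(self) -> None:
        for p in (self.false_alarm, self.lapse, self.word_guess, self.word_lapse):
            if not (0 <= p < 1):
                raise ValueError("probabilities must lie in [0, 1)")
        if self.psychometric_scale <= 0 or self.word_scale <= 0:
            raise ValueError("psychometric scales must be positive")


def better_ear_threshold(profile: ListenerProfile, freq: float) -> float:
    try:
        left, right = profile.thresholds[float(freq)]
    except KeyError:
        raise MissingFrequencyError(f"no threshold at {freq} Hz") from None
    return min(left, right)


def pta(profile: ListenerProfile, freqs=SCREEN_FREQUENCIES) -> float:
    """Better-ear pure-tone average over the screening frequencies."""
    return float(np.mean([better_ear_threshold(profile, f) for f in freqs]))


def detection_probability(profile: ListenerProfile, freq: float, level_hl: float) -> float:
    thr = better_ear_threshold(profile, freq)
    core = _logistic(
        (level_hl - thr - profile.detection_midpoint_offset) / profile.psychometric_scale
    )
    return profile.false_alarm + (1 - profile.false_alarm - profile.lapse) * core


def respond_detection(
    profile: ListenerProfile, freq: float, level_hl: float, rng: np.random.Generator
) -> bool:
    """Bernoulli draw from the detection psychometric function."""
    return bool(rng.random() < detection_probability(profile, freq, level_hl))


def word_probability(profile: ListenerProfile, level_sl: float) -> float:
    core = _logistic((level_sl - profile.word_midpoint_offset) / profile.word_scale)
    return profile.word_guess + (1 - profile.word_guess - profile.word_lapse) * core


def respond_word(
    profile: ListenerProfile, level_sl: float, rng: np.random.Generator
) -> bool:
    """Bernoulli draw: correct identification of one closed-set word."""
    return bool(rng.random() < word_probability(profile, level_sl))


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a simulated validation cohort."""

    n_normal: int = 31
    n_impaired: int = 24
    severity_mix: dict[str, float] = field(
        default_factory=lambda: {"moderately_severe": 1 / 3, "severe": 1 / 3, "profound": 1 / 3}
    )
    age_range_months: tuple[float, float] = (0.0, 72.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_impaired < 0:
            raise ValueError("cohort counts must be >= 0")
        for label in self.severity_mix:
            if label not in SEVERITY_RANGES:
                raise ValueError(f"unknown severity label {label!r}")


def make_cohort(
    spec: CohortSpec, freqs=SCREEN_FREQUENCIES
) -> tuple[list[ListenerProfile], pd.DataFrame]:
    """Generate listener profiles plus the matching gold-standard threshold table.

    Normal-hearing thresholds draw uniformly (integer dB) from [0, 15] per
    ear and frequency; impaired thresholds draw from the disjoint severity
    band chosen for that child, both ears within the band.  The returned
    gold table (subject, frequency, ear, threshold) is exactly the drawn
    truth, so agreement statistics measure the screener, not the simulator.
    """
    rng = np.random.default_rng(spec.seed)
    profiles: list[ListenerProfile] = []
    rows: list[dict] = []

    def add(subject: str, band: tuple[int, int], group: str) -> None:
        thresholds = {}
        for f in freqs:
            left = int(rng.integers(band[0], band[1] + 1))
            right = int(rng.integers(band[0], band[1] + 1))
            thresholds[float(f)] = (float(left), float(right))
            rows.append({"subject": subject, "frequency": float(f), "ear": "left",
                         "threshold": float(left), "group": group})
            rows.append({"subject": subject, "frequency": float(f), "ear": "right",
                         "threshold": float(right), "group": group})
        lo, hi = spec.age_range_months
        age = float(rng.uniform(lo, hi))
        profiles.append(ListenerProfile(subject=subject, thresholds=thresholds,
                                        age_months=age))

    for i in range(spec.n_normal):
        add(f"N{i + 1:03d}", NORMAL_RANGE, "normal")

    labels = sorted(spec.severity_mix)
    weights = np.array([spec.severity_mix[k] for k in labels], dtype=float)
    if spec.n_impaired and weights.sum() <= 0:
        raise ValueError("severity mix weights must sum to > 0")
    for i in range(spec.n_impaired):
        label = labels[int(rng.choice(len(labels), p=weights / weights.sum()))]
        add(f"I{i + 1:03d}", SEVERITY_RANGES[label], label)

    gold = pd.DataFrame(rows, columns=["subject", "frequency", "ear", "threshold", "group"])
    return profiles, gold


def gold_label(
    gold: pd.DataFrame, subject: str, freq: float, cutoff: float = 60.0
) -> str:
    """Gold-standard screening label: refer iff the better-ear threshold exceeds the cutoff.

    A threshold exactly at the cutoff counts as pass.
    """
    sel = gold[(gold["subject"] == subject) & (gold["frequency"] == float(freq))]
    if sel.empty:
        raise MissingFrequencyError(f"no gold threshold for {subject} at {freq} Hz")
    best = sel["threshold"].min()
    return "refer" if best > cutoff else "pass"
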