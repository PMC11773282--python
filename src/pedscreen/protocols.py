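"""Age-gated screening and threshold-tracking procedures.

Three modules, selected automatically by age:

* BOA  (behavioral observation audiometry, 0-12 months): unconditioned
  behavioral responses to band-limited stimuli; thresholds tracked by a
  5-dB ascending method with thrice-at-level confirmation.
* SSAT (speech-spectrum awareness task, 12-36 months): detection of
  speech-spectrum stimuli; thresholds tracked by the Hughson-Westlake
  procedure (descend 10 dB after a response, ascend 5 dB after a miss,
  threshold at the lowest level with >=2 responses on 3 ascending trials).
* SRT  (speech recognition task, 36-72 months): closed-set picture
  identification of six spondee words; pass requires 5 of 6 correct.

A single-level screening session presents each frequency at the screening
level (default 60 dB HL) behind an A-weighted ambient-noise gate and
returns an automatic overall pass/refer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Protocol

import numpy as np

from .calibration import SCREEN_FREQUENCIES, NoiseGateConfig, noise_gate
from .listener_sim import ListenerProfile, pta, respond_detection, respond_word

__all__ = [
    "Module",
    "ScreeningConfig",
    "TrialRecord",
    "ThresholdResult",
    "SessionResult",
    "NoisyEnvironmentError",
    "NO_RESPONSE",
    "Responder",
    "SimulatedResponder",
    "DeterministicResponder",
    "select_module",
    "boa_ascending_threshold",
    "hughson_westlake_threshold",
    "srt_block",
    "run_screening_session",
    "determine_sensation_level",
]

NO_RESPONSE = "no_response"  # tracker hit the output ceiling without criterion


class Module(str, Enum):
    BOA = "BOA"
    SSAT = "SSAT"
    SRT = "SRT"


class NoisyEnvironmentError(RuntimeError):
    """Ambient noise at/above the gate threshold; carries the measured dBA."""

    def __init__(self, dba: float, threshold: float):
        super().__init__(f"ambient noise {dba:.1f} dBA >= gate threshold {threshold:.1f} dBA")
        self.dba = dba
        self.threshold = threshold


@dataclass(frozen=True)
class ScreeningConfig:
    frequencies: tuple[float, ...] = SCREEN_FREQUENCIES
    screen_level: float = 60.0    # dB HL
    gate: NoiseGateConfig = field(default_factory=NoiseGateConfig)
    max_level: float = 90.0       # dB HL output ceiling
    min_level: float = -10.0      # dB HL grid floor
    boa_start: float = 20.0       # dB HL
    step: float = 5.0             # dB grid

    def __post_init__(self) -> None:
        for lv in (self.screen_level, self.max_level, self.min_level, self.boa_start):
            if abs(lv / self.step - round(lv / self.step)) > 1e-9:
                raise ValueError(f"level {lv} not on the {self.step}-dB grid")


@dataclass(frozen=True)
class TrialRecord:
    index: int
    frequency: float
    level: float
    stimulus: str
    responded: bool
    annotation: str = ""   # e.g. reinforcement events; never alters state


@dataclass(frozen=True)
class ThresholdResult:
    frequency: float
    threshold: float | str      # dB HL on the 5-dB grid, or NO_RESPONSE
    method: str                 # "ascending" | "hughson_westlake"
    trials: tuple[TrialRecord, ...]


@dataclass(frozen=True)
class SessionResult:
    subject: str
    module: Module
    outcomes: dict[float, str]       # freq -> "responded"/"no_response" (SRT: all freqs share)
    words_correct: int | None        # SRT only
    overall: str                     # "pass" | "refer"
    trials: tuple[TrialRecord, ...]
    gate_dba: float
    seed: int | None = None


class Responder(Protocol):
    """What a screening procedure needs from a listener (real or simulated)."""

    def detect(self, freq: float, level_hl: float) -> bool: ...
    def identify_word(self, word: str, level_hl: float) -> bool: ...


class SimulatedResponder:
    """Wraps a :class:`ListenerProfile` and an RNG as a Responder.

    Word presentations at a given dB HL are converted to sensation level
    against the listener's own better-ear pure-tone average.
    """

    def __init__(self, profile: ListenerProfile, rng: np.random.Generator | int | None = None):
        self.profile = profile
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def detect(self, freq: float, level_hl: float) -> bool:
        return respond_detection(self.profile, freq, level_hl, self.rng)

    def identify_word(self, word: str, level_hl: float) -> bool:
        level_sl = level_hl - pta(self.profile)
        return respond_word(self.profile, level_sl, self.rng)


class DeterministicResponder:
    """Responds iff level >= a fixed per-frequency cutoff; for oracle walks."""

    def __init__(self, cutoff: float | dict[float, float], word_cutoff: float | None = None):
        self._cutoff = cutoff
        self._word_cutoff = word_cutoff if word_cutoff is not None else (
            cutoff if isinstance(cutoff, (int, float)) else 0.0
        )

    def detect(self, freq: float, level_hl: float) -> bool:
        c = self._cutoff[freq] if isinstance(self._cutoff, dict) else self._cutoff
        return level_hl >= c

    def identify_word(self, word: str, level_hl: float) -> bool:
        return level_hl >= self._word_cutoff


def select_module(age_months: float) -> Module:
    """BOA below 12 months, SSAT from 12 to 36, SRT from 36 to 72 (half-open bins)."""
    if age_months < 0 or age_months >= 72:
        raise ValueError(f"age {age_months} months outside the screener's 0-72 month range")
    if age_months < 12:
        return Module.BOA
    if age_months < 36:
        return Module.SSAT
    return Module.SRT


def _confirm_at_level(
    responder: Responder, freq: float, level: float, stimulus: str,
    trials: list[TrialRecord],
) -> bool:
    """Present up to 3 times at one level; confirmed iff >=2 responses.

    Stops early once 2 responses or 2 misses decide the outcome.
    """
    yes = no = 0
    while yes < 2 and no < 2:
        r = responder.detect(freq, level)
        trials.append(TrialRecord(len(trials), freq, level, stimulus, r))
        yes += r
        no += not r
    return yes >= 2


def boa_ascending_threshold(
    responder: Responder,
    freq: float,
    start: float | None = None,
    cfg: ScreeningConfig | None = None,
    stimulus: str = "band_noise",
) -> ThresholdResult:
    """Ascending minimum-response-level search.

    One presentation per level; a response triggers up to two confirmation
    presentations at the same level, and the level is accepted as the
    minimum response level when >=2 of the 3 draw responses.  Otherwise the
    level rises by one 5-dB step, up to the output ceiling.
    """
    cfg = cfg or ScreeningConfig()
    level = cfg.boa_start if start is None else start
    if abs(level / cfg.step - round(level / cfg.step)) > 1e-9:
        raise ValueError(f"start level {level} not on the {cfg.step}-dB grid")
    trials: list[TrialRecord] = []
    while level <= cfg.max_level:
        first = responder.detect(freq, level)
        trials.append(TrialRecord(len(trials), freq, level, stimulus, first))
        if first:
            yes, no = 1, 0
            while yes < 2 and no < 2:
                r = responder.detect(freq, level)
                trials.append(TrialRecord(len(trials), freq, level, stimulus, r))
                yes += r
                no += not r
            if yes >= 2:
                return ThresholdResult(freq, level, "ascending", tuple(trials))
        level += cfg.step
    return ThresholdResult(freq, NO_RESPONSE, "ascending", tuple(trials))


def hughson_westlake_threshold(
    responder: Responder,
    freq: float,
    start: float = 60.0,
    cfg: ScreeningConfig | None = None,
    stimulus: str = "band_noise",
) -> ThresholdResult:
    """Hughson-Westlake adaptive threshold search.

    Descend 10 dB after each response, ascend 5 dB after each miss;
    threshold is the lowest level collecting >=2 responses out of up to 3
    ascending-run presentations; a level that accumulates 3 ascending
    presentations with fewer than 2 responses has its tally cleared.
    Descent clips at the grid floor; repeated misses at the ceiling return
    NO_RESPONSE.
    """
    cfg = cfg or ScreeningConfig()
    if abs(start / cfg.step - round(start / cfg.step)) > 1e-9:
        raise ValueError(f"start level {start} not on the {cfg.step}-dB grid")
    trials: list[TrialRecord] = []
    asc_pres: dict[float, int] = {}
    asc_resp: dict[float, int] = {}
    level = min(start, cfg.max_level)
    ascending = False          # was this level reached by an ascent?
    ceiling_misses = 0
    floor_responses = 0
    # hard cap on total presentations guards against pathological responders
    while len(trials) < 200:
        r = responder.detect(freq, level)
        trials.append(TrialRecord(len(trials), freq, level, stimulus, r))
        if ascending:
            asc_pres[level] = asc_pres.get(level, 0) + 1
            asc_resp[level] = asc_resp.get(level, 0) + r
            if asc_resp[level] >= 2:
                return ThresholdResult(freq, level, "hughson_westlake", tuple(trials))
            if asc_pres[level] >= 3:
                asc_pres[level] = asc_resp[level] = 0
        if r:
            nxt = level - 2 * cfg.step
            if nxt < cfg.min_level:
                if level == cfg.min_level:
                    floor_responses += 1
                    if floor_responses >= 2:
                        return ThresholdResult(
                            freq, cfg.min_level, "hughson_westlake", tuple(trials)
                        )
                nxt = cfg.min_level
            level, ascending = nxt, False
        else:
            floor_responses = 0
            nxt = level + cfg.step
            if nxt > cfg.max_level:
                if level == cfg.max_level:
                    ceiling_misses += 1
                    if ceiling_misses >= 3:
                        return ThresholdResult(freq, NO_RESPONSE, "hughson_westlake", tuple(trials))
                nxt = cfg.max_level
            level, ascending = nxt, True
    return ThresholdResult(freq, NO_RESPONSE, "hughson_westlake", tuple(trials))


def srt_block(
    responder: Responder, words: list[str], level_hl: float
) -> tuple[int, str]:
    """One six-word closed-set block; pass iff >=5 of 6 identified correctly."""
    if len(words) != 6:
        raise ValueError(f"a block holds exactly 6 words, got {len(words)}")
    correct = sum(responder.identify_word(w, level_hl) for w in words)
    return correct, ("pass" if correct >= 5 else "refer")


DEFAULT_SRT_WORDS = ("word1", "word2", "word3", "word4", "word5", "word6")


def run_screening_session(
    responder: Responder,
    age_months: float,
    cfg: ScreeningConfig | None = None,
    ambient_dba: float = 40.0,
    subject: str = "anon",
    words: tuple[str, ...] = DEFAULT_SRT_WORDS,
    seed: int | None = None,
) -> SessionResult:
    """Single-level screening with automatic pass/refer.

    Denies with :class:`NoisyEnvironmentError` when the ambient level fails
    the gate.  BOA/SSAT: each frequency is presented at the screening level
    up to three times; the frequency passes with >=2 responses.  SRT: one
    six-word block at the screening level, pass iff 5 of 6 correct.
    Overall pass requires every tested frequency (or the word block) to pass.
    """
    cfg = cfg or ScreeningConfig()
    if not noise_gate(ambient_dba, cfg.gate):
        raise NoisyEnvironmentError(ambient_dba, cfg.gate.threshold_dba)
    module = select_module(age_months)
    trials: list[TrialRecord] = []
    outcomes: dict[float, str] = {}
    words_correct: int | None = None

    if module is Module.SRT:
        correct, verdict = srt_block(responder, list(words), cfg.screen_level)
        words_correct = correct
        for f in cfg.frequencies:
            outcomes[f] = "responded" if verdict == "pass" else "no_response"
        overall = verdict
    else:
        for f in cfg.frequencies:
            ok = _confirm_at_level(responder, f, cfg.screen_level, module.value, trials)
            outcomes[f] = "responded" if ok else "no_response"
        overall = "pass" if all(v == "responded" for v in outcomes.values()) else "refer"

    return SessionResult(
        subject=subject,
        module=module,
        outcomes=outcomes,
        words_correct=words_correct,
        overall=overall,
        trials=tuple(trials),
        gate_dba=ambient_dba,
        seed=seed,
    )


def determine_sensation_level(
    proportions: dict[float, float], criterion: float = 0.80
) -> float | None:
    """Smallest sensation level whose proportion correct meets the criterion.

    ``proportions`` maps dB SL -> proportion correct in [0, 1]; returns
    None when no tested level qualifies.
    """
    if not proportions:
        raise ValueError("no sensation levels supplied")
    for level in sorted(proportions):
        p = proportions[level]
        if not (0 <= p <= 1):
            raise ValueError(f"proportion {p} at {level} dB SL outside [0, 1]")
        if p >= criterion:
            return level
    return None
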