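"""Agreement statistics for beta-validating screener outcomes.

Screener pass/refer calls are cross-tabulated against gold-standard
audiometric labels (refer iff the better-ear threshold exceeds the
screening cutoff) per frequency and pooled, and chance-corrected agreement
is summarized by Cohen's kappa:

    po = (a + d) / n
    pe = ((a + b)(a + c) + (c + d)(b + d)) / n^2
    kappa = (po - pe) / (1 - pe)

with the large-sample standard error sqrt(po (1 - po) / (n (1 - pe)^2))
and a 95% Wald interval clipped to [-1, 1].  Qualitative labels follow the
conventional scale (poor / fair / moderate / good / very good, with exact
kappa = 1 reported as perfect agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .listener_sim import gold_label
from .protocols import SessionResult

__all__ = [
    "CrossTab2x2",
    "AgreementResult",
    "UndefinedKappaError",
    "cohen_kappa",
    "kappa_label",
    "agreement_by_frequency",
    "familiarity_filter",
]


class UndefinedKappaError(ZeroDivisionError):
    """Degenerate margins (pe = 1): kappa has no defined value."""


@dataclass(frozen=True)
class CrossTab2x2:
    """Screener (rows) x gold standard (columns) pass/refer counts.

    a: pass/pass, b: pass/refer, c: refer/pass, d: refer/refer.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty cross-tabulation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def __add__(self, other: "CrossTab2x2") -> "CrossTab2x2":
        return CrossTab2x2(self.a + other.a, self.b + other.b,
                           self.c + other.c, self.d + other.d)


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    label: str
    po: float
    pe: float
    n: int


def cohen_kappa(t: CrossTab2x2, se_method: str = "large_sample") -> AgreementResult:
    """Cohen's kappa with standard error, 95% CI, and qualitative label.

    ``se_method``: "large_sample" (default) uses sqrt(po(1-po)/(n(1-pe)^2));
    "fleiss" uses the Fleiss-Cohen-Everitt variance.
    """
    n = t.n
    po = (t.a + t.d) / n
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if pe >= 1.0:
        raise UndefinedKappaError("chance agreement pe = 1; kappa undefined")
    kappa = (po - pe) / (1 - pe)

    if se_method == "large_sample":
        se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    elif se_method == "fleiss":
        # Fleiss, Cohen & Everitt (1969) asymptotic variance for 2 categories
        p = [[t.a / n, t.b / n], [t.c / n, t.d / n]]
        row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]
        col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]
        term1 = sum(
            p[i][i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(2)
        )
        term2 = (1 - kappa) ** 2 * sum(
            p[i][j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
        )
        term3 = (kappa - pe * (1 - kappa)) ** 2
        se = math.sqrt(max(term1 + term2 - term3, 0.0) / (n * (1 - pe) ** 2))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    lo = max(kappa - 1.96 * se, -1.0)
    hi = min(kappa + 1.96 * se, 1.0)
    return AgreementResult(kappa=kappa, se=se, ci95=(lo, hi),
                           label=kappa_label(kappa), po=po, pe=pe, n=n)


def kappa_label(kappa: float) -> str:
    """Conventional qualitative band for a kappa value."""
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa == 1.0:
        return "perfect"
    if kappa >= 0.81:
        return "very good"
    if kappa >= 0.61:
        return "good"
    if kappa >= 0.41:
        return "moderate"
    if kappa >= 0.21:
        return "fair"
    return "poor"


def agreement_by_frequency(
    sessions: list[SessionResult],
    gold: pd.DataFrame,
    cutoff: float = 60.0,
) -> tuple[dict[float, CrossTab2x2], CrossTab2x2]:
    """Cross-tabulate screener vs gold labels per frequency, plus the pooled table.

    Each session contributes one cell per tested frequency; the pooled table
    is the cell-wise sum over frequencies (its n is therefore
    subjects x frequencies).
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    counts: dict[float, dict[str, int]] = {}
    for s in sessions:
        for f, outcome in s.outcomes.items():
            screener = "pass" if outcome == "responded" else "refer"
            truth = gold_label(gold, s.subject, f, cutoff)
            cell = ("a" if truth == "pass" else "b") if screener == "pass" else (
                "c" if truth == "pass" else "d")
            counts.setdefault(f, {"a": 0, "b": 0, "c": 0, "d": 0})[cell] += 1
    tables = {f: CrossTab2x2(**c) for f, c in sorted(counts.items())}
    pooled = CrossTab2x2(
        sum(t.a for t in tables.values()),
        sum(t.b for t in tables.values()),
        sum(t.c for t in tables.values()),
        sum(t.d for t in tables.values()),
    )
    return tables, pooled


def agreement_per_subject(
    sessions: list[SessionResult], gold: pd.DataFrame, cutoff: float = 60.0
) -> CrossTab2x2:
    """Alternative overall table: one cell per child (all-frequency concordance).

    Screener overall pass/refer crossed with a gold label that refers iff
    any frequency's better-ear threshold exceeds the cutoff.
    """
    a = b = c = d = 0
    for s in sessions:
        truth = "refer" if any(
            gold_label(gold, s.subject, f, cutoff) == "refer" for f in s.outcomes
        ) else "pass"
        if s.overall == "pass":
            a += truth == "pass"
            b += truth == "refer"
        else:
            c += truth == "pass"
            d += truth == "refer"
    return CrossTab2x2(a, b, c, d)


def familiarity_filter(
    familiarity: dict[str, float] | pd.Series, cutoff: float = 0.85
) -> list[str]:
    """Words identifiable by at least the cutoff proportion of children.

    The boundary is inclusive; input order is preserved.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    items = familiarity.items() if hasattr(familiarity, "items") else familiarity
    pairs = list(items)
    if not pairs:
        raise ValueError("empty familiarity table")
    for w, p in pairs:
        if not (0 <= p <= 1):
            raise ValueError(f"familiarity {p} for {w!r} outside [0, 1]")
    return [w for w, p in pairs if p >= cutoff]
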