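"""Differential rhythmicity between two conditions.

Each gene's rhythm of a given class is compared across paired conditions
(e.g. wild type vs knockout): a rhythm present only in condition A is
*abolished*, present only in B is *gained*, and when present in both the
relative amplitudes (amplitude / mean, robust to baseline shifts between
genotypes) decide *dampened* / *increased* / *unchanged*.  Also provides
cohort count/percentage summaries, set-overlap summaries (Venn-style
method comparisons), and the harmonic period-lock check relating
ultradian periods to the circadian period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import GeneCall, relative_amplitude

CATEGORIES = ("abolished", "dampened", "increased", "gained", "unchanged")


@dataclass(frozen=True)
class RhythmDelta:
    """Per-gene differential-rhythm record for one rhythm class."""

    gene_id: str
    category: str
    rel_amplitude_a: float | None
    rel_amplitude_b: float | None
    phase_a: float | None
    phase_b: float | None
    period_a: float | None
    period_b: float | None


def categorize(call_a: GeneCall, call_b: GeneCall, rhythm_class: str) -> RhythmDelta:
    """Differential category of one gene's rhythm of the given class.

    When both conditions carry a matching component, the
    largest-amplitude one in each condition represents the gene and the
    comparison is on relative amplitude with strict inequalities (exact
    ties fall to "unchanged").
    """
    if call_a.gene_id != call_b.gene_id:
        raise ValueError(
            f"gene id mismatch: {call_a.gene_id!r} vs {call_b.gene_id!r}"
        )
    comps_a = call_a.matched.get(rhythm_class, [])
    comps_b = call_b.matched.get(rhythm_class, [])

    def best(call, comps):
        if not comps:
            return None, None, None, None
        c = max(comps, key=lambda c: c.amplitude)
        return (
            relative_amplitude(c, call.mean),
            c.peak_time,
            c.period,
            c,
        )

    ra, pa, ta, _ = best(call_a, comps_a)
    rb, pb, tb, _ = best(call_b, comps_b)

    if comps_a and not comps_b:
        category = "abolished"
    elif comps_b and not comps_a:
        category = "gained"
    elif not comps_a and not comps_b:
        category = "unchanged"
    elif rb < ra:
        category = "dampened"
    elif rb > ra:
        category = "increased"
    else:
        category = "unchanged"
    return RhythmDelta(call_a.gene_id, category, ra, rb, pa, pb, ta, tb)


@dataclass(frozen=True)
class CohortSummary:
    """Category counts with exact fractions and one-decimal percentages."""

    counts: dict[str, int]
    total: int
    fractions: dict[str, float]
    percentages: dict[str, float]


def cohort_summary(deltas: list[RhythmDelta]) -> CohortSummary:
    """Counts and percentages per differential category."""
    if not deltas:
        raise ValueError("deltas must be nonempty")
    counts = {c: 0 for c in CATEGORIES}
    for d in deltas:
        counts[d.category] += 1
    total = len(deltas)
    fractions = {c: counts[c] / total for c in CATEGORIES}
    percentages = {c: round(100.0 * fractions[c], 1) for c in CATEGORIES}
    return CohortSummary(counts, total, fractions, percentages)


def overlap_summary(set_a, set_b) -> tuple[int, int, int]:
    """(|A∩B|, |A\\B|, |B\\A|) for two gene-id sets."""
    a, b = set(set_a), set(set_b)
    return len(a & b), len(a - b), len(b - a)


@dataclass(frozen=True)
class HarmonicLock:
    """Nearest-integer period ratio and the implied circadian period."""

    ratio: int
    implied_circadian: float
    locked: bool


def harmonic_lock_ratio(
    period_harmonic: float,
    period_circadian: float,
    tolerance: float = 0.05,
) -> HarmonicLock:
    """Check whether an ultradian period is an integer fraction of circadian.

    ``ratio = round(T_circadian / T_harmonic)``; the harmonic is
    period-locked when the implied circadian period
    ``ratio * T_harmonic`` is within the relative tolerance of the
    observed circadian period.
    """
    if period_harmonic <= 0 or period_circadian <= 0:
        raise ValueError("periods must be positive")
    ratio = int(round(period_circadian / period_harmonic))
    implied = ratio * period_harmonic
    locked = (
        ratio >= 1
        and abs(implied - period_circadian) / period_circadian <= tolerance
    )
    return HarmonicLock(ratio, implied, locked)
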