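"""Rhythm classification: criteria windows, gene calls, dominant rhythms.

A decomposition's components are matched against closed period/decay
windows plus an expression threshold (and, for binding-site series, an
optional peak-time window).  A gene carries a class flag for every class
with at least one matching component, so a gene can be simultaneously
circadian and 12-h cycling; the *dominant* class is the class of the
single largest-amplitude component, and dominant labels are mutually
exclusive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pencil import Decomposition, OscillationComponent


@dataclass(frozen=True)
class RhythmCriteria:
    """Closed classification windows for one rhythm class."""

    name: str
    period_window: tuple[float, float]
    decay_window: tuple[float, float]
    mean_threshold: float = 0.0
    peak_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.period_window[0] < self.period_window[1]:
            raise ValueError(f"invalid period window {self.period_window}")
        if not self.decay_window[0] < self.decay_window[1]:
            raise ValueError(f"invalid decay window {self.decay_window}")

    def matches(self, component: OscillationComponent, mean: float) -> bool:
        """Inclusive-window membership plus strict mean threshold."""
        t_lo, t_hi = self.period_window
        d_lo, d_hi = self.decay_window
        ok = (
            t_lo <= component.period <= t_hi
            and d_lo <= component.decay <= d_hi
            and mean > self.mean_threshold
        )
        if ok and self.peak_window is not None:
            p_lo, p_hi = self.peak_window
            ok = p_lo <= component.peak_time <= p_hi
        return ok


# Windows exactly as used for the hepatic in-vivo transcriptome, the
# serum-synchronized MMH-D3 culture (tighter windows chosen from the
# observed period distributions), and the 12-h binding-site (cistrome)
# selection with its 0-3 h peak-time gate.
_PRESETS: dict[str, RhythmCriteria] = {
    "liver_circadian": RhythmCriteria(
        "liver_circadian", (21.0, 25.0), (0.8, 1.2), 0.1
    ),
    "liver_12h": RhythmCriteria("liver_12h", (10.5, 13.5), (0.8, 1.2), 0.1),
    "liver_8h": RhythmCriteria("liver_8h", (7.0, 9.0), (0.8, 1.2), 0.1),
    "mmh_d3_circadian": RhythmCriteria(
        "mmh_d3_circadian", (20.5, 23.5), (0.9, 1.1), 0.0
    ),
    "mmh_d3_12h": RhythmCriteria("mmh_d3_12h", (9.5, 12.5), (0.9, 1.1), 0.0),
    "cistrome_12h": RhythmCriteria(
        "cistrome_12h", (10.5, 13.5), (0.8, 1.2), 0.0, (0.0, 3.0)
    ),
}


def criteria_preset(name: str) -> RhythmCriteria:
    """Named criteria preset; raises listing the valid names if unknown."""
    try:
        return _PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(_PRESETS))
        raise ValueError(f"unknown preset {name!r}; valid presets: {valid}") from None


def relative_amplitude(component: OscillationComponent, mean: float) -> float:
    """Amplitude divided by the gene's mean expression (mean must be > 0)."""
    if mean <= 0:
        raise ValueError(f"mean expression must be positive, got {mean}")
    return component.amplitude / mean


def classify_components(
    decomposition: Decomposition, criteria: RhythmCriteria
) -> list[OscillationComponent]:
    """Components of the decomposition that satisfy the criteria."""
    return [
        c for c in decomposition.components
        if criteria.matches(c, decomposition.mean)
    ]


@dataclass
class GeneCall:
    """Per-gene rhythm labels.

    ``flags`` holds every class with at least one matching component;
    ``matched`` maps class name to its matching components (amplitude
    order preserved); ``dominant`` is the class of the overall
    largest-amplitude component if that component matched a class, else
    None.
    """

    gene_id: str
    flags: set[str]
    dominant: str | None
    matched: dict[str, list[OscillationComponent]]
    mean: float

    def relative_amplitudes(self, rhythm_class: str) -> list[float]:
        return [
            relative_amplitude(c, self.mean)
            for c in self.matched.get(rhythm_class, [])
        ]


def call_gene(
    gene_id: str,
    decomposition: Decomposition,
    criteria_by_class: dict[str, RhythmCriteria],
) -> GeneCall:
    """Classify all components and derive class flags plus the dominant class."""
    matched = {
        cls: classify_components(decomposition, crit)
        for cls, crit in criteria_by_class.items()
    }
    flags = {cls for cls, comps in matched.items() if comps}
    dominant = None
    if decomposition.components:
        top = decomposition.components[0]  # already amplitude-ranked
        for cls in criteria_by_class:
            if any(c is top for c in matched[cls]):
                dominant = cls
                break
    return GeneCall(
        gene_id=gene_id,
        flags=flags,
        dominant=dominant,
        matched={cls: comps for cls, comps in matched.items() if comps},
        mean=decomposition.mean,
    )
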