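"""Synthetic expression cohorts with known ground truth.

Emulates the statistical structure of a rhythm-profiling time course:
24 timepoints at 2-h spacing over 48 h in duplicate, a log-normal
baseline-expression distribution with a non-expressed fraction below the
background threshold, genes carrying 0-3 superimposed damped oscillations
with periods near 24, 12, and 8 h, 12-h phases drawn from a bimodal
circular distribution with dawn/dusk modes, and an optional paired
"knockout" condition in which 12-h components are abolished, dampened, or
increased.  Every draw is recorded so recovery of periods, decays,
amplitudes, phases, class labels, and condition effects can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pencil import OscillationComponent
from .preprocess import ExpressionMatrix, check_uniform_timepoints
from .signals import CoverageProfile

GENE_CLASSES = (
    "null",
    "circadian",
    "twelvehour",
    "mixed",
    "eighthour",
    "subthreshold",
)

#: Period band used by the generator for its 12-h components; matches the
#: 12-h classification window so noise-free recovery is exact.
TWELVE_H_BAND = (10.5, 13.5)


@dataclass(frozen=True)
class PhaseModel:
    """Bimodal circular model for 12-h peak times.

    A mixture of two wrapped-normal modes (hours on the 24-h day); the
    defaults put the modes at dawn (0 h) and dusk (12 h) with equal
    weight and 1-h spread.
    """

    modes: tuple[float, float] = (0.0, 12.0)
    sd: float = 1.0
    weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("phase-model weights must sum to 1")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        which = rng.random(size) < self.weights[0]
        centers = np.where(which, self.modes[0], self.modes[1])
        return (centers + rng.normal(0.0, self.sd, size)) % 24.0


@dataclass(frozen=True)
class EffectModel:
    """How the paired condition alters 12-h components.

    Proportions (over genes that truly carry a 12-h component) must sum
    to 1.  The defaults reproduce the observed split of 12-h rhythms that
    were abolished, dampened, or increased upon loss of the 12-h clock
    regulator.  The dampening factor halves the amplitude — a dampened
    rhythm remains detectable, which is what distinguishes it from an
    abolished one.
    """

    abolished: float = 0.545
    dampened: float = 0.316
    increased: float = 0.139
    unchanged: float = 0.0
    dampen_factor: float = 0.5
    boost_factor: float = 2.0

    def __post_init__(self) -> None:
        props = (self.abolished, self.dampened, self.increased, self.unchanged)
        if any(p < 0 or p > 1 for p in props):
            raise ValueError("effect proportions must lie in [0, 1]")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"effect proportions must sum to 1, got {sum(props)}")
        if not 0 < self.dampen_factor < 1:
            raise ValueError(
                f"dampening factor must be < 1, got {self.dampen_factor}"
            )
        if self.boost_factor <= 1:
            raise ValueError(f"boost factor must be > 1, got {self.boost_factor}")


def _default_fractions() -> dict[str, float]:
    return {
        "null": 0.30,
        "circadian": 0.20,
        "twelvehour": 0.15,
        "mixed": 0.15,
        "eighthour": 0.08,
        "subthreshold": 0.12,
    }


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort.

    ``noise_sd`` is the additive Gaussian noise scale as a fraction of
    each gene's baseline mean; ``rel_amplitude_range`` bounds the
    per-component amplitude relative to the baseline.  With the defaults
    (relative amplitude 0.3-0.7, noise 0.1) the amplitude-to-noise ratio
    averages 5.
    """

    n_genes: int = 1000
    timepoints: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 48.0, 2.0)
    )
    n_replicates: int = 2
    class_fractions: dict[str, float] = field(default_factory=_default_fractions)
    baseline_lognormal: tuple[float, float] = (1.0, 1.2)
    noise_sd: float = 0.1
    rel_amplitude_range: tuple[float, float] = (0.3, 0.7)
    phase_model: PhaseModel = field(default_factory=PhaseModel)
    effect_model: EffectModel = field(default_factory=EffectModel)
    seed: int = 0

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        check_uniform_timepoints(self.timepoints)
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        fracs = list(self.class_fractions.values())
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {sum(fracs)}")


@dataclass
class GeneTruth:
    """Generator-side record for one gene."""

    gene_id: str
    class_label: str
    mean: float
    components: tuple[OscillationComponent, ...]
    effect: str = "unchanged"
    components_b: tuple[OscillationComponent, ...] | None = None


@dataclass
class GroundTruth:
    """Per-gene truth records, indexable by gene id."""

    genes: list[GeneTruth]

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}

    def __getitem__(self, gene_id: str) -> GeneTruth:
        return self._by_id[gene_id]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self):
        import pandas as pd

        rows = []
        for g in self.genes:
            if g.components:
                for i, c in enumerate(g.components):
                    rows.append(
                        {
                            "gene_id": g.gene_id,
                            "class": g.class_label,
                            "mean": g.mean,
                            "effect": g.effect,
                            "component": i,
                            "period": c.period,
                            "decay": c.decay,
                            "amplitude": c.amplitude,
                            "peak_time": c.peak_time,
                        }
                    )
            else:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "class": g.class_label,
                        "mean": g.mean,
                        "effect": g.effect,
                        "component": -1,
                        "period": np.nan,
                        "decay": np.nan,
                        "amplitude": np.nan,
                        "peak_time": np.nan,
                    }
                )
        return pd.DataFrame(rows)


def simulate_series(
    components,
    mean: float,
    noise_sd: float,
    timepoints,
    replicates: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Forward model: mean + damped cosines + i.i.d. Gaussian noise.

    Returns an array of shape ``(n_timepoints, replicates)``; replicates
    share the true components and differ only in noise.
    """
    t = np.asarray(timepoints, dtype=float)
    check_uniform_timepoints(t)
    if mean < 0:
        raise ValueError("mean must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    clean = np.full(t.size, float(mean))
    for c in components:
        clean = clean + c.evaluate(t)
    out = np.repeat(clean[:, None], replicates, axis=1)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, (t.size, replicates))
    return out


def _draw_component(
    rng: np.random.Generator,
    kind: str,
    baseline: float,
    spec: SyntheticSpec,
    peak: float | None = None,
) -> OscillationComponent:
    """One component with class-appropriate period/decay/amplitude/phase."""
    if kind == "circadian":
        period = float(np.clip(rng.normal(21.70, 2.58), 21.2, 24.8))
        peak_t = rng.uniform(0.0, period) if peak is None else peak
    elif kind == "twelvehour":
        period = float(np.clip(rng.normal(11.62, 0.48), 10.8, 13.2))
        peak_t = spec.phase_model.draw(rng, 1)[0] if peak is None else peak
    elif kind == "eighthour":
        period = float(np.clip(rng.normal(8.0, 0.3), 7.2, 8.8))
        peak_t = rng.uniform(0.0, period) if peak is None else peak
    else:  # pragma: no cover - internal misuse
        raise ValueError(kind)
    decay = float(rng.uniform(0.9, 1.1))
    lo, hi = spec.rel_amplitude_range
    amplitude = float(rng.uniform(lo, hi)) * baseline
    return OscillationComponent.from_peak_time(period, decay, amplitude, peak_t)


def _component_kinds(class_label: str) -> tuple[str, ...]:
    return {
        "null": (),
        "circadian": ("circadian",),
        "twelvehour": ("twelvehour",),
        "mixed": ("circadian", "twelvehour"),
        "eighthour": ("eighthour",),
        "subthreshold": ("twelvehour",),
    }[class_label]


def _draw_truth(spec: SyntheticSpec, rng: np.random.Generator) -> list[GeneTruth]:
    classes = list(spec.class_fractions)
    probs = np.array([spec.class_fractions[c] for c in classes])
    labels = rng.choice(classes, size=spec.n_genes, p=probs)
    meanlog, sdlog = spec.baseline_lognormal
    truths = []
    for i, label in enumerate(labels):
        if label == "subthreshold":
            baseline = float(rng.uniform(0.01, 0.09))
        else:
            baseline = float(np.exp(rng.normal(meanlog, sdlog)))
            while baseline <= 0.15:  # keep expressed genes above the filter
                baseline = float(np.exp(rng.normal(meanlog, sdlog)))
        comps = tuple(
            _draw_component(rng, kind, baseline, spec)
            for kind in _component_kinds(label)
        )
        truths.append(GeneTruth(f"gene_{i:05d}", label, baseline, comps))
    return truths


def _truth_matrix(
    truths: list[GeneTruth],
    spec: SyntheticSpec,
    rng: np.random.Generator,
    condition_b: bool = False,
) -> ExpressionMatrix:
    values = np.empty((len(truths), spec.timepoints.size, spec.n_replicates))
    for i, g in enumerate(truths):
        comps = g.components_b if condition_b else g.components
        values[i] = simulate_series(
            comps,
            g.mean,
            spec.noise_sd * g.mean,
            spec.timepoints,
            spec.n_replicates,
            rng,
        )
    return ExpressionMatrix([g.gene_id for g in truths], spec.timepoints, values)


def simulate_cohort(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """One-condition cohort: expression matrix plus full ground truth."""
    rng = np.random.default_rng(spec.seed)
    truths = _draw_truth(spec, rng)
    matrix = _truth_matrix(truths, spec, rng)
    return matrix, GroundTruth(truths)


def _is_twelve_h(component: OscillationComponent) -> bool:
    lo, hi = TWELVE_H_BAND
    return lo <= component.period <= hi


def _apply_effect(
    g: GeneTruth, effect: str, model: EffectModel
) -> tuple[OscillationComponent, ...]:
    factor = {
        "abolished": 0.0,
        "dampened": model.dampen_factor,
        "increased": model.boost_factor,
        "unchanged": 1.0,
    }[effect]
    out = []
    for c in g.components:
        if _is_twelve_h(c):
            out.append(replace(c, amplitude=c.amplitude * factor))
        else:
            out.append(c)
    return tuple(out)


def simulate_two_conditions(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Paired cohorts: condition B alters 12-h amplitudes per the effect model.

    Genes carrying a true 12-h component are partitioned exactly into
    abolished / dampened / increased / unchanged per the effect-model
    proportions (largest-remainder apportionment, order randomized); all
    other components are identical between conditions, so conditions
    differ only in their 12-h rhythms and in the noise draws.
    """
    rng = np.random.default_rng(spec.seed)
    truths = _draw_truth(spec, rng)
    model = spec.effect_model

    twelve_idx = [i for i, g in enumerate(truths) if any(map(_is_twelve_h, g.components))]
    n12 = len(twelve_idx)
    props = {
        "abolished": model.abolished,
        "dampened": model.dampened,
        "increased": model.increased,
        "unchanged": model.unchanged,
    }
    counts = {k: int(np.floor(p * n12)) for k, p in props.items()}
    remainders = sorted(
        props, key=lambda k: (props[k] * n12) - counts[k], reverse=True
    )
    for k in remainders:
        if sum(counts.values()) >= n12:
            break
        counts[k] += 1
    labels = [k for k in ("abolished", "dampened", "increased", "unchanged")
              for _ in range(counts[k])]
    order = rng.permutation(n12)
    for pos, idx in enumerate(order):
        g = truths[twelve_idx[idx]]
        g.effect = labels[pos]
    for g in truths:
        g.components_b = _apply_effect(g, g.effect, model)

    matrix_a = _truth_matrix(truths, spec, rng)
    matrix_b = _truth_matrix(truths, spec, rng, condition_b=True)
    return matrix_a, matrix_b, GroundTruth(truths)


def simulate_coverage_profile(
    pre_pause_level: float,
    body_level: float,
    pre_pause_length: int,
    body_length: int,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    bin_width: float = 1.0,
) -> CoverageProfile:
    """Piecewise-constant run-on coverage track with a recorded pause boundary."""
    if pre_pause_length <= 0 or body_length <= 0:
        raise ValueError("segment lengths must be positive")
    if pre_pause_level < 0 or body_level < 0:
        raise ValueError("signal levels must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    density = np.concatenate(
        [
            np.full(pre_pause_length, float(pre_pause_level)),
            np.full(body_length, float(body_level)),
        ]
    )
    if noise_sd > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        density = np.clip(density + rng.normal(0.0, noise_sd, density.size), 0.0, None)
    return CoverageProfile(
        density=density, boundary=pre_pause_length, bin_width=bin_width
    )
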