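"""Matrix-pencil decomposition of uniformly sampled time series.

A uniformly sampled series is modelled as a mean plus a small number of
exponentially damped sinusoids,

    x(t) = mu + sum_k A_k * d_k**(t/T_k) * cos(2*pi*t/T_k + phi_k) + residual,

where ``T_k`` is the period in hours, ``d_k`` the per-cycle amplitude ratio
(1 = sustained, <1 damped, >1 growing), ``A_k`` the amplitude in expression
units and ``phi_k`` the mathematical phase in radians.  The estimator is the
matrix-pencil (eigenvalue/pencil) method: the poles ``z_j`` of the signal are
the generalized eigenvalues of a pair of shifted Hankel matrices built from
the mean-adjusted series, and each complex-conjugate pole pair maps to one
oscillatory component.  Unlike fixed-period regression methods, the pencil
recovers *all* superimposed oscillations without pre-assigning a period
range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi

#: Singular values below this fraction of the largest are treated as noise
#: directions and pruned before the pencil eigen-step.
RANK_TOLERANCE = 1e-10

#: Absolute tolerance used when deciding whether a pole is real (trend) or a
#: member of a complex-conjugate pair.
CONJUGATE_TOLERANCE = 1e-8


@dataclass(frozen=True)
class OscillationComponent:
    """One exponentially damped sinusoid.

    Attributes
    ----------
    period:
        Period ``T`` in hours, > 0.
    decay:
        Per-cycle amplitude ratio ``d`` (dimensionless); 1 means sustained.
    amplitude:
        Amplitude ``A`` in expression units, >= 0.
    phase:
        Mathematical phase ``phi`` in radians, wrapped to ``[0, 2*pi)``.
    """

    period: float
    decay: float
    amplitude: float
    phase: float

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.decay <= 0:
            raise ValueError(f"decay must be positive, got {self.decay}")
        object.__setattr__(self, "phase", float(self.phase) % TWO_PI)

    @property
    def peak_time(self) -> float:
        """Biological phase: time of peak of the undamped cosine, in [0, T)."""
        return biological_phase(self)

    @classmethod
    def from_peak_time(
        cls, period: float, decay: float, amplitude: float, peak_time: float
    ) -> "OscillationComponent":
        """Build a component from its time of peak instead of its phase."""
        phase = (-TWO_PI * peak_time / period) % TWO_PI
        return cls(period=period, decay=decay, amplitude=amplitude, phase=phase)

    def evaluate(self, t: np.ndarray | float) -> np.ndarray:
        """Component value at time(s) ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        return (
            self.amplitude
            * self.decay ** (t / self.period)
            * np.cos(TWO_PI * t / self.period + self.phase)
        )


def biological_phase(component: OscillationComponent) -> float:
    """Time of peak of the undamped cosine: ``((-phi) mod 2*pi) * T / (2*pi)``."""
    p = ((-component.phase) % TWO_PI) * component.period / TWO_PI
    return p % component.period


@dataclass(frozen=True)
class Decomposition:
    """Result of a matrix-pencil fit: mean + ranked components + residual.

    Components are sorted by amplitude descending, ties broken by period
    descending.
    """

    mean: float
    components: tuple[OscillationComponent, ...]
    residual_rms: float
    n_samples: int
    dt: float
    pencil_l: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))


def _rank_key(c: OscillationComponent) -> tuple[float, float]:
    return (-c.amplitude, -c.period)


def decompose(
    series: np.ndarray,
    dt: float = 2.0,
    k: int = 3,
    pencil_fraction: float = 0.5,
    t_start: float = 0.0,
    decay_per_cycle: bool = True,
) -> Decomposition:
    """Decompose a uniform series into up to ``k`` damped sinusoids.

    Parameters
    ----------
    series:
        Sampled values at uniform spacing ``dt`` hours, first sample at
        ``t_start``.
    dt:
        Sampling interval in hours.
    k:
        Maximum number of oscillatory components returned.
    pencil_fraction:
        Pencil parameter as a fraction of the series length; the Hankel
        window is ``L = round(pencil_fraction * N)``.
    t_start:
        Time of the first sample; phases and amplitudes are referred to
        absolute time so that ``reconstruct`` evaluates at the original
        hours.
    decay_per_cycle:
        If True (default) report decay as the per-cycle ratio
        ``|z|**(T/dt)``; if False report the per-sample pole magnitude
        ``|z|``.

    Notes
    -----
    Poles whose period exceeds the observation span ``N*dt`` are treated as
    trend; poles at or beyond the Nyquist limit (period <= 2*dt) are not
    identifiable and are discarded.  Both still participate in the
    least-squares coefficient fit so the reported components are not biased
    by the trend.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 2 * (2 * k + 1):
        raise ValueError(
            f"series too short: need at least {2 * (2 * k + 1)} samples "
            f"for k={k}, got {n}"
        )
    if dt <= 0:
        raise ValueError("dt must be positive")

    mu = float(x.mean())
    y = x - mu

    pencil_l = int(round(pencil_fraction * n))
    max_rank = 2 * k + 1
    # keep the pencil admissible: rank <= L <= N - rank
    pencil_l = min(max(pencil_l, max_rank), n - max_rank)

    if np.max(np.abs(y)) <= 1e-300:
        return Decomposition(mu, (), 0.0, n, dt, pencil_l)

    # Hankel data matrix, rows (N-L) x (L+1); Y1 drops the last column,
    # Y2 drops the first.  Pencil eigenvalues of (Y2, Y1) are the poles.
    idx = np.arange(n - pencil_l)[:, None] + np.arange(pencil_l + 1)[None, :]
    big = y[idx]
    y1 = big[:, :-1]
    y2 = big[:, 1:]

    u, s, vh = np.linalg.svd(y1, full_matrices=False)
    rank = int(np.sum(s > RANK_TOLERANCE * s[0]))
    rank = min(rank, max_rank)
    if rank == 0:
        return Decomposition(mu, (), float(np.sqrt(np.mean(y**2))), n, dt, pencil_l)

    a = (u[:, :rank].T @ y2 @ vh[:rank].T) / s[:rank]
    poles = np.linalg.eigvals(a)

    # classify poles: real -> trend; conjugate pairs -> oscillations
    osc_poles: list[complex] = []
    unmatched = 0
    pos = [z for z in poles if z.imag > CONJUGATE_TOLERANCE]
    neg = [z for z in poles if z.imag < -CONJUGATE_TOLERANCE]
    for z in pos:
        if neg:
            dists = [abs(np.conj(z) - w) for w in neg]
            j = int(np.argmin(dists))
            if dists[j] <= CONJUGATE_TOLERANCE * max(1.0, abs(z)):
                neg.pop(j)
                osc_poles.append(z)
                continue
        unmatched += 1
    unmatched += len(neg)
    if unmatched:
        logger.warning("discarding %d unpaired complex pole(s)", unmatched)

    # least-squares coefficients against the full pole basis plus a constant,
    # so trend poles absorb what they should
    basis_poles = np.asarray(poles, dtype=complex)
    nn = np.arange(n)
    basis = np.empty((n, basis_poles.size + 1), dtype=complex)
    basis[:, 0] = 1.0
    if basis_poles.size:
        basis[:, 1:] = basis_poles[None, :] ** nn[:, None]
    coef, *_ = np.linalg.lstsq(basis, y.astype(complex), rcond=None)

    span = n * dt
    components: list[OscillationComponent] = []
    for z in osc_poles:
        omega = math.atan2(z.imag, z.real)  # in (0, pi)
        period = TWO_PI * dt / omega
        if period > span or period <= 2 * dt:
            continue
        j = int(np.argmin(np.abs(basis_poles - z))) + 1
        c = coef[j]
        amplitude = 2.0 * abs(c)
        phase = math.atan2(c.imag, c.real)
        mag = abs(z)
        decay_cycle = mag ** (period / dt)
        # refer phase/amplitude to absolute time if the series starts at t_start
        if t_start != 0.0:
            phase = phase - TWO_PI * t_start / period
            amplitude = amplitude * decay_cycle ** (-t_start / period)
        decay = decay_cycle if decay_per_cycle else mag
        components.append(
            OscillationComponent(
                period=period, decay=decay, amplitude=amplitude, phase=phase
            )
        )

    components.sort(key=_rank_key)
    components = components[:k]

    # damped sinusoids have a nonzero sample mean over a finite window; the
    # reported mu makes the reconstruction unbiased at the sample times
    times = t_start + dt * nn
    comp_sum = np.zeros(n)
    for comp in components:
        d_cycle = comp.decay if decay_per_cycle else comp.decay ** (comp.period / dt)
        comp_sum = comp_sum + comp.amplitude * d_cycle ** (
            times / comp.period
        ) * np.cos(TWO_PI * times / comp.period + comp.phase)
    mu = float(x.mean() - comp_sum.mean())
    residual_rms = float(np.sqrt(np.mean((x - mu - comp_sum) ** 2)))

    return Decomposition(
        mean=mu,
        components=tuple(components),
        residual_rms=residual_rms,
        n_samples=n,
        dt=dt,
        pencil_l=pencil_l,
    )


def reconstruct(
    decomposition: Decomposition,
    timepoints: np.ndarray,
    include: list[int] | None = None,
) -> np.ndarray:
    """Evaluate ``mu + sum of included components`` at the given hours.

    ``include`` selects components by index into
    ``decomposition.components``; None means all.
    """
    t = np.asarray(timepoints, dtype=float)
    comps = decomposition.components
    if include is None:
        chosen = list(range(len(comps)))
    else:
        chosen = list(include)
        for i in chosen:
            if not (0 <= i < len(comps)):
                raise IndexError(
                    f"unknown component index {i}; decomposition has "
                    f"{len(comps)} component(s)"
                )
    out = np.full(t.shape, decomposition.mean, dtype=float)
    for i in chosen:
        out += comps[i].evaluate(t)
    return out


def remove_components(
    series: np.ndarray,
    decomposition: Decomposition,
    period_window: tuple[float, float],
    timepoints: np.ndarray | None = None,
) -> np.ndarray:
    """Subtract every component whose period falls in ``period_window``.

    Used e.g. to strip all superimposed circadian rhythms from a series
    before re-testing it for ultradian rhythmicity.
    """
    lo, hi = period_window
    if lo > hi:
        raise ValueError(f"inverted period window: [{lo}, {hi}]")
    x = np.asarray(series, dtype=float)
    if timepoints is None:
        timepoints = decomposition.dt * np.arange(x.size)
    t = np.asarray(timepoints, dtype=float)
    out = x.astype(float).copy()
    for comp in decomposition.components:
        if lo <= comp.period <= hi:
            out -= comp.evaluate(t)
    return out
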