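"""Expression-matrix container and preparation steps.

Covers replicate averaging, the expressed-gene filter, derivation of the
background expression threshold from non-expressed marker genes, polynomial
detrending with mean restoration, and log2 preparation for downstream rank
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionMatrix:
    """Genes x uniformly spaced timepoints (x optional replicates).

    ``values`` has shape ``(n_genes, n_timepoints)`` or
    ``(n_genes, n_timepoints, n_replicates)``.  Timepoints are hours and
    must be strictly increasing with uniform spacing.
    """

    genes: list[str]
    timepoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be 2-D or 3-D")
        if self.values.shape[0] != len(self.genes):
            raise ValueError("values row count does not match gene count")
        if self.values.shape[1] != self.timepoints.size:
            raise ValueError("values column count does not match timepoints")
        check_uniform_timepoints(self.timepoints)

    @property
    def dt(self) -> float:
        return float(self.timepoints[1] - self.timepoints[0])

    @property
    def n_replicates(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[2]

    def series(self, gene: str) -> np.ndarray:
        """Single-gene series (replicate-averaged if replicates present)."""
        i = self.genes.index(gene)
        v = self.values[i]
        return v if v.ndim == 1 else v.mean(axis=1)


def check_uniform_timepoints(timepoints: np.ndarray, rtol: float = 1e-9) -> float:
    """Validate strictly increasing, uniformly spaced hours; return dt."""
    t = np.asarray(timepoints, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two timepoints")
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        i = int(np.argmax(gaps <= 0))
        raise ValueError(
            f"timepoints not strictly increasing at t={t[i]} -> t={t[i + 1]}"
        )
    dt = gaps[0]
    bad = np.where(np.abs(gaps - dt) > rtol * max(dt, 1.0))[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-uniform sampling: gap {gaps[i]:g} h between t={t[i]:g} "
            f"and t={t[i + 1]:g} (expected {dt:g} h)"
        )
    return float(dt)


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Arithmetic mean across replicates; removes the replicate axis."""
    v = matrix.values
    if not np.all(np.isfinite(v)):
        gi, ti = np.argwhere(~np.isfinite(v.reshape(v.shape[0], v.shape[1], -1)))[0][:2]
        raise ValueError(
            f"missing value for gene {matrix.genes[gi]!r} at "
            f"t={matrix.timepoints[ti]:g} h"
        )
    averaged = v if v.ndim == 2 else v.mean(axis=2)
    return ExpressionMatrix(matrix.genes, matrix.timepoints, averaged)


def expression_filter(matrix: ExpressionMatrix, threshold: float = 0.1) -> np.ndarray:
    """Boolean mask of genes whose overall mean is strictly above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    v = matrix.values
    means = v.reshape(v.shape[0], -1).mean(axis=1)
    return means > threshold


def background_threshold(marker_means, decimals: int = 1) -> float:
    """Background expression level: marker-gene mean rounded *up*.

    Derived from a panel of genes known not to be expressed in the tissue;
    the panel average is rounded up (ceiling) at the given decimal place.
    """
    marker_means = np.asarray(marker_means, dtype=float)
    if marker_means.size == 0:
        raise ValueError("marker_means must be nonempty")
    scale = 10.0**decimals
    return math.ceil(marker_means.mean() * scale - 1e-12) / scale


def polynomial_detrend(series: np.ndarray, order: int = 3,
                       timepoints: np.ndarray | None = None) -> np.ndarray:
    """Subtract a least-squares polynomial, then restore the raw mean.

    Removes slow baseline drift (e.g. in serum-synchronized cell cultures)
    while keeping the output mean equal to the input mean, so expression
    filters and relative amplitudes stay interpretable.
    """
    x = np.asarray(series, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= x.size - 1:
        raise ValueError(
            f"order {order} too high for series of length {x.size}: "
            "a (near-)perfect fit would zero the series"
        )
    t = np.arange(x.size, dtype=float) if timepoints is None else np.asarray(
        timepoints, dtype=float
    )
    coeffs = np.polynomial.polynomial.polyfit(t, x, order)
    trend = np.polynomial.polynomial.polyval(t, coeffs)
    return x - trend + x.mean()


def log2_prepare(series: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Elementwise ``log2(value + pseudocount)``; rejects nonpositive args."""
    x = np.asarray(series, dtype=float) + pseudocount
    if np.any(x <= 0):
        bad = float(np.asarray(series, dtype=float)[np.argmax(x <= 0)])
        raise ValueError(
            f"log2 argument not positive: value {bad:g} with "
            f"pseudocount {pseudocount:g}"
        )
    return np.log2(x)
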