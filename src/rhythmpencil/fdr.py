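"""Permutation-based FDR for rhythm calls, plus plumbing significance tools.

The false discovery rate of a rhythm class is estimated by shuffling the
time labels of the expression matrix, re-running the decomposition and
classification on each shuffled dataset, and taking the ratio of the mean
number of rhythmic profiles found in the permuted data (false positives)
to the number found in the original data.  A harmonic F-test and
Benjamini-Hochberg adjustment are provided as generic cross-checks for
fixed-period significance testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import RhythmCriteria, classify_components
from .pencil import decompose
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FdrResult:
    """Observed vs permuted rhythmic-gene counts and their ratio.

    ``fdr`` is ``mean(permuted_counts) / observed`` and is None (with
    ``undefined`` set) when nothing was called rhythmic in the original
    data.
    """

    observed: int
    permuted_counts: tuple[int, ...]
    fdr: float | None
    n_permutations: int
    seed: int
    undefined: bool = False

    @property
    def mean_permuted(self) -> float:
        return float(np.mean(self.permuted_counts))


def permute_times(
    matrix: ExpressionMatrix, seed: int | np.random.Generator = 0
) -> ExpressionMatrix:
    """Shuffle the time labels: one column permutation shared by all genes."""
    if matrix.timepoints.size < 2:
        raise ValueError("need at least two timepoints to permute")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    order = rng.permutation(matrix.timepoints.size)
    return ExpressionMatrix(
        matrix.genes, matrix.timepoints, matrix.values[:, order]
    )


def count_rhythmic(
    matrix: ExpressionMatrix,
    criteria: RhythmCriteria,
    k: int = 3,
    pencil_fraction: float = 0.5,
    per_gene_permutation: np.random.Generator | None = None,
) -> int:
    """Number of genes with >= 1 component matching the criteria.

    When ``per_gene_permutation`` is given, each gene's series is
    independently shuffled before decomposition (sensitivity-analysis
    mode; the default shared-shuffle null is applied by the caller via
    :func:`permute_times`).
    """
    count = 0
    dt = matrix.dt
    for i in range(len(matrix.genes)):
        series = matrix.values[i]
        if series.ndim == 2:
            series = series.mean(axis=1)
        if per_gene_permutation is not None:
            series = series[per_gene_permutation.permutation(series.size)]
        dec = decompose(series, dt=dt, k=k, pencil_fraction=pencil_fraction)
        if classify_components(dec, criteria):
            count += 1
    return count


def estimate_fdr(
    matrix: ExpressionMatrix,
    criteria: RhythmCriteria,
    k: int = 3,
    n_permutations: int = 10_000,
    seed: int = 0,
    pencil_fraction: float = 0.5,
    per_gene: bool = False,
) -> FdrResult:
    """Permutation FDR: mean permuted rhythmic count over observed count.

    ``per_gene=False`` (default) shuffles time labels once per
    permutation replicate, shared across genes, preserving cross-gene
    correlation under the null; ``per_gene=True`` shuffles each gene
    independently.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = count_rhythmic(matrix, criteria, k, pencil_fraction)
    rng = np.random.default_rng(seed)
    permuted = []
    for _ in range(n_permutations):
        if per_gene:
            n_perm = count_rhythmic(
                matrix, criteria, k, pencil_fraction, per_gene_permutation=rng
            )
        else:
            shuffled = permute_times(matrix, rng)
            n_perm = count_rhythmic(shuffled, criteria, k, pencil_fraction)
        permuted.append(n_perm)
    if observed == 0:
        logger.warning("no rhythmic genes in the original data; FDR undefined")
        return FdrResult(0, tuple(permuted), None, n_permutations, seed, True)
    fdr = float(np.mean(permuted)) / observed
    return FdrResult(observed, tuple(permuted), fdr, n_permutations, seed)


def harmonic_f_test(
    series: np.ndarray, period: float, dt: float = 2.0
) -> float:
    """F-test of a sine+cosine pair at ``period`` against the constant model.

    Plumbing cross-check for fixed-period rhythmicity; returns the
    p-value (1.0 for a zero-variance series).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= 3:
        raise ValueError("series must be longer than 3 samples")
    if period <= 2 * dt:
        raise ValueError(
            f"period {period} h not resolvable at sampling interval {dt} h"
        )
    t = dt * np.arange(n)
    rss0 = float(np.sum((x - x.mean()) ** 2))
    if rss0 == 0.0:
        return 1.0
    design = np.column_stack(
        [
            np.ones(n),
            np.cos(2 * np.pi * t / period),
            np.sin(2 * np.pi * t / period),
        ]
    )
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    rss1 = float(np.sum((x - design @ coef) ** 2))
    df2 = n - 3
    if rss1 <= 0:
        return 0.0
    f = ((rss0 - rss1) / 2.0) / (rss1 / df2)
    return float(stats.f.sf(f, 2, df2))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
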