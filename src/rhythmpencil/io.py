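"""Readers/writers, pipeline configuration, and the end-to-end driver.

Formats are plain text: expression matrices as TSV with a ``gene_id``
column and timepoint headers like ``CT0``/``ZT2``/``14`` (optionally with
replicate suffixes ``CT0_r1``), results as TSV tables and JSON summaries
with stable key order, all at full float precision so round trips are
lossless.  ``run_pipeline`` ties the stages together:
preprocess -> decompose -> classify -> fdr -> compare -> phases.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .classify import GeneCall, call_gene, criteria_preset, relative_amplitude
from .compare import categorize, cohort_summary
from .fdr import estimate_fdr
from .pencil import Decomposition, decompose
from .phases import PhaseSample, polar_histogram
from .preprocess import (
    ExpressionMatrix,
    average_replicates,
    expression_filter,
    polynomial_detrend,
)

logger = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^(?:CT|ZT)?(\d+(?:\.\d+)?)(?:_r(?:ep)?(\d+))?$", re.I)

FLOAT_FORMAT = "%.17g"


def _parse_label(label: str) -> tuple[float, int]:
    """(hours, replicate index) from a column label; replicate defaults to 1."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(
            f"cannot parse timepoint label {label!r}; expected e.g. "
            "'CT0', 'ZT2', '14' or 'CT0_r1'"
        )
    return float(m.group(1)), int(m.group(2) or 1)


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read the expression-matrix TSV dialect.

    First column holds unique gene ids; remaining headers are timepoint
    labels, optionally with replicate suffixes.  Validates numeric cells
    and uniform time spacing, naming the offending row/column on error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need a gene column and >= 2 timepoints")
    genes = df.iloc[:, 0].tolist()
    dupes = sorted({g for g in genes if genes.count(g) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate gene id(s): {dupes[:5]}")
    labels = [_parse_label(c) for c in df.columns[1:]]
    hours = sorted({h for h, _ in labels})
    reps = sorted({r for _, r in labels})
    if sorted(labels) != [(h, r) for h in hours for r in reps]:
        raise ValueError(f"{path}: timepoint/replicate grid is incomplete")
    raw = np.empty((len(genes), len(labels)))
    for j, col in enumerate(df.columns[1:]):
        try:
            raw[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} for gene "
                f"{genes[row]!r} in column {col!r}"
            ) from None
    values = np.empty((len(genes), len(hours), len(reps)))
    for j, (h, r) in enumerate(labels):
        values[:, hours.index(h), reps.index(r)] = raw[:, j]
    if len(reps) == 1:
        values = values[:, :, 0]
    return ExpressionMatrix(genes, np.array(hours), values)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV dialect (CT labels, ``_r<k>`` replicate suffixes)."""

    def fmt(h: float) -> str:
        return f"{h:g}"

    if matrix.values.ndim == 2:
        cols = [f"CT{fmt(h)}" for h in matrix.timepoints]
        flat = matrix.values
    else:
        cols = [
            f"CT{fmt(h)}_r{r + 1}"
            for h in matrix.timepoints
            for r in range(matrix.n_replicates)
        ]
        flat = matrix.values.reshape(len(matrix.genes), -1)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "gene_id", matrix.genes)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write named tables as TSV files; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(p)
    return written


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


DEFAULT_PRESETS = {
    "circadian": "liver_circadian",
    "twelvehour": "liver_12h",
    "eighthour": "liver_8h",
}


@dataclass
class PipelineConfig:
    """Everything a full pipeline run depends on."""

    out_dir: str = "results"
    input_a: str | None = None
    input_b: str | None = None
    simulate: bool = False
    n_genes: int = 200
    two_conditions: bool = True
    k: int = 3
    pencil_fraction: float = 0.5
    expression_threshold: float = 0.1
    detrend_order: int | None = None
    presets: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PRESETS))
    n_permutations: int = 100
    phase_period: float = 12.0
    phase_bins: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for cls, name in self.presets.items():
            criteria_preset(name)  # validates
        if not self.simulate and self.input_a is None:
            raise ValueError("config needs either an input path or simulate=true")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def decompose_matrix(
    matrix: ExpressionMatrix,
    k: int = 3,
    pencil_fraction: float = 0.5,
) -> dict[str, Decomposition]:
    """Pencil decomposition of every gene of a replicate-averaged matrix."""
    t0 = float(matrix.timepoints[0])
    return {
        gene: decompose(
            matrix.values[i], dt=matrix.dt, k=k,
            pencil_fraction=pencil_fraction, t_start=t0,
        )
        for i, gene in enumerate(matrix.genes)
    }


def decompositions_frame(decomps: dict[str, Decomposition]) -> pd.DataFrame:
    """Long-format per-component table of decomposition results."""
    rows = []
    for gene, dec in decomps.items():
        if not dec.components:
            rows.append(
                {
                    "gene_id": gene, "mean": dec.mean, "component": -1,
                    "period": np.nan, "decay": np.nan, "amplitude": np.nan,
                    "relative_amplitude": np.nan, "math_phase": np.nan,
                    "peak_time": np.nan, "residual_rms": dec.residual_rms,
                }
            )
        for i, c in enumerate(dec.components):
            rows.append(
                {
                    "gene_id": gene, "mean": dec.mean, "component": i,
                    "period": c.period, "decay": c.decay, "amplitude": c.amplitude,
                    "relative_amplitude": (
                        c.amplitude / dec.mean if dec.mean > 0 else np.nan
                    ),
                    "math_phase": c.phase, "peak_time": c.peak_time,
                    "residual_rms": dec.residual_rms,
                }
            )
    return pd.DataFrame(rows)


def calls_frame(calls: dict[str, GeneCall]) -> pd.DataFrame:
    """Per-gene calls table: class flags, dominant class, matched components."""
    rows = []
    for gene, call in calls.items():
        base = {
            "gene_id": gene,
            "mean": call.mean,
            "circadian": int("circadian" in call.flags),
            "twelvehour": int("twelvehour" in call.flags),
            "eighthour": int("eighthour" in call.flags),
            "dominant": call.dominant or "none",
        }
        if not call.matched:
            rows.append({**base, "class": "none", "period": np.nan,
                         "decay": np.nan, "amplitude": np.nan,
                         "relative_amplitude": np.nan, "peak_time": np.nan})
        for cls, comps in sorted(call.matched.items()):
            for c in comps:
                rows.append(
                    {
                        **base, "class": cls, "period": c.period,
                        "decay": c.decay, "amplitude": c.amplitude,
                        "relative_amplitude": relative_amplitude(c, call.mean)
                        if call.mean > 0 else np.nan,
                        "peak_time": c.peak_time,
                    }
                )
    return pd.DataFrame(rows)


def _prepare(matrix: ExpressionMatrix, config: PipelineConfig) -> ExpressionMatrix:
    avg = average_replicates(matrix)
    mask = expression_filter(avg, config.expression_threshold)
    logger.info(
        "%d of %d genes pass the expression filter (> %g)",
        int(mask.sum()), len(avg.genes), config.expression_threshold,
    )
    values = avg.values[mask]
    genes = [g for g, keep in zip(avg.genes, mask) if keep]
    if config.detrend_order is not None:
        values = np.vstack(
            [
                polynomial_detrend(v, config.detrend_order, avg.timepoints)
                for v in values
            ]
        )
    return ExpressionMatrix(genes, avg.timepoints, values)


def _classify_all(
    decomps: dict[str, Decomposition], config: PipelineConfig
) -> dict[str, GeneCall]:
    criteria = {cls: criteria_preset(name) for cls, name in config.presets.items()}
    return {g: call_gene(g, dec, criteria) for g, dec in decomps.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write results + manifest under ``config.out_dir``.

    Returns a result bundle with the in-memory objects (matrices, calls,
    FDR results, deltas, phase summaries) and the manifest dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    bundle: dict = {"config": config}

    if config.simulate:
        spec = synthetic.SyntheticSpec(n_genes=config.n_genes, seed=config.seed)
        if config.two_conditions:
            mat_a, mat_b, truth = synthetic.simulate_two_conditions(spec)
        else:
            mat_a, truth = synthetic.simulate_cohort(spec)
            mat_b = None
        write_matrix(mat_a, out_dir / "matrix_A.tsv")
        written.append(out_dir / "matrix_A.tsv")
        if mat_b is not None:
            write_matrix(mat_b, out_dir / "matrix_B.tsv")
            written.append(out_dir / "matrix_B.tsv")
        truth.to_frame().to_csv(
            out_dir / "ground_truth.tsv", sep="\t", index=False,
            float_format=FLOAT_FORMAT,
        )
        written.append(out_dir / "ground_truth.tsv")
        bundle["truth"] = truth
    else:
        mat_a = read_matrix(config.input_a)
        mat_b = read_matrix(config.input_b) if config.input_b else None

    conditions = {"A": mat_a}
    if mat_b is not None:
        conditions["B"] = mat_b

    calls_by_condition: dict[str, dict[str, GeneCall]] = {}
    for name, matrix in conditions.items():
        prepared = _prepare(matrix, config)
        decomps = decompose_matrix(prepared, config.k, config.pencil_fraction)
        calls = _classify_all(decomps, config)
        calls_by_condition[name] = calls
        dec_path = out_dir / f"decompositions_{name}.tsv"
        decompositions_frame(decomps).to_csv(
            dec_path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )
        calls_path = out_dir / f"calls_{name}.tsv"
        calls_frame(calls).to_csv(
            calls_path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )
        written += [dec_path, calls_path]
        bundle[f"prepared_{name}"] = prepared
        bundle[f"calls_{name}"] = calls

    # permutation FDR per rhythm class on condition A
    fdr_summary = {}
    prepared_a = bundle["prepared_A"]
    for cls, preset_name in config.presets.items():
        result = estimate_fdr(
            prepared_a,
            criteria_preset(preset_name),
            k=config.k,
            n_permutations=config.n_permutations,
            seed=config.seed,
            pencil_fraction=config.pencil_fraction,
        )
        fdr_summary[cls] = {
            "observed": result.observed,
            "mean_permuted": result.mean_permuted,
            "sd_permuted": float(np.std(result.permuted_counts)),
            "fdr": result.fdr,
            "undefined": result.undefined,
            "n_permutations": result.n_permutations,
        }
    write_json(fdr_summary, out_dir / "fdr.json")
    written.append(out_dir / "fdr.json")
    bundle["fdr"] = fdr_summary

    if mat_b is not None:
        common = [
            g for g in calls_by_condition["A"]
            if g in calls_by_condition["B"]
        ]
        deltas = [
            categorize(
                calls_by_condition["A"][g], calls_by_condition["B"][g],
                "twelvehour",
            )
            for g in common
        ]
        delta_df = pd.DataFrame([dataclasses.asdict(d) for d in deltas])
        delta_df.to_csv(
            out_dir / "deltas_twelvehour.tsv", sep="\t", index=False,
            float_format=FLOAT_FORMAT,
        )
        written.append(out_dir / "deltas_twelvehour.tsv")
        affected = [d for d in deltas if d.rel_amplitude_a is not None]
        if affected:
            summary = cohort_summary(affected)
            write_json(
                {
                    "counts": summary.counts,
                    "total": summary.total,
                    "percentages": summary.percentages,
                },
                out_dir / "compare_summary.json",
            )
            written.append(out_dir / "compare_summary.json")
            bundle["compare_summary"] = summary
        bundle["deltas"] = deltas

    # phase summary of 12-h components on the 12-h circle
    phase_summary = {}
    for name, calls in calls_by_condition.items():
        peaks = [
            max(c.matched["twelvehour"], key=lambda x: x.amplitude).peak_time
            for c in calls.values()
            if "twelvehour" in c.matched
        ]
        if peaks:
            sample = PhaseSample(
                np.array(peaks), config.phase_period, label=name
            )
            phase_summary[name] = {
                "n": len(sample),
                "circular_mean_h": sample.circular_mean(),
                "histogram": polar_histogram(
                    sample, config.phase_bins
                ).tolist(),
            }
    write_json(phase_summary, out_dir / "phases.json")
    written.append(out_dir / "phases.json")
    bundle["phases"] = phase_summary

    manifest = {
        "stages": [
            "preprocess", "decompose", "classify", "fdr", "compare", "phases",
        ],
        "config": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in dataclasses.asdict(config).items()
        },
        "seed": config.seed,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
    }
    write_json(manifest, out_dir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
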