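# rhythmpencil

Detection of superimposed circadian (~24 h), ultradian 12-h and 8-h rhythms
in uniformly sampled omics time courses, built around the matrix-pencil
(eigenvalue/pencil) spectral decomposition.

Mammalian tissues run several molecular clocks at once: a gene's expression
over two days of 2-hourly sampling is often a *sum* of a circadian rhythm,
a 12-h rhythm and sometimes an 8-h harmonic, each with its own amplitude,
phase and damping. Fixed-period regression methods (cosinor, JTK_CYCLE-style
rank tests) must pre-assign a period window and see only one rhythm at a
time; the pencil method instead recovers *all* superimposed components of a
series without pre-assigning periods, which is what makes the 12-h
transcriptome tractable next to the dominant circadian signal. This package
is aimed at chronobiologists and computational biologists analysing bulk
RNA-Seq, ChIP-Seq or run-on time courses.

## Model

Each replicate-averaged series is modelled as

```
x(t) = μ + Σ_k  A_k · d_k^(t/T_k) · cos(2π t / T_k + φ_k) + ε(t)
```

with period `T_k` (hours), per-cycle decay `d_k` (1 = sustained, <1 damped,
>1 growing), amplitude `A_k`, and phase `φ_k`; the biological phase (time of
peak) is `p_k = ((−φ_k) mod 2π) · T_k / 2π`. Writing the sampled,
mean-adjusted series as `x_n = Σ_j c_j z_j^n`, the signal poles `z_j` are the
generalized eigenvalues of the pencil `(Y₂, Y₁)` of two shifted Hankel
matrices built from the data (rank-truncated via SVD); each
complex-conjugate pole pair gives one component with `T = 2πΔt/|arg z|` and
`d = |z|^(T/Δt)`, and the coefficients `c_j` follow by least squares.

On top of the decomposition the package provides:

- **classification** of components into rhythm classes by closed
  period/decay windows plus an expression floor (circadian 21–25 h, 12-h
  10.5–13.5 h, 8-h 7–9 h; decay 0.8–1.2; mean FPKM > 0.1), with gene-level
  flags and a mutually exclusive *dominant* class;
- **permutation FDR**: shuffle the time labels, rerun decomposition +
  classification, and report mean permuted count / observed count;
- **circular phase statistics**: circular means and paired phase shifts,
  polar histogram counts, the Watson–Wheeler uniform-scores test, and
  progressive phase-delay assessment along ordered gene groups;
- **two-condition comparison** labelling each gene's rhythm as abolished,
  dampened, increased, gained or unchanged between paired conditions
  (judged on relative amplitude `A/μ`), plus harmonic period-lock checks;
- **signal metrics**: AUC-based transcription initiation/elongation proxies
  from run-on coverage and bona fide 12-h binding-site selection;
- a **synthetic-cohort generator** with complete ground truth, so every
  stage is testable without external data.

## Worked example

```python
import numpy as np
from rhythmpencil import OscillationComponent, decompose, simulate_series

t = np.arange(0, 48, 2.0)          # CT0..CT46 at 2-h steps
components = [
    OscillationComponent.from_peak_time(period=24, decay=0.95, amplitude=2.0, peak_time=8.0),
    OscillationComponent.from_peak_time(period=12, decay=1.00, amplitude=1.2, peak_time=1.0),
]
series = simulate_series(components, mean=5.0, noise_sd=0.1, timepoints=t, seed=7)[:, 0]

dec = decompose(series, dt=2.0, k=3)
print(f"mean = {dec.mean:.3f}, residual rms = {dec.residual_rms:.3f}")
for c in dec.components:
    print(f"T = {c.period:5.2f} h   decay = {c.decay:.3f}   "
          f"A = {c.amplitude:.3f}   peak = {c.peak_time:.2f} h")
```

prints

```
mean = 4.968, residual rms = 0.059
T = 23.85 h   decay = 0.968   A = 1.957   peak = 8.03 h
T = 12.00 h   decay = 0.967   A = 1.291   peak = 1.02 h
T =  7.84 h   decay = 0.760   A = 0.066   peak = 5.90 h
```

The two generating rhythms are recovered with their periods, decays,
amplitudes and peak times; the third, tiny component (amplitude 0.066,
decay far outside the 0.8–1.2 window) is noise and would be discarded by
every classification preset. Components are ranked by amplitude, so the
damped circadian rhythm comes first; at zero noise the recovery is exact to
about ten significant digits.

A full pipeline run (simulate → preprocess → decompose → classify →
permutation FDR → two-condition comparison → phase summaries) is one
command:

```sh
rhythmpencil run --out-dir results/demo --n-genes 200 --n-perm 100 --seed 1
```

which writes per-gene decomposition and call tables (TSV), FDR and phase
summaries (JSON) and a manifest with checksums of every output.

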