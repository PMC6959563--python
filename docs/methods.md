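# Methods

## Signal model and estimator

A uniformly sampled series (N samples at spacing Δt hours, typically N = 24,
Δt = 2) is modelled as a mean plus up to K exponentially damped sinusoids:

    x(t) = μ + Σ_k A_k d_k^(t/T_k) cos(2π t/T_k + φ_k) + ε(t).

The estimator is the matrix pencil. The mean-adjusted series is arranged
into a Hankel matrix of window L = round(pencil_fraction · N) (default
pencil_fraction 0.5, the standard bias/variance compromise for short
series); the two shifted sub-matrices Y₁, Y₂ form a pencil whose
generalized eigenvalues are the signal poles z_j. Y₁ is rank-truncated by
SVD before the eigenvalue step: at most 2K+1 directions are kept and
singular values below 1e-10 of the largest are pruned. K is fixed at 3 —
the sampling design resolves at most the third harmonic of the circadian
rhythm, so data-driven model-order selection is deliberately not attempted.

Pole handling:

- complex poles come in exact conjugate pairs (the pencil matrix is real);
  each pair with |arg z| strictly between 2π/N and π becomes one component
  with T = 2πΔt/|arg z| and per-cycle decay d = |z|^(T/Δt);
- poles implying periods longer than the observation span (N·Δt, 48 h) are
  treated as trend, and periods at or below the Nyquist limit 2Δt are not
  identifiable; both kinds still enter the least-squares coefficient fit so
  the reported components are not biased by trend, but they are never
  reported as oscillations;
- amplitudes and phases come from a complex least-squares fit of the full
  pole basis plus a constant: A = 2|c|, φ = arg c.

Reported μ is defined so that the reconstruction is unbiased at the sample
times: μ = mean(x) − mean(Σ reported components). This matters because a
damped sinusoid has a nonzero sample mean over a finite window; defining μ
this way makes reconstruct(mean + all components) reproduce a noiseless
rank-≤K series exactly (residual ~1e-14) and keeps relative amplitudes
A/μ interpretable.

Conventions chosen where the field literature varies:

- **decay** is the per-cycle amplitude ratio d = |z|^(T/Δt), so d = 1 is a
  sustained oscillation and the classification window 0.8–1.2 brackets
  sustained rhythms; the per-sample magnitude |z| is available via
  `decay_per_cycle=False` for sensitivity analysis;
- **phase**: positive-cosine convention with φ ∈ [0, 2π); the biological
  phase (time of peak) p = ((−φ) mod 2π)·T/2π ∈ [0, T) is defined from the
  undamped cosine — the damped maximum shifts slightly, but the undamped
  definition is the reproducible bookkeeping choice;
- **ties** in amplitude rank are broken by longer period first;
- component ranking and the "dominant" class use absolute amplitude A, not
  A/μ.

## Classification

A component matches a rhythm class when its period and decay fall in the
class's closed windows, the gene's mean exceeds the expression floor
(strict >), and — for binding-site criteria — its peak time falls in the
peak window (read in hours, i.e. on the biological phase). Presets:

| preset            | period (h)   | decay     | mean floor | peak (h) |
|-------------------|--------------|-----------|------------|----------|
| liver_circadian   | 21–25        | 0.8–1.2   | 0.1        | —        |
| liver_12h         | 10.5–13.5    | 0.8–1.2   | 0.1        | —        |
| liver_8h          | 7–9          | 0.8–1.2   | 0.1        | —        |
| mmh_d3_circadian  | 20.5–23.5    | 0.9–1.1   | 0 *        | —        |
| mmh_d3_12h        | 9.5–12.5     | 0.9–1.1   | 0 *        | —        |
| cistrome_12h      | 10.5–13.5    | 0.8–1.2   | 0          | 0–3      |

\* the culture-cell workflow applies its expression cut (mean > 20) as an
upstream filter rather than inside the rhythm criteria, so those presets
carry no mean floor.

The expression floor of 0.1 FPKM is derivable from data with
`background_threshold`: the mean expression of a panel of known
non-expressed marker genes, rounded *up* (ceiling) at the first decimal —
rounding up, not to nearest, is the operative rule.

A gene holds one flag per class with ≥1 matching component (a gene can be
both circadian and 12-h cycling); its dominant class is the class of the
single largest-amplitude component, provided that component matched —
dominant labels are therefore mutually exclusive. Genes failing the
expression filter are excluded upstream and produce no calls.

## Permutation FDR

The FDR of a class is mean permuted count / observed count, where each
permutation replicate shuffles the time labels and reruns
decomposition + classification. One column permutation is shared by all
genes within a replicate — "shuffling the time labels" is read as
relabelling the samples, which preserves cross-gene correlation under the
null; an independent per-gene mode exists behind a flag for sensitivity
analysis. The reference procedure uses 10,000 permutations (the package
default); the test suite and acceptance script run 100 with the identical
estimator, which bounds the Monte-Carlo error of the ratio at the few-percent
level on a 2,000-gene cohort. When nothing is called rhythmic in the
original data the FDR is reported as undefined rather than dividing by
zero.

## Circular phase statistics

Phases live on the circle of their rhythm's period; 12-h phases are
analysed modulo 12 h, so the dawn and dusk modes of the bimodal 12-h phase
distribution coincide — matching polar plots drawn over one period. Paired
phase differences are wrapped to (−T/2, T/2] before circular averaging
(required for sub-hour mean shifts to be meaningful); positive = delay,
negative = advance. The Watson–Wheeler uniform-scores statistic
W = 2Σ_g (C_g² + S_g²)/n_g is referred to χ² with 2(g−1) degrees of
freedom; ties get midranks with a warning. The χ² approximation is
accurate at group sizes ≳10 (measured type-I error 0.050 at α = 0.05,
n = 50/group) but rough below that: against full enumeration at n = 6+6
the p-value can deviate by ~0.1 in the mid-range, so the implementation
warns for small groups and offers `method="exact"` (full enumeration,
two-sample) instead. Progressive phase delay along an ordered group
sequence reports, for every adjacent pair, the unpaired circular mean
difference and the Watson–Wheeler p-value, plus a monotone-delay flag; an
omnibus test over all groups is available from the same function family
since the pairwise scheme is not canonical.

## Two-condition comparison

Rhythms of a class are compared per gene: present only in A → abolished;
only in B → gained; in both, by relative amplitude A/μ with strict
inequalities → dampened / increased / unchanged (exact ties, measure-zero
on real data, fall to unchanged). Relative amplitude — not absolute — is
used so baseline-expression shifts between genotypes do not masquerade as
rhythm changes. When several components of a gene match the class window,
the largest-amplitude one represents the gene. Percentages in cohort
summaries are rounded to one decimal with the exact fractions retained
alongside.

The harmonic period-lock check reports k = round(T_circ/T_harm), the
implied circadian period k·T_harm, and a lock flag at a default 5%
relative tolerance.

## Signal metrics

Coverage tracks are piecewise-constant per-bin densities; the AUC over an
index range is the exact integral of that step function (bin sum × bin
width), which is additive over contiguous ranges by construction.
Transcription initiation is the AUC of the pre-pausing segment, elongation
the AUC of the gene body. The pause boundary is a required input (index or
fraction of gene length; the CLI defaults to the first 10% purely as a
convenience) — it is not inferred, because no operational definition of the
pre-pausing extent is assumed. Binding-site intervals use 0-based
half-open (BED) coordinates. Bona fide 12-h binding sites are intensity
time courses (typically 12 points at 4-h spacing) whose pencil
decomposition contains a component matching the cistrome preset; with 12
timepoints the component count adapts to 2, since K = 3 needs at least 14
samples.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: 24 timepoints at
Δt = 2 h over 48 h in duplicate; log-normal baselines (meanlog 1.0,
sdlog 1.2, resampled above 0.15 so expressed genes clear the filter) with a
sub-threshold class drawn below 0.1; gene classes null / circadian /
12-h / mixed(24+12) / 8-h / sub-threshold with default fractions
0.30/0.20/0.15/0.15/0.08/0.12; periods drawn from the observed
distributions (circadian N(21.7, 2.58) clipped to the class window, 12-h
N(11.62, 0.48), 8-h N(8, 0.3)); sustained decays U(0.9, 1.1); circadian
phases uniform; 12-h peak times from an equal-weight two-mode wrapped
normal at 0 h and 12 h (sd 1 h). Noise is additive Gaussian on the
expression scale with sd expressed as a fraction of the baseline mean
(default 0.1); replicates share true components and differ only in noise.
With relative amplitudes fixed at 0.5 and noise 0.1, the amplitude-to-noise
ratio of an analysed single-replicate series is exactly 5 — the condition
used by the recovery suites.

The paired-condition generator partitions genes carrying a true 12-h
component exactly (largest-remainder apportionment, order randomized) into
abolished / dampened / increased / unchanged with default proportions
0.545/0.316/0.139/0, zeroing, halving or doubling the 12-h amplitude
respectively and leaving every other component untouched. The dampening
factor of 0.5 reflects that a *dampened* rhythm is by definition one that
remains detectable at reduced amplitude; effect-label recovery is scored on
the generated partition, i.e. over genes truly carrying a 12-h component.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: count-based (negative-binomial) noise,
library-level normalization artifacts, trend/baseline drift (except where
tests add it explicitly for the detrending step), correlated noise between
genes, and unequal replicate quality. One master seed drives all streams,
so cohorts are byte-reproducible.

## Numerical choices and degenerate inputs

- Conjugate-pair matching tolerance 1e-8 (pairs are exact up to rounding
  since the pencil matrix is real; unpaired complex poles are discarded
  with a warning).
- An all-constant series returns zero components, not an error; a series
  with any non-finite value, non-uniform sampling (the offending gap is
  named), or fewer than 2(2K+1) samples is rejected.
- Polynomial detrending (default order 3 where used) subtracts an
  ordinary-least-squares polynomial on the raw hour values and restores
  the raw mean; it is idempotent at the same order. Orders ≥ length−1 are
  rejected since a perfect fit would zero the series.
- Missing values are errors naming gene and timepoint; no imputation, as
  the pencil needs complete uniform series.
- TSV output uses 17 significant digits, so write→read round trips are
  lossless and reruns are byte-identical.

## Problem sizes used by the verification suites

Noiseless recovery: 500 random 1–3-component signals (periods 6–30 h with
≥20% separation, decays 0.85–1.15, amplitude ratio ≤ 100), all parameters
recovered to <1e-6 relative error. Noisy recovery: 1,000 genes at
amplitude-to-noise 5. FDR calibration: 2,000 pure-noise genes, 100
permutations. Watson–Wheeler: 2,000 null simulations at n = 50/group, and
20 exhaustive-enumeration comparisons at n = 6+6. Two-condition recovery:
2,000 genes. These sizes keep the whole verification run at about a minute
on one CPU while leaving Monte-Carlo error well inside the asserted
margins.
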