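# Methods notes

This document records the modelling assumptions, parameter choices and
numerical conventions behind `surfdecode`, in the spirit of a package
methods appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The experimental design being emulated

One run lasts 368 s: 23 contiguous 16-s blocks sampled at TR = 2 s
(184 volumes after discarding 4 dummy volumes). Sixteen blocks are
experimental — four conditions (Glossy `G`, Glossy Control `GC`, Rough
`R`, Rough Control `RC`), four repeats each, in a seeded pseudo-random
order per run — and seven are fixation: one leading, one trailing, and
five interposed after the 3rd, 5th, 8th, 11th and 13th stimulus blocks.
The main study has 16 participants × 9 runs; the control (imagery)
study has 6 participants × 10 runs with the same block structure. A
somatosensory localiser run alternates 10 air-on and 10 air-off 16-s
blocks. During each block participants perform a 1-back task (1 target
+ 14 non-target decisions per block).

## Signal model

Per voxel `v` and volume `t`:

```
signal = B · (1 + Σ_c (HRF ∗ boxcar_c)(t) · (s + a·p_c[v]) / 100)
         + d · sin(2πt·TR/T_d + φ) + AR1(t)
```

* `B` — baseline, default 100 raw units (1 unit = 1 % signal change).
* `p_c` — unit-norm, mutually orthogonal condition patterns (QR of a
  seeded Gaussian matrix, signs fixed for determinism), shared across a
  participant's runs, independent across participants. `a`
  (`pattern_amplitude`, % signal change) scales the condition-specific
  component; `a = 0` makes labels carry no information, which defines
  the null simulations.
* `s` (`shared_amplitude`) — condition-independent task response,
  default 0.5 %.
* HRF — canonical double-gamma (peaks 6 s / undershoot 16 s, ratio
  1/6) sampled at TR and normalised to unit sum, so a sustained block
  plateaus at exactly the modelled amplitude. A pure 4-s-delay kernel
  is provided; with it, generation and the 4-s extraction shift cancel
  exactly, which the tests exploit to validate the analysis window
  against closed-form plateau values.
* Drift — a run-wide sinusoid (default amplitude 0.3 units, period
  128 s, seeded random phase) common to all voxels, standing in for
  slow scanner drift.
* Noise — stationary AR(1) per voxel (marginal SD 1 unit, lag-1
  correlation 0.3), independent across voxels.
* Dummy volumes are generated at the head of the run for the
  convolution timeline and then discarded; all block onsets are 0-based
  post-dummy volume indices.

Seeding: a single master `SeedSequence` expands deterministically into
participant → (patterns, localiser, behaviour, runs) → (schedule,
noise) streams, so every dataset is bit-reproducible and participants
are independent.

The original study states no effect sizes or noise levels in signal
units; the generator's amplitude/noise defaults are package choices,
not claims about the paper's data. The shared task amplitude (0.5 %)
and drift (0.3 units) were fixed so that a well-behaved run's
global-signal variance (≈0.11 %²) sits below the 0.23 %² exclusion
threshold — in the emulated study the large majority of runs passed
that criterion, so generator defaults that excluded every run would
contradict the design being emulated. QC exclusion behaviour is tested
with deliberately drifty runs instead.

## QC statistic

"Global signal variance" is defined as the variance (population
denominator) of `100·(ḡ(t) − mean ḡ)/mean ḡ`, where `ḡ` is the mean
over voxels at each volume — i.e. the variance of the global percent
signal change, in %². This is the only scale-free reading of a 0.23 %
criterion; it is invariant to rescaling the raw signal, which the
tests assert. The threshold applies strictly (`> 0.23` excludes).

## GLM and voxel selection

Runs are concatenated; the design holds one double-gamma-convolved
boxcar regressor per condition (fixation is the implicit baseline) and
one intercept per run to absorb run baselines. Whether the original
analysis fit per run or concatenated is unstated; concatenation with
run intercepts is the package's choice and affects only the synthetic
t-maps. OLS is fit voxel-wise; `dof = N − rank(X)`. Selection modes:

* `top_positive` — up to 250 voxels with `t > 0` on the equal-weight
  all-conditions contrast, ranked by t (visual-ROI rule);
* `significant` — voxels with two-sided `p < α` (default 0.05,
  uncorrected — the original alpha is unstated) on the air-on contrast,
  then top-250 by t (somatosensory-ROI rule).

Ties in t are broken by voxel index for determinism.

## Pattern extraction

Within each run the selected voxels are z-scored over time using the
population (1/N) SD — the denominator convention is unstated in the
source and fixed here for determinism. The series is then shifted 4 s
(2 volumes) and each experimental block's pattern is the mean of its 8
shifted volumes. Baseline differences are removed by subtracting the
mean pattern *per run* (default): the stated aim of the subtraction is
to remove baseline differences across conditions *and runs*, and
per-run centering is the variant that removes run baselines; a
`global` scope (grand-mean subtraction) is provided since the original
wording is ambiguous between the two.

## Decoding

Binary linear SVM (libsvm C-SVC, `C = 1`, no kernel, no feature
scaling beyond the pipeline's z-scoring — regularisation is unstated
in the source and fixed at the conventional default), leave-one-run-out
cross-validation in run-id order. With 9 runs and balanced contrasts:
32 training patterns per class and 4 + 4 tests per fold; with 10 runs,
36 per class. Pooled-Matte contrasts (class B = GC ∪ RC) keep all test
patterns (4 + 8 per fold) but subsample the training majority class to
the minority count — **per training run** (4 of 8 per run), seeded.
Per-run rather than global subsampling matters: a global subsample
leaves the pooled class unevenly spread over runs while the minority
class is even, and with within-run pattern correlations this
empirically tilts null predictions toward the pooled class (null mean
accuracy ≈ 0.504 instead of 0.500). Per-run subsampling makes the two
class assignments exchangeable within every run, so the shuffled-label
null is exactly unbiased; it also reproduces the design's 32 training
patterns per class. Whether the original analysis balanced at all is
unstated; balancing is the reading consistent with both the stated
training counts and a 0.5 chance level.

For permutation testing the identical libsvm solver is run on a
precomputed linear Gram matrix (patterns never change across
permutations, only labels), which removes per-call overhead; the tests
assert exact prediction agreement between this path and
`sklearn.svm.SVC(kernel="linear")`.

## Permutation null and baseline

For each of 1000 permutations, each participant's leave-one-run-out
decoding is re-run with condition labels shuffled within run, drawing a
*fresh shuffle for every test fold*, and participants' mean accuracies
are averaged into one group value. The baseline is the nearest-rank
upper 95th percentile of these group means, averaged across ROIs when
several are analysed.

Two readings deserve justification:

* **Group-level percentile.** The percentile is taken on the
  across-participant means. A per-participant percentile would sit near
  `0.5 + 1.645·√(0.25/72) ≈ 0.598` for a 72-test participant —
  far above the printed baselines (≈0.52 for 16 participants) — whereas
  the group-mean reading matches the closed binomial form
  `0.5 + 1.645·√(0.25/(n_tests·n_participants))`.
* **Per-fold re-shuffling.** Folds share 7/8 of their training data; a
  single shuffle per permutation leaves a ≈0.06 inter-fold accuracy
  correlation that over-disperses the group-mean null by ~20 % in SD
  and would push the baseline almost a full accuracy point above the
  binomial form the published values follow. Independent per-fold
  shuffles (labels shuffled "per test") restore binomial dispersion;
  the test suite checks the resulting null against Binomial(72, ½) by
  a KS test.

Shuffling stays within run, preserving per-run class counts and the
run-wise CV structure. Empirical percentiles use the nearest-rank
method for determinism.

## Group statistics

* One-sample t against the baseline: upper-tailed,
  `α_corrected = 0.05/m`; zero-variance samples map to `p ∈ {0, ½, 1}`
  by the sign of the mean difference.
* Two-way repeated-measures ANOVA: classical within-subject SS
  decomposition on a complete subjects × A × B array; each effect is
  tested against its own subject-interaction error term. No sphericity
  correction is applied (none is used in the emulated analysis).
* Tukey HSD on a within-subject factor: `q = |Δmean| / √(MS_err/n)`
  with that factor's interaction error term rescaled to the marginal
  scale, p from the studentized-range distribution; a null simulation
  in the tests checks the implied family-wise type-I rate (~5 %).
* Wilcoxon signed-rank: zero differences dropped; exact sign-flip
  enumeration (average ranks for ties) for n ≤ 12 — the rating
  experiment has n = 7, where all-one-signed differences give
  p = 2/2⁷ = 0.015625 — tie-corrected normal approximation with
  continuity correction otherwise; Z always reported from the normal
  approximation.
* d′ = Φ⁻¹(hit) − Φ⁻¹(FA), equal-variance convention with
  `P(hit) = Φ(d′/2 − c)`, `P(FA) = Φ(−d′/2 − c)` on the generator
  side; the log-linear correction (+0.5 per cell, +1 per denominator)
  is applied only when an observed rate is 0 or 1, and flagged.

## Image statistics

Contrast is SD/mean over pixels (population SD); skew is the third
standardised moment, defined as 0 for constant images. Statistics run
over the full frame by default with an optional object mask — which
region the original figure used is unstated. No canonical
"power-spectrum difference" exists, so the package uses the RMS
difference of radially-averaged log₁₀-amplitude 2-D FFT spectra per
image pair, averaged over all unordered pairs (a full-2-D RMS variant
is available). The procedural stimulus generator is a stand-in for the
original rendered objects: a smooth shading field plus kind-specific
features (sparse specular blobs for glossy, multiplicative wave-texture
shading modulation for rough, reflectance modulation for painted). It
guarantees the orderings the tests check (glossy > matte in skew,
rough > matte in contrast at matched seeds) but does not reproduce the
original images' absolute statistics, which depend on unreleased
renders.

## Problem sizes and what passing tests show

Simulations use ~30–100 voxels per ROI and 1000 permutations (the
published permutation count); the acceptance run simulates the full 16-
and 6-participant groups. The synthetic generator reproduces the
*structure* of the study — block timing, counts, fold sizes, chance
level, null dispersion — but not spatial autocorrelation, motion,
physiological noise, inter-subject variability in effect size, or real
hemodynamic variability. Passing tests therefore certify the analysis
machinery and the design-determined quantities (e.g. permutation
baselines, which depend only on the fold structure and group size),
not the recoverability of the original biological effects. One known
inconsistency in the emulated study's reporting: the main-design
R-vs-M baseline is printed as 53.80 % while the structurally identical
G-vs-M case prints 51.95 %; under any label-permutation scheme these
coincide in expectation, so the package does not attempt to reproduce
the former.
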