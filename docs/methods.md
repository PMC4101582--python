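# Methods

## The transform

Derivative component analysis treats each m/z channel not as an atomic
feature but as a superposition of dyadic frequency components. A J-level
orthogonal DWT is applied to every sample's spectrum along the m/z axis
(one transform per row; rows are independent). With periodized boundaries
the transform is orthonormal: level-j matrices have `ceil(n_{j-1}/2)`
columns (exactly `p/2^j` for dyadic p), coefficient energy equals signal
energy, and the inverse is exact to machine precision — this holds for
non-dyadic widths too (e.g. 15000 channels), which is why no padding
option exists. The symmetric boundary mode is available for users who
prefer it; it changes coefficient counts slightly and is not the default.

Fine detail matrices (levels `1..τ`) are then individually replaced by a
rank-m PCA reconstruction across samples: center each coefficient column
by its mean over samples, truncate the SVD of the centered matrix at m
(the Frobenius-optimal rank-m approximation), add the mean back. Coarse
levels (`j > τ`) and the approximation pass through untouched, and the
inverse DWT returns a same-shape panel ("meta-data").

Why this denoises: independent per-channel noise contributes an
approximately isotropic bulk to each fine-band covariance, so its
variance is spread over all `n_j` directions, while structure shared
across samples concentrates on a few directions. Keeping one direction
removes the bulk of the noise energy in the two finest bands (~3/4 of all
channels' noise for τ=2) at the cost of whatever shared structure lies
outside the first component. The flip side, stated plainly: a class
signal survives the reduction only if the variance along its direction is
strong enough to surface in the leading principal component — in spiked-
covariance terms, above the detection threshold `σ²·sqrt(n_j/n)`. Signals
below that threshold are *removed* by the transform, and the pipeline can
underperform a plain SVM there. Denoising is a bet on the subtle
structure being coherent across samples.

### Parameters

- `wavelet` — orthogonal, compact support; default `db8`. Orthogonality
  is required (energy bookkeeping and exact inversion); compact support
  keeps the fine bands local in m/z.
- `J` (decomposition level) — default 7; feasible range
  `2^J ≤ n_channels`, recommended `4 ≤ J ≤ ceil(log2 p)`. Too small a J
  leaves little room to place the cutoff.
- `τ` (fine/coarse cutoff) — default 2; recommended `1 < τ ≤ J/2`.
  Levels `1..τ` are reduced. `τ = 0` is the identity pipeline (useful as
  a control).
- `m` (components per fine level) — default 1. Alternatively
  `ratio_threshold` ρ picks the smallest m with explained-variance ratio
  `ρ_m ≥ ρ` per level; ρ = 0.60 is the customary setting. On heavily
  noise-dominated synthetic panels ρ_1 can be far below 0.60; the ratio
  is logged per level so users can see what the reduction kept.
- `fit_mode` — `transductive` (default) fits the per-level PCA on the
  full panel before any train/test split, which is how this family of
  pipelines is conventionally run; `inductive` fits on training folds
  only and projects held-out samples onto the stored loadings
  (`apply_model`), which is the leakage-free option. Both are recorded in
  every evaluation report. On the synthetic designs the two give similar
  comparisons; users making generalization claims should use inductive.

Numerical conventions: PCA via SVD of the centered matrix; each loading's
largest-magnitude entry is made positive (reconstruction is
sign-invariant, but stored loadings are then reproducible); ties in
biomarker statistics rank the lower channel index first; an SVM decision
value of exactly 0 predicts +1; in pairwise multiclass models the
lexicographically smaller class code maps to +1, and max-wins voting ties
break by the larger summed |decision value|, then the lower class code.
A zero-variance feature scores t = 0, p = 1 (two identical constant
groups) rather than raising.

## Classification and ranking

The SVM layer is the standard soft-margin linear C-SVM (solved by
libsvm's SMO through scikit-learn, tolerance 1e-6), exposed in dual form
(support alphas, vectors, labels, bias, and `w = Σ αᵢcᵢyᵢ`) so the KKT
identities — `Σ αᵢcᵢ = 0`, `0 ≤ αᵢ ≤ C`, margin support vectors at
decision value ±1, primal/dual agreement — are directly testable. C
defaults to 1 and is logged; no feature scaling is applied before the
SVM (none is conventional for these intensity panels; apply your own if
desired). Multiclass uses one-against-one with max-wins voting.

Biomarker ranking scores every channel of the meta-data with the
absolute two-sample t statistic (Welch by default; pooled variance with
`n1+n2-2` df behind a flag — both forms are in common use and the table
records which was used) or the one-way F statistic for k > 2 classes.
P-values are two-sided and uncorrected by default, matching the
univariate-filter convention this pipeline is compared against
(p < 0.05); Benjamini–Hochberg is available behind a flag. The
separability check trains a linear SVM with large C (1e6) on the top-k
channels only and reports training accuracy; "separable" means exactly
1.0.

## Evaluation harness

Repeated stratified k-fold CV (defaults k=5, 10 repeats; the repeat
count is a package choice — dispersions need replication). Fold
assignment is seeded and stratified so small classes stay balanced; the
per-repeat seed is `seed + repeat`. For multiclass labels, accuracy is
top-1; sensitivity/specificity/PPV are computed only under an explicit
binarization map (e.g. grouping disease stages against controls), which
is recorded in the report. A zero denominator (e.g. PPV with no positive
calls) yields null in the report with a warning, never a crash. Reports
are JSON with `schema_version` and the full effective configuration;
identical seed + configuration reproduces a report byte-for-byte.

The `fs_svm` baseline filters channels at raw p < 0.05 (t-test for
binary, one-way ANOVA otherwise) before the same SVM; the filter follows
`fit_mode` like the transform does. If the filter keeps nothing it falls
back to all channels with a warning.

## The synthetic generator

Each clean spectrum is `baseline + Σ Gaussian peaks + a_g · ripple`,
scaled per sample by a lognormal factor (total-ion-current variation)
and degraded by iid Gaussian channel noise. The ripple is a *fixed*
zero-mean, unit-RMS template, band-limited to the two finest dyadic
bands (white noise from a dedicated seed, wavelet band-pass, 30%/70%
energy split between levels 1 and 2) — it is the operational meaning of
"subtle structure": invisible to the eye under the peaks, concentrated
exactly where the transform's default fine levels look. The noise-free,
per-sample-scaled matrix is returned alongside as ground truth.

Presets (all 1024 channels over 1000–10000 Da, six shared peaks,
noise_sd 1.0):

- `binary_global` — 50+50 samples; class 2 multiplies two peak heights by
  1.6 and 0.6; no ripple; scale jitter 0.05. Classes are disjoint on the
  differential peak apexes, so three ranked biomarkers separate them
  completely.
- `binary_subtle` — 50+50 samples; identical peaks; ripple amplitudes
  1.435 vs 1.565 (a shared amplitude 1.5 with a ±0.065 class offset);
  scale jitter 0.2. The shared amplitude times the scale jitter puts a
  strong common variance direction along the ripple in the fine bands,
  comfortably above the detection threshold, so the rank-1 reduction
  retains the class offset while stripping the white noise; per channel
  the class-mean gap (≤ ~0.4 intensity units) is far below both the
  noise floor and the peak heights, which is what defeats raw-space and
  univariate-filter classifiers. This is the design on which the
  transform-then-classify pipeline beats a plain linear SVM by ~10
  accuracy points.
- `three_class` — 40+40+40; class 2 peak heights exactly intermediate
  between classes 1 and 3, mimicking an intermediate pathological stage.

The `scale` argument multiplies the differential effect (height gaps or
amplitude offset) linearly.

What the generator does *not* emulate: isotope envelopes, detector
saturation, m/z calibration drift, heteroscedastic (intensity-dependent)
noise, correlated chemical baseline noise, batch effects. Passing tests
on these panels therefore demonstrates the transform's mechanism —
fine-band noise suppression with retention of coherent subtle structure
— not performance on any real instrument's output.

## Problem sizes

The comparison study uses ten independent 100×1024 panels with one round
of stratified 5-fold CV each (50 fold-level accuracies per method), a
size at which the whole study runs in seconds while the accuracy gap
(~10 points) is an order of magnitude larger than its spread across
seeds. The acceptance script reports: both mean accuracies and their gap
(percent), the top-3 biomarker training accuracy on `binary_global`
(percent), the relative Frobenius reconstruction error of the DWT
round-trip, and the meta/raw distance-to-truth ratio on `binary_subtle`
(< 1 means denoising moved the panel toward the noise-free truth;
typical value ≈ 0.52).

## Known limitations

- Transductive mode uses unlabeled test spectra when fitting the
  per-level PCA; accuracy estimates under it are not fully out-of-sample.
- Rank-1 reduction can erase class signal below the fine-band detection
  threshold (see above); the identity control (`τ = 0`) and the logged
  ρ_m per level are the diagnostics.
- The t/F ranking assumes approximately normal intensities; no
  multiple-testing correction is applied by default.
- Linear kernel only, by design; no probability calibration.
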