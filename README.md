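# dca-spectra

Derivative component analysis (DCA) for mass-spectral serum proteomic
profiles: a multiresolution denoising / implicit feature-selection
transform, a linear-SVM disease-diagnosis pipeline built on it, t/F-statistic
biomarker ranking, a cross-validation harness, and a synthetic spectrum
generator for controlled experiments.

## The problem

SELDI/MALDI-TOF serum profiles are sample-by-m/z intensity panels
(typically ~10² samples × 10³–10⁴ channels) in which disease signal is a
mixture of *global* structure (peak heights, baseline) and *subtle*
high-frequency structure, buried under per-channel noise. Classifiers fed
the raw panel waste capacity on that noise; univariate feature filters
discard the subtle structure entirely.

## The method

For a panel `X` (rows = samples), DCA:

1. applies a J-level orthogonal discrete wavelet transform ('db8' by
   default, periodized) to every spectrum along the m/z axis, giving
   detail matrices `cD1..cDJ` (level 1 = finest band) and approximation
   `cAJ`; column counts halve at each level (10×1024 at J=5 → cD1 is
   10×512, cD5 and cA5 are 10×32);
2. replaces each *fine* detail matrix (levels `j ≤ τ`, default τ=2) by its
   rank-m PCA reconstruction across samples,
   `cDj ← mean + Σ_{i≤m} s_i u_i vᵢᵀ` (default m=1, or the smallest m whose
   variability-explanation ratio `ρ_m = Σ_{i≤m}σ_i / Σσ_i` reaches a
   threshold, customarily 0.60), keeping coarser levels and `cAJ` intact;
3. inverts the transform, yielding same-shape *meta-data* `X*`.

Independent noise spreads its variance over all directions of a fine band,
so a rank-1 reconstruction suppresses it while retaining shared
high-frequency structure — including class differences too subtle for
per-channel statistics. On the meta-data the package trains soft-margin
linear SVMs (binary C-SVM; one-against-one with max-wins voting for k > 2
classes), ranks channels by two-sample t (binary, Welch or pooled) or
one-way F statistics (DCA-MARK), and evaluates everything by repeated
stratified k-fold cross-validation with accuracy / sensitivity
`TP/(TP+FN)` / specificity `TN/(TN+FP)` / PPV `TP/(TP+FP)`.

## Worked example

Generate a synthetic two-class panel whose classes differ only in a subtle
high-frequency component, then compare DCA-SVM against a plain linear SVM:

```sh
dca simulate --preset binary_subtle --seed 7 --output sim.csv
dca evaluate --input sim.csv --methods dca_svm,svm \
    --repeats 3 --seed 1 --report report.json
```

which prints

```
wrote 100x1024 panel (binary_subtle, seed 7) to sim.csv
dca_svm: accuracy 0.8533 +/- 0.0611
svm: accuracy 0.7400 +/- 0.1021
```

— the denoised pipeline classifies the subtle-effect design about 11
points better than the same SVM on raw intensities, with a smaller spread
across folds. On a panel whose classes differ globally, three ranked
biomarkers are enough for complete linear separation:

```sh
dca simulate --preset binary_global --seed 3 --output glob.csv
dca biomarkers --input glob.csv --top 3 --output bio.csv \
    --export-coords coords.csv
```

```
 rank  channel          mz  statistic      p_value kind
    1      543 5768.328446  45.607675 1.464077e-58    t
    2      544 5777.126100  45.514568 8.480814e-59    t
    3      573 6032.258065  45.224886 1.045199e-59    t
top-3 training accuracy: 1.0000 (separable: True)
```

The top channels sit on the differential peak near 5950 Da; `coords.csv`
holds each sample's coordinates on those three channels for 3-D plotting.

Library use mirrors the CLI:

```python
from dca import DCAConfig, fit_transform, preset, generate

noisy, truth = generate(preset("binary_subtle", seed=7))
meta, model = fit_transform(noisy, DCAConfig())   # db8, J=7, tau=2, m=1
```

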