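# Methods

This note documents the models, conventions and numerical choices behind
`echotexture`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic speckle cohorts

**Model.** Fully developed ultrasound speckle is the envelope of a
circular complex Gaussian scatterer field; its amplitude is Rayleigh
distributed. Each ROI is built as

```
I(x, y) = B(x, y) · E(x, y)
```

* `E` — envelope of a complex Gaussian white field smoothed with a
  Gaussian kernel of σ = `speckle_grain`/2 (default grain 2 px, the
  speckle cell size), normalized to unit mean. Its marginal stays
  Rayleigh; the test suite checks a KS distance < 0.05 to a fitted
  Rayleigh on 10⁴ pixels.
* `B` — echogenicity map `exp(0.4·Z)` where `Z` is a smoothed Gaussian
  field (correlation length `bg_smoothness`, default 32 px) standardized
  to zero mean and unit variance per ROI. Standardizing per ROI pins the
  overall brightness; without it the smooth field's realized mean wanders
  and image-to-image gain variance swamps any class effect.

**Class effect.** Cases receive an oriented sinusoidal echogenicity
modulation *under* the speckle:

```
B ← max(B + 0.5 · effect_size · mean(B) · cos(2π u / (2·effect_scale) + φ), 0)
```

with `u` the coordinate along `effect_orientation` (0/45/90/135°, matching
the Gabor bank's H/Z/V/N convention) and φ a per-subject uniform phase
shared by the subject's two frames. Three deliberate choices:

* *multiplicative placement* (modulate `B`, then multiply by `E`) — an
  earlier additive-band variant clipped its troughs at zero intensity,
  which handed the classifiers a trivial dark-pixel-floor marker
  (the 1st-percentile feature became a perfect class separator); moving the
  band under the speckle keeps the signal in oriented texture;
* *amplitude tied to the scalar ROI-mean of `B`* — scales with overall
  gain but not with the local background pattern, keeping the within-class
  variance of the matched Gabor response small;
* *wavelength `2·effect_scale`* — exactly the carrier wavelength of the
  Gabor filter with envelope size `effect_scale`, so `effect_scale=8` at
  90° targets `Gab8V`.

At `effect_size = 1.0` the matched-band Gabor magnitude separates the
classes by roughly twenty pooled standard deviations (measured in the test
suite, threshold > 3); `effect_size = 0` makes the classes exchangeable,
verified by a KS-calibration test on repeated 50 vs 50 cohorts.

**Display mapping.** Amplitudes map linearly from the fixed window
[0, 6] (unit-mean speckle units) to the 8-bit range — fixed scanner gain,
values above the window saturate. Optional log compression
(`log1p(1000·I/6)/log1p(1000)`) emulates B-mode dynamic-range compression
and is off by default; all texture checks run on the linear mapping.

**Cohort layout.** Defaults 64 cases / 46 controls, two frames per subject
(phases R and T: end-diastole and end-systole) with independent speckle and
the shared subject-level band phase. The generator makes no attempt at
anatomical realism (chambers, leads, ECG gating); what passing tests show
is that the *pipeline* recovers a planted oriented-texture effect at the
stated cohort sizes — not that real PICM texture looks like this.

## 2. The 250-feature battery

Ordering and naming come from a fixed registry (nine groups,
9/5/5/28/24/24/28/11/116 features). Conventions:

* **Histogram** — population moments, excess kurtosis, nearest-rank
  percentiles (1, 10, 50, 90, 99%). Zero-variance images have
  skewness = kurtosis = 0 by convention.
* **AR model** — causal four-neighbour first-order autoregression fitted
  by ordinary least squares on the mean-subtracted image; `Sigma` is the
  residual SD. Constant images: θ = 0, σ = 0.
* **Gradient** — central differences on interior pixels (no ½ factor);
  `GrNonZeros` is the percentage of interior pixels with non-zero
  magnitude.
* **HOG** — one whole-ROI cell (no block grid), signed orientation in
  [0°, 360°), magnitude-weighted votes, L1 normalization; zero-gradient
  pixels do not vote, and an all-flat image leaves the histograms at zero.
* **Gabor** — complex kernels with isotropic Gaussian envelope σ = s,
  carrier wavelength λ = 2s (one cycle per 2σ), truncated at 3σ,
  envelope-L1-normalized; the image is mean-subtracted before filtering
  and the feature is the mean response magnitude over the fully-supported
  region. Envelope sizes {2, 4, 6, 8, 10, 12}: six sizes are needed for 24
  features and the even ladder contains the sizes that appear in ranked
  outputs; the set is configurable. All filters share one padded FFT of
  the image.
* **Wavelet** — 8-level Haar decomposition; feature = mean squared detail
  coefficient per level × channel (LH/HL/HH mapped to pywt's cH/cV/cD).
  Images smaller than 256² support fewer dyadic levels; missing energies
  are filled with 0 and flagged with a `RuntimeWarning` (fill-and-flag
  rule), so the vector length is always 250.
* **Quantization** (GLCM/GLRLM precondition) — 64 levels over the
  μ ± 3σ window, clipped; the window convention of the MaZda-lineage
  texture software this feature set follows. Constant images fall back to
  the full-range window. Other groups consume raw intensities.
* **GLRLM** — maximal runs along H/Z/V/N; the seven statistics (short/long
  run emphasis, gray-level and run-length non-uniformity and their
  normalized forms, fraction) use the classical definitions written out in
  the extractor docstring.
* **GLCM** — one symmetric matrix at distance 1 pooled over all four
  directions (11 statistics, not 44: pooling follows the "all directions"
  reading), log base 2, 0·log 0 = 0, correlation of a degenerate
  single-level matrix defined as 1.
* **LBP** — `Oc4` classic 4-neighbour codes, `Tr4` transition codes
  (sign changes between circularly consecutive neighbours), `Cs{4,8,12}`
  center-symmetric codes on circles of radius 1, 1, 2 with bilinear
  interpolation of off-grid samples. Ties (equality) count as "≥" → bit 1.
  All histograms are L1-normalized.

GLCM, GLRLM and all five LBP histograms are property-tested against
independent brute-force enumerators (pair enumeration, run walking,
per-pixel code loops with `scipy.ndimage.map_coordinates` as an
independent bilinear path) on 100 random small images each, and the
oriented groups against the exact 90°-rotation swap H↔V, Z↔N.

## 3. Screening and Relief-F

* Normality: Lilliefors-corrected one-sample KS (statsmodels
  implementation); reported per feature, not used as a gate. Zero-variance
  samples return p = 0 (degenerate).
* Gate: classical equal-variance two-sample t-test, two-sided raw
  P < 0.05, **no multiplicity correction** — the screening stage
  deliberately mirrors a raw-alpha workflow; with 250 features this admits
  ~12 false positives per null cohort, which the downstream sweep treats
  as candidates only.
* Relief-F: two-class form (the multiclass prior weight reduces to 1),
  k = 5 neighbours, all instances; Manhattan distance on range-normalized
  features; neighbour ties broken by lowest sample index, making scores
  exactly permutation-invariant. Scores live in [−1, 1]; constant features
  score exactly 0. Ranking is gate-first (only t-significant features are
  scored and ranked), ties by registry order; shortfalls below the
  requested top-10 are returned in full and flagged.

## 4. Evaluation harness

* **Split**: subjects (not images) are drawn per class without
  replacement to the fixed training allocation (50 patients, 38 controls
  out of 64/46 — the printed allocation, not naive 80% rounding), so both
  frames of a subject stay on one side. Disjointness is asserted on every
  run.
* **LOOCV**: n fits on n−1 training samples; the n pooled held-out
  predictions are scored once (one training row per model). Degenerate
  single-class folds fall back to majority-vote prediction.
* **Metrics**: confusion-matrix rates as percentages rounded to two
  decimals; AUC via the empirical ROC (Mann–Whitney equivalence is
  oracle-tested to 10⁻¹⁰). Single-class truth vectors flag the undefined
  rate as NaN rather than 0.
* **Sweep**: k = 1..10 over the ranked list; the reported "best k" per
  classifier maximizes test accuracy (ties to the smaller k), mirroring
  the source protocol's best-performance reading.
* **Classifiers** are scikit-learn estimators configured with the fixed
  hyperparameters; the bespoke content of this package is the protocol,
  not the solvers. "Regression cost 1" is read as SVM C = 1; AdaBoost's
  quoted square regression loss is a toolbox quirk with no classification
  counterpart and is ignored; the phase-specific random-forest settings
  follow the listed order with T first. SVM features are z-scored inside
  each training fold via a pipeline; tree ensembles consume raw features.

**Null behaviour.** With `effect_size = 0`, the best-of-sweep test
accuracy is *not* centred at 50%: the 14:8 test imbalance gives every
majority-leaning classifier a 63.6% floor, and maximizing over
4 classifiers × 10 k inflates it further. The calibration check therefore
constrains the 20-seed mean of the best test accuracy to the 95% binomial
band for n = 22 around chance — a genuine class-signal leak would push it
above the band, while the observed means sit just above the majority
floor. Similarly, pooled LOOCV accuracy under a permutation null is biased
below 50% with super-binomial variance (the held-out sample's class is the
training minority), so that check is one-sided: no skill above chance on
the across-seed mean.

## 5. Problem sizes and determinism

Default ROIs are 256² (all 8 wavelet levels exist). The test suite's
end-to-end checks use the full 64/46 cohort at 256² for the strong-effect
recovery and 128² ROIs for the 20-seed null calibration; 128² supports the
whole feature battery (largest Gabor support 73 px) with level-8 wavelet
energies under the fill-and-flag rule, and cohort/split arithmetic is
unchanged. `scripts/acceptance.py` uses the same sizes with 5 null seeds.

A single master seed fans out to per-stage child seeds
(cohort / split / classifier) via `numpy.random.SeedSequence`, recorded in
`summary.json`; a replay from the saved config reproduces every CSV
byte-for-byte (tested).

## 6. Known limitations

* The simulator emulates speckle statistics and an oriented-band effect
  only; no anatomy, attenuation, scan-line geometry, or phase-to-phase
  deformation. Passing the recovery tests validates the pipeline's
  mechanics, not clinical performance.
* Relief-F is O(n² · features) on the training cohort — fine at cohort
  scale, not meant for thousands of samples.
* The raw-alpha gate plus best-of-sweep selection is faithful to the
  source protocol but optimistically biased on small test sets; the null
  calibration quantifies that bias rather than removing it.
* Real-data ingestion expects pre-cut grayscale ROI rasters; ROI drawing,
  DICOM cine parsing and ECG gating are out of scope.
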