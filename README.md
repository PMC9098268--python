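# echotexture

Texture-radiomics pipeline for two-class classification of echocardiographic
regions of interest (ROIs), built around the question of whether chronic
right-ventricular pacing leaves a detectable signature in myocardial
ultrasound texture. Pacing-induced cardiomyopathy (PICM) develops silently
under high-burden pacing and is usually caught only after the ejection
fraction has already dropped; a computer-aided detection (CAD) tool that
classifies B-mode texture of the myocardium at end-diastole ("R-wave" frame)
and end-systole ("T-wave" frame) is one route to earlier detection.

The package is aimed at researchers who want a fully reproducible, tested
version of that analysis chain. Because clinical echocardiograms of this
kind are not publicly available, the package ships a speckle-image simulator
that generates two-class cohorts with a controllable, oriented-band texture
effect, so every stage of the pipeline can be exercised and validated end to
end.

## What the pipeline computes

1. **Synthetic cohort** (`echotexture.synthetic`). Each ROI is
   `I = B·E`: a smooth log-normal echogenicity map `B` times the unit-mean
   Rayleigh envelope `E` of a correlated circular complex Gaussian field
   (fully developed speckle). The case class additionally carries an
   oriented sinusoidal echogenicity modulation (wave vector at
   0/45/90/135°, wavelength `2·s` pixels) under the speckle, so the class
   signal lives in oriented band energy. Default cohort: 64 cases, 46
   controls, two frames (phases R and T) per subject.

2. **250 texture features** (`echotexture.features`), nine groups:
   histogram (9), causal 2-D autoregressive model θ₁..θ₄, σ (5), gradient
   (5), whole-ROI histograms of oriented gradients with 4/8/16 bins (28),
   Gabor magnitudes `Gab{s}{d}` for envelope sizes s ∈ {2,4,6,8,10,12} and
   directions H/Z/V/N (24), Haar wavelet subband energies `HaarS{1..8}{LH,HL,HH}`
   (24), gray-level run-length statistics per direction (28), Haralick
   co-occurrence statistics pooled over the four distance-1 directions (11),
   and local binary patterns — overcomplete `Oc4`, transition `Tr4`,
   center-symmetric `Cs4/Cs8/Cs12` histograms (116).

3. **Screening and ranking** (`echotexture.screening`): Lilliefors KS
   normality check, equal-variance two-sample t-test gate at P < 0.05, then
   two-class Relief-F (k = 5 nearest hits/misses, Manhattan distance on
   range-normalized features, scores in [−1, 1]) and a top-10 ranking.

4. **Evaluation harness** (`echotexture.harness`): subject-level 80/20
   split reproducing the printed allocation (50 + 38 train, 14 + 8 test),
   leave-one-out CV on the training partition, and an incremental top-k
   feature sweep (k = 1..10) over four fixed classifiers — CART decision
   tree (min split 5, depth 20), RBF-SVM (C = 1, tol 0.10, per-fold
   z-scoring), random forest (29/5/8 for T, 28/3/5 for R), and AdaBoost
   (50 stumps, learning rate 0.1). Patients are the positive class;
   sensitivity, specificity, accuracy (percent) and ROC AUC are reported
   for training (pooled LOOCV predictions) and test.

## Worked example

```python
from echotexture import RunConfig, run

result = run(RunConfig(out_dir="demo_run", master_seed=7))
print(result.ranked["R"].head(5).to_string(index=False))
print(result.report[result.report.phase == "R"].head(4).to_string(index=False))
```

prints (numbers from this exact invocation):

```
    Group  Rank Feature    Score
Histogram     1  Perc01 0.928409
    Gabor     2   Gab8V 0.892879
    Gabor     3  Gab10V 0.887936
    Gabor     4   Gab6V 0.873723
Histogram     5  Perc10 0.856439

phase    classifier    stage  k  sensitivity  specificity  accuracy  auc
    R decision_tree training  1        100.0        100.0     100.0  1.0
    R decision_tree     test  1        100.0        100.0     100.0  1.0
    R       svm_rbf training  1        100.0        100.0     100.0  1.0
    R       svm_rbf     test  1        100.0        100.0     100.0  1.0
```

The default cohort injects a strong vertical band effect
(`effect_size=1.0` at 90°, scale 8): the matched Gabor feature `Gab8V` and
its orientation neighbours rank at the top, and every classifier separates
the held-out 14 patients / 8 controls perfectly. Weaker effects
(e.g. `CohortSpec(effect_size=0.25)`) produce graded rankings and
accuracies; `effect_size=0` is an exchangeable null. The run directory
contains the feature tables, screening and ranking CSVs, accuracy-vs-k
sweep curves (CSV + PNG), a two-feature scatter, `report.csv`, and a
`summary.json` with all 16 classifier × phase × stage metric rows plus the
stage seeds.

The same pipeline is scriptable from the shell:

```bash
echotexture all --seed 7 --out-dir demo_run
echotexture simulate --seed 7 --out-dir demo_run --n-cases 64 --n-controls 46
echotexture rank --out-dir demo_run --features demo_run/features_R.csv
```

To analyse real ROI images instead of synthetic ones, write a
`manifest.csv` (columns `subject_id, class, phase, path, seed`) pointing at
8/16-bit grayscale PNG/TIFF files and start from `echotexture extract`.

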