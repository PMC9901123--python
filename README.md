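# gbp-radiomics

Dual-modality ultrasound radiomics for gallbladder polypoid lesions: a
tested, reusable implementation of a pipeline that discriminates
**gallbladder neoplastic polyps** (adenoma spectrum, precancerous) from
**cholesterol polyps** (benign) using paired **B-mode** and **SMI**
(superb microvascular imaging) panels of the same lesion section.

It is aimed at researchers in ultrasound radiomics who want the full
analysis chain — delineation-to-mask preprocessing, a fixed feature bank,
reproducibility filtering, sparse feature selection, SVM classification and
paired model comparison — as inspectable, seeded, unit-tested code rather
than a one-off analysis script. Because the underlying patient cohort is not
public, the package ships a calibrated synthetic phantom generator so every
stage runs and is testable end to end.

## Method

For each lesion with delineated contour and co-registered panels:

1. **Preprocess** — rasterize the contour to a binary mask (pixel-center
   even-odd rule), derive the rectangular reference band around the lesion
   and the bright (within-lesion Otsu) sub-region, and map the contour onto
   the SMI panel by the inter-panel translation.
2. **Features** — per modality, 91 spatial features: 28 first-order
   histogram statistics (IMean, IMedian, Std_I, CoV, entropy, skewness,
   kurtosis, the lesion/reference ratios RImean and RImedian, …), 60 GLCM
   texture features (energy, contrast, entropy, homogeneity at offsets
   d = 1..15, 32 gray levels, direction-averaged, pairs confined to the
   lesion) and 3 binary-texture features (AR, CDD, DD). From the B-mode mask
   additionally 15 morphological features (Area, C.area, Maj.Len, …).
   B-mode: 106 features; SMI: 91; dual table: 197 columns.
3. **Selection** — keep features with inter-observer ICC(2,1) > 0.6
   (computed from repeat delineations by two observers), z-score on training
   rows, then L1-penalized logistic regression over a 100-point penalty path
   with the penalty chosen by 5-fold cross-validated deviance.
4. **Classify** — per repeat, one stratified 8:2 split shared by the
   B-mode / SMI / dual models; RBF-SVM grid search (C ∈ 2⁻⁵..2¹⁵,
   γ ∈ 2⁻¹⁵..2³) tuned by 5-fold CV AUC on the training rows; metrics
   AUC / ACC / SEN / SPE / YI (= SEN + SPE − 1) on train and test; five
   repeats give mean ± SD summaries, ROC and calibration curves.
5. **Compare** — for each metric and each dual-vs-single pair, paired
   differences across repeats are tested with a paired t-test when
   Shapiro-Wilk finds them normal, otherwise the Wilcoxon signed-rank test,
   with the mean difference and 95% CI reported.

See `docs/methods.md` for the full model description, parameter defaults,
phantom calibration and known limitations.

## Worked example

```python
from gbp_radiomics import PipelineConfig, run_pipeline
from gbp_radiomics.classify import summary_table

cfg = PipelineConfig(n_lesions=40, n_neoplastic=12, n_repeats=3, master_seed=3)
result = run_pipeline(cfg)
print(summary_table(result.protocol).to_string(index=False))
print(result.comparisons[["metric", "pair", "mean_diff", "p_value", "test_used"]]
      .round(3).to_string(index=False))
```

prints

```
split model           AUC           ACC           SEN           SPE             YI
train     B 1.000 ± 0.000 1.000 ± 0.000 1.000 ± 0.000 1.000 ± 0.000  1.000 ± 0.000
train   SMI 0.903 ± 0.087 0.812 ± 0.108 0.500 ± 0.265 0.955 ± 0.045  0.455 ± 0.300
train  dual 1.000 ± 0.000 1.000 ± 0.000 1.000 ± 0.000 1.000 ± 0.000  1.000 ± 0.000
 test     B 1.000 ± 0.000 1.000 ± 0.000 1.000 ± 0.000 1.000 ± 0.000  1.000 ± 0.000
 test   SMI 0.722 ± 0.173 0.625 ± 0.125 0.167 ± 0.289 0.778 ± 0.255 -0.056 ± 0.096
 test  dual 1.000 ± 0.000 1.000 ± 0.000 1.000 ± 0.000 1.000 ± 0.000  1.000 ± 0.000
metric     pair  mean_diff  p_value test_used
   AUC   dual-B      0.000    1.000  paired-t
   AUC dual-SMI      0.278    0.109  paired-t
   ACC   dual-B      0.000    1.000  paired-t
   ACC dual-SMI      0.375    0.035  paired-t
   SEN   dual-B      0.000    1.000  paired-t
   SEN dual-SMI      0.833    0.250  wilcoxon
   SPE   dual-B      0.000    1.000  paired-t
   SPE dual-SMI      0.222    0.270  paired-t
    YI   dual-B      0.000    1.000  paired-t
    YI dual-SMI      1.056    0.250  wilcoxon
```

Reading the output: on this small strong-contrast phantom cohort the B-mode
and dual-modality models separate the classes perfectly (the phantom's
B-mode class contrast — size, shape irregularity, interior texture — is
deliberately strong), while the SMI model, whose only class signal is the
differing prevalence of microvascular tracks, performs modestly; the
comparison table accordingly finds a significant dual-vs-SMI accuracy gain
(p = 0.035) and no dual-vs-B difference. Per-run metrics, selected feature
lists, ROC/calibration points and plots are written when an output directory
is passed (`run_pipeline(cfg, out_dir=...)`).

The same pipeline is scriptable from the shell:

```bash
gbp simulate --n 100 --n-neoplastic 29 --seed 7 --out data/
gbp extract  --data data/ --out feats/
gbp run      --seed 7 --out results/run1/
```

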