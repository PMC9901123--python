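# Methods

`gbp-radiomics` reimplements, as a tested pipeline, a dual-modality
ultrasound radiomics workflow for discriminating gallbladder neoplastic
polyps (adenoma spectrum, precancerous) from cholesterol polyps (benign).
Each lesion contributes one co-registered pair of grayscale panels — a
B-mode image and a superb microvascular imaging (SMI) panel — plus manual
lesion delineations. The pipeline rasterizes the delineations into masks,
extracts a fixed feature bank per modality, filters the bank on
inter-observer reproducibility, reduces it with an L1-penalized logistic
regression, trains an RBF-kernel SVM per modality (B-mode, SMI, dual) under
a repeated stratified 8:2 protocol, and compares the three models with
paired tests.

The clinical cohort behind the original study (100 lesions, 71 cholesterol /
29 neoplastic) is not publicly deposited. The package therefore ships a
first-class synthetic phantom generator whose class-conditional statistics
are calibrated to the published cohort description, so every stage of the
analysis is exercisable and testable at desk scale.

## Synthetic phantom cohort

Each case is a 256×256 pixel, 8-bit image pair at 0.2 mm/pixel
(51.2 mm field of view). The published description implies lesion diameters
up to 28 mm, which must fit the frame with a margin while an 8 mm lesion
still spans 40 px; 0.2 mm/px satisfies both.

- **Geometry.** The lesion boundary is an ellipse (random aspect ratio
  1–1.25) plus a low-order Fourier radial perturbation (harmonics 2–5).
  The perturbation amplitude encodes "irregular shape"; neoplastic lesions
  get a larger amplitude (0.12 vs 0.04 relative), matching the reported
  excess of irregular shapes in the neoplastic class.
- **Diameters.** Sampled from a triangular distribution whose (min, mode,
  max) equal the published per-class (min, median, max): (8, 13, 21) mm for
  cholesterol, (8, 17, 28) mm for neoplastic. The triangular family matches
  the printed median and range with no free parameters; its median deviates
  from its mode by well under the 15% calibration tolerance asserted in
  tests.
- **Echo texture.** B-mode intensity is a class-mean field (lesion interior
  ~115 for cholesterol, ~95 for neoplastic, lumen ~30) multiplied by
  unit-mean gamma speckle — the standard first-order approximation of fully
  developed speckle. The gamma shape controls interior homogeneity:
  5 (heterogeneous) for cholesterol vs 12 (homogeneous) for neoplastic,
  encoding the reported observation that adenomas have a more uniform pixel
  distribution. Cholesterol lesions additionally carry Poisson-seeded
  hyperechoic punctate foci (density 0.015/px, ~1.2 px wide, peaking
  60–140 gray levels above the local mean); the neoplastic class is nearly
  free of them (0.001/px).
- **Vascularity.** Per-class vessel probability equals the published
  prevalence: 38/71 ≈ 0.535 (cholesterol) and 26/29 ≈ 0.897 (neoplastic).
  Vascular cases receive 1–3 bright curvilinear random-walk tracks, 1–3 px
  wide, inside or adjacent to the lesion in the SMI panel. Non-vascular
  lesion interiors sit at or below the SMI background level.
- **Observer delineations.** Three contours per case — observer A twice,
  observer B once — are the true contour displaced radially by a smooth
  correlated noise field (Gaussian-smoothed circular white noise over vertex
  angle). The field is scaled so the mean absolute radial deviation equals
  `jitter_px` (default 1.5 px ≈ 0.3 mm), i.e. observers err smoothly rather
  than per-vertex independently.
- **Determinism.** One master seed fans out to per-stage, per-case child
  seeds via SHA-256 of `(seed, tag)`; identical spec + seed reproduces the
  cohort bit-for-bit.

What the phantom does **not** emulate: beam physics (no PSF convolution,
attenuation, shadowing or scan conversion), anatomy outside the lumen,
Doppler velocity information, and inter-patient variation in gain or depth
settings. Passing tests therefore demonstrate that the analysis machinery is
correct and well-calibrated on data with the assumed statistical structure —
not that the clinical discrimination figures transfer to real patients. By
design the default class contrast is strong: the end-to-end acceptance check
expects the dual-modality model to reach test AUC ≥ 0.9, and the B-mode
model typically saturates near 1.0 on these phantoms.

## Preprocessing

Coordinates are 0-based with x = column, y = row and pixel centers at
integer positions. A pixel belongs to a polygon iff its center is inside
under the even-odd rule; boundary points resolve by the half-open crossing
convention, so an axis-aligned square with corners (10,10)–(20,20) yields
exactly 100 pixels. Masks must be single connected components of ≥ 16 px.

- **Reference band**: the lesion bounding box dilated by `margin_px`
  (default 10 px) on all sides, clipped to the image, minus the lesion —
  a deterministic reading of "the rectangular area expanding outwards from
  the lesion".
- **High-intensity sub-region**: within-lesion Otsu threshold (parameter
  free and reproducible; no published rule exists). The bright class is
  `intensity > threshold` (the threshold value itself belongs to the dark
  class, the standard histogram-edge convention). A constant lesion returns
  the whole lesion with a warning.
- **Panel mapping**: the B-mode contour is translated onto the SMI panel by
  the inter-panel offset (pure translation — the system displays the same
  section side by side), preserving shape metrics exactly.

## Feature bank

Exactly 91 spatial features per modality, plus 15 morphological features
computed once from the B-mode mask (lesion geometry is common to both
panels): B-mode vectors have 106 entries, SMI vectors 91, and the dual table
197 columns suffixed `_B`/`_SMI`.

- **First-order (28).** The nine canonical members — IMean, IMedian, Std_I
  (population SD), CoV, 32-bin histogram entropy (bits, bins spanning
  [0, 255]), skewness and excess kurtosis (population moments, Fisher),
  RImean and RImedian (lesion/reference-band ratios) — plus a frozen
  19-member extension (min, max, range, percentiles 10/25/75/90, IQR, mean
  absolute deviation, robust MAD over the 10–90% core, RMS, energy,
  histogram uniformity, variance, 90–10 percentile range, reference mean and
  SD, lesion−reference mean difference, lesion/reference SD ratio) so the
  spatial bank totals exactly 91. Only the nine canonical members have
  published definitions; the extension inventory is this package's frozen
  choice.
- **GLCM (60).** Energy Σp², contrast Σ(i−j)²p, entropy −Σp·log₂p and
  homogeneity Σp/(1+|i−j|) at every offset d = 1..15. Matrices use 32 gray
  levels quantized over the within-lesion min–max range (making the features
  invariant to image-wide affine intensity rescaling), count only pixel
  pairs with both ends inside the lesion, are symmetrized, and average the
  four directions 0°/45°/90°/135° (each direction normalized, then averaged
  over directions with at least one valid pair). An offset with no valid
  pair degenerates to (Ener, Cont, Entr, Homo) = (1, 0, 0, 1) with a
  warning — the single-cell limit.
- **Binary texture (3).** AR = |bright| / |lesion|; CDD = mean distance of
  bright pixels to the lesion centroid; DD = mean distance of bright pixels
  to their own centroid; CDD and DD are normalized by the lesion equivalent
  radius √(area/π), making them scale-free. An empty bright region yields
  (0, 0, 0).
- **Morphology (15).** Area, convex area, major/minor axis of the
  second-moment ellipse, perimeter, circularity 4πA/P², solidity,
  eccentricity, extent, aspect ratio, equivalent diameter, convex perimeter,
  convexity, bounding-box width/height — lengths in mm, areas in mm². The
  convex area is the count of lattice points covered by the convex hull
  polygon of the mask's pixel centers, which keeps it on the same
  pixel-count scale as Area (so Area ≤ C.area holds by construction and
  convex lesions satisfy C.area ≈ Area), unlike a rasterized hull image,
  which systematically over-counts by several percent on discs.

## Feature selection

- **ICC filter.** Features pass iff the inter-observer ICC — observer A's
  first delineation vs observer B's — exceeds 0.6 strictly. The
  intra-observer ICC (A's two repetitions) is reported but does not gate.
  The ICC form is ICC(2,1): two-way random effects, absolute agreement,
  single measurement, from the standard mean-squares decomposition; a
  zero-variance table is defined as perfect agreement (ICC 1) with a
  warning. The implementation is validated against pingouin's ICC(A,1) to
  1e-9.
- **Normalization.** Per-feature z-scoring with mean and population SD
  estimated on training rows only; columns constant on the training rows are
  dropped with a warning.
- **LASSO.** L1-penalized logistic regression over a 100-point penalty path
  from λ_max (the smallest penalty giving the all-zero solution) down four
  decades. Path fits are warm-started along the path (saga solver, loose
  tolerance — the path only ranks penalties); the penalty minimizing mean
  5-fold cross-validated deviance is then refit tightly, and the selected
  set is the nonzero coefficients, ordered by |coefficient|. Ties in CV
  deviance resolve to the strongest penalty (sparsest model). Correctness at
  the chosen penalty is verified against an independent IRLS +
  coordinate-descent solver to 1e-6.
- **Leakage scope.** By default the ICC filter, normalization statistics and
  LASSO are all computed on the training rows of each repeat
  (`selection_scope="train"`), the defensible leakage-free reading of a
  selection step described before the classification protocol;
  `selection_scope="all"` reproduces the literal whole-cohort reading.

## Classification protocol

Per repeat (5 repeats by default): one stratified 8:2 train/test split
shared by all three modality models (so per-repeat test metrics are paired);
per modality, the selection cascade runs on the training rows, then an
exhaustive grid search over RBF-SVM cost C ∈ 2^{−5..15} and width
γ ∈ 2^{−15..3}, both stepped by powers of 4 (the width endpoint 2³ appended
since stepping from 2^{−15} lands on 2¹), with stratified 5-fold CV
maximizing mean AUC. Exact AUC ties — routine on strongly separable
phantoms — break on mean CV accuracy, then grid order. The winning pair is
refit on all training rows with Platt scaling.

The positive class is the neoplastic polyp. AUC is the rank statistic (ties
half). The hard operating point is decision score 0, equivalently calibrated
probability 0.5: the score fed to the evaluator is the Platt log-odds, a
strictly monotone transform of the SVM margin (AUC unchanged) whose zero sits
at calibrated risk 0.5 rather than the unscaled margin midpoint — without
this, AUC-tied degenerate grid points can classify every case as the
majority class. YI = SEN + SPE − 1 holds exactly per run. If selection
retains no feature the model falls back to a constant score (AUC 0.5 by the
tie convention), which keeps permutation nulls centered. ROC curves are
exact step curves whose trapezoidal area equals the rank AUC to 1e-12;
calibration curves use 5 equal-width bins on predicted risk.

## Model comparison

For each metric (AUC, ACC, SEN, SPE, YI) and each pair (dual vs B-mode, dual
vs SMI), the per-repeat test metrics are differenced pairwise. Shapiro-Wilk
at α = 0.05 on the differences selects the branch: paired t-test with a
t-based 95% CI when normal, Wilcoxon signed-rank (exact for n ≤ 25, zeros
dropped) otherwise — a concrete instantiation of the qualitative
"normal → t, seriously skewed → Wilcoxon" rule. The mean difference and its
t-based CI are always reported descriptively, marked with an asterisk on
Wilcoxon rows. With the default protocol the paired n is the 5 repeats:
each repeat yields exactly one test-set evaluation, so repeat-level pairs
are the natural unit; `paired_compare` accepts any aligned series of length
≥ 3 if a configuration produces more runs. All-zero differences short-
circuit to p = 1 with a degenerate (0, 0) CI. No multiple-testing correction
is applied across the 10 comparisons, matching the original analysis; the
10 p-values should be read accordingly.

## Problem sizes and reproducibility

Defaults: 100 lesions (29 neoplastic), 3 delineations, 5 protocol repeats.
On one CPU the full pipeline (generate, extract 3×100 panels-pairs, 5
repeats × 3 models of selection + tuning, paired stats) runs in a few
minutes; extraction is ~0.1 s per case. A single master seed reproduces
every stage bit-for-bit, and the results bundle's manifest records the
config hash so reruns can be verified byte-identically.

## Known limitations

- The 91-feature inventory reproduces the published counts and all named
  members, but the unpublished remainder of the original inventory (names
  like `RAR3`, `AR_O2` appear in its selection table without definitions)
  cannot be reconstructed; the extension features here are documented
  look-alikes, not reverse-engineered equivalents.
- Phantom class contrast is deliberately strong; absolute metric values on
  synthetic cohorts are not comparable to the published clinical values, and
  the B-mode model's saturation (AUC ≈ 1) compresses the dual-vs-single
  differences that the paired tests examine.
- Platt probabilities from small training sets (80 cases) are only roughly
  calibrated; calibration curves on a 20-case test split are noisy.
- The Wilcoxon branch at n = 5 has a minimum attainable two-sided p of
  0.0625; significance claims at the default repeat count rest mostly on the
  t branch.
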