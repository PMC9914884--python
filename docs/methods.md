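# Methods

`nodetex` implements a classical (MaZda-style) texture-analysis workflow
for discriminating two lesion classes on grey-scale 3D MRI regions of
interest, together with a calibrated phantom generator that lets the
whole pipeline be exercised and tested without clinical data. This note
records the model, the conventions that had to be fixed where the
classical tools leave them ambiguous, and what the synthetic cohorts do
and do not demonstrate.

## Intensity normalization and quantization

All features operate on ROI voxels remapped by the "mu +/- 3 sigma"
rule: with `mu` and `sigma` the mean and standard deviation of the
in-ROI intensities, values are clipped to `[mu - 3 sigma, mu + 3 sigma]`
and mapped linearly onto `Ng = 2**bits` integer grey levels,

    level = 1 + floor((clip(x) - (mu - 3s)) / (6s) * (Ng - 1) + 0.5),

so `mu - 3s -> 1` and `mu + 3s -> Ng` exactly and the map is monotone.
The bin-edge convention (round-half-up at mid levels) is ours; any
monotone endpoint-exact convention would do, but it must be fixed for
reproducibility. `mu`/`sigma` use the population (divide-by-N)
convention usual for image statistics; a `ddof` parameter exposes the
sample convention. A constant ROI maps to the single mid-scale level
with a warning. Because the clip range is an affine function of the
data, the whole pipeline is invariant to affine intensity changes
(scanner gain/offset) — tested property.

The default is `bits = 6` (64 levels), matching the `S6` token in the
feature-name grammar used throughout the reports.

## Feature families

All families are computed in-plane on the axial slices of the 3D ROI
and pooled over slices. Out-of-ROI voxels never contribute.

**Co-occurrence (GLCM).** For a direction in {H 0deg, V 90deg, Z 45deg,
N 135deg} and distance d in 1..5, co-occurrence counts of level pairs at
that offset (both ends in-ROI) are accumulated symmetrically (each pair
in both orders) over all slices, then normalized. Eleven Haralick
features per matrix: AngScMom, Contrast, Correlat, SumOfSqs, InvDfMom,
SumAverg, SumVarnc, SumEntrp, Entropy, DifVarnc, DifEntrp. Conventions
we had to fix: entropies use the natural logarithm (configurable) with
`0 log 0 := 0`; `DifVarnc` is the variance of the difference
distribution `p_{x-y}` about its own mean (the other common reading,
second moment about zero, is `Contrast`); `Correlat` is reported
missing, not NaN, when a marginal variance vanishes. Counts are pooled
across slices rather than per-slice features averaged; with per-slice
ROIs of similar size the two differ little, but pooling keeps small
slices from dominating.

**Feature names.** `CZ1S6Entropy` = grey channel `C`, direction `Z`,
inter-pixel distance 1, `S` normalization, 6 bits, feature Entropy. The
digit after the direction letter is the GLCM distance and the digit
after `S` is the bit depth; this makes the reported feature sets a
coherent distance-1..5 grid. Run-length names keep the direction but
have no distance (`CHS6RLNonUni`); histogram/gradient/wavelet names keep
only `C...S<bits>`; autoregressive parameters are conventionally printed
bare (`Teta1`..`Teta4`, `SigmaAR`). Parsing and serialization round-trip
bijectively.

**Run length.** Maximal runs of equal level along each line of a slice
in the four directions, broken by out-of-ROI voxels. Five features per
direction: ShrtREmp, LngREmph, GLevNonU, RLNonUni, and Fraction (runs
per ROI voxel).

**Histogram.** Mean, population variance, skewness, excess kurtosis and
percentiles 1/10/50/90/99 (linear interpolation) of the in-ROI levels;
shape statistics are missing for constant ROIs.

**Absolute gradient.** In-plane central differences
`((x[r,c+1]-x[r,c-1])/2, (x[r+1,c]-x[r-1,c])/2)` at voxels whose four
in-plane neighbours are in-ROI; mean, variance, skewness, kurtosis and
nonzero fraction of the magnitude.

**Autoregressive model.** Least-squares fit of each level on its four
causal neighbours (west, northwest, north, northeast) after mean
centring, pooled over slices; `SigmaAR` is the residual standard
deviation. The neighbourhood definition is ours (the classical tools do
not document it). Constructed inputs can make the design rank
deficient (e.g. an image whose rows repeat makes W and NW identical);
we return the minimum-norm least-squares solution, which recovers the
generating coefficients in such cases, and flag the family missing only
for fully degenerate (constant) ROIs or fewer than 20 usable voxels.

**Wavelet.** Per-slice 2D Haar decomposition of the mask bounding box,
out-of-ROI voxels filled with the slice ROI mean to limit edge
artefacts. Subband `XY` means X filter along rows and Y along columns
(so period-2 stripes along columns load on `LH`). Energy = mean squared
coefficient over coefficients whose 2^s-block support touches the ROI,
pooled over slices; scales whose `2**s` exceeds the bounding box are
missing. Default: scales 1..5.

The default grid is 220 GLCM + 20 run-length + 9 histogram + 5 gradient
+ 5 AR + 20 wavelet = 279 features per lesion. Any individual failure
is recorded as a missing value (NaN in tables); extraction never aborts
a batch.

## Feature selection and classification

The Fisher coefficient of a feature is
`F = (mu_a - mu_b)^2 / (s_a^2 + s_b^2)` with population variances (the
unweighted two-class form; a class-size weighted pooled variant is
available). Features are ranked by descending F with ties broken by
name; the top 10 form the selected set and `F > 3` flags "good
discriminatory potential". Features with missing values are excluded
from ranking with a logged count.

Classification is k-nearest-neighbour with leave-one-out evaluation,
`k = 1` by default (the classical default; the choice is configurable
but must be odd). Features are z-scored inside each fold using
statistics of the training lesions only. Distance ties at the
neighbourhood boundary and voting ties both resolve toward the lower
class label, making the evaluation fully deterministic.

## Statistics

- **Mann-Whitney U** with midrank ties; exact distribution when the
  combined sample is at most 20 without ties, tie-corrected normal
  approximation (no continuity correction) otherwise. Group medians
  and IQRs use linear-interpolation percentiles.
- **ROC analysis.** The empirical AUC is the Mann-Whitney probability
  (concordant pairs + half ties) / (n1 n2) — an identity tested
  against a brute-force pair counter. The 95% CI uses the DeLong
  variance (Wald, clipped to [0, 1]); our DeLong components and the
  paired AUC-difference test match pROC to 1e-9 on a frozen fixture.
  The operating point maximizes the Youden index `J = sens + spec - 1`
  over observed score values, reported as a strict `>` criterion, ties
  resolved to the lowest criterion; sensitivity/specificity carry
  Clopper-Pearson exact binomial CIs. Orientation is auto-flipped so
  the reported AUC is at least 0.5, with the flip flagged and the raw
  (positive-class-high) AUC retained.
- **Multivariate step.** Ordinary least squares of the 0/1 outcome on
  all selected features simultaneously ("enter" model), with
  per-coefficient SE/t/p, `VIF_j = 1/(1 - R2_j)`, R2, adjusted R2 and
  the multiple correlation `sqrt(R2)`. A linear model, not logistic,
  because the conventional clinical-package report this mirrors (R2,
  VIF, coefficient table) is the linear one; its fitted values are the
  combined predictor scored by a final ROC analysis.
- No multiple-testing correction is applied across the selected
  features; the workflow this package reproduces applies none, and the
  omission is intentional and should be kept in mind when reading
  per-feature p-values.

## Synthetic cohorts

`CohortSpec` defaults generate 39 "benign" and 17 "malignant" lesions:
ellipsoidal ROIs (in-plane semi-axes 9-12 voxels, through-plane 4-6, in
a 48x48x16 volume at nominal 1 mm spacing) whose interior is a smoothed
Gaussian random field (correlation scale 1.6 voxels benign, 1.5
malignant) plus white noise (sd 0.05 of the field sd), with two
additional components:

- **Punctate extremes** (both classes): 5% of ROI voxels carry spikes
  of +/- 55 field-sd units. These emulate small vessels/debris. They
  are what brings the co-occurrence entropy down to the 2.4-2.8 range
  observed for real T2 lymph nodes at 6-bit quantization: a plain
  Gaussian field always spreads over ~45 of the 64 levels (entropy
  near 6) because the mu +/- 3 sigma window is proportional to the
  data spread, whereas a few extreme voxels widen sigma so the tissue
  bulk concentrates on a handful of levels.
- **Multi-focal blobs** (malignant only): a random impulse field
  smoothed at 3.2 voxels, scaled to 0.8 of the field sd, mimicking
  multi-focal architectural disorder. Broad blobs widen the occupied
  level range and raise all co-occurrence entropies; we found (and the
  test suite encodes) that fine-scale perturbations instead make
  run-length and inverse-difference-moment features the top
  discriminators, so the blob scale is the decisive calibration
  parameter for reproducing an entropy-led feature ranking.

With these defaults the median `CZ1S6Entropy` is ~2.43 (benign) vs
~2.80 (malignant), the scale reported for non-metastatic vs metastatic
nodes. Lesion radii are class-identical by default so size cannot act
as the separating signal; `clinical_sizes=True` switches to radii
echoing clinical short-axis diameters (benign ~7 mm, malignant ~18 mm
median). Everything is a pure function of `(spec.seed, lesion_seed)`.

**What passing tests show.** On pooled default cohorts (20 seeds,
n = 1120 lesions) the top-10 Fisher set consists entirely of
entropy-type features ({Entropy, SumEntrp, DifEntrp}), the top Fisher
coefficient exceeds 3, the top-feature AUC exceeds 0.85 and 1-NN LOO
accuracy exceeds 85%; on zero-effect cohorts the top-feature AUC is at
chance and Mann-Whitney rejects at the nominal 5%. The family is
defined as entropy-type rather than the plain `Entropy` variants only:
joint, sum and difference entropies of the same co-occurrence
distribution are near-collinear on any single-mechanism texture, so
their mutual F-order is cohort-sampling noise; likewise the top-10
membership at a single n = 39/17 cohort fluctuates, which is why the
calibration property is stated for the pooled cohorts. The phantoms
emulate texture contrast only — no MR physics, Rician noise, partial
volume, inter-scanner effects or anatomical context — so these results
demonstrate the correctness and calibration of the pipeline, not
clinical performance.

## Problem sizes and runtimes

Defaults were chosen so the full test suite (including the 20 + 20
cohort calibration runs, each cohort 56 lesions of ~4000 ROI voxels)
completes in under two minutes on one CPU, and the acceptance script
(one full default cohort end to end) in well under a minute. Feature
extraction is ~40 ms per lesion.

## Known limitations

- GLCM directions are in-plane only; through-plane offsets are out of
  scope (the anisotropic slice thickness of typical T2 protocols makes
  them hard to interpret anyway).
- The wavelet family uses the Haar basis only.
- `roc_analysis` restricts criteria to observed score values, as
  clinical packages do; with heavy ties the optimal strict-`>`
  threshold between observed values is not considered.
- The OLS-based multivariate step is a reporting convention, not a
  probability model; its fitted values are used only as a ranking
  score.
- The generator's calibration constants are tied to 6-bit quantization
  and natural-log entropies; changing either moves the absolute entropy
  scale (the class contrast survives).
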