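# Methods

This note documents the models, conventions and design choices behind
`radbcr`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Imaging and discretization

Volumes are 3-D scalar NIfTI images with voxel spacing taken from the
header; the tumor ROI is a 0/1 mask on the same grid. NaN voxels are
rejected at load rather than imputed — silent imputation would corrupt
texture statistics. No isotropic resampling stage is applied: spacing is
carried through only for shape features, and texture matrices are
computed on the native grid. This is a documented limitation; with
anisotropic voxels the 13 scan "directions" are geometrically unequal.

Gray levels are quantized per lesion. *Fixed bin number* (FBN, the
default):

    level = min(G, floor(G * (x - min) / (max - min)) + 1),

with a constant ROI mapped entirely to level 1; min/max are computed on
ROI voxels only, which makes all FBN texture features invariant to any
positive affine rescaling of the intensities (relevant for multi-scanner
data). *Fixed bin size*: `level = floor((x - min)/width) + 1`. The
default study grid is FBN with G ∈ {8, 32}; the full configurable grid
is G ∈ {8, 16, 32, 64}. The exact parametrization grid used in the
clinical setting this workflow models is not public, so the grid here is
explicit configuration, and the analysis logic is independent of its
size.

## Wavelet bank

One pass of the coiflet-1 decomposition low/high-pass filters (6 taps,
from PyWavelets) is applied along each array axis without down-sampling
(stationary/à-trous convention), yielding eight sub-bands LLL … HHH plus
the untouched original: nine images aligned with the ROI mask. An
undecimated transform is required because features are extracted from
the filtered images under the *original* mask; a decimated transform
would break that alignment. Boundary handling is whole-sample symmetric
(mirror) padding; the first label letter refers to the first array axis.
Filtering is separable and linear, both of which are property-tested.

## Texture matrices and features

* **GLSZM** — zones are connected components (26-neighbour default,
  6-neighbour available) of constant gray level inside the ROI;
  `s(i, j)` counts zones of level *i* and size *j*. Conservation law:
  Σ j·s(i,j) equals the ROI voxel count.
* **GLRLM** — maximal collinear runs per direction, summed over the 13
  unique 3-D directions (IBSI "merged" aggregation). The implementation
  uses the sliding-window identity (runs of length exactly j =
  c_j − 2c_{j+1} + c_{j+2}, where c_k counts k-long constant windows),
  which is fully vectorized; tests compare it against an explicit
  per-line scanner.
* **GLCM** — symmetric distance-1 co-occurrences over the same 13
  directions.

The catalog is 14 GLSZM + 14 GLRLM + 6 GLCM features per (sequence,
sub-band, scheme) plus 12 first-order and 4 shape features per sequence
— 1256 variants per patient for two sequences and two schemes; the
closed-form count is exposed as `expected_row_length`. Features
undefined on degenerate ROIs (one occupied gray level) are emitted as
NaN and excluded from selection, never coerced to 0.

**Direction of SZE.** Small zone emphasis is (1/N_s) Σ s(i,j)/j².
Because zones are weighted by 1/size², fragmenting a zone into smaller
pieces *raises* SZE: heterogeneous lesions score high, homogeneous ones
low (a single zone of size N scores 1/N²). Descriptions sometimes state
the opposite sign convention; all analysis steps here (absolute-
correlation selection, orientation-corrected AUC) are invariant to the
sign of the association, so only the documentation convention matters,
and this package follows the formula.

## Cohort handling

The 2:1 train/test split is stratified on (event, scanner) with a
half-up per-stratum rounding rule, so both sides carry both scanners and
both outcome classes whenever stratum sizes allow; for 107 patients this
gives a 70–73 / 37–34 split depending on stratum boundaries.

Radiomic features are z-scored to mean 0 / SD 1 (n−1 denominator)
*within each scanner group, separately on each cohort side*. Computing
test-side parameters on the test side leaks no information into
training and is the convention this workflow models; note that FBN
texture features are already affine-invariant per lesion, so per-scanner
z-scoring mainly matters for first-order and shape features. Zero-
variance features within a group are set to 0 with a warning.

SMOTE balances the training classes exactly: each synthetic minority row
is x + u·(x_nn − x), u ~ U(0,1), with x_nn among the k = 5 nearest
minority neighbours (Euclidean, in the supplied feature space). No
environment-provided implementation is used; the algorithm is small and
is property-tested (originals untouched, synthetics inside the minority
bounding box, exact balance).

## Stability selection

With SMOTE applied first (default), the training table is subsampled 100
times at a 2:1 ratio with class stratification; per variant, the
absolute point-biserial Pearson correlation with the outcome is computed
on every subsample (no early exit — the full matrix is kept as audit
evidence). A variant is stable when |PC| > 0.3 (strict inequality;
configurable) in at least ⌈0.95·100⌉ subsamples. One variant per base
feature — defined as the (sequence, feature name) pair, with sub-band
and discretization as the parametrization axes — is retained by maximum
mean |PC| (ties: lexicographically smallest key, logged). Finally,
candidates are ranked by mean |PC| and accepted greedily unless their
absolute Pearson correlation with an already-accepted candidate exceeds
0.7. The procedure is deterministic given (table, labels, config, seed).

**Known limitation: SMOTE before selection inflates null correlations.**
Synthetic minority rows recycle the original minority values, so on an
imbalanced null table (e.g. 11 events of 70) the post-SMOTE
point-biserial correlation of a pure-noise feature is inflated by about
√(0.25/pq) ≈ 1.4 relative to the unbalanced value, and that inflation is
*stable* across subsamples of the augmented table. The measured
consequence (see the acceptance suite) is a per-feature null pass rate
of roughly 3%, so an all-noise table of 50 features typically retains
one to three features rather than none, whereas the stability rule
applied without SMOTE controls the per-feature null rate well below 1%.
The SMOTE-first ordering is retained because it is the workflow this
package implements; `SelectionConfig(use_smote=False)` provides the
originals-only sensitivity analysis. Practitioners should treat
survivor lists from SMOTE-first selection as needing the downstream
test-side evaluation they get here, not as FDR-controlled discoveries.

## Survival evaluation

AUC is the rank statistic with mid-ranks for ties (tested equal to
trapezoidal ROC integration); when the raw AUC is below 0.5 the
orientation is flipped and flagged, so reported AUCs are ≥ 0.5 with an
explicit "high/low predicts event" direction. P-values come from the
Mann–Whitney test (exact for small tie-free samples, otherwise normal
approximation with tie correction). Youden cutoffs scan midpoints of
consecutive distinct values and break ties toward higher sensitivity.
No multiple-testing correction is applied in the univariate tables,
matching the workflow modeled here (which relies on the aggressive
selection step instead); a logistic odds-ratio report is available as a
cross-check on the Cox hazard ratios.

Cox fits use the partial likelihood with Efron tie handling (lifelines).
Complete or near separation — a real possibility once covariates are
dichotomized in a 17-event cohort — is detected as non-finite or
absurdly large coefficients (|log HR| > 10) and handled by a flagged
ridge-penalized refit (penalizer 0.1) rather than reporting divergent
estimates. Kaplan–Meier curves are product-limit estimates; the
two-group log-rank test is two-sided with 1 df.

The three models are built on the training side only: every candidate
variable is dichotomized at its train-side Youden point; the clinical
model is the additive score of the best subset (≤ 2 factors, chosen by
train AUC; ties prefer fewer factors) of clinical covariates, the
radiomics model likewise over the selected radiomic variants, and the
combined model is the union of both factor sets. Model scores are
dichotomized at a train-side Youden cutoff into risk groups for KM,
log-rank and a univariate Cox HR. All frozen decisions are serialized in
`StudyResults.train_artifacts()`, and a poisoning test verifies that
altering test-side data leaves that serialization byte-identical. When
no radiomic variant survives selection the radiomics score is
identically zero and its AUC is 0.5 by convention — the model honestly
predicts nothing.

## Synthetic cohort

The generator emulates the study conditions this pipeline targets:
n = 107, a 70/30 two-scanner mix (75/32 patients), a 16% target event
fraction with administrative censoring uniform on 24–100 months, age ~
N(65, 6) truncated to [45, 80], pre-operative PSA log-normal with mean
9 ng/mL, Gleason ≤ 7 in ~85%, pT3 in ~65%, positive margins in ~60%,
and a CAPRA-S-like 0–12 ordinal derived from its components.

Tumor images are ellipsoidal ROIs (radii uniform on 3.5–7 voxels,
sub-millilitre lesions at 1 mm spacing) over Gaussian random fields:
white noise smoothed with a kernel of width ℓ (drawn uniformly on
[1, 6] voxels per patient), rescaled to unit contrast *within the ROI*,
plus i.i.d. noise of SD 0.15. Normalizing contrast inside the ROI is
essential: it makes the noise level mean the same thing at every ℓ, so
the correlation length maps monotonically onto zone size — the exact
construct size-zone features measure (mean SZE falls monotonically as ℓ
grows; tested). The hazard's linear predictor is 2.0 per SD of −ℓ (more
heterogeneous tumors recur more) plus 0.3 per SD of age and of log PSA;
event times follow a Weibull proportional-hazards law (shape 1.2) whose
baseline scale is solved numerically so the expected event fraction
equals the target. The ADC image carries the outcome-linked ℓ; the T2
image gets an independent nuisance ℓ, reflecting the ADC-dominant
signal this workflow models. Scanner B applies an affine intensity
distortion (×1.3 + 0.5) — the artifact per-scanner z-scoring is designed
to remove. Per-patient latent truth (ℓ, linear predictor) is stored
separately and consumed only by parameter-recovery tests.

What the generator does **not** emulate: MRI physics (k-space, coils,
diffusion), cross-sequence registration error, segmentation variability,
non-ellipsoidal lesion shapes, and PSA kinetics behind the recurrence
definition. Passing end-to-end tests therefore demonstrates that the
pipeline recovers a texture-encoded hazard under its own assumptions,
not clinical performance.

## Problem sizes and numerics

Default end-to-end runs use 32³ volumes, the FBN{8, 32} grid and 1256
feature variants; one full study (generation, extraction, selection,
evaluation) takes roughly 15 s on one CPU, and the replicated
end-to-end checks use 10 seeds. Matrix-feature computations are exact
integer tabulations; correlation and AUC computations are vectorized
with explicit zero-variance conventions (correlation 0, AUC 0.5).
Numerical tolerances in tests are 1e-12 relative for matrix/feature
oracles and 1e-10 for separability/linearity of the filter bank.
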