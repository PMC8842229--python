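# Methods

## Problem and overall design

Adaptive radiotherapy (ART) for nasopharyngeal carcinoma (NPC) — mid-course
re-imaging and re-planning — is triggered by patient-specific anatomical
change during the 6–7 week treatment course. `artomics` implements a
pre-treatment prediction pipeline for ART eligibility built from four
feature families extracted from co-registered planning data:

* **Radiomics (R)** — intensity and texture statistics of the CT-like and
  two MR-like channels inside tumour and parotid volumes of interest
  (VOIs), after a filter-bank decomposition;
* **Morphology (M)** — shape descriptors of the same VOI masks;
* **Dosiomics (D)** — dose-volume-histogram (DVH) scalars, spatial dose
  gradients, and texture of the 3D dose map inside all eight VOIs;
* **Contouromics (C)** — descriptors of the geometric relationship between
  VOI pairs, from the overlap-volume histogram (OVH) and the
  projection-overlap-volume (POV).

Models are evaluated under 20 stratified 70/30 train/hold-out resamplings
with inner 10-fold cross-validation: Ridge classifiers for single-family
models and multi-kernel learning (MKL) for fused models. Because no
patient data ship with the package, a synthetic cohort generator provides
inputs whose signal content is known and auditable.

## Data model and geometry conventions

Arrays are indexed `(x, y, z)` with per-axis voxel spacing in mm; all
geometry is computed at voxel centres in physical mm. A voxel belongs to a
VOI iff its stored label is positive (no partial volumes). "Surface"
voxels are mask voxels with a six-connected background neighbour. Exact
nearest-distance queries use the exact Euclidean distance transform, which
equals the brute-force all-pairs minimum for voxel centres.

Parotid laterality follows the median rule: for each parotid, the median
over **all** its voxels of the minimum distance to the GTVnp **surface**;
the smaller median is the ipsilateral parotid. Even-length medians are the
mean of the two central values; an exact tie (only possible in artificial
mirror-symmetric scenes) resolves to the left parotid with a logged
warning. Note the assignment of labelled masks is invariant under any
rigid motion, including mirroring; "mirroring swaps the assignment" holds
once sides are relabelled anatomically after the flip, which is how the
equivariance tests are phrased.

## Feature catalogues

The catalogue of record is fixed in code; every count below is asserted in
tests.

**Intensity/texture engine (93 features per image-VOI).** 18 first-order
statistics (the common 17 plus the standard deviation; total energy
excluded), 24 grey-level co-occurrence (GLCM), 16 run-length (GLRLM), 16
size-zone (GLSZM), 14 dependence (GLDM) and 5 neighbouring-grey-tone
(NGTDM) features. Conventions: 13 unique 3D directions at Chebyshev
distance 1; GLCM matrices are symmetrised, normalised per direction and
averaged before features are computed; GLRLM matrices are summed over
directions (run percentage divides by voxels x directions); GLSZM zones
are 26-connected; GLDM uses alpha = 0 with dependence = 1 + equal-level
in-mask 26-neighbours; NGTDM neighbourhood averages use in-mask
26-neighbours, voxels without any contributing 0. Degenerate inputs fall
back to documented constants (coarseness 1e6; correlation 1; skewness and
kurtosis 0 at zero variance) — never NaN. VOIs under 8 voxels are
rejected.

**Discretisation.** Fixed bin width for CT-like images (25 native units)
and the dose map (1 Gy); fixed 64-bin count for MR-like images, whose
intensities are z-scored over the body region (voxels above the constant
background floor) beforehand.

**Preprocessing and filter bank.** Volumes and masks are resampled to an
isotropic grid (trilinear / nearest-neighbour). The default spacing is
2 mm — the synthetic cohort's native grid — so desk-scale runs skip
interpolation; it is a config field, not a constant. The filter bank
yields 12 response images: original; Laplacian-of-Gaussian at 1, 3 and
6 mm (implemented as Gaussian smoothing followed by the exact 7-point
discrete Laplacian, which annihilates constants exactly — the sampled LoG
kernel does not at sub-voxel sigma); and the 8 sub-bands of a single-level
stationary Coiflet-1 wavelet transform (low-pass retains the sqrt(2) per
axis gain; axes are symmetric-padded to even length).

**Radiomics sources.** Ten modality-VOI pairs (CT: GTVnp, GTVn, IpsiPG,
ContraPG; T1 and T2: GTVnp, IpsiPG, ContraPG), giving 10 x 12 x 93 =
11,160 columns.

**Morphology (14 x 4 VOIs = 56).** Elongation/flatness and the three axis
lengths come from the eigenvalues of the voxel-centre covariance (axis
length = 4 sqrt(eigenvalue)); surface area and mesh volume from a marching-
cubes mesh of a lightly smoothed (sigma 0.8 voxel) indicator — raw binary
meshes are staircase surfaces whose inflated area breaks sphericity of a
digitised ball; maximum 2D diameters are the largest in-plane surface-
voxel distances with the plane fixed along x (column), y (row) and z
(slice); maximum 3D diameter is the largest pairwise surface-voxel
distance (convex hull accelerated).

**Dosiomics (201 x 8 VOIs = 1,608).** 102 DVH scalars: Dmax, Dmin, Dmean
(exact, unbinned) and D_x% for x = 1..99 — the minimum dose received by
the hottest x% of the VOI, read off the descending-sorted dose vector at
index ceil(x% N) (upper-value interpolation: the value is a dose some
voxel actually receives). 6 gradient features: mean and SD per VOI of the
central-difference gradient component (Gy/mm) along each axis
(`numpy.gradient` boundary handling). 93 texture features: the shared
intensity engine on the dose map, original image only. V_xGy
(volume-at-dose) features are deliberately excluded from the catalogue of
record.

**Contouromics (33 x 4 pairs = 132).** For an ordered pair (A, B): the
OVH is the distribution over A's voxels of the signed distance to B's
surface (negative inside B); its 21 scalars are the distances at volume
fractions 0, 5, ..., 100% (quantiles that actual voxels attain). The POV
at angle theta is the fraction of A inside the one-sided shadow of B
extruded along the axial direction (cos theta, sin theta, 0), sampled at
12 angles in 30-degree steps; a voxel is in the shadow iff a B voxel lies
behind it in the same slice within half a voxel laterally. Pairs:
PTVn_low_dose–SC, GTVnp–IpsiPG, GTVnp–ContraPG, GTVnp–SC.

## Feature selection

24 combinations of one supervised ranker (Fisher score, ReliefF,
chi-square after min-max scaling, k-NN mutual information) and one
unsupervised scorer (variance, Laplacian score, SPEC, MCFS, NDFS, UDFS).
The supervised ranker keeps the top `k_sup` (default 100) features on
training rows only; the unsupervised scorer re-ranks the standardised
survivors and keeps `k_final` (default 30). The spectral scorers run on a
5-NN heat-kernel sample graph; MCFS uses LARS regression on 2 spectral
embedding axes; NDFS/UDFS are 20-iteration reweighted implementations of
the standard objectives. These are compact research-grade implementations
whose fixed internal settings are the catalogue of record; they are
deterministic by construction.

Selection stability across resampled training sets is the mean pairwise
Jaccard index (1 iff all selections identical). The AUC/stability
trade-off over the 24 combinations is resolved on a decision graph:
min-max normalise both axes, pick the largest Euclidean norm; ties go to
higher raw AUC, then lexicographic name. The full 24-way search is
exposed (`evaluate_combinations`, CLI `select`) but `run_pipeline`
defaults to fisher+variance: the search's cost on the 11k-column
radiomics table is large while its outcome on synthetic cohorts is
dominated by the planted signal.

## Models and evaluation

**Splits.** 20 stratified 70/30 partitions (stratification is necessary
at 26% prevalence, where unstratified 10-folds would often lose a class)
plus stratified inner 10-fold assignments, all determined by one seed.

**Ridge.** L2-penalised least squares on +/-1 labels over standardised
features (training-set mean/SD applied to hold-out); the penalty is chosen
from a 13-point logarithmic grid (1e-3..1e3) by mean inner-fold validation
AUC, computed efficiently from one SVD per fold. Inner folds whose
training or validation part is single-class are skipped (they carry no
ranking information).

**MKL.** Per omics block: Gaussian kernels with gamma in
{1e-3, 1e-2, 0.1, 1, 10} on standardised features and polynomial kernels
(x.y / n_features)^d for d = 1, 2, 3 (no bias, so degree 1 is linear and
the single-block linear case is dual to Ridge — an equivalence the tests
exploit). Kernel weights are the positive parts of each kernel's centred
alignment with the label kernel, normalised to sum 1 (uniform fallback if
all vanish); the combined Gram matrix (PSD-checked to 1e-8 on its smallest
eigenvalue) feeds kernel ridge with an inner-CV-tuned penalty. Alignment
weighting was chosen over margin-based MKL for determinism and
testability; it is a config-level alternative point.

**Backward elimination.** Feature frequency = number of the 20 iterations
selecting it. The frequency ranking (ties: smaller mean |standardised
ridge coefficient| over the iterations selecting the feature, then
lexicographic) fixes a global removal order, but at every size each
iteration's model is retrained on the surviving members of *its own*
training-derived selection. This detail is load-bearing: scoring one
frequency-pooled global set on the per-iteration hold-outs leaks —
every row sits in most training sets, so "frequently selected" features
are whole-cohort correlated, and with 11k candidate noise features that
alone yields hold-out AUCs near 0.88 on label-independent data. With
per-iteration sets only the removal *order* and the chosen *size* pool
information across splits. The size whose mean hold-out AUC is maximal
wins (ties favour the smaller set); the reported final feature list is
the global top-size by the same ranking.

A residual optimism remains and is measured rather than hidden: under
the null, a feature's selection frequency is still monotone in its
whole-cohort label correlation (via recurrence through the per-iteration
supervised gate), so deep truncation keeps mildly cohort-correlated
features. The null-calibration test quantifies this: on zero-effect
cohorts the small-catalogue models (M, D, C) sit near chance, while the
radiomics-containing models settle around 0.62 — a property of
frequency-ranked elimination over a ~11k-feature pool (a pure
iid-noise simulation of the same procedure gives ~0.66), and a caveat
that applies equally to reported hold-out AUCs of this protocol on real
data.

**Statistics.** AUC is the Mann–Whitney probability with ties counted
one half. Headline summaries are mean, sample SD (n-1) and the
normal-approximation 95% CI mean +/- 1.96 SD / sqrt(20), reported to 3
decimals — the CI form reproduces reference values computed from printed
(mean, SD) pairs to 3 decimals, which the t-quantile version does not.
Model pairs on identical split plans are compared with two-sided paired
t-tests (identical vectors report p = 1 with a warning; a constant
non-zero difference reports p = 0). Clinical covariates use chi-square
tests without continuity correction (categorical; expected counts < 1
flagged) and two-sided two-sample t-tests (continuous; zero pooled
variance flagged). Pairwise p-values are reported raw, without
multiple-testing correction.

## Synthetic cohort generator

The generator is first-class, tested code, not a fixture. Defaults: 135
patients at 35/135 (~26%) ART prevalence, a 64 x 64 x 48 grid at 2 mm
isotropic spacing. Anatomy is topological rather than realistic:
ellipsoidal GTVnp near the posterior midline, a lateral-inferior nodal
GTVn, lateral parotids, tubular brainstem with the spinal cord as its
inferior continuation, and nodal planning target volumes as true 3 mm /
8 mm physical dilations of GTVn (so the strict nesting
GTVn ⊂ PTVn_high ⊂ PTVn_low holds by construction). Dose is a sum of
anisotropic Gaussian blobs calibrated so the mean dose is ~70 Gy in
PTVn_high_dose and ~60 Gy in PTVn_low_dose, plus parotid-directed
components; it is non-negative everywhere.

**Signal planting.** Four independent standardised latents per patient,
N(d, 1) for ART-positive and N(0, 1) otherwise, each mapped to exactly
one feature family:

| channel | latent target | read by | default d | Bayes AUC |
|---|---|---|---|---|
| texture | within-VOI correlated-noise variance (shared across CT/T1/T2 and the four tumour/parotid VOIs) | first-order/texture radiomics | 2.0 | 0.92 |
| dose | ipsilateral-parotid mean dose (35 + 8 d_p Gy) | DVH dosiomics | 1.2 | 0.80 |
| morph | GTVnp log-volume (SD 0.04) | morphology | 0.5 | 0.64 |
| contour | GTVnp-to-spinal-cord distance (2 mm per latent unit) | contouromics | 0.15 | 0.54 |

The Bayes AUC of a planted statistic is Phi(d / sqrt(2)); the defaults
bracket the qualitative single-family ordering R > D > M > C the pipeline
must recover. Three design points keep the channels separable, found by
auditing realised effect sizes during generator design:

* the texture latent drives the noise **variance**, estimated from ~600
  correlated voxels, so the realised effect attenuates mildly (~0.9 x);
  sharing one latent across modalities and VOIs lets multi-feature models
  recover nearly the full planted effect;
* the ipsilateral dose component is rendered **last**, so the planted
  parotid mean dose is exact rather than perturbed by PTV spillover;
* the GTVnp volume SD is deliberately tiny in physical terms (~0.2 mm of
  radius) while organ **positions** carry independent mm-scale jitter:
  morphology reads the volume nearly noiselessly, but inter-organ distance
  features see it only at voxelisation-noise level. Without this the
  volume latent leaks through the OVH distance spread and the contour
  model absorbs the morphology signal.

`signal_audit` recomputes, for any cohort, the realised Cohen's d of each
planted statistic and its implied Bayes AUC; it is the instrument the
channel-separation claims are tested with.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: anatomical realism beyond topology and
adjacency (no Hounsfield calibration, no planning-system dose engine, no
inter-organ correlation structure), realistic between-patient volume
variation (real GTV volumes span an order of magnitude; here volume
variation is compressed to keep the channels auditable), multi-channel
confounding (real radiomics correlates with volume and dose), and any
biological link between texture and treatment response. The pipeline's
recovery of the planted ordering validates the machinery, not the
clinical claim.

## Problem sizes and numerical choices

Cohort-scale runs use n = 135 with the full 20-split protocol; the
acceptance script builds the four single-family models at that scale, and
the test suite additionally runs a zero-effect cohort (null calibration,
every model's mean hold-out AUC within [0.38, 0.62]) and three master
seeds of the default-effect cohort (ordering recovery with R >= 0.85 and
C <= 0.65 required in at least 2 of 3 seeds, matching the 9/10 seed-level
rate at the sample size run). The end-to-end nine-model smoke run uses
n = 60 with reduced selection sizes. Oracle suites use randomised masks of
up to a few hundred voxels where brute-force all-pairs computation is
exact and fast.

Floating-point contracts: feature-table CSV round-trips are lossless to
1e-10; distance oracles agree to 1e-9 mm; PSD tolerance for combined
kernels is 1e-8 on the smallest eigenvalue. Degenerate-input behaviour
(constant images, single-voxel masks, empty VOIs, single-class folds) is
an explicit error or a documented fallback throughout.

## Known limitations

* The unsupervised spectral selectors are compact implementations; they
  match the standard objectives but not any particular reference library's
  iteration counts or stopping rules.
* POV is defined for axial (in-plane) projection directions only.
* The backward-elimination size choice maximises hold-out AUC, so reported
  hold-out means carry the protocol's optimism; the null-calibration bound
  quantifies it at chance level.
* DICOM/DICOM-RT inputs are out of scope; NIfTI + CSV are the on-disk
  formats, and volumes are assumed co-registered.
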