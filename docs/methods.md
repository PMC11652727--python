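# Methods

This note documents the models and procedures `mammoread` implements,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic experiments do and do not
establish. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. From annotations to suspicious areas

**Inputs.** Per-reader annotations (reader id, case, view ∈ {CC, MLO},
side ∈ {L, R}, 0-based pixel coordinates, 1–5 suspicion rating), lesion
truth tables (centre, radius in mm, subtype) and pixel spacing in
mm/pixel. Each (case, view, side) combination is an independent image.

**Pooling.** Ratings < 3 are negative; ≥ 3 positive. The cutoff is a
`PipelineThresholds` field.

**Lesion hit test.** A positive mark belongs to a lesion when its
distance to the lesion centre is ≤ the hit radius (default 12.5 mm,
converted to pixels via the spacing; the boundary is inclusive). Ties
between lesions break to the nearest, then table order (logged). Marks
matched to a lesion join that lesion's *cancer area*; cancer areas are
seeded from the truth table even when nobody marked them, because an
all-reader miss must still contribute a row to the false-negative
analysis. All remaining positive marks form *normal areas*.

**Clustering rule.** Normal-area marks are grouped so that no two marks
in a group are farther apart than `cluster_max_distance` (default
250 px, applied in original-image pixel coordinates). Complete-linkage
agglomerative clustering cut at that threshold realizes the rule
exactly, because complete-linkage merge heights equal cluster diameters.
The partition is invariant to input order; the test suite checks it
against a naive O(n³) agglomerator on random point sets.

**Bounding boxes.** Inclusive axis-aligned boxes extend `bbox_margin`
(default 10 px) beyond the extreme marks and are clipped to the image.
Membership of a mark in an area, for response building, is the
point-in-box test.

**Response matrix.** For a normal area, a reader scores 1 (false
positive) when they placed ≥ 1 positive mark inside the box. For a
cancer area, a reader scores 1 (false negative) when they placed *no*
positive mark inside the box — a negative mark or silence both count as
a miss. Otherwise 0.

**Difficulty labels.** Separately per area kind: an area whose false-
response count exceeds the median over areas of that kind is
*difficult*; count ≤ median is *easy*. If all counts are equal the
labelling degenerates to all-easy and a warning is emitted. The median
rule is a config knob (`difficulty_rule`), since operational deployments
may want a different threshold.

## 2. Reader outlier exclusion

Readers are clustered on the rows of the response matrix with Euclidean
distance and Ward's minimum-variance linkage (scipy), one dendrogram
per error branch: false positives on normal areas, false negatives on
cancer areas. The *outer branch* — readers who join the remainder of
the tree at disproportionate height — is excluded from false-positive
model construction, together with normal areas marked only by excluded
readers. The false-negative branch keeps every reader and every cancer
area.

**Peel criterion.** "Outer branch" needs a numeric definition. The rule
used: starting at the root, peel the smaller child branch while

    (root height − remaining-subtree height) > gap_factor × remaining-subtree height

then recurse into the remainder; stop when the relative gap closes or
when `max_outliers` (default 25 % of the roster) would be exceeded.
The criterion is *relative* because Ward merge heights grow cumulatively
with cohort size: an absolute or median-referenced gap threshold either
fires never or always depending on n. The default `gap_factor = 0.25`
comes from characterising the two regimes on simulated cohorts: with
planted ×4-rate over-callers the root-to-remainder height ratio was
≥ 1.40 across seeds, while outlier-free cohorts stayed ≤ 1.15, so 0.25
sits between the regimes with margin on both sides. An empty outlier
set is an expected outcome (typical for the false-negative branch). The
rule is a declared, configurable substitute for what was originally a
human consensus judgement, and a config override can force or forbid
specific exclusions.

## 3. Image preparation

Order of operations: resample → normalize → crop → quantize (the order
is configurable; features are computed on images that went through the
same path).

* **Resampling** — bicubic spline interpolation onto a target spacing
  (default 0.1 mm/pixel); output size = round(size × original/target).
  Upsampling beyond ×20 warns about interpolation artefacts.
* **Normalization** — zero mean, unit variance; statistics over the
  whole image by default, with a mask-restricted option (which of the
  two the original analysis used is unknown; per-image whole-frame is
  the default because it needs no segmentation). Normalization is
  idempotent and invariant to affine intensity changes.
* **Quantization** — clip to mean ± 3 SD, then equal-width binning into
  L = 64 levels over the clipped data range. All matrix-family features
  depend on this choice; it is stated here prominently because the
  source pipeline never documents its quantization.

## 4. The 201-feature bank

Family cardinalities (asserted at import): first-order 28; GLCM 88;
GLRLM 6; GLSM 6; GLDS 15; NGTDM 15; SFM 8; fractal 1; Laws 18; Gabor 6;
MR 8; Fourier 2 — totals 28 + 139 + 34 = 201. The family-internal
name lists below are this package's normative reference (the original
study's full feature list was never published; these reproduce its
printed family counts and every feature it names).

* **First-order (28)** — mean, SD, variance, skewness, kurtosis, min,
  max, range, median, p05/p10/p25/p75/p90/p95, IQR, interdecile range,
  energy, RMS, entropy (64-bin, bits), uniformity, mean absolute
  deviation, median absolute deviation, coefficient of variation,
  histogram mode, smoothness 1−1/(1+σ²), sum, 10 % trimmed mean.
  Undefined moments on constant input return 0 with a flag.
* **GLCM (88)** — symmetric co-occurrence matrices at offsets
  {1, 3, 5, 9}, accumulated over the four principal directions
  (diagonals step the offset along both axes — chessboard convention)
  and normalized. 22 features per offset: the Haralick set (energy,
  contrast, correlation, variance, inverse difference moment, sum
  average/variance/entropy, entropy, difference variance/entropy,
  the two information measures of correlation) plus autocorrelation,
  cluster shade/prominence/tendency, dissimilarity, maximum
  probability, inverse difference (plain and normalized) and inverse
  variance. Offsets exceeding the ROI produce flagged zeros.
* **GLRLM (6)** — run-length matrices in four directions, averaged:
  short/long run emphasis, grey-level nonuniformity, run-length
  nonuniformity, run percentage, low-grey-run emphasis.
* **GLSM (6)** — statistics of the central-difference gradient
  magnitude: mean, variance, skewness, kurtosis, energy, entropy.
* **GLDS (15)** — absolute deviation of each pixel from its local
  w × w mean (w ∈ {3, 5, 7}); per window: mean, contrast (mean squared
  deviation), and 32-bin histogram energy, entropy and inverse
  difference moment.
* **NGTDM (15)** — Amadasun–King coarseness, contrast, busyness,
  complexity and strength at neighbourhood radii {1, 2, 3}, computed on
  the valid interior; coarseness is capped at 10⁶ on flat input.
* **SFM (8)** — over displacement windows of spacing 4 and 8:
  coarseness (reciprocal mean dissimilarity), contrast (RMS unit-lag
  squared difference), periodicity (relative depth of the dissimilarity
  minimum) and roughness (3 − the log-log variogram slope of
  dissimilarity against Chebyshev lag).
* **Fractal (1)** — differential box-counting dimension, least-squares
  fit over block sizes {2, 4, 8, 16} (fewer on small ROIs, flagged).
* **Laws (18)** — 5×5 kernels from L5/E5/S5/R5 outer products; the nine
  symmetry-averaged maps (LE, LS, LR, ES, ER, SR, EE, SS, RR) rectified
  and pooled with a 15×15 mean filter; mean and SD per energy map.
* **Gabor (6)** — even-symmetric (cosine) kernels at carrier wavelength
  4 px/cycle and orientations 0°–150° in 30° steps; envelope SD from a
  one-octave bandwidth (σ ≈ 0.56 λ), unit aspect ratio, DC-corrected so
  flat regions respond exactly zero. Feature: mean |response| over the
  ROI.
* **MR8 (8)** — the 38-kernel root filter set: Gaussian (σ = 10 px,
  unit DC gain), Laplacian-of-Gaussian (σ = 10 px), and oriented edge
  (first-derivative) and bar (second-derivative) anisotropic Gaussians
  at scales (σx, σy) ∈ {(1,3), (2,6), (4,12)} × 6 orientations, all
  zero-mean (except the Gaussian) and L1-normalized. Per scale the six
  oriented responses collapse to one: edge maps keep the maximum
  *magnitude* (odd filters carry an arbitrary sign, orientation being
  defined mod 180°), bar maps keep the signed value of the
  maximum-magnitude orientation (the statistic must be sign-preserving
  for even filters). Feature: mean of each of the 8 maps.
* **Fourier (2)** — fractions of non-DC spectral power below and above
  the radial frequency Nyquist/4. They partition the non-DC power; a
  constant ROI returns (0, 0).

All convolutions use reflect (half-sample-symmetric) padding; a kernel
larger than the ROI pads and flags. Aggregation statistics (mean
|response| for Gabor, signed mean for MR8) are design choices — the
absolute feature magnitudes of the source study are not comparable and
not targets.

## 5. Difficulty model

Random forest with `max_features="sqrt"`, unlimited depth,
impurity-based splits. Evaluation protocol:

* **Outer loop** — leave-one-out; every area is scored exactly once out
  of fold.
* **Inner loop** — per outer iteration, repeated (×3) 3-fold stratified
  CV selects the forest size from `tree_grid` by mean inner-validation
  AUC (ties break to the smaller forest). The study-scale default grid
  is {100, 250, 500, 1000}.
* **Inside every inner training fold**, in order: SMOTE oversampling of
  the minority class to parity (synthetic rows are convex combinations
  of k = 5 minority neighbours; k shrinks with warnings for tiny
  minorities); a variance filter keeping features with raw
  (pre-standardization) training variance > 1; standardization to
  training mean/SD. Validation and test rows never contribute to any of
  these statistics — an invariant enforced by a NaN-poisoning test.
  The winning forest is refit on the full outer-training set (variance
  filter and standardization refit there; SMOTE stays inside the inner
  loop) to score the held-out sample.
* **Metrics** — AUC over out-of-fold scores with a 2000-replicate
  stratified-bootstrap percentile 95% CI; accuracy at threshold 0.5.
  Two models are compared with z = ΔAUC / √(SE₁² + SE₂²) using
  bootstrap SEs and a two-tailed normal p — a declared substitute, as
  the original comparison method was unstated.

The variance filter operates on *raw* features even though the
surrounding text of the source pipeline orders standardization first;
unit-variance features can never exceed a variance-1 threshold, so the
literal order is self-contradictory and the raw-variance reading is
implemented. Whether SMOTE rows should enter the standardization
statistics is equally unstated; both modes exist, synthetic rows
included by default (they are part of the training set once created).

A master seed fans out deterministically per outer fold and per
(error-branch, view) pipeline; identical configuration and seed
reproduce identical scores bit for bit.

## 6. Discriminative-feature statistics

Each outer fold records the refit forest's top-10 features by impurity
importance. The five most frequent names across folds (ties broken by
mean within-fold rank, then name) are compared between easy and
difficult groups on the *original* (unstandardized) feature values:
two-tailed Mann-Whitney U (exact for combined n ≤ 20 without ties,
normal approximation with tie correction otherwise), Bonferroni
correction with family size = the 5 tested features, FWER .05 with a
strict-< significance rule, and median (p25–p75, linear-interpolation
quantiles) summaries. Views are pooled by default; a per-view mode
exists.

## 7. The synthetic cohort generator

The generator emulates the study design end to end: 40 normal + 20
cancer cases by default (one cancer case carries two lesions, giving 21
lesions), CC and MLO views, a 16-reader cohort with 2 planted outlier
over-callers (×4 false-positive rate), lesion subtypes drawn with the
9/2/2/5/3 stellate / architectural distortion / calcification /
discrete mass / non-specific density case mix, and Gaussian jitter
(SD 8 px) on annotation placement with at most one annotation per
reader per planted area.

**Images.** A half-ellipse breast mask on a smooth Gaussian random
field; planted areas are 64×64 patches blended in under a Hann window;
lesions add a Gaussian blob of 12.5 mm nominal radius.

**Difficulty as orientation coherence.** Every planted area carries the
same expected power in the ~4 px/cycle texture band, realized as
envelope-modulated sinusoidal carriers over the six canonical
orientations with per-area amplitude jitter (±20 %). Easy areas spread
that power evenly across orientations; difficult areas concentrate 80 %
of it in the cohort's main orientation. This makes difficulty a
property of oriented *structure* (an architectural-distortion-like
signature) rather than raw high-frequency energy: direction-averaged
statistics overlap between classes by construction, while
orientation-selective responses — the Gabor bank and the oriented MR
filters — carry the class signal. With `difficulty_effect = 0` the two
classes are exchangeable and the model's AUC must hover near 0.5.

**Response model.** Per reader × area, one Bernoulli draw: normal-area
false-positive rate = base rate (0.10) × difficulty multiplier (3.0 for
difficult areas) × outlier multiplier (4.0 for planted outliers),
capped at 0.95; cancer-area miss rate = base (0.30) × difficulty
multiplier (2.5), outlier status not applied (the planted outliers are
over-callers, not under-callers). Positive marks rate uniformly from
{3, 4, 5}; non-responders leave a rating < 3 mark with probability
0.05. Realized per-reader rates converge to these configured rates
(checked at 1000 areas within three binomial SDs).

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real mammograms: real parenchymal anatomy and
its density categories, lesion-subtype-specific appearance, inter-view
correlation of the same finding, reader rating calibration, multiple
marks per reader per area, and scanner/vendor intensity characteristics.
The synthetic experiments validate the *machinery* (no leakage, correct
arithmetic, recoverability of planted structure at realistic rates),
not clinical performance.

## 8. Problem sizes used in tests and the acceptance script

The demonstration experiments run at reduced scale, chosen as the
smallest sizes at which the tested properties are statistically
unambiguous: difficulty-recovery cohorts of 24 areas (16 easy / 8
difficult, 64×64 patches), null cohorts of n = 60 with 30 synthetic
features, forest grids of {5, 15} to {25, 50} trees, and 20–50
Monte-Carlo seeds per property. The study-scale defaults
(`ModelConfig.tree_grid = (100, 250, 500, 1000)`, 2000 bootstrap
replicates, 250 px clustering) remain the library defaults for real
data. Synthetic-cohort runs shrink the clustering threshold to ~60 px
to match the generator's image scale.

## 9. Known limitations

* The outer-branch peel rule is a formalisation of what was originally
  a consensus judgement; its `gap_factor` generalises across the
  simulated regimes but has no claim to matching any particular human
  decision.
* GLDS here is the windowed-deviation variant (deviation from the local
  w × w mean); the displacement-vector formulation found elsewhere in
  the literature would give a different 15-feature set.
* The Gabor/MR aggregation statistics and the 64-level quantization are
  normative choices of this package; feature values are therefore not
  numerically comparable to other implementations, only rank/behaviour
  comparable.
* Leave-one-out AUCs on small cancer-area samples are high-variance;
  the bootstrap CI quantifies but does not remove this.
* The texture-band construction ties difficulty to a single coherent
  orientation per cohort; mixed-orientation difficulty would weaken the
  per-orientation Gabor statistics even when the model still separates
  the classes.
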