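# Methods

`mammodiff` reimplements, as a tested pipeline, an analysis for predicting
which normal (cancer-free) screening mammograms radiology trainees find
hardest to interpret: whole-breast ("global") radiomic features feed a
boosted-tree classifier of hardest- vs easiest-to-interpret cases, with
reader-panel difficulty scoring upstream and nonparametric screening
alongside. Because the clinical images and reader ratings such studies use
are restricted, the package ships a synthetic-data generator with a known
planted signal, so that every stage — and the recovery of the planted
signal by the full pipeline — is testable end to end.

## Difficulty scoring and case selection

Each reader rates each case on the 1–5 RANZCR scale (1 normal, 2 benign,
3–5 equivocal to malignant). For a truly normal case, a rating ≥ 3 is a
false-positive call, and the case's **difficulty score** is the fraction
of readers who made one:

    score(c) = #{r : rating(r, c) ≥ 3} / #{r : rating(r, c) observed}.

Missing ratings are excluded from numerator and denominator (a reader who
skipped a case did not read it). Cases at or above the 75th percentile of
scores are labelled *hardest*, at or below the 25th percentile *easiest*;
the middle half is excluded from modelling. Percentiles use linear
interpolation between order statistics (configurable); boundary ties are
included on the qualifying side, honouring "within and above / within and
below". If every score is identical the two rules would label each case
both ways; that degenerate input yields all-excluded with a warning. With
280 distinct scores the rule retains exactly 70 + 70 = 140 cases
(560 images at four views per case). BI-RADS density categories A/B map to
a *low-density* group and C/D to *high-density*; difficulty is compared
between the groups with a two-sample Kruskal–Wallis test (midranks,
tie-corrected chi-square approximation, via `scipy.stats.kruskal`).

## Image standardisation

Images are rescaled to 8 bits (linear min–max, round half up) so that the
fixed segmentation threshold is meaningful across bit depths. The breast
mask is `pixels > 100` with only the largest 8-connected component kept
(removing labels and other disconnected bright artefacts) and interior
holes filled; the strict inequality makes masks bit-reproducible, and a
per-file threshold override table replaces interactive adjustment.
MONOCHROME1 DICOMs are inverted on load so brighter always means denser
tissue. Right-laterality views are mirrored so every chest wall sits on
the left, and image + mask are cropped to the mask's tight bounding box.
All coordinates are row-major and 0-based with half-open ranges.

## Regions of interest

Two ROI schemes are delineated on the cropped mask:

* **Lattice (ROI)**: distinct-block tiling with 214 × 214-pixel squares
  anchored at the crop origin; partial edge tiles are discarded and a tile
  qualifies only if at least 50 % of its pixels are breast (the coverage
  cutoff is exposed in config; without it, boundary tiles would dilute
  texture with background zeros).
* **Largest inscribed square (SQ)**: the biggest axis-aligned all-breast
  square, found by binary search over the side length on an integral
  image (a k-square exists iff some k × k window sums to k²; existence is
  monotone in k). Ties resolve to the topmost, then leftmost corner. The
  classic dynamic program gives the identical answer and serves as the
  test oracle.

## The 34 global radiomic features

Seventeen quantities are computed per region, each under both ROI schemes
(SQ value once on the square; lattice value = SD of the per-block values,
sample SD by default), giving the 34-feature roster: 15 GLCM quantities ×
2 + coarseness (NGTDM) × 2 + range (first-order) × 2 = 30 + 2 + 2.
Region intensities are min–max quantised to 64 gray levels (bin width
(max − min + 1)/levels, so a constant region maps to level 1); the GLCM
accumulates co-occurrences at distance 1 over the four standard directions
(0°, 45°, 90°, 135°), symmetrised and normalised to sum 1. The GLCM
quantities are Haralick's 13 computable classics (energy, contrast,
correlation, variance, inverse difference moment, sum average/variance/
entropy, entropy, difference variance/entropy, and both information
measures of correlation) plus the third and fourth central co-moments

    cluster shade      = Σᵢⱼ (i + j − μx − μy)³ p(i, j)
    cluster prominence = Σᵢⱼ (i + j − μx − μy)⁴ p(i, j).

Entropies are base-2 with 0·log 0 = 0; a zero-variance GLCM has
correlation defined as 0 and the information measures fall back to 0 when
their denominators vanish. NGTDM coarseness is (ε + Σᵢ pᵢ sᵢ)⁻¹ with
ε = 10⁻⁶, where sᵢ accumulates |level − 8-neighbour mean| over interior
pixels and pᵢ is the level's share of interior pixels. Range is max − min
of raw (unquantised) intensities, so it is shift- but not scale-invariant;
every quantised feature is invariant to global intensity shifts.

Per-case features are the coordinate-wise mean of the four view vectors
(LCC, RCC, LMLO, RMLO). Feature columns are z-scored across cases (mean 0,
sample SD 1; zero-variance columns become 0 with a warning), and the
fitted transform is kept so held-out cases can be projected.

Two reconstruction notes. First, the roster above follows from the stated
composition (30 GLCM + 2 NGTDM + 2 first-order) and the SQ_*/ROI_Std_*_all
naming of the two exemplar features; quantisation depth, offset set and
coverage cutoff are this package's choices, exposed in config. Second, a
frequently repeated claim — that any transpose-symmetric GLCM has zero
cluster shade — is false (mass on the diagonal can skew i + j); the odd
co-moment vanishes when the GLCM is also centrally symmetric,
p(i, j) = p(L+1−i, L+1−j), and that is the invariant the tests assert.

## Classifier, validation, inference

The classifier is LogitBoost: a stagewise additive logistic model where
each round computes Newton working responses z = (y − p)/(p(1 − p))
(clamped to ±4) and weights w = p(1 − p) from the current probabilities
p = 1/(1 + e⁻²ᶠ), fits a depth-limited regression tree to (X, z, w), and
updates F ← F + ½·η·tree(X). Defaults: 100 rounds, shrinkage η = 0.1,
**depth-1 trees (stumps) with 70 % per-round case subsampling**
(stochastic boosting). The depth/subsampling defaults matter for the
importance analysis: with deterministic depth-2 trees, split-gain
importance piles almost entirely onto whichever of two comparably strong
features is marginally stronger in that sample (observed ratios above
2:1), which makes elbow-based selection of a two-feature set unstable;
stumps plus subsampling decorrelate the round-by-round split choices and
spread importance in proportion to feature strength. All four
hyperparameters are exposed in `BoostConfig`.

Feature importance credits each split's weighted squared-error risk
reduction (parent impurity minus children, weighted by node mass) to the
split feature, summed over all trees and normalised to sum 1. The scree
selection sorts importances descending and places the elbow at the
largest consecutive drop (first occurrence on ties); features strictly
above the elbow are selected. Validation is leave-one-out
cross-validation: one fit per case with that case held out, and the
z-score transform refitted inside each fold from the training cases only
(a config flag restores a single global normalisation). Discrimination is
the Mann–Whitney AUC (ties count ½) with a DeLong variance-based 95 %
interval, truncated to [0, 1] and collapsed to the point estimate with a
warning when the variance degenerates (e.g. perfect separation).
Per-feature screening is the two-group Kruskal–Wallis test at α = 0.05
with no multiplicity adjustment; a Bonferroni column is reported alongside
for transparency.

## Synthetic data: what is emulated, and how the signal is planted

The generator mirrors the study shape — 280 normal cases, four views per
case, 137 readers — and every output is a pure function of (config, seed).

**Masks** are half-ellipses against the chest-wall edge (vertical
semi-axis 0.42·H, horizontal 0.88·W) with a smooth random boundary
perturbation: the simplest connected, hole-free shape that makes the
inscribed-square search non-trivial. Right views are rendered in left
orientation and mirrored, so the preprocessing flip restores the rendered
pixel grid exactly.

**Ratings.** Reader r misclassifies case c with probability
logistic(logit(d_c) + b_r), b_r ~ N(0, 0.4); d = 0 and d = 1 force the
respective side. Within {1, 2} and {3, 4, 5} the rating is uniform, since
the analysis only thresholds at ≥ 3. Latent difficulties are drawn per
class from Beta shapes mapped onto disjoint supports — easiest
0.35·Beta(2, 5) ∈ (0, .35), middle 0.35 + 0.10·Beta(2, 2), hardest
0.45 + 0.5·Beta(5, 2) ∈ (.45, .95) — so a hardest case's latent always
exceeds an easiest case's (the distribution of real difficulty scores is
not public; this is a documented free choice).

**Texture.** The parenchyma is a Gaussian random field (base intensity
172, boundary-clipped at ±3.2 SD so the foreground always clears the
segmentation threshold even after jitter; high-density C/D cases are
brighter by 18 and finer-grained by ×0.7). The field's SD and correlation
length are drawn per case from U(13, 16) and U(7, 11) as class-independent
nuisance — emulating natural case-to-case texture variability, and, by
design, large enough that incidental responses of non-planted features to
the planted mechanisms stay inside natural variation. Exactly two texture
parameters depend on the difficulty class:

* **blob_count** (easiest 0, hardest 22): smooth Gaussian blob clusters
  (σ = 10 px) pulled alternately towards base ± 65, symmetric about the
  field mean so the third co-moment cancels while the fourth — cluster
  prominence on the inscribed square — accumulates from both tails. Blobs
  are dealt round-robin across lattice cells so every block carries the
  same expected blob mass (otherwise the across-block SDs of other
  features would inherit a class signal).
* **range_jitter_sd** (easiest 0.030, hardest 0.044): each lattice cell
  outside the inscribed square is darkened by 1 − |N(0, sd)| (floored at
  0.88). Because this is a pure rescaling, a block's min–max-quantised
  gray levels — and hence all its GLCM/NGTDM features — are unchanged,
  while its intensity range scales; the across-block SD of range is the
  planted readout.

Tiny marker dots (2 × 2 px, values 0 and base + 65) pin every block's min
and max so block ranges respond to the jitter deterministically and the
square's quantisation bins are stable across images; they are placed
before the jitter so they scale with their cell. Middle-class cases
interpolate the two planted parameters by latent difficulty; hardest and
easiest cases use their class presets. The generator cell grid is anchored
at the mask's bounding box so it coincides with the lattice a downstream
crop produces — with the shipped texture parameters the threshold-100
segmentation reproduces the generated mask exactly, which the tests
assert.

What the generator does **not** emulate: pectoral muscle, anatomic
parenchymal patterns, lesions, scanner/vendor effects, reader learning or
case-order effects. Passing tests therefore demonstrate that the pipeline
measures what it claims and recovers a known signal of realistic effect
size under realistic nuisance variation — not that the specific features
would rank the same way on clinical data.

## Problem sizes and numerical choices

The planted-signal benchmark is 140 cases (70 hardest / 70 easiest,
560 images at 1600 × 640) read by 137 simulated readers; model labels for
that benchmark come from the generator's ground-truth classes (quartile
labelling of a balanced two-class set would retain only half the cases —
the rating → quartile path is exercised on the 280-case design, where the
tie-free latent scores split exactly 70/70/140). Null calibration permutes
labels 100 times: the Kruskal–Wallis false-positive rate is evaluated on
the full 140-case table and the LOOCV AUC on balanced 32-case subsamples
per replicate — large enough to keep the known pessimistic bias of
leave-one-out AUC under the null mild, small enough that one hundred full
LOOCV loops stay affordable. Oracle
suites use 50 random instances per operation; the Kruskal–Wallis
permutation comparison uses 10⁵ permutations at 100 + 100 samples, with
the comparison tolerance split into a 10⁻³ systematic budget plus three
Monte-Carlo SDs of the permutation estimate itself.

On the 140-case benchmark the pipeline reaches LOOCV AUC ≈ 0.95–0.99 and
the scree selection returns exactly {SQ_Cluster_prominence,
ROI_Std_Range_all} in most runs; because the elbow rule compares
consecutive importance gaps, datasets where one planted feature randomly
dominates can collapse the selection to one feature — the chosen model
defaults make this the exception rather than the rule, but it is a known
sensitivity of elbow-type selection, not a pipeline failure.

## Known limitations

* The scree elbow (maximum consecutive drop) is a deterministic stand-in
  for a visual judgement; it is sensitive near importance profiles where
  the top gap rivals the second gap.
* The DeLong interval is asymptotic; with perfect separation it collapses
  to a point rather than reporting finite uncertainty.
* Per-block features include background zeros in boundary blocks (by
  design, bounded by the 50 % coverage rule); constant-breast-on-black
  images therefore do not zero the lattice-SD features, although constant
  full-frame images do.
* The generator's planted mechanisms are engineered to be separable in
  exactly two features; real mammographic difficulty is unlikely to be so
  low-dimensional.
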