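# Methods

## The verification problem and the feature model

Given a pair of single-face images, the task is a binary decision: same
person (label 0) or identical twins (label 1). The method rests on local
keypoint matching. Each image yields a set of keypoints with descriptors;
an exhaustive (brute-force) matcher compares every descriptor of image A
against every descriptor of image B under the kind's metric — Euclidean for
float descriptors (SIFT, 128-d; SURF, 64-d by default, 128-d in extended
mode), Hamming for binary ones (ORB, 256 bits). Per A-keypoint the two
nearest B-neighbours are retained and a filter keeps the *good matches*.
The default filter is Lowe's ratio test: keep the best match iff
d1 < 0.7 · d2. The published description of the 70% rule is ambiguous; two
alternative readings — d1 < 0.7 · min(n_A, n_B) (`PAPER_LITERAL`) and
d1 ≤ c · d_min (`MIN_DIST_SCALE`) — are implemented for sensitivity
analysis but are not defaults, because the phrase "the distance between the
two nearest neighbours is divided by their ratio" describes the ratio test.

Keypoints of A that own a good match are **matched** (M of them), all others
**mismatched** (U), with M + U = K. Matching is one-directional A→B by
default (a mutual-best `cross_check` flag exists); candidates with a single
neighbour pass the ratio test by default (there is no contesting neighbour)
and can be configured to be dropped or to raise.

Keypoints are assigned to eight canonical regions of the 468-vertex face
mesh — left/right eye, left/right eyebrow, nose, lips, face curve, face
oval — defined by frozen vertex-index lists. Assignment is **multi-label**
(the oval contains every other region) and **boundary-inclusive** (a point
on a region contour belongs to the region; contour keypoints must not vanish
from all regions). Eye and eyebrow polygons are the convex hull of their
indexed points, whose printed order does not trace a simple ring; nose,
lips, face-curve and oval keep the listed order as a closed ring with
repeats dropped after first appearance.

Two 16-value feature schemas are computed per descriptor kind:

* `TABLE3` (default): per region r, m_r/M and u_r/U, named
  `{KIND}_{REGION}_{MATCH|MIS_MATCH}`. This is the layout under which the
  per-feature class statistics are reported, with left/right eyes and the
  oval indexed separately.
* `EQUATIONS`: the printed formula set — M/K, U/K, the seven-region
  concentrations Σm_r/M and Σu_r/U (the "seven regions" are the eight minus
  the oval, which spans the whole face and would make the concentration ≈ 1
  always), and twelve per-region mismatch ratios u_r/M and u_r/U over curve,
  mouth, eyes (L+R), eyebrows (L+R), nose, oval. The u_r/M family may exceed
  1 when u_r > M; values are kept as computed and the vector flagged, since
  clipping would hide exactly the signal of interest.

Zero-denominator ratios are defined as 0 and logged, keeping feature tables
rectangular for degenerate pairs. Per-kind vectors are fused by
concatenation in a fixed order (SIFT, SURF, ORB), giving 16 × |kinds|
columns; any non-empty subset of kinds is supported.

Counts are taken over image A's keypoints by default (`count_side` ∈
{A, B, MEAN}); the mismatch definition is symmetric in spirit but the
published description computes one side, and MEAN is provided for users who
want both.

## Classification and evaluation

Features are standardized to train-set mean/SD and fed to one of four
reference models behind a single fit/predict/score contract: an RBF-kernel
SVM, LightGBM, XGBoost, and a nearest-centroid classifier whose score is the
difference of Euclidean distances to the two class centroids. Library
defaults, fixed seed, no hyperparameter tuning — the method is reported
without tuning and the comparison should reflect that. Label 1 (twin pair)
is the positive class. The split is 80/20, stratified by default,
deterministic per seed, with |test| = round(0.2 · n).

Metrics come from the confusion matrix: accuracy (TP+TN)/total, precision
TP/(TP+FP), recall TP/(TP+FN), specificity TN/(TN+FP),
F1 = 2TP/(2TP+FP+FN). Zero-denominator metrics are reported as NaN with a
warning, never silently as 0. ROC/AUC is computed in-package by sorting
scores, grouping ties, and trapezoidal integration; tests cross-check it
against scikit-learn.

## Statistical feature validation

Per feature and class: mean, sample SD (n−1), and a 95% confidence interval
mean ± t₀.₉₇₅,ₙ₋₁ · sd/√n. Class differences are tested two-sided with
Welch's unequal-variance t-test (Welch–Satterthwaite degrees of freedom) and
the Mann-Whitney U test (midrank ties; exact p by enumeration when
n₀+n₁ ≤ 12 with no ties — the bound keeps enumeration trivially cheap —
otherwise the tie- and continuity-corrected normal approximation). Features
are ranked by Welch p. Raw p-values are reported, as in the source analysis;
a Benjamini–Hochberg flag is available but off by default. The scipy
implementations stand behind these functions; the test suite checks them
against the textbook formula and full enumeration independently.

## The synthetic data model

The generator emulates the *structure* of real twin-pair data — not its
imagery. Its defaults are the study conditions:

* **Landmark template.** A deterministic 468-point layout on a 512×512
  canvas in which all eight canonical regions are simple, positive-area
  polygons; the seven non-oval regions are pairwise interior-disjoint and
  all lie inside the oval. The published index lists share a few vertices
  across regions (the mouth corners and chin point between lips and face
  curve; two eyebrow indices inside the lips list), so perfect disjointness
  is impossible in the set-theoretic sense; the template places shared
  vertices as tangency points: lips and face curve share boundary chords,
  one stray eyebrow vertex is the tip of a short lip spike resting on the
  eyebrow strip's edge, and the other coincides with a mouth corner as a
  zero-length ring edge. The layout is synthetic geometry chosen for exact
  ground truth, not facial anatomy.
* **Pairs.** K = 300 keypoints per image (a few hundred is what local
  detectors typically return on a cropped face); a planted fraction
  M/K = 0.5 of A's keypoints has a descriptor counterpart in B (A's
  descriptor plus isotropic Gaussian noise for float kinds, i.i.d. bit
  flips for binary kinds, both governed by the single noise parameter
  σ = 0.05),
  all other keypoints get independent random descriptors. Under this model
  the ratio test provably recovers exactly the planted correspondences as
  σ → 0, and with the default σ the planted/clutter distance gap is ~20×,
  so recovery remains exact in practice.
* **Class structure.** The two classes differ *only* in per-region mismatch
  rates (fraction of U falling in region r), drawn per pair from a truncated
  normal (sd 0.02 between pairs) around class means taken from the reported
  per-feature class statistics: nose 0.0352 vs 0.0720, left eye 0.0352 vs
  0.0666, right eye 0.0366 vs 0.0678, face curve 0.0455 vs 0.0748, lips
  0.0362 vs 0.0564; eyebrows (absent from the reported top-10) get a modest
  0.0360 vs 0.0500. Matched-keypoint region rates are class-independent.
  Keeping the class difference purely in the mismatch rates isolates the
  feature definitions under test. Region counts are drawn by a single
  multinomial (binomial marginals, never exceeding the budget); remaining
  keypoints split between inside-oval background and outside-face background
  (50/50).
* **Determinism.** Identical spec + seed reproduce bitwise-identical
  bundles; cohort pair seeds derive from one seed sequence. Cohort backends
  regenerate pairs on demand from their seeds, so large cohorts never hold
  all descriptors in memory.

What passing tests on this generator do and do not show: they verify the
feature definitions, the matcher, the counting geometry, the classifier
harness and the statistics *exactly*, because every planted quantity is
recoverable; they do not certify accuracy on real twin imagery, where
detector noise, pose, illumination and landmark error enter. Real-image
support is wired through the same contracts (scikit-image SIFT/ORB backends,
landmark file replay), so swapping the synthetic backend for real inputs is
a data question, not a code change.

## Numerical and design choices

* Pixel coordinates, origin top-left, x rightward, y downward; normalized
  detector outputs are scaled by image size on ingest.
* KNN ties break on the smaller B index; good-match lists are sorted by
  distance; all-zero self-matches are kept under every rule.
* The printed face-oval index list duplicates the face-curve list (an
  apparent erratum); the default oval is the standard face-oval contour of
  the 468 topology, and `oval_as_printed=True` reproduces the printed
  duplicate.
* Multiple detected faces: highest confidence wins, with a warning
  (single-face crops are assumed).
* Degenerate region polygons (collinear or self-intersecting rings) raise
  rather than being silently repaired.
* The 0/0 → 0 rule for ratios, and NaN (never 0) for undefined metrics.
* Verification problem sizes: matcher-oracle checks use 100 random instances
  per metric at n ≤ 45; rate recovery uses K = 2000 over 20 seeds; the
  classification check uses 400 pairs per class at K = 300, the size at
  which per-feature effects of the reported magnitude yield a comfortably
  separable cohort.

## Known limitations

* SURF has no unencumbered implementation; on real images the SURF backend
  reports itself unavailable and the pipeline runs on the remaining kinds
  (synthetic SURF descriptors are fully supported).
* The real-image landmark path expects precomputed landmark files (or an
  optionally installed external face-mesh detector); the package does not
  reimplement the detector.
* The generator plants class structure only in mismatch-rate means; it does
  not emulate pose, expression or illumination effects, nor correlations
  between descriptor kinds beyond shared region counts.
* Reported headline accuracies on the licensed twin corpora are not
  reproducible without those datasets; the acceptance suite substitutes
  property-based checks on the synthetic conditions above.
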