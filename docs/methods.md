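# Methods

`slskit` implements a complete screening-analysis pipeline for single-leg
squat (SLS) movement quality: a cohort of participants performs single-leg
squats in front of a frontal camera, a 2D pose estimator yields per-frame
landmarks, and the pipeline grades each participant into one of three
ordinal classes (0 = good, 1 = moderate, 2 = poor) from frontal-plane
kinematics. Because the underlying study cohort's videos are not publicly
deposited, the package includes a first-class synthetic landmark generator
that emulates the cohort's published class-conditional kinematics; every
downstream stage is exercised against it.

## Kinematic model

Three angles summarize frontal-plane movement quality, all in degrees,
computed per frame in a y-up coordinate frame:

* **Trunk lateral tilt** `θ_T`: unsigned angle between the vertical axis and
  the segment joining the shoulder midpoint and hip midpoint; range [0, 90].
* **Pelvic lateral tilt** `θ_P`: unsigned angle between the inter-hip
  segment and the horizontal; range [0, 90].
* **Knee valgus** `θ_K`: 180° minus the interior angle of the hip–knee–ankle
  chain at the knee, signed by the side of the hip→ankle line the knee falls
  on. Medial deviation (valgus) is positive, lateral (varus) negative; the
  medial direction is resolved from the weight-bearing side assuming the
  subject faces the camera.

Per repetition, the **peak deviation** is extracted: the maximum of the
unsigned trunk and pelvic series, and for the knee the *signed value at the
frame of maximum absolute deviation*. The max-|·| convention (rather than a
signed maximum) is required for a varus-dominated repetition to produce a
negative knee peak, which the good class's negative mean implies. A signed
maximum starting from a neutral first frame could never be negative.

Frames in which any required landmark's visibility falls below 0.5
(configurable) are linearly interpolated from neighbors; gaps longer than 5
frames, or more than 50% low-visibility frames, fail the repetition. No
temporal smoothing is applied by default (an optional centered moving
average is exposed); peak-based features are sensitive to smoothing, so it
is off unless the caller opts in.

## Synthetic cohort generator

The generator's defaults emulate the study cohort: 105 participants
(28/41/36 per class), 3 repetitions each, 30 Hz, with per-class peak-angle
means/SDs (degrees):

| class | trunk | pelvis | knee |
|---|---|---|---|
| good (0) | 6.00 (2.47) | 6.31 (1.93) | −2.63 (2.55) |
| moderate (1) | 7.24 (3.23) | 8.50 (2.76) | 3.67 (3.75) |
| poor (2) | 10.24 (6.34) | 10.38 (4.94) | 13.24 (9.71) |

Per repetition, a (trunk, pelvis, knee) peak target is drawn from the
class-conditional trivariate normal with a common pairwise correlation of
0.3 (configurable; no correlation structure is published, so this moderate
positive coupling is a modeling choice reflecting that compensatory
deviations tend to co-occur). Negative trunk/pelvis draws — which are
magnitudes — are clamped to 0. Clamping, rather than resampling, is used
because rejection of joint draws measurably inflates the class means (up to
+0.8° for the poor-class trunk) and leaks into the knee marginal through
the correlation; clamping touches ≤5% of draws and bounds the worst mean
offset at about +0.14°, which the unit tests verify against the analytic
clamped-normal mean.

A forward kinematic model then realizes each target as landmark
trajectories: the weight-bearing ankle sits at the origin; the hip–knee–
ankle triangle realizes the knee angle by the law of cosines with the knee
offset medially or laterally; the contralateral hip drops by the pelvic
tilt; and the shoulder midpoint leans over the stance limb by the trunk
tilt. Every angle is scaled by a half-cosine depth profile `s(t) = (1 −
cos 2πt/(T−1))/2`, rising from 0 at stance to 1 at mid-sequence. The
published analysis uses only peak deviations, which are invariant to the
time-course shape, so the profile choice is immaterial downstream; with the
default odd frame count (61 ≈ a 2 s squat at 30 Hz) the mid frame attains
the peak exactly, making the noise-free generator→extractor round trip
exact to ~1e-14°.

Segment lengths default to a ~3 m frontal 1080p view (torso 450 px, pelvis
width 160 px, thigh 400 px, shank 380 px, shoulder width 300 px); all angle
computations are scale-invariant, so these only set the pixel scale that
landmark noise acts on.

`landmark_noise_sd` defaults to **0**: the per-class SDs above were measured
*through* a pose tracker, so they already contain tracking noise, and adding
jitter on top would double-count that variance. It would also bias peak
extraction upward, since the maximum of a noisy series exceeds the maximum
of its mean — an effect the Monte-Carlo tests quantify (at 2 px jitter the
mean peak error stays under 1°). Robustness studies can turn noise on
explicitly; the acceptance script uses 0.2 px ("small noise") for its
round-trip targets.

Repetition-level classes are drawn so each participant's worst repetition
equals the assigned class (others uniform over classes ≤ it), matching the
poorest-repetition labeling rule; aggregation takes the label of the worst
repetition and the features of the earliest repetition achieving it.

### What the generator does and does not emulate

It reproduces the class-conditional peak-angle distributions, the cohort
composition, the labeling rule, and the geometry linking landmarks to
angles. It does not emulate pose-estimator failure modes (occlusion,
identity swaps, depth-induced foreshortening), sagittal-plane motion,
rater disagreement (repetition labels are exact), or temporal dynamics
beyond the smooth depth profile. Passing tests therefore demonstrate the
*pipeline's* correctness and the statistical behavior of the method under
the published effect sizes — not the field accuracy of any pose estimator.

## Features

Seventeen features per participant: the 3 primary peaks; 7 ratios (knee/
trunk, knee²/trunk, knee/pelvis, knee²/pelvis, knee/(trunk+pelvis),
knee²/(trunk+pelvis), trunk/pelvis); 3 interactions (trunk×knee,
trunk×pelvis, pelvis×knee); 3 squares (trunk², pelvis², knee²); and the
composite **summated angle** = trunk + pelvis + knee. The signed knee peak
enters ratios and interactions directly (varus contributes negatively);
squared terms discard the sign by construction. Ratio denominators with
magnitude below 1e-6° are clamped sign-preservingly to ±1e-6 (0 treated as
positive); trunk and pelvis peaks are nonnegative, so the guard only fires
on pathological inputs.

## Feature selection

Stage 1 filters by one-way ANOVA F across the three classes with
Benjamini–Hochberg step-up correction across the 17 features; features with
adjusted q < 0.05 pass (the threshold is applied to adjusted q-values). A
feature with zero within-class variance but distinct class means is
perfectly separating: F = +∞, p = 0, retained. Stage 2 is recursive feature
elimination with a 200-tree random forest, dropping the least important
feature (impurity importance) per iteration and recording stratified 5-fold
CV accuracy at every feature count; the retained subset is the count with
maximal mean accuracy, ties broken toward fewer features. The final set is
the intersection. Both stages run on the training split only, to avoid
selection leakage into the held-out evaluation; an empty intersection falls
back to the wrapper set with a warning. Feature columns are canonicalized
to registry order internally so results are invariant to input column
order.

## Classifiers and evaluation

Data are split 70/30 with stratification (105 → 73/32). Seven classifiers —
logistic regression (saga solver, L1/L2), SVM, k-NN, random forest,
gradient boosting, LightGBM, AdaBoost — are grid-searched under stratified
5-fold CV on macro-F1. The scale-sensitive three carry a z-score
standardizer inside their pipeline, so scaling statistics never use
held-out-fold rows. Default grids sweep the published search dimensions:
C ∈ {0.01, 0.1, 1, 10} and penalty ∈ {L1, L2}; kernel ∈ {linear, RBF} with
C ∈ {0.1, 1, 10}; k ∈ {3,5,7,9} with Euclidean/Manhattan metrics; tree
depth ∈ {2,3,5,∅} with 100/200/400 estimators; learning rate ∈
{0.05, 0.1, 0.5, 1.0} for boosting.

Held-out metrics: accuracy; macro-F1 (unweighted mean of per-class F1);
macro one-vs-rest AUC from class-membership scores (predicted probabilities
where available, decision-function scores otherwise — classes absent from
the test labels are excluded from the macro mean with a warning); macro
one-vs-rest sensitivity and specificity (single published values per model
do not define the averaging, so the macro average is this package's
documented interpretation); and the 3×3 confusion matrix in class order
0, 1, 2. Weighted Cohen kappa (linear weights by default; quadratic
available) quantifies rater agreement for ordinal labels.

## Prediction instability

For fractions 10/30/50/70/90% of the cohort, 100 stratified subsamples
(without replacement) are drawn per fraction; a classifier is fitted on
each and the SD of its accuracy across replicates is the instability at
that fraction. By default every replicate is evaluated on the full fixed
dataset: evaluating on the subsample's complement (available as
`eval_mode="complement"`) shrinks the evaluation set as the fraction grows,
which raises the binomial evaluation-noise floor and can mask the decline
the analysis is designed to reveal. With a fixed evaluation set the noise
floor is constant and the curve isolates training-set-size effects. The
metric is SD of accuracy; "variability of performance" admits alternatives
(IQR, SD of macro-F1) which the API can accommodate via its table output.

## Explanation

**Global.** Interventional Shapley values: the coalition value of a feature
subset is the mean model score with absent features replaced by background
rows (a seeded subsample of the training split, ≤50 rows). Up to 12
features, all 2^p coalitions are enumerated, so the efficiency axiom —
base value + Σ attributions = model score — holds to machine precision
(verified at 1e-6); beyond 12, a seeded Monte-Carlo permutation estimator
is used. Class-wise mean |attribution| is reported per class and summed
into a global ranking.

**Local.** A LIME-style surrogate: each feature of the instance is
discretized into quartile bins of the background; 5000 perturbations keep
or reset each feature to random background values; a ridge regression on
the keep indicators, weighted by exp(−d²/κ²) with κ = 0.75·√p over binary
distance d, yields signed contributions toward the predicted class, each
reported with the instance's bin interval. Constant background features are
skipped with a warning. Both explainers are deterministic for a fixed seed.

## Numerical and degenerate-input choices

* Angles: `atan2`-based formulations for axis angles (stable near 0°/90°);
  arccos with clipped cosine for the interior knee angle; collinear chains
  give exactly 0 valgus.
* Coincident landmarks raise `DegenerateGeometryError`; ≥50% low-visibility
  frames or >5-frame gaps raise `SequenceQualityError`.
* Knee-peak ties (equal |deviation| at several frames) take the earliest.
* Wrapper CV-accuracy ties take the smaller subset; kappa inputs must be
  nonempty; `n_boot = 1` yields instability 0 with a warning; fractions too
  small for 2-per-class stratification are skipped with a warning.
* Infeasible peak targets (|angle| > 90°) are rejected by the generator.

## Problem sizes used in the test suite

The suite replicates the analysis at the study's own scale (n = 105,
500-trial Monte-Carlo checks, 100 bootstrap replicates, 10 replicate
cohorts for seed-averaged properties, 10 000 random placements for the
geometry oracle). These sizes give the statistical properties comfortable
margins (3-SE bands, majority-vote replicate checks) while keeping the
whole suite at desk scale.

## Known limitations

* The synthetic world's class overlap is fully determined by the published
  means/SDs and the assumed 0.3 correlation; real pose-estimated data will
  have heavier tails and structured (non-isotropic) tracking error.
* Classification metrics on synthetic cohorts bracket but do not reproduce
  the published held-out numbers, which depend on an undeposited cohort and
  unpublished grid values and CV seeds.
* The knee-peak sign convention and the macro averaging of sensitivity/
  specificity are documented interpretations of ambiguous reporting, not
  assertions of the original authors' intent.
* Repetition segmentation is out of scope: inputs are single-repetition
  sequences.
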