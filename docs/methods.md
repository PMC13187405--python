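# Methods

This note documents the measurement definitions, statistical procedures and
design choices behind `mskmark`, and what the synthetic generators do and do
not emulate.

## Coordinate and unit conventions

Arrays are indexed `(slice, row, col)`, 0-based, with half-open bounding
boxes. Spacing `(sx, sy, sz)` is in mm: `sx` row spacing, `sy` column
spacing, `sz` slice thickness; voxel volume is `sx·sy·sz` mm³. The
cranio-caudal direction for sagittal spine slices is a configuration field
(`io.cranio_caudal_axis`, default `row`) rather than an inference from image
headers — axis handling is easy to get silently wrong, so it is explicit.
All outputs are in mm, cm³, ms, or z units.

## Thickness

Thickness of sheet-like structures (cartilage plates, menisci) is measured
per slice: the binary compartment mask is reduced to its 2D medial axis, and
at each skeleton pixel the Euclidean distance to the nearest background is
computed on a spacing-aware distance transform (no label resampling, so
anisotropic in-plane grids are handled exactly). The medial-axis distance is
the local half-width; `full_width` mode (the default, flagged in output
metadata) doubles it to report laminar thickness. All skeleton samples are
pooled across slices and averaged per compartment. Both modes are exposed
because "distance to the nearest boundary" admits either reading; downstream
consumers see which was used.

Numerical choices: no half-voxel boundary correction is applied. On slab
phantoms the uncorrected estimator is exact for even voxel counts across the
slab and off by one spacing for odd counts; a −s/2 correction inverts that
trade and additionally biases curved shapes (annuli) low. The uncorrected
estimator stays within one in-plane spacing of truth across widths
{2, 5, 10.5} mm and spacings {0.25, 0.5, 1} mm, which is the accuracy
contract the tests enforce. Compartments with fewer than 5 skeleton pixels
per volume (configurable) return NaN with a warning — the medial axis of a
few-pixel blob is noise, not a measurement. Empty compartments return NaN,
never raise.

## Disc heights

Connected components per slice are disc instances; the slice-level height of
an instance is its axis-aligned bounding-box extent along the declared
cranio-caudal axis times the spacing on that axis. An axis-aligned (not
rotated minimum-area) box is used deliberately: the quantity of interest is
the cranio-caudal extent, which the axis-aligned box gives directly once
orientation is declared. Instances are associated into levels by nearest
reference centroid, where the reference centroids come from the slices
showing the most instances; overlapping centroid ranges trigger a warning
and fall back to nearest-centroid assignment. The per-level height is the
maximum across slices.

## Volumes and relaxometry

Volume is voxel count × voxel volume, reported in cm³; it is additive over
disjoint labels and exact by construction. Relaxometry means clip masked
voxel values to 0–100 ms and average over the pooled voxels of the
compartment (pooled-voxel mean rather than mean-of-slice-means; the two
differ only under strongly varying per-slice support, and the pooled mean
weights every voxel equally).

## Reference z-scoring

`ReferenceStats` freezes per-feature mean and sample SD (ddof = 1) from a
designated reference subset — healthy knees for triage, baseline KL 0–1
knees for longitudinal modeling — once, globally. Per-fold re-standardization
is deliberately not supported: the reference is part of the measurement
definition, not of the model fit. Zero reference SD or a reference smaller
than 3 rows is an error naming the offending feature.

## Segmentation evaluation

Dice and Jaccard are computed per slice. Slices with an empty reference are
excluded from aggregation by default (scoring them 1 inflates averages on
sparse structures); a flag includes them as 1 when the prediction is also
empty, for sensitivity analyses. An empty prediction against a non-empty
reference scores 0. Slices aggregate to subjects by the mean, subjects to
structures by the median, and dataset tails report median / 5th percentile
(linear interpolation between order statistics) / minimum to expose
worst-case behavior. Paired model comparison: Friedman across ≥3 models
(undefined and reported as NaN for 2, where the pairwise test is the whole
comparison), two-sided Wilcoxon signed-rank per pair, BH step-up at 5%.
Identical paired samples yield Wilcoxon p = 1 rather than an error.

## Agreement analysis

The assumption gate is a pure function of two p-values: parametric iff
Shapiro-Wilk on the paired differences and Levene (mean-centered, matching
the classical test) across the two methods both have p ≥ 0.05. Constant
differences leave Shapiro-Wilk undefined and route non-parametric with a
warning.

Parametric ICC comes from the two-way mean-squares decomposition, single
measurement. Both the consistency form, (MSR−MSE)/(MSR+(k−1)MSE), and the
absolute-agreement form, which adds the rater variance term k(MSC−MSE)/n to
the denominator, are implemented because the usual naming conventions mix
the two; consistency is the default and the output records the definition
used. CIs are F-based (Satterthwaite df for the absolute form); both
estimators match `pingouin`'s ICC(C,1)/ICC(A,1) to machine precision in the
cross-check tests. The non-parametric ICC is the random-intercept variance
ratio σ²_subject/(σ²_subject+σ²_error) via one-way ANOVA method-of-moments
(unclipped, so a null ICC can be negative and its CI can cover 0), with a
percentile CI from subject-level bootstrap resamples (default 10,000).

Bland-Altman is mean ± 1.96·SD or median with 2.5/97.5 percentile limits,
per the gate. Regression puts the reference on x (a declared convention);
the parametric path is OLS with R², the non-parametric path a Gaussian
process (RBF + White kernel) fit on standardized inputs with a 95% pointwise
band, degrading to Spearman-only on failure. Spearman's ρ is always
reported, and its p-values are BH-adjusted across the analysis batch.

## Triage cascade

Features are the six z-scored biomarkers (cartilage thickness and bone
volume for femur, tibia, patella) plus sex, age, weight. Stage A and B each
stack elastic-net logistic regression (mixing 0.5, class-balanced), XGBoost
and histogram gradient boosting under 5-fold subject-grouped stratified CV;
the logistic meta-learner is itself cross-validated on the same folds so
every scan carries exactly one out-of-fold stacked probability, and no
subject straddles a fold (asserted). Boosted learners run single-threaded
with pinned seeds for determinism. Hyperparameters beyond those named are
config-pinned defaults (XGBoost: 200 trees, depth 3, learning rate 0.1).

Operating points: the threshold grid is the sorted unique out-of-fold
probabilities (exact, no binning) plus a point just above the maximum; the
smallest threshold achieving the specificity target is selected, which
resolves ties toward higher sensitivity, and the decision rule is inclusive
(p ≥ t forwards). The achieved specificity on the selection set is ≥ the
target by construction; an operating point reachable only with zero
sensitivity warns. Routing partitions scans into removed-at-A /
not-forwarded-at-B / forwarded, with Stage B defined only on the Stage-A
pass set. Stage C fits an equal-weight LR/XGBoost ensemble per localization
task on the routed subset without additional cross-validation — apparent
performance, optimistic by construction, and documented as such — with
10-equal-width-bin calibration curves (empty bins omitted, no
recalibration). Metrics carry percentile 95% CIs from subject-level
bootstrap (default 2000 draws); degenerate single-class resamples are
redrawn and counted. Workload is forwarded_fraction × 1000 × per-exam
minutes, with hours reported to one decimal.

## Landmark risk modeling

The landmark at 48 months defines t0; the risk set is knees event-free and
uncensored at t0 with complete thickness levels and annual changes (the
consecutive-visit difference divided by the elapsed years — "annual change"
is otherwise underdefined) through t0. The binary outcome is an event in
(t0, t0+horizon]. Knees censored inside the window without an event are
coded 0 and flagged, with an exclusion switch — the primary convention is
declared rather than inherited, since binary-outcome construction under
within-window censoring admits either. The incident-OA task restricts to
baseline KL < 2. Trajectory features are z-scored to the KL 0–1 reference;
age, sex and BMI are appended unscaled.

Models: 400-tree random forest (min_samples_leaf 10) and L2 logistic
regression, class-balanced, under 5-fold participant-grouped stratified CV
(paired knees co-assigned, asserted). Isotonic calibration is fit per fold
on the training split only, against internal 3-fold cross-validated
predictions — a model's predictions on its own training data are
over-confident, and isotonic fit on them collapses to hard 0/1 outputs —
then applied to the held-out fold, which keeps calibrated probabilities
monotone in raw probabilities within each fold. Evaluation: AUC with
percentile bootstrap CI (1000 knee-level draws), Brier score for raw and
calibrated probabilities, and calibration slope as the coefficient of a
logistic fit of outcome on the prediction's log-odds (NaN with a warning for
constant predictions). Decision curves follow the net-benefit definition
NB(pt) = TP/n − (FP/n)·pt/(1−pt) with treat-all/treat-none references,
percentile bootstrap bands (2000 draws), and an optional constant
per-intervention harm subtracted from the model curve — a declared,
clearly-labeled interpretation of test-harm penalties, not a standard form.
Cox comparators use month-0 features (time measured from the landmark,
small ridge penalty for stability); Harrell's C counts concordant over
comparable pairs with ties at 0.5 (validated against both brute-force pair
enumeration and `lifelines`), and the IPCW C uses Kaplan-Meier censoring
weights truncated at the horizon. Kaplan-Meier curves split at the median
calibrated risk.

## Synthetic generators

The phantoms rasterize implicit surfaces by center-of-voxel inclusion —
exact, and checkable against a brute-force oracle. Slab phantoms span the
full array along their length so the medial axis has no end branches,
matching the unbounded analytic slab; annuli and ellipsoids are closed
shapes with background margins.

The cross-sectional cohort draws six biomarkers at unit SD around per-class
means: each abnormality class (normal, cartilage-only, bone-only, both)
shifts a named subset of biomarkers by a stated amount in reference-SD
units (defaults: −1.5 SD cartilage thickness, +1.2 SD bone volume), so
class-conditional sample means recover the specification directly and
tissue/joint labels derive from which biomarkers are shifted — making the
any-abnormal hierarchy consistent by construction. Demographics (sex
Bernoulli 0.5, age 51 ± 17 yr, weight 78 ± 18 kg, matching a mixed adult
MSK imaging population) are sampled independently of labels so biomarker
signal can be isolated in recovery tests.

The longitudinal cohort gives each knee per-compartment linear thickness
trajectories (baseline 2.2 ± 0.25 mm, slope −0.06 ± 0.12 mm/yr — a
population where progressors lose cartilage at rates up to ~0.2 mm/yr while
stable knees do not change) over visits at 0/12/24/36/48 months, with
events drawn by inverse-transform sampling from a piecewise-constant hazard
updated per visit interval: λ(t) = λ0·exp(β·cumulative loss in mm), λ0 =
5×10⁻⁴/month, β = 1.5/mm, extrapolated linearly past the last visit, with
administrative censoring at 96 months. These values were fixed once by
forward simulation to give an OAI-like regime — roughly 93% of knees still
at risk at the landmark, ~20% events in the 48→96 window, and out-of-fold
RF discrimination near 0.75 — before any recovery test was written. Setting
β = 0 decouples events from trajectories exactly, which the null tests
exploit. With two knees per participant, pairs share demographics and
participant id (the grouping contract), though trajectories remain
independent.

What the generators do not emulate: image intensities, noise textures,
motion or metal artifacts, segmentation errors, real lesion geometry,
informative censoring, or correlation between demographics and disease.
Passing tests therefore demonstrate that the measurement and decision
machinery is correct and recovers known signal under clean conditions — not
that any particular clinical performance level transfers to real cohorts.

## Problem sizes

The test suite and the acceptance script run the cascade on 400–930-knee
cross-sectional cohorts and the landmark models on 400–1000-knee
longitudinal cohorts, with 10–3000-draw bootstraps depending on context —
sizes chosen so the full pipeline exercises every code path on a single CPU
in minutes while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* The 2D slice-wise medial axis underestimates thickness of strongly
  oblique sheets relative to a 3D normal-direction measurement; the source
  masks are slice-annotated, so a 3D skeleton would mix annotation and
  measurement error.
* Disc level association by centroid ordering assumes levels do not overlap
  along the cranio-caudal axis within a slice; pathological fusions would
  need manual level maps.
* Stage C reports apparent performance on the routed subset (no nested CV),
  inherited from the cascade design; its numbers are optimistic.
* The GP regression band is a pointwise 95% predictive interval, not a
  simultaneous band.
* Isotonic calibration can still emit a small fraction of hard 0/1
  probabilities at the support edges; the calibration-slope logit clips at
  10⁻⁹, so those knees carry extreme leverage in the slope and the Brier
  score is the more robust calibrated-accuracy summary.
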