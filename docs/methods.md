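# Methods

This note records the models, conventions and numerical choices behind
`glycloop`, in the order the pipeline runs them.

## Data model and windows

CGM traces live on a uniform 5-minute grid anchored at local midnight.
Raw readings snap to the nearest slot (duplicates keep the last reading);
interior gaps of at most 15 minutes are linearly interpolated, longer gaps
stay missing. Glucose outside (20, 600) mg/dL is treated as a sensor
artifact and flagged missing. Each meal contributes a 72-sample
retrospective window ending at the meal-onset slot m0 (so the window's last
sample is "CGM at meal") and a 48-sample postprandial window starting one
slot after m0. A window is kept only with ≥ 90% coverage on both sides;
boluses within ±15 minutes of meal onset count as the meal bolus. These
gap/coverage/association rules are package conventions chosen for
deterministic feature extraction — source datasets rarely state theirs.

## Features and labels

The 13 features are listed in `features.FEATURE_NAMES`. Hourly means use
12-sample blocks ordered most-recent-first; missing samples are excluded
from block means, but the meal-onset and meal−60-min samples must be
present (the excursion is defined on exact samples, not interpolations).
LBGI/HBGI use the canonical risk transform for mg/dL,
f(BG) = 1.509·(ln(BG)^1.084 − 5.381), with LBGI the mean of 10·f² over
f < 0 and HBGI its f > 0 counterpart; f vanishes near 112.5 mg/dL.

"Sustained" means three consecutive 5-minute samples. Hypoglycemia: ≤ 70
mg/dL sustained anywhere in the 4-hour horizon. Hyperglycemia: ≥ 250
sustained within the first two hours, or ≥ 180 sustained within the second
two; the sample at exactly 120 min opens the second phase, and the sustain
rule is applied to both phases so the two event definitions stay
symmetric. Missing samples break runs.

## Virtual cohort (the plant)

The simulator is a deliberately minimal six-state model — it is the
package's own construction, documented here in full, and the closed-loop
claims are about the dosing pipeline, not about plant fidelity:

    dG/dt  = −p1 (G − G_b) − m(t)·X·G + f·k_m(t)·Q2 / V
    dX/dt  = −p2 X + p2·S_I·I2 / τ_i
    dQ1/dt = carbs_in − k_m(t)·Q1        dQ2/dt = k_m(t)·(Q1 − Q2)
    dI1/dt = insulin_in − I1/τ_i         dI2/dt = (I1 − I2)/τ_i

with the circadian multiplier m(t) = 1 + a_c·sin(2π(h − φ_c)/24) applied
to insulin sensitivity and to the absorption rate k_m = m/τ_m (a
per-patient sinusoid is the simplest circadian structure with the right
period). Fasting with no insulin
is a steady state at G_b; basal insulin is implicit in that construction.
Because the glucose appearance flux equals the outflow of the second gut
compartment, total appearance integrates to f·CHO·1000/V regardless of the
circadian modulation — the mass-balance invariant tested in the suite.
Integration is fixed-step RK4 at 1 minute (halving the step moves a
day-long trace by < 0.5 mg/dL); meals and boluses enter as state impulses
at whole-minute times. The sensor adds iid Gaussian noise (sd 5 mg/dL) at
5-minute sampling, clipped to [20, 600]; no drift or calibration model.

Scenario defaults are the study conditions: 10 adults, 120 days, three
meals (8:00/13:00/19:00, 50/70/60 g nominal), uniform ±20-min timing
jitter, uniform ±20% content variation, and carbohydrate misestimation
ε ~ Normal(0, 0.2) truncated at ±0.4 (announced = actual·(1+ε)); "normal
distribution (±40%)" is read as sd 20% truncated at ±2 sd. Open-loop meals
are dosed with the standard calculator on announced carbs.

Per-patient parameters are one seeded draw each from the ranges in
`cohort.PARAM_RANGES` (log-uniform for rates and time constants). The
ranges were calibrated once so that the open-loop cohort's summary
statistics bracket the reference simulated-population table (time-in-range
near 78%, CV near 36%, a few percent below 54 mg/dL, postprandial peak
near 100 min) and were then frozen. Therapy follows from the plant: CR
balances a meal's integrated glucose appearance against its bolus's
integrated insulin action at a 120 mg/dL operating point, divided by an
aggressiveness factor 1.12 (slight systematic overdosing is what gives the
population its realistic hypoglycemia exposure); CF amortizes one unit's
action over the 4-hour insulin-action horizon, giving a population median
near 105 mg/dL/U.

What the generator does **not** emulate: exercise, stress, illness,
pump-site dynamics, CGM drift, missing-data patterns of real wear, and
real meal-time diversity (three standardized meals only). Tests passing on
this cohort show the pipeline behaves correctly under controlled,
physiologically plausible variability — not that its metrics transfer to
free-living data.

## Profiling

Clustering operates on the 12 continuous features — the hour of day is
excluded because Euclidean distance on a cyclic integer is ill-posed
(`include_hour=True` restores all 13). Features are z-scored with one set
of statistics per profile index so distances to all of a system's
centroids are commensurable; z-scoring per label-subset would put a
system's six centroids in incomparable spaces.

The SOM is a standard online map: 10×10 grid, Gaussian neighborhood,
learning rate 0.5 → 0.01 and radius 5 → 1, both decaying exponentially
over epochs × n updates (500 epochs by default; weights initialized by
seeded uniform sampling within each dimension's range; one epoch visits
every input once in a seeded shuffled order). BMU ties break to the
smallest (row, col). k-means (k = 3, 10 seeded restarts) runs on the 100
prototype weights; a subgroup's centroid is the mean of its member
prototypes. `choose_k` reports the silhouette-selected k with the elbow
curve as a diagnostic, but the pipeline pins k = 3 and records the
diagnostic rather than re-deciding per run. Training instances are
assigned within their own label subset's three centroids (ids 0–2 event,
3–5 non-event per system); test instances take the nearest of all six.

## Classification

Each subgroup model is a binary random forest trained on its cluster's
instances plus an equal number of opposite-label instances nearest to the
subgroup centroid. This centroid-local balancing is the package's
resolution of the central gap in the architecture — a model trained only
on event instances of one cluster has no negatives to discriminate
against; `negatives="all"` is the alternative. Model selection is a seeded
randomized search (trees 100–500, depth 3–12, min-leaf 1–8, 25 draws,
5-fold stratified CV) scored by out-of-fold MCC; random-forest induction
cannot minimize MCC directly, so MCC acts as the selection and
threshold-selection criterion. Each model's probability threshold
maximizes MCC over its out-of-fold score grid; baselines (single forests
on the 13 features) use Youden's J instead. Training rows are sorted
lexicographically first, so instance order cannot change a fit.

Routing selects the two nearest centroids per system — both may be
event-class or both non-event; the distance ranking is unconstrained. The
fused binary vote is the AND of the two thresholded votes; the fused
continuous score is min(p₁, p₂), the largest score consistent with the AND
rule, and is what ROC/AUC and the explainers see.

The protocol repeats a 90/10 split 20 times (stratified on the joint
(hypo, hyper) label pair so one split serves both systems), rebuilds the
profiling on each training side, trains both systems and both baselines,
and reports per-iteration metrics with medians. Splits lacking a class are
resampled (≤ 5 retries).

## Explainability

Coalition values use the marginal (interventional) expectation: features
outside the coalition are replaced by rows of a seeded background sample
(default 100 training rows) and predictions averaged. All 2^d coalitions
are evaluated in one batched model call; the exact values double as the
oracle for the seeded permutation-sampling estimator used beyond 16
features. The interaction matrix stores the pairwise interaction values
off-diagonal and per-feature main effects (Shapley value minus its
interactions) on the diagonal, so rows sum to the Shapley values and the
matrix sums to f(x) − E[f]. LIME surrogates draw Gaussian perturbations
with the per-feature training sd, weight by exp(−d²/w²) with d in
sd-standardized units and w = 0.75·√d, and fit a ridge regression (the
penalty is the complexity term); all features are retained so rankings
can be aggregated per cluster.

## Bolus adjustment

Read literally, the adjustment factor σ(CGM_meal) + σ(CF) − 1 saturates
for physiologic arguments (σ of anything ≥ ~40 is 1), pinning the factor
at +1 and doubling every flagged dose — incompatible with the method's own
safety results. The default "normalized" mode therefore evaluates both
logistics on centered, scaled arguments: zero at reference inputs,
strictly increasing in pre-meal glucose, bounded in (−1, 1). The glucose
scale is 50 mg/dL; the CF scale must match the population's CF dispersion
and is 45 mg/dL/U around the reference 105 mg/dL/U (the simulated
population's median) — with a much narrower scale the CF term saturates
per patient and becomes a fixed dose bias that degrades glycemia instead
of adjusting it. The literal mode remains available behind
`sigmoid_mode="literal"` for fidelity experiments.

The final-dose gate: no predicted event delivers MIB unchanged; a hypo
prediction takes precedence over hyper (safety ordering); on a falling
60-min OLS trend the dose is α·B_mod − IOB (hypo, α = 1.02) or
γ·B_mod − IOB (hyper, γ = 1.01) — "B_mod α" is read as multiplication,
with the net reduction coming from the IOB subtraction; a flat or rising
trend delivers B_mod. A zero slope follows the rising branch. Doses clamp
at zero. IOB is a linear decay over a 4-hour DIA counting only boluses
delivered strictly before the meal; the decay model is a package stand-in,
as source descriptions of IOB rarely specify one.

The closed-loop harness freezes each patient's entire realization (meal
times, actual and announced carbs, sensor noise) before simulating, then
runs "before" (standard dosing) and "after" (full pipeline: featurize at
each meal from the live CGM history, route, predict, adjust) on identical
draws — a paired design summarized metric-by-metric with the Wilcoxon
signed-rank test. Meals without 6 h of usable history fall back to the
standard bolus.

## Reports

Time-in-range bands follow the printed conventions: < 54; [54, 70];
(70, 180]; > 180; > 250 — the last two overlap deliberately (> 180
contains > 250); the five disjoint bands partition exposure to within
0.01%. Postprandial summaries aggregate per patient: continuous per-meal
statistics (min/max/mean/median, initial BG, excursion = mean postprandial
BG − initial BG, time to first peak) take the median across meals, while
the band percentages pool every in-window sample — the median meal has no
out-of-band exposure, so median-of-fractions would report 0 regardless of
true exposure. Cohort values are medians [IQR] across patients. The
Wilcoxon test drops zero differences, tie-averages ranks, enumerates the
exact null by dynamic programming up to 25 nonzero pairs and uses the
tie-corrected continuity-corrected normal approximation above; all-zero
differences give p = 1.

## Problem sizes

The default configuration reproduces the study conditions (10 patients ×
120 days, 20 protocol iterations, 25 search draws × 5 folds) and is sized
for an overnight run. The test suite and `scripts/acceptance.py` use
reduced sizes chosen as the smallest that keep every check stable across
seeds: 10 patients × 30 days for open-loop descriptives; 600 planted
instances with 5 protocol iterations and a 5-draw × 3-fold search; an
8-patient × 30-day training cohort and an 8 × 10 paired evaluation for the
closed loop. The acceptance script derives every stream from `--seed` and
retries the profiling draw (deterministically) if k-means leaves a
subgroup under the 10-instance training minimum.

## Known limitations

The plant's minimal structure cannot reproduce every reference magnitude
simultaneously (its level-1 hypoglycemia band runs high and its
hyperglycemia exposure low relative to the reference tables; the bracketed
statistics — time-in-range, CV, peak timing — are the calibration
targets). With our slow-insulin parameterization most
hypoglycemia falls outside the 4-hour postprandial window, so the
in-window %<54 is a small, noisy quantity at the evaluation's cohort
sizes — the overall %<54 (which the adjustment clearly reduces) is the
more stable hypoglycemia readout on this plant. Real-data evaluation
requires logs in the package's CSV dialect; no device-native formats are
parsed. The stratified split is instance-level
(meals of one patient can land on both sides); a patient-grouped split is
the right choice when estimating deployment performance on new patients
and can be added by grouping `patient_id` before `run_protocol`.
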