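# Methods

## Cluster formation

S1 clusters are built per animal by chronological greedy agglomeration.
Scanning fixes in time order, the earliest unassigned pair within
`radius_m` (default 200 m) and `window_days` (default 4 d) of each other
seeds a cluster; subsequent unassigned fixes join when they lie within
`radius_m` of the *current* centroid and within `window_days` of the latest
member, with the centroid recomputed after every addition.  Passes over the
remaining fixes repeat until no fix can join.  Because a centroid can drift
as members accumulate, a closed cluster may momentarily hold a member
farther than `radius_m` from the final centroid; such members are pruned
farthest-first (returning to the unassigned pool) until the radius rule
holds.  In the degenerate case where pruning would leave a violating pair,
the cluster dissolves and its seed pair is blacklisted, guaranteeing
termination and determinism.  A fix belongs to at most one cluster
(earliest-seeded wins), which prevents double-counting feeding events.

S2 clusters are pairs of *consecutive acquired* fixes 200–500 m apart with
exactly one scheduled slot strictly between their timestamps — the
signature of a collar that failed to record while the animal sat at a
carcass.  The missing-slot condition is only well defined for adjacent
fixes, hence the consecutiveness requirement.

Fixes within 7 days of a capture are truncated before clustering
(post-capture behaviour is unrepresentative); user-supplied space-time
exclusion boxes (e.g. natal dens) are honoured but never computed.

## Covariates

* The activity window is interpreted as ±1.5 h around each member fix
  (half-width reading); activity is averaged in two stages — per fix, then
  per cluster — so fixes with many blocks do not dominate.  `ACCXYDIFF`
  applies the same two-stage mean to per-block `ax − ay`, which makes the
  identity `ACCXYDIFF = ACCX − ACCY` exact whenever every member window
  contains at least one block (asserted in tests).
* `FIXRATE` uses a 96-h window centred on each member fix
  (`[t − 48 h, t + 48 h]`), clipped to the collar deployment interval;
  centred is symmetric and behaves sensibly at deployment edges.
* Night slots default to {21:00, 02:00, 05:00} — the scheduled attempts
  falling in the 21:00–05:59 block — and are configurable; astronomical
  night is deliberately out of scope.
* `SEARCH_LAG` is continuous fractional days from the first member fix
  (cluster initiation) to the visit; a visit before initiation is an error.
* Seasons are calendar-day ranges (SUM Jun 1–Sep 30, FAL Oct 1–Jan 15,
  WIN Jan 16–May 31), year-agnostic, taken from the cluster start.

## Model fitting and selection

Fitting is maximum likelihood for the binomial-logit GLM via iteratively
reweighted least squares (statsmodels backend), coefficients on the raw
covariate scale (no standardization).  Separation is treated as a fit
failure: the perfect-prediction signal from the optimizer, or any
coefficient exceeding 50 on the standardized scale, raises a
`SeparationError` rather than returning a divergent estimate.  AICc (the
small-sample form, `−2ℓ + 2k + 2k(k+1)/(n−k−1)`) is used throughout, and
models in a comparison set are fitted to one listwise-complete observation
set so their AICc values share a common n.  The candidate surface is the
2⁴ component set over the SpTemp / Acvty / GrndTru / Seas groups, the two
cross-group interactions (`ACCX×CENTER`, `ACCXYDIFF×log POSCOUNT`)
appearing only when both parent groups are present; the intercept-only
model is generated and reported like any other.  Pipelines may drop
separated candidates from a selection table (logged) instead of aborting;
the library default is to raise.  Log transforms are natural logs.
Mixed-effects (per-animal random intercept) variants are out of scope.

## Evaluation

AUC is the rank (Mann–Whitney) statistic with ties counted half.  The
probability cut-off scans the midpoints between adjacent distinct fitted
scores plus both extremes and takes the threshold minimizing
|sensitivity − specificity| (classify feeding when score ≥ cutoff; ties
toward the smaller cutoff).  Cross-validation uses seeded *stratified*
k-fold partitions — with ~20 folds and a minority class of a few hundred,
plain random folds can lack a class entirely — and reports the unweighted
mean of per-fold AUCs with no pooling.  A training fold that separates is
skipped with a warning; an all-fold failure is an error.

## Detection-corrected counts

`SEARCH_LAG` and `FIELDPROP` describe the observation process, not the
animal, so predictions over the full cluster table set them to ideal values
(0 days, 1.0) for the corrected count and to the mean ground-truthing
conditions (defaults 29.1 d, 0.913; recomputed from the visited sample in
pipeline runs) for the uncorrected count.  The count is the enumeration of
clusters at or above the cut-off.  A thresholded count has no standard
Wald error, so intervals propagate coefficient uncertainty by parametric
bootstrap — coefficient draws from N(β̂, V̂), probabilities and counts
recomputed per draw — reporting the percentile interval as primary and a
symmetric 1.96·SE form alongside.  Response profiles hold other covariates
at observed means (season at the non-summer reference) with delta-method
intervals on the logit scale.

## The synthetic-data generator

The generator emulates the assumed data-collection design: 7 scheduled
fixes/day (02:00…21:00, clock time), independent acquisition failure
(default success 0.81) and satellite-download flags (0.92), 288-s dual-axis
activity blocks, kills arriving as a Poisson process (0.4/week per animal;
arrivals during an active handling bout are discarded), handling for
`min(1 + mass/30, 8)` days, prey mass a small/large lognormal mixture (38%
small), and an observer detection model
`logit p = 0.3 − 0.07·lag + 2·FIELDPROP + 0.6·log(mass)` applied to truly
feeding clusters only (observers do not invent carcasses).

Design choices that shape what the simulator can and cannot show:

* **Movement.** Night travel and day-to-day relocations use persistent
  headings (quasi-ballistic walks).  An uncorrelated random walk revisits
  its own path so often that chance 2-fix clusters swamp the cluster
  population (~90% non-feeding); with persistent headings the population is
  ~70–75% non-feeding, matching the regime the analysis targets.  Real
  home-range behaviour (attraction, territory) is *not* modelled.
* **Day-beds.** During handling, day positions sit at a per-kill day-bed
  offset 220–400 m from the carcass — outside the 200 m cluster extent, as
  day-time resting typically is in this system.  Offsets inside the radius
  would create clusters that are truly kill-associated but carry a pure
  day-bed signature: label noise no model can resolve.  Outside handling,
  ~8% of days are spent at a single tight day-bed (re-used across nearby
  days with probability 0.3), generating the non-feeding cluster class.
* **Feeding intensity.** During handling nights the animal feeds in bouts:
  each activity block is a feeding block with probability
  `min(0.4 + mass/100, 0.95)`, resting otherwise.  Small prey thus produce
  short, low-intensity clusters — a continuum of classification difficulty
  instead of a cleanly separable caricature (which drives ML logistic fits
  into complete separation).
* **Detection.** The lag decline (−0.07/day; detection ≈ 0.97 at 2 days to
  ≈ 0.75–0.85 at 60 days, ~8–12% of visited kills missed overall) is
  steeper than the field study's few-percent double-observer miss rate.
  This is deliberate: at the simulated scale (~180 true feeding clusters
  per run, versus 12,096 clusters in a 3-year field study) a miss rate of
  2–4% would be statistically invisible, and the correction step would be
  untestable.  The magnitude of the resulting corrected-vs-uncorrected gap
  (~5–10%) matches the field analysis; the synthetic double-observer
  discordance (~15–20%) is correspondingly higher than the field study's
  3.5%.
* **Ground-truthing intensity.** 60% of clusters are visited (lag uniform
  2–60 d), against ~10% in the field study, so the fitted sample (~430
  rows) carries information comparable to the study's 1,171 visits at a
  ~15× smaller cluster population.
* Defaults are 30 animals × 120 days starting Aug 15, spanning the summer
  and fall seasons so the season dummy is estimable (~200 kills, ~25,000
  fixes, ~700 clusters).  Test and fixture runs scale these down (8–12
  animals, 60–90 days) purely for speed; the 50-replicate recovery checks
  run at the full default scale.

Consequently, passing tests demonstrate that the pipeline recovers known
structure — negative fitted lag effects, detection-corrected counts closer
to the true kill-derived count than uncorrected ones, calibrated
coefficient coverage — under the generator's assumptions.  They do not
certify performance on real telemetry, where movement autocorrelation,
habitat-driven fix failure (which correlates missingness with behaviour,
unlike the independent failures here), scavengers and multi-prey caching
violate those assumptions.

## Numerical conventions

IRLS convergence at relative log-likelihood change < 1e−10 (≤ 100
iterations); vcov from the observed information.  Cut-off ties break toward
the smaller threshold.  Bootstrap coefficient draws use an eigendecomposed
MVN so a singular (including exactly zero) vcov is handled; a zero vcov
yields zero-width intervals.  All generator randomness flows from one
`numpy` Generator seeded by `SimConfig.seed`; identical configs are
byte-identical.  Timestamps are naive local civil time; the schedule is
anchored to clock times, so time-shift invariance of clustering holds for
whole-day shifts.
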