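# Methods

`sbpatterns` implements a two-phase clustering procedure for deriving
diurnal sedentary-behavior (SB) patterns from hip-worn accelerometry, an
association stage linking those patterns to longitudinal physical
functioning (PF), and a synthetic cohort generator that provides ground
truth for every stage. This note records the models, the conventions and
defaults that matter, and what the synthetic data do and do not establish.

## Accelerometer preprocessing

Raw input is a vector-magnitude count stream at 15-s epochs over ~7
calendar days per participant, plus a daily sleep log of in-bed and
out-of-bed clock times.

**Non-wear.** The Choi algorithm operates on minute-level counts (sums of
four epochs): a non-wear interval is a run of ≥ 90 consecutive zero-count
minutes, in which a ≤ 2-minute non-zero interruption is tolerated when the
zero runs immediately flanking it are each ≥ 30 minutes long; tolerated
interruption minutes are themselves non-wear, and interruptions at a run
boundary are never tolerated. The tolerance applies to interruptions of any
count magnitude (the published rule does not bound them; this choice is
flagged for sensitivity work).

**In-bed time.** Missing sleep-log fields are imputed with the
participant's circular mean of available same-field times (the circular
mean handles bedtimes that straddle midnight); participants missing a field
on every day receive population constants in-bed 22:45 / out-of-bed 07:22.
For calendar day *d*, in-bed time is [midnight, out-of-bed) plus [in-bed,
midnight); an in-bed time before noon is read as "after midnight" and is
covered by the next day's morning window.

**Classification.** Per-epoch priority is in-bed > non-wear > intensity.
Intensity uses cutpoints calibrated for older women wearing the device at
the hip: sedentary ≤ 18 counts/15 s, MVPA > 519, light in between. A
calendar day is *adherent* with ≥ 600 minutes of awake wear (the inclusive
reading of "10 h or more"); participants need ≥ 4 adherent days. Days are
bounded at midnight; overnight wear is split.

## Daily trajectories

Sedentary minutes are summed per clock-hour bin. A day's trajectory is 14
consecutive hourly values starting at the first clock-hour bin at or after
the resolved wake time with 60 full minutes of awake wear ("awake-and-worn"
reading; a wear-only variant sits behind `require_awake=False`). Any hour
with < 60 minutes of awake-wear coverage is missing — the strictest
consistent reading of an hourly bin "with missing data". Days with > 50% of
hours missing are dropped (configurable guard); days with no qualifying
start hour are dropped with a logged reason.

**Copy-Mean imputation.** With population mean curve M (hour-wise mean of
all observed day-hours), an interior gap between observed hours a < b is
filled with

    imputed(t) = LinInterp_obs(t) + [ M(t) − LinInterp_M(t) ]

so the imputed segment follows the chord between the observed endpoints
plus the mean curve's local deviation from its own chord. Leading/trailing
gaps carry the nearest observed value shifted by M(t) − M(nearest). Values
are clipped to [0, 60]; observed entries are never modified. The canonical
method is deterministic; an optional mean-zero Gaussian jitter (default SD
0, seed-controlled) is available because some descriptions add stochastic
variation.

## Two-phase clustering

**Phase I (days).** Lloyd's k-means with squared Euclidean distance on the
14-dimensional trajectories; each of 5 restarts initialises with k distinct
observed trajectories; empty clusters are re-seeded with the point farthest
from its centroid; iteration stops when assignments stabilise (max 100).
The restart with the highest Calinski–Harabasz criterion

    CH = [tr(B)/(k−1)] / [tr(W)/(n−k)]

is kept (W = 0 with distinct centroids returns +inf as a documented
sentinel). k is chosen over k ∈ {2..6} by arg-max CH; a diagnostics table
(CH, spherical-Gaussian AIC/BIC, SSE) is exposed for manual review, with a
`stable=False` flag when CH decays monotonically from the smallest k — the
signature of unclustered data. AIC/BIC never drive selection. Day clusters
are lettered A, B, C, … by descending centroid total sedentary minutes.

**Phase II (participants).** Each retained participant (≥ 4 trajectory
days) is summarised by the proportions of their days in each day cluster
(proportions, not counts, because participants contribute 4–7 days).
Agglomerative clustering with complete linkage and Euclidean distance on
the raw proportion vectors; the dendrogram is cut at every K ∈ {2..8} by
merge order (R `cutree` semantics via `scipy.cluster.hierarchy.cut_tree`,
which yields exactly K clusters even under tied merge heights — ties are
routine on lattice-valued proportions). The cut maximising average
silhouette width, s(i) = (b−a)/max(a,b) with singletons scored 0, wins;
ties go to the smaller K. Patterns are numbered 1..K by the day-cluster
letter that dominates them, so pattern 1 is the A-dominated (high-SB)
group.

**Concordance.** The clock-aligned variant rebuilds trajectories from a
fixed start hour (default 08:00) and re-runs both phases; cluster labels
are matched across variants by maximal overlap (Hungarian assignment on the
confusion matrix) before computing the % of days / participants classified
identically.

## Association with physical functioning

PF (0–100, higher = better) is modelled with a linear mixed model with a
person-level random intercept:

    pf_it = β0 + pattern_i + t + pattern_i×t + covariates_i + b_i + ε_it

with t in years since baseline (t = 0 at baseline, so the intercept surface
is baseline PF). Covariates: age, race-ethnicity, BMI, education, smoking,
alcohol use, morbidity count, self-rated health, and optionally total
sedentary time. Estimation is REML for reported estimates; ML fits feed the
likelihood-ratio test. Rows are complete cases; empty pattern × stratum
cells raise a named error.

**Effect modification by MVPA.** MVPA is dichotomised at the sample median
(strictly greater → high; ties → low, documented). The full model adds the
binary stratum, all two-way terms and the pattern×t×MVPA three-way term;
the LRT compares full vs reduced ML fits (χ², df = parameter difference).

**Stratified estimates.** Per pattern × stratum cell, the baseline is the
linear predictor at t = 0 with continuous covariates at their sample means
and categoricals at explicit clinical reference levels (White,
high-school-or-less, non-smoker, no alcohol, zero morbidities, excellent
health — overridable); the slope is ∂/∂t of the linear predictor. SEs come
from the fixed-effect covariance by the delta method; within-stratum
pairwise pattern contrasts and within-pattern stratum contrasts are Wald
z-tests, unadjusted by default with an optional multiple-testing
correction. Estimates are invariant to the pattern reference level; a
reparameterised refit reproduces the delta-method SEs (tested).

## Synthetic cohort generator

The generator is the package's acceptance surface: it emulates the study
design with known latent labels.

**Day structure.** Four hourly SB archetypes over the 14 waking hours
(minutes/hour): A high and gently rising (46–54), B low start rising
steeply (22–55), C morning-high with a ~6-h decline then rising (46–32–46),
D low and flat (22–30). Totals are ordered A > B > C > D so the generator's
letters coincide with the model's volume-ordered letters. Hourly SB is
drawn Normal(archetype value, 5) truncated to the available minutes; hours
are conditionally independent given the archetype (no within-day
autocorrelation is claimed). Wake ~ 07:20 ± 40 min, in-bed ~ 22:30 ± 45
min, so the 14th trajectory hour is missing for ~25–30% of days and Copy
Mean is exercised on every run. Sedentary epochs draw counts uniformly on
[0, 18], light on (18, 519], MVPA on (519, 5000]; in-bed epochs are zero
with sparse low-count "stirring". MVPA minutes (per-pattern means 28.6 /
54.2 / 50.7 / 82.1 min/day) are placed among non-sedentary minutes with an
early-day exponential preference. Non-wear bouts (≥ 90 min, ~0.1/day) are
zeroed inside waking hours; ~3% of days (60% for a 5% "low-adherence"
subgroup) receive a long bout that defeats the 600-min bar, giving ~95%
participant retention.

**Participant structure.** Four latent patterns with weights (.361, .248,
.183, .208); pattern k draws each day's archetype from a mixture with 0.85
mass on archetype k and little mass on the opposite extreme. This dominance
is deliberately higher than real cohorts show (printed medians of the
dominant-day share are nearer 60–67%): with at most 7 days per participant,
a 0.6-dominant mixture is not recoverable at ARI ≥ 0.8 by any classifier
(the Bayes ceiling is ≈ 0.85–0.9 and complete linkage loses ~0.1 more), so
the default is a cleaner caricature chosen for identifiability. Passing
recovery tests therefore demonstrate the pipeline's correctness on
separable data, not its resolution on real, messier cohorts. Relatedly,
wake- vs clock-aligned concordance is ~99% here versus ~80% in real data.

**PF truth.** pf = baseline[s,p] + slope[s,p]·t + covariate effects + b_i +
ε, clipped to [0, 100], with b_i ~ N(0, 12²), ε ~ N(0, 7²), 7 annual
assessments and 25% missed post-baseline visits (median ~5 of 7 available).
The stratum s is the latent MVPA against 45.4 min/day — the population
median of the MVPA mixture — so the analysis-side sample-median split
estimates the same cut. Baselines/slopes default to the printed stratified
surface (e.g. low-MVPA pattern 2 declines 3.0 points/year, high-MVPA
pattern 3 declines 1.6). Ceiling clipping affects < 1% of draws and biases
estimates by ≪ 1 SE at n = 1000. Covariates are drawn independently of
pattern, so adjusted cell means equal the configured truth; real cohorts
confound pattern with age, BMI and morbidity, which this generator does not
emulate.

## Numerical conventions and degenerate inputs

- All randomness flows from one root seed through named substreams
  (cohort, PF panel, kml restarts, imputation jitter); identical config +
  seed reproduces byte-identical artifacts and reports.
- Tie-breaks: first/smallest index everywhere (restarts, silhouette K,
  Hungarian matching through scipy's deterministic assignment).
- CH with W = 0 → +inf; silhouette for singletons or coincident points →
  0; all-equal MVPA → all-low with a warning; k larger than the number of
  distinct trajectories, empty candidate ranges, empty clusters, and
  all-missing trajectories raise errors rather than guessing.
- Problem sizes used by the shipped checks: clustering recovery on 500
  participants × 7 days; mixed-model recovery on 20 replicates of 1000
  participants; pipeline determinism on 150 participants.

## Known limitations

- The generator's count spectra are band-uniform, not realistic count
  distributions; only the cutpoint bands matter downstream.
- No weekday/weekend structure, no within-day SB autocorrelation, no
  pattern-covariate confounding, no raw 30-Hz signal.
- Automated k selection is arg-max CH; the source procedure also weighed
  visual inspection, which no algorithm reproduces — the diagnostics table
  is exposed for that purpose.
- Complete linkage on proportion vectors is sensitive to bridge points
  between clusters; on weakly separated cohorts the silhouette-chosen K is
  stable but individual assignments near cluster boundaries are not.
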