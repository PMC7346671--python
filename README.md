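# sbpatterns

Diurnal sedentary-behavior (SB) patterns from hip-worn accelerometry, and
their association with physical-functioning trajectories in older adults.

Most accelerometer studies reduce sedentary behavior to one number — total
sedentary minutes per day — which hides *when* during the day sitting
accumulates. `sbpatterns` implements a two-phase clustering procedure that
recovers diurnal timing structure, plus the longitudinal mixed-model stage
that relates it to health:

1. **Preprocessing** — 15-s vector-magnitude counts are summed to minutes;
   non-wear is detected with the Choi algorithm (90-min window, 30-min
   stream frame, 2-min tolerance); in-bed time comes from sleep logs (with
   circular-mean imputation of missing bed times); epochs are classified
   with cutpoints calibrated for older women (sedentary ≤ 18 counts/15 s,
   MVPA > 519); calendar days with ≥ 600 min awake wear are kept, and
   participants need ≥ 4 such days.
2. **Phase I (days)** — each day becomes a wake-aligned vector of sedentary
   minutes over 14 consecutive hours (missing hours imputed by Copy Mean);
   longitudinal k-means with 5 restarts clusters the days, with the number
   of clusters k chosen by the Calinski–Harabasz criterion
   CH = [tr(B)/(k−1)] / [tr(W)/(n−k)].
3. **Phase II (participants)** — each participant is the vector of
   proportions of their days in each day cluster; complete-linkage
   hierarchical clustering groups participants, with K chosen by average
   silhouette width s(i) = (b−a)/max(a,b).
4. **Association** — physical functioning PF_it (0–100) follows a linear
   mixed model with a person random intercept,
   `PF_it = pattern_i + t + pattern_i×t + covariates_i + b_i + ε_it`,
   with MVPA effect modification tested by a likelihood-ratio test on the
   pattern×t×MVPA interaction and reported as a stratified baseline/slope
   surface per pattern × MVPA (median-split) cell.

Because cohort accelerometer data of this kind are not openly deposited,
the package ships a first-class synthetic cohort generator
(`sbpatterns.synthetic`) that emulates the full study design — four latent
day archetypes, participant-level archetype mixtures, non-wear bouts,
sleep-log missingness, and a PF panel drawn from a known random-intercept
model — so every stage can be verified against ground truth.

## Worked example

`examples/04_two_phase_clustering.py` generates a 150-participant cohort,
preprocesses it and runs both clustering phases:

```
Phase I diagnostics (one row per candidate k):
 k     ch     aic     bic      sse  stable
 2  831.5 93202.4 93343.4 835529.7    True
 3  872.3 87700.0 87909.0 552243.4    True
 4 1219.5 80550.8 80827.8 322662.5    True
 5  937.1 80309.7 80654.9 316228.6    True
 6  764.4 80118.3 80531.4 311074.5    True
chosen k = 4; day-cluster letters by SB volume: {2: 'A', 3: 'B', 1: 'C', 0: 'D'}
day-level ARI vs planted archetypes: 0.990

Phase II: chosen K = 4, avg silhouette 0.756
participant-level ARI vs planted patterns: 0.952
```

The Calinski–Harabasz criterion peaks at k = 4 — the number of planted day
archetypes — and the silhouette-chosen K = 4 matches the planted
participant patterns; the adjusted Rand indices near 1 say the recovered
partitions agree with the latent truth up to labeling. Day clusters are
lettered A–D by descending sedentary volume, and participant patterns 1–4
by the day cluster that dominates them, so "pattern 1" is the
high-SB-throughout-the-day group.

`examples/05_pf_association.py` continues to the association stage and
prints the stratified surface, e.g. (n = 800, truth in parentheses):

```
LRT for MVPA effect modification: chi2 = 123.1, df = 8, p = 7.70e-23
  pattern 2 MVPA low : baseline  73.8 (2.1)  slope -3.10 (0.17)   # truth 75.1, -3.0
  pattern 2 MVPA high: baseline  79.7 (1.9)  slope -1.75 (0.13)   # truth 81.5, -1.9
```

Each cell shows adjusted baseline PF points and decline in points/year;
the low-MVPA moderate-SB pattern declines fastest, and high MVPA
attenuates the decline — the structure the generator plants.

Other examples: `01_simulate_cohort.py` (what the generator emits),
`02_nonwear_detection.py` (the Choi rule on a constructed stream),
`03_daily_trajectories.py` (trajectory extraction and Copy-Mean
imputation). A thin CLI wraps the pipeline:
`sbpatterns simulate|preprocess|run --seed 1 --out <dir>`.

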