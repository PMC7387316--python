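# Methods

This note documents the models, parameters, numerical conventions and
design choices behind `memtrack`, and what the synthetic-data validation
does and does not establish.

## The pipeline

### Discovery (Step 1)

The unit of discovery is a within-subject comparison pair: two
*consecutive* testing visits whose HVLT retention scores differ by at least
20% **relative to the earlier visit** (|R₂−R₁|/R₁ ≥ 0.2). The relative
(rather than absolute-point) reading and the restriction to consecutive
visits are design choices; both the threshold and the pairing rule are
arguments to `select_comparison_pairs`. A zero earlier retention counts as
a maximal change when the later score is positive, and is logged.

DE scoring works on normalized log2 expression: the per-pair score is
sign(Δ)·1 for |fold| ≥ 1.2, sign(Δ)·0.5 for 1.1 ≤ |fold| < 1.2, else 0,
with closed boundaries compared on the log2 scale with a 1e-9 tolerance so
a difference of exactly log2(1.2) earns full points. AP scoring awards ±1
for Present/Absent flips between the high- and low-memory visit; the
precise flip rule is a reconstruction of the stated intent (capturing genes
turning on and off) and is isolated in `score_pair_ap`.

Raw scores sum per-pair scores over all pairs and subjects with equal
weight (no down-weighting of subjects contributing many pairs). Internal
points use percent of the per-method maximum |raw| score with inclusive
thresholds 33.3/50/80 → 2/4/6. DE and AP are combined by **max** (not
sum), with DE winning point ties and conflicting nonzero directions
flagged; the max rule is the one consistent with the published worked
examples the test suite pins.

### CFG prioritization (Step 2)

External evidence scoring is a capped sum over six lines of evidence
(human genetic 2, human brain 4, human peripheral 2, non-human genetic 1,
non-human brain 2, non-human peripheral 1): one or more records on a line
earns the full cap, so the score is monotone and idempotent under record
duplication and bounded by 12. Evidence direction is recorded but does not
modulate the score; fractional line awards are not given. Gene-level
external scores are broadcast to every probeset of the gene while internal
points stay probeset-level. Selection reports use the deterministic order
(total desc, |raw| desc, probeset id asc); the default carry-forward
threshold is total ≥ 10, with ≥ 12 marking top candidates. The disorder
filter defaults to "AD" but accepts any tag, which also powers the
cross-disorder annotation report.

### Testing (Step 3)

Expression is Z-scored within gender × diagnosis strata (population-SD
convention, ddof = 0) to remove range artefacts before markers are
combined; singleton and zero-variance strata yield zeros with a warning.
Panels sum Z-scores of increased-risk members minus decreased-risk
members.

*Visits*, not subjects, are the unit of analysis, matching the reporting
convention of per-visit case counts; repeated visits per subject therefore
correlate observations (see Limitations). The state label is retention
≤ 40. AUC is computed from the Mann–Whitney U statistic with midrank tie
handling; the p-value is the one-sided Mann–Whitney test in the direction
of the marker's stated risk. No multiple-testing correction is applied by
default (nominal p < 0.05), mirroring the reporting convention the
pipeline emulates.

The longitudinal composite is defined for visits with at least one prior
visit: level, slope (L_t/L_{t−1})/Δdays computed on normalized (pre-Z)
levels so the ratio is well defined on the positive log2 scale, running
max level (running min for decreased-risk markers) and running max slope,
each Z-scored by stratum across the cohort and summed. Δdays must be
positive; a zero previous level leaves that visit's slope undefined and
excludes the visit with a warning.

Trait prediction fits a Cox proportional-hazards model per group with the
oriented measure as sole covariate (no age/gender covariates), using time
in days from each visit to the event or censoring. Robust
cluster-by-subject standard errors are available via
`cluster_by_subject=True` but off by default. Zero-event groups are
reported untestable; non-convergent fits are flagged rather than raised.

### CFE and enrichment

The 30-point CFE score adds discovery points (≤6), external CFG points
(≤12), and state and trait prediction tiers. A tier is the *best* level
achieved — 6 for a nominally significant result in all subjects, 4 in a
gender group, 2 in a gender × diagnosis group — not a sum over levels, and
either cross-sectional or longitudinal results may furnish it. Survival
folds are array size / stage survivors; set-enrichment folds compare a
candidate list's in-set percentage to a reference pool (e.g. the
1468-gene circadian clock database — 18 core, 331 immediate, 1119 distant
— against a 21,000-gene genome). Reported folds are rendered to the
nearest 0.1 below 10, nearest integer between 10 and 100, and nearest
hundred above 100.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, not
microarray physics. Defaults (all configurable in `CohortConfig`):

| parameter | default | meaning |
|---|---|---|
| n_subjects | 150 | cohort size |
| visits_range | 2–6 | visits per subject, uniform; 90–180 d apart |
| strata | 82% male; BP .34 / SZA .23 / SZ .18 / MDD .15 / PTSD .10 | gender × diagnosis weights, patterned on a male-predominant psychiatric cohort |
| retention_mean / between / within SD | 60 / 12 / 12 (%) | subject-level Gaussian mean + i.i.d. Gaussian visit noise, clipped to [0,100] |
| n_probesets | 1000 | array size (20 + 20 planted) |
| effect_size | 0.5 | log2 shift per 10 retention points on planted probesets |
| noise_sd | 0.25 | visit-level log2 noise |
| baseline_mean / probe SD / subject SD | 7 / 1.5 / 0.5 | log2 baseline hierarchy |
| ap_call_threshold | 6.0 | log2 level below which a call is Absent |
| event_base_hazard / coefficient / censor_day | 5e-5 /d, 0.5, 4600 d | exponential events, log-hazard linear in the planted panel score |

These values were chosen once as a realistic regime for this kind of
cohort: the retention model yields roughly 70% of subjects with a ≥20%
consecutive change and ~11% low-memory visits, visit spacing matches a
3–6-month testing schedule, and the censoring horizon corresponds to about
12.6 years of follow-up. Expression is generated directly on the post-RMA
log2 scale (planted probesets: baseline + effect_size·(R−60)/10 + noise;
decreased probesets negate the slope), and Present/Absent calls come from
a fixed log2 threshold rather than a detection p-value model — sufficient
to exercise AP scoring. Event times are drawn independently per visit
from an exponential with rate `base·exp(β·score)`, where the score is
computed exactly as the testing stage computes panel scores; this is the
simplest model a Cox regression on per-visit observations recovers
without bias. Censoring is administrative at `censor_day` after each
visit.

All randomness derives from one integer seed through `SeedSequence`
substreams; identical (config, seed) regenerates byte-identical outputs,
which the pipeline manifest verifies with SHA-256 digests.

What passing tests on synthetic data do **not** show: robustness to batch
effects, probe saturation, RMA normalization choices, medication changes,
non-Gaussian retention dynamics, or informative censoring — none of which
the generator simulates.

## Validation design

* Scoring arithmetic (caps, totals, tiers, folds, internal-point mapping)
  is pinned against hand-checked worked examples, including a golden table
  of nine published biomarker score decompositions.
* Discovery raw scores are checked for exact equality against a naive
  per-pair Python loop on tiny cohorts, plus antisymmetry under high/low
  relabeling.
* Recovery: at the default planted effect size, ≥90% of planted probesets
  earn internal points ≥2 with the correct direction across 20 seeds; the
  planted panel's state AUC is ≥0.75 in ≥90% of seeds and beats the median
  of 100 random equal-size panels; the mean Cox estimate over 50 seeds
  falls within 2 SE of the generating coefficient.
* Null calibration is run with one analyzed visit per subject, where
  observations are independent and the nominal Mann–Whitney level applies:
  AUC centers at 0.5, log-HR at 0, and the p < 0.05 rate is 5% ± 2% over
  1000 marker-tests.

## Limitations

* With repeated visits per subject, both marker values (subject baseline)
  and low-memory labels (subject-level retention) are clustered, so
  nominal per-visit p-values are anti-conservative. This is inherent to
  the per-visit testing convention the package reproduces; the
  `cluster_by_subject` option mitigates it for Cox models, and
  subject-level aggregation before state testing is the analogous remedy
  for AUC p-values.
* The AP flip rule and the DE/AP max combination are reconstructions
  constrained by worked examples, not published formulas; both are
  isolated behind small functions and configurable.
* The longitudinal composite pools all eligible visits when Z-scoring its
  four components, so it is constant only when every included visit
  carries identical component values (e.g. identical two-visit
  trajectories), not merely identical per-subject trajectories of unequal
  visit depth.
* Cox fits on small gender × diagnosis subgroups with few events can be
  unstable; such fits are flagged (`converged=False`) rather than
  suppressed.
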