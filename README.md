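# memtrack

Blood gene-expression biomarkers that track short-term memory, and a
pipeline to discover, prioritize and test them.

Short-term memory dysfunction is an early feature of Alzheimer disease and
related dementias. Because brain tissue cannot be sampled in living
subjects, one practical strategy is to find *blood* transcripts whose
expression tracks a memory phenotype within subjects over time, then ask
whether those transcripts predict current low-memory states and future
cognitive decline in independent subjects. `memtrack` implements that
strategy as a tested, reusable Python library for researchers working with
longitudinal phenotype + expression cohorts (psychiatric or otherwise):

1. **Discovery (within-subject).** Subjects with a ≥20% relative change in
   the HVLT retention score *R* between consecutive visits contribute
   high- vs low-memory comparison pairs. Per pair, each probeset is scored
   by differential expression (DE): ±1 if the fold change
   2^(log₂x_high − log₂x_low) is ≥1.2, ±0.5 if in [1.1, 1.2), else 0; and
   by absent/present calls (AP): ±1 for a detection-call flip. Scores are
   summed across all pairs and subjects into a raw score per probeset, and
   converted to internal points by percent of the maximum |raw| score:
   ≥80% → 6, ≥50% → 4, ≥33.3% → 2.
2. **Prioritization (CFG).** Each gene's published evidence is scored with
   capped line-of-evidence weights — human genetic 2, human brain
   expression 4, human peripheral 2, non-human genetic 1, non-human brain
   2, non-human peripheral 1 — so external points ≤ 12 and total CFG =
   internal + external ≤ 18. Candidates are carried forward at CFG ≥ 10.
3. **Testing (independent cohort).** Marker measures are Z-scored by
   gender × diagnosis; panels combine members by signed summation
   (Σz_increased − Σz_decreased). *State*: ROC AUC (Mann–Whitney rank
   statistic) for low-memory visits (R ≤ 40), cross-sectionally and with a
   longitudinal composite (level, slope (L_t/L_{t−1})/Δdays, running
   max level — min for decreased markers — and running max slope, each
   Z-scored and summed). *Trait*: Cox proportional hazards on days from
   visit to future positive neuropsychological testing, HR oriented so
   HR > 1 means increased risk.
4. **Convergent functional evidence (CFE).** A 30-point tabulation per
   biomarker: discovery (≤6) + external CFG (≤12) + state tier + trait
   tier (6 if significant in all subjects, 4 by gender, 2 by
   gender × diagnosis), plus funnel-survival and clock-gene enrichment
   folds and cross-disorder annotation.

A synthetic longitudinal cohort generator (`memtrack.cohort`) plants
retention-tracking probesets and a panel-driven exponential time-to-event
outcome with known ground truth, so the whole pipeline is testable without
any data downloads.

## Worked example

```python
from memtrack.cohort import CohortConfig, generate_study, panel_truth_to_definition
from memtrack.prediction import Marker, test_marker

study = generate_study(CohortConfig(n_subjects=100, n_probesets=300, seed=2))
panel = Marker("PLANTED_PANEL", tuple(panel_truth_to_definition(study.truth)))
state, trait = test_marker(study.expression, study.visits, panel)
```

prints (see `examples/04_predict_state_trait.py`):

```
state (low-memory) prediction:
mode group  n_low  n_total   auc  p_value
   C   ALL     55      421 0.977 1.98e-30
   L   ALL     42      321  0.96  3.4e-22
...
trait (future neuropsych positivity) prediction:
mode group  n_events  n_total  hazard_ratio  p_value
   C   ALL       181      421          1.64 8.16e-73
...
```

The planted panel separates low-memory visits from the rest almost
perfectly (AUC 0.98 across 421 visits, 55 of them low-memory), and its
cross-sectional hazard ratio of 1.64 per unit panel score recovers the
generating log-hazard coefficient of 0.5 (e^0.5 ≈ 1.65). The other
scripts under `examples/` walk through simulation, discovery scoring, CFG
prioritization and CFE/enrichment reporting, one capability each.

A thin CLI mirrors the library:

```sh
memtrack run --seed 7 --out out/        # full pipeline with manifest
memtrack simulate|discover|prioritize|predict-state|predict-trait|cfe|enrich --help
```

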