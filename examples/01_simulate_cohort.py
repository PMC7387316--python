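"""Generate a synthetic longitudinal cohort and inspect its structure.

Builds a 60-subject psychiatric cohort with repeated testing visits, a
memory-retention phenotype, planted retention-tracking probesets and a
planted-panel-driven time-to-event outcome, then prints summary counts.
"""

from memtrack.cohort import CohortConfig, generate_study

config = CohortConfig(n_subjects=60, n_probesets=300, seed=1)
study = generate_study(config)

n_visits = len(study.visits)
n_events = int(study.visits.neuropsych_event.sum())
planted = study.truth[study.truth.direction != "null"]

print(f"subjects: {len(study.subjects)}  visits: {n_visits}")
print(study.subjects.groupby(["gender", "diagnosis"]).size().rename("n").to_string())
print(f"retention: mean {study.visits.retention.mean():.1f}, "
      f"low-memory visits (<=40): {(study.visits.retention <= 40).sum()}")
print(f"planted probesets: {len(planted)} "
      f"({(planted.direction == 'increased_in_high_memory').sum()} increased, "
      f"{(planted.direction == 'decreased_in_high_memory').sum()} decreased)")
print(f"future neuropsych events before censoring: {n_events}/{n_visits} visits")
# The stratum table mirrors a male-predominant psychiatric cohort; the
# low-memory visit count is what the state-prediction stage later classifies.
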