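"""Step 3: test the planted biomarker panel for state and trait prediction.

State: ROC AUC for classifying low-memory visits (retention <= 40), from
cross-sectional (C) and longitudinal (L) composite measures, in all
subjects and personalized by gender and gender x diagnosis.  Trait: Cox
regression of time to future positive neuropsychological testing.
"""

import logging

from memtrack.cohort import CohortConfig, generate_study, panel_truth_to_definition
from memtrack.prediction import Marker, test_marker

# silence repeated singleton-stratum notices from the tiny female subgroups
logging.getLogger("memtrack").setLevel(logging.ERROR)

study = generate_study(CohortConfig(n_subjects=100, n_probesets=300, seed=2))
panel = Marker("PLANTED_PANEL", tuple(panel_truth_to_definition(study.truth)))

state, trait = test_marker(study.expression, study.visits, panel)

cols = ["mode", "group", "n_low", "n_total", "auc", "p_value"]
print("state (low-memory) prediction:")
print(state.loc[state.testable & (state.group_type != "gender_dx"), cols]
      .to_string(index=False, float_format=lambda x: f"{x:.3g}"))

tcols = ["mode", "group", "n_events", "n_total", "hazard_ratio", "p_value"]
print("\ntrait (future neuropsych positivity) prediction:")
print(trait.loc[trait.testable & (trait.group_type != "gender_dx"), tcols]
      .to_string(index=False, float_format=lambda x: f"{x:.3g}"))
# AUC > 0.5 / HR > 1 mean the panel's risk direction predicts the adverse
# state or outcome; at the default planted effect size the panel separates
# low-memory visits almost perfectly and its hazard ratio recovers the
# generating log-hazard coefficient (~e^0.5 per unit score).
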