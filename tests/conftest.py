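import numpy as np
import pandas as pd
import pytest

from memtrack.cohort import CohortConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_subjects=40, n_probesets=120,
                        n_planted_increased=8, n_planted_decreased=8,
                        panel_size=6, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


def make_visits(retentions_by_subject, interval=100, strata=None):
    """Build a visit table from {subject: [retention, ...]} for hand-worked cases."""
    rows = []
    v = 0
    for i, (sid, rets) in enumerate(retentions_by_subject.items()):
        g, d = (strata or {}).get(sid, ("M", "BP"))
        for j, r in enumerate(rets):
            rows.append(
                {
                    "visit_id": f"v{v:03d}", "subject_id": sid, "gender": g,
                    "diagnosis": d, "day": j * interval, "retention": float(r),
                    "neuropsych_event": False, "event_day": np.nan,
                }
            )
            v += 1
    return pd.DataFrame(rows)
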