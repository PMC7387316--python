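"""Synthetic longitudinal cohort generator.

Emulates the data structure of a within-subject psychiatric cohort followed
over repeated testing visits: at each visit a short-term memory retention
score (Hopkins Verbal Learning Test retention, percent of earlier recall
retained at delayed recall) is measured and whole-blood gene expression is
profiled on a microarray-style platform (normalized log2 intensities with
Present/Absent detection calls).

The generator plants probesets whose expression tracks retention linearly on
the log2 scale, in a stated direction and with a stated effect size, plus a
time-to-event outcome (future positive neuropsychological testing) whose
hazard is log-linear in a planted marker-panel score.  Ground truth is
returned alongside the data so downstream recovery can be measured.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` substreams, so an identical
``(config, seed)`` regenerates identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENDERS = ("M", "F")
DIAGNOSES = ("BP", "MDD", "SZ", "SZA", "PTSD")

#: Gender x diagnosis sampling weights patterned on a male-predominant
#: psychiatric cohort (82% male; BP/MDD/SZA/SZ/PTSD mix).
DEFAULT_STRATA: tuple[tuple[tuple[str, str], float], ...] = tuple(
    ((g, d), gw * dw)
    for g, gw in (("M", 0.82), ("F", 0.18))
    for d, dw in (("BP", 0.34), ("MDD", 0.15), ("SZA", 0.23), ("SZ", 0.18), ("PTSD", 0.10))
)


class CohortConfigError(ValueError):
    """Raised when a :class:`CohortConfig` fails validation."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Units: expression values and ``effect_size``/``noise_sd``/baseline fields
    are log2 intensity units; retention fields are percent in [0, 100];
    ``effect_size`` is the log2 expression shift per 10 retention points;
    hazards are per day.
    """

    n_subjects: int = 150
    visits_range: tuple[int, int] = (2, 6)
    strata: tuple[tuple[tuple[str, str], float], ...] = DEFAULT_STRATA
    n_probesets: int = 1000
    n_planted_increased: int = 20
    n_planted_decreased: int = 20
    effect_size: float = 0.5
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_probe_sd: float = 1.5
    baseline_mean_sd: float = 0.5
    retention_mean: float = 60.0
    retention_between_sd: float = 12.0
    retention_within_sd: float = 12.0
    visit_interval_days_range: tuple[int, int] = (90, 180)
    panel_size: int = 10
    event_hazard_coefficient: float = 0.5
    event_base_hazard: float = 5e-5
    censor_day: float = 4600.0
    ap_call_threshold: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise CohortConfigError("n_subjects must be positive")
        if self.n_probesets <= 0:
            raise CohortConfigError("n_probesets must be positive")
        if self.n_planted_increased < 0 or self.n_planted_decreased < 0:
            raise CohortConfigError("planted counts must be non-negative")
        if self.n_planted_increased + self.n_planted_decreased > self.n_probesets:
            raise CohortConfigError("planted probesets exceed n_probesets")
        if not self.strata:
            raise CohortConfigError("strata must be non-empty")
        if any(w < 0 for _, w in self.strata) or sum(w for _, w in self.strata) <= 0:
            raise CohortConfigError("stratum weights must be non-negative with positive sum")
        lo, hi = self.visits_range
        if not (2 <= lo <= hi <= 6):
            raise CohortConfigError("visits_range must lie within [2, 6]")
        if self.effect_size < 0:
            raise CohortConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise CohortConfigError("noise_sd must be > 0")
        if self.censor_day < 0:
            raise CohortConfigError("censor_day must be >= 0")
        if self.event_base_hazard <= 0:
            raise CohortConfigError("event_base_hazard must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strata"] = [[list(k), w] for k, w in self.strata]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "strata" in d:
            d["strata"] = tuple((tuple(k), float(w)) for k, w in d["strata"])
        for key in ("visits_range", "visit_interval_days_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _streams(config: CohortConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate subject and visit tables.

    Returns
    -------
    subjects : DataFrame with columns subject_id, gender, diagnosis.
    visits : DataFrame with columns visit_id, subject_id, gender, diagnosis,
        day, retention, neuropsych_event, event_day.  Outcome columns are
        placeholders (False / NaN) until :func:`generate_outcomes` fills them.

    The retention model is a subject-level Gaussian mean
    ``N(retention_mean, retention_between_sd)`` plus i.i.d. Gaussian visit
    noise ``N(0, retention_within_sd)``, clipped to [0, 100].
    """
    config.validate()
    rng_subj, rng_visits, _, _ = _streams(config, 4)

    keys = [k for k, _ in config.strata]
    weights = np.array([w for _, w in config.strata], dtype=float)
    weights = weights / weights.sum()
    stratum_idx = rng_subj.choice(len(keys), size=config.n_subjects, p=weights)
    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(config.n_subjects)],
            "gender": [keys[i][0] for i in stratum_idx],
            "diagnosis": [keys[i][1] for i in stratum_idx],
        }
    )

    lo, hi = config.visits_range
    n_visits = rng_visits.integers(lo, hi + 1, size=config.n_subjects)
    subj_mean = rng_visits.normal(config.retention_mean, config.retention_between_sd, config.n_subjects)

    rows = []
    visit_counter = 0
    d_lo, d_hi = config.visit_interval_days_range
    for i, sub in subjects.iterrows():
        k = int(n_visits[i])
        intervals = rng_visits.integers(d_lo, d_hi + 1, size=k - 1)
        days = np.concatenate([[0], np.cumsum(intervals)])
        retention = np.clip(
            subj_mean[i] + rng_visits.normal(0.0, config.retention_within_sd, k), 0.0, 100.0
        )
        for j in range(k):
            rows.append(
                {
                    "visit_id": f"V{visit_counter:05d}",
                    "subject_id": sub.subject_id,
                    "gender": sub.gender,
                    "diagnosis": sub.diagnosis,
                    "day": int(days[j]),
                    "retention": float(retention[j]),
                    "neuropsych_event": False,
                    "event_day": np.nan,
                }
            )
            visit_counter += 1
    visits = pd.DataFrame(rows)
    return subjects, visits


def generate_expression(
    subjects: pd.DataFrame, visits: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the probeset x visit expression matrix, detection calls and truth.

    Planted *increased* probesets follow
    ``baseline + effect_size * (retention - retention_mean) / 10 + noise``;
    *decreased* probesets negate the slope; null probesets are baseline+noise.
    Baselines decompose into a per-probeset grand mean and a per-subject
    offset (between-subject variation).  Calls are Present where the value
    exceeds ``ap_call_threshold``, Absent otherwise.

    Returns (expression, calls, truth); truth has columns probeset_id,
    gene_symbol, direction, in_outcome_panel.  Probesets map 1:1 to synthetic
    gene symbols.
    """
    config.validate()
    if visits.empty:
        raise CohortConfigError("cohort has no visits")
    _, _, rng_expr, _ = _streams(config, 4)

    n_p = config.n_probesets
    probeset_ids = [f"P{i:05d}_at" for i in range(n_p)]
    gene_symbols = [f"GENE{i:05d}" for i in range(n_p)]

    n_inc, n_dec = config.n_planted_increased, config.n_planted_decreased
    direction = np.array(["null"] * n_p, dtype=object)
    direction[:n_inc] = "increased_in_high_memory"
    direction[n_inc : n_inc + n_dec] = "decreased_in_high_memory"
    slope_sign = np.zeros(n_p)
    slope_sign[:n_inc] = 1.0
    slope_sign[n_inc : n_inc + n_dec] = -1.0

    # Outcome panel: alternate increased/decreased planted markers.
    in_panel = np.zeros(n_p, dtype=bool)
    take_inc = min((config.panel_size + 1) // 2, n_inc)
    take_dec = min(config.panel_size - take_inc, n_dec)
    in_panel[:take_inc] = True
    in_panel[n_inc : n_inc + take_dec] = True

    grand = rng_expr.normal(config.baseline_mean, config.baseline_probe_sd, n_p)
    subj_index = {s: i for i, s in enumerate(subjects.subject_id)}
    subj_offset = rng_expr.normal(0.0, config.baseline_mean_sd, (n_p, len(subj_index)))

    n_v = len(visits)
    subj_col = visits.subject_id.map(subj_index).to_numpy()
    ret = visits.retention.to_numpy()
    signal = np.outer(slope_sign * config.effect_size, (ret - config.retention_mean) / 10.0)
    noise = rng_expr.normal(0.0, config.noise_sd, (n_p, n_v))
    values = grand[:, None] + subj_offset[:, subj_col] + signal + noise
    values = np.clip(values, 0.0, None)

    expr = pd.DataFrame(values, index=pd.Index(probeset_ids, name="probeset_id"),
                        columns=visits.visit_id.to_numpy())
    calls = pd.DataFrame(
        np.where(values > config.ap_call_threshold, "P", "A"),
        index=expr.index, columns=expr.columns,
    )
    truth = pd.DataFrame(
        {
            "probeset_id": probeset_ids,
            "gene_symbol": gene_symbols,
            "direction": direction,
            "in_outcome_panel": in_panel,
        }
    )
    return expr, calls, truth


def panel_truth_to_definition(truth: pd.DataFrame):
    """Panel definition [(probeset_id, risk direction)] for the planted panel.

    Markers increased in high memory are *decreased-risk* markers for the
    cognitive-decline outcome (and vice versa): low expression of a
    high-memory marker signals risk.
    """
    rows = truth[truth.in_outcome_panel]
    members = []
    for _, r in rows.iterrows():
        risk = "decreased_risk" if r.direction == "increased_in_high_memory" else "increased_risk"
        members.append((r.probeset_id, risk))
    return members


def generate_outcomes(
    visits: pd.DataFrame,
    expr: pd.DataFrame,
    truth: pd.DataFrame,
    config: CohortConfig,
) -> pd.DataFrame:
    """Attach time-to-event outcomes driven by the planted panel.

    Each visit draws an independent exponential event time with rate
    ``event_base_hazard * exp(event_hazard_coefficient * score)``, where
    ``score`` is the planted-panel score of that visit (sum of stratum
    Z-scored increased-risk members minus decreased-risk members, the same
    statistic the testing stage computes).  Follow-up is administratively
    censored at ``censor_day`` days after the visit.
    """
    from . import prediction

    config.validate()
    _, _, _, rng_ev = _streams(config, 4)

    visits = visits.copy()
    members = panel_truth_to_definition(truth)
    if members and config.event_hazard_coefficient != 0.0:
        z = pd.DataFrame(
            {
                pid: prediction.zscore_by_stratum(expr.loc[pid], visits)
                for pid, _ in members
            }
        ).T
        score = prediction.panel_score(z, members).reindex(visits.visit_id).to_numpy()
    else:
        score = np.zeros(len(visits))

    rate = config.event_base_hazard * np.exp(config.event_hazard_coefficient * score)
    t = rng_ev.exponential(1.0 / rate)
    event = t < config.censor_day
    visits["neuropsych_event"] = event
    visits["event_day"] = np.where(event, t, config.censor_day)
    return visits


def generate_evidence(
    truth: pd.DataFrame,
    config: CohortConfig,
    planted_line_prob: float = 0.7,
    null_line_prob: float = 0.02,
    disorder: str = "AD",
) -> pd.DataFrame:
    """Synthesize a curated literature-evidence table.

    Planted genes carry a record on each evidence line with probability
    ``planted_line_prob``; null genes with ``null_line_prob`` — emulating a
    field in which true memory/dementia biomarkers have accumulated
    convergent published evidence.  A second sweep adds cross-disorder tags
    (stress, aging, suicide) preferentially on planted genes.
    """
    from .cfg import EVIDENCE_LINES

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 977]).generate_state(1)[0])
    rows = []
    planted = truth.direction.ne("null").to_numpy()
    for i, r in truth.iterrows():
        p = planted_line_prob if planted[i] else null_line_prob
        for line in EVIDENCE_LINES:
            if rng.random() < p:
                dirn = rng.choice(["up", "down", "unspecified"])
                rows.append(
                    {
                        "gene_symbol": r.gene_symbol,
                        "line": line,
                        "direction": dirn,
                        "source_tag": f"synth:{r.gene_symbol}:{line}",
                        "disorder_tag": disorder,
                    }
                )
        for other in ("stress", "aging", "suicide"):
            if rng.random() < (0.5 if planted[i] else 0.05):
                rows.append(
                    {
                        "gene_symbol": r.gene_symbol,
                        "line": "human_peripheral_expression",
                        "direction": "unspecified",
                        "source_tag": f"synth:{r.gene_symbol}:{other}",
                        "disorder_tag": other,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_symbol", "line", "direction", "source_tag", "disorder_tag"])


@dataclass
class SyntheticStudy:
    """A fully generated study: cohort, expression, calls, truth, evidence."""

    config: CohortConfig
    subjects: pd.DataFrame
    visits: pd.DataFrame
    expression: pd.DataFrame
    calls: pd.DataFrame
    truth: pd.DataFrame
    evidence: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_study(config: CohortConfig, with_evidence: bool = True) -> SyntheticStudy:
    """Run the full generator: cohort -> expression -> outcomes (-> evidence)."""
    subjects, visits = generate_cohort(config)
    expr, calls, truth = generate_expression(subjects, visits, config)
    visits = generate_outcomes(visits, expr, truth, config)
    evidence = generate_evidence(truth, config) if with_evidence else pd.DataFrame()
    return SyntheticStudy(config, subjects, visits, expr, calls, truth, evidence)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write metadata/expression/calls/truth/evidence TSVs plus the config JSON."""
    from . import io as mio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": out / "metadata.tsv",
        "expression": out / "expression.tsv",
        "calls": out / "calls.tsv",
        "truth": out / "truth.tsv",
        "evidence": out / "evidence.tsv",
        "config": out / "config.json",
    }
    mio.write_metadata(study.visits, paths["metadata"])
    mio.write_expression(study.expression, paths["expression"])
    mio.write_calls(study.calls, paths["calls"])
    mio.write_table(study.truth, paths["truth"])
    mio.write_table(study.evidence, paths["evidence"])
    paths["config"].write_text(json.dumps(study.config.to_dict(), indent=2) + "\n")
    return paths
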