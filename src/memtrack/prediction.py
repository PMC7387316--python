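"""Step 3 — testing biomarkers in an independent cohort.

Two kinds of prediction, each run on all subjects and, in personalized
fashion, by gender and by gender x diagnosis:

* **state** — does the marker separate low-memory visits (retention <= 40)
  from the rest?  Measured by ROC AUC computed from the Mann-Whitney rank
  statistic, with a one-sided rank-test p-value (ties by midranks).
* **trait** — does the marker predict *future* positive neuropsychological
  testing for cognitive impairment?  A Cox proportional-hazards regression
  on the time in days from the testing visit to the positive test (censored
  at end of follow-up), with the marker measure as sole covariate.

Marker measures come in two modes: cross-sectional (the expression level at
one visit, Z-scored by gender and diagnosis) and longitudinal (a composite
of level, slope, running max level — min for decreased markers — and running
max slope, each Z-scored by stratum and summed; defined only for visits with
at least one prior visit).

Every measure is oriented by the marker's stated risk direction before
testing, so AUC > 0.5 and hazard ratio > 1 always mean "the marker's risk
direction predicts the adverse state/outcome".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOW_MEMORY_CUTOFF = 40.0

GROUPINGS = ("ALL", "gender", "gender_dx")


# ---------------------------------------------------------------------------
# normalization and panel composition

def zscore_by_stratum(values: pd.Series, meta: pd.DataFrame) -> pd.Series:
    """Z-score a per-visit series within each (gender, diagnosis) stratum.

    Uses the population SD convention (ddof=0), so every stratum has mean 0
    and SD exactly 1 afterwards.  Singleton or zero-variance strata cannot be
    standardized; their values become 0 with a warning.
    """
    meta = meta.set_index("visit_id") if "visit_id" in meta.columns else meta
    aligned = meta.loc[values.index]
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for (g, d), idx in aligned.groupby(["gender", "diagnosis"], sort=False).groups.items():
        v = values.loc[idx].astype(float)
        sd = v.std(ddof=0)
        if len(v) < 2 or sd == 0 or not np.isfinite(sd):
            logger.warning("stratum (%s, %s): cannot standardize (n=%d, sd=%s); set to 0",
                           g, d, len(v), sd)
            out.loc[idx] = 0.0
        else:
            out.loc[idx] = (v - v.mean()) / sd
    return out


def zscore_matrix_by_stratum(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`zscore_by_stratum` over a probeset x visit matrix."""
    meta = meta.set_index("visit_id") if "visit_id" in meta.columns else meta
    aligned = meta.loc[expr.columns]
    out = pd.DataFrame(0.0, index=expr.index, columns=expr.columns)
    for (g, d), idx in aligned.groupby(["gender", "diagnosis"], sort=False).groups.items():
        sub = expr[idx].astype(float)
        sd = sub.std(axis=1, ddof=0)
        ok = (sd > 0) & np.isfinite(sd) & (sub.shape[1] >= 2)
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd.where(ok, 1.0), axis=0)
        out[idx] = z.where(ok, 0.0)
        if not bool(np.all(ok)):
            logger.warning("stratum (%s, %s): %d probesets not standardizable; set to 0",
                           g, d, int((~ok).sum()))
    return out


def panel_score(z_values: pd.DataFrame, members: list[tuple[str, str]]) -> pd.Series:
    """Combine Z-scored markers into a panel score per visit.

    score = sum of increased-risk members minus sum of decreased-risk
    members.  ``z_values`` is probesets x visits; ``members`` is a list of
    (probeset_id, direction) with direction in {increased_risk,
    decreased_risk}.
    """
    if not members:
        raise ValueError("panel has no members")
    seen = set()
    total = pd.Series(0.0, index=z_values.columns, dtype=float)
    for pid, direction in members:
        if pid in seen:
            raise ValueError(f"duplicate panel member {pid!r}")
        seen.add(pid)
        if pid not in z_values.index:
            raise KeyError(f"panel member {pid!r} missing from matrix")
        sign = {"increased_risk": 1.0, "decreased_risk": -1.0}.get(direction)
        if sign is None:
            raise ValueError(f"unknown panel direction {direction!r}")
        total = total + sign * z_values.loc[pid].astype(float)
    return total


# ---------------------------------------------------------------------------
# longitudinal composite

def longitudinal_measure(
    levels: pd.Series,
    visits: pd.DataFrame,
    direction: str = "increased_risk",
    return_components: bool = False,
) -> pd.Series | pd.DataFrame:
    """Longitudinal composite measure per visit.

    For each subject with >= 2 visits, at each visit from the second on,
    compute on the normalized (pre-Z-score) expression levels:

    * level  ``L_t``
    * slope  ``(L_t / L_{t-1}) / (days between visits)``
    * running extreme of levels up to t (max for increased-risk markers,
      min for decreased-risk ones)
    * running max of slopes up to t

    Each of the four series is then Z-scored by gender and diagnosis across
    the cohort and summed.  Single-visit subjects contribute nothing; a zero
    previous level leaves that visit's slope undefined and the visit is
    excluded with a warning.
    """
    meta = visits.set_index("visit_id") if "visit_id" in visits.columns else visits
    rows = []
    for sid, grp in meta.loc[meta.index.intersection(levels.index)].groupby("subject_id", sort=False):
        grp = grp.sort_values("day")
        if len(grp) < 2:
            continue
        ids = grp.index.to_numpy()
        days = grp["day"].to_numpy(dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError(f"subject {sid}: visit days must be strictly increasing")
        lv = levels.loc[ids].to_numpy(dtype=float)
        slopes = np.full(len(ids), np.nan)
        for t in range(1, len(ids)):
            if lv[t - 1] == 0.0:
                logger.warning("subject %s: zero level at %s, slope undefined for %s",
                               sid, ids[t - 1], ids[t])
                continue
            slopes[t] = (lv[t] / lv[t - 1]) / (days[t] - days[t - 1])
        ext_fn = np.fmin if direction == "decreased_risk" else np.fmax
        for t in range(1, len(ids)):
            if np.isnan(slopes[t]):
                continue
            run_ext = ext_fn.reduce(lv[: t + 1])
            run_max_slope = np.nanmax(slopes[1 : t + 1])
            rows.append((ids[t], lv[t], slopes[t], run_ext, run_max_slope))
    if not rows:
        return pd.DataFrame() if return_components else pd.Series(dtype=float)
    df = pd.DataFrame(rows, columns=["visit_id", "level", "slope", "run_ext", "run_max_slope"])
    df = df.set_index("visit_id")
    if return_components:
        return df
    composite = sum(zscore_by_stratum(df[c], meta) for c in df.columns)
    return composite


# ---------------------------------------------------------------------------
# grouping helpers

def _iter_groups(meta: pd.DataFrame, grouping: str):
    if grouping == "ALL":
        yield "ALL", "ALL", pd.Series(True, index=meta.index)
    elif grouping == "gender":
        for g, idx in meta.groupby("gender").groups.items():
            yield "gender", str(g), meta.index.isin(idx)
    elif grouping == "gender_dx":
        for (g, d), idx in meta.groupby(["gender", "diagnosis"]).groups.items():
            yield "gender_dx", f"{g}-{d}", meta.index.isin(idx)
    else:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")


def _orient(measure: pd.Series, direction: str) -> pd.Series:
    if direction == "increased_risk":
        return measure.astype(float)
    if direction == "decreased_risk":
        return -measure.astype(float)
    raise ValueError(f"unknown risk direction {direction!r}")


# ---------------------------------------------------------------------------
# state prediction (ROC)

def rank_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC from the Mann-Whitney U statistic (midranks for ties)."""
    u = stats.mannwhitneyu(cases, controls, alternative="greater").statistic
    return float(u) / (len(cases) * len(controls))


def predict_state(
    measure: pd.Series,
    visits: pd.DataFrame,
    direction: str = "increased_risk",
    cutoff: float = LOW_MEMORY_CUTOFF,
    grouping: str = "ALL",
    marker: str = "marker",
    mode: str = "C",
) -> pd.DataFrame:
    """ROC analysis of a marker measure against the low-memory state.

    Visits (not subjects) are the unit of analysis.  A visit is a case when
    retention <= cutoff.  Groups with fewer than one case or one control are
    reported as untestable rows rather than raising.
    """
    meta = visits.set_index("visit_id") if "visit_id" in visits.columns else visits
    measure = measure.dropna()
    meta = meta.loc[meta.index.intersection(measure.index)]
    x = _orient(measure.loc[meta.index], direction)
    low = meta["retention"] <= cutoff
    rows = []
    for gtype, label, mask in _iter_groups(meta, grouping):
        xm, lm = x[mask], low[mask]
        n1, n0 = int(lm.sum()), int((~lm).sum())
        row = {
            "marker": marker, "mode": mode, "group_type": gtype, "group": label,
            "n_low": n1, "n_total": n1 + n0,
            "auc": np.nan, "p_value": np.nan, "testable": n1 >= 1 and n0 >= 1,
        }
        if row["testable"]:
            res = stats.mannwhitneyu(xm[lm], xm[~lm], alternative="greater")
            row["auc"] = float(res.statistic) / (n1 * n0)
            row["p_value"] = float(res.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait prediction (Cox)

def predict_trait(
    measure: pd.Series,
    visits: pd.DataFrame,
    direction: str = "increased_risk",
    grouping: str = "ALL",
    marker: str = "marker",
    mode: str = "C",
    cluster_by_subject: bool = False,
) -> pd.DataFrame:
    """Cox proportional-hazards test of a marker measure against the
    time-to-event outcome.

    Each visit is an observation; time runs from that visit to the positive
    neuropsychological test (``event_day``, with ``neuropsych_event``
    marking events vs censoring).  The hazard ratio is per unit of the
    oriented measure, so HR > 1 means increased risk along the marker's risk
    direction.  Groups with zero events are untestable; non-convergent fits
    are flagged, not raised.  ``cluster_by_subject`` requests robust
    (sandwich) standard errors clustered on subject, for repeated visits.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    meta = visits.set_index("visit_id") if "visit_id" in visits.columns else visits
    measure = measure.dropna()
    meta = meta.loc[meta.index.intersection(measure.index)]
    x = _orient(measure.loc[meta.index], direction)
    rows = []
    for gtype, label, mask in _iter_groups(meta, grouping):
        sub = meta[mask]
        n_events = int(sub["neuropsych_event"].sum())
        row = {
            "marker": marker, "mode": mode, "group_type": gtype, "group": label,
            "n_events": n_events, "n_total": len(sub),
            "hazard_ratio": np.nan, "p_value": np.nan,
            "testable": n_events >= 1, "converged": False,
        }
        if row["testable"]:
            df = pd.DataFrame(
                {
                    "duration": sub["event_day"].astype(float),
                    "event": sub["neuropsych_event"].astype(bool),
                    "x": x[mask].to_numpy(),
                }
            )
            if df["x"].std(ddof=0) == 0:
                row["testable"] = False
            else:
                cph = CoxPHFitter()
                kwargs = {}
                if cluster_by_subject:
                    df["subject_id"] = sub["subject_id"].to_numpy()
                    kwargs["cluster_col"] = "subject_id"
                    kwargs["robust"] = True
                try:
                    cph.fit(df, duration_col="duration", event_col="event", **kwargs)
                    row["hazard_ratio"] = float(np.exp(cph.params_["x"]))
                    row["p_value"] = float(cph.summary.loc["x", "p"])
                    row["converged"] = True
                except (ConvergenceError, ValueError) as exc:  # flagged, not fatal
                    logger.warning("Cox fit failed for group %s: %s", label, exc)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# high-level driver

@dataclass(frozen=True)
class Marker:
    """A testable marker: a single probeset or a named panel."""

    name: str
    members: tuple[tuple[str, str], ...]  # (probeset_id, risk direction)

    @classmethod
    def single(cls, probeset_id: str, direction: str) -> "Marker":
        return cls(probeset_id, ((probeset_id, direction),))


def marker_measures(
    expr: pd.DataFrame, visits: pd.DataFrame, marker: Marker
) -> dict[str, pd.Series]:
    """Cross-sectional (C) and longitudinal (L) measures for a marker.

    C: stratum Z-scored levels, combined across panel members by signed
    summation.  L: the longitudinal composite per member (computed on
    normalized levels, then stratum Z-scored internally), signed-summed
    across members.
    """
    meta = visits.set_index("visit_id") if "visit_id" in visits.columns else visits
    z = pd.DataFrame(
        {pid: zscore_by_stratum(expr.loc[pid], meta) for pid, _ in marker.members}
    ).T
    cross = panel_score(z, list(marker.members))

    longi = None
    for pid, direction in marker.members:
        comp = longitudinal_measure(expr.loc[pid], meta, direction)
        signed = comp if direction == "increased_risk" else -comp
        longi = signed if longi is None else longi.add(signed, fill_value=np.nan)
    return {"C": cross, "L": longi if longi is not None else pd.Series(dtype=float)}


def test_marker(
    expr: pd.DataFrame,
    visits: pd.DataFrame,
    marker: Marker,
    cutoff: float = LOW_MEMORY_CUTOFF,
    cluster_by_subject: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run state and trait predictions for a marker in every grouping/mode.

    Because measures are already oriented member-by-member inside
    ``marker_measures`` (signed summation), the combined measure is treated
    as increased-risk.  Returns (state_results, trait_results).
    """
    measures = marker_measures(expr, visits, marker)
    state_frames, trait_frames = [], []
    for mode, measure in measures.items():
        if measure.empty:
            continue
        for grouping in GROUPINGS:
            state_frames.append(
                predict_state(measure, visits, "increased_risk", cutoff, grouping,
                              marker=marker.name, mode=mode)
            )
            trait_frames.append(
                predict_trait(measure, visits, "increased_risk", grouping,
                              marker=marker.name, mode=mode,
                              cluster_by_subject=cluster_by_subject)
            )
    state = pd.concat(state_frames, ignore_index=True) if state_frames else pd.DataFrame()
    trait = pd.concat(trait_frames, ignore_index=True) if trait_frames else pd.DataFrame()
    return state, trait
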