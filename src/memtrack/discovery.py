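"""Step 1 — within-subject discovery of probesets that track memory retention.

A subject whose retention score changes by at least 20% (relative to the
earlier visit) between two consecutive testing visits contributes a
high-memory vs low-memory comparison pair.  Each probeset is scored per pair
by two methods:

* DE (differential expression): fold change ``2**(log2 high - log2 low)``;
  at least 1.2-fold gives +1/-1 (sign = increased/decreased in the
  high-memory visit), between 1.1- and 1.2-fold gives +0.5/-0.5, below
  1.1-fold gives 0.
* AP (absent/present): a detection-call flip, Present at the high-memory
  visit and Absent at the low one, gives +1; the reverse flip gives -1;
  no flip gives 0 — capturing genes turning on/off.

Per-pair scores are summed across all pairs and subjects into a raw score
per probeset, then converted to internal points by percent of the maximum
absolute raw score per method: >=80% -> 6, >=50% -> 4, >=33.3% -> 2
(boundaries inclusive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal-point tiers as (percent-of-max threshold, points), highest first.
INTERNAL_TIERS: tuple[tuple[float, int], ...] = ((80.0, 6), (50.0, 4), (33.3, 2))

DE_FOLD_FULL = 1.2
DE_FOLD_HALF = 1.1


@dataclass(frozen=True)
class ComparisonPair:
    """One within-subject high- vs low-memory visit comparison."""

    subject_id: str
    high_visit_id: str
    low_visit_id: str
    retention_high: float
    retention_low: float
    relative_change: float


def select_comparison_pairs(
    visits: pd.DataFrame, change_threshold: float = 0.20
) -> list[ComparisonPair]:
    """Find every consecutive visit pair with a qualifying retention change.

    ``visits`` needs columns subject_id, visit_id, day, retention.  The
    relative change is measured against the earlier visit,
    ``|R2 - R1| / R1``; the visit with the higher retention is labeled high.
    A zero earlier retention qualifies iff the later one is positive
    (treated as a maximal change) and is logged.  Visits with missing
    retention are skipped with a warning.
    """
    pairs: list[ComparisonPair] = []
    for sid, grp in visits.groupby("subject_id", sort=True):
        grp = grp.sort_values("day")
        rows = list(grp.itertuples())
        for a, b in zip(rows, rows[1:]):
            if pd.isna(a.retention) or pd.isna(b.retention):
                logger.warning("subject %s: missing retention, pair (%s, %s) skipped",
                               sid, a.visit_id, b.visit_id)
                continue
            r1, r2 = float(a.retention), float(b.retention)
            if r1 == 0.0:
                if r2 <= 0.0:
                    continue
                logger.warning("subject %s: zero baseline retention at %s treated as maximal change",
                               sid, a.visit_id)
                rel = math.inf
            else:
                rel = abs(r2 - r1) / r1
            if rel < change_threshold:
                continue
            hi, lo = (b, a) if r2 > r1 else (a, b)
            pairs.append(
                ComparisonPair(
                    subject_id=str(sid),
                    high_visit_id=hi.visit_id,
                    low_visit_id=lo.visit_id,
                    retention_high=max(r1, r2),
                    retention_low=min(r1, r2),
                    relative_change=rel,
                )
            )
    return pairs


def score_pair_de(expr: pd.DataFrame, pair: ComparisonPair) -> pd.Series:
    """DE scores for one pair: per-probeset values in {-1, -0.5, 0, +0.5, +1}."""
    for v in (pair.high_visit_id, pair.low_visit_id):
        if v not in expr.columns:
            raise KeyError(f"visit {v!r} not present in expression matrix")
    d = expr[pair.high_visit_id] - expr[pair.low_visit_id]
    return _de_from_log2_diff(d)


def _de_from_log2_diff(d: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    # closed boundaries at 1.1 and 1.2, compared on the log2 scale with a
    # one-part-in-1e9 tolerance so a difference of exactly log2(1.2) scores
    # full points regardless of float round-trip error
    eps = 1e-9
    mag_d = np.abs(np.asarray(d, dtype=float))
    mag = np.where(mag_d >= np.log2(DE_FOLD_FULL) - eps, 1.0,
                   np.where(mag_d >= np.log2(DE_FOLD_HALF) - eps, 0.5, 0.0))
    out = np.sign(d) * mag
    if isinstance(d, pd.Series):
        return pd.Series(out, index=d.index)
    return out


def score_pair_ap(calls: pd.DataFrame, pair: ComparisonPair) -> pd.Series:
    """AP scores for one pair: +1 for an off->on flip into the high-memory
    visit, -1 for on->off, 0 otherwise."""
    for v in (pair.high_visit_id, pair.low_visit_id):
        if v not in calls.columns:
            raise KeyError(f"visit {v!r} not present in call matrix")
    hi = calls[pair.high_visit_id].to_numpy()
    lo = calls[pair.low_visit_id].to_numpy()
    score = np.where((hi == "P") & (lo == "A"), 1.0, np.where((hi == "A") & (lo == "P"), -1.0, 0.0))
    return pd.Series(score, index=calls.index)


def sum_raw_scores(
    pairs: list[ComparisonPair],
    expr: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    method: str = "DE",
) -> pd.Series:
    """Sum per-pair scores across all comparisons into a raw score per probeset.

    Vectorized over pairs; covers every probeset in the matrix (probesets
    never scoring contribute 0).
    """
    if method == "DE":
        if expr is None:
            raise ValueError("DE scoring requires the expression matrix")
        index = expr.index
        if not pairs:
            return pd.Series(0.0, index=index)
        hi = expr[[p.high_visit_id for p in pairs]].to_numpy()
        lo = expr[[p.low_visit_id for p in pairs]].to_numpy()
        scores = _de_from_log2_diff(hi - lo)
        return pd.Series(scores.sum(axis=1), index=index)
    if method == "AP":
        if calls is None:
            logger.warning("AP scoring skipped: no call matrix supplied")
            return pd.Series(dtype=float)
        index = calls.index
        if not pairs:
            return pd.Series(0.0, index=index)
        hi = calls[[p.high_visit_id for p in pairs]].to_numpy()
        lo = calls[[p.low_visit_id for p in pairs]].to_numpy()
        scores = np.where((hi == "P") & (lo == "A"), 1.0,
                          np.where((hi == "A") & (lo == "P"), -1.0, 0.0))
        return pd.Series(scores.sum(axis=1), index=index)
    raise ValueError(f"unknown method {method!r}")


def points_from_percent(percent_of_max: float, tiers=INTERNAL_TIERS) -> int:
    """Map a percent-of-maximum raw score to internal points (6/4/2/0)."""
    for threshold, pts in tiers:
        if percent_of_max >= threshold:
            return pts
    return 0


def assign_internal_points(raw_scores: pd.Series, method: str) -> pd.DataFrame:
    """Convert raw scores to internal discovery points for one method.

    percent_of_max = 100 * |raw| / max |raw| over all probesets (per method);
    direction follows the sign of the raw score.  An all-zero raw-score
    vector yields all-zero points with a warning.
    """
    raw = raw_scores.astype(float)
    max_abs = raw.abs().max()
    if not np.isfinite(max_abs) or max_abs == 0:
        logger.warning("all raw scores are zero for method %s; no internal points assigned", method)
        pct = pd.Series(0.0, index=raw.index)
    else:
        pct = 100.0 * raw.abs() / max_abs
    points = pct.map(points_from_percent).astype(int)
    direction = pd.Series(
        np.where(raw > 0, "increased", np.where(raw < 0, "decreased", "none")),
        index=raw.index,
    )
    return pd.DataFrame(
        {
            "probeset_id": raw.index,
            "method": method,
            "raw_score": raw.to_numpy(),
            "percent_of_max": pct.to_numpy(),
            "direction": direction.to_numpy(),
            "internal_points": points.to_numpy(),
        }
    ).set_index("probeset_id", drop=False)


def combine_methods(de: pd.DataFrame, ap: pd.DataFrame | None) -> pd.DataFrame:
    """Combine DE and AP internal points per probeset.

    The combined score is the maximum of the two methods' points; the
    direction follows the max-scoring method (DE wins ties).  Probesets whose
    methods give nonzero points in opposite directions are flagged.
    """
    if ap is None or ap.empty:
        out = de[["probeset_id", "internal_points", "direction"]].copy()
        out["conflict"] = False
        out["best_method"] = "DE"
        out["raw_score"] = de["raw_score"]
        return out
    idx = de.index.union(ap.index)
    de = de.reindex(idx)
    ap = ap.reindex(idx)
    de_pts = de["internal_points"].fillna(0).astype(int)
    ap_pts = ap["internal_points"].fillna(0).astype(int)
    de_wins = de_pts >= ap_pts
    out = pd.DataFrame(index=idx)
    out["probeset_id"] = idx
    out["internal_points"] = np.where(de_wins, de_pts, ap_pts)
    out["direction"] = np.where(de_wins, de["direction"], ap["direction"])
    out["best_method"] = np.where(de_wins, "DE", "AP")
    out["raw_score"] = np.where(de_wins, de["raw_score"], ap["raw_score"])
    out["conflict"] = (
        (de_pts > 0) & (ap_pts > 0) & (de["direction"] != ap["direction"])
    )
    n_conflicts = int(out["conflict"].sum())
    if n_conflicts:
        logger.warning("%d probesets have conflicting DE/AP directions", n_conflicts)
    return out


def run_discovery(
    expr: pd.DataFrame,
    calls: pd.DataFrame | None,
    visits: pd.DataFrame,
    change_threshold: float = 0.20,
) -> pd.DataFrame:
    """Full Step 1: pairs -> per-method raw scores/points -> combined table.

    Returns a long table with one row per (probeset, method) plus a
    ``COMBINED`` pseudo-method row carrying the max-points combination used
    by prioritization.
    """
    pairs = select_comparison_pairs(visits, change_threshold)
    logger.info("discovery: %d qualifying comparison pairs", len(pairs))
    de = assign_internal_points(sum_raw_scores(pairs, expr=expr, method="DE"), "DE")
    frames = [de]
    ap = None
    if calls is not None and not calls.empty:
        ap = assign_internal_points(sum_raw_scores(pairs, calls=calls, method="AP"), "AP")
        frames.append(ap)
    combined = combine_methods(de, ap)
    combined = combined.assign(
        method="COMBINED",
        percent_of_max=np.nan,
    )[["probeset_id", "method", "raw_score", "percent_of_max", "direction", "internal_points"]]
    long = pd.concat(
        [f[["probeset_id", "method", "raw_score", "percent_of_max", "direction", "internal_points"]]
         for f in frames]
        + [combined],
        ignore_index=True,
    )
    return long
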