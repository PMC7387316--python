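"""Step 2 — Convergent Functional Genomics (CFG) prioritization.

Candidate genes from discovery are scored against a curated database of
published evidence lines.  Each of six lines of evidence is *capped*: any
positive finding on a line earns that line's full weight, no matter how many
studies support it (avoiding popularity bias).  Human evidence outweighs
non-human, brain outweighs peripheral/genetic:

====================================  ===
human genetic                           2
human brain expression                  4
human peripheral expression             2
non-human genetic                       1
non-human brain expression              2
non-human peripheral expression         1
====================================  ===

External points therefore max out at 12; adding the internal discovery score
(max 6) gives a total CFG score capped at 18.  Candidates are carried
forward at total >= 10 (top candidates >= 12).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVIDENCE_LINES = (
    "human_genetic",
    "human_brain_expression",
    "human_peripheral_expression",
    "nonhuman_genetic",
    "nonhuman_brain_expression",
    "nonhuman_peripheral_expression",
)

DEFAULT_LINE_CAPS: dict[str, float] = {
    "human_genetic": 2.0,
    "human_brain_expression": 4.0,
    "human_peripheral_expression": 2.0,
    "nonhuman_genetic": 1.0,
    "nonhuman_brain_expression": 2.0,
    "nonhuman_peripheral_expression": 1.0,
}

MAX_EXTERNAL = 12.0
MAX_INTERNAL = 6
MAX_TOTAL = 18.0

DEFAULT_CFG_THRESHOLD = 10.0
TOP_CFG_THRESHOLD = 12.0


@dataclass(frozen=True)
class LineWeights:
    """Per-line caps; defaults sum to the 12-point external maximum."""

    caps: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LINE_CAPS))

    def __post_init__(self):
        unknown = set(self.caps) - set(EVIDENCE_LINES)
        if unknown:
            raise ValueError(f"unknown evidence lines: {sorted(unknown)}")

    @property
    def max_external(self) -> float:
        return float(sum(self.caps.values()))


def validate_evidence(records: pd.DataFrame) -> pd.DataFrame:
    """Check the evidence table's line vocabulary; returns the table."""
    if records.empty:
        return records
    bad = ~records["line"].isin(EVIDENCE_LINES)
    if bad.any():
        first = records.loc[bad].iloc[0]
        raise ValueError(
            f"unknown evidence line {first['line']!r} for gene {first['gene_symbol']!r}"
        )
    return records


def score_external(
    gene_symbol: str,
    records: pd.DataFrame,
    weights: LineWeights | None = None,
    disorder_filter: str | None = "AD",
) -> float:
    """Capped external CFG score for one gene.

    Each evidence line with at least one record (after the disorder filter)
    contributes its full cap; extra studies on the same line add nothing.
    """
    weights = weights or LineWeights()
    validate_evidence(records)
    if records.empty:
        return 0.0
    sub = records[records["gene_symbol"] == gene_symbol]
    if disorder_filter is not None and "disorder_tag" in sub.columns:
        sub = sub[sub["disorder_tag"] == disorder_filter]
    lines_present = set(sub["line"].unique())
    return float(sum(cap for line, cap in weights.caps.items() if line in lines_present))


def score_external_all(
    records: pd.DataFrame,
    weights: LineWeights | None = None,
    disorder_filter: str | None = "AD",
) -> pd.Series:
    """Vectorized external scores for every gene appearing in the table."""
    weights = weights or LineWeights()
    validate_evidence(records)
    if records.empty:
        return pd.Series(dtype=float, name="external_points")
    sub = records
    if disorder_filter is not None and "disorder_tag" in sub.columns:
        sub = sub[sub["disorder_tag"] == disorder_filter]
    caps = pd.Series(weights.caps)
    present = sub.drop_duplicates(["gene_symbol", "line"])
    scores = (
        present.assign(cap=present["line"].map(caps))
        .groupby("gene_symbol")["cap"]
        .sum()
    )
    return scores.rename("external_points")


def total_cfg(internal_points: int, external_points: float) -> float:
    """Total CFG score = internal (0/2/4/6) + capped external (0..12)."""
    if internal_points not in (0, 2, 4, 6):
        raise ValueError(f"internal_points must be in {{0,2,4,6}}, got {internal_points}")
    if not (0.0 <= external_points <= MAX_EXTERNAL):
        raise ValueError(f"external_points must lie in [0, {MAX_EXTERNAL}], got {external_points}")
    return float(internal_points) + float(external_points)


def prioritize(
    discovery: pd.DataFrame,
    evidence: pd.DataFrame,
    gene_map: pd.DataFrame | None = None,
    weights: LineWeights | None = None,
    disorder_filter: str | None = "AD",
    threshold: float = DEFAULT_CFG_THRESHOLD,
) -> pd.DataFrame:
    """Score every discovered probeset: internal + broadcast gene-level external.

    ``discovery`` is the COMBINED rows of the Step 1 output (probeset_id,
    internal_points, direction, raw_score).  ``gene_map`` maps probeset_id ->
    gene_symbol (one primary symbol per probeset); gene-level external scores
    are broadcast to all probesets of the gene while internal points stay
    probeset-level.
    """
    d = discovery.reset_index(drop=True).copy()
    if gene_map is not None:
        mapping = gene_map.set_index("probeset_id")["gene_symbol"]
        d["gene_symbol"] = d["probeset_id"].map(mapping)
    elif "gene_symbol" not in d.columns:
        d["gene_symbol"] = d["probeset_id"]
    ext = score_external_all(evidence, weights, disorder_filter)
    d["external_points"] = d["gene_symbol"].map(ext).fillna(0.0)
    d["total"] = [
        total_cfg(int(i), float(e)) for i, e in zip(d["internal_points"], d["external_points"])
    ]
    d["selected"] = d["total"] >= threshold
    d = d.sort_values(
        by=["total", "raw_score", "probeset_id"],
        key=lambda s: s.abs() if s.name == "raw_score" else s,
        ascending=[False, False, True],
    ).reset_index(drop=True)
    return d[
        ["probeset_id", "gene_symbol", "internal_points", "external_points",
         "total", "direction", "raw_score", "selected"]
    ]


def select_candidates(scores: pd.DataFrame, threshold: float = DEFAULT_CFG_THRESHOLD) -> pd.DataFrame:
    """Probesets with total CFG >= threshold, deterministically ordered.

    Order: total desc, |raw score| desc, probeset_id asc.  The unique gene
    count is logged (the paper-style "n probesets, m genes" report).
    """
    sel = scores[scores["total"] >= threshold].copy()
    raw = sel["raw_score"].abs() if "raw_score" in sel.columns else 0.0
    sel = sel.assign(_absraw=raw).sort_values(
        ["total", "_absraw", "probeset_id"], ascending=[False, False, True]
    ).drop(columns="_absraw").reset_index(drop=True)
    n_genes = sel["gene_symbol"].nunique() if "gene_symbol" in sel.columns else len(sel)
    logger.info("CFG >= %s: %d probesets, %d genes", threshold, len(sel), n_genes)
    return sel
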