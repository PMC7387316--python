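"""Convergent Functional Evidence (CFE) tabulation and enrichment statistics.

The CFE score summarizes, per biomarker, every stage of the pipeline on a
30-point scale: discovery (up to 6 internal points), prioritization (up to
12 external literature points), state prediction and trait prediction (up to
6 points each).  Prediction points are tiered by the most general group in
which the marker significantly predicts (nominal p < 0.05): all subjects ->
6, a gender subgroup -> 4, a gender x diagnosis subgroup -> 2, none -> 0;
either cross-sectional or longitudinal results may furnish the tier.

Also implemented here: the funnel "survival" enrichment fold (how many of
the array's probesets survive a pipeline stage) and set-enrichment folds
such as circadian clock-gene enrichment against a genome-wide reference,
with the reporting convention used for printed folds (nearest 0.1 below 10,
nearest integer from 10 to 100, nearest hundred above).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SIGNIFICANCE = 0.05

MAX_DISCOVERY = 6
MAX_EXTERNAL = 12.0
MAX_PREDICTION = 6
MAX_CFE = 30.0

#: Prediction-point tiers: most general significant group wins.
PREDICTION_TIERS = (("ALL", 6), ("gender", 4), ("gender_dx", 2))

#: Circadian clock-gene database shape: class -> gene count.
CLOCK_CLASS_COUNTS = {"core": 18, "immediate": 331, "distant": 1119}
CLOCK_TOTAL = sum(CLOCK_CLASS_COUNTS.values())  # 1468
GENOME_SIZE = 21000


def prediction_points(results: pd.DataFrame, alpha: float = SIGNIFICANCE) -> int:
    """Points for one marker's state (or trait) results across groupings.

    ``results`` rows need ``group_type`` in {ALL, gender, gender_dx} and
    ``p_value``; both cross-sectional and longitudinal rows may be present
    and either can furnish the tier.  Returns 6/4/2/0 for the *best* tier
    achieved (tiers do not add).
    """
    if results is None or len(results) == 0:
        return 0
    sig = results[(results["p_value"].notna()) & (results["p_value"] < alpha)]
    for group_type, pts in PREDICTION_TIERS:
        if (sig["group_type"] == group_type).any():
            return pts
    return 0


@dataclass(frozen=True)
class CFEScore:
    probeset_id: str
    gene_symbol: str
    discovery_points: int
    external_points: float
    state_points: int
    trait_points: int

    @property
    def total(self) -> float:
        return self.discovery_points + self.external_points + self.state_points + self.trait_points


def cfe_total(
    discovery_points: int,
    external_points: float,
    state_points: int,
    trait_points: int,
) -> float:
    """Total CFE score: discovery + external + state tier + trait tier (<= 30)."""
    if discovery_points not in (0, 2, 4, 6):
        raise ValueError(f"discovery_points must be in {{0,2,4,6}}, got {discovery_points}")
    if not (0.0 <= external_points <= MAX_EXTERNAL):
        raise ValueError(f"external_points must lie in [0, {MAX_EXTERNAL}]")
    for name, pts in (("state_points", state_points), ("trait_points", trait_points)):
        if pts not in (0, 2, 4, 6):
            raise ValueError(f"{name} must be in {{0,2,4,6}}, got {pts}")
    return float(discovery_points) + float(external_points) + state_points + trait_points


def tabulate_cfe(
    prioritization: pd.DataFrame,
    state_results: pd.DataFrame,
    trait_results: pd.DataFrame,
    alpha: float = SIGNIFICANCE,
) -> pd.DataFrame:
    """Build the CFE table for every marker in the prioritization output.

    State/trait results are matched on their ``marker`` column (probeset id
    or panel name).  The report is sorted by total desc, then |raw score|
    desc, then probeset id asc.
    """
    rows = []
    for _, r in prioritization.iterrows():
        pid = r["probeset_id"]
        st = state_results[state_results["marker"] == pid] if len(state_results) else state_results
        tr = trait_results[trait_results["marker"] == pid] if len(trait_results) else trait_results
        sp = prediction_points(st, alpha)
        tp = prediction_points(tr, alpha)
        rows.append(
            {
                "probeset_id": pid,
                "gene_symbol": r.get("gene_symbol", pid),
                "discovery_points": int(r["internal_points"]),
                "external_points": float(r["external_points"]),
                "state_points": sp,
                "trait_points": tp,
                "total": cfe_total(int(r["internal_points"]), float(r["external_points"]), sp, tp),
                "raw_score": float(r.get("raw_score", 0.0)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.assign(_absraw=out["raw_score"].abs()).sort_values(
            ["total", "_absraw", "probeset_id"], ascending=[False, False, True]
        ).drop(columns="_absraw").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# enrichment statistics

def render_fold(fold: float) -> float:
    """Round a fold for reporting: nearest 0.1 below 10, nearest integer in
    [10, 100], nearest hundred above 100."""
    if fold < 10:
        return round(fold, 1)
    if fold <= 100:
        return float(round(fold))
    return float(round(fold / 100.0) * 100)


@dataclass(frozen=True)
class EnrichmentResult:
    selected_in_set: int
    selected_total: int
    reference_in_set: int
    reference_total: int

    @property
    def selected_fraction(self) -> float:
        """Percent of the selected list in the gene set."""
        return 100.0 * self.selected_in_set / self.selected_total

    @property
    def reference_fraction(self) -> float:
        return 100.0 * self.reference_in_set / self.reference_total

    @property
    def fold(self) -> float:
        return self.selected_fraction / self.reference_fraction

    @property
    def fold_rendered(self) -> float:
        return render_fold(self.fold)


def enrichment_fold(
    selected_in_set: int,
    selected_total: int,
    reference_in_set: int,
    reference_total: int,
) -> EnrichmentResult:
    """Fold enrichment of a gene set in a selected list vs a reference pool.

    E.g. circadian genes among candidate biomarkers vs their genome-wide
    fraction.  Raises if the reference fraction is zero (fold undefined).
    """
    if selected_total <= 0 or reference_total <= 0:
        raise ValueError("totals must be positive")
    if selected_in_set > selected_total or reference_in_set > reference_total:
        raise ValueError("counts cannot exceed totals")
    if reference_in_set == 0:
        raise ValueError("reference fraction is zero; fold undefined")
    return EnrichmentResult(selected_in_set, selected_total, reference_in_set, reference_total)


def survival_fold(n_survivors: int, n_total_probesets: int) -> float:
    """Funnel enrichment: array size / probesets surviving a stage."""
    if n_survivors <= 0:
        raise ValueError("zero survivors; fold undefined")
    if n_survivors > n_total_probesets:
        raise ValueError("survivors exceed the array size")
    return n_total_probesets / n_survivors


def load_clock_db(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a clock-gene table (gene_symbol, class in core/immediate/distant)."""
    bad = ~table["class"].isin(CLOCK_CLASS_COUNTS)
    if bad.any():
        raise ValueError(f"unknown clock class {table.loc[bad, 'class'].iloc[0]!r}")
    if table["gene_symbol"].duplicated().any():
        raise ValueError("duplicate gene in clock database")
    return table


def clock_enrichment(
    candidate_genes: list[str],
    clock_db: pd.DataFrame,
    genome_size: int = GENOME_SIZE,
) -> EnrichmentResult:
    """Circadian enrichment of a candidate gene list against the genome."""
    clock = set(load_clock_db(clock_db)["gene_symbol"])
    genes = set(candidate_genes)
    return enrichment_fold(len(genes & clock), len(genes), len(clock), genome_size)


def annotate_cross_disorder(
    genes: list[str], evidence: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene disorder evidence table plus summary overlap percentages.

    For each gene, the set of disorder tags with at least one evidence
    record (duplicates counted once).  The summary maps each disorder to the
    percent of input genes carrying it.
    """
    per_gene = []
    if len(evidence) and "disorder_tag" in evidence.columns:
        grouped = evidence.groupby("gene_symbol")["disorder_tag"].agg(lambda s: sorted(set(s)))
    else:
        grouped = pd.Series(dtype=object)
    for g in genes:
        tags = grouped.get(g, [])
        per_gene.append({"gene_symbol": g, "disorders": ";".join(tags), "n_disorders": len(tags)})
    table = pd.DataFrame(per_gene)
    summary: dict[str, float] = {}
    if genes:
        all_tags = sorted({t for row in per_gene for t in (row["disorders"].split(";") if row["disorders"] else [])})
        for t in all_tags:
            n = sum(1 for row in per_gene if t in row["disorders"].split(";"))
            summary[t] = 100.0 * n / len(genes)
    return table, summary
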