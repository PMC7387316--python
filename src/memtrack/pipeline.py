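"""End-to-end pipeline driver with a reproducibility manifest.

Stages: simulate -> discover -> prioritize -> predict-state -> predict-trait
-> cfe -> enrich.  Every stage writes its TSV under the output directory;
the manifest records the configuration snapshot, seed, package version and
SHA-256 digests of every stage output, so a re-run with the same seed can be
verified byte-for-byte (the manifest's own timestamp is excluded from that
comparison).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__, cfe, cfg, cohort, discovery, io, prediction

logger = logging.getLogger(__name__)

STAGES = ("simulate", "discover", "prioritize", "predict_state", "predict_trait", "cfe", "enrich")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: cohort.CohortConfig,
    out_dir: str | Path,
    seed: int | None = None,
    cfg_threshold: float = cfg.DEFAULT_CFG_THRESHOLD,
    change_threshold: float = 0.20,
    max_tested_markers: int = 25,
    timestamps: bool = True,
) -> dict:
    """Run the full synthetic pipeline and return the manifest dict.

    ``max_tested_markers`` bounds how many top CFG candidates (plus the
    planted panel) are carried into the testing stage, keeping runtime
    proportional to the interesting part of the ranking.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = cohort.CohortConfig.from_dict({**config.to_dict(), "seed": int(seed)})

    outputs: dict[str, Path] = {}
    stage = "simulate"
    try:
        study = cohort.generate_study(config)
        outputs.update(cohort.write_study(study, out))

        stage = "discover"
        disc = discovery.run_discovery(study.expression, study.calls, study.visits, change_threshold)
        outputs["discovery"] = out / "discovery.tsv"
        io.write_table(disc, outputs["discovery"])
        combined = disc[disc["method"] == "COMBINED"].set_index("probeset_id", drop=False)
        n_pairs = len(discovery.select_comparison_pairs(study.visits, change_threshold))
        n_scored = int((combined["internal_points"] >= 2).sum())
        logger.info("funnel: %d probesets on array, %d with internal >= 2",
                    config.n_probesets, n_scored)

        stage = "prioritize"
        gene_map = study.truth[["probeset_id", "gene_symbol"]]
        prio = cfg.prioritize(combined, study.evidence, gene_map, threshold=cfg_threshold)
        outputs["prioritization"] = out / "prioritization.tsv"
        io.write_table(prio, outputs["prioritization"])
        selected = cfg.select_candidates(prio, cfg_threshold)

        stage = "predict_state"
        tested = selected.head(max_tested_markers)
        markers = [
            prediction.Marker.single(
                r.probeset_id,
                "decreased_risk" if r.direction == "increased" else "increased_risk",
            )
            for r in tested.itertuples()
            if r.direction in ("increased", "decreased")
        ]
        panel_members = cohort.panel_truth_to_definition(study.truth)
        if panel_members:
            markers.append(prediction.Marker("PLANTED_PANEL", tuple(panel_members)))
        state_frames, trait_frames = [], []
        for m in markers:
            st, tr = prediction.test_marker(study.expression, study.visits, m)
            state_frames.append(st)
            trait_frames.append(tr)
        state = pd.concat(state_frames, ignore_index=True) if state_frames else pd.DataFrame()
        outputs["state"] = out / "state.tsv"
        io.write_table(state, outputs["state"])

        stage = "predict_trait"
        trait = pd.concat(trait_frames, ignore_index=True) if trait_frames else pd.DataFrame()
        outputs["trait"] = out / "trait.tsv"
        io.write_table(trait, outputs["trait"])

        stage = "cfe"
        cfe_table = cfe.tabulate_cfe(
            prio[prio["probeset_id"].isin(tested["probeset_id"])], state, trait
        )
        outputs["cfe"] = out / "cfe.tsv"
        io.write_table(cfe_table, outputs["cfe"])

        stage = "enrich"
        planted_genes = set(study.truth.loc[study.truth.direction != "null", "gene_symbol"])
        sel_genes = set(selected["gene_symbol"])
        enrich = {
            "survival_fold_internal": cfe.survival_fold(max(n_scored, 1), config.n_probesets),
            "survival_fold_cfg": cfe.survival_fold(max(len(selected), 1), config.n_probesets),
            "n_pairs": n_pairs,
            "n_internal_ge2": n_scored,
            "n_selected_probesets": int(len(selected)),
            "n_selected_genes": int(selected["gene_symbol"].nunique()),
            "planted_fraction_selected": (
                100.0 * len(sel_genes & planted_genes) / len(sel_genes) if sel_genes else 0.0
            ),
            "planted_fraction_genome": 100.0 * len(planted_genes) / config.n_probesets,
        }
        outputs["enrichment"] = out / "enrichment.json"
        outputs["enrichment"].write_text(json.dumps(enrich, indent=2, sort_keys=True) + "\n")
    except Exception as exc:  # partial outputs are retained on disk
        raise StageError(stage, exc) from exc

    manifest = {
        "tool": "memtrack",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "cfg_threshold": cfg_threshold,
        "change_threshold": change_threshold,
        "stages": list(STAGES),
        "outputs": {k: {"path": str(p), "sha256": _digest(p)} for k, p in outputs.items()},
    }
    if timestamps:
        manifest["completed_at"] = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
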