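"""One-command orchestration: visit log in, analysis report out.

Stages run in order: ingest -> bout segmentation -> motivated-bee filter ->
eight-bout bins -> visitation matrices -> per-bee metrics -> modularity with
fixed-margins nulls -> persistence of bee-flower associations -> (optional)
interaction models. All intermediate tables are written under the output
directory and the JSON report reconciles with them; a master seed fans out
to per-stage substreams so any stage can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .interactions import (
    build_interaction_table,
    build_revisit_table,
    classify_interaction,
    fit_replacement_model,
    fit_revisit_model,
    read_interaction_log,
)
from .metrics import compute_metrics, fit_modularity_lm, fit_specificity_lmm, variance_inflation
from .modularity import dirt_lpa_wb_plus
from .nullmodels import modularity_zscore
from .persistence import association_counts, persistence_table
from .visitlog import (
    VisitLog,
    bin_by_bouts,
    build_visitation_matrix,
    filter_motivated,
    read_visit_log,
    segment_bouts,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable analysis settings (defaults mirror the study design)."""

    min_visits: int = 21  # motivated filter: strictly more than 20 visits
    bouts_per_bin: int = 8
    gap_threshold: float = 300.0  # seconds; bout delimiter fallback
    merge_trailing: bool = True
    n_null: int = 100
    reps: int = 10
    z_threshold: float = 2.0
    alpha: float = 0.05

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    visit_log,
    interaction_log=None,
    config: PipelineConfig | None = None,
    out_dir="results/pipeline",
    seed: int = 0,
) -> dict:
    """Execute the full analysis and return the report (also written as
    ``report.json`` under ``out_dir``).

    ``visit_log`` is a CSV path or an already-validated :class:`VisitLog`;
    ``interaction_log`` an optional encounter CSV path (or event list).
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"software_version": __version__, "seed": seed, "config": asdict(cfg)}

    current_stage = {"name": "start"}

    def stage(name):
        current_stage["name"] = name
        logger.info("stage: %s", name)

    try:
        stage("ingest")
        if isinstance(visit_log, (str, Path)):
            report["input_digest"] = _digest(visit_log)
            log = read_visit_log(visit_log)
        else:
            log = visit_log
        report["n_visits_raw"] = len(log)

        stage("filter")
        log = filter_motivated(log, min_visits=cfg.min_visits)
        report["retained_bees"] = list(log.bees)
        report["n_retained_bees"] = len(log.bees)
        report["n_visits_retained"] = len(log)
        report["max_visits_per_bee"] = int(log.per_bee_totals().max()) if len(log) else 0

        stage("bouts")
        bouts = segment_bouts(log, gap_threshold=cfg.gap_threshold)
        report["n_bouts"] = len(bouts)
        report["mean_unique_flowers_per_bout"] = (
            float(np.mean([b.n_unique_flowers for b in bouts])) if bouts else float("nan")
        )

        stage("bins")
        bins = bin_by_bouts(bouts, bouts_per_bin=cfg.bouts_per_bin, merge_trailing=cfg.merge_trailing)
        report["n_bins"] = len(bins)

        stage("matrices")
        matrices = [build_visitation_matrix(b, log.flowers) for b in bins]
        for m in matrices:
            m.to_tsv(out / f"matrix_bin{m.bin_index:02d}.tsv")
        report["mean_bees_per_bin"] = float(np.mean([m.n_bees for m in matrices]))
        report["total_matrix_visits"] = int(sum(m.total for m in matrices))

        stage("metrics")
        metrics = compute_metrics(matrices)
        metrics.to_csv(out / "metrics.csv", index=False)
        report["metrics_table"] = "metrics.csv"
        report["n_metric_rows"] = len(metrics)
        if len(metrics) > 3 and metrics["bee_id"].nunique() >= 2:
            corr = float(np.corrcoef(metrics["activity"], metrics["experience"])[0, 1])
            report["activity_experience_correlation"] = corr
            vif = variance_inflation(metrics[["activity", "experience"]])
            report["vif"] = {k: float(v) for k, v in vif["vif"].items()}
            lmm = fit_specificity_lmm(metrics)
            lmm.to_json(out / "specificity_lmm.json")
            report["specificity_lmm"] = lmm.to_dict()

        stage("modularity")
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(matrices))
        per_bin = []
        partitions = []
        for m, child in zip(matrices, children):
            sub = int(child.generate_state(1)[0] % (2**31))
            part = dirt_lpa_wb_plus(m, reps=cfg.reps, rng_seed=sub)
            comp = modularity_zscore(m, n_null=cfg.n_null, reps=cfg.reps, rng_seed=sub)
            partitions.append((m, part))
            per_bin.append(
                {
                    "bin_index": m.bin_index,
                    "matrix": f"matrix_bin{m.bin_index:02d}.tsv",
                    "n_bees": m.n_bees,
                    "Q_obs": comp.Q_obs,
                    "null_mean": comp.null_mean,
                    "null_sd": comp.null_sd,
                    "z": None if np.isnan(comp.z) else comp.z,
                    "significant": bool(comp.significant),
                }
            )
        report["per_bin"] = per_bin
        report["n_significant_bins"] = int(sum(r["significant"] for r in per_bin))
        pd.DataFrame(per_bin).to_csv(out / "modularity.csv", index=False)

        if len(per_bin) >= 5 and len(metrics):
            summaries = pd.DataFrame(
                [
                    {
                        "bin_index": r["bin_index"],
                        "modularity": r["Q_obs"],
                        "mean_activity": metrics[metrics["bin_index"] == r["bin_index"]]["activity"].mean(),
                        "mean_experience": metrics[metrics["bin_index"] == r["bin_index"]]["experience"].mean(),
                        "n_bees": r["n_bees"],
                    }
                    for r in per_bin
                ]
            )
            lm = fit_modularity_lm(summaries)
            lm.to_json(out / "modularity_lm.json")
            report["modularity_lm"] = lm.to_dict()

        stage("persistence")
        assoc = association_counts(partitions, log.flowers)
        assoc.counts.to_csv(out / "associations.csv")
        pers = persistence_table(assoc, alpha=cfg.alpha)
        pers.to_csv(out / "persistence.csv", index=False)
        report["n_persistent_bees"] = int(pers["significant"].sum()) if len(pers) else 0
        report["n_tested_bees"] = len(pers)

        if interaction_log is not None:
            stage("interactions")
            events = (
                read_interaction_log(interaction_log)
                if isinstance(interaction_log, (str, Path))
                else interaction_log
            )
            classified = [classify_interaction(e) for e in events]
            table = build_interaction_table(classified, metrics=metrics, bins=bins)
            table.to_csv(out / "interaction_table.csv", index=False)
            report["n_interaction_events"] = len(events)
            report["n_contact_events"] = len(table)
            try:
                rep_fit = fit_replacement_model(table)
                rep_fit.to_json(out / "replacement_glmm.json")
                report["replacement_model"] = rep_fit.to_dict()
            except ValueError as err:
                report["replacement_model"] = {"error": str(err)}
            revisit = build_revisit_table(classified, bouts)
            if len(revisit):
                revisit.to_csv(out / "revisit_table.csv", index=False)
                try:
                    rv_fit = fit_revisit_model(revisit)
                    rv_fit.to_json(out / "revisit_glmm.json")
                    report["revisit_model"] = rv_fit.to_dict()
                except ValueError as err:
                    report["revisit_model"] = {"error": str(err)}
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{current_stage['name']}': {err}") from err

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
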