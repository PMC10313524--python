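"""End-to-end orchestration of the synthetic trial analysis.

Runs simulate → evaluability filter → borrowing fit → reduction summaries →
response evaluation → pharmacodynamic associations, writing every stage's
outputs plus a manifest (config hash, seeds, versions, per-stage row counts,
content hashes).  Identical configuration gives bit-identical summary files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .borrowing import BorrowingModel, ModelConfig, groups_from_records
from .cohort import (
    eligibility_filter,
    read_cohort_table,
    read_external_control_table,
    write_cohort_table,
    write_external_control_table,
)
from .design import OCConfig, operating_characteristics
from .response import LesionSeries, classify_best_response, orr
from .simulate import (
    DEFAULT_CONFIG,
    ArmSpec,
    ExpressionSpec,
    GeneratorConfig,
    SpdSpec,
    simulate_cohort,
    simulate_expression,
    write_expression_matrix,
    write_gmt,
)
from .associations import per_gene_association, preranked_gsea, top_split_clusters

logger = logging.getLogger("idhtrial")

STAGES = ("simulate", "filter", "fit", "summarize", "response", "associations")


class ConfigError(ValueError):
    """Invalid or missing configuration section."""


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def default_run_config() -> dict:
    """The demo configuration: study conditions throughout."""
    return {
        "seed": 0,
        "generator": {},         # defaults = printed study conditions
        "model": {},             # ModelConfig defaults
        "response": {"level": 0.95},
        "associations": {"n_perm": 200, "min_size": 15, "max_size": 500,
                         "n_sets": 10, "set_size": 25},
        "oc": None,              # optional; run via the `oc` subcommand
    }


def _generator_config(section: dict) -> GeneratorConfig:
    kwargs: dict[str, Any] = {}
    if "arms" in section:
        kwargs["arms"] = tuple(ArmSpec(**a) for a in section["arms"])
    for key in ("p_insufficient_tissue", "p_midh1_not_confirmed",
                "p_incorrect_dosing", "p_missed_doses"):
        if key in section:
            kwargs[key] = float(section[key])
    if "expression" in section:
        kwargs["expression"] = ExpressionSpec(**section["expression"])
    if "spd" in section:
        kwargs["spd"] = SpdSpec(**section["spd"])
    return GeneratorConfig(**kwargs) if kwargs else DEFAULT_CONFIG


def _model_config(section: dict) -> ModelConfig:
    return ModelConfig(**section) if section else ModelConfig()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute all stages; return (and write) the run manifest.

    Any stage error aborts with a stage-labeled message; outputs of completed
    stages are retained next to a ``FAILED`` marker file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("generator", "model"):
        if key not in config:
            raise ConfigError(f"missing config section '{key}'")
    seed = int(config.get("seed", 0))
    # validate configuration up front so bad configs fail before any stage runs
    try:
        gen_cfg = _generator_config(config["generator"])
        model_cfg = _model_config(config["model"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
        "outputs": {},
    }
    stage = "setup"
    try:
        # -- simulate
        stage = "simulate"
        subjects, externals = simulate_cohort(gen_cfg, seed=seed)
        cohort_path = outdir / "cohort.csv"
        external_path = outdir / "external_controls.csv"
        write_cohort_table(subjects, cohort_path)
        write_external_control_table(externals, external_path)
        manifest["stages"][stage] = {"subjects": len(subjects),
                                     "externals": len(externals), "seed": seed}
        logger.info("simulate: %d subjects, %d external controls (seed %d)",
                    len(subjects), len(externals), seed)

        # -- filter
        stage = "filter"
        subjects = read_cohort_table(cohort_path)
        externals = read_external_control_table(external_path)
        analysis_set = eligibility_filter(subjects)
        pd.DataFrame(
            [{"subject_id": sid, "reason": reason.value}
             for sid, reason in analysis_set.exclusions]
        ).to_csv(outdir / "exclusions.csv", index=False)
        manifest["stages"][stage] = {"included": analysis_set.n_included,
                                     "excluded": analysis_set.n_excluded}

        # -- fit
        stage = "fit"
        groups = groups_from_records(analysis_set.included, externals)
        fit_seed = seed + 1
        results = BorrowingModel(groups, config=model_cfg).fit(seed=fit_seed)
        results.draws.to_frame().to_csv(outdir / "draws.csv", index=False)
        manifest["stages"][stage] = {
            "groups": list(results.draws.group_labels),
            "chains": model_cfg.chains,
            "seed": fit_seed,
            "max_rhat": results.diagnostics()["max_rhat"],
        }
        logger.info("fit: seed %d, %d chains, max Rhat %.4f", fit_seed,
                    model_cfg.chains, manifest["stages"][stage]["max_rhat"])

        # -- summarize
        stage = "summarize"
        rows = []
        for arm in results.model.treated_labels:
            s = results.reduction_summary(arm)
            rows.append({"arm": arm, "mean_reduction_pct": s.mean,
                         "cri_lower": s.lower, "cri_upper": s.upper,
                         "prob_lower": results.prob_treatment_lower(arm),
                         "ess": s.ess})
        pd.DataFrame(rows).to_csv(outdir / "reduction_summary.csv", index=False,
                                  float_format="%.6g")
        manifest["stages"][stage] = {"arms": len(rows)}

        # -- response
        stage = "response"
        level = float(config.get("response", {}).get("level", 0.95))
        resp_rows, orr_rows = [], []
        by_arm: dict[str, list] = {}
        for rec in subjects:
            if not rec.arm.treated:
                continue
            series = LesionSeries(rec.subject_id, rec.baseline_spd,
                                  rec.lesion_days, rec.lesion_spd)
            best = classify_best_response(series)
            by_arm.setdefault(rec.arm.value, []).append(best)
            resp_rows.append({"subject_id": rec.subject_id, "arm": rec.arm.value,
                              "category": best.category.value,
                              "best_percent_change": best.best_percent_change})
        for arm, responses in sorted(by_arm.items()):
            result = orr(responses, level=level)
            orr_rows.append({"arm": arm, "responders": result.responders,
                             "n": result.n, "orr_pct": result.orr,
                             "ci_lower": result.ci[0], "ci_upper": result.ci[1]})
        pd.DataFrame(resp_rows).to_csv(outdir / "best_response.csv", index=False)
        pd.DataFrame(orr_rows).to_csv(outdir / "orr.csv", index=False)
        manifest["stages"][stage] = {"subjects": len(resp_rows), "arms": len(orr_rows)}

        # -- associations
        stage = "associations"
        assoc_cfg = config.get("associations", {}) or {}
        expr_subjects = [r for r in analysis_set.included
                         if r.tumor_2hg is not None and r.tumor_2hg > 0]
        covariate = np.array([math.log10(r.tumor_2hg) for r in expr_subjects])
        expr_seed = seed + 2
        matrix, gene_ids, signature = simulate_expression(
            gen_cfg, covariate, seed=expr_seed)
        write_expression_matrix(matrix, gene_ids,
                                [r.subject_id for r in expr_subjects],
                                outdir / "expression.tsv")
        gene_stats = per_gene_association(matrix, covariate, gene_ids)
        pd.DataFrame([dataclasses.asdict(g) for g in gene_stats]).to_csv(
            outdir / "gene_stats.csv", index=False)

        sets = _demo_gene_sets(gene_ids, signature,
                               n_sets=int(assoc_cfg.get("n_sets", 10)),
                               set_size=int(assoc_cfg.get("set_size", 25)),
                               seed=seed + 3)
        write_gmt(sets, outdir / "gene_sets.gmt")
        enrichment = preranked_gsea(
            gene_stats, sets,
            n_perm=int(assoc_cfg.get("n_perm", 200)),
            min_size=int(assoc_cfg.get("min_size", 15)),
            max_size=int(assoc_cfg.get("max_size", 500)),
            seed=seed + 4,
        )
        pd.DataFrame([dataclasses.asdict(e) for e in enrichment]).to_csv(
            outdir / "enrichment.csv", index=False)
        labels, (t, p) = top_split_clusters(
            np.log2(matrix[: len(signature)]), covariate)
        pd.DataFrame({"subject_id": [r.subject_id for r in expr_subjects],
                      "cluster": labels}).to_csv(outdir / "clusters.csv", index=False)
        manifest["stages"][stage] = {"genes": len(gene_stats),
                                     "sets": len(enrichment),
                                     "cluster_t": t, "cluster_p": p,
                                     "seeds": [expr_seed, seed + 3, seed + 4]}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=float))
    return manifest


def _demo_gene_sets(gene_ids, signature, n_sets: int, set_size: int, seed: int
                    ) -> dict[str, list[str]]:
    """Gene-set collection for the demo run: the planted signature plus
    random background sets (a sanity-scale stand-in for a curated collection)."""
    rng = np.random.default_rng(seed)
    sets = {"SIGNATURE_2HG": list(signature)}
    for i in range(n_sets):
        picks = rng.choice(len(gene_ids), size=set_size, replace=False)
        sets[f"RANDOM_{i + 1:02d}"] = [gene_ids[j] for j in picks]
    return sets


def run_oc(config: dict, outdir) -> pd.DataFrame:
    """Run the operating-characteristics sweep defined in the `oc` section."""
    section = config.get("oc")
    if not section:
        raise ConfigError("missing config section 'oc'")
    oc_cfg = OCConfig(
        treated=ArmSpec(**section["treated"]),
        internal_control=ArmSpec(**section["internal_control"]),
        external_control=ArmSpec(**section["external_control"]),
        n_grid=tuple(section.get("n_grid", ())),
        p_star=float(section.get("p_star", 0.975)),
        replicates=int(section.get("replicates", 200)),
        base_seed=int(section.get("base_seed", config.get("seed", 0))),
        model_config=_model_config(section.get("model", {})),
    )
    results = operating_characteristics(oc_cfg)
    frame = pd.DataFrame([
        {"n_treated": r.n_treated, "replicates": r.replicates,
         "detection_rate": r.detection_rate, "detection_se": r.detection_se,
         "mean_reduction": r.mean_reduction, "true_reduction": r.true_reduction,
         "coverage": r.coverage, "mean_ci_width": r.mean_ci_width,
         "first_seed": r.seeds[0], "last_seed": r.seeds[-1]}
        for r in results
    ])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "operating_characteristics.csv", index=False)
    return frame
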