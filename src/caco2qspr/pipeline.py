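"""End-to-end modeling pipeline with per-stage manifests.

``run_all`` chains the full workflow on one descriptor table:

  curate -> prune -> mcfilter -> split -> importance -> select
  -> tune/train -> validate -> ad -> diversity

Every stage writes its artifact plus a JSON manifest (input hashes, seed,
parameters, outputs) into the run directory, so a rerun with the same
configuration reproduces identical manifests.  Per-stage seeds are derived
deterministically from the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from caco2qspr import ad as ad_mod
from caco2qspr import chemspace, feature_selection, mc_filter, validation
from caco2qspr import models as models_mod
from caco2qspr.datatable import DescriptorTable, curate_table, read_table, write_table
from caco2qspr.optimizer import OptimizerConfig

logger = logging.getLogger(__name__)

STAGES = [
    "curate", "prune", "mcfilter", "split", "importance",
    "select", "train", "validate", "ad", "diversity",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


class PipelineRun:
    def __init__(self, workdir: str | Path, global_seed: int = 0):
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.global_seed = global_seed

    def write_manifest(self, stage: str, params: dict, inputs: list[Path], outputs: list[Path]):
        manifest = {
            "stage": stage,
            "seed": stage_seed(self.global_seed, stage),
            "params": params,
            "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        path = self.workdir / f"manifest_{stage}.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_json_default))
        return path

    def write_json(self, name: str, payload) -> Path:
        path = self.workdir / name
        path.write_text(json.dumps(payload, indent=2, default=_json_default))
        return path


def run_all(config: dict) -> Path:
    """Execute the whole pipeline as configured; returns the run directory.

    Minimal config: ``{"input": <csv path>, "workdir": <dir>, "seed": <int>}``.
    Stage parameters live under keys named after the stage; see the CLI
    reference for the full schema.
    """
    seed = int(config.get("seed", 0))
    run = PipelineRun(config["workdir"], global_seed=seed)
    wd = run.workdir
    current_stage = "curate"
    try:
        # --- curate + prune ------------------------------------------------
        cur_cfg = config.get("curation", {})
        table = read_table(config["input"], column_map=config.get("column_map"))
        table, reports = curate_table(
            table,
            var_threshold=cur_cfg.get("var_threshold", 0.3),
            r_threshold=cur_cfg.get("r_threshold", 0.85),
        )
        curated_path = wd / "curated.csv"
        write_table(table, curated_path)
        run.write_json("curation_report.json", [dataclasses.asdict(r) for r in reports])
        run.write_manifest("curate", cur_cfg, [Path(config["input"])],
                           [curated_path, wd / "curation_report.json"])
        run.write_manifest("prune", cur_cfg, [curated_path], [curated_path])

        # --- mcfilter ------------------------------------------------------
        current_stage = "mcfilter"
        mc_cfg = config.get("mc_filter", {})
        profile = mc_filter.mc_residual_profile(
            table,
            n_iterations=mc_cfg.get("n_iterations", 2000),
            test_fraction=mc_cfg.get("test_fraction", 0.10),
            seed=stage_seed(seed, "mcfilter"),
        )
        opt = OptimizerConfig(
            population_size=mc_cfg.get("population_size", 30),
            max_iterations=mc_cfg.get("opt_iterations", 50),
            seed=stage_seed(seed, "mcfilter-opt"),
            bounds=mc_cfg.get("bounds", mc_filter.DEFAULT_BOUNDS),
        )
        mc_result = mc_filter.optimize_thresholds(
            table, profile,
            bounds=tuple(map(tuple, mc_cfg.get("bounds", mc_filter.DEFAULT_BOUNDS))),
            max_removed_frac=mc_cfg.get("max_removed_frac", 0.02),
            opt=opt,
            rule=mc_cfg.get("rule", "union"),
            cv_seed=stage_seed(seed, "mcfilter-cv"),
        )
        logger.info("mcfilter: removed %d compounds, thresholds mean_lim=%.3f std_lim=%.3f",
                    len(mc_result.removed_ids), mc_result.thresholds.mean_lim,
                    mc_result.thresholds.std_lim)
        table = mc_result.retained_table
        retained_path = wd / "retained.csv"
        write_table(table, retained_path)
        pd.DataFrame({"id": mc_result.removed_ids}).to_csv(wd / "removed_ids.csv", index=False)
        run.write_json("mcfilter_report.json", {
            "thresholds": dataclasses.asdict(mc_result.thresholds),
            "objective_r_cv5_sq": mc_result.objective_value,
            "removed_fraction": mc_result.removed_fraction,
            "removed_ids": mc_result.removed_ids,
        })
        run.write_manifest("mcfilter", mc_cfg, [curated_path],
                           [retained_path, wd / "removed_ids.csv", wd / "mcfilter_report.json"])

        # --- split ---------------------------------------------------------
        current_stage = "split"
        sp_cfg = config.get("split", {})
        proj, scores_mat = chemspace.pca_reduce(table, var_target=sp_cfg.get("var_target", 0.90))
        grid = chemspace.SOMGrid(
            rows=sp_cfg.get("som_rows", 3), cols=sp_cfg.get("som_cols", 3),
            epochs=sp_cfg.get("som_epochs", 500), seed=stage_seed(seed, "split"),
        )
        clusters = chemspace.som_cluster(scores_mat, grid)
        split = chemspace.stratified_split(
            table, clusters,
            test_every=sp_cfg.get("test_every", 5), offset=sp_cfg.get("offset", 3),
        )
        split_path = wd / "split.csv"
        pd.DataFrame({"id": table.ids, "set": split.labels}).to_csv(split_path, index=False)
        run.write_manifest("split", sp_cfg, [retained_path], [split_path])
        train_tab = table.subset_rows(np.flatnonzero(split.train_mask))
        test_tab = table.subset_rows(np.flatnonzero(split.test_mask))

        # --- importance + selection ---------------------------------------
        current_stage = "importance"
        fs_cfg = config.get("selection", {})
        scores = feature_selection.mdi_importance(
            train_tab, models_mod.ModelSpec(family="mlr"),
            n_repeats=fs_cfg.get("n_repeats", 10), seed=stage_seed(seed, "importance"),
        )
        imp_path = wd / "importance.csv"
        pd.DataFrame({
            "descriptor": scores.descriptor_names,
            "score": scores.score, "rank": scores.rank,
        }).to_csv(imp_path, index=False)
        run.write_manifest("importance", fs_cfg, [retained_path], [imp_path])

        current_stage = "select"
        curve = feature_selection.importance_curve(
            train_tab, scores, k_max=fs_cfg.get("k_max", train_tab.p),
            cv_seed=stage_seed(seed, "select-cv"),
        )
        head = scores.top(curve.best_k)
        opt = OptimizerConfig(
            population_size=fs_cfg.get("population_size", 30),
            max_iterations=fs_cfg.get("opt_iterations", 30),
            seed=stage_seed(seed, "select-opt"), mode="binary",
        )
        ranks = np.array([scores.rank[scores.descriptor_names.index(nm)] for nm in head], float)
        subset = feature_selection.hqpso_subset(
            train_tab, head, max_selected=fs_cfg.get("max_selected", 60),
            opt=opt, mdi_rank=ranks, cv_seed=stage_seed(seed, "select-cv"),
        )
        final_k = min(fs_cfg.get("final_k", 50), len(subset))
        sub_scores = {nm: scores.score[scores.descriptor_names.index(nm)] for nm in subset}
        selected = sorted(subset, key=lambda nm: -sub_scores[nm])[:final_k]
        sel_path = wd / "selected_descriptors.txt"
        sel_path.write_text("\n".join(selected) + "\n")
        run.write_json("importance_curve.json", {"points": curve.points, "best_k": curve.best_k})
        run.write_manifest("select", fs_cfg, [imp_path], [sel_path])
        train_sel = train_tab.subset_columns(selected)
        test_sel = test_tab.subset_columns(selected)

        # --- tune + train --------------------------------------------------
        current_stage = "train"
        md_cfg = config.get("model", {})
        family = md_cfg.get("family", "dual_rbf")
        if "params" in md_cfg:
            spec = models_mod.ModelSpec(family=family, params=md_cfg["params"])
        elif family == "mlr":
            spec = models_mod.ModelSpec(family="mlr")
        else:
            spec = models_mod.tune_hyperparams(
                train_sel, family,
                fitness_kind=md_cfg.get("fitness_kind",
                                        "robustness_only" if family == "gbm" else "balanced"),
                opt=OptimizerConfig(
                    population_size=md_cfg.get("population_size", 30),
                    max_iterations=md_cfg.get("opt_iterations", 20),
                    seed=stage_seed(seed, "train-opt"),
                    bounds=md_cfg.get("bounds", models_mod.DEFAULT_BOUNDS[family]),
                ),
                cv_seed=stage_seed(seed, "train-cv"),
            )
        metrics, model = validation.evaluate_model(
            train_sel, spec, test_sel, cv_seed=stage_seed(seed, "train-cv"))
        model_path = run.write_json("model.json", models_mod.model_to_dict(model, spec))
        run.write_manifest("train", md_cfg, [sel_path], [model_path])

        # --- validate ------------------------------------------------------
        current_stage = "validate"
        va_cfg = config.get("validation", {})
        gt = validation.golbraikh_tropsha(test_sel.y, model.predict(test_sel.X))
        topliss, topliss_ok = validation.topliss_ratio(train_sel.n, train_sel.p)
        gap, gap_ok = validation.overfit_gap(metrics.r_sq, metrics.r_cv5_sq)
        yrand = validation.y_randomization(
            train_sel, spec, n_runs=va_cfg.get("n_yrand", 1000),
            seed=stage_seed(seed, "validate"), cv_seed=stage_seed(seed, "train-cv"),
        )
        val_path = run.write_json("validation_report.json", {
            "metrics": dataclasses.asdict(metrics),
            "golbraikh_tropsha": gt.to_dict(),
            "topliss_ratio": {"value": topliss, "passes": topliss_ok},
            "overfit_gap": {"value": gap, "passes": gap_ok},
            "y_randomization": yrand.summary(),
        })
        run.write_manifest("validate", va_cfg, [model_path], [val_path])

        # --- applicability domain -----------------------------------------
        current_stage = "ad"
        sel_scores = feature_selection.mdi_importance(
            train_sel, spec, n_repeats=config.get("ad", {}).get("n_repeats", 10),
            seed=stage_seed(seed, "ad"),
        )
        lev = ad_mod.leverage_fit(train_sel.X)
        iwd = ad_mod.iwd_fit(train_sel.X, sel_scores.normalized())
        rows = []
        for dom, tag in ((lev, "leverage"), (iwd, "iwd")):
            tr_rows = ad_mod.williams_data(
                dom, train_sel.X, train_sel.y, model.predict(train_sel.X),
                rmse_ref=metrics.rmse_f, ids=train_sel.ids,
                set_labels=["train"] * train_sel.n)
            te_rows = ad_mod.williams_data(
                dom, test_sel.X, test_sel.y, model.predict(test_sel.X),
                rmse_ref=metrics.rmse_f, ids=test_sel.ids,
                set_labels=["test"] * test_sel.n)
            cov = ad_mod.coverage(tr_rows + te_rows)
            rows.append({"method": tag, "coverage": cov,
                         "threshold": dom.warning_leverage if tag == "leverage" else dom.threshold,
                         "response_outliers": [r.id for r in tr_rows + te_rows
                                               if r.response_outlier]})
        ad_path = run.write_json("ad_report.json", rows)
        run.write_manifest("ad", config.get("ad", {}), [model_path], [ad_path])

        # --- diversity -----------------------------------------------------
        current_stage = "diversity"
        full_sel = table.subset_columns(selected)
        sim = chemspace.tanimoto_matrix(full_sel)
        full_split = chemspace.SplitAssignment(
            labels=split.labels, cluster_ids=split.cluster_ids, positions=split.positions)
        div = chemspace.diversity_report(sim, full_split, y=table.y)
        div_path = run.write_json("diversity_report.json", dataclasses.asdict(div))
        run.write_manifest("diversity", {}, [retained_path], [div_path])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current_stage!r} "
                           f"(run directory {wd})") from exc
    return wd
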