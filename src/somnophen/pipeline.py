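"""End-to-end pipeline: simulate -> extract -> classify / cluster.

``RunConfig`` collects every tunable parameter with its default; the
manifest written next to the results records the configuration and every
seed used, so a rerun with the same config reproduces the aggregates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .catalog import FEATURE_NAMES, FEATURE_SETS, SET_ORDER
from .cluster import cluster_group, compare_clusters, pca_space, preprocess
from .evaluate import (
    EvalConfig,
    balanced_exclusion_model,
    evaluate_task,
    select_top_features,
)
from .features import extract_cohort_features, write_feature_table
from .synthetic import GroupSpec, generate_cohort


@dataclass
class RunConfig:
    """Configuration of one end-to-end run on a synthetic cohort."""

    out_dir: str = "results"
    seed: int = 0
    specs: list[GroupSpec] = field(default_factory=lambda: [GroupSpec()])
    eval_config: EvalConfig | None = None
    run_classify: bool = True
    run_cluster: bool = True
    k_range: tuple[int, int] = (2, 10)
    top_k: int = 8


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and return a summary dict (also written out)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds_used = {"master": config.seed}

    records, cohort, _truth = generate_cohort(config.specs, seed=config.seed)
    table = extract_cohort_features(records, cohort, missing_seed=config.seed + 1)
    seeds_used["missing_injection"] = config.seed + 1
    write_feature_table(table, out / "features.csv")

    summary: dict = {"n_participants": len(table), "n_features": len(FEATURE_NAMES)}

    if config.run_classify:
        eval_config = config.eval_config or EvalConfig(seed=config.seed + 2)
        seeds_used["evaluation"] = eval_config.seed
        labels = table["group"].unique().tolist()
        task_results = {}
        for i, g1 in enumerate(labels):
            for g2 in labels[i + 1 :]:
                pair_table = table[table["group"].isin([g1, g2])]
                rankings = {}
                per_set = {}
                for set_name in SET_ORDER:
                    res = evaluate_task(
                        pair_table, list(FEATURE_SETS[set_name]), eval_config
                    )
                    rankings[set_name] = res.importance
                    per_set[set_name] = {
                        "auc": res.mean_auc,
                        "auc_sd": res.sd_auc,
                        "f1": res.mean_f1,
                    }
                combined = select_top_features(rankings, k=config.top_k)
                res_combined = evaluate_task(pair_table, combined, eval_config)
                task = f"{g1}_vs_{g2}"
                task_results[task] = {
                    "per_set": per_set,
                    "combined": {
                        "n_features": len(combined),
                        "auc": res_combined.mean_auc,
                        "f1": res_combined.mean_f1,
                    },
                }
                pd.DataFrame(
                    {
                        "run": np.arange(eval_config.n_runs),
                        "auc": res_combined.auc_runs,
                        "f1": res_combined.f1_runs,
                    }
                ).to_csv(out / f"metrics_{task}.csv", index=False)
                res_combined.importance.to_csv(
                    out / f"importance_{task}.csv", index=False
                )
                res_combined.mean_roc.to_csv(out / f"roc_{task}.csv", index=False)
        summary["classification"] = task_results

    if config.run_cluster:
        pre = preprocess(table, list(FEATURE_NAMES), on_excess_missing="drop")
        coords = pca_space(pre.values)
        summary["pca_components"] = int(coords.shape[1])
        cluster_summaries = {}
        for label, part in table.groupby("group", sort=False):
            idx = part.index.to_numpy()
            pts = coords[[table.index.get_loc(i) for i in idx]]
            try:
                result = cluster_group(
                    pts, group=label, k_range=config.k_range, seed=config.seed + 3
                )
            except ValueError:
                continue
            pd.DataFrame(
                {
                    "participant_id": part["participant_id"],
                    "cluster": result.assignments,
                }
            ).to_csv(out / f"clusters_{label}.csv", index=False)
            entry = {
                "k": result.k,
                "sizes": np.bincount(result.assignments).tolist(),
                "excluded": result.excluded_clusters,
            }
            if len(result.retained_clusters) >= 2:
                comparison = compare_clusters(
                    part.reset_index(drop=True), result, list(FEATURE_NAMES)
                )
                comparison.to_csv(out / f"comparison_{label}.csv", index=False)
                entry["n_significant"] = int(comparison["sig"].sum())
                entry["n_significant_adj"] = int(comparison["sig_adj"].sum())
            cluster_summaries[label] = entry
        summary["clustering"] = cluster_summaries

    manifest = {
        "seeds": seeds_used,
        "config": _config_dict(config),
        "summary": summary,
    }
    io.write_manifest(manifest, out / "manifest.yaml")
    return summary


def _config_dict(config: RunConfig) -> dict:
    return _plain(dataclasses.asdict(config))


def _plain(obj):
    """Reduce a config tree to YAML-safe builtins (lists, dicts, scalars)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
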