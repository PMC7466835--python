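"""End-to-end orchestration: simulate (or load) -> epochs -> search ->
orient -> weights -> summaries -> group statistics.

One analysis is run per group x condition (two groups x three
conditions = six graphs), each on the
pooled standardized condition epochs of that group's subjects.  All
artifacts are written under an output directory with a manifest that
records the config hash and seed, so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .design import TaskDesign, build_task_design
from .epochs import DEFAULT_LAG_VOLUMES, extract_epochs, standardize
from .evaluate import adjacency_metrics, orientation_accuracy
from .exceptions import DegenerateSignalError, EmonetError, MissingDataError
from .ges import ScoreConfig, select_penalty
from .graphs import Cpdag, Dag
from .lofs import lofs_orient
from .sem import build_weight_table, group_mean_weights
from .simulate import (
    DEFAULT_ROIS,
    CohortSpec,
    TaskRun,
    generate_cohort,
    sample_ground_truth,
)
from .stats import bonferroni, paired_t, pearson_r, rm_anova, two_sample_t
from .summary import DEFAULT_LAYERS, classify_edges, edges_common_to_all, shared_adjacencies

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "rois": list(DEFAULT_ROIS),
    "layers": dict(DEFAULT_LAYERS),
    "design": {
        "tr": 2.0,
        "n_blocks": 12,
        "images_per_block": 5,
        "stim_seconds": 4.0,
        "fixation_seconds": 20.0,
        "conditions": ["negative", "neutral", "positive"],
    },
    "simulate": {
        "groups": [
            {"label": "HC", "n_subjects": 14},
            {"label": "GAD", "n_subjects": 16},
        ],
        "edge_density": 0.25,
        "weight_range": [0.4, 0.8],
        "noise": "laplace",
        "noise_scale": 1.0,
        "ar": 0.3,
    },
    "epochs": {"lag_volumes": DEFAULT_LAG_VOLUMES},
    "search": {"penalty_grid": [1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0], "max_parents": None},
    "orientation": {"fix_v_structures": False, "max_exhaustive": 12, "n_restarts": 5},
    "stats": {"clinical_table": None},
    "output": None,
}


def load_config(path_or_dict) -> dict:
    """Merge a YAML file or dict over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict)
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base, over):
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                merge(base[k], v)
            else:
                base[k] = v

    merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All artifacts of one end-to-end run."""

    design: TaskDesign
    patterns: dict[tuple[str, str], Cpdag]
    penalties: dict[tuple[str, str], float]
    graphs: dict[tuple[str, str], Dag]
    weights: pd.DataFrame
    summaries: dict[tuple[str, str], dict]
    shared: dict[tuple[str, str, str], dict]
    stats: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _build_design(cfg: dict) -> TaskDesign:
    d = cfg["design"]
    return build_task_design(
        tr=d["tr"],
        n_blocks=d["n_blocks"],
        images_per_block=d["images_per_block"],
        stim_seconds=d["stim_seconds"],
        fixation_seconds=d["fixation_seconds"],
        condition_labels=list(d["conditions"]),
        seed=cfg["seed"],
    )


def _simulate_cohort(cfg: dict, design: TaskDesign):
    sim = cfg["simulate"]
    rois = tuple(cfg["rois"])
    truths: dict[str, dict] = {}
    specs = []
    for gi, grp in enumerate(sim["groups"]):
        models = {}
        for ci, cond in enumerate(design.conditions):
            truth_seed = np.random.SeedSequence(
                [int(cfg["seed"]), 1000 + gi, ci]
            )
            models[cond] = sample_ground_truth(
                rois,
                edge_density=sim["edge_density"],
                weight_range=tuple(sim["weight_range"]),
                noise_family=sim["noise"],
                noise_scale=sim.get("noise_scale", 1.0),
                ar_coefficient=sim["ar"],
                seed=truth_seed,
                forbid_triangles=True,
            )
        truths[grp["label"]] = models
        specs.append(
            CohortSpec(group=grp["label"], n_subjects=grp["n_subjects"], models=models)
        )
    runs = generate_cohort(specs, design, cfg["seed"])
    return runs, truths


def _load_cohort(cfg: dict):
    runs = [run for run, _ in eio.read_cohort(cfg["data"]["dir"])]
    return runs, None


def run_pipeline(config=None) -> PipelineResult:
    """Run the full analysis described by ``config`` (dict or YAML path).

    Raises
    ------
    EmonetError
        Any stage failure, annotated with the stage and the offending
        group/condition/subject.
    """
    cfg = load_config(config or {})
    design = _build_design(cfg)

    if "data" in cfg and cfg.get("data"):
        runs, truths = _load_cohort(cfg)
    else:
        runs, truths = _simulate_cohort(cfg, design)

    groups = sorted({r.group for r in runs})
    conditions = design.conditions
    lag = cfg["epochs"]["lag_volumes"]

    # 1. condition epochs, standardized per subject x condition
    epochs: dict[tuple[str, str, str], object] = {}
    for run in runs:
        try:
            per_cond = extract_epochs(run, design, lag_volumes=lag)
        except EmonetError as err:
            raise type(err)(f"epoch extraction, subject {run.subject!r}: {err}") from err
        for cond in conditions:
            if cond not in per_cond:
                raise MissingDataError(
                    f"subject {run.subject!r} has no epochs for condition {cond!r}"
                )
            epochs[(run.subject, run.group, cond)] = standardize(per_cond[cond])

    # 2. structure search + orientation per group x condition
    search_cfg = ScoreConfig(
        penalty_grid=tuple(cfg["search"]["penalty_grid"]),
        max_parents=cfg["search"]["max_parents"],
    )
    orient_cfg = cfg["orientation"]
    patterns, penalties, graphs = {}, {}, {}
    for group in groups:
        for cond in conditions:
            datasets = [
                epochs[key] for key in sorted(epochs) if key[1] == group and key[2] == cond
            ]
            try:
                c, pattern = select_penalty(datasets, search_cfg)
                dag = lofs_orient(
                    pattern,
                    datasets,
                    fix_v_structures=orient_cfg["fix_v_structures"],
                    max_exhaustive=orient_cfg["max_exhaustive"],
                    n_restarts=orient_cfg["n_restarts"],
                    seed=cfg["seed"],
                )
            except EmonetError as err:
                raise type(err)(
                    f"network search, group {group!r} condition {cond!r}: {err}"
                ) from err
            patterns[(group, cond)] = pattern
            penalties[(group, cond)] = c
            graphs[(group, cond)] = dag

    # 3. per-subject SEM weights
    weights = build_weight_table(graphs, epochs)

    # 4. summaries and shared connections
    layers = dict(cfg["layers"])
    summaries = {
        key: classify_edges(dag, layers).to_dict() for key, dag in graphs.items()
    }
    shared: dict[tuple[str, str, str], dict] = {}
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            for cond in conditions:
                pairs = shared_adjacencies(graphs[(g1, cond)], graphs[(g2, cond)])
                shared[(g1, g2, cond)] = {
                    f"{a}-{b}": agree for (a, b), agree in pairs.items()
                }

    # 5. inferential layer
    stats_report = _run_stats(cfg, groups, conditions, graphs, weights, shared)

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "n_subjects": len(runs),
        "n_graphs": len(graphs),
        "groups": {g: sum(r.group == g for r in runs) for g in groups},
        "conditions": list(conditions),
        "penalties": {f"{g}/{c}": p for (g, c), p in sorted(penalties.items())},
    }
    if truths is not None:
        recovery = {}
        for (group, cond), dag in graphs.items():
            truth = truths[group][cond].dag()
            precision, recall = adjacency_metrics(truth, patterns[(group, cond)])
            recovery[f"{group}/{cond}"] = {
                "precision": precision,
                "recall": recall,
                "direction_accuracy": orientation_accuracy(truth, dag),
            }
        manifest["recovery"] = recovery

    result = PipelineResult(
        design=design,
        patterns=patterns,
        penalties=penalties,
        graphs=graphs,
        weights=weights,
        summaries=summaries,
        shared=shared,
        stats=stats_report,
        manifest=manifest,
    )
    if cfg.get("output"):
        write_outputs(result, cfg["output"])
    return result


def _edge_strengths(
    weights: pd.DataFrame, group: str, cond: str, pair: tuple[str, str]
) -> pd.Series:
    """Per-subject coefficient of the (possibly reversed) adjacency."""
    a, b = pair
    sel = weights[
        (weights["group"] == group)
        & (weights["condition"] == cond)
        & (
            ((weights["source"] == a) & (weights["target"] == b))
            | ((weights["source"] == b) & (weights["target"] == a))
        )
    ]
    return sel.set_index("subject")["coefficient"]


def _run_stats(cfg, groups, conditions, graphs, weights, shared) -> list[dict]:
    report: list[dict] = []

    # between-group t tests on connections shared under each condition
    for (g1, g2, cond), pairs in shared.items():
        for pair_label in sorted(pairs):
            a, b = pair_label.split("-")
            x = _edge_strengths(weights, g1, cond, (a, b))
            y = _edge_strengths(weights, g2, cond, (a, b))
            try:
                res = two_sample_t(x.to_numpy(), y.to_numpy())
            except (DegenerateSignalError, ValueError) as err:
                report.append(
                    {"test": "two_sample_t", "edge": pair_label, "condition": cond,
                     "groups": [g1, g2], "error": str(err)}
                )
                continue
            report.append(
                {
                    "test": "two_sample_t",
                    "edge": pair_label,
                    "condition": cond,
                    "groups": [g1, g2],
                    "t": res.statistic,
                    "df": res.df[0],
                    "p": res.p_two_tailed,
                }
            )

    # within-group condition effects on connections common to all conditions
    for group in groups:
        dags = [graphs[(group, c)] for c in conditions]
        for a, b in sorted(edges_common_to_all(dags)):
            table = pd.DataFrame(
                {c: _edge_strengths(weights, group, c, (a, b)) for c in conditions}
            ).dropna()
            if len(table) < 2 or len(conditions) < 2:
                continue
            try:
                res = rm_anova(table)
            except (DegenerateSignalError, ValueError) as err:
                report.append(
                    {"test": "rm_anova", "edge": f"{a}-{b}", "group": group,
                     "error": str(err)}
                )
                continue
            entry = {
                "test": "rm_anova",
                "edge": f"{a}-{b}",
                "group": group,
                "F": res.statistic,
                "df": list(res.df),
                "p": res.p_two_tailed,
                "partial_eta_squared": res.effect_size,
            }
            if res.p_two_tailed < 0.05 and len(conditions) >= 2:
                pair_tests = []
                raw_ps = []
                for i, c1 in enumerate(conditions):
                    for c2 in conditions[i + 1 :]:
                        pt = paired_t(table[c1].to_numpy(), table[c2].to_numpy())
                        pair_tests.append(
                            {
                                "conditions": [c1, c2],
                                "t": pt.statistic,
                                "df": pt.df[0],
                                "p": pt.p_two_tailed,
                                "cohens_d": pt.effect_size,
                            }
                        )
                        raw_ps.append(pt.p_two_tailed)
                adjusted = bonferroni(raw_ps, family_size=len(raw_ps))
                for entry_i, adj in zip(pair_tests, adjusted):
                    entry_i["p_bonferroni"] = adj
                entry["pairwise"] = pair_tests
            report.append(entry)

    # optional clinical correlations (e.g. anxiety score vs edge strength)
    clin_path = cfg["stats"].get("clinical_table")
    if clin_path:
        clinical = pd.read_csv(clin_path)
        score_cols = [c for c in clinical.columns if c != "subject"]
        clinical = clinical.set_index("subject")
        for (group, cond), dag in sorted(graphs.items()):
            for a, b in sorted(dag.skeleton()):
                strengths = _edge_strengths(weights, group, cond, (a, b))
                joined = pd.concat([strengths, clinical], axis=1, join="inner")
                for col in score_cols:
                    sub = joined[["coefficient", col]].dropna()
                    if len(sub) < 3 or sub[col].std() == 0:
                        continue
                    res = pearson_r(sub["coefficient"], sub[col])
                    report.append(
                        {
                            "test": "pearson_r",
                            "edge": f"{a}-{b}",
                            "group": group,
                            "condition": cond,
                            "score": col,
                            "r": res.statistic,
                            "n": int(len(sub)),
                            "p": res.p_two_tailed,
                        }
                    )
    return report


def write_outputs(result: PipelineResult, directory) -> None:
    """Write graphs, weights, summaries, stats and manifest under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (group, cond), dag in sorted(result.graphs.items()):
        eio.write_graph(dag, directory / f"graph_{group}_{cond}.tsv")
        eio.write_graph(dag, directory / f"graph_{group}_{cond}.dot", fmt="dot")
        eio.write_graph(
            result.patterns[(group, cond)], directory / f"pattern_{group}_{cond}.tsv"
        )
    result.weights.to_csv(directory / "weights.tsv", sep="\t", index=False)
    group_mean_weights(result.weights).to_csv(
        directory / "group_mean_weights.tsv", sep="\t", index=False
    )
    (directory / "summaries.json").write_text(
        json.dumps(
            {f"{g}/{c}": s for (g, c), s in sorted(result.summaries.items())},
            indent=2,
        )
    )
    (directory / "shared_edges.json").write_text(
        json.dumps(
            {f"{g1}/{g2}/{c}": v for (g1, g2, c), v in sorted(result.shared.items())},
            indent=2,
        )
    )
    (directory / "stats.json").write_text(json.dumps(result.stats, indent=2))
    (directory / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
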