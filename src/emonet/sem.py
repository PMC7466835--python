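"""Per-subject SEM connection strengths for an oriented network.

Each node with parents is regressed on its parent columns by ordinary
least squares (no intercept; inputs are standardized), and the edge
coefficient of u -> v is the fitted coefficient of u in v's regression.
Estimation is per subject against the group-common graph, so the
subject-level coefficients feed directly into paired tests and
repeated-measures ANOVAs with subject-level degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import CollinearityError, MissingDataError
from .graphs import Dag, Edge
from .simulate import RoiTimeSeries

WEIGHT_COLUMNS = ["subject", "group", "condition", "source", "target", "coefficient"]


def fit_subject_weights(dag: Dag, series: RoiTimeSeries) -> dict[Edge, float]:
    """OLS path coefficients of every directed edge for one subject.

    Raises
    ------
    CollinearityError
        Naming the node whose parent columns are singular.
    """
    missing = set(dag.nodes) - set(series.rois)
    if missing:
        raise ValueError(f"series lacks columns for nodes {sorted(missing)}")
    max_indeg = max((len(dag.parents(n)) for n in dag.nodes), default=0)
    if series.n_timepoints <= max_indeg + 2:
        raise ValueError(
            f"{series.n_timepoints} rows too few for in-degree {max_indeg}"
        )
    out: dict[Edge, float] = {}
    for node in dag.nodes:
        parents = sorted(dag.parents(node))
        if not parents:
            continue
        x = series.data[parents].to_numpy(dtype=float)
        y = series.data[node].to_numpy(dtype=float)
        gram = x.T @ x
        if np.linalg.matrix_rank(gram) < len(parents):
            raise CollinearityError(f"collinear parents {parents} of node {node!r}")
        beta = np.linalg.solve(gram, x.T @ y)
        for p, b in zip(parents, beta):
            out[(p, node)] = float(b)
    return out


def build_weight_table(
    graphs: dict[tuple[str, str], Dag],
    epochs: dict[tuple[str, str, str], RoiTimeSeries],
) -> pd.DataFrame:
    """Tidy table of per-subject edge coefficients.

    Parameters
    ----------
    graphs
        Mapping (group, condition) -> oriented graph.
    epochs
        Mapping (subject, group, condition) -> standardized condition
        epochs.  Every subject of a group must have an entry for every
        condition that group has a graph for.

    Returns
    -------
    DataFrame with columns subject, group, condition, source, target,
    coefficient: one row per subject x directed edge.
    """
    subjects: dict[str, set[str]] = {}
    for _, group, _ in epochs:
        subjects.setdefault(group, set())
    for subject, group, _ in epochs:
        subjects[group].add(subject)

    missing = []
    for (group, condition) in graphs:
        for subject in sorted(subjects.get(group, ())):
            if (subject, group, condition) not in epochs:
                missing.append((subject, group, condition))
    if missing:
        raise MissingDataError(f"missing subject x condition epochs: {missing}")

    rows = []
    for (group, condition), dag in sorted(graphs.items()):
        for subject in sorted(subjects.get(group, ())):
            series = epochs[(subject, group, condition)]
            for (src, dst), coef in sorted(
                fit_subject_weights(dag, series).items()
            ):
                rows.append((subject, group, condition, src, dst, coef))
    return pd.DataFrame(rows, columns=WEIGHT_COLUMNS)


def group_mean_weights(table: pd.DataFrame) -> pd.DataFrame:
    """Group-level strength: mean coefficient across subjects per edge."""
    return (
        table.groupby(["group", "condition", "source", "target"], as_index=False)[
            "coefficient"
        ]
        .mean()
        .rename(columns={"coefficient": "mean_coefficient"})
    )
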