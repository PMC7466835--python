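"""File I/O: ROI time-series tables, edge-list graphs, cohorts.

Time series travel as rectangular TSV/CSV tables with an ROI header row;
graphs as sorted edge-list TSVs (source, target, type) that round-trip
exactly, with optional DOT and GraphML export; simulated cohorts as one
TSV per subject plus a JSON sidecar recording design, group, seed, and
ground-truth edges for test harnesses.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .design import TaskDesign
from .exceptions import ParseError
from .graphs import Cpdag, Dag
from .simulate import Block, RoiTimeSeries, TaskRun

GRAPH_FORMATS = ("edgelist", "dot", "graphml")


def read_timeseries(
    path,
    fmt: str | None = None,
    subject: str = "unknown",
    group: str = "unknown",
    condition: str = "unknown",
) -> RoiTimeSeries:
    """Read a labeled numeric table as an ROI time series.

    ``fmt`` is "tsv" or "csv"; inferred from the suffix when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt == "csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ParseError(f"{path}: duplicate ROI labels {dupes}")
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as err:  # pandas raises several parse error types
        raise ParseError(f"{path}: {err}") from err
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        for c in non_numeric:
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric value in column {c!r} near line {line}")
    if df.isna().any().any():
        row = int(df[df.isna().any(axis=1)].index[0]) + 2
        raise ParseError(f"{path}: missing value near line {row}")
    return RoiTimeSeries(
        subject=subject, group=group, condition=condition, data=df.astype(float)
    )


def write_timeseries(series: RoiTimeSeries, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt == "csv" else "\t"
    series.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Graphs
# ---------------------------------------------------------------------------


def _graph_rows(graph: Dag | Cpdag):
    if isinstance(graph, Dag):
        for u, v in sorted(graph.edges):
            yield u, v, "directed"
    else:
        for u, v in sorted(graph.directed):
            yield u, v, "directed"
        for a, b in sorted(graph.undirected):
            yield a, b, "undirected"


def write_graph(graph: Dag | Cpdag, path, fmt: str = "edgelist") -> None:
    """Serialize a graph deterministically (sorted rows / sorted nodes)."""
    path = Path(path)
    if fmt not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; choose from {GRAPH_FORMATS}")
    if fmt == "edgelist":
        lines = ["source\ttarget\ttype"]
        lines += [f"{u}\t{v}\t{kind}" for u, v, kind in _graph_rows(graph)]
        lines += [f"# node\t{n}" for n in graph.nodes]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "dot":
        lines = ["digraph emonet {"]
        for n in graph.nodes:
            lines.append(f'    "{n}";')
        for u, v, kind in _graph_rows(graph):
            attr = "" if kind == "directed" else " [dir=none]"
            lines.append(f'    "{u}" -> "{v}"{attr};')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:  # graphml
        g = nx.DiGraph()
        g.add_nodes_from(graph.nodes)
        for u, v, kind in _graph_rows(graph):
            g.add_edge(u, v, type=kind)
        nx.write_graphml(g, path)


def read_graph(path) -> Dag | Cpdag:
    """Read an edge-list TSV written by :func:`write_graph`.

    Returns a :class:`Dag` when all rows are directed, otherwise a
    :class:`Cpdag`.
    """
    path = Path(path)
    directed, undirected, nodes = set(), set(), []
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != ["source", "target", "type"]:
        raise ParseError(f"{path}: not an emonet edge-list file")
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("# node\t"):
            nodes.append(line.split("\t", 1)[1])
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}:{ln}: expected 3 columns")
        u, v, kind = parts
        if kind == "directed":
            directed.add((u, v))
        elif kind == "undirected":
            undirected.add((u, v))
        else:
            raise ParseError(f"{path}:{ln}: unknown edge type {kind!r}")
    if not nodes:
        nodes = sorted({n for e in directed | undirected for n in e})
    if undirected:
        return Cpdag(tuple(nodes), frozenset(directed), frozenset(undirected))
    return Dag(tuple(nodes), frozenset(directed))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def write_cohort(
    runs: list[TaskRun],
    design: TaskDesign,
    directory,
    truths: dict | None = None,
    seed: int | None = None,
) -> None:
    """One TSV per subject run plus a JSON sidecar per subject.

    The sidecar records the design, group, block annotations, master
    seed, and (when ``truths`` maps group -> condition -> edge list) the
    generating edges, so downstream harnesses can score recovery.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for run in runs:
        stem = directory / f"{run.subject}_run"
        run.series.data.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)
        sidecar = {
            "subject": run.subject,
            "group": run.group,
            "seed": seed,
            "design": dataclasses.asdict(design),
            "blocks": [dataclasses.asdict(b) for b in run.blocks],
        }
        if truths and run.group in truths:
            sidecar["ground_truth_edges"] = {
                cond: sorted(map(list, model.edges))
                for cond, model in truths[run.group].items()
            }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_cohort(directory) -> list[tuple[TaskRun, dict]]:
    """Read runs written by :func:`write_cohort` with their sidecars."""
    directory = Path(directory)
    out = []
    for sidecar_path in sorted(directory.glob("*_run.json")):
        meta = json.loads(sidecar_path.read_text())
        tsv = sidecar_path.with_suffix(".tsv")
        series = read_timeseries(
            tsv, subject=meta["subject"], group=meta["group"], condition="full_run"
        )
        blocks = tuple(Block(**b) for b in meta["blocks"])
        out.append((TaskRun(series=series, blocks=blocks), meta))
    return out
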