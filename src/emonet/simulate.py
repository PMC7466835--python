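"""Synthetic multi-subject ROI time series with known directed structure.

Data are generated from a linear structural equation model with acyclic
contemporaneous coupling: at each time point t,

    x_t = B x_t + e_t        =>        x_t = (I - B)^(-1) e_t

where B[v, u] is the weight of directed edge u -> v and e_t are
independent innovations.  Innovations can be Laplace (default; the heavy
tails make edge directions identifiable from regression residuals),
Gaussian (directions become unidentifiable - retained to test that the
orientation stage degrades as theory predicts), or centered squared
Gaussian (a skewed alternative).  An optional AR(1) filter on each
innovation stream mimics the temporal smoothness of BOLD data without
changing the contemporaneous structure.

Scales are parameterized so ``noise_scale`` is the innovation standard
deviation for every family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import TaskDesign
from .exceptions import (
    CyclicGraphError,
    EmptyGroupError,
    MissingModelError,
    StabilityError,
)
from .graphs import Dag, Edge

#: The eight regions of interest of the emotion-reactivity network.
DEFAULT_ROIS = (
    "LSFG",
    "RSFG",
    "LACC",
    "LMFG",
    "RInsula",
    "LParah",
    "RParah",
    "LAmygdala",
)

NOISE_FAMILIES = ("gaussian", "laplace", "squared_gaussian")

#: Weights above this magnitude are rejected as numerically risky.
MAX_ABS_WEIGHT = 1.5


@dataclass(frozen=True)
class GroundTruthModel:
    """Generating directed network for one condition.

    ``weights`` maps each directed edge to its SEM coefficient; the edge
    set (keys) must be acyclic over ``nodes``.
    """

    nodes: tuple[str, ...]
    weights: dict[Edge, float] = field(default_factory=dict)
    noise_family: str = "laplace"
    noise_scale: float = 1.0
    ar_coefficient: float = 0.3

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "weights", {tuple(e): float(w) for e, w in self.weights.items()}
        )
        if self.noise_family not in NOISE_FAMILIES:
            raise ValueError(
                f"noise_family must be one of {NOISE_FAMILIES}, got {self.noise_family!r}"
            )
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if not 0 <= self.ar_coefficient < 1:
            raise StabilityError(
                f"ar_coefficient must be in [0, 1), got {self.ar_coefficient}"
            )
        for e, w in self.weights.items():
            if abs(w) > MAX_ABS_WEIGHT:
                raise StabilityError(
                    f"|weight| {abs(w):.3g} of edge {e} exceeds {MAX_ABS_WEIGHT}"
                )
        # acyclicity check (raises CyclicGraphError)
        self.dag()

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(self.weights)

    def dag(self) -> Dag:
        return Dag(self.nodes, frozenset(self.weights))

    def coefficient_matrix(self) -> np.ndarray:
        """B with B[v, u] = weight of u -> v (node order = ``nodes``)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        b = np.zeros((len(self.nodes), len(self.nodes)))
        for (u, v), w in self.weights.items():
            b[idx[v], idx[u]] = w
        return b

    def null_model(self) -> "GroundTruthModel":
        """Edge-free copy (used for fixation periods)."""
        return replace(self, weights={})

    def implied_covariance(self) -> np.ndarray:
        """Stationary covariance (I-B)^-1 D (I-B)^-T of the SEM.

        D is the innovation covariance; with AR(1) filtering each stream's
        variance is noise_scale^2 / (1 - ar^2).
        """
        b = self.coefficient_matrix()
        ainv = np.linalg.inv(np.eye(len(self.nodes)) - b)
        var = self.noise_scale**2 / (1.0 - self.ar_coefficient**2)
        return ainv @ (var * np.eye(len(self.nodes))) @ ainv.T


@dataclass(frozen=True)
class CohortSpec:
    """One group of subjects sharing per-condition generating models."""

    group: str
    n_subjects: int
    models: dict[str, GroundTruthModel]
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise EmptyGroupError(f"group {self.group!r} has no subjects")
        node_sets = {m.nodes for m in self.models.values()}
        if len(node_sets) > 1:
            raise ValueError("all condition models must share the same node list")


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject x condition matrix of ROI signals (rows = time points)."""

    subject: str
    group: str
    condition: str
    data: pd.DataFrame

    def __post_init__(self):
        if self.data.isna().any().any():
            raise ValueError("time series contains missing values")

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_timepoints(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass(frozen=True)
class Block:
    """Row-index span of one block: [start, stim_start) is fixation."""

    condition: str
    start: int
    stim_start: int
    stop: int


@dataclass(frozen=True)
class TaskRun:
    """A full-run time series with its block annotations."""

    series: RoiTimeSeries
    blocks: tuple[Block, ...]

    @property
    def subject(self) -> str:
        return self.series.subject

    @property
    def group(self) -> str:
        return self.series.group


# ---------------------------------------------------------------------------
# Sampling and simulation
# ---------------------------------------------------------------------------


def sample_ground_truth(
    nodes,
    edge_density: float | None = 0.25,
    edges=None,
    weight_range: tuple[float, float] = (0.4, 0.8),
    noise_family: str = "laplace",
    noise_scale: float = 1.0,
    ar_coefficient: float = 0.3,
    seed: int = 0,
    forbid_triangles: bool = False,
) -> GroundTruthModel:
    """Sample a random acyclic generating model.

    A random topological order of ``nodes`` is drawn, and each
    earlier-to-later pair becomes an edge with probability
    ``edge_density``; weights are uniform on ``weight_range`` with random
    sign.  ``weight_range`` must exclude a neighbourhood of zero so that
    true edges are detectable.  Passing ``edges`` explicitly skips
    sampling (weights are still drawn); an explicit cyclic edge list
    raises :class:`CyclicGraphError`.

    With ``forbid_triangles`` the sampler rejects any edge that would
    close a 3-clique in the skeleton, matching the analysis-side
    assumption that the true network is triangle-free (the penalty
    escalation of the search stage removes all triangles by design).
    """
    nodes = tuple(nodes)
    if not nodes:
        raise ValueError("nodes must be non-empty")
    lo, hi = weight_range
    if not (0 < lo <= hi):
        raise ValueError("weight_range must satisfy 0 < lo <= hi (sign is drawn)")
    if lo < 0.05:
        raise ValueError("weight_range must exclude a neighbourhood of 0")
    rng = np.random.default_rng(seed)

    if edges is not None:
        edge_list = [tuple(e) for e in edges]
        Dag(nodes, frozenset(edge_list))  # raises CyclicGraphError on a cycle
    else:
        order = list(nodes)
        rng.shuffle(order)
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        edge_list = []
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                u, v = order[i], order[j]
                if rng.random() >= edge_density:
                    continue
                if forbid_triangles and (adj[u] & adj[v]):
                    continue
                edge_list.append((u, v))
                adj[u].add(v)
                adj[v].add(u)

    weights = {}
    for e in edge_list:
        w = rng.uniform(lo, hi)
        if rng.random() < 0.5:
            w = -w
        weights[e] = w
    return GroundTruthModel(
        nodes=nodes,
        weights=weights,
        noise_family=noise_family,
        noise_scale=noise_scale,
        ar_coefficient=ar_coefficient,
    )


def _innovations(
    model: GroundTruthModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    p = len(model.nodes)
    s = model.noise_scale
    if model.noise_family == "gaussian":
        z = rng.normal(0.0, s, size=(n, p))
    elif model.noise_family == "laplace":
        z = rng.laplace(0.0, s / np.sqrt(2.0), size=(n, p))
    else:  # squared_gaussian: centered chi^2_1, sd = noise_scale
        g = rng.normal(size=(n, p))
        z = s * (g**2 - 1.0) / np.sqrt(2.0)
    a = model.ar_coefficient
    if a > 0:
        e = np.empty_like(z)
        e[0] = z[0] / np.sqrt(1.0 - a**2)  # stationary start
        for t in range(1, n):
            e[t] = a * e[t - 1] + z[t]
        return e
    return z


def simulate_condition_series(
    model: GroundTruthModel,
    n_timepoints: int,
    seed,
    subject: str = "sim",
    group: str = "sim",
    condition: str = "condition",
) -> RoiTimeSeries:
    """Simulate one condition's series from the SEM x = Bx + e.

    Rows are solved in topological order (equivalently x = (I-B)^-1 e).
    Bit-identical for a fixed seed.
    """
    if n_timepoints < 20:
        raise ValueError("n_timepoints must be >= 20")
    rng = np.random.default_rng(seed)
    e = _innovations(model, n_timepoints, rng)
    b = model.coefficient_matrix()
    x = e @ np.linalg.inv(np.eye(len(model.nodes)) - b).T
    df = pd.DataFrame(x, columns=list(model.nodes))
    return RoiTimeSeries(subject=subject, group=group, condition=condition, data=df)


def simulate_run(
    subject: str,
    group: str,
    design: TaskDesign,
    per_condition_models: dict[str, GroundTruthModel],
    seed,
) -> TaskRun:
    """Simulate a full block-design run for one subject.

    Fixation volumes come from the edge-free null model (so that epoch
    extraction is exercised against structure-free baseline data);
    stimulus volumes come from the block's condition model.  Total rows =
    design duration / TR.
    """
    for cond in design.conditions:
        if cond not in per_condition_models:
            raise MissingModelError(f"no generating model for condition {cond!r}")
    node_sets = {m.nodes for m in per_condition_models.values()}
    if len(node_sets) != 1:
        raise ValueError("per-condition models must share the same node list")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(2 * design.n_blocks)
    any_model = next(iter(per_condition_models.values()))
    null = any_model.null_model()

    segments = []
    blocks = []
    row = 0
    for i, cond in enumerate(design.condition_order):
        start = row
        if design.fixation_volumes > 0:
            fix = simulate_condition_series(
                null,
                max(design.fixation_volumes, 20),
                child_seeds[2 * i],
                subject,
                group,
                "fixation",
            )
            segments.append(fix.data.iloc[: design.fixation_volumes])
            row += design.fixation_volumes
        stim_start = row
        stim = simulate_condition_series(
            per_condition_models[cond],
            max(design.stimulus_volumes, 20),
            child_seeds[2 * i + 1],
            subject,
            group,
            cond,
        )
        segments.append(stim.data.iloc[: design.stimulus_volumes])
        row += design.stimulus_volumes
        blocks.append(Block(condition=cond, start=start, stim_start=stim_start, stop=row))

    data = pd.concat(segments, ignore_index=True)
    series = RoiTimeSeries(subject=subject, group=group, condition="full_run", data=data)
    return TaskRun(series=series, blocks=tuple(blocks))


def generate_cohort(
    specs: list[CohortSpec], design: TaskDesign, seed: int
) -> list[TaskRun]:
    """One full run per subject across all groups.

    Per-subject seeds derive deterministically from ``seed`` via
    ``numpy.random.SeedSequence([seed, group_index, subject_index])``.
    """
    labels = [s.group for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be distinct")
    runs = []
    for gi, spec in enumerate(specs):
        for cond in design.conditions:
            if cond not in spec.models:
                raise MissingModelError(
                    f"group {spec.group!r} has no model for condition {cond!r}"
                )
        for si in range(spec.n_subjects):
            sid = f"{spec.group}{si + 1:02d}"
            subj_seed = np.random.SeedSequence([int(seed), spec.seed, gi, si])
            runs.append(simulate_run(sid, spec.group, design, spec.models, subj_seed))
    return runs
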