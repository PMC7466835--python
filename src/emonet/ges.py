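"""Greedy equivalence search with pooled per-subject BIC.

This is the multi-subject ("IMaGES-style") variant of GES: the local
score of a node given a parent set is the arithmetic mean, over
subjects, of the per-subject Gaussian BIC

    s(y | P) = -n ln(sigma_hat^2) - c (|P| + 1) ln(n),

where sigma_hat^2 is the ML residual variance of regressing y on P
without intercept (data are standardized), and c >= 1 is the penalty
discount multiplying the complexity penalty.  Constants common to all
parent sets are dropped.

The search runs over equivalence classes (CPDAGs) with the standard
Insert/Delete operators: forward from the empty graph, applying the
valid insertion with the largest positive pooled-score improvement,
then backward deletions, each move followed by rebuilding the completed
pattern.  Because task-fMRI data easily produce spurious triangulated
patterns, :func:`select_penalty` escalates c along a grid and returns
the first triangle-free result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CollinearityError, NoTriangleFreeGraphError
from .graphs import Cpdag, Dag, Edge, _pair, cpdag_of, pdag_to_dag
from .simulate import RoiTimeSeries

#: Score improvements below this are treated as ties / no improvement.
IMPROVEMENT_TOL = 1e-9

#: Escalation grid for the penalty discount.  Induced dependences from
#: common causes can hold a spurious triangle chord in place well past
#: c = 4, so the grid extends until the complexity penalty dominates them.
DEFAULT_PENALTY_GRID = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0)


@dataclass(frozen=True)
class ScoreConfig:
    """Search settings: penalty grid and optional parent cap."""

    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID
    max_parents: int | None = None

    def __post_init__(self):
        grid = tuple(float(c) for c in self.penalty_grid)
        object.__setattr__(self, "penalty_grid", grid)
        if not grid:
            raise ValueError("penalty_grid must be non-empty")
        if grid[0] < 1.0:
            raise ValueError("penalty grid must start at >= 1")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("penalty grid must be strictly increasing")


class _SubjectStats:
    """Sufficient statistics (X'X / n) of one standardized dataset."""

    def __init__(self, series: RoiTimeSeries):
        x = series.values()
        self.n = x.shape[0]
        self.s = x.T @ x / self.n
        self.index = {name: i for i, name in enumerate(series.rois)}

    def residual_variance(self, node: str, parents: frozenset[str]) -> float:
        yi = self.index[node]
        if not parents:
            return float(self.s[yi, yi])
        pi = [self.index[p] for p in sorted(parents)]
        spp = self.s[np.ix_(pi, pi)]
        spy = self.s[pi, yi]
        try:
            beta = np.linalg.solve(spp, spy)
        except np.linalg.LinAlgError as err:
            raise CollinearityError(
                f"singular regressor matrix for node {node!r} "
                f"with parents {sorted(parents)}"
            ) from err
        var = float(self.s[yi, yi] - spy @ beta)
        return max(var, 1e-12)


def local_bic(
    data: RoiTimeSeries, node: str, parents, c: float = 1.0
) -> float:
    """Per-subject local BIC of ``node`` given ``parents`` (higher is better)."""
    parents = frozenset(parents)
    if node in parents:
        raise ValueError(f"node {node!r} cannot be its own parent")
    stats = _SubjectStats(data)
    if len(parents) > stats.n - 2:
        raise ValueError(
            f"parent set of size {len(parents)} too large for {stats.n} rows"
        )
    var = stats.residual_variance(node, parents)
    n = stats.n
    return -n * np.log(var) - c * (len(parents) + 1) * np.log(n)


class PooledScorer:
    """Cached arithmetic-mean-over-subjects local BIC."""

    def __init__(self, datasets: list[RoiTimeSeries], c: float):
        if not datasets:
            raise ValueError("at least one dataset required")
        labels = {d.rois for d in datasets}
        if len(labels) != 1:
            raise ValueError("datasets must share ROI labels")
        self.nodes = datasets[0].rois
        self.c = float(c)
        self._stats = [_SubjectStats(d) for d in datasets]
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def local(self, node: str, parents) -> float:
        parents = frozenset(parents)
        key = (node, parents)
        if key not in self._cache:
            k = len(parents) + 1
            total = 0.0
            for st in self._stats:
                var = st.residual_variance(node, parents)
                total += -st.n * np.log(var) - self.c * k * np.log(st.n)
            self._cache[key] = total / len(self._stats)
        return self._cache[key]

    def total(self, dag: Dag) -> float:
        """Decomposable total score: sum of local scores over nodes."""
        return sum(self.local(n, dag.parents(n)) for n in dag.nodes)


def pooled_score(
    datasets: list[RoiTimeSeries], node: str, parents, c: float = 1.0
) -> float:
    """Arithmetic mean of :func:`local_bic` over datasets."""
    return PooledScorer(datasets, c).local(node, frozenset(parents))


# ---------------------------------------------------------------------------
# Search state
# ---------------------------------------------------------------------------


@dataclass
class _State:
    """Mutable CPDAG during search: directed parents + undirected neighbours."""

    nodes: tuple[str, ...]
    parents: dict[str, set[str]] = field(default_factory=dict)
    neighbors: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def empty(cls, nodes):
        nodes = tuple(nodes)
        return cls(
            nodes,
            {n: set() for n in nodes},
            {n: set() for n in nodes},
        )

    @classmethod
    def from_cpdag(cls, cp: Cpdag):
        st = cls.empty(cp.nodes)
        for u, v in cp.directed:
            st.parents[v].add(u)
        for a, b in cp.undirected:
            st.neighbors[a].add(b)
            st.neighbors[b].add(a)
        return st

    def to_cpdag(self) -> Cpdag:
        directed = {
            (u, v) for v in self.nodes for u in self.parents[v]
        }
        undirected = {
            _pair(a, b) for a in self.nodes for b in self.neighbors[a]
        }
        return Cpdag(self.nodes, frozenset(directed), frozenset(undirected))

    def adjacent(self, a: str, b: str) -> bool:
        return (
            b in self.neighbors[a]
            or a in self.parents[b]
            or b in self.parents[a]
        )

    def adjacency(self, a: str) -> set[str]:
        out = set(self.neighbors[a]) | set(self.parents[a])
        out |= {v for v in self.nodes if a in self.parents[v]}
        return out

    def is_clique(self, group) -> bool:
        return all(
            self.adjacent(a, b) for a, b in itertools.combinations(group, 2)
        )

    def semi_directed_path(self, src: str, dst: str, blocked) -> bool:
        """Is there a path src -> dst along directed (forward) or undirected
        edges that avoids ``blocked``?"""
        if src in blocked:
            return False
        seen = {src}
        stack = [src]
        while stack:
            x = stack.pop()
            nxt = set(self.neighbors[x]) | {
                v for v in self.nodes if x in self.parents[v]
            }
            for y in nxt:
                if y in blocked or y in seen:
                    continue
                if y == dst:
                    return True
                seen.add(y)
                stack.append(y)
        return False

    def rebuild(self) -> "_State":
        """Recompute the completed pattern of the current PDAG."""
        directed = {(u, v) for v in self.nodes for u in self.parents[v]}
        undirected = {
            _pair(a, b) for a in self.nodes for b in self.neighbors[a]
        }
        dag = pdag_to_dag(self.nodes, directed, undirected)
        return _State.from_cpdag(cpdag_of(dag))


def _subsets(items):
    items = sorted(items)
    for r in range(len(items) + 1):
        yield from itertools.combinations(items, r)


def _forward_moves(state: _State, scorer: PooledScorer, max_parents):
    """Yield (delta, y, x, T) for every valid Insert(x, y, T)."""
    for y in state.nodes:
        for x in state.nodes:
            if x == y or state.adjacent(x, y):
                continue
            na = {z for z in state.neighbors[y] if state.adjacent(z, x)}
            t0 = [z for z in state.neighbors[y] if not state.adjacent(z, x)]
            for t in _subsets(t0):
                s = na | set(t)
                if max_parents is not None and (
                    len(state.parents[y]) + len(s) + 1 > max_parents
                ):
                    continue
                if not state.is_clique(s):
                    continue
                if state.semi_directed_path(y, x, s):
                    continue
                base = frozenset(state.parents[y]) | s
                delta = scorer.local(y, base | {x}) - scorer.local(y, base)
                yield delta, y, x, tuple(t)


def _backward_moves(state: _State, scorer: PooledScorer):
    """Yield (delta, y, x, H) for every valid Delete(x, y, H)."""
    pairs = []
    for y in state.nodes:
        for x in state.parents[y]:
            pairs.append((x, y))
        for x in state.neighbors[y]:
            if (x, y) not in pairs:
                pairs.append((x, y))
    for x, y in pairs:
        na = {z for z in state.neighbors[y] if state.adjacent(z, x)}
        for h in _subsets(na):
            keep = na - set(h)
            if not state.is_clique(keep):
                continue
            base = (frozenset(state.parents[y]) | keep) - {x}
            delta = scorer.local(y, base) - scorer.local(y, base | {x})
            yield delta, y, x, tuple(h)


def _apply_insert(state: _State, y: str, x: str, t) -> _State:
    state.parents[y].add(x)
    for z in t:
        state.neighbors[y].discard(z)
        state.neighbors[z].discard(y)
        state.parents[y].add(z)
    return state.rebuild()


def _apply_delete(state: _State, y: str, x: str, h) -> _State:
    state.parents[y].discard(x)
    state.neighbors[y].discard(x)
    state.neighbors[x].discard(y)
    for z in h:
        # orient y - z as y -> z
        if z in state.neighbors[y]:
            state.neighbors[y].discard(z)
            state.neighbors[z].discard(y)
            state.parents[z].add(y)
        # orient x - z as x -> z
        if z in state.neighbors[x]:
            state.neighbors[x].discard(z)
            state.neighbors[z].discard(x)
            state.parents[z].add(x)
    return state.rebuild()


def _best_move(moves):
    """Largest-delta move; ties broken lexicographically on (y, x, set)."""
    best = None
    for delta, y, x, extra in moves:
        if delta <= IMPROVEMENT_TOL:
            continue
        key = (-delta, y, x, extra)
        if best is None or key < best[0]:
            best = (key, delta, y, x, extra)
    return best


def ges(
    datasets: list[RoiTimeSeries],
    c: float = 1.0,
    config: ScoreConfig | None = None,
) -> Cpdag:
    """Two-stage greedy equivalence search at penalty discount ``c``.

    Starts from the empty graph; the forward stage repeatedly applies the
    valid Insert operator with the largest positive pooled-score
    improvement (scored via the local change at the child node),
    rebuilding the completed pattern after each move, until no insertion
    improves; the backward stage then applies improving Delete operators
    to a local optimum.  Returns the final pattern.
    """
    config = config or ScoreConfig()
    scorer = PooledScorer(datasets, c)
    state = _State.empty(scorer.nodes)

    while True:
        move = _best_move(_forward_moves(state, scorer, config.max_parents))
        if move is None:
            break
        _, _, y, x, t = move
        state = _apply_insert(state, y, x, t)

    while True:
        move = _best_move(_backward_moves(state, scorer))
        if move is None:
            break
        _, _, y, x, h = move
        state = _apply_delete(state, y, x, h)

    return state.to_cpdag()


def select_penalty(
    datasets: list[RoiTimeSeries], config: ScoreConfig | None = None
) -> tuple[float, Cpdag]:
    """Escalate the penalty discount until the pattern has no triangles.

    Runs :func:`ges` at each grid value in increasing order and returns
    the first (c, graph) whose skeleton contains no 3-clique.

    Raises
    ------
    NoTriangleFreeGraphError
        If the grid is exhausted with triangles remaining; the last graph
        is attached to the exception.
    """
    config = config or ScoreConfig()
    last = None
    for c in config.penalty_grid:
        graph = ges(datasets, c=c, config=config)
        last = graph
        if not graph.has_triangle():
            return c, graph
    raise NoTriangleFreeGraphError(
        f"no triangle-free graph on penalty grid {config.penalty_grid}",
        last_graph=last,
    )
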