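"""Non-Gaussianity-based edge orientation (LOFS with Anderson-Darling).

Given the adjacency structure found by the search stage, the orientation
stage exploits the linear-SEM identifiability result: when innovations
are independent and non-Gaussian, the regression residuals of the true
causal model are less Gaussian than those of any mis-oriented model.
Holding the skeleton fixed, we search acyclic direction assignments of
the undirected edges and maximize the total departure from normality of
the per-node regression residuals, summed over subjects, measured by the
Anderson-Darling A^2 statistic.

With Gaussian innovations the objective carries no directional
information and accuracy falls to chance - a property, not a defect, and
one the test suite checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps

from .exceptions import CyclicGraphError, DegenerateSignalError
from .graphs import Cpdag, Dag, Edge, pdag_to_dag
from .simulate import RoiTimeSeries

#: Clamp for normal CDF values before taking logs.
PHI_CLAMP = 1e-15

#: 5% critical value of A^2 for normality with estimated mean and variance
#: (case 4 of the classical tables).
AD_CRITICAL_5PCT = 0.752


def anderson_darling(sample) -> float:
    """Anderson-Darling A^2 statistic against the normal family.

    The sample is studentized by its own mean and (ddof=1) standard
    deviation, sorted, and scored as

        A^2 = -n - (1/n) * sum_i (2i-1) [ln F(z_(i)) + ln(1 - F(z_(n+1-i)))]

    with F the standard normal CDF, probabilities clamped away from
    {0, 1}.  Invariant to affine transforms of the sample.  Larger values
    mean stronger departure from normality.
    """
    x = np.asarray(sample, dtype=float).ravel()
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 observations, got {n}")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise DegenerateSignalError("constant sample has no A^2 statistic")
    z = np.sort((x - x.mean()) / sd)
    cdf = np.clip(sps.norm.cdf(z), PHI_CLAMP, 1.0 - PHI_CLAMP)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1.0 - cdf[::-1])))
    return float(a2)


def residual_nongaussianity(
    datasets: list[RoiTimeSeries], node: str, parents
) -> float:
    """Sum over subjects of A^2 of the node's regression residuals.

    Within each subject the node is regressed on its parents by OLS
    without intercept (standardized data); an empty parent set scores the
    node's own column.
    """
    parents = sorted(parents)
    total = 0.0
    for d in datasets:
        y = d.data[node].to_numpy(dtype=float)
        if parents:
            x = d.data[parents].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
        else:
            resid = y
        total += anderson_darling(resid)
    return total


class _Objective:
    """Cached total-A^2 objective over direction assignments."""

    def __init__(self, datasets):
        self.datasets = datasets
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def node_score(self, node: str, parents: frozenset[str]) -> float:
        key = (node, parents)
        if key not in self._cache:
            self._cache[key] = residual_nongaussianity(
                self.datasets, node, parents
            )
        return self._cache[key]

    def total(self, parents_map: dict[str, frozenset[str]]) -> float:
        return sum(self.node_score(n, p) for n, p in parents_map.items())


def _parents_map(nodes, edges) -> dict[str, frozenset[str]]:
    pa: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        pa[v].add(u)
    return {n: frozenset(p) for n, p in pa.items()}


def _is_acyclic(nodes, edges) -> bool:
    # Kahn's algorithm on a small edge set
    pa: dict[str, set[str]] = {n: set() for n in nodes}
    ch: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        pa[v].add(u)
        ch[u].add(v)
    avail = [n for n in nodes if not pa[n]]
    seen = 0
    while avail:
        x = avail.pop()
        seen += 1
        for y in ch[x]:
            pa[y].discard(x)
            if not pa[y]:
                avail.append(y)
    return seen == len(nodes)


def _random_acyclic_orientation(
    nodes, fixed: set[Edge], und: list[Edge], rng
) -> set[Edge] | None:
    """Orient ``und`` along a random topological order consistent with
    ``fixed`` (randomized Kahn)."""
    pa: dict[str, set[str]] = {n: set() for n in nodes}
    ch: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in fixed:
        pa[v].add(u)
        ch[u].add(v)
    avail = sorted(n for n in nodes if not pa[n])
    order = []
    while avail:
        x = avail.pop(rng.integers(len(avail)))
        order.append(x)
        for y in sorted(ch[x]):
            pa[y].discard(x)
            if not pa[y]:
                avail.append(y)
        avail.sort()
    if len(order) != len(nodes):
        return None
    rank = {n: i for i, n in enumerate(order)}
    return {
        (a, b) if rank[a] < rank[b] else (b, a) for a, b in und
    }


def lofs_orient(
    skeleton: Cpdag,
    datasets: list[RoiTimeSeries],
    fix_v_structures: bool = False,
    max_exhaustive: int = 12,
    n_restarts: int = 5,
    seed: int = 0,
) -> Dag:
    """Orient a pattern into the least-Gaussian-residual DAG.

    The adjacency structure is held fixed and every edge direction is
    searched, as in fixed-structure orientation proper: the search stage
    is trusted for adjacencies but not for arrows, since near-tied
    equivalence classes (e.g. which nodes of a chordless four-cycle are
    the colliders) are routinely mis-resolved at fMRI sample sizes while
    the residual-non-Gaussianity objective separates them cleanly.  Pass
    ``fix_v_structures=True`` to keep the pattern's compelled arrows
    (v-structures and their Meek consequences) immutable and search only
    the undirected edges.  All acyclic assignments of the free edges are
    enumerated exhaustively when there are at most ``max_exhaustive`` of
    them; otherwise a node-wise greedy flip search with ``n_restarts``
    seeded random restarts is used.  Exhaustive ties resolve to the first
    assignment in lexicographic edge-direction order.
    """
    nodes = skeleton.nodes
    if fix_v_structures:
        fixed = set(skeleton.directed)
        und = sorted(skeleton.undirected)
    else:
        fixed = set()
        und = sorted(skeleton.skeleton())

    if not und:
        return Dag(nodes, frozenset(fixed))

    obj = _Objective(datasets)

    if len(und) <= max_exhaustive:
        best = None
        for bits in itertools.product((0, 1), repeat=len(und)):
            edges = set(fixed)
            for (a, b), flip in zip(und, bits):
                edges.add((b, a) if flip else (a, b))
            if not _is_acyclic(nodes, edges):
                continue
            score = obj.total(_parents_map(nodes, edges))
            if best is None or score > best[0] + 1e-12:
                best = (score, edges)
        if best is None:
            raise CyclicGraphError(
                "no acyclic orientation of the pattern exists"
            )
        return Dag(nodes, frozenset(best[1]))

    # Greedy node-wise hill-climbing with restarts
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        oriented = _random_acyclic_orientation(nodes, fixed, und, rng)
        if oriented is None:
            raise CyclicGraphError("no acyclic orientation of the pattern exists")
        edges = set(fixed) | oriented
        score = obj.total(_parents_map(nodes, edges))
        improved = True
        while improved:
            improved = False
            for node in sorted(nodes):
                for a, b in und:
                    if node not in (a, b):
                        continue
                    cur = (a, b) if (a, b) in edges else (b, a)
                    flipped = (cur[1], cur[0])
                    trial = (edges - {cur}) | {flipped}
                    if not _is_acyclic(nodes, trial):
                        continue
                    trial_score = obj.total(_parents_map(nodes, trial))
                    if trial_score > score + 1e-12:
                        edges, score = trial, trial_score
                        improved = True
        if best is None or score > best[0] + 1e-12:
            best = (score, edges)
    return Dag(nodes, frozenset(best[1]))
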