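"""Directed and partially directed acyclic graphs over ROI labels.

A :class:`Dag` is a fully directed acyclic graph; a :class:`Cpdag` is the
completed pattern (CPDAG) representing a Markov equivalence class, with a
directed part (compelled edges) and an undirected part (reversible edges).

Conversion from a DAG to its CPDAG keeps the skeleton, directs the
v-structure edges, and closes under Meek's orientation rules.  Rules R1-R3
are applied; R4 cannot fire when every initial orientation comes from the
v-structures of a consistent DAG (it is only needed in the presence of
background knowledge), which is the only way partially directed graphs
arise in this package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .exceptions import CyclicGraphError

Edge = tuple[str, str]


def _pair(a: str, b: str) -> Edge:
    """Canonical (sorted) representation of an unordered node pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Dag:
    """A directed acyclic graph over labeled nodes.

    Parameters
    ----------
    nodes
        Ordered node labels (the ROI order of the data columns).
    edges
        Directed edges as (source, target) pairs.
    """

    nodes: tuple[str, ...]
    edges: frozenset[Edge] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")
        for u, v in self.edges:
            if u == v:
                raise CyclicGraphError(f"self-loop at {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CyclicGraphError(f"edge set contains a cycle: {cycle}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> frozenset[str]:
        return frozenset(u for u, v in self.edges if v == node)

    def children(self, node: str) -> frozenset[str]:
        return frozenset(v for u, v in self.edges if u == node)

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    def skeleton(self) -> frozenset[Edge]:
        """Unordered adjacency pairs."""
        return frozenset(_pair(u, v) for u, v in self.edges)

    def topological_order(self) -> list[str]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return list(
            nx.lexicographical_topological_sort(
                self.to_networkx(), key=lambda n: order[n]
            )
        )


@dataclass(frozen=True)
class Cpdag:
    """A completed partially directed acyclic graph (pattern).

    ``directed`` holds compelled edges as (source, target); ``undirected``
    holds reversible edges as canonical sorted pairs.  The two sets are
    disjoint and the directed part is acyclic.
    """

    nodes: tuple[str, ...]
    directed: frozenset[Edge] = field(default_factory=frozenset)
    undirected: frozenset[Edge] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "directed", frozenset(tuple(e) for e in self.directed)
        )
        object.__setattr__(
            self, "undirected", frozenset(_pair(*e) for e in self.undirected)
        )
        dir_pairs = {_pair(u, v) for u, v in self.directed}
        if dir_pairs & self.undirected:
            raise ValueError("an edge cannot be both directed and undirected")
        for u, v in self.directed | self.undirected:
            if u == v:
                raise CyclicGraphError(f"self-loop at {u!r}")
        Dag(self.nodes, self.directed)  # acyclicity of the directed part

    def skeleton(self) -> frozenset[Edge]:
        return frozenset(_pair(u, v) for u, v in self.directed) | self.undirected

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)

    def adjacent(self, a: str, b: str) -> bool:
        return _pair(a, b) in self.skeleton()

    def has_triangle(self) -> bool:
        """True if the skeleton contains any 3-clique."""
        skel = self.skeleton()
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in skel:
            adj[a].add(b)
            adj[b].add(a)
        for a, b in skel:
            if adj[a] & adj[b]:
                return True
        return False


# ---------------------------------------------------------------------------
# PDAG manipulation: Meek closure, consistent extension, DAG -> CPDAG
# ---------------------------------------------------------------------------


def _meek_closure(
    nodes: tuple[str, ...], directed: set[Edge], undirected: set[Edge]
) -> None:
    """Close ``directed``/``undirected`` (mutated in place) under Meek R1-R3."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    pa: dict[str, set[str]] = {n: set() for n in nodes}
    ch: dict[str, set[str]] = {n: set() for n in nodes}
    nb: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in directed:
        adj[u].add(v)
        adj[v].add(u)
        pa[v].add(u)
        ch[u].add(v)
    for a, b in undirected:
        adj[a].add(b)
        adj[b].add(a)
        nb[a].add(b)
        nb[b].add(a)

    def orient(a: str, b: str) -> None:
        undirected.discard(_pair(a, b))
        directed.add((a, b))
        nb[a].discard(b)
        nb[b].discard(a)
        pa[b].add(a)
        ch[a].add(b)

    changed = True
    while changed:
        changed = False
        for a, b in sorted(undirected):
            for x, y in ((a, b), (b, a)):
                # R1: c -> x, x - y, c and y nonadjacent  =>  x -> y
                if any(c not in adj[y] and c != y for c in pa[x]):
                    orient(x, y)
                    changed = True
                    break
                # R2: x -> c -> y with x - y  =>  x -> y
                if ch[x] & pa[y]:
                    orient(x, y)
                    changed = True
                    break
                # R3: x - c -> y, x - d -> y, c and d nonadjacent  =>  x -> y
                cands = nb[x] & pa[y]
                if any(
                    d not in adj[c]
                    for c, d in itertools.combinations(sorted(cands), 2)
                ):
                    orient(x, y)
                    changed = True
                    break
            if changed:
                break


def cpdag_of(dag: Dag) -> Cpdag:
    """Completed pattern of a DAG: skeleton + v-structures + Meek closure.

    Two DAGs are Markov equivalent iff they share skeleton and
    v-structures; the CPDAG directs exactly the compelled edges.
    """
    directed: set[Edge] = set()
    adj = {n: dag.parents(n) | dag.children(n) for n in dag.nodes}
    for z in dag.nodes:
        ps = sorted(dag.parents(z))
        for x, y in itertools.combinations(ps, 2):
            if y not in adj[x]:  # v-structure x -> z <- y
                directed.add((x, z))
                directed.add((y, z))
    undirected = {
        _pair(u, v) for u, v in dag.edges if (u, v) not in directed
    }
    _meek_closure(dag.nodes, directed, undirected)
    return Cpdag(dag.nodes, frozenset(directed), frozenset(undirected))


def pdag_to_dag(
    nodes: tuple[str, ...], directed: set[Edge], undirected: set[Edge]
) -> Dag:
    """Consistent DAG extension of a PDAG (Dor & Tarsi's algorithm).

    Repeatedly removes a node x that (a) has no outgoing directed edge and
    (b) whose undirected neighbours are adjacent to every other neighbour
    of x, orienting all undirected edges into x.  Deterministic: candidate
    nodes are scanned in sorted label order.

    Raises
    ------
    CyclicGraphError
        If no consistent extension exists.
    """
    directed = set(directed)
    undirected = {_pair(*e) for e in undirected}
    out: set[Edge] = set(directed)
    remaining = set(nodes)

    adj: dict[str, set[str]] = {n: set() for n in nodes}
    pa: dict[str, set[str]] = {n: set() for n in nodes}
    ch: dict[str, set[str]] = {n: set() for n in nodes}
    nb: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in directed:
        adj[u].add(v)
        adj[v].add(u)
        pa[v].add(u)
        ch[u].add(v)
    for a, b in undirected:
        adj[a].add(b)
        adj[b].add(a)
        nb[a].add(b)
        nb[b].add(a)

    while remaining:
        found = None
        for x in sorted(remaining):
            if ch[x] & remaining:
                continue
            neighbours = adj[x] & remaining
            ok = True
            for y in nb[x] & remaining:
                if not (neighbours - {y}) <= adj[y]:
                    ok = False
                    break
            if ok:
                found = x
                break
        if found is None:
            raise CyclicGraphError("PDAG admits no consistent DAG extension")
        x = found
        for y in nb[x] & remaining:
            out.add((y, x))
        remaining.discard(x)

    return Dag(nodes, frozenset(out))


def enumerate_dags(nodes: tuple[str, ...]):
    """Yield every labeled DAG on ``nodes`` (3 states per unordered pair).

    Intended for exhaustive-search oracles on very small node sets; the
    count grows super-exponentially (25 DAGs on 3 nodes, 543 on 4).
    """
    nodes = tuple(nodes)
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (a, b), s in zip(pairs, states):
            if s == 1:
                edges.add((a, b))
            elif s == 2:
                edges.add((b, a))
        try:
            yield Dag(nodes, frozenset(edges))
        except CyclicGraphError:
            continue
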