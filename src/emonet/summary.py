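"""Graph-level descriptors: top-down vs bottom-up edges, density, degrees,
and connections shared between graphs.

ROIs belong to one of two layers: "prefrontal" (cognitive-control
regions) or "limbic" (emotion-generating regions).  A directed edge is
top-down if it runs prefrontal -> limbic, bottom-up if limbic ->
prefrontal, lateral within a layer.  A connection shared by two graphs
is a shared unordered adjacency; whether the directions also agree is
reported as a separate flag.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import LayerMappingError
from .graphs import Dag, Edge, _pair

PREFRONTAL = "prefrontal"
LIMBIC = "limbic"

#: Default layer assignment of the eight ROIs (the ACC is grouped with
#: the prefrontal control layer).
DEFAULT_LAYERS: dict[str, str] = {
    "LSFG": PREFRONTAL,
    "RSFG": PREFRONTAL,
    "LMFG": PREFRONTAL,
    "LACC": PREFRONTAL,
    "RInsula": LIMBIC,
    "LParah": LIMBIC,
    "RParah": LIMBIC,
    "LAmygdala": LIMBIC,
}

TOP_DOWN = "top_down"
BOTTOM_UP = "bottom_up"
LATERAL = "lateral"


@dataclass(frozen=True)
class NetworkSummary:
    """Edge-class counts, density and degree profile of one graph."""

    n_edges: int
    n_top_down: int
    n_bottom_up: int
    n_lateral: int
    degree: dict[str, int]
    edge_classes: dict[Edge, str]

    @property
    def density(self) -> int:
        """Raw edge count (how the graphs are compared in practice)."""
        return self.n_edges

    def normalized_density(self) -> float:
        n = len(self.degree)
        possible = n * (n - 1) / 2
        return self.n_edges / possible if possible else 0.0

    def to_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "n_top_down": self.n_top_down,
            "n_bottom_up": self.n_bottom_up,
            "n_lateral": self.n_lateral,
            "density": self.density,
            "normalized_density": self.normalized_density(),
            "degree": dict(sorted(self.degree.items())),
            "edge_classes": {
                f"{u}->{v}": c for (u, v), c in sorted(self.edge_classes.items())
            },
        }


def classify_edge(edge: Edge, layers: dict[str, str]) -> str:
    u, v = edge
    try:
        lu, lv = layers[u], layers[v]
    except KeyError as err:
        raise LayerMappingError(f"node {err.args[0]!r} has no layer") from err
    if lu == lv:
        return LATERAL
    return TOP_DOWN if lu == PREFRONTAL else BOTTOM_UP


def classify_edges(dag: Dag, layers: dict[str, str] | None = None) -> NetworkSummary:
    """Label every directed edge top_down / bottom_up / lateral.

    Raises
    ------
    LayerMappingError
        If any graph node lacks a layer assignment.
    """
    layers = DEFAULT_LAYERS if layers is None else layers
    unmapped = [n for n in dag.nodes if n not in layers]
    if unmapped:
        raise LayerMappingError(f"nodes without layer: {unmapped}")
    if set(layers.values()) - {PREFRONTAL, LIMBIC}:
        raise LayerMappingError(
            f"layers must be {PREFRONTAL!r} or {LIMBIC!r}"
        )
    classes = {e: classify_edge(e, layers) for e in sorted(dag.edges)}
    counts = {TOP_DOWN: 0, BOTTOM_UP: 0, LATERAL: 0}
    for c in classes.values():
        counts[c] += 1
    degree = {n: dag.degree(n) for n in dag.nodes}
    return NetworkSummary(
        n_edges=len(dag.edges),
        n_top_down=counts[TOP_DOWN],
        n_bottom_up=counts[BOTTOM_UP],
        n_lateral=counts[LATERAL],
        degree=degree,
        edge_classes=classes,
    )


def shared_adjacencies(g1: Dag, g2: Dag) -> dict[Edge, bool]:
    """Unordered pairs adjacent in both graphs.

    Returns a mapping sorted-pair -> True when the edge direction also
    agrees.  Symmetric in its arguments.

    Raises
    ------
    ValueError
        If the graphs are over different node sets.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share the same node universe")
    shared = g1.skeleton() & g2.skeleton()
    out = {}
    for pair in sorted(shared):
        a, b = pair
        d1 = (a, b) in g1.edges
        d2 = (a, b) in g2.edges
        out[pair] = d1 == d2
    return out


def edges_common_to_all(dags: list[Dag]) -> set[Edge]:
    """Unordered adjacencies present in every graph of the list."""
    if not dags:
        return set()
    common = dags[0].skeleton()
    for d in dags[1:]:
        common = common & d.skeleton()
    return set(common)
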