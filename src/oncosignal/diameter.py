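"""Weighted diameter and average path length under three directivity conventions.

Link weights behave like interaction probabilities: the heavier the link
the *shorter* it should be as a path segment.  The raw, probability-like
weight of an edge is p = base**LW (the product of the endpoint
abundances); each edge is mapped to a non-negative length by the negative
logarithmic mapping

    d = ln(p_max / p) = ln(base) * (LW_max - LW)     ("neglog-maxnorm")
    d = ln(p_sum / p)                                ("neglog-sumnorm")

where p_max (p_sum) is the maximum (total) raw weight of the state's
links.  The strongest link then has distance 0 under the default,
Dijkstra's shortest path minimizes -sum ln p and is the most likely
transition path, and multiplying every abundance by a common factor
cancels from the ratio, leaving all distances unchanged.

Three directivity conventions are analyzed:

- ``undirected``: every link is treated as undirected;
- ``directed``: only activating/inhibiting links, with their direction;
- ``mixed``: directed links keep their direction and each undirected link
  is replaced by two opposite arcs of equal distance.

Graphs are restricted to the largest (strongly, for directed/mixed)
connected component before the all-pairs computation, since diameter over
unreachable pairs is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .io_formats import DIRECTED_TYPES, UNDIRECTED, UNKNOWN, SignalingNetwork
from .weights import WeightedStateNetwork

CONVENTIONS = ("undirected", "directed", "mixed")
DISTANCE_MAPS = ("neglog-maxnorm", "neglog-sumnorm")


@dataclass
class DistanceGraph:
    """Distance-mapped view of a weighted state network under one convention."""

    graph: nx.Graph | nx.DiGraph  # edge attribute "distance"
    convention: str
    distance_map: str
    state: str
    norm: float  # normalizing raw weight (max or sum of base**LW)

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class ConventionReport:
    """Diameter and mean shortest-path length for one convention (one grid cell)."""

    convention: str
    diameter: float
    average_path_length: float
    diameter_endpoints: tuple[str, str]
    diameter_path: list[str]
    n_reachable_pairs: int
    n_nodes: int


def build_view(
    w: WeightedStateNetwork,
    convention: str,
    distance_map: str = "neglog-maxnorm",
    norm: float | None = None,
) -> DistanceGraph:
    """Build the distance graph of one state under one directivity convention.

    The normalization constant defaults to the state's own raw link
    weights (``base**LW``), independently of the convention, so distances
    are comparable across conventions (and nested arc sets give nested
    distances).  When comparing several states, pass a shared ``norm`` on
    the raw-weight scale (e.g. the study-wide maximum) so cross-state
    distance differences reflect only the weights, not each state's own
    extreme link; :func:`diameter_grid` does this automatically.  Parallel
    arcs keep the minimum distance.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if distance_map not in DISTANCE_MAPS:
        raise ValueError(f"unknown distance map {distance_map!r}")
    raw = {k: w.log_base ** v for k, v in w.pair_weights.items()}
    raw_max = max(raw.values())
    if norm is None:
        norm = raw_max if distance_map == "neglog-maxnorm" else sum(raw.values())
    elif distance_map == "neglog-maxnorm" and norm < raw_max * (1 - 1e-12):
        raise ValueError("shared norm must be >= the state's maximum raw link weight")

    def dist(s: str, t: str) -> float:
        key = (s, t) if s <= t else (t, s)
        return max(math.log(norm / raw[key]), 0.0)

    if convention == "undirected":
        g: nx.Graph | nx.DiGraph = nx.Graph()
        for s, t, _ in w.base.edges:
            d = dist(s, t)
            if not g.has_edge(s, t) or d < g[s][t]["distance"]:
                g.add_edge(s, t, distance=d)
    else:
        g = nx.DiGraph()
        for s, t, kind in w.base.edges:
            if kind == UNKNOWN:
                continue
            d = dist(s, t)
            if kind in DIRECTED_TYPES:
                arcs = [(s, t)]
            elif convention == "mixed":
                arcs = [(s, t), (t, s)]  # undirected link -> two opposite arcs
            else:
                continue  # directed convention drops undirected links
            for u, v in arcs:
                if not g.has_edge(u, v) or d < g[u][v]["distance"]:
                    g.add_edge(u, v, distance=d)
    if g.number_of_edges() == 0:
        raise ValueError(f"no arcs under convention {convention!r}")

    if convention == "undirected":
        components = nx.connected_components(g)
    else:
        components = nx.strongly_connected_components(g)
    comps = sorted(components, key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    g = g.subgraph(keep).copy()
    if g.number_of_nodes() < 2:
        raise ValueError(
            f"largest component under convention {convention!r} has < 2 nodes"
        )
    return DistanceGraph(
        graph=g, convention=convention, distance_map=distance_map,
        state=w.state, norm=norm,
    )


def _all_pairs(g: DistanceGraph) -> dict[str, dict[str, float]]:
    return dict(nx.all_pairs_dijkstra_path_length(g.graph, weight="distance"))


def weighted_diameter(g: DistanceGraph) -> tuple[float, tuple[str, str], list[str]]:
    """Longest shortest path over reachable ordered pairs (Dijkstra all-pairs).

    Returns the diameter, the realizing (source, target) pair, and the node
    path; the diameter equals the sum of arc distances along the path.
    Ties are resolved toward the lexicographically smallest (source, target).
    """
    lengths = _all_pairs(g)
    best: tuple[float, tuple[str, str]] | None = None
    for u in sorted(lengths):
        for v in sorted(lengths[u]):
            if u == v:
                continue
            d = lengths[u][v]
            if best is None or d > best[0] + 1e-15 or (
                abs(d - best[0]) <= 1e-15 and (u, v) < best[1]
            ):
                best = (d, (u, v))
    if best is None:
        raise ValueError("no reachable pair in distance graph")
    diam, (u, v) = best
    path = nx.dijkstra_path(g.graph, u, v, weight="distance")
    return diam, (u, v), path


def average_path_length(g: DistanceGraph) -> float:
    """Mean shortest-path distance over reachable ordered pairs (i != j)."""
    lengths = _all_pairs(g)
    total, count = 0.0, 0
    for u, targets in lengths.items():
        for v, d in targets.items():
            if u != v:
                total += d
                count += 1
    if count == 0:
        raise ValueError("no reachable pair in distance graph")
    return total / count


def convention_report(g: DistanceGraph) -> ConventionReport:
    """Diameter and average path length of one view, computed in one pass."""
    lengths = _all_pairs(g)
    best: tuple[float, tuple[str, str]] | None = None
    total, count = 0.0, 0
    for u in sorted(lengths):
        for v in sorted(lengths[u]):
            if u == v:
                continue
            d = lengths[u][v]
            total += d
            count += 1
            if best is None or d > best[0] + 1e-15 or (
                abs(d - best[0]) <= 1e-15 and (u, v) < best[1]
            ):
                best = (d, (u, v))
    if best is None:
        raise ValueError("no reachable pair in distance graph")
    diam, (u, v) = best
    path = nx.dijkstra_path(g.graph, u, v, weight="distance")
    mean = total / count  # symmetric distances: ordered and unordered means agree
    if not g.directed:
        count //= 2  # report unordered pair count for the undirected convention
    return ConventionReport(
        convention=g.convention,
        diameter=diam,
        average_path_length=mean,
        diameter_endpoints=(u, v),
        diameter_path=path,
        n_reachable_pairs=count,
        n_nodes=g.n_nodes,
    )


def diameter_grid(
    weighted: Mapping[str, WeightedStateNetwork],
    conventions: Iterable[str] = CONVENTIONS,
    distance_map: str = "neglog-maxnorm",
) -> dict[str, dict[str, ConventionReport]]:
    """State x convention grid of diameter reports (the headline table shape).

    All states share one normalization constant (the study-wide maximum or
    total raw link weight), so the grid's cross-state diameter differences
    are driven purely by the link weights.  A state that strengthens some
    links then gets shorter distances, never artificially longer ones
    through its own inflated normalizer.
    """
    raw = {
        s: [w.log_base ** v for v in w.pair_weights.values()]
        for s, w in weighted.items()
    }
    if distance_map == "neglog-maxnorm":
        shared = max(max(v) for v in raw.values())
    else:
        shared = max(sum(v) for v in raw.values())
    return {
        state: {
            conv: convention_report(build_view(w, conv, distance_map, norm=shared))
            for conv in conventions
        }
        for state, w in weighted.items()
    }
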