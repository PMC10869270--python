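"""Mosaic data topology (MDT).

The MDT is an undirected graph with one node per dataset and an edge between
every pair of datasets sharing at least one feature name, weighted by the
exact number of shared features. Projection between datasets that share no
features is routed along weighted shortest paths of this graph.

Path cost is ``1 / n_shared_features`` per edge, so routes through large
feature overlaps (well-conditioned regression bridges) are preferred. Ties
are broken by hop count, then lexicographically on the node sequence, which
makes embeddings reproducible.
"""

from __future__ import annotations

import heapq
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx

from .dataset import Dataset, check_collection


def build_mdt(datasets: Sequence[Dataset]) -> nx.Graph:
    """Build the mosaic data topology for a dataset collection.

    Returns a :class:`networkx.Graph` whose nodes are dataset names and whose
    edges carry ``weight`` (shared feature count) and ``cost`` (1/weight).
    """
    check_collection(list(datasets))
    g = nx.Graph()
    for d in datasets:
        if d.n_features == 0 or d.n_cells == 0:
            raise ValueError(f"dataset {d.name!r} is empty")
        g.add_node(d.name)
    panels = {d.name: d.feature_set for d in datasets}
    names = [d.name for d in datasets]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            n_shared = len(panels[a] & panels[b])
            if n_shared >= 1:
                g.add_edge(a, b, weight=n_shared, cost=1.0 / n_shared)
    return g


def connected_components(topology: nx.Graph) -> list[set[str]]:
    return [set(c) for c in nx.connected_components(topology)]


def assert_connected(topology: nx.Graph) -> None:
    """Raise unless every dataset is reachable from every other.

    Integration requires a connected MDT; otherwise some dataset can never be
    projected onto the reference space.
    """
    comps = connected_components(topology)
    if len(comps) > 1:
        desc = "; ".join("{" + ", ".join(sorted(c)) + "}" for c in comps)
        raise ValueError(
            f"mosaic data topology is disconnected ({len(comps)} components): {desc}. "
            "Every dataset must share features with some chain of other datasets."
        )


def shortest_path(topology: nx.Graph, source: str, target: str) -> list[str]:
    """Minimum-cost path from `source` to `target`.

    Cost of an edge is 1/weight, computed in exact rational arithmetic so
    that equal-cost alternatives are recognized exactly. Among minimum-cost
    paths the one with fewest hops is chosen, then the lexicographically
    smallest node sequence.
    """
    for node in (source, target):
        if node not in topology:
            raise KeyError(f"unknown dataset {node!r} in topology")
    if source == target:
        return [source]

    # Dijkstra with lexicographic priority (cost, hops, path).
    best: dict[str, tuple[Fraction, int, tuple[str, ...]]] = {}
    heap: list[tuple[Fraction, int, tuple[str, ...]]] = [(Fraction(0), 0, (source,))]
    while heap:
        cost, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in best and best[node] <= (cost, hops, path):
            continue
        best[node] = (cost, hops, path)
        if node == target:
            return list(path)
        for nbr in topology.neighbors(node):
            if nbr in path:
                continue
            w = topology.edges[node, nbr]["weight"]
            cand = (cost + Fraction(1, int(w)), hops + 1, path + (nbr,))
            if nbr not in best or cand < best[nbr]:
                heapq.heappush(heap, cand)
    raise ValueError(
        f"no path between {source!r} and {target!r}; topology is disconnected"
    )


def edge_table(topology: nx.Graph) -> list[tuple[str, str, int]]:
    """Edge list as (source, target, n_shared_features), sorted for stable output."""
    rows = []
    for a, b, data in topology.edges(data=True):
        lo, hi = sorted((a, b))
        rows.append((lo, hi, int(data["weight"])))
    return sorted(rows)


def write_edge_list(topology: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tn_shared_features\n")
        for a, b, w in edge_table(topology):
            fh.write(f"{a}\t{b}\t{w}\n")


def to_dot(topology: nx.Graph) -> str:
    """DOT text for quick visualization of the topology."""
    lines = ["graph mdt {"]
    for node in sorted(topology.nodes):
        lines.append(f'  "{node}";')
    for a, b, w in edge_table(topology):
        lines.append(f'  "{a}" -- "{b}" [label="{w}"];')
    lines.append("}")
    return "\n".join(lines)


def shared_features(a: Dataset, b: Dataset) -> list[str]:
    """Shared feature names between two datasets, in `a`'s feature order."""
    bset = b.feature_set
    return [f for f in a.features if f in bset]


def mdt_summary(topology: nx.Graph) -> str:
    comps = connected_components(topology)
    lines = [
        f"MDT: {topology.number_of_nodes()} datasets, "
        f"{topology.number_of_edges()} edges, {len(comps)} component(s)"
    ]
    for a, b, w in edge_table(topology):
        lines.append(f"  {a} -- {b}: {w} shared features")
    return "\n".join(lines)
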