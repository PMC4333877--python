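"""Bipartite vaccine-adverse-event signal networks and their topology.

An edge joins vaccine v and symptom s when the pair's PRR (pooled, or a
single year's) strictly exceeds a threshold (1 by default); nodes exist
only where incident to at least one edge. Metrics follow the usual
unweighted definitions: average degree 2L/N, average path length the mean
breadth-first-search distance over unordered reachable node pairs, and
diameter the largest finite such distance.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .associations import AssociationSummary

VACCINE = "vaccine"
SYMPTOM = "symptom"

#: scope sentinel: build from pooled PRRs
OVERALL = "overall"


def node_id(kind: str, name: str) -> str:
    return f"{kind}::{name}"


def average_degree(n_nodes: int, n_links: int) -> float:
    """Mean degree of an undirected graph: 2 * links / nodes."""
    if n_nodes == 0:
        return math.nan
    return 2.0 * n_links / n_nodes


@dataclasses.dataclass(frozen=True)
class NetworkMetrics:
    n_node: int
    n_link: int
    average_degree: float
    average_path_length: float
    diameter: int

    @property
    def defined(self) -> bool:
        return self.n_node > 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_network(
    summaries: Mapping[tuple[str, str], AssociationSummary] | Iterable[AssociationSummary],
    scope: int | str = OVERALL,
    threshold: float = 1.0,
) -> nx.Graph:
    """Build the signal network for a scope (a year, or OVERALL for pooled PRRs).

    Edges require PRR strictly above ``threshold``; pairs whose PRR is
    undefined in scope never qualify. Node attributes: ``kind``
    (vaccine/symptom) and ``label`` (the code or term); edge attribute
    ``prr`` carries the qualifying value.
    """
    if isinstance(summaries, Mapping):
        summaries = summaries.values()
    graph = nx.Graph(scope=str(scope))
    for summary in summaries:
        if scope == OVERALL:
            value = summary.overall_prr
        else:
            detail = summary.yearly.get(scope)
            value = detail.prr if detail is not None else None
        if value is None or value <= threshold:
            continue
        v = node_id(VACCINE, summary.vaccine)
        s = node_id(SYMPTOM, summary.symptom)
        graph.add_node(v, kind=VACCINE, label=summary.vaccine)
        graph.add_node(s, kind=SYMPTOM, label=summary.symptom)
        graph.add_edge(v, s, prr=float(value))
    return graph


def metrics(net: nx.Graph) -> NetworkMetrics:
    """Topology metrics by breadth-first search.

    Path length averages over unordered pairs of *distinct, reachable*
    nodes; pairs in different components are excluded rather than treated
    as infinite. An empty network yields NaN metrics (``defined`` False).
    """
    n_node = net.number_of_nodes()
    n_link = net.number_of_edges()
    if n_node == 0:
        return NetworkMetrics(0, 0, math.nan, math.nan, 0)
    order = {node: i for i, node in enumerate(net.nodes)}
    total = 0
    pairs = 0
    diameter = 0
    for source, dists in nx.all_pairs_shortest_path_length(net):
        for target, d in dists.items():
            if order[source] < order[target]:
                total += d
                pairs += 1
                if d > diameter:
                    diameter = d
    apl = total / pairs if pairs else math.nan
    return NetworkMetrics(
        n_node=n_node,
        n_link=n_link,
        average_degree=average_degree(n_node, n_link),
        average_path_length=apl,
        diameter=diameter,
    )


@dataclasses.dataclass(frozen=True)
class OverlapRegion:
    """One region of the node-set Venn decomposition."""

    years: tuple[int, ...]  # exactly these networks contain the nodes
    vaccines: tuple[str, ...]
    symptoms: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.vaccines) + len(self.symptoms)


@dataclasses.dataclass(frozen=True)
class OverlapReport:
    """Venn decomposition of node sets across per-year networks."""

    years: tuple[int, ...]
    regions: dict[tuple[int, ...], OverlapRegion]

    def region(self, *years: int) -> OverlapRegion:
        key = tuple(sorted(years))
        return self.regions.get(key, OverlapRegion(years=key, vaccines=(), symptoms=()))

    @property
    def intersection_all(self) -> OverlapRegion:
        return self.region(*self.years)

    @property
    def union_count(self) -> int:
        return sum(r.count for r in self.regions.values())


def compare_years(nets: Mapping[int, nx.Graph]) -> OverlapReport:
    """Exclusive Venn regions of the node sets of two or more networks.

    Each node in the union is assigned to exactly one region keyed by the
    sorted tuple of years whose networks contain it; region members are
    reported split by node kind.
    """
    if len(nets) < 2:
        raise ValueError("compare_years needs at least two networks")
    years = tuple(sorted(nets))
    membership: dict[str, list[int]] = {}
    kinds: dict[str, tuple[str, str]] = {}
    for year in years:
        for node, attrs in nets[year].nodes(data=True):
            membership.setdefault(node, []).append(year)
            kinds[node] = (attrs["kind"], attrs["label"])
    grouped: dict[tuple[int, ...], dict[str, list[str]]] = {}
    for node, member_years in membership.items():
        key = tuple(member_years)
        bucket = grouped.setdefault(key, {VACCINE: [], SYMPTOM: []})
        kind, label = kinds[node]
        bucket[kind].append(label)
    regions = {
        key: OverlapRegion(
            years=key,
            vaccines=tuple(sorted(bucket[VACCINE])),
            symptoms=tuple(sorted(bucket[SYMPTOM])),
        )
        for key, bucket in grouped.items()
    }
    return OverlapReport(years=years, regions=regions)


def edge_list_frame(net: nx.Graph) -> pd.DataFrame:
    """Edges as (source, target, source_type, target_type, prr), vaccine first."""
    rows = []
    for a, b, attrs in net.edges(data=True):
        if net.nodes[a]["kind"] != VACCINE:
            a, b = b, a
        rows.append({
            "source": net.nodes[a]["label"],
            "target": net.nodes[b]["label"],
            "source_type": net.nodes[a]["kind"],
            "target_type": net.nodes[b]["kind"],
            "prr": attrs["prr"],
        })
    frame = pd.DataFrame(rows, columns=["source", "target", "source_type", "target_type", "prr"])
    return frame.sort_values(["source", "target"], ignore_index=True)


def write_edge_list(net: nx.Graph, path) -> None:
    edge_list_frame(net).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, str(path))
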