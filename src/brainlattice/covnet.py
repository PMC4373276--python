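"""Co-authorship network over PIs.

Every PI is a node; an edge joins two PIs who appear together on at least
``threshold`` studies (default 2 — a single joint paper is treated as too
weak evidence of a working relationship). Nodes carry a group label from a
chosen similarity-clustering cut, so a small same-colored connected cluster
reads as "authors doing similar work who actually work together".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .corpus import CorpusTables, PIRoster

#: Minimum joint-paper count for an edge.
DEFAULT_EDGE_THRESHOLD = 2
#: Group label attached to nodes absent from the grouping.
UNGROUPED = 0


def pair_counts(tables: CorpusTables, roster: PIRoster) -> dict[tuple[str, str], int]:
    """Joint-paper counts over unordered PI pairs co-listed on a study.

    Keys are sorted (a, b) tuples; single-author papers contribute nothing.
    """
    if not roster.pis:
        raise ValueError("empty PI roster")
    counts: dict[tuple[str, str], int] = {}
    for _, grp in tables.authorship.groupby("study_id"):
        pis_on_paper = sorted(set(grp["author"]) & roster.pis)
        for a, b in combinations(pis_on_paper, 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


@dataclass
class CollabNetwork:
    """PI collaboration graph; nodes have a ``group`` attribute, edges a
    ``weight`` (joint-paper count)."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other) -> bool:
        if not isinstance(other, CollabNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data="group"))
            == dict(other.graph.nodes(data="group"))
            and nx.get_edge_attributes(self.graph, "weight")
            == nx.get_edge_attributes(other.graph, "weight")
        )


def build_network(
    counts: dict[tuple[str, str], int],
    roster: PIRoster,
    threshold: int = DEFAULT_EDGE_THRESHOLD,
    groups: dict[str, int] | None = None,
) -> CollabNetwork:
    """Network with every roster PI as a node and edges where the joint
    count reaches ``threshold``; isolated PIs are retained."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    groups = groups or {}
    g = nx.Graph()
    for pi in sorted(roster.pis):
        g.add_node(pi, group=int(groups.get(pi, UNGROUPED)))
    for (a, b), n in sorted(counts.items()):
        if a == b:
            continue
        if n >= threshold and a in roster.pis and b in roster.pis:
            g.add_edge(a, b, weight=int(n))
    return CollabNetwork(graph=g)


def collaborators_of(
    counts: dict[tuple[str, str], int], author: str, min_joint: int = DEFAULT_EDGE_THRESHOLD
) -> set[str]:
    """PIs with >= min_joint joint papers with ``author``."""
    out = set()
    for (a, b), n in counts.items():
        if n >= min_joint:
            if a == author:
                out.add(b)
            elif b == author:
                out.add(a)
    return out


def collaboration_score(
    ranked: list[tuple[str, float]], collaborators: set[str], rank: int
) -> float:
    """Percentage of the top-``rank`` similar authors (self excluded) that
    the focal author has actually worked with."""
    if rank < 1:
        raise ValueError("rank must be >= 1 (position 0 is the author itself)")
    top = [a for a, _ in ranked[1 : rank + 1]]
    if len(top) < rank:
        raise ValueError(f"rank {rank} exceeds list length {len(ranked) - 1}")
    hits = sum(1 for a in top if a in collaborators)
    return 100.0 * hits / rank


def same_group_edge_fraction(net: CollabNetwork) -> float:
    """Fraction of edges whose endpoints share a group label (diagnostic of
    how cleanly similarity groups map onto actual collaboration)."""
    edges = list(net.graph.edges)
    if not edges:
        return float("nan")
    same = sum(
        1
        for a, b in edges
        if net.graph.nodes[a]["group"] == net.graph.nodes[b]["group"]
    )
    return same / len(edges)


def export_d3(net: CollabNetwork, path) -> dict:
    """Write the force-directed-graph JSON dialect:
    ``{"nodes": [{"id", "group"}], "links": [{"source", "target", "value"}]}``
    with nodes and links in stable sorted order."""
    payload = {
        "nodes": [
            {"id": n, "group": int(net.graph.nodes[n]["group"])}
            for n in sorted(net.graph.nodes)
        ],
        "links": [
            {"source": a, "target": b, "value": int(net.graph.edges[a, b]["weight"])}
            for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    return payload


def read_d3(path) -> CollabNetwork:
    payload = json.loads(Path(path).read_text())
    g = nx.Graph()
    for node in payload["nodes"]:
        g.add_node(node["id"], group=int(node["group"]))
    for link in payload["links"]:
        g.add_edge(link["source"], link["target"], weight=int(link["value"]))
    return CollabNetwork(graph=g)


def write_edge_list(counts: dict[tuple[str, str], int], path) -> None:
    """Edge-list TSV: pi_a, pi_b, n_joint (all counted pairs, unthresholded)."""
    rows = [
        {"pi_a": a, "pi_b": b, "n_joint": n} for (a, b), n in sorted(counts.items())
    ]
    pd.DataFrame(rows, columns=["pi_a", "pi_b", "n_joint"]).to_csv(
        path, sep="\t", index=False
    )
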