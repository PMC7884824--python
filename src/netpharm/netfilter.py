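"""Interaction-network construction and two-stage median hub filtering.

Stage 1 keeps nodes whose degree strictly exceeds twice the median degree
("hubs").  Stage 2 induces the hub-hub subnetwork, recomputes degree,
betweenness and closeness there, and keeps nodes strictly above the median of
all three simultaneously ("major hubs").  Major hubs carrying the
putative-target role are the candidate therapeutic targets.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "InteractionEdge",
    "PharmNetwork",
    "CentralityRecord",
    "HubSelection",
    "build_network",
    "centralities",
    "select_hubs",
    "refine_major_hubs",
    "classify_candidates",
    "read_edge_list",
    "write_sif",
    "write_node_attributes",
]

ROLE_TARGET = "putative_target"
ROLE_DISEASE = "disease_gene"
ROLE_BOTH = "both"


@dataclass(frozen=True)
class InteractionEdge:
    a: str
    b: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1]: {self.confidence}")


@dataclass
class PharmNetwork:
    """Undirected simple graph over putative targets and disease genes."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]


@dataclass(frozen=True)
class CentralityRecord:
    node: str
    degree: int
    betweenness: float
    closeness: float


@dataclass(frozen=True)
class HubSelection:
    hubs: frozenset[str]
    major_hubs: frozenset[str]
    candidate_targets: frozenset[str]
    disease_genes: frozenset[str]


def build_network(
    targets: Iterable[str],
    disease_genes: Iterable[str],
    edges: Iterable[InteractionEdge],
    min_conf: float = 0.4,
) -> PharmNetwork:
    """Assemble the target/disease-gene network at an edge-confidence cutoff.

    Nodes are the union of the two gene sets, with role ``both`` for genes in
    both.  An edge survives iff confidence >= ``min_conf`` and both endpoints
    are in the node universe; self-loops and duplicates are discarded.
    """
    if not 0.0 <= min_conf <= 1.0:
        raise ValueError("min_conf must lie in [0, 1]")
    targets = set(targets)
    disease_genes = set(disease_genes)
    universe = targets | disease_genes
    if not universe:
        raise ValueError("empty node universe")

    g = nx.Graph()
    for node in universe:
        if node in targets and node in disease_genes:
            role = ROLE_BOTH
        elif node in targets:
            role = ROLE_TARGET
        else:
            role = ROLE_DISEASE
        g.add_node(node, role=role)
    for e in edges:
        if e.confidence < min_conf or e.a == e.b:
            continue
        if e.a in universe and e.b in universe:
            g.add_edge(e.a, e.b)
    return PharmNetwork(g)


def centralities(net: PharmNetwork) -> list[CentralityRecord]:
    """Degree, shortest-path betweenness and closeness of every node.

    Betweenness is pair-normalized by (n-1)(n-2)/2 (undirected, unweighted).
    Closeness follows the within-component convention: number of reachable
    nodes divided by the sum of shortest-path distances to them, 0 for
    isolated nodes.
    """
    g = net.graph
    btw = nx.betweenness_centrality(g, normalized=True)
    records = []
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node)
        reach = len(lengths) - 1  # excludes the node itself
        total = sum(lengths.values())
        close = reach / total if total > 0 else 0.0
        records.append(
            CentralityRecord(
                node=node,
                degree=g.degree(node),
                betweenness=btw[node],
                closeness=close,
            )
        )
    return records


def select_hubs(records: Sequence[CentralityRecord]) -> set[str]:
    """Nodes with degree strictly greater than 2 x median degree.

    Median of an even-length list is the mean of the two central order
    statistics; ties at the threshold are excluded.
    """
    if not records:
        raise ValueError("no centrality records")
    med = statistics.median(r.degree for r in records)
    return {r.node for r in records if r.degree > 2 * med}


def refine_major_hubs(net: PharmNetwork, hubs: Iterable[str]) -> set[str]:
    """Second-stage filter on the hub-induced subnetwork.

    Induces the subgraph of direct hub-hub edges, recomputes all three
    centralities on it, and keeps nodes strictly above the median in degree
    AND betweenness AND closeness simultaneously.
    """
    hubs = set(hubs)
    if not hubs <= net.nodes:
        raise ValueError("hubs must be a subset of network nodes")
    if not hubs:
        return set()
    sub = PharmNetwork(net.graph.subgraph(hubs).copy())
    records = centralities(sub)
    med_deg = statistics.median(r.degree for r in records)
    med_btw = statistics.median(r.betweenness for r in records)
    med_clo = statistics.median(r.closeness for r in records)
    return {
        r.node
        for r in records
        if r.degree > med_deg and r.betweenness > med_btw and r.closeness > med_clo
    }


def classify_candidates(
    major: Iterable[str],
    net: PharmNetwork,
    hubs: Optional[Iterable[str]] = None,
) -> HubSelection:
    """Partition major hubs by role into candidate targets and disease genes.

    Dual-role (``both``) nodes are counted in BOTH subsets; the two subset
    sizes can therefore sum to more than the number of major hubs.
    """
    major = set(major)
    if not major <= net.nodes:
        raise ValueError("major hubs must be a subset of network nodes")
    candidates = {n for n in major if net.role(n) in (ROLE_TARGET, ROLE_BOTH)}
    disease = {n for n in major if net.role(n) in (ROLE_DISEASE, ROLE_BOTH)}
    return HubSelection(
        hubs=frozenset(hubs if hubs is not None else major),
        major_hubs=frozenset(major),
        candidate_targets=frozenset(candidates),
        disease_genes=frozenset(disease),
    )


# ---------------------------------------------------------------------------
# File formats

def read_edge_list(path) -> list[InteractionEdge]:
    """Read a TSV edge list: node_a, node_b, combined_score.

    Scores in 0-1000 (STRING convention) are autodetected and divided by
    1000; scores already in [0, 1] pass through unchanged.
    """
    raw: list[tuple[str, str, float]] = []
    with open(path, newline="") as fh:
        for ln in fh:
            if ln.startswith("#") or ln.startswith("node_a\t") or not ln.strip():
                continue
            a, b, score = ln.rstrip("\n").split("\t")
            raw.append((a, b, float(score)))
    scale = 1000.0 if any(s > 1.0 for _, _, s in raw) else 1.0
    return [InteractionEdge(a, b, s / scale) for a, b, s in raw]


def write_sif(net: PharmNetwork, path, interaction: str = "pp") -> None:
    """Export as simple interaction format (node <tab> type <tab> node)."""
    with open(path, "w") as fh:
        isolated = [n for n in sorted(net.graph.nodes) if net.graph.degree(n) == 0]
        for a, b in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges)):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def write_node_attributes(
    net: PharmNetwork,
    records: Sequence[CentralityRecord],
    hubs: set[str],
    major_hubs: set[str],
    path,
    header_comment: str = "",
) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node", "role", "degree", "betweenness", "closeness", "hub", "major_hub"])
        for r in sorted(records, key=lambda r: r.node):
            w.writerow(
                [
                    r.node,
                    net.role(r.node),
                    r.degree,
                    f"{r.betweenness:.6f}",
                    f"{r.closeness:.6f}",
                    int(r.node in hubs),
                    int(r.node in major_hubs),
                ]
            )
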