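"""Gene-gene co-occurrence network construction and analysis.

Two genes are connected when they are mentioned in the same abstract; the
edge weight is the number of such abstracts. The analysis pipeline mirrors
the common literature-network recipe: extract the giant component, prune
weak edges (weight < 10 by default), then compute betweenness and
(harmonic) closeness centralities on the unweighted skeleton and a
modularity-maximizing community partition on the weighted graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from itertools import combinations

import networkx as nx
import pandas as pd

from .gene_annotation import AnnotatedAbstract


def _pct2(part: int, whole: int) -> float:
    if whole == 0:
        return 0.0
    return float(
        (Decimal(100 * part) / Decimal(whole)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_EVEN
        )
    )


def build_network(annotated: list[AnnotatedAbstract]) -> nx.Graph:
    """Weighted co-occurrence graph over all mentioned genes.

    Nodes include genes that never co-occur with another (singletons);
    an abstract with gene set G contributes one count to each of the
    C(|G|, 2) pairs.
    """
    net = nx.Graph()
    for ann in annotated:
        genes = sorted(ann.genes)
        net.add_nodes_from(genes)
        for a, b in combinations(genes, 2):
            if net.has_edge(a, b):
                net[a][b]["weight"] += 1
            else:
                net.add_edge(a, b, weight=1)
    return net


def giant_component(net: nx.Graph) -> nx.Graph:
    """The component with the most nodes; ties broken by edge count, then
    by lexicographically smallest member."""
    if net.number_of_nodes() == 0:
        raise ValueError("cannot take the giant component of an empty network")
    components = [net.subgraph(c).copy() for c in nx.connected_components(net)]
    return min(
        components,
        key=lambda g: (
            -g.number_of_nodes(),
            -g.number_of_edges(),
            min(map(str, g.nodes)),
        ),
    )


def prune(net: nx.Graph, min_weight: int = 10) -> nx.Graph:
    """Drop edges with weight < min_weight, then isolated nodes."""
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    out = net.copy()
    weak = [
        (a, b) for a, b, w in out.edges(data="weight") if w < min_weight
    ]
    out.remove_edges_from(weak)
    out.remove_nodes_from(list(nx.isolates(out)))
    return out


@dataclass
class CentralityResult:
    """Per-node centralities and community labels, plus the modularity score."""

    betweenness: dict[str, float]
    closeness: dict[str, float]
    modularity_class: dict[str, int]
    modularity: float

    def to_frame(self) -> pd.DataFrame:
        nodes = sorted(
            set(self.betweenness) | set(self.closeness) | set(self.modularity_class)
        )
        return pd.DataFrame(
            {
                "gene": nodes,
                "betweenness": [self.betweenness.get(n, 0.0) for n in nodes],
                "closeness": [self.closeness.get(n, 0.0) for n in nodes],
                "modularity_class": [self.modularity_class.get(n, -1) for n in nodes],
            }
        )


def centralities(net: nx.Graph) -> tuple[dict[str, float], dict[str, float]]:
    """Normalized betweenness and harmonic closeness on the unweighted
    skeleton. The harmonic variant (mean reciprocal distance) is
    well-defined on disconnected graphs; both lie in [0, 1]."""
    n = net.number_of_nodes()
    if n <= 1:
        return ({node: 0.0 for node in net}, {node: 0.0 for node in net})
    betweenness = nx.betweenness_centrality(net, normalized=True, weight=None)
    harmonic = nx.harmonic_centrality(net)
    closeness = {node: h / (n - 1) for node, h in harmonic.items()}
    return betweenness, closeness


def communities(
    net: nx.Graph, seed: int, resolution: float = 1.0
) -> tuple[dict[str, int], float]:
    """Weighted greedy-multilevel (Louvain) modularity partition.

    Deterministic given the seed. Labels are contiguous from 0, assigned to
    communities sorted by descending size then smallest member. An edgeless
    network gets one singleton community per node and modularity 0.
    """
    if net.number_of_edges() == 0:
        labels = {node: i for i, node in enumerate(sorted(net.nodes))}
        return labels, 0.0
    parts = nx.community.louvain_communities(
        net, weight="weight", resolution=resolution, seed=seed
    )
    parts = sorted(parts, key=lambda c: (-len(c), min(c)))
    labels = {node: i for i, comm in enumerate(parts) for node in comm}
    score = nx.community.modularity(net, parts, weight="weight")
    return labels, score


def analyze(net: nx.Graph, seed: int, resolution: float = 1.0) -> CentralityResult:
    betweenness, closeness = centralities(net)
    labels, score = communities(net, seed=seed, resolution=resolution)
    return CentralityResult(
        betweenness=betweenness,
        closeness=closeness,
        modularity_class=labels,
        modularity=score,
    )


def summarize(full: nx.Graph, giant: nx.Graph, pruned: nx.Graph) -> pd.DataFrame:
    """Node/edge counts per stage with 2-decimal percentages of the full
    network. Percentages are always recomputed from the counts."""
    if not set(giant.nodes) <= set(full.nodes):
        raise ValueError("giant component is not a subgraph of the full network")
    if not set(pruned.nodes) <= set(giant.nodes):
        raise ValueError("pruned network is not a subgraph of the giant component")
    n_full, e_full = full.number_of_nodes(), full.number_of_edges()
    rows = []
    for stage, g in [("full", full), ("giant", giant), ("pruned", pruned)]:
        rows.append(
            {
                "stage": stage,
                "nodes": g.number_of_nodes(),
                "node_pct": _pct2(g.number_of_nodes(), n_full),
                "edges": g.number_of_edges(),
                "edge_pct": _pct2(g.number_of_edges(), e_full),
            }
        )
    return pd.DataFrame(rows, columns=["stage", "nodes", "node_pct", "edges", "edge_pct"])


def write_edgelist(net: nx.Graph, path) -> None:
    """gene1 TAB gene2 TAB weight, sorted for stable output."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\t{net[a][b]['weight']}\n")


def read_edgelist(path) -> nx.Graph:
    net = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            a, b, w = line.rstrip("\n").split("\t")
            net.add_edge(a, b, weight=int(w))
    return net


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
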