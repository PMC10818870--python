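"""Network topology: summary indices, modules, and Zi-Pi hub roles."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

#: Within-module degree z-score above which a node is a (module or network) hub.
ZI_HUB = 2.5
#: Participation coefficient above which a node is a connector.
PI_CONNECTOR = 0.62


@dataclass
class TopologySummary:
    node_count: int
    edge_count: int
    average_degree: float
    average_distance: float
    component_count: int
    module_count: int | None = None
    modularity: float | None = None


def topology_summary(net: nx.Graph) -> TopologySummary:
    """Node/edge counts, average degree 2E/N, and average shortest-path
    distance over connected node pairs (pairs in different components are
    excluded; the component count is reported alongside)."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    e = net.number_of_edges()
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1  # excludes self
    # each unordered pair counted twice
    avg_dist = (total / pairs) if pairs else float("nan")
    return TopologySummary(
        node_count=n,
        edge_count=e,
        average_degree=2.0 * e / n,
        average_distance=avg_dist,
        component_count=nx.number_connected_components(net),
    )


def detect_modules(net: nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Partition nodes into modules by greedy modularity maximization.

    Returns (node -> module id map, modularity score). The greedy CNM
    algorithm is deterministic; ``seed`` is accepted for interface stability
    with stochastic alternatives.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    communities = nx.community.greedy_modularity_communities(net)
    partition = {}
    for m, comm in enumerate(communities):
        for node in comm:
            partition[node] = m
    q = nx.community.modularity(net, communities)
    return partition, float(q)


def zipi(net: nx.Graph, partition: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi = (k_within - mean_module) / sd_module (0 when sd = 0);
    Pi = 1 - sum_m (k_im / k_i)^2. Roles: module_hub (Zi > 2.5, Pi <= 0.62),
    connector (Pi > 0.62, Zi <= 2.5), network_hub (both exceeded),
    peripheral otherwise.
    """
    missing = [v for v in net.nodes if v not in partition]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing[:5]}")
    within = {}
    per_module_links = {}
    for node in net.nodes:
        m = partition[node]
        counts: dict = {}
        for nb in net.neighbors(node):
            counts[partition[nb]] = counts.get(partition[nb], 0) + 1
        per_module_links[node] = counts
        within[node] = counts.get(m, 0)
    # z-score of within-degree, per module
    by_module: dict = {}
    for node in net.nodes:
        by_module.setdefault(partition[node], []).append(within[node])
    mod_stats = {m: (np.mean(v), np.std(v)) for m, v in by_module.items()}
    rows = []
    for node in net.nodes:
        k = net.degree(node)
        if k == 0:
            raise ValueError(f"isolated node {node!r}; remove isolates first")
        mu, sd = mod_stats[partition[node]]
        zi = (within[node] - mu) / sd if sd > 0 else 0.0
        pi = 1.0 - sum((c / k) ** 2 for c in per_module_links[node].values())
        if zi > ZI_HUB and pi > PI_CONNECTOR:
            role = "network_hub"
        elif zi > ZI_HUB:
            role = "module_hub"
        elif pi > PI_CONNECTOR:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"node": node, "module": partition[node], "Zi": zi,
                     "Pi": pi, "role": role})
    return pd.DataFrame(rows).set_index("node")
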