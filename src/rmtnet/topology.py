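"""Network construction, module detection and topology metrics (Step III).

All metrics are computed on the unweighted skeleton (a link either exists or
not); similarity weights are retained on edges for export only.  Module
detection is greedy (CNM-style) modularity maximisation with deterministic
behaviour given the node labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_model import (EcoNetwork, OtuTable, SimilarityMatrix, TopologyPanel,
                       ValidationError)
from .rmt import truncate_similarity


class EmptyNetworkError(ValidationError):
    """Signal that no edge survives the threshold."""


@dataclass
class ModulePartition:
    """Node -> module assignment with its Newman modularity Q."""

    assignment: dict[str, int]
    sizes: dict[int, int]
    q: float

    @property
    def n_modules(self) -> int:
        return len(self.sizes)

    def n_modules_larger_than(self, min_size: int) -> int:
        return sum(1 for s in self.sizes.values() if s > min_size)


def build_network(sim: SimilarityMatrix, threshold: float,
                  table: OtuTable | None = None) -> EcoNetwork:
    """Build the co-occurrence network of all pairs with |r| >= threshold.

    Nodes are OTUs with at least one qualifying link; edge weight is the
    similarity, edge sign the sign of the underlying correlation.  Raises
    :class:`EmptyNetworkError` when nothing survives.
    """
    trunc = truncate_similarity(sim, threshold)
    if trunc.is_empty:
        raise EmptyNetworkError(
            f"no similarity reaches the threshold {threshold}")
    ids = trunc.otu_ids
    index = {o: i for i, o in enumerate(sim.otu_ids)}
    edges = []
    m = trunc.matrix
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if m[i, j] > 0:
                sign = int(sim.raw_sign[index[ids[i]], index[ids[j]]])
                edges.append((ids[i], ids[j], float(m[i, j]), sign))
    taxa = ({o: table.phylum_of(o) for o in ids} if table is not None else None)
    return EcoNetwork(list(ids), edges, float(threshold), node_taxa=taxa)


def average_degree(n_nodes: int, n_links: int) -> float:
    """Mean degree 2L/N."""
    if n_nodes <= 0:
        raise ValidationError("average degree needs at least one node")
    return 2.0 * n_links / n_nodes


def density(n_nodes: int, n_links: int) -> float:
    """Links as a fraction of possible pairs, L / (N(N-1)/2)."""
    if n_nodes < 2:
        raise ValidationError("density needs at least two nodes")
    return n_links / (n_nodes * (n_nodes - 1) / 2.0)


def clustering_stats(net: EcoNetwork) -> tuple[float, float]:
    """(average local clustering, transitivity = 3 triangles / triples)."""
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    return float(nx.average_clustering(g)), float(nx.transitivity(g))


def path_stats(net: EcoNetwork) -> tuple[float, float, float]:
    """Shortest-path panel on the unweighted graph.

    Returns (average path distance over *reachable* unordered pairs,
    geodesic efficiency = mean of 1/d over *all* unordered pairs with
    1/inf = 0, Krackhardt connectedness = reachable pairs / all pairs).
    """
    g = net.to_networkx()
    n = g.number_of_nodes()
    if n == 0:
        raise ValidationError("empty network")
    total_pairs = n * (n - 1) / 2.0
    dist_sum = 0.0
    inv_sum = 0.0
    reachable = 0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            if src < dst:  # each unordered pair once
                dist_sum += d
                inv_sum += 1.0 / d
                reachable += 1
    avg_path = dist_sum / reachable if reachable else float("nan")
    efficiency = inv_sum / total_pairs if total_pairs else float("nan")
    connectedness = reachable / total_pairs if total_pairs else float("nan")
    return avg_path, efficiency, connectedness


def powerlaw_r2(net: EcoNetwork) -> float | None:
    """R^2 of the log10(frequency) ~ log10(degree) regression.

    The scale-free credibility statistic: degrees with nonzero frequency
    enter an ordinary least-squares fit on the log-log scale.  Returns None
    when fewer than 3 distinct degrees exist (regression undefined).
    """
    g = net.to_networkx()
    degrees = np.array([d for _, d in g.degree()])
    ks, freq = np.unique(degrees[degrees > 0], return_counts=True)
    if ks.size < 3:
        return None
    x = np.log10(ks.astype(float))
    y = np.log10(freq.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0
    return float(1.0 - (resid ** 2).sum() / ss_tot)


def detect_modules(net: EcoNetwork) -> ModulePartition:
    """Greedy (CNM) modularity maximisation with deterministic labelling.

    Modules are numbered 1..k by decreasing size (ties by smallest member
    label) and Q is Newman's modularity of the returned partition.
    """
    g = net.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValidationError("empty network")
    if g.number_of_edges() == 0:
        raise ValidationError("network has no edges")
    communities = nx.community.greedy_modularity_communities(g)
    communities = sorted((sorted(c) for c in communities),
                         key=lambda c: (-len(c), c[0]))
    assignment = {node: m for m, comm in enumerate(communities, start=1)
                  for node in comm}
    sizes = {m: len(comm) for m, comm in enumerate(communities, start=1)}
    q = float(nx.community.modularity(g, [set(c) for c in communities]))
    return ModulePartition(assignment, sizes, q)


def newman_q(net: EcoNetwork, assignment: dict[str, int]) -> float:
    """Newman modularity Q = sum_c (e_c/m - (d_c/2m)^2) for any partition."""
    g = net.to_networkx()
    groups: dict[int, set] = {}
    for node, m in assignment.items():
        groups.setdefault(m, set()).add(node)
    return float(nx.community.modularity(g, list(groups.values())))


def topology_panel(net: EcoNetwork, partition: ModulePartition,
                   n_original_otus: int,
                   min_module_size_for_reporting: int = 5) -> TopologyPanel:
    """Assemble the full topology comparison panel for one network."""
    n, l = net.n_nodes, net.n_links
    avg_clust, trans = clustering_stats(net)
    avg_path, efficiency, connectedness = path_stats(net)
    r2 = powerlaw_r2(net)
    g = net.to_networkx()
    return TopologyPanel(
        n_original_otus=n_original_otus,
        total_nodes=n,
        total_links=l,
        r_square_power_law=float("nan") if r2 is None else r2,
        avg_degree=average_degree(n, l),
        avg_clustering=avg_clust,
        avg_path_distance=avg_path,
        geodesic_efficiency=efficiency,
        maximal_degree=int(max(d for _, d in g.degree())),
        density=density(n, l),
        transitivity=trans,
        connectedness=connectedness,
        n_modules=partition.n_modules,
        n_modules_large=partition.n_modules_larger_than(
            min_module_size_for_reporting),
        modularity=partition.q,
        threshold=net.threshold,
    )
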