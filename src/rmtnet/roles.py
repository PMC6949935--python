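"""Topological node roles: within-module Zi, among-module Pi (Step III).

Zi is the z-score of a node's link count into its own module (population
standard deviation over the module's members, after Guimera & Amaral); Pi is
the participation coefficient 1 - sum_t (k_it / k_i)^2 over modules t.  The
four-way classification cuts at Zi = 2.5 and Pi = 0.62, boundaries falling
into the <= branches: peripherals, module hubs (high Zi), connectors (high
Pi) and network hubs (both).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import EcoNetwork
from .topology import ModulePartition

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLES = ("peripheral", "module_hub", "connector", "network_hub")


@dataclass
class NodeRole:
    node: str
    zi: float
    pi: float
    role: str
    module: int
    phylum: str = "Unclassified"


def _neighbor_modules(net: EcoNetwork,
                      assignment: dict[str, int]) -> dict[str, dict[int, int]]:
    """node -> {module -> link count into that module}."""
    counts: dict[str, dict[int, int]] = {n: {} for n in net.nodes}
    for a, b, *_ in net.edges:
        counts[a][assignment[b]] = counts[a].get(assignment[b], 0) + 1
        counts[b][assignment[a]] = counts[b].get(assignment[a], 0) + 1
    return counts


def compute_zi(net: EcoNetwork,
               partition: ModulePartition) -> dict[str, float]:
    """Within-module connectivity z-score per node.

    Modules whose members all have equal within-module degree (sd = 0,
    including singletons) give Zi = 0: the members are topologically
    equivalent, hence none is a hub.
    """
    assignment = partition.assignment
    counts = _neighbor_modules(net, assignment)
    k_in = {n: counts[n].get(assignment[n], 0) for n in net.nodes}
    zi: dict[str, float] = {}
    for module in partition.sizes:
        members = [n for n in net.nodes if assignment[n] == module]
        vals = np.array([k_in[n] for n in members], dtype=float)
        mean, sd = vals.mean(), vals.std()  # population sd
        for n in members:
            zi[n] = 0.0 if sd == 0 else float((k_in[n] - mean) / sd)
    return zi


def compute_pi(net: EcoNetwork,
               partition: ModulePartition) -> dict[str, float]:
    """Participation coefficient per node: 1 - sum_t (k_it/k_i)^2."""
    counts = _neighbor_modules(net, partition.assignment)
    pi: dict[str, float] = {}
    for n in net.nodes:
        k = sum(counts[n].values())
        pi[n] = float(1.0 - sum((c / k) ** 2 for c in counts[n].values()))
    return pi


def classify_roles(zi_pi: dict[str, tuple[float, float]]) -> dict[str, str]:
    """Strict 2.5 / 0.62 cuts; exact boundary values fall in <= branches."""
    roles: dict[str, str] = {}
    for node, (zi, pi) in zi_pi.items():
        if zi > ZI_THRESHOLD:
            roles[node] = "network_hub" if pi > PI_THRESHOLD else "module_hub"
        else:
            roles[node] = "connector" if pi > PI_THRESHOLD else "peripheral"
    return roles


def node_roles(net: EcoNetwork, partition: ModulePartition,
               taxonomy: dict[str, str] | None = None) -> list[NodeRole]:
    zi = compute_zi(net, partition)
    pi = compute_pi(net, partition)
    roles = classify_roles({n: (zi[n], pi[n]) for n in net.nodes})
    taxa = net.node_taxa or {}
    out = []
    for n in net.nodes:
        phylum = taxa.get(n) or (taxonomy or {}).get(n) or "Unclassified"
        out.append(NodeRole(n, zi[n], pi[n], roles[n],
                            partition.assignment[n], phylum))
    return out


def zp_table(roles: list[NodeRole]) -> tuple[pd.DataFrame, pd.Series]:
    """Long table for the Z-p scatter plus role counts.

    Columns: node, zi, pi, role, module, phylum.  The counts sum to the
    node count (roles partition the nodes).
    """
    df = pd.DataFrame(
        [(r.node, r.zi, r.pi, r.role, r.module, r.phylum) for r in roles],
        columns=["node", "zi", "pi", "role", "module", "phylum"])
    counts = df["role"].value_counts().reindex(ROLES, fill_value=0)
    return df, counts
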