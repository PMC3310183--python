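"""Protein-interaction network: loading, centrality, functional similarity.

The network is an undirected simple graph over opaque gene identifiers,
held as a :class:`networkx.Graph`.  Betweenness centrality follows the
unordered-pair normalization

    B(n) = [ sum_{s!=n!=t} sigma_st(n) / sigma_st ] / [ (N-1)(N-2)/2 ]

with the sum over unordered pairs {s, t} not containing n; pairs with no
connecting path contribute 0 and N stays the full node count.  This is
exactly networkx's normalized betweenness for undirected graphs.

Functional similarity between a gene and a drug's target set is a sum of
a decaying kernel of unweighted shortest-path length over the drug's
in-network targets; the default Gaussian kernel exp(-L^2) makes a gene
that is itself a target contribute 1 and an unreachable target 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "LoadReport",
    "load_network",
    "degree",
    "betweenness",
    "betweenness_centrality",
    "functional_similarity",
    "functional_profile",
    "functional_profile_matrix",
    "top_fraction_nodes",
    "KERNELS",
]

#: Distance -> similarity transforms selectable in config.
KERNELS = {
    "gauss": lambda d: math.exp(-(d * d)),
    "exp": lambda d: math.exp(-d),
    "inverse": lambda d: 1.0 / (1.0 + d),
}


@dataclass
class LoadReport:
    """What the edge-list loader kept and dropped."""

    n_nodes: int
    n_edges: int
    n_self_loops_dropped: int
    n_duplicate_edges_dropped: int
    n_components: int
    component_sizes: tuple


def load_network(path) -> nx.Graph:
    """Load an undirected simple graph from a two-column edge-list file.

    Lines starting with ``#`` and blank lines are ignored.  Self-loops are
    dropped (nodes appearing only in self-loops are dropped entirely);
    duplicate and reversed-duplicate edges collapse to one.  A
    :class:`LoadReport` is attached as ``G.graph["load_report"]``.

    Raises
    ------
    ValueError
        On a line with fewer than two fields (with its line number), or if
        the file yields an empty graph.
    """
    g = nx.Graph()
    self_loops = 0
    duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two identifiers, got {line!r}"
                )
            a, b = fields[0], fields[1]
            if a == b:
                self_loops += 1
                continue
            if g.has_edge(a, b):
                duplicates += 1
                continue
            g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no usable interactions found")
    comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    g.graph["load_report"] = LoadReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_self_loops_dropped=self_loops,
        n_duplicate_edges_dropped=duplicates,
        n_components=len(comps),
        component_sizes=tuple(comps),
    )
    return g


def _require_node(net: nx.Graph, node: str) -> None:
    if node not in net:
        raise ValueError(f"gene {node!r} is not in the network")


def degree(net: nx.Graph, node: str) -> int:
    """Number of distinct interaction partners of ``node``."""
    _require_node(net, node)
    return net.degree(node)


def betweenness_centrality(net: nx.Graph) -> dict:
    """Normalized betweenness for every node (values in [0, 1]).

    Requires at least 3 nodes, otherwise the normalizing pair count
    (N-1)(N-2)/2 degenerates.  O(N*E); compute once and reuse.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("betweenness needs a network of at least 3 nodes")
    return nx.betweenness_centrality(net, normalized=True)


def betweenness(net: nx.Graph, node: str) -> float:
    """Normalized betweenness of one node (recomputes the full pass)."""
    _require_node(net, node)
    return betweenness_centrality(net)[node]


def functional_similarity(
    net: nx.Graph, gene: str, targets, kernel: str = "gauss"
) -> float:
    """Kernel-summed network proximity of ``gene`` to a drug's target set.

    Sum over the in-network targets of ``kernel`` applied to the
    unweighted shortest-path length; targets outside the network or
    unreachable from ``gene`` contribute 0.  Monotone non-decreasing in
    the target set.
    """
    _require_node(net, gene)
    kfun = KERNELS[kernel]
    dists = nx.single_source_shortest_path_length(net, gene)
    return float(sum(kfun(dists[t]) for t in targets if t in dists))


def functional_profile(net: nx.Graph, gene: str, space, kernel: str = "gauss") -> np.ndarray:
    """Functional-similarity profile of one gene over the drug space."""
    _require_node(net, gene)
    kfun = KERNELS[kernel]
    dists = nx.single_source_shortest_path_length(net, gene)
    out = np.zeros(len(space), dtype=float)
    for i, drug in enumerate(space):
        out[i] = sum(kfun(dists[t]) for t in drug.targets if t in dists)
    return out


def functional_profile_matrix(net: nx.Graph, space, kernel: str = "gauss"):
    """Functional profiles of every network gene, as one (N, D) matrix.

    Returns ``(genes, M)`` where ``genes`` is the sorted node list and row
    i of ``M`` is :func:`functional_profile` of ``genes[i]``.  Profiles
    are query-independent, so this is computed once per (space, network)
    and reused across all query compounds.  One BFS per distinct target
    gene (targets shared between drugs are traversed once).
    """
    genes = sorted(net.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    kfun = KERNELS[kernel]
    n = len(genes)
    m = np.zeros((n, len(space)), dtype=float)

    kernel_vec_cache: dict = {}  # target gene -> kernel-of-distance vector
    for j, drug in enumerate(space):
        for t in sorted(drug.targets):
            if t not in idx:
                continue  # target not in the network: contributes nothing
            vec = kernel_vec_cache.get(t)
            if vec is None:
                vec = np.zeros(n, dtype=float)
                for node, d in nx.single_source_shortest_path_length(net, t).items():
                    vec[idx[node]] = kfun(d)
                kernel_vec_cache[t] = vec
            m[:, j] += vec
    return genes, m


def top_fraction_nodes(net: nx.Graph, metric: str, fraction: float) -> frozenset:
    """The floor(fraction*N) highest-degree or highest-betweenness nodes.

    At least one node is always returned.  Ties are broken by descending
    metric value then ascending identifier, so the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if metric == "degree":
        values = dict(net.degree())
    elif metric == "betweenness":
        values = betweenness_centrality(net)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    count = max(1, int(fraction * net.number_of_nodes()))
    ranked = sorted(values, key=lambda g: (-values[g], g))
    return frozenset(ranked[:count])
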