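"""Cell communities and the merged cell-community network.

Communities in the weighted cell-cell association network come from one
of three igraph algorithms (edge betweenness with the dendrogram cut at
maximum modularity, recursive leading-eigenvector splitting, or Louvain
weighted-modularity optimisation).  Cells of the same community (or the
same phenotype, when labels are supplied) collapse to a single node, and
the edge between two community nodes is the arithmetic mean of the
existing cell-cell edge weights between the groups — pairs with no edge
contribute nothing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp

from .graphs import CorrelationNetwork
from .types import PhenotypeTable

__all__ = ["CommunityNetwork", "detect_communities", "merge_to_community_network"]

_METHODS = ("edge_betweenness", "leading_eigen", "louvain")


@dataclass
class CommunityNetwork:
    communities: list[str]
    adjacency: sp.csr_matrix  # mean inter-community weights
    members: dict[str, list[str]]


def _to_igraph(cellnet: CorrelationNetwork) -> ig.Graph:
    coo = sp.triu(cellnet.adjacency, k=1).tocoo()
    g = ig.Graph(n=cellnet.n_nodes)
    g.add_edges(list(zip(coo.row.tolist(), coo.col.tolist())))
    g.es["weight"] = coo.data.tolist()
    g.vs["name"] = list(cellnet.nodes)
    return g


def detect_communities(
    cellnet: CorrelationNetwork, method: str = "louvain", seed: int = 0
) -> dict[str, str]:
    """Partition cells into communities; returns cell -> community id.

    igraph's RNG is Python's ``random`` module, seeded here so Louvain's
    node sweep order (and therefore the partition) is reproducible.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if cellnet.n_nodes == 0:
        raise ValueError("empty network")
    g = _to_igraph(cellnet)
    weights = g.es["weight"] if g.ecount() else None
    random.seed(seed)
    if method == "louvain":
        clustering = g.community_multilevel(weights=weights)
    elif method == "leading_eigen":
        clustering = g.community_leading_eigenvector(weights=weights)
    else:
        dendro = g.community_edge_betweenness(weights=weights)
        # cut the dendrogram at maximum modularity over achievable counts
        # (igraph's optimal_count can be unreachable on disconnected graphs)
        n_comp = len(g.connected_components())
        best_q, clustering = -np.inf, None
        for n_clusters in range(n_comp, g.vcount() + 1):
            cl = dendro.as_clustering(n=n_clusters)
            q = g.modularity(cl.membership, weights=weights)
            if q > best_q:
                best_q, clustering = q, cl
    return {
        g.vs[v]["name"]: f"community_{k}"
        for k, block in enumerate(clustering)
        for v in block
    }


def merge_to_community_network(
    cellnet: CorrelationNetwork,
    partition: dict[str, str] | PhenotypeTable,
) -> CommunityNetwork:
    """Collapse cells to community nodes, averaging inter-group edge weights."""
    if isinstance(partition, PhenotypeTable):
        partition = dict(partition.assignments)
    missing = [c for c in cellnet.nodes if c not in partition]
    if missing:
        raise ValueError(f"partition does not cover cells {missing[:5]}")
    labels = list(dict.fromkeys(partition[c] for c in cellnet.nodes))
    members: dict[str, list[str]] = {lab: [] for lab in labels}
    for c in cellnet.nodes:
        members[partition[c]].append(c)
    empty = [lab for lab, cells in members.items() if not cells]
    if empty:
        raise ValueError(f"groups with zero members: {empty}")
    li = {lab: i for i, lab in enumerate(labels)}
    node_group = np.array([li[partition[c]] for c in cellnet.nodes])
    coo = sp.triu(cellnet.adjacency, k=1).tocoo()
    sums = {}
    counts = {}
    for i, j, w in zip(coo.row, coo.col, coo.data):
        a, b = node_group[i], node_group[j]
        if a == b:
            continue  # within-group edges don't enter inter-group averaging
        key = (min(a, b), max(a, b))
        sums[key] = sums.get(key, 0.0) + w
        counts[key] = counts.get(key, 0) + 1
    k = len(labels)
    adj = sp.lil_matrix((k, k))
    for key, s in sums.items():
        mean = s / counts[key]
        adj[key[0], key[1]] = mean
        adj[key[1], key[0]] = mean
    return CommunityNetwork(labels, adj.tocsr(), members)
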