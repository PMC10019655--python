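"""Spectral k-means clustering of the key-target subnetwork.

Nodes are embedded with the eigenvectors of the symmetric normalized
graph Laplacian belonging to the k smallest eigenvalues, then grouped by
k-means (k-means++ initialization, 100 restarts, seeded), the standard
spectral-clustering recipe.  On a graph with k connected components the
embedding reduces to component indicators, so clusters coincide with
components.  Cluster ids are relabelled 1..k by the lexicographically
smallest member gene, making the assignment deterministic for a given
seed.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

__all__ = ["spectral_kmeans", "cluster_sizes"]


def spectral_kmeans(g: nx.Graph, k: int = 3, seed: int = 0) -> dict[str, int]:
    """Cluster graph nodes into k groups; returns gene -> cluster id (1..k).

    Requires ``k >= 2`` and at least k nodes.  Deterministic given the
    seed.
    """
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} nodes")
    lap = nx.normalized_laplacian_matrix(g, nodelist=nodes).toarray()
    lap = (lap + lap.T) / 2.0  # enforce exact symmetry for eigh
    _, vecs = eigh(lap)
    embedding = vecs[:, :k]
    km = KMeans(n_clusters=k, init="k-means++", n_init=100, random_state=seed)
    labels = km.fit_predict(embedding)
    if len(set(labels)) != k:
        raise RuntimeError(f"k-means produced fewer than {k} non-empty clusters")
    # stable relabelling: order clusters by their smallest member symbol
    members: dict[int, list[str]] = {}
    for node, lab in zip(nodes, labels):
        members.setdefault(int(lab), []).append(node)
    order = sorted(members, key=lambda lab: min(members[lab]))
    relabel = {lab: i + 1 for i, lab in enumerate(order)}
    return {node: relabel[int(lab)] for node, lab in zip(nodes, labels)}


def cluster_sizes(assignment: dict[str, int]) -> dict[int, int]:
    """Number of genes per cluster id."""
    out: dict[int, int] = {}
    for cid in assignment.values():
        out[cid] = out.get(cid, 0) + 1
    return dict(sorted(out.items()))
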