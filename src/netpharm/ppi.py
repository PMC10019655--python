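"""PPI network construction and topological key-target screening.

The scored edge list (STRING combined-score convention) is thresholded at
a minimum confidence (default 0.4, inclusive) over a fixed gene universe.
Proteins left without any surviving interaction are discarded as isolates.
On the isolate-free network two topological parameters are computed per
node: degree (incident edge count) and betweenness centrality (fraction of
all-pairs shortest paths passing through the node, Brandes' algorithm,
unweighted, normalized by (n−1)(n−2)/2).  Key targets are the nodes
strictly above the network mean on *both* parameters.  Reporting-grade
metrics are then recomputed inside the induced key-target subnetwork
(second pass), whose degree column sums to twice its edge count.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .models import PPIEdge, TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "MIN_SCORE_DEFAULT",
    "build_ppi_graph",
    "remove_isolates",
    "centrality_metrics",
    "screen_key_targets",
    "induced_subgraph",
    "subnetwork_metrics",
    "edge_count_from_degrees",
]

MIN_SCORE_DEFAULT = 0.4


def build_ppi_graph(
    edges: Iterable[PPIEdge],
    node_universe: TargetSet | Iterable[str] | None = None,
    min_score: float = MIN_SCORE_DEFAULT,
) -> nx.Graph:
    """Build the undirected scored PPI graph over a gene universe.

    Edges scoring below ``min_score`` are dropped (threshold inclusive:
    a score equal to the minimum is kept).  Nodes of the universe without
    surviving edges remain in the graph as isolates until
    :func:`remove_isolates`.  Edges with an endpoint outside the universe
    are dropped with a warning.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    g = nx.Graph(min_score=min_score)
    universe: set[str] | None = None
    if node_universe is not None:
        genes = node_universe.genes if isinstance(node_universe, TargetSet) else node_universe
        universe = set(genes)
        g.add_nodes_from(sorted(universe))
    n_outside = 0
    for e in edges:
        if universe is not None and (e.a not in universe or e.b not in universe):
            n_outside += 1
            continue
        if e.score >= min_score:
            g.add_edge(e.a, e.b, score=e.score)
    if n_outside:
        logger.warning("dropped %d edge(s) with endpoints outside the universe", n_outside)
    return g


def remove_isolates(g: nx.Graph) -> tuple[nx.Graph, list[str]]:
    """Drop zero-degree nodes; return the pruned copy and the removed list."""
    removed = sorted(n for n in g.nodes if g.degree(n) == 0)
    pruned = g.copy()
    pruned.remove_nodes_from(removed)
    return pruned, removed


def centrality_metrics(g: nx.Graph) -> pd.DataFrame:
    """Per-gene degree and normalized betweenness centrality.

    Betweenness follows Brandes' shortest-path accumulation on the
    unweighted graph (edge scores gate existence, not path length),
    normalized by (n−1)(n−2)/2; unreachable pairs contribute nothing.
    Graphs with fewer than three nodes get betweenness 0 with a warning
    (the normalizer is undefined).  Rows are sorted by descending degree,
    then gene symbol.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if n < 3:
        warnings.warn("betweenness undefined for n < 3; reporting 0", stacklevel=2)
        bc = {v: 0.0 for v in g.nodes}
    else:
        bc = nx.betweenness_centrality(g, normalized=True)
    rows = [
        {"gene": v, "degree": int(g.degree(v)), "betweenness": float(bc[v])}
        for v in g.nodes
    ]
    df = pd.DataFrame(rows, columns=["gene", "degree", "betweenness"])
    return df.sort_values(["degree", "gene"], ascending=[False, True]).reset_index(drop=True)


def screen_key_targets(table: pd.DataFrame) -> list[str]:
    """Genes strictly above the mean on both degree and betweenness.

    The means are arithmetic over the given (isolate-free) table; a tie at
    the mean is not above it, so perfectly regular graphs select nothing.
    Output is sorted by descending degree then gene and is invariant to
    input row order.
    """
    if table.empty:
        raise ValueError("empty centrality table")
    mean_deg = table["degree"].mean()
    mean_bc = table["betweenness"].mean()
    hits = table[(table["degree"] > mean_deg) & (table["betweenness"] > mean_bc)]
    hits = hits.sort_values(["degree", "gene"], ascending=[False, True])
    return hits["gene"].tolist()


def induced_subgraph(g: nx.Graph, keep: Sequence[str]) -> nx.Graph:
    """Subgraph on ``keep`` retaining only internal edges."""
    missing = [n for n in keep if n not in g]
    if missing:
        raise ValueError(f"nodes not in graph: {', '.join(map(str, missing))}")
    return g.subgraph(keep).copy()


def subnetwork_metrics(g: nx.Graph) -> pd.DataFrame:
    """Second-pass metrics computed *within* a subnetwork.

    Identical computation to :func:`centrality_metrics`; provided as a
    named step because reported key-target tables use subnetwork-internal
    degree and betweenness, not the full-network values used to screen.
    """
    return centrality_metrics(g)


def edge_count_from_degrees(degrees: Iterable[int]) -> int:
    """Edge count from a degree sequence via the handshake lemma (Σd / 2)."""
    total = 0
    for d in degrees:
        if d < 0:
            raise ValueError("degrees must be non-negative")
        total += int(d)
    if total % 2:
        raise ValueError(f"invalid degree sequence: odd degree sum {total}")
    return total // 2
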