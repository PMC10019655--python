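"""Compound–target bipartite network assembly.

The two-layer network joins ADME-passing compounds (upper layer, coloured
by source herb: one colour per exclusive herb, a third for shared
compounds) to the screened key targets (lower layer, coloured by cluster).
Compound-target edges are restricted to key targets; compounds left
without any surviving edge are dropped and reported.  A target counts as
*shared between herbs* when it is adjacent to compounds attributed to at
least two distinct herbs — compounds sourced from both herbs vouch for
both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .models import CompoundRecord, CTEdge

logger = logging.getLogger(__name__)

__all__ = ["CTNetwork", "assemble_ct_network", "shared_key_targets"]


@dataclass
class CTNetwork:
    """Bipartite compound–target network plus assembly bookkeeping."""

    graph: nx.Graph
    dropped_compounds: list[int] = field(default_factory=list)

    @property
    def compound_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("layer") == "compound"
        )

    @property
    def target_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("layer") == "target"
        )

    def summary(self) -> dict:
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_compounds": len(self.compound_nodes),
            "n_targets": len(self.target_nodes),
            "dropped_compounds": sorted(self.dropped_compounds),
        }


def _herb_class(herbs: frozenset[str]) -> str:
    if len(herbs) == 1:
        return f"{next(iter(herbs))}-only"
    return "shared"


def assemble_ct_network(
    compounds: Sequence[CompoundRecord],
    edges: Iterable[CTEdge],
    key_targets: Sequence[str],
    clusters: Mapping[str, int] | None = None,
) -> CTNetwork:
    """Assemble the bipartite network of compounds versus key targets.

    Compound nodes are named ``CID:<pubchem_cid>`` to keep the two layers
    disjoint and carry ``name``, ``herb_class`` and ``herbs`` attributes;
    target nodes carry their ``cluster`` id when a cluster assignment is
    given.  Edges to non-key targets are discarded; compounds with no
    remaining edge are dropped and listed in the result.
    """
    if not key_targets:
        raise ValueError("key_targets must be non-empty")
    keep = set(key_targets)
    by_cid = {c.pubchem_cid: c for c in compounds}
    g = nx.Graph()
    touched: set[int] = set()
    for e in edges:
        rec = by_cid.get(e.compound)
        if rec is None:
            logger.warning("edge %s->%s: unknown compound, skipped", e.compound, e.target)
            continue
        if e.target not in keep:
            continue
        cnode = f"CID:{rec.pubchem_cid}"
        if cnode not in g:
            g.add_node(
                cnode,
                layer="compound",
                name=rec.name,
                herb_class=_herb_class(rec.herbs),
                herbs=";".join(sorted(rec.herbs)),
            )
        if e.target not in g:
            attrs = {"layer": "target"}
            if clusters is not None and e.target in clusters:
                attrs["cluster"] = int(clusters[e.target])
            g.add_node(e.target, **attrs)
        g.add_edge(cnode, e.target, interaction="ct")
        touched.add(rec.pubchem_cid)
    dropped = sorted(set(by_cid) - touched)
    if g.number_of_edges() == 0:
        logger.warning("no compound-target edges survive the key-target filter")
    return CTNetwork(graph=g, dropped_compounds=dropped)


def shared_key_targets(net: CTNetwork) -> list[str]:
    """Key targets adjacent to compounds of at least two distinct herbs.

    Compounds attributed to several herbs count as evidence for each of
    them, so a target reached only by one dual-source compound is still
    shared.
    """
    shared: list[str] = []
    for t in net.target_nodes:
        herbs: set[str] = set()
        for c in net.graph.neighbors(t):
            herbs.update(net.graph.nodes[c]["herbs"].split(";"))
        if len(herbs) >= 2:
            shared.append(t)
    return sorted(shared)
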