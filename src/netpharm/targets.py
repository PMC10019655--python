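"""Target-set algebra: herb target unions, disease sets, and overlaps.

Each ADME-passing compound has a set of protein targets; a herb's target
set is the union over all of its passing compounds (compounds shared
between herbs contribute to every source herb).  Disease gene sets from
independent databases are combined (intersection by default) and the
herb–disease overlap forms the universe for downstream PPI screening.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .adme import VennPartition
from .models import CompoundRecord, CTEdge, TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "herb_target_union",
    "combine_disease_sets",
    "overlap_with_disease",
    "venn_counts",
]


def herb_target_union(
    herb: str,
    compounds: Sequence[CompoundRecord],
    edges: Iterable[CTEdge],
) -> TargetSet:
    """Union of targets of all compounds attributed to ``herb``.

    ``compounds`` should already be ADME-filtered.  Edges referring to
    compounds absent from the table are skipped with a warning.
    """
    herb = herb.strip().upper()
    by_cid = {c.pubchem_cid: c for c in compounds}
    genes: set[str] = set()
    for e in edges:
        rec = by_cid.get(e.compound)
        if rec is None:
            logger.warning("edge %s->%s: unknown compound, skipped", e.compound, e.target)
            continue
        if herb in rec.herbs:
            genes.add(e.target)
    return TargetSet(herb, frozenset(genes))


def combine_disease_sets(
    s1: TargetSet, s2: TargetSet, mode: str = "intersection"
) -> TargetSet:
    """Combine two disease gene sets by intersection (default) or union."""
    if not s1.label or not s2.label:
        raise ValueError("disease sets must be labelled")
    if mode == "intersection":
        genes = s1.genes & s2.genes
    elif mode == "union":
        genes = s1.genes | s2.genes
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    return TargetSet(f"{s1.label}_{mode}_{s2.label}", genes)


def overlap_with_disease(herb_targets: TargetSet, disease: TargetSet) -> TargetSet:
    """Targets of the herb(s) that are also disease-associated genes."""
    return TargetSet(
        f"{herb_targets.label}&{disease.label}", herb_targets.genes & disease.genes
    )


def venn_counts(sets: Sequence[TargetSet]) -> VennPartition:
    """Partition the union of gene sets into exclusive/shared Venn blocks.

    Generalizes compound partitioning to gene sets (block keys are set
    labels); genes act as the partitioned elements.  Blocks are disjoint
    and exhaustive over the union of all inputs.
    """
    if not sets:
        raise ValueError("at least one gene set required")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("gene set labels must be unique")
    membership: dict[str, frozenset[str]] = {}
    for s in sets:
        for g in s.genes:
            membership[g] = membership.get(g, frozenset()) | {s.label}
    part = VennPartition()
    for g, labs in membership.items():
        if len(labs) == 1:
            (lab,) = labs
            part.exclusive.setdefault(lab, set()).add(g)  # type: ignore[arg-type]
        else:
            part.shared.setdefault(tuple(sorted(labs)), set()).add(g)  # type: ignore[arg-type]
    return part
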