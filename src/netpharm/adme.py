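"""ADME screening of herbal compounds and Venn partitioning by source herb.

Candidate compounds are kept when they satisfy both absorption-oriented
filters: oral bioavailability OB ≥ 30 % and drug-likeness DL ≥ 0.18
(inclusive thresholds).  Survivors are then partitioned by their full set
of source herbs — the blocks of a Venn diagram: herb-exclusive compounds
and compounds shared by each herb combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .models import CompoundRecord

__all__ = [
    "OB_MIN_DEFAULT",
    "DL_MIN_DEFAULT",
    "VennPartition",
    "filter_compounds",
    "partition_by_source",
]

OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.18


@dataclass
class VennPartition:
    """Disjoint blocks of compound ids keyed by herb-code combination.

    ``exclusive`` maps a single herb code to compounds found only in that
    herb; ``shared`` maps a sorted herb-code tuple (length ≥ 2) to the
    compounds attributed to exactly that combination.  Blocks are pairwise
    disjoint and jointly exhaustive over the input.
    """

    exclusive: dict[str, set[int]] = field(default_factory=dict)
    shared: dict[tuple[str, ...], set[int]] = field(default_factory=dict)

    def block_sizes(self) -> dict[str, int]:
        out = {h: len(s) for h, s in sorted(self.exclusive.items())}
        for combo, s in sorted(self.shared.items()):
            out["&".join(combo)] = len(s)
        return out

    def total(self) -> int:
        return sum(len(s) for s in self.exclusive.values()) + sum(
            len(s) for s in self.shared.values()
        )


def filter_compounds(
    records: Sequence[CompoundRecord],
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
) -> list[CompoundRecord]:
    """Retain compounds with ob ≥ ob_min and dl ≥ dl_min (both inclusive).

    Input order is preserved.  The filter is monotone: raising either
    threshold can only shrink the retained set.
    """
    for v, name in ((ob_min, "ob_min"), (dl_min, "dl_min")):
        if not (v == v and abs(v) != float("inf")):
            raise ValueError(f"{name} must be finite")
    return [r for r in records if r.ob >= ob_min and r.dl >= dl_min]


def partition_by_source(records: Iterable[CompoundRecord]) -> VennPartition:
    """Partition compounds by their full source-herb combination.

    Each compound lands in exactly one block: ``exclusive[h]`` when it is
    attributed to a single herb, else ``shared[(h1, h2, ...)]`` keyed by
    the sorted combination.  Records sharing a PubChem CID are counted
    once under the union of their herb attributions.
    """
    merged: dict[int, frozenset[str]] = {}
    for r in records:
        merged[r.pubchem_cid] = merged.get(r.pubchem_cid, frozenset()) | r.herbs
    part = VennPartition()
    for cid, herbs in merged.items():
        if len(herbs) == 1:
            (h,) = herbs
            part.exclusive.setdefault(h, set()).add(cid)
        else:
            combo = tuple(sorted(herbs))
            part.shared.setdefault(combo, set()).add(cid)
    return part
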