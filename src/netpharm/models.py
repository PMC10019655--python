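"""Core domain types shared by every pipeline stage.

The pipeline reasons about four kinds of entities: herbs and the
prescriptions that combine them, chemical compounds with their ADME
descriptors (oral bioavailability OB and drug-likeness DL), gene symbols
standing for protein targets, and annotation gene sets used for
over-representation analysis.  All types are lightweight frozen
dataclasses; heavier tabular/graph state lives in pandas / networkx
containers produced by the stage modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Herb",
    "Prescription",
    "CompoundRecord",
    "CTEdge",
    "PPIEdge",
    "GeneSet",
    "GeneSetCollection",
    "TargetSet",
    "normalize_symbol",
]

_SYMBOL_RE = re.compile(r"^[A-Z0-9][A-Z0-9._\-]*$")


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol to the canonical uppercase token form.

    Raises ``ValueError`` for empty or malformed symbols.  Symbols are
    treated as opaque validated tokens; no live identifier resolution is
    attempted.
    """
    s = str(symbol).strip().upper()
    if not s or not _SYMBOL_RE.match(s):
        raise ValueError(f"invalid gene symbol: {symbol!r}")
    return s


@dataclass(frozen=True)
class Herb:
    """A medicinal herb, identified by a short uppercase code (e.g. ``EH``)."""

    code: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.code or not self.code.strip():
            raise ValueError("herb code must be non-empty")


@dataclass(frozen=True)
class Prescription:
    """A multi-herb formula; must contain at least two distinct herbs."""

    id: str
    herbs: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "herbs", frozenset(self.herbs))
        if len(self.herbs) < 2:
            raise ValueError(
                f"prescription {self.id!r} must contain at least two herbs"
            )


@dataclass(frozen=True)
class CompoundRecord:
    """One compound row: identity plus the OB/DL ADME descriptors.

    ``ob`` is oral bioavailability in percent, ``dl`` the unitless
    drug-likeness score in [0, 1].  ``herbs`` lists the source herb codes;
    a compound present in several herbs carries them all in one record.
    """

    name: str
    pubchem_cid: int
    mw: float
    ob: float
    dl: float
    herbs: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "herbs", frozenset(self.herbs))
        if self.pubchem_cid <= 0:
            raise ValueError(f"{self.name}: pubchem_cid must be positive")
        if self.ob < 0:
            raise ValueError(f"{self.name}: OB must be non-negative")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"{self.name}: DL must lie in [0, 1]")
        if not self.herbs:
            raise ValueError(f"{self.name}: at least one source herb required")


@dataclass(frozen=True)
class CTEdge:
    """A compound-to-target link (PubChem CID -> gene symbol)."""

    compound: int
    target: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", normalize_symbol(self.target))


@dataclass(frozen=True)
class PPIEdge:
    """An undirected scored protein-protein association.

    Endpoints are stored in sorted order so that the unordered pair has a
    single canonical representation; the score is a confidence in [0, 1]
    (STRING combined-score convention after rescaling).
    """

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        a = normalize_symbol(self.a)
        b = normalize_symbol(self.b)
        if a == b:
            raise ValueError(f"self-interaction {a!r} is not allowed")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1] for {a}-{b}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


VALID_CATEGORIES = ("KEGG", "BP", "CC", "MF", "other")


@dataclass(frozen=True)
class GeneSet:
    """One annotation term (pathway or GO-style) with its member genes."""

    term_id: str
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genes", frozenset(normalize_symbol(g) for g in self.genes)
        )
        if not self.genes:
            raise ValueError(f"gene set {self.term_id!r} is empty")
        if self.category not in VALID_CATEGORIES:
            object.__setattr__(self, "category", "other")


@dataclass
class GeneSetCollection:
    """An ordered mapping of term-id -> :class:`GeneSet` (a GMT in memory)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.term_id in self.sets:
            raise ValueError(f"duplicate term id {gs.term_id!r}")
        self.sets[gs.term_id] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self:
            out |= gs.genes
        return frozenset(out)

    def by_category(self) -> Mapping[str, list[GeneSet]]:
        out: dict[str, list[GeneSet]] = {}
        for gs in self:
            out.setdefault(gs.category, []).append(gs)
        return out


@dataclass(frozen=True)
class TargetSet:
    """A labelled, deduplicated set of gene symbols."""

    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genes", frozenset(normalize_symbol(g) for g in self.genes)
        )

    @classmethod
    def from_iter(cls, label: str, genes: Iterable[str]) -> "TargetSet":
        return cls(label, frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes
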