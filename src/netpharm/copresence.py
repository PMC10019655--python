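"""Herb co-prescription analysis.

Prescriptions containing several herbs define a bipartite (2-mode)
membership structure: a binary incidence matrix with herbs in rows and
prescriptions in columns, where 1 marks presence.  Projecting the 2-mode
matrix onto the herb side (the matrix product B·Bᵀ, Breiger's method)
yields the 1-mode co-prescription network whose off-diagonal entries count
prescriptions shared by a herb pair and whose diagonal holds herb
frequencies.  Pairwise similarity is measured two ways: the set Jaccard
coefficient over presence sets, and Pearson correlation between binary
rows (the phi coefficient) for heatmap display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .models import Prescription

__all__ = [
    "IncidenceMatrix",
    "SimilarityMatrix",
    "build_incidence",
    "project_comembership",
    "jaccard_matrix",
    "pearson_matrix",
    "order_for_heatmap",
    "herb_network",
]


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary herbs × prescriptions membership matrix (the 2-mode network)."""

    herbs: tuple[str, ...]
    prescriptions: tuple[str, ...]
    values: np.ndarray  # shape (n_herbs, n_prescriptions), dtype int8

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.herbs), len(self.prescriptions)):
            raise ValueError("incidence shape does not match labels")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("incidence values must be binary")
        if (v.sum(axis=1) == 0).any():
            empty = [h for h, s in zip(self.herbs, v.sum(axis=1)) if s == 0]
            raise ValueError(f"all-zero herb row(s): {', '.join(empty)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.herbs),
                            columns=list(self.prescriptions))

    @property
    def frequencies(self) -> np.ndarray:
        """Number of prescriptions containing each herb (row sums)."""
        return self.values.sum(axis=1)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric herb × herb coefficient matrix of a stated kind."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str  # {cooccurrence-count, jaccard, pearson}

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("similarity shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def build_incidence(prescriptions: Sequence[Prescription]) -> IncidenceMatrix:
    """Arrange prescriptions in a binary herbs × prescriptions matrix.

    Herb rows are the sorted union of all herbs; prescription columns keep
    input order.  Prescriptions with fewer than two herbs are rejected (the
    :class:`~netpharm.models.Prescription` constructor already enforces
    this; re-checked here for inputs built by other means).
    """
    if not prescriptions:
        raise ValueError("at least one prescription required")
    for p in prescriptions:
        if len(p.herbs) < 2:
            raise ValueError(f"prescription {p.id!r} has fewer than two herbs")
    ids = [p.id for p in prescriptions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate prescription ids")
    herbs = tuple(sorted(set().union(*(p.herbs for p in prescriptions))))
    m = np.zeros((len(herbs), len(prescriptions)), dtype=np.int8)
    index = {h: i for i, h in enumerate(herbs)}
    for j, p in enumerate(prescriptions):
        for h in p.herbs:
            m[index[h], j] = 1
    return IncidenceMatrix(herbs, tuple(ids), m)


def project_comembership(m: IncidenceMatrix) -> SimilarityMatrix:
    """Project the 2-mode matrix onto herbs: co-occurrence counts B·Bᵀ.

    Entry (h1, h2) counts prescriptions containing both herbs; the
    diagonal equals each herb's frequency.
    """
    b = m.values.astype(np.int64)
    return SimilarityMatrix(m.herbs, b @ b.T, "cooccurrence-count")


def jaccard_matrix(m: IncidenceMatrix) -> SimilarityMatrix:
    """Jaccard coefficients J = |P(h1) ∩ P(h2)| / |P(h1) ∪ P(h2)|.

    Computed over presence sets only: co-absence of two herbs contributes
    nothing, so rarely-used herbs are not rewarded for being jointly
    missing from most prescriptions.
    """
    b = m.values.astype(np.int64)
    inter = b @ b.T
    freq = m.frequencies.astype(np.int64)
    union = freq[:, None] + freq[None, :] - inter
    # rows are never all-zero, so union > 0 everywhere
    return SimilarityMatrix(m.herbs, inter / union, "jaccard")


def pearson_matrix(m: IncidenceMatrix) -> SimilarityMatrix:
    """Pairwise Pearson correlation between binary herb rows (phi).

    Herbs present in every prescription (or absent — excluded upstream)
    have zero row variance; their correlations are set to 0 by convention
    with a warning, so heatmaps never fail on ubiquitous herbs.  Requires
    at least two prescriptions.
    """
    if len(m.prescriptions) < 2:
        raise ValueError("Pearson correlation requires >= 2 prescriptions")
    v = m.values.astype(float)
    sd = v.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        names = [h for h, c in zip(m.herbs, constant) if c]
        warnings.warn(
            f"zero-variance herb row(s) {', '.join(names)}: correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(v)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(m.herbs, r, "pearson")


def order_for_heatmap(s: SimilarityMatrix) -> list[str]:
    """Leaf order from average-linkage hierarchical clustering on 1 − r.

    Accepts a pearson (or jaccard) similarity matrix and returns the label
    permutation used to display a clustered heatmap.
    """
    n = len(s.labels)
    if n <= 2:
        return list(s.labels)
    d = 1.0 - s.values
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    return [s.labels[i] for i in leaves_list(z)]


def herb_network(
    co: SimilarityMatrix, jac: SimilarityMatrix
) -> nx.Graph:
    """Build the attributed 1-mode herb network.

    Nodes carry ``frequency`` (diagonal of the co-occurrence projection)
    and ``degree``; an edge joins every herb pair co-prescribed at least
    once, weighted by its Jaccard coefficient.
    """
    if co.kind != "cooccurrence-count" or jac.kind != "jaccard":
        raise ValueError("expected (cooccurrence-count, jaccard) matrices")
    if co.labels != jac.labels:
        raise ValueError("similarity matrices have mismatched labels")
    g = nx.Graph()
    for i, h in enumerate(co.labels):
        g.add_node(h, frequency=int(co.values[i, i]))
    n = len(co.labels)
    for i in range(n):
        for j in range(i + 1, n):
            c = co.values[i, j]
            if c >= 1:
                g.add_edge(
                    co.labels[i],
                    co.labels[j],
                    cooccurrence=int(c),
                    weight=float(jac.values[i, j]),
                )
    for h in g.nodes:
        g.nodes[h]["degree"] = g.degree(h)
    return g
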