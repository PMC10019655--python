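"""Hypergeometric over-representation analysis with BH correction.

For a query gene set of size n drawn from a background universe of size
N, a term with K annotated genes and k of them in the query is scored by
the upper-tail hypergeometric probability

    p = P[X >= k],   X ~ Hypergeometric(N, K, n),

the classic over-representation test.  P-values are adjusted per
annotation category (KEGG / BP / CC / MF, mirroring per-ontology
reporting) with the Benjamini–Hochberg step-up procedure; a global
adjustment is available by flag.  Results feed bubble-chart exports
(−log10 p, gene count, gene ratio k/n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import GeneSetCollection, TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRow",
    "hypergeometric_enrich",
    "bh_adjust",
    "top_terms",
    "enrichment_frame",
]


@dataclass
class EnrichmentRow:
    """One tested annotation term (a bubble-chart datum)."""

    term_id: str
    term_name: str
    category: str
    k_overlap: int
    K_term: int
    n_query: int
    N_background: int
    p: float
    q: float
    gene_ratio: float
    genes: tuple[str, ...]


def hypergeometric_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k]."""
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (same order as input)."""
    if len(pvalues) == 0:
        return []
    if any(not (0.0 < p <= 1.0) for p in pvalues):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(list(pvalues), method="fdr_bh")
    return [float(v) for v in q]


def hypergeometric_enrich(
    query: TargetSet,
    annotations: GeneSetCollection,
    background: TargetSet | None = None,
    bh_scope: str = "per-category",
) -> list[EnrichmentRow]:
    """Test every annotation term for over-representation in the query.

    ``background`` defaults to the union of all annotation genes.  Query
    genes missing from the background are dropped with a warning (the
    DAVID-style behaviour for unmapped identifiers); each term is
    intersected with the background before testing.  Only terms with at
    least one query gene are reported.  ``bh_scope`` is ``per-category``
    (default) or ``global``.  Rows are sorted by (p, term_id).
    """
    if bh_scope not in {"per-category", "global"}:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    if len(annotations) == 0:
        raise ValueError("empty annotation collection")
    bg = set(background.genes) if background is not None else set(annotations.all_genes())
    if not bg:
        raise ValueError("empty background universe")
    q_genes = set(query.genes)
    if not q_genes:
        raise ValueError("empty query set")
    dropped = q_genes - bg
    if dropped:
        logger.warning(
            "%d query gene(s) absent from background dropped: %s",
            len(dropped), ", ".join(sorted(dropped)[:5]),
        )
        q_genes -= dropped
    if not q_genes:
        raise ValueError("no query genes left in the background universe")
    N = len(bg)
    n = len(q_genes)
    rows: list[EnrichmentRow] = []
    for gs in annotations:
        members = gs.genes & bg
        if not members:
            continue
        overlap = sorted(members & q_genes)
        k = len(overlap)
        if k < 1:
            continue
        K = len(members)
        p = hypergeometric_p(k, N, K, n)
        rows.append(
            EnrichmentRow(
                term_id=gs.term_id,
                term_name=gs.name,
                category=gs.category,
                k_overlap=k,
                K_term=K,
                n_query=n,
                N_background=N,
                p=p,
                q=p,  # filled below
                gene_ratio=k / n,
                genes=tuple(overlap),
            )
        )
    if bh_scope == "global":
        groups: dict[str, list[EnrichmentRow]] = {"all": rows}
    else:
        groups = {}
        for r in rows:
            groups.setdefault(r.category, []).append(r)
    for grp in groups.values():
        qvals = bh_adjust([r.p for r in grp])
        for r, qv in zip(grp, qvals):
            r.q = qv
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def top_terms(
    rows: Iterable[EnrichmentRow], n: int = 20, by_category: bool = True
) -> list[EnrichmentRow]:
    """The n terms with the lowest p (ties broken by term id).

    With ``by_category`` the truncation applies within each category
    separately (top-n per ontology), preserving ascending-p order.
    """
    ordered = sorted(rows, key=lambda r: (r.p, r.term_id))
    if not by_category:
        return ordered[:n]
    kept: list[EnrichmentRow] = []
    counts: dict[str, int] = {}
    for r in ordered:
        c = counts.get(r.category, 0)
        if c < n:
            kept.append(r)
            counts[r.category] = c + 1
    return kept


def enrichment_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view of enrichment rows (for TSV export / bubble charts)."""
    recs = []
    for r in rows:
        recs.append(
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "category": r.category,
                "k_overlap": r.k_overlap,
                "K_term": r.K_term,
                "n_query": r.n_query,
                "N_background": r.N_background,
                "p": r.p,
                "q": r.q,
                "gene_ratio": r.gene_ratio,
                "genes": ";".join(r.genes),
            }
        )
    return pd.DataFrame(
        recs,
        columns=[
            "term_id", "term_name", "category", "k_overlap", "K_term",
            "n_query", "N_background", "p", "q", "gene_ratio", "genes",
        ],
    )
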