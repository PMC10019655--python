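from __future__ import annotations

import pytest

from netpharm.enrich import (
    EnrichmentRow,
    bh_adjust,
    hypergeometric_enrich,
    hypergeometric_p,
    top_terms,
)
from netpharm.models import GeneSet, GeneSetCollection, TargetSet


def _collection(*sets: GeneSet) -> GeneSetCollection:
    coll = GeneSetCollection()
    for gs in sets:
        coll.add(gs)
    return coll


def _genes(n: int, prefix="G") -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


class TestHypergeometricP:
    def test_full_overlap_closed_form(self):
        # N=10, K=5, n=5, k=5 -> C(5,5)C(5,0)/C(10,5) = 1/252
        assert hypergeometric_p(5, 10, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_term_equal_to_universe_is_certain(self):
        assert hypergeometric_p(3, 20, 20, 3) == pytest.approx(1.0)

    def test_monotone_decreasing_in_overlap(self):
        ps = [hypergeometric_p(k, 50, 10, 12) for k in range(1, 11)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestEnrich:
    def test_rows_require_positive_overlap(self):
        genes = _genes(20)
        coll = _collection(
            GeneSet("HIT", "overlapping", "KEGG", frozenset(genes[:5])),
            GeneSet("MISS", "disjoint", "KEGG", frozenset(genes[10:15])),
            GeneSet("BG", "background filler", "BP", frozenset(genes)),
        )
        rows = hypergeometric_enrich(TargetSet("q", frozenset(genes[:5])), coll)
        assert {r.term_id for r in rows} == {"HIT", "BG"}

    def test_counts_and_gene_ratio(self):
        genes = _genes(10)
        coll = _collection(
            GeneSet("T", "t", "KEGG", frozenset(genes[:5])),
            GeneSet("ALL", "universe", "KEGG", frozenset(genes)),
        )
        rows = hypergeometric_enrich(TargetSet("q", frozenset(genes[:5])), coll)
        hit = next(r for r in rows if r.term_id == "T")
        assert (hit.k_overlap, hit.K_term, hit.n_query, hit.N_background) == (5, 5, 5, 10)
        assert hit.p == pytest.approx(1 / 252)
        assert hit.gene_ratio == 1.0
        full = next(r for r in rows if r.term_id == "ALL")
        assert full.p == pytest.approx(1.0)

    def test_per_category_vs_global_bh(self):
        genes = _genes(30)
        sets = [
            GeneSet(f"K{i}", "k", "KEGG", frozenset(genes[i:i + 8])) for i in range(4)
        ] + [
            GeneSet(f"B{i}", "b", "BP", frozenset(genes[i + 2:i + 10])) for i in range(4)
        ]
        query = TargetSet("q", frozenset(genes[:8]))
        per = hypergeometric_enrich(query, _collection(*sets), bh_scope="per-category")
        glob = hypergeometric_enrich(query, _collection(*sets), bh_scope="global")
        assert [r.p for r in per] == [r.p for r in glob]  # p unaffected
        assert all(r.q >= r.p for r in per + glob)

    def test_empty_query_rejected(self):
        coll = _collection(GeneSet("T", "t", "KEGG", frozenset({"A"})))
        with pytest.raises(ValueError):
            hypergeometric_enrich(TargetSet("q", frozenset()), coll)

    def test_query_genes_outside_background_dropped(self, caplog):
        coll = _collection(GeneSet("T", "t", "KEGG", frozenset({"A", "B"})))
        with caplog.at_level("WARNING"):
            rows = hypergeometric_enrich(TargetSet("q", frozenset({"A", "ZZZ"})), coll)
        assert rows[0].n_query == 1


class TestBH:
    def test_evenly_spaced_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_never_below_p_and_order_preserving(self):
        ps = [0.04, 0.001, 0.5, 0.2, 0.013]
        qs = bh_adjust(ps)
        assert all(q >= p for p, q in zip(ps, qs))
        for i in range(len(ps)):
            for j in range(len(ps)):
                if ps[i] < ps[j]:
                    assert qs[i] <= qs[j]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestTopTerms:
    @staticmethod
    def _row(tid, p, cat="KEGG"):
        return EnrichmentRow(tid, tid, cat, 1, 5, 10, 100, p, p, 0.1, ("X",))

    def test_truncates_per_category(self):
        rows = [self._row(f"K{i}", 0.01 * (i + 1)) for i in range(5)]
        rows += [self._row(f"B{i}", 0.02 * (i + 1), "BP") for i in range(5)]
        top = top_terms(rows, n=2, by_category=True)
        assert [r.term_id for r in top if r.category == "KEGG"] == ["K0", "K1"]
        assert [r.term_id for r in top if r.category == "BP"] == ["B0", "B1"]

    def test_n_larger_than_rows_returns_all(self):
        rows = [self._row("A", 0.3), self._row("B", 0.1)]
        assert len(top_terms(rows, n=10)) == 2

    def test_ties_broken_by_term_id(self):
        rows = [self._row("B", 0.05), self._row("A", 0.05)]
        assert [r.term_id for r in top_terms(rows, n=1, by_category=False)] == ["A"]
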