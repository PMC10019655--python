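from __future__ import annotations

import numpy as np
import pytest

from _oracles import brute_comembership
from netpharm import io as npio
from netpharm.copresence import (
    IncidenceMatrix,
    build_incidence,
    herb_network,
    jaccard_matrix,
    order_for_heatmap,
    pearson_matrix,
    project_comembership,
)
from netpharm.models import Prescription
from netpharm.synthetic import gen_prescriptions


def _random_incidence(rng, n_herbs=10, n_presc=6) -> IncidenceMatrix:
    while True:
        m = (rng.random((n_herbs, n_presc)) < 0.4).astype(int)
        if (m.sum(axis=1) > 0).all() and (m.sum(axis=0) >= 2).all():
            break
    herbs = tuple(f"H{i:02d}" for i in range(n_herbs))
    return IncidenceMatrix(herbs, tuple(f"P{j}" for j in range(n_presc)), m)


class TestBuildIncidence:
    def test_small_example(self, toy_prescriptions):
        inc = build_incidence(toy_prescriptions)
        assert inc.herbs == ("A", "B", "C")
        assert inc.to_frame().loc["B"].tolist() == [1, 1]

    def test_single_prescription_is_column_of_ones(self):
        inc = build_incidence([Prescription("P1", frozenset({"A", "B"}))])
        assert inc.values.shape == (2, 1)
        assert inc.values.sum() == 2

    def test_synthetic_defaults_give_17_by_9(self):
        prescriptions, truth = gen_prescriptions(seed=3)
        inc = build_incidence(prescriptions)
        assert len(inc.prescriptions) == 9
        # rows are the herbs actually used; never more than the 17 generated
        assert set(inc.herbs) <= set(truth.extra["herbs"])
        assert len(inc.herbs) <= 17

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            IncidenceMatrix(("A", "B"), ("P1",), np.array([[1], [0]]))


class TestProjection:
    def test_forced_example(self):
        inc = IncidenceMatrix(
            ("A", "B", "C"), ("P1", "P2", "P3"),
            np.array([[1, 1, 0], [0, 1, 1], [0, 0, 1]]),
        )
        co = project_comembership(inc)
        assert co.value("A", "B") == 1
        assert co.value("A", "C") == 0
        assert np.diag(co.values).tolist() == [2, 2, 1]

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            inc = _random_incidence(rng)
            co = project_comembership(inc)
            assert np.array_equal(co.values, brute_comembership(inc))

    def test_bounded_by_min_frequency(self):
        inc = _random_incidence(np.random.default_rng(8))
        co = project_comembership(inc)
        freq = inc.frequencies
        for i in range(len(inc.herbs)):
            for j in range(len(inc.herbs)):
                assert co.values[i, j] <= min(freq[i], freq[j])


class TestJaccard:
    def test_formula_example(self):
        # P(A) = {1,2}, P(B) = {2,3} -> J = 1/3
        inc = IncidenceMatrix(
            ("A", "B"), ("P1", "P2", "P3"), np.array([[1, 1, 0], [0, 1, 1]])
        )
        assert jaccard_matrix(inc).value("A", "B") == pytest.approx(1 / 3)

    def test_identical_and_disjoint_membership(self):
        inc = IncidenceMatrix(
            ("A", "B", "C"), ("P1", "P2"),
            np.array([[1, 1], [1, 1], [1, 0]]),
        )
        j = jaccard_matrix(inc)
        assert j.value("A", "B") == 1.0
        assert j.value("B", "C") == pytest.approx(0.5)

    def test_co_absence_contributes_nothing(self):
        # two rare herbs absent together from 8 of 10 prescriptions but
        # never co-present: presence-set Jaccard must be 0
        m = np.zeros((3, 10), dtype=int)
        m[0, 0] = 1
        m[1, 1] = 1
        m[2, :] = 1  # anchor herb keeps all columns non-degenerate
        inc = IncidenceMatrix(("R1", "R2", "X"), tuple(f"P{i}" for i in range(10)), m)
        assert jaccard_matrix(inc).value("R1", "R2") == 0.0

    def test_bounds_symmetry_unit_diagonal(self):
        inc = _random_incidence(np.random.default_rng(13))
        j = jaccard_matrix(inc)
        assert ((j.values >= 0) & (j.values <= 1)).all()
        assert np.allclose(j.values, j.values.T)
        assert np.allclose(np.diag(j.values), 1.0)


class TestPearson:
    def test_identical_rows_correlate_fully(self):
        inc = IncidenceMatrix(
            ("A", "B", "C"), ("P1", "P2", "P3"),
            np.array([[1, 0, 1], [1, 0, 1], [0, 1, 1]]),
        )
        assert pearson_matrix(inc).value("A", "B") == pytest.approx(1.0)

    def test_complementary_rows_anticorrelate(self):
        inc = IncidenceMatrix(
            ("A", "B"), ("P1", "P2", "P3"), np.array([[1, 0, 1], [0, 1, 0]])
        )
        assert pearson_matrix(inc).value("A", "B") == pytest.approx(-1.0)

    def test_ubiquitous_herb_gets_zero_by_convention(self):
        inc = IncidenceMatrix(
            ("A", "B"), ("P1", "P2"), np.array([[1, 1], [1, 0]])
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            p = pearson_matrix(inc)
        assert p.value("A", "B") == 0.0

    def test_single_prescription_is_an_error(self):
        inc = IncidenceMatrix(("A", "B"), ("P1",), np.array([[1], [1]]))
        with pytest.raises(ValueError):
            pearson_matrix(inc)

    def test_heatmap_order_is_a_permutation(self):
        inc = _random_incidence(np.random.default_rng(21))
        order = order_for_heatmap(pearson_matrix(inc))
        assert sorted(order) == sorted(inc.herbs)


class TestHerbNetwork:
    def test_edges_and_degrees(self):
        inc = IncidenceMatrix(
            ("A", "B", "C"), ("P1", "P2", "P3"),
            np.array([[1, 1, 0], [0, 1, 1], [0, 0, 1]]),
        )
        g = herb_network(project_comembership(inc), jaccard_matrix(inc))
        assert set(map(frozenset, g.edges)) == {frozenset("AB"), frozenset("BC")}
        assert g.nodes["B"]["degree"] == 2
        assert g.nodes["A"]["frequency"] == 2

    def test_graphml_round_trip_preserves_jaccard_weight(self, tmp_path):
        inc = _random_incidence(np.random.default_rng(2))
        g = herb_network(project_comembership(inc), jaccard_matrix(inc))
        out = tmp_path / "herb.graphml"
        npio.write_network(g, out, "graphml")
        back = npio.read_network(out)
        for a, b, d in g.edges(data=True):
            assert back.edges[a, b]["weight"] == pytest.approx(d["weight"])

    def test_label_mismatch_rejected(self):
        inc1 = _random_incidence(np.random.default_rng(1), n_herbs=4)
        inc2 = _random_incidence(np.random.default_rng(2), n_herbs=5)
        with pytest.raises(ValueError):
            herb_network(project_comembership(inc1), jaccard_matrix(inc2))
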