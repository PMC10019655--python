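from __future__ import annotations

import hashlib
from pathlib import Path

import pytest

from netpharm.adme import filter_compounds, partition_by_source
from netpharm.ppi import build_ppi_graph, remove_isolates
from netpharm.synthetic import (
    SyntheticTruth,
    gen_bundle,
    gen_compounds,
    gen_ct_edges,
    gen_ppi,
    gen_prescriptions,
)


def _dir_hashes(d: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir()) if p.is_file()
    }


class TestPrescriptions:
    def test_degenerate_probabilities_give_pure_pair(self):
        prescriptions, truth = gen_prescriptions(pair_prob=1.0, bg_prob=0.0, seed=0)
        for p in prescriptions:
            assert p.herbs == frozenset(truth.planted_pair)

    def test_same_seed_regenerates_identically(self):
        a, _ = gen_prescriptions(seed=9)
        b, _ = gen_prescriptions(seed=9)
        assert a == b

    def test_every_prescription_has_two_herbs(self):
        prescriptions, _ = gen_prescriptions(bg_prob=0.05, pair_prob=0.1, seed=1)
        assert all(len(p.herbs) >= 2 for p in prescriptions)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            gen_prescriptions(pair_prob=1.5)


class TestCompounds:
    def test_default_partition_is_study_shaped(self):
        compounds, _ = gen_compounds(seed=0)
        part = partition_by_source(filter_compounds(compounds))
        assert len(part.exclusive["EH"]) == 15
        assert len(part.exclusive["CS"]) == 7
        assert len(part.shared[("CS", "EH")]) == 2

    def test_decoys_are_exactly_what_the_filter_removes(self):
        compounds, truth = gen_compounds(fail_fraction=0.5, seed=3)
        kept = {c.pubchem_cid for c in filter_compounds(compounds)}
        assert kept == set(truth.extra["passing_cids"])
        assert kept.isdisjoint(truth.extra["decoy_cids"])
        assert len(truth.extra["decoy_cids"]) == 12  # half of 24

    def test_no_shared_compounds_empties_shared_block(self):
        compounds, _ = gen_compounds(n_shared=0, seed=0)
        part = partition_by_source(filter_compounds(compounds))
        assert part.shared == {}


class TestCTEdgesAndPPI:
    def test_non_nested_pools_overlap_partially(self):
        compounds, _ = gen_compounds(seed=1)
        _, truth = gen_ct_edges(compounds, nested_subset=False, seed=1)
        cs = set(truth.extra["cs_targets"])
        eh = set(truth.extra["eh_targets"])
        assert not cs <= eh and cs & eh

    def test_planted_isolates_are_exactly_removed(self):
        genes = [f"G{i:03d}" for i in range(80)]
        edges, truth = gen_ppi(genes, n_isolates=17, seed=5)
        g = build_ppi_graph(edges, genes, 0.4)
        _, removed = remove_isolates(g)
        assert removed == truth.planted_isolates
        assert len(removed) == 17

    def test_hub_edges_survive_thresholding(self):
        genes = [f"G{i:03d}" for i in range(50)]
        edges, truth = gen_ppi(genes, n_isolates=0, seed=2)
        for e in edges:
            if e.a in truth.planted_hubs or e.b in truth.planted_hubs:
                assert e.score >= 0.4

    def test_impossible_isolate_count_rejected(self):
        with pytest.raises(ValueError):
            gen_ppi(["A", "B", "C"], n_hubs=2, n_isolates=5, seed=0)


class TestBundle:
    def test_regeneration_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        gen_bundle(d1, seed=7)
        gen_bundle(d2, seed=7)
        assert _dir_hashes(d1) == _dir_hashes(d2)

    def test_truth_round_trips_through_json(self, tmp_path):
        paths, truth = gen_bundle(tmp_path / "x", seed=3)
        back = SyntheticTruth.read(paths["truth"])
        assert back.planted_pair == truth.planted_pair
        assert back.planted_hubs == truth.planted_hubs
        assert back.planted_isolates == truth.planted_isolates
        assert back.planted_shared_targets == truth.planted_shared_targets
        assert back.planted_enriched_term == truth.planted_enriched_term

    def test_dual_targets_are_hub_genes_inside_the_overlap(self, tmp_path):
        _, truth = gen_bundle(tmp_path / "y", seed=4)
        dual = set(truth.planted_shared_targets)
        assert dual <= set(truth.planted_hubs)
        assert dual <= set(truth.extra["overlap_genes"])
        assert len(dual) == 3
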