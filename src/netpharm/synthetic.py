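"""Seeded generators for every pipeline input, with planted ground truth.

The generators emulate the shape of a two-herb network-pharmacology
study without any database access: nine prescriptions over seventeen
herbs with one dominant co-prescribed pair; compound tables whose
ADME-passing rows split 15 / 7 / 2 between the two herbs plus decoys
straddling the OB/DL thresholds; compound-target edges with the minor
herb's targets nested inside the major herb's and three targets reachable
from both herbs; a scored PPI layer with planted hubs and seventeen
isolated proteins; disease gene lists engineered to intersect the herb
targets in a chosen number of genes; and an annotation collection with
exactly one genuinely enriched term planted inside a target cluster.

Every generator returns its data plus a truth fragment, and
:func:`gen_bundle` writes a complete input bundle together with
``truth.json`` — sufficient to score recovery of every planted feature
without re-running the generators.  A single top-level seed derives
per-generator sub-seeds by fixed offsets, so regeneration is
byte-identical and partial regeneration is stable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io as npio
from .adme import DL_MIN_DEFAULT, OB_MIN_DEFAULT, filter_compounds
from .cluster import spectral_kmeans
from .models import (
    CompoundRecord,
    CTEdge,
    GeneSet,
    GeneSetCollection,
    PPIEdge,
    Prescription,
    TargetSet,
)
from .ppi import build_ppi_graph, induced_subgraph, centrality_metrics, remove_isolates, screen_key_targets

__all__ = [
    "SyntheticTruth",
    "gen_prescriptions",
    "gen_compounds",
    "gen_ct_edges",
    "gen_disease_set",
    "gen_ppi",
    "gen_annotations",
    "gen_bundle",
]

_MODULUS = 2_147_483_629  # large prime below 2**31


def subseed(seed: int, offset: int) -> int:
    """Derive a per-generator sub-seed from the top-level seed."""
    return (int(seed) * 1_000_003 + 97 * int(offset) + 17) % _MODULUS


@dataclass
class SyntheticTruth:
    """Planted structure of a generated dataset, serialized alongside it."""

    planted_pair: tuple[str, str] | None = None
    planted_hubs: list[str] = field(default_factory=list)
    planted_isolates: list[str] = field(default_factory=list)
    planted_shared_targets: list[str] = field(default_factory=list)
    planted_enriched_term: str | None = None
    nested_subset: bool | None = None
    params: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        npio.write_report(self.to_dict(), path)

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        t = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if t.planted_pair is not None:
            t.planted_pair = tuple(t.planted_pair)
        return t


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# prescriptions
# ---------------------------------------------------------------------------

def gen_prescriptions(
    n_presc: int = 9,
    n_herbs: int = 17,
    pair_prob: float = 0.8,
    bg_prob: float = 0.25,
    seed: int = 0,
    pair: tuple[str, str] = ("EH", "CS"),
) -> tuple[list[Prescription], SyntheticTruth]:
    """Prescriptions with one dominant planted herb pair.

    With probability ``pair_prob`` both planted herbs enter a
    prescription together; otherwise each enters independently at
    ``bg_prob``, like every background herb.  Draws with fewer than two
    herbs are redrawn.
    """
    _check_prob(pair_prob, "pair_prob")
    _check_prob(bg_prob, "bg_prob")
    if n_herbs < 4:
        raise ValueError("n_herbs must be at least 4")
    if n_presc < 1:
        raise ValueError("n_presc must be positive")
    rng = np.random.default_rng(seed)
    herbs = [pair[0], pair[1]] + [f"H{i:02d}" for i in range(3, n_herbs + 1)]
    prescriptions: list[Prescription] = []
    for j in range(1, n_presc + 1):
        while True:
            chosen: set[str] = set()
            if rng.random() < pair_prob:
                chosen.update(pair)
            else:
                for h in pair:
                    if rng.random() < bg_prob:
                        chosen.add(h)
            for h in herbs[2:]:
                if rng.random() < bg_prob:
                    chosen.add(h)
            if len(chosen) >= 2:
                break
        prescriptions.append(Prescription(f"P{j}", frozenset(chosen)))
    truth = SyntheticTruth(
        planted_pair=pair,
        params={
            "n_presc": n_presc, "n_herbs": n_herbs,
            "pair_prob": pair_prob, "bg_prob": bg_prob, "seed": int(seed),
        },
        extra={"herbs": herbs},
    )
    return prescriptions, truth


# ---------------------------------------------------------------------------
# compounds
# ---------------------------------------------------------------------------

def gen_compounds(
    n_eh: int = 15,
    n_cs: int = 7,
    n_shared: int = 2,
    ob_range: tuple[float, float] = (30.0, 80.0),
    dl_range: tuple[float, float] = (0.18, 0.8),
    fail_fraction: float = 0.0,
    seed: int = 0,
    herbs: tuple[str, str] = ("EH", "CS"),
) -> tuple[list[CompoundRecord], SyntheticTruth]:
    """Compound table with planted ADME-passing rows and decoys.

    Passing compounds draw OB ~ U(ob_range) and DL ~ U(dl_range), both
    ranges above the screening thresholds; ``fail_fraction`` of additional
    decoys fall below at least one threshold and must be rejected by the
    filter.  PubChem CIDs are synthetic and unique.
    """
    for n, name in ((n_eh, "n_eh"), (n_cs, "n_cs"), (n_shared, "n_shared")):
        if n < 0:
            raise ValueError(f"{name} must be non-negative")
    _check_prob(fail_fraction, "fail_fraction")
    rng = np.random.default_rng(seed)
    records: list[CompoundRecord] = []
    cid = 1_000_000

    def draw(tag: str, source: frozenset[str], passing: bool) -> CompoundRecord:
        nonlocal cid
        cid += 1
        mw = float(np.round(rng.uniform(150, 600), 2))
        if passing:
            ob = float(np.round(rng.uniform(*ob_range), 2))
            dl = float(np.round(rng.uniform(*dl_range), 3))
        else:
            mode = rng.integers(3)  # fail ob, dl, or both
            ob = float(np.round(rng.uniform(1.0, OB_MIN_DEFAULT - 0.1), 2)) \
                if mode in (0, 2) else float(np.round(rng.uniform(*ob_range), 2))
            dl = float(np.round(rng.uniform(0.01, DL_MIN_DEFAULT - 0.01), 3)) \
                if mode in (1, 2) else float(np.round(rng.uniform(*dl_range), 3))
        return CompoundRecord(f"{tag}{cid - 1_000_000:03d}", cid, mw, ob, dl, source)

    eh, cs = herbs
    for _ in range(n_shared):
        records.append(draw("SHARED", frozenset(herbs), True))
    for _ in range(n_eh):
        records.append(draw(f"{eh}C", frozenset({eh}), True))
    for _ in range(n_cs):
        records.append(draw(f"{cs}C", frozenset({cs}), True))
    n_pass = len(records)
    n_decoys = int(round(fail_fraction * n_pass))
    decoy_cids: list[int] = []
    for _ in range(n_decoys):
        source = frozenset({eh if rng.random() < 0.5 else cs})
        rec = draw("DECOY", source, False)
        decoy_cids.append(rec.pubchem_cid)
        records.append(rec)
    truth = SyntheticTruth(
        params={
            "n_eh": n_eh, "n_cs": n_cs, "n_shared": n_shared,
            "fail_fraction": fail_fraction, "seed": int(seed),
        },
        extra={
            "passing_cids": [r.pubchem_cid for r in records[:n_pass]],
            "decoy_cids": decoy_cids,
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# compound -> target edges
# ---------------------------------------------------------------------------

def gen_ct_edges(
    compounds: Sequence[CompoundRecord],
    n_targets: int = 223,
    n_cs_targets: int = 31,
    targets_per_compound: tuple[int, int] = (4, 14),
    n_dual_herb_targets: int = 3,
    nested_subset: bool = True,
    seed: int = 0,
    herbs: tuple[str, str] = ("EH", "CS"),
) -> tuple[list[CTEdge], SyntheticTruth]:
    """Compound-target edges with a nested minor-herb target pool.

    The major herb's passing compounds cover a pool of ``n_targets``
    genes; the minor herb's pool has ``n_cs_targets`` genes and, with
    ``nested_subset``, is a strict subset of the major pool.
    ``n_dual_herb_targets`` genes of the minor pool are guaranteed to be
    reachable from compounds of both herbs.  Decoy compounds (failing the
    ADME filter) also receive edges so that filtering is exercised.
    """
    if n_cs_targets > n_targets:
        raise ValueError("n_cs_targets cannot exceed n_targets")
    if n_dual_herb_targets > n_cs_targets:
        raise ValueError("n_dual_herb_targets cannot exceed n_cs_targets")
    lo, hi = targets_per_compound
    if lo < 1 or hi < lo:
        raise ValueError("targets_per_compound must be a (lo, hi) with 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    eh, cs = herbs
    eh_pool = [f"G{i:04d}" for i in range(1, n_targets + 1)]
    if nested_subset:
        cs_pool = sorted(str(t) for t in rng.choice(eh_pool, size=n_cs_targets, replace=False))
    else:
        n_inside = n_cs_targets // 2
        inside = sorted(str(t) for t in rng.choice(eh_pool, size=n_inside, replace=False))
        outside = [f"C{i:04d}" for i in range(1, n_cs_targets - n_inside + 1)]
        cs_pool = inside + outside
    dual = sorted(str(t) for t in rng.choice(cs_pool, size=n_dual_herb_targets, replace=False))

    passing = filter_compounds(list(compounds))
    eh_only = [c for c in passing if c.herbs == frozenset({eh})]
    cs_only = [c for c in passing if c.herbs == frozenset({cs})]
    shared = [c for c in passing if c.herbs == frozenset({eh, cs})]
    decoys = [c for c in compounds if c not in passing]

    pairs: set[tuple[int, str]] = set()

    def add_draws(comp: CompoundRecord, pool: Sequence[str]) -> None:
        size = min(int(rng.integers(lo, hi + 1)), len(pool))
        for t in rng.choice(pool, size=size, replace=False):
            pairs.add((comp.pubchem_cid, str(t)))

    for c in eh_only:
        add_draws(c, eh_pool)
    for c in cs_only + shared:
        add_draws(c, cs_pool)
    for c in decoys:
        add_draws(c, eh_pool)

    # guarantee pool coverage so the herb target unions equal the pools;
    # genes outside the minor pool are assigned to single-herb compounds
    # only, so shared compounds never leak major-pool genes into the minor
    # herb's union
    def cover(pool: Sequence[str], owners: Sequence[CompoundRecord]) -> None:
        owner_cids = {o.pubchem_cid for o in owners}
        covered = {t for cid, t in pairs if cid in owner_cids}
        for t in pool:
            if t not in covered:
                owner = owners[int(rng.integers(len(owners)))]
                pairs.add((owner.pubchem_cid, t))

    if eh_only:
        cover(eh_pool, eh_only)
    elif shared:
        cover(cs_pool, shared)
    if cs_only or shared:
        cover(cs_pool, cs_only + shared)

    # guarantee the dual-herb targets are reachable from both herbs
    for t in dual:
        if eh_only:
            pairs.add((eh_only[int(rng.integers(len(eh_only)))].pubchem_cid, t))
        if cs_only:
            pairs.add((cs_only[int(rng.integers(len(cs_only)))].pubchem_cid, t))

    edges = [CTEdge(cid, t) for cid, t in sorted(pairs)]
    truth = SyntheticTruth(
        planted_shared_targets=dual,
        nested_subset=nested_subset,
        params={
            "n_targets": n_targets, "n_cs_targets": n_cs_targets,
            "targets_per_compound": list(targets_per_compound),
            "n_dual_herb_targets": n_dual_herb_targets, "seed": int(seed),
        },
        extra={"eh_targets": sorted(eh_pool), "cs_targets": sorted(cs_pool)},
    )
    return edges, truth


# ---------------------------------------------------------------------------
# disease gene set
# ---------------------------------------------------------------------------

def gen_disease_set(
    target_universe: Sequence[str],
    overlap_k: int = 152,
    n_extra: int = 2047,
    seed: int = 0,
    must_include: Sequence[str] = (),
    label: str = "disease",
) -> tuple[TargetSet, SyntheticTruth]:
    """A disease gene set overlapping the target universe in exactly k genes.

    ``must_include`` pins chosen universe genes (e.g. planted key targets)
    inside the overlap; ``n_extra`` disease-only genes are added on top.
    """
    universe = sorted(set(target_universe))
    if overlap_k > len(universe):
        raise ValueError("overlap_k cannot exceed the universe size")
    must = sorted(set(must_include))
    if not set(must) <= set(universe):
        raise ValueError("must_include genes must belong to the universe")
    if len(must) > overlap_k:
        raise ValueError("must_include larger than overlap_k")
    rng = np.random.default_rng(seed)
    remaining = [g for g in universe if g not in set(must)]
    extra_in = sorted(rng.choice(remaining, size=overlap_k - len(must), replace=False))
    overlap = sorted(must + [str(g) for g in extra_in])
    disease_only = [f"D{i:05d}" for i in range(1, n_extra + 1)]
    ts = TargetSet(label, frozenset(overlap + disease_only))
    truth = SyntheticTruth(
        params={"overlap_k": overlap_k, "n_extra": n_extra, "seed": int(seed)},
        extra={"overlap_genes": overlap},
    )
    return ts, truth


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------

def gen_ppi(
    genes: Sequence[str],
    n_hubs: int = 10,
    hub_attach: float = 0.6,
    bg_density: float = 0.05,
    n_isolates: int = 17,
    score_range: tuple[float, float] = (0.15, 0.99),
    seed: int = 0,
    hubs: Sequence[str] | None = None,
    min_score: float = 0.4,
) -> tuple[list[PPIEdge], SyntheticTruth]:
    """Scored PPI edges with planted hubs and planted isolates.

    Hubs attach to a random ``hub_attach`` fraction of non-isolate nodes
    with scores at or above ``min_score`` (so hub edges survive
    thresholding); background pairs appear at ``bg_density`` with scores
    uniform over ``score_range``, a controlled fraction of which falls
    below the threshold to exercise filtering.  Planted isolates receive
    no edges at all.  Every non-isolate node is guaranteed at least one
    surviving edge, so isolate removal finds exactly ``n_isolates``.
    """
    _check_prob(hub_attach, "hub_attach")
    _check_prob(bg_density, "bg_density")
    genes = sorted(set(genes))
    if hubs is not None and not set(hubs) <= set(genes):
        raise ValueError("explicit hubs must belong to the gene universe")
    if n_isolates + (len(hubs) if hubs is not None else n_hubs) > len(genes):
        raise ValueError("not enough genes for the requested hubs and isolates")
    rng = np.random.default_rng(seed)
    if hubs is None:
        hubs = sorted(str(h) for h in rng.choice(genes, size=n_hubs, replace=False))
    else:
        hubs = sorted(hubs)
    non_hub = [g for g in genes if g not in set(hubs)]
    isolates = sorted(str(g) for g in rng.choice(non_hub, size=n_isolates, replace=False))
    iso = set(isolates)
    connected = [g for g in genes if g not in iso]
    hub_set = set(hubs)
    lo, hi = score_range
    hub_lo = max(min_score, lo)

    edges: dict[tuple[str, str], float] = {}
    for i, u in enumerate(connected):
        for v in connected[i + 1:]:
            if u in hub_set or v in hub_set:
                if rng.random() < hub_attach:
                    edges[(u, v)] = float(np.round(rng.uniform(hub_lo, hi), 3))
            elif rng.random() < bg_density:
                edges[(u, v)] = float(np.round(rng.uniform(lo, hi), 3))

    # keep "exactly n_isolates removed" exact: re-wire any node whose every
    # edge fell below the threshold
    surviving_deg: dict[str, int] = {g: 0 for g in connected}
    for (u, v), s in edges.items():
        if s >= min_score:
            surviving_deg[u] += 1
            surviving_deg[v] += 1
    anchors = hubs if hubs else connected
    for g in connected:
        if surviving_deg[g] == 0:
            other = anchors[int(rng.integers(len(anchors)))]
            if other == g:
                other = next(x for x in connected if x != g)
            key = (g, other) if g < other else (other, g)
            edges[key] = float(np.round(rng.uniform(hub_lo, hi), 3))

    edge_list = [PPIEdge(a, b, s) for (a, b), s in sorted(edges.items())]
    truth = SyntheticTruth(
        planted_hubs=list(hubs),
        planted_isolates=isolates,
        params={
            "n_hubs": len(hubs), "hub_attach": hub_attach,
            "bg_density": bg_density, "n_isolates": n_isolates,
            "score_range": list(score_range), "min_score": min_score,
            "seed": int(seed),
        },
    )
    return edge_list, truth


# ---------------------------------------------------------------------------
# annotation gene sets
# ---------------------------------------------------------------------------

def gen_annotations(
    clusters: Mapping[str, int],
    term_size: int = 8,
    n_noise_terms: int = 30,
    seed: int = 0,
    planted_cluster: int | None = None,
    gene_pool: Sequence[str] | None = None,
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Annotation collection with one planted enriched term.

    The planted term is a strict subset of the designated cluster's genes
    (category KEGG); by default the largest cluster is designated, so the
    planted term is as large as the clustering allows.  Noise terms of
    the same size are uniform draws from the gene pool (default: all
    clustered genes) spread across the KEGG / BP / CC / MF categories.
    """
    if planted_cluster is None:
        sizes: dict[int, int] = {}
        for cid in clusters.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        planted_cluster = max(sorted(sizes), key=lambda cid: sizes[cid])
    members = sorted(g for g, cid in clusters.items() if cid == planted_cluster)
    if len(members) < 2:
        raise ValueError(f"cluster {planted_cluster} too small to plant a term in")
    rng = np.random.default_rng(seed)
    planted_size = min(term_size, len(members) - 1)
    planted = sorted(str(g) for g in rng.choice(members, size=planted_size, replace=False))
    pool = sorted(set(gene_pool)) if gene_pool is not None else sorted(clusters)
    if len(pool) < 2:
        raise ValueError("gene pool too small")
    coll = GeneSetCollection()
    coll.add(GeneSet("PLANTED", "planted synthetic term", "KEGG", frozenset(planted)))
    cats = ["KEGG", "BP", "CC", "MF"]
    # noise terms match the planted term's size: with equal K, the fully
    # query-contained planted term attains the minimal possible p
    noise_size = min(planted_size, len(pool))
    for i in range(n_noise_terms):
        genes = rng.choice(pool, size=noise_size, replace=False)
        coll.add(
            GeneSet(
                f"NOISE{i:03d}",
                f"synthetic noise term {i}",
                cats[i % len(cats)],
                frozenset(str(g) for g in genes),
            )
        )
    truth = SyntheticTruth(
        planted_enriched_term="PLANTED",
        params={
            "term_size": term_size, "n_noise_terms": n_noise_terms,
            "planted_cluster": planted_cluster, "seed": int(seed),
        },
        extra={"planted_genes": planted},
    )
    return coll, truth


# ---------------------------------------------------------------------------
# full input bundle
# ---------------------------------------------------------------------------

def gen_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_presc: int = 9,
    n_herbs: int = 17,
    pair_prob: float = 0.8,
    bg_prob: float = 0.25,
    n_eh: int = 15,
    n_cs: int = 7,
    n_shared: int = 2,
    fail_fraction: float = 0.5,
    n_targets: int = 223,
    n_cs_targets: int = 31,
    n_dual_herb_targets: int = 3,
    nested_subset: bool = True,
    overlap_k: int = 152,
    n_disease_extra: int = 2047,
    n_hubs: int = 10,
    hub_attach: float = 0.6,
    bg_density: float = 0.05,
    n_isolates: int = 17,
    k_clusters: int = 3,
    term_size: int = 8,
    n_noise_terms: int = 30,
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write a complete, internally consistent input bundle plus truth.json.

    The defaults mirror the observed magnitudes of the emulated study
    (9 prescriptions over 17 herbs, 15/7/2 passing compounds, a 152-gene
    herb-disease overlap, 17 PPI isolates, 3 dual-herb key targets, 3
    clusters) so that fixture outputs are study-shaped.  Planted hubs are
    chosen inside the disease overlap and include the dual-herb targets,
    making every downstream recovery claim scorable from truth.json.
    Also writes a ready-to-run ``config.yaml`` for the pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    prescriptions, t_presc = gen_prescriptions(
        n_presc, n_herbs, pair_prob, bg_prob, seed=subseed(seed, 0)
    )
    compounds, t_comp = gen_compounds(
        n_eh, n_cs, n_shared, fail_fraction=fail_fraction, seed=subseed(seed, 1)
    )
    ct_edges, t_ct = gen_ct_edges(
        compounds,
        n_targets=n_targets,
        n_cs_targets=n_cs_targets,
        n_dual_herb_targets=n_dual_herb_targets,
        nested_subset=nested_subset,
        seed=subseed(seed, 2),
    )
    universe = sorted(set(t_ct.extra["eh_targets"]) | set(t_ct.extra["cs_targets"]))
    disease_core, t_dis = gen_disease_set(
        universe,
        overlap_k=overlap_k,
        n_extra=n_disease_extra,
        seed=subseed(seed, 3),
        must_include=t_ct.planted_shared_targets,
    )
    overlap = t_dis.extra["overlap_genes"]

    rng = np.random.default_rng(subseed(seed, 4))
    non_dual = [g for g in overlap if g not in set(t_ct.planted_shared_targets)]
    hubs = sorted(
        set(t_ct.planted_shared_targets)
        | {str(g) for g in rng.choice(non_dual, size=n_hubs - n_dual_herb_targets, replace=False)}
    )
    ppi_edges, t_ppi = gen_ppi(
        overlap,
        hub_attach=hub_attach,
        bg_density=bg_density,
        n_isolates=n_isolates,
        seed=subseed(seed, 5),
        hubs=hubs,
    )

    # two disease lists whose intersection is exactly the core disease set
    rng2 = np.random.default_rng(subseed(seed, 6))
    n_private = 200
    list_a = sorted(disease_core.genes) + [f"DA{i:04d}" for i in range(1, n_private + 1)]
    list_b = sorted(disease_core.genes) + [f"DB{i:04d}" for i in range(1, n_private + 1)]
    rng2.shuffle(list_a)
    rng2.shuffle(list_b)

    # derive the key-target clustering the pipeline will see, then plant
    # the enriched annotation term inside one of its clusters
    g = build_ppi_graph(ppi_edges, overlap, min_score=0.4)
    g, _removed = remove_isolates(g)
    key = screen_key_targets(centrality_metrics(g))
    sub = induced_subgraph(g, key)
    clusters = spectral_kmeans(sub, k=k_clusters, seed=subseed(seed, 7))
    annotations, t_ann = gen_annotations(
        clusters,
        term_size=term_size,
        n_noise_terms=n_noise_terms,
        seed=subseed(seed, 8),
        gene_pool=overlap,
    )

    paths = {
        "prescriptions": outdir / "prescriptions.tsv",
        "compounds": outdir / "compounds.tsv",
        "ct_edges": outdir / "ct_edges.tsv",
        "disease_a": outdir / "disease_a.txt",
        "disease_b": outdir / "disease_b.txt",
        "ppi_edges": outdir / "ppi_edges.tsv",
        "annotations": outdir / "annotations.gmt",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    npio.write_prescriptions(prescriptions, paths["prescriptions"])
    npio.write_compound_table(compounds, paths["compounds"])
    npio.write_ct_edges(ct_edges, paths["ct_edges"])
    npio.write_gene_list(list_a, paths["disease_a"])
    npio.write_gene_list(list_b, paths["disease_b"])
    npio.write_ppi_edges(ppi_edges, paths["ppi_edges"])
    npio.write_gene_sets(annotations, paths["annotations"])

    truth = SyntheticTruth(
        planted_pair=t_presc.planted_pair,
        planted_hubs=t_ppi.planted_hubs,
        planted_isolates=t_ppi.planted_isolates,
        planted_shared_targets=t_ct.planted_shared_targets,
        planted_enriched_term=t_ann.planted_enriched_term,
        nested_subset=nested_subset,
        params={
            "seed": int(seed),
            "prescriptions": t_presc.params,
            "compounds": t_comp.params,
            "ct_edges": t_ct.params,
            "disease": t_dis.params,
            "ppi": t_ppi.params,
            "annotations": t_ann.params,
            "k_clusters": k_clusters,
        },
        extra={
            "passing_cids": t_comp.extra["passing_cids"],
            "decoy_cids": t_comp.extra["decoy_cids"],
            "eh_targets": t_ct.extra["eh_targets"],
            "cs_targets": t_ct.extra["cs_targets"],
            "overlap_genes": overlap,
            "expected_key_targets": key,
            "planted_term_genes": t_ann.extra["planted_genes"],
        },
    )
    truth.write(paths["truth"])

    # paths are written relative to the bundle directory, so a bundle is
    # relocatable and regeneration is byte-identical across directories
    config = {
        "prescriptions": paths["prescriptions"].name,
        "compounds": paths["compounds"].name,
        "ct_edges": paths["ct_edges"].name,
        "disease": [paths["disease_a"].name, paths["disease_b"].name],
        "ppi_edges": paths["ppi_edges"].name,
        "annotations": paths["annotations"].name,
        "ob_min": OB_MIN_DEFAULT,
        "dl_min": DL_MIN_DEFAULT,
        "ppi_min_score": 0.4,
        "disease_combine_mode": "intersection",
        "k_clusters": k_clusters,
        "top_n_terms": 20,
        "bh_scope": "per-category",
        "seed": int(seed),
        "outdir": "results",
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths, truth
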