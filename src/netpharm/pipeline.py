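"""End-to-end pipeline orchestration from a single configuration.

Stages run in fixed order — herb co-prescription network, ADME screen,
target-set algebra, PPI key-target screening, subnetwork clustering,
enrichment, compound-target network — each writing its artifacts under
the output directory, and the run closes with a ``report.json`` carrying
every count a reader needs to audit the run.  All randomness flows from
the single config seed; two runs with the same config produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as npio
from .adme import DL_MIN_DEFAULT, OB_MIN_DEFAULT, filter_compounds, partition_by_source
from .cluster import cluster_sizes, spectral_kmeans
from .copresence import (
    build_incidence,
    herb_network,
    jaccard_matrix,
    order_for_heatmap,
    pearson_matrix,
    project_comembership,
)
from .ctnet import assemble_ct_network, shared_key_targets
from .enrich import enrichment_frame, hypergeometric_enrich, top_terms
from .models import TargetSet
from .ppi import (
    MIN_SCORE_DEFAULT,
    build_ppi_graph,
    centrality_metrics,
    edge_count_from_degrees,
    induced_subgraph,
    remove_isolates,
    screen_key_targets,
    subnetwork_metrics,
)
from .targets import combine_disease_sets, herb_target_union, overlap_with_disease

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths and every tunable threshold of the pipeline."""

    prescriptions: str
    compounds: str
    ct_edges: str
    disease: list[str]
    ppi_edges: str
    annotations: str
    synonyms: str | None = None
    ob_min: float = OB_MIN_DEFAULT
    dl_min: float = DL_MIN_DEFAULT
    ppi_min_score: float = MIN_SCORE_DEFAULT
    disease_combine_mode: str = "intersection"
    k_clusters: int = 3
    top_n_terms: int = 20
    bh_scope: str = "per-category"
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.disease, str):
            self.disease = [self.disease]
        if not 1 <= len(self.disease) <= 2:
            raise ValueError("one or two disease gene lists are required")
        if not 0.0 <= self.ppi_min_score <= 1.0:
            raise ValueError("ppi_min_score must lie in [0, 1]")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be at least 2")
        if self.top_n_terms < 1:
            raise ValueError("top_n_terms must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config; relative paths are resolved against the file's dir."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")

        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else path.parent / q)

        for key in ("prescriptions", "compounds", "ct_edges", "ppi_edges",
                    "annotations", "synonyms", "outdir"):
            if raw.get(key) is not None:
                raw[key] = resolve(raw[key])
        if "disease" in raw:
            d = raw["disease"]
            raw["disease"] = [resolve(p) for p in (d if isinstance(d, list) else [d])]
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", stage, dt)
                return False
            logger.error("stage %s: failed after %.2fs (%s)", stage, dt, exc)
            raise PipelineError(stage, exc) from exc

    return _Timer()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the JSON-ready run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}

    with _timed("herb-network"):
        prescriptions = npio.read_prescriptions(config.prescriptions)
        inc = build_incidence(prescriptions)
        co = project_comembership(inc)
        jac = jaccard_matrix(inc)
        pear = pearson_matrix(inc)
        order = order_for_heatmap(pear)
        net = herb_network(co, jac)
        inc.to_frame().to_csv(out / "incidence.tsv", sep="\t")
        co.to_frame().to_csv(out / "cooccurrence.tsv", sep="\t")
        jac.to_frame().to_csv(out / "jaccard.tsv", sep="\t")
        pear.to_frame().loc[order, order].to_csv(out / "pearson_clustered.tsv", sep="\t")
        npio.write_network(net, out / "herb_network.graphml", "graphml")
        # top co-prescribed pair: maximum off-diagonal count, lexicographic ties
        best, best_c = None, -1
        for i in range(len(co.labels)):
            for j in range(i + 1, len(co.labels)):
                c = int(co.values[i, j])
                if c > best_c:
                    best, best_c = (co.labels[i], co.labels[j]), c
        report["herb_network"] = {
            "n_herbs": len(inc.herbs),
            "n_prescriptions": len(inc.prescriptions),
            "top_pair": sorted(best) if best else None,
            "top_pair_cooccurrence": best_c,
            "n_edges": net.number_of_edges(),
        }

    with _timed("adme"):
        records = npio.read_compound_table(config.compounds)
        passing = filter_compounds(records, config.ob_min, config.dl_min)
        part = partition_by_source(passing)
        npio.write_compound_table(passing, out / "compounds_pass.tsv")
        report["adme"] = {
            "n_input": len(records),
            "n_retained": len(passing),
            "venn": part.block_sizes(),
        }

    with _timed("targets"):
        ct_edges = npio.read_ct_edges(config.ct_edges)
        # edges of ADME-rejected compounds are dropped by design, silently
        passing_cids = {c.pubchem_cid for c in passing}
        ct_edges = [e for e in ct_edges if e.compound in passing_cids]
        herb_codes = sorted({h for c in passing for h in c.herbs})
        herb_sets = {h: herb_target_union(h, passing, ct_edges) for h in herb_codes}
        disease_lists = [
            TargetSet(f"disease{i+1}", frozenset(npio.read_gene_list(p)))
            for i, p in enumerate(config.disease)
        ]
        if len(disease_lists) == 2:
            disease = combine_disease_sets(
                disease_lists[0], disease_lists[1], config.disease_combine_mode
            )
        else:
            disease = disease_lists[0]
        all_herb = TargetSet("herb_union", frozenset().union(*(s.genes for s in herb_sets.values())))
        overlap = overlap_with_disease(all_herb, disease)
        for h, s in herb_sets.items():
            npio.write_gene_list(sorted(s.genes), out / f"targets_{h}.txt")
        npio.write_gene_list(sorted(overlap.genes), out / "targets_overlap.txt")
        subset_flags = {}
        for h1 in herb_codes:
            for h2 in herb_codes:
                if h1 != h2:
                    subset_flags[f"{h1}_subset_of_{h2}"] = bool(
                        herb_sets[h1].genes <= herb_sets[h2].genes
                    )
        report["targets"] = {
            "per_herb": {h: len(s) for h, s in herb_sets.items()},
            "herb_union": len(all_herb),
            "disease": len(disease),
            "overlap": len(overlap),
            "subset_flags": subset_flags,
        }

    with _timed("ppi"):
        ppi_edges = npio.read_ppi_edges(config.ppi_edges)
        g_full = build_ppi_graph(ppi_edges, overlap, config.ppi_min_score)
        g, removed = remove_isolates(g_full)
        metrics = centrality_metrics(g)
        metrics.to_csv(out / "centrality.tsv", sep="\t", index=False)
        key = screen_key_targets(metrics)
        npio.write_gene_list(key, out / "key_targets.txt")
        sub = induced_subgraph(g, key)
        sub_metrics = subnetwork_metrics(sub)
        sub_metrics.to_csv(out / "subnetwork_metrics.tsv", sep="\t", index=False)
        npio.write_network(sub, out / "subnetwork.graphml", "graphml")
        npio.write_network(sub, out / "subnetwork.sif", "sif", interaction="pp")
        report["ppi"] = {
            "n_nodes": g_full.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "isolates_removed": len(removed),
            "isolates": removed,
            "n_key_targets": len(key),
            "key_targets": key,
            "subnetwork_edges": edge_count_from_degrees(sub_metrics["degree"]),
        }

    with _timed("cluster"):
        clusters = spectral_kmeans(sub, config.k_clusters, config.seed)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("gene\tcluster\n")
            for gsym in sorted(clusters):
                fh.write(f"{gsym}\t{clusters[gsym]}\n")
        report["cluster"] = {
            "k": config.k_clusters,
            "sizes": {str(k): v for k, v in cluster_sizes(clusters).items()},
        }

    with _timed("enrich"):
        annotations = npio.read_gene_sets(config.annotations)
        query = TargetSet("key_targets", frozenset(key))
        rows = hypergeometric_enrich(query, annotations, bh_scope=config.bh_scope)
        top = top_terms(rows, config.top_n_terms, by_category=True)
        enrichment_frame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        bubble = enrichment_frame(top)
        bubble["neg_log10_p"] = [-math.log10(p) if p > 0 else math.inf for p in bubble["p"]]
        bubble[["term_id", "term_name", "category", "neg_log10_p", "k_overlap", "gene_ratio"]].to_csv(
            out / "bubble_chart.tsv", sep="\t", index=False
        )
        by_cat: dict[str, list[str]] = {}
        for r in top:
            by_cat.setdefault(r.category, []).append(r.term_id)
        report["enrich"] = {
            "n_terms_tested": len(rows),
            "min_p_term": rows[0].term_id if rows else None,
            "min_p": rows[0].p if rows else None,
            "top_terms": by_cat,
        }

    with _timed("ct-network"):
        net = assemble_ct_network(passing, ct_edges, key, clusters)
        if net.graph.number_of_nodes() > 0:
            npio.write_network(net.graph, out / "ct_network.graphml", "graphml")
            npio.write_network(net.graph, out / "ct_network.sif", "sif", interaction="ct")
        shared = shared_key_targets(net)
        report["ct_network"] = {**net.summary(), "shared_key_targets": shared}

    npio.write_report(report, out / "report.json")
    return report
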