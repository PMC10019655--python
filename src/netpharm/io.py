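"""Readers and writers for every external format the pipeline touches.

Tabular inputs (compound tables, compound-target edges, PPI edge lists,
prescription membership) are TSV/CSV with a header row; gene sets use the
GMT convention; networks are exported as SIF, GraphML or a plain edge TSV
for downstream visualisation (e.g. Cytoscape).  All gene symbols are
uppercased on ingest.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .models import (
    CompoundRecord,
    CTEdge,
    GeneSet,
    GeneSetCollection,
    PPIEdge,
    Prescription,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_compound_table",
    "write_compound_table",
    "read_ct_edges",
    "write_ct_edges",
    "read_ppi_edges",
    "write_ppi_edges",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_list",
    "write_gene_list",
    "read_prescriptions",
    "write_prescriptions",
    "read_synonym_map",
    "write_network",
    "read_network",
    "write_report",
]


class FormatError(ValueError):
    """An input file does not conform to its expected layout."""


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# compound tables (TCMSP-style layout: name / pubchem_cid / mw / ob / dl / herbs)
# ---------------------------------------------------------------------------

def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table with OB/DL descriptors.

    Expected header columns: ``name, pubchem_cid, mw, ob, dl, herbs`` where
    ``herbs`` is a semicolon-joined list of source herb codes.  Rows with
    non-numeric OB/DL raise a row-level :class:`FormatError` carrying the
    line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    _require_columns(df, ["name", "pubchem_cid", "mw", "ob", "dl", "herbs"], path)
    records: list[CompoundRecord] = []
    seen_cids: set[int] = set()
    for i, row in df.iterrows():
        line_no = int(i) + 2  # header is line 1
        try:
            cid = int(str(row["pubchem_cid"]).strip())
            mw = float(row["mw"])
            ob = float(row["ob"])
            dl = float(row["dl"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {line_no}: non-numeric field ({exc})")
        herbs = frozenset(
            h.strip().upper() for h in str(row["herbs"]).split(";") if h.strip()
        )
        if not herbs:
            raise FormatError(f"{path}: line {line_no}: empty herbs field")
        if cid in seen_cids:
            raise FormatError(f"{path}: line {line_no}: duplicate pubchem_cid {cid}")
        seen_cids.add(cid)
        records.append(
            CompoundRecord(str(row["name"]).strip(), cid, mw, ob, dl, herbs)
        )
    return records


def write_compound_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["name", "pubchem_cid", "mw", "ob", "dl", "herbs"])
        for r in records:
            w.writerow(
                [r.name, r.pubchem_cid, r.mw, r.ob, r.dl, ";".join(sorted(r.herbs))]
            )


# ---------------------------------------------------------------------------
# compound -> target edges
# ---------------------------------------------------------------------------

def read_ct_edges(path: str | Path) -> list[CTEdge]:
    """Read compound-target edges (columns ``pubchem_cid, target``).

    Duplicate (compound, target) pairs are collapsed; order of first
    appearance is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    _require_columns(df, ["pubchem_cid", "target"], path)
    edges: list[CTEdge] = []
    seen: set[tuple[int, str]] = set()
    for _, row in df.iterrows():
        e = CTEdge(int(str(row["pubchem_cid"]).strip()), str(row["target"]))
        if (e.compound, e.target) not in seen:
            seen.add((e.compound, e.target))
            edges.append(e)
    return edges


def write_ct_edges(edges: Iterable[CTEdge], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=_sep_for(path))
        w.writerow(["pubchem_cid", "target"])
        for e in edges:
            w.writerow([e.compound, e.target])


# ---------------------------------------------------------------------------
# scored PPI edge lists (STRING-export style)
# ---------------------------------------------------------------------------

_PPI_COLSETS = [
    ("protein1", "protein2", "combined_score"),
    ("a", "b", "score"),
]


def read_ppi_edges(path: str | Path, score_scale: str = "auto") -> list[PPIEdge]:
    """Read a scored PPI edge list and normalize scores to [0, 1].

    ``score_scale``:

    * ``auto`` — if any score exceeds 1 the file is taken to use STRING's
      0-1000 integer convention and scores are divided by 1000;
    * ``unit`` — scores are already in [0, 1];
    * ``thousand`` — always divide by 1000.

    Self-loops are dropped (logged); duplicate unordered pairs are collapsed
    keeping the maximum score.  Idempotent on already-clean input.
    """
    if score_scale not in {"auto", "unit", "thousand"}:
        raise ValueError(f"unknown score_scale {score_scale!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for cols in _PPI_COLSETS:
        if all(c in df.columns for c in cols):
            ca, cb, cs = cols
            break
    else:
        if df.shape[1] == 3:
            ca, cb, cs = df.columns
        else:
            raise FormatError(
                f"{path}: cannot identify gene/score columns "
                f"(have {list(df.columns)})"
            )
    scores = pd.to_numeric(df[cs], errors="coerce")
    if scores.isna().any():
        raise FormatError(f"{path}: non-numeric score values")
    if score_scale == "thousand" or (score_scale == "auto" and (scores > 1).any()):
        scores = scores / 1000.0
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for a, b, s in zip(df[ca], df[cb], scores):
        a = normalize_symbol(a)
        b = normalize_symbol(b)
        if a == b:
            n_self += 1
            continue
        if not 0.0 <= s <= 1.0:
            raise FormatError(f"{path}: score {s} outside [0, 1] after scaling")
        key = (a, b) if a < b else (b, a)
        if s > best.get(key, -1.0):
            best[key] = float(s)
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    return [PPIEdge(a, b, s) for (a, b), s in best.items()]


def write_ppi_edges(edges: Iterable[PPIEdge], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=_sep_for(path))
        w.writerow(["protein1", "protein2", "combined_score"])
        for e in edges:
            w.writerow([e.a, e.b, e.score])


# ---------------------------------------------------------------------------
# gene sets (GMT) and plain gene lists
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term-id TAB description TAB member genes...).

    The description field may carry a category prefix ``KEGG|``, ``BP|``,
    ``CC|`` or ``MF|``; unprefixed terms fall into category ``other``.
    Terms with no members are skipped with a warning.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("%s: skipping memberless term %r", path, parts[0])
                continue
            term_id, desc = parts[0], parts[1]
            members = [g for g in parts[2:] if g.strip()]
            if not members:
                logger.warning("%s: skipping memberless term %r", path, term_id)
                continue
            if "|" in desc:
                cat, name = desc.split("|", 1)
            else:
                cat, name = "other", desc
            coll.add(GeneSet(term_id, name, cat, frozenset(members)))
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            desc = f"{gs.category}|{gs.name}"
            fh.write("\t".join([gs.term_id, desc, *sorted(gs.genes)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list (deduplicated, order kept)."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            sym = normalize_symbol(token)
            if sym not in seen:
                seen.add(sym)
                out.append(sym)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Read a two-column alias -> official-symbol map (TSV, header row)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: synonym map needs two columns")
    alias_col, sym_col = df.columns[:2]
    return {
        normalize_symbol(a): normalize_symbol(s)
        for a, s in zip(df[alias_col], df[sym_col])
    }


# ---------------------------------------------------------------------------
# prescriptions (long TSV or binary incidence CSV)
# ---------------------------------------------------------------------------

def read_prescriptions(path: str | Path) -> list[Prescription]:
    """Read prescriptions from a long-format table.

    Columns ``prescription_id, herb``; one row per (prescription, herb)
    membership.  Prescription order follows first appearance.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    _require_columns(df, ["prescription_id", "herb"], path)
    groups: dict[str, set[str]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        pid = str(row["prescription_id"]).strip()
        herb = str(row["herb"]).strip().upper()
        if pid not in groups:
            groups[pid] = set()
            order.append(pid)
        groups[pid].add(herb)
    return [Prescription(pid, frozenset(groups[pid])) for pid in order]


def write_prescriptions(prescriptions: Iterable[Prescription], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=_sep_for(path))
        w.writerow(["prescription_id", "herb"])
        for p in prescriptions:
            for h in sorted(p.herbs):
                w.writerow([p.id, h])


# ---------------------------------------------------------------------------
# network export/import
# ---------------------------------------------------------------------------

def write_network(
    graph: nx.Graph, path: str | Path, fmt: str = "graphml", interaction: str = "pp"
) -> None:
    """Write a graph as SIF, GraphML or a plain edge TSV.

    SIF lines use the given interaction label (``pp`` for protein-protein,
    ``ct`` for compound-target); an edge-level ``interaction`` attribute
    overrides it.  Node/edge order is sorted so output is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("refusing to write an empty graph")
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            written: set[str] = set()
            for a, b, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
                label = data.get("interaction", interaction)
                fh.write(f"{a}\t{label}\t{b}\n")
                written.add(str(a))
                written.add(str(b))
            for n in sorted(graph.nodes, key=str):
                if str(n) not in written:
                    fh.write(f"{n}\n")
    elif fmt == "graphml":
        # stable ordering for byte-identical re-runs
        g2 = nx.Graph()
        g2.graph.update(graph.graph)
        for n in sorted(graph.nodes, key=str):
            g2.add_node(n, **graph.nodes[n])
        for a, b in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
            g2.add_edge(a, b, **graph.edges[a, b])
        nx.write_graphml(g2, path)
    elif fmt == "edge-tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            attrs = sorted({k for _, _, d in graph.edges(data=True) for k in d})
            w.writerow(["source", "target", *attrs])
            for a, b, d in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
                w.writerow([a, b, *[d.get(k, "") for k in attrs]])
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path) -> nx.Graph:
    """Read a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(path)


def write_report(results: dict, path: str | Path) -> None:
    """Write a JSON report with stable key ordering (deterministic bytes)."""
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
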