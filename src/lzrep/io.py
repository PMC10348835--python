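"""Repertoire readers and graph serialisation.

Repertoires arrive as AIRR Rearrangement TSV (columns ``junction`` /
``junction_aa`` / ``v_call`` / ``j_call`` / ``duplicate_count``) or generic
CSV with a caller-supplied column mapping.  Graphs are persisted as
schema-versioned canonical JSON (sorted keys, byte-stable for equal graphs)
with an optional GraphML export for visualisation tools.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import RepertoireIOError, SerializationError
from .graph import LZGraph, parse_node_key
from .repertoire import (
    AMINO_ACID,
    NUCLEOTIDE,
    Repertoire,
    SequenceRecord,
    validate_sequence,
)
from .errors import AlphabetError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

AIRR_TSV = "airr_tsv"
CSV = "csv"

_GENE_SEP = "||"


def read_repertoire(
    path: str | Path,
    format: str = AIRR_TSV,
    column_map: Mapping[str, str] | None = None,
    scope: str = AMINO_ACID,
    *,
    strict: bool = True,
) -> Repertoire:
    """Read a repertoire table.

    ``column_map`` maps source column names to the canonical AIRR names
    (``junction``, ``junction_aa``, ``v_call``, ``j_call``,
    ``duplicate_count``).  Rows with empty junctions are always dropped;
    rows failing alphabet validation are fatal in strict mode and
    dropped-with-warning otherwise.  ``duplicate_count`` defaults to 1 when
    the column is absent.
    """
    path = Path(path)
    if format not in (AIRR_TSV, CSV):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == AIRR_TSV else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    seq_col = "junction" if scope == NUCLEOTIDE else "junction_aa"
    if seq_col not in df.columns:
        raise RepertoireIOError(
            f"{path}: required column {seq_col!r} is missing "
            f"(columns present: {list(df.columns)})"
        )
    has_genes = "v_call" in df.columns and "j_call" in df.columns
    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        raw = getattr(row, seq_col)
        if not isinstance(raw, str) or not raw.strip():
            continue  # empty junctions always dropped
        try:
            seq = validate_sequence(raw.strip(), scope)
        except AlphabetError as exc:
            if strict:
                raise RepertoireIOError(f"{path}, line {row_number}: {exc}") from exc
            logger.warning("%s, line %d: dropped — %s", path, row_number, exc)
            continue
        v = getattr(row, "v_call", None) if has_genes else None
        j = getattr(row, "j_call", None) if has_genes else None
        v = v if isinstance(v, str) and v else None
        j = j if isinstance(j, str) and j else None
        if (v is None) != (j is None):
            v = j = None
        dup = getattr(row, "duplicate_count", None)
        try:
            dup = int(dup) if dup is not None and str(dup).strip() else 1
        except (TypeError, ValueError):
            dup = 1
        records.append(
            SequenceRecord(seq, v_call=v, j_call=j, duplicate_count=max(dup, 1))
        )
    if not records:
        raise RepertoireIOError(f"{path}: no valid rows survived reading")
    return Repertoire(
        records=records,
        scope=scope,
        metadata={"source": str(path), "format": format},
    )


# ---------------------------------------------------------------------------
# graph JSON document
# ---------------------------------------------------------------------------


def _graph_document(graph: LZGraph) -> dict:
    edges = []
    for u, v in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
        entry: dict = {
            "source": str(u),
            "target": str(v),
            "count": graph.edge_count(u, v),
        }
        if graph.with_genes:
            entry["gene_usage"] = {
                f"{p[0]}{_GENE_SEP}{p[1]}": c
                for p, c in sorted(graph.gene_usage(u, v).items())
            }
        edges.append(entry)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "scheme": graph.scheme,
        "with_genes": graph.with_genes,
        "n_sequences": graph.n_sequences,
        "nodes": sorted(str(n) for n in graph.nodes),
        "edges": edges,
        "init_counts": {str(k): v for k, v in sorted(graph.init_counts.items(), key=lambda kv: str(kv[0]))},
        "term_counts": {str(k): v for k, v in sorted(graph.term_counts.items(), key=lambda kv: str(kv[0]))},
        "v_frequencies": dict(sorted(graph.v_frequencies.items())),
        "j_frequencies": dict(sorted(graph.j_frequencies.items())),
    }
    return doc


def write_graph(graph: LZGraph, path: str | Path) -> None:
    """Serialise a graph to canonical JSON (sorted keys, byte-stable)."""
    doc = _graph_document(graph)
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def read_graph(path: str | Path) -> LZGraph:
    """Load a graph document; round trips :func:`write_graph` exactly."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise SerializationError(f"cannot read graph document {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SerializationError(
            f"{path}: schema_version {version!r} is not supported "
            f"(expected {SCHEMA_VERSION}); migrate the document first"
        )
    scheme = doc["scheme"]
    graph = LZGraph(scheme, with_genes=doc["with_genes"])
    key = lambda s: parse_node_key(s, scheme)  # noqa: E731
    for rendered in doc["nodes"]:
        graph._g.add_node(key(rendered))
    for entry in doc["edges"]:
        attrs: dict = {"count": entry["count"]}
        if graph.with_genes:
            usage = Counter()
            for joint, c in entry["gene_usage"].items():
                v, _, j = joint.partition(_GENE_SEP)
                usage[(v, j)] = c
            attrs["gene_usage"] = usage
        graph._g.add_edge(key(entry["source"]), key(entry["target"]), **attrs)
    graph.init_counts = Counter({key(k): v for k, v in doc["init_counts"].items()})
    graph.term_counts = Counter({key(k): v for k, v in doc["term_counts"].items()})
    graph.n_sequences = doc["n_sequences"]
    graph.v_frequencies = Counter(doc["v_frequencies"])
    graph.j_frequencies = Counter(doc["j_frequencies"])
    graph._finalise()
    return graph


def write_graphml(graph: LZGraph, path: str | Path) -> None:
    """GraphML export (for Cytoscape/Gephi); attributes are stringified."""
    import networkx as nx

    g = nx.DiGraph()
    for node in graph.nodes:
        g.add_node(
            str(node),
            init_count=graph.init_counts.get(node, 0),
            term_count=graph.term_counts.get(node, 0),
        )
    for u, v in graph.edges:
        attrs = {
            "count": graph.edge_count(u, v),
            "weight": graph.weight(u, v),
        }
        if graph.with_genes:
            attrs["gene_usage"] = json.dumps(
                {f"{p[0]}{_GENE_SEP}{p[1]}": c for p, c in sorted(graph.gene_usage(u, v).items())}
            )
        g.add_edge(str(u), str(v), **attrs)
    nx.write_graphml(g, str(path))
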