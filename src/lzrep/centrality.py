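"""Graph-level feature vectors and per-sequence diagnostics.

* Eigenvector centrality of the naive LZGraph as a repertoire feature
  vector: solve A x = λ x for the dominant eigenpair of the weighted
  directed adjacency A, so a node scores highly when it is adjacent to
  other high-scoring nodes.
* The sequence variation curve C = {δ+(s_i)}: the number of immediate
  alternatives (distinct-successor out-degree) at each subpattern of a
  sequence's path through a reference graph, with 0 for absent nodes.
* LZ-Centrality: the mean of C — a constant-query-time proxy for how
  central a sequence is within a repertoire (empirically anti-correlated
  with its mean pairwise Levenshtein distance to the repertoire).
* Gene variation matrices: per path edge, the probability of each V (or J)
  allele given the edge's joint gene-usage counts, with a distinguished
  never-observed marker (NaN) and an α filter dropping alleles absent from
  more than α percent of the path's edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bow import BowDictionary
from .decomposition import lz76_decompose
from .errors import ConvergenceError, SchemeError
from .graph import NAIVE, LZGraph, NodeKey, encode_path

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# eigencentrality
# ---------------------------------------------------------------------------


@dataclass
class CentralityVector:
    """Dominant eigenpair of a graph's weighted adjacency.

    ``values`` is L2-normalised and nonnegatively oriented when computed on
    the graph's own nodes; re-indexing onto an external vocabulary inserts
    zeros for absent nodes (so cross-repertoire vectors share a basis) and
    does not re-normalise.
    """

    node_order: list[str]
    values: np.ndarray
    eigenvalue: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.node_order)


def eigencentrality_features(
    graph: LZGraph,
    vocabulary: "BowDictionary | list[str] | None" = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> CentralityVector:
    """Dominant-eigenpair centrality of a naive LZGraph by power iteration.

    Positional (ndp/aap) graphs are DAGs, hence nilpotent adjacency with
    spectral radius 0 — eigencentrality is meaningless there and refused.

    The iteration uses the shift x ← (A + I) x, which leaves eigenvectors
    unchanged while making the dominant eigenvalue strictly largest in
    magnitude even when A has a periodic component (e.g. 2-cycles whose
    spectrum is ±w).  λ is recovered from the Rayleigh quotient;
    convergence is declared on the eigenpair residual ‖Ax − λx‖ ≤ ``tol``,
    checked periodically.  Each step is one sparse matrix-vector product,
    so even the generous default iteration budget stays cheap; graphs with
    a narrow spectral gap simply take more steps.
    """
    if graph.scheme != NAIVE:
        raise SchemeError(
            "eigencentrality is defined on the naive graph; positional "
            f"({graph.scheme}) graphs are acyclic, so their adjacency is "
            "nilpotent and the dominant eigenvalue is 0"
        )
    if graph.check_dag()[0]:
        # a cycle-free naive graph (possible for very small repertoires) is
        # nilpotent too: the dominant eigenvalue is 0 and the centrality
        # vector is not defined
        raise SchemeError(
            "this naive graph contains no cycles, so its adjacency is "
            "nilpotent and eigenvector centrality is undefined; use a "
            "deeper repertoire or BOW features instead"
        )
    from scipy import sparse

    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise ValueError("graph has no nodes")
    index = {node: i for i, node in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v in graph.edges:
        rows.append(index[u])
        cols.append(index[v])
        vals.append(graph.weight(u, v))
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    x = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    residual = np.inf
    for it in range(1, max_iter + 1):
        y = x + A @ x
        y_norm = np.linalg.norm(y)
        if y_norm == 0:
            raise ConvergenceError("power iteration collapsed to zero")
        x = y / y_norm
        if it % 10 == 0 or it == max_iter:
            Ax = A @ x
            lam = float(x @ Ax)
            residual = float(np.linalg.norm(Ax - lam * x))
            if residual <= tol:
                break
    if residual > 1e-8:
        raise ConvergenceError(
            f"power iteration residual {residual:.3e} above 1e-8 after "
            f"{max_iter} iterations"
        )
    if x.sum() < 0:
        x = -x
    x = np.where(np.abs(x) < 1e-15, 0.0, x)

    if vocabulary is None:
        return CentralityVector([str(nd) for nd in nodes], x, lam)

    tokens = list(vocabulary.tokens) if isinstance(vocabulary, BowDictionary) else [
        str(t) for t in vocabulary
    ]
    rendered = {str(nd): i for nd, i in index.items()}
    aligned = np.zeros(len(tokens))
    hits = 0
    for k, tok in enumerate(tokens):
        i = rendered.get(tok)
        if i is not None:
            aligned[k] = x[i]
            hits += 1
    if hits == 0:
        logger.warning(
            "vocabulary shares no nodes with the graph; returning zeros"
        )
        warnings.warn(
            "vocabulary shares no nodes with the graph; centrality vector "
            "is all zeros",
            stacklevel=2,
        )
    return CentralityVector(tokens, aligned, lam)


# ---------------------------------------------------------------------------
# variation curve / LZ-Centrality
# ---------------------------------------------------------------------------


@dataclass
class VariationCurve:
    """Out-degree profile of one sequence's path through a reference graph."""

    sequence: str
    subpatterns: list[str]
    out_degrees: list[int]

    @property
    def lz_centrality(self) -> float:
        return float(np.mean(self.out_degrees))


def variation_curve(graph: LZGraph, sequence: str) -> VariationCurve:
    """δ+ (distinct successors) at each subpattern node; 0 for absent nodes."""
    path = encode_path(lz76_decompose(sequence), graph.scheme)
    degrees = [graph.out_degree(n) if n in graph.nodes else 0 for n in path]
    return VariationCurve(
        sequence=sequence,
        subpatterns=[n.subpattern for n in path],
        out_degrees=degrees,
    )


def lz_centrality(graph: LZGraph, sequence: str) -> float:
    """Mean out-degree along the sequence's path (higher = more central)."""
    return variation_curve(graph, sequence).lz_centrality


# ---------------------------------------------------------------------------
# gene variation
# ---------------------------------------------------------------------------


@dataclass
class GeneUsageMatrix:
    """Allele-by-edge selection probabilities along one sequence path.

    ``probabilities`` has one row per retained allele and one column per
    path edge; NaN marks "never observed" (the black cells of a usage heat
    map).  ``full_path_alleles`` were observed on every edge.  Retained
    alleles are absent from at most ``alpha`` percent of the path's edges.
    """

    gene: str  # "V" or "J"
    alleles: list[str]
    edges: list[str]
    probabilities: pd.DataFrame
    full_path_alleles: list[str]
    alpha: float
    unique_allele_counts: list[int]  # distinct alleles observed at each edge


def _marginal_edge_shares(graph: LZGraph, u: NodeKey, v: NodeKey, which: int):
    usage = graph.gene_usage(u, v)
    total = sum(usage.values())
    shares: dict[str, float] = {}
    for pair, count in usage.items():
        shares[pair[which]] = shares.get(pair[which], 0.0) + count / total
    return shares


def gene_variation(
    graph: LZGraph, sequence: str, alpha: float = 50.0
) -> tuple[GeneUsageMatrix, GeneUsageMatrix]:
    """V and J allele usage along a sequence's path edges.

    For each pair of sequential subpatterns the joint (V, J) counts stored
    on that edge are marginalised to the requested gene; each allele's entry
    is its share of the edge's transitions.  Alleles absent from more than
    ``alpha`` percent of the path's edges are omitted (``alpha=0`` keeps
    only full-path alleles; ``alpha=100`` keeps everything).
    """
    if not graph.with_genes:
        raise SchemeError("gene_variation requires a gene-layer graph")
    path = encode_path(lz76_decompose(sequence), graph.scheme)
    pairs = [
        (u, v) for u, v in zip(path, path[1:]) if graph.has_edge(u, v)
    ]
    if not pairs:
        raise ValueError(
            f"no edge of the path of {sequence!r} exists in the graph"
        )
    edge_labels = [f"{u}->{v}" for u, v in pairs]
    out = []
    for which, gene in ((0, "V"), (1, "J")):
        per_edge = [_marginal_edge_shares(graph, u, v, which) for u, v in pairs]
        alleles = sorted({a for shares in per_edge for a in shares})
        mat = pd.DataFrame(np.nan, index=alleles, columns=edge_labels)
        for label, shares in zip(edge_labels, per_edge):
            for a, p in shares.items():
                mat.loc[a, label] = p
        absent_frac = mat.isna().mean(axis=1)
        keep = [a for a in alleles if absent_frac[a] * 100.0 <= alpha]
        full = [a for a in alleles if absent_frac[a] == 0.0]
        out.append(
            GeneUsageMatrix(
                gene=gene,
                alleles=keep,
                edges=edge_labels,
                probabilities=mat.loc[keep],
                full_path_alleles=full,
                alpha=alpha,
                unique_allele_counts=[len(s) for s in per_edge],
            )
        )
    return out[0], out[1]
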