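"""Generation probability of a sequence under a positional LZGraph (LZPgen).

LZPgen of a sequence s with decomposition path X = (x1 … xn) is

    Pgen(s) = P(X0) · Π_i w(x_{i-1}, x_i)

i.e. the marginal probability of the path's first node among observed
initial states, times the product of transition weights along the path.
Unlike mechanistic recombination models this requires no gene annotation:
only the structural statistics of the source repertoire enter.

When a query path uses transitions never observed while building the graph,
each missing factor is imputed with the geometric mean of the *present* edge
weights of that same path: graph weights are log-linear in nature, and the
geometric mean preserves the multiplicative (log-additive) structure.  A
missing initial state is treated the same way as a missing edge and enters
the same imputation.  If no edge of the path is present at all, the
geometric mean is undefined and the probability is reported as 0 with
``degenerate=True`` instead of raising, so batch workflows never abort.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .decomposition import lz76_decompose
from .errors import SchemeError
from .graph import NAIVE, LZGraph, NodeKey, encode_path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PgenResult:
    """LZPgen of one sequence.

    ``n_edges`` counts the factors of the probability product (the
    initial-state marginal plus one factor per transition, i.e. the path
    length); ``n_imputed`` of them were filled with ``imputed_value``, the
    geometric mean of the present edge weights.
    """

    sequence: str
    probability: float
    log10_probability: float
    n_edges: int
    n_imputed: int
    imputed_value: float | None = None
    degenerate: bool = False


def _geometric_mean(values: Sequence[float]) -> float:
    return math.exp(sum(math.log(v) for v in values) / len(values))


def lzpgen(
    graph: LZGraph,
    sequence: str,
    *,
    allow_naive: bool = False,
    _path: "Sequence[NodeKey] | None" = None,
) -> PgenResult:
    """LZPgen of ``sequence`` under ``graph`` (ndp for nucleotides, aap for
    amino acids).

    The naive graph contains cycles, which makes its LZPgen hard to
    interpret; it is refused unless ``allow_naive=True``.
    """
    if graph.scheme == NAIVE and not allow_naive:
        raise SchemeError(
            "the naive graph contains cycles, which makes the interpretation "
            "of its LZPgen less meaningful; build an ndp (nucleotide) or aap "
            "(amino acid) graph, or pass allow_naive=True"
        )
    path = (
        list(_path)
        if _path is not None
        else encode_path(lz76_decompose(sequence), graph.scheme)
    )
    n_factors = len(path)

    # factor list: None marks a missing (to-impute) factor
    factors: list[float | None] = []
    first = path[0]
    p0 = graph.initial_probability(first)
    factors.append(p0 if p0 > 0 else None)
    present_edges: list[float] = []
    for u, v in zip(path, path[1:]):
        if graph.has_edge(u, v):
            w = graph.weight(u, v)
            factors.append(w)
            present_edges.append(w)
        else:
            factors.append(None)

    n_imputed = sum(1 for f in factors if f is None)
    if n_imputed == 0:
        prob = math.prod(factors)  # type: ignore[arg-type]
        return PgenResult(sequence, prob, math.log10(prob), n_factors, 0)
    if not present_edges:
        # nothing to take a geometric mean of: declared degenerate
        return PgenResult(
            sequence, 0.0, -math.inf, n_factors, n_imputed, None, degenerate=True
        )
    gm = _geometric_mean(present_edges)
    prob = math.prod(gm if f is None else f for f in factors)
    return PgenResult(sequence, prob, math.log10(prob), n_factors, n_imputed, gm)


def lzpgen_batch(
    graph: LZGraph,
    sequences: Iterable[str],
    *,
    allow_naive: bool = False,
) -> list[PgenResult | None]:
    """Elementwise :func:`lzpgen` with a shared path-encoding cache.

    Per-sequence failures (e.g. alphabet errors) are collected, not fatal:
    the corresponding entry is ``None`` and a warning is emitted.  Order is
    preserved.
    """
    cache: dict[str, list[NodeKey]] = {}
    out: list[PgenResult | None] = []
    for i, seq in enumerate(sequences):
        try:
            path = cache.get(seq)
            if path is None:
                path = encode_path(lz76_decompose(seq), graph.scheme)
                cache[seq] = path
            out.append(lzpgen(graph, seq, allow_naive=allow_naive, _path=path))
        except SchemeError:
            raise  # a wrong scheme is a caller error, not a data error
        except Exception as exc:  # noqa: BLE001 - collected by contract
            warnings.warn(f"sequence {i} ({seq!r}): {exc}", stacklevel=2)
            logger.warning("lzpgen_batch: sequence %d failed: %s", i, exc)
            out.append(None)
    return out
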