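"""Stochastic sequence generation from a fitted LZGraph.

Two simulation modes reproduce the statistical properties of the source
repertoire:

* **Unconstrained** — start at an initial state drawn from the empirical
  P(X0); repeatedly draw the next node from the out-edge weight
  distribution.  On entering a terminal node T the walk stops with
  certainty if no other terminal node is reachable from T, and otherwise
  stops with the conditional probability PT(T) = Ψ(T)/(Ψ(T)+Σ_{x∈U}Ψ(x));
  a declined stop resumes sampling from the full out-edge distribution.
* **Genomically constrained** — additionally draws a V and a J allele from
  their marginal source-repertoire frequencies and restricts every step to
  edges with nonzero joint (V, J) support, renormalising weights over the
  admissible out-edges.  Stopping uses the unrestricted Ψ.  A dead end (no
  admissible out-edge at a non-terminal node) triggers a full restart with
  the same (V, J) draw, bounded by ``max_restarts``.

Successor draws use inverse-CDF sampling over successors ordered
lexicographically by rendered node key, so a fixed seed reproduces outputs
byte-for-byte across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GenerationError, SchemeError
from .graph import LZGraph, NodeKey

UNCONSTRAINED = "unconstrained"
CONSTRAINED = "constrained"


@dataclass(frozen=True)
class GenerationConfig:
    mode: str = UNCONSTRAINED
    seed: int = 0
    max_steps: int | None = None  # default: 10 x longest source path
    max_restarts: int = 100

    def __post_init__(self) -> None:
        if self.mode not in (UNCONSTRAINED, CONSTRAINED):
            raise ValueError(f"unknown generation mode {self.mode!r}")
        if self.max_steps is not None and self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if self.max_restarts <= 0:
            raise ValueError("max_restarts must be positive")


@dataclass(frozen=True)
class GeneratedSequence:
    """One simulated sequence and the graph path that emitted it."""

    sequence: str
    path: tuple[NodeKey, ...]
    v_call: str | None = None
    j_call: str | None = None
    n_restarts: int = 0


def _default_max_steps(graph: LZGraph) -> int:
    # generous cap that only cyclic (naive) graphs can realistically hit
    if graph.scheme == "naive":
        return 10 * max(graph.node_and_edge_counts()[0], 1)
    return 10 * max(_longest_path_len(graph), 1)


def _longest_path_len(graph: LZGraph) -> int:
    # positional graphs: max number of subpatterns along any source path,
    # bounded by the max terminal position
    best = 1
    for t in graph.term_counts:
        if t.position is not None:
            best = max(best, t.position + len(t.subpattern) - 1)
    return best


def _sorted_with_probs(items: Sequence, probs: Sequence[float]):
    order = np.argsort([str(i) for i in items], kind="stable")
    items = [items[i] for i in order]
    p = np.asarray([probs[i] for i in order], dtype=float)
    return items, p / p.sum()


def _draw(rng: np.random.Generator, items: Sequence, probs: Sequence[float]):
    """Inverse-CDF draw over items sorted by rendered key (seed-stable)."""
    items, p = _sorted_with_probs(items, probs)
    u = rng.random()
    idx = int(np.searchsorted(np.cumsum(p), u, side="right"))
    return items[min(idx, len(items) - 1)]


def _draw_initial(graph: LZGraph, rng: np.random.Generator) -> NodeKey:
    nodes = list(graph.init_counts)
    return _draw(rng, nodes, [graph.init_counts[n] for n in nodes])


def _admissible(graph: LZGraph, node: NodeKey, pair) -> list[NodeKey]:
    return [
        s for s in graph.successors(node) if graph.gene_usage(node, s).get(pair, 0) > 0
    ]


def _walk(
    graph: LZGraph,
    rng: np.random.Generator,
    max_steps: int,
    pair=None,
) -> "tuple[NodeKey, ...] | None":
    """One random walk; returns the path, or None on a constrained dead end."""
    node = _draw_initial(graph, rng)
    path = [node]
    while True:
        if node in graph.term_counts:
            if not graph.reachable_terminals(node):
                break  # unconditional stop
            if rng.random() < graph.terminal_stop_probability(node):
                break
        succs = (
            graph.successors(node) if pair is None else _admissible(graph, node, pair)
        )
        if not succs:
            if node in graph.term_counts:
                break  # nowhere admissible to go, but stopping here is legal
            return None  # constrained dead end
        node = _draw(rng, succs, [graph.weight(path[-1], s) for s in succs])
        path.append(node)
        if len(path) > max_steps:
            raise GenerationError(
                f"walk exceeded max_steps={max_steps}; the {graph.scheme!r} "
                "graph likely contains a cycle"
            )
    return tuple(path)


def generate_unconstrained(
    graph: LZGraph,
    config: GenerationConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> GeneratedSequence:
    """Simulate one sequence from initial/transition/termination statistics."""
    config = config or GenerationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    max_steps = config.max_steps or _default_max_steps(graph)
    path = _walk(graph, rng, max_steps)
    assert path is not None  # unconstrained walks cannot dead-end
    return GeneratedSequence(
        sequence="".join(n.subpattern for n in path), path=path
    )


def generate_constrained(
    graph: LZGraph,
    config: GenerationConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> GeneratedSequence:
    """Simulate one sequence restricted to edges supporting a drawn (V, J)."""
    if not graph.with_genes:
        raise SchemeError("constrained generation requires a gene-layer graph")
    config = config or GenerationConfig(mode=CONSTRAINED)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    max_steps = config.max_steps or _default_max_steps(graph)
    v_names = list(graph.v_frequencies)
    v = _draw(rng, v_names, [graph.v_frequencies[x] for x in v_names])
    j_names = list(graph.j_frequencies)
    j = _draw(rng, j_names, [graph.j_frequencies[x] for x in j_names])
    pair = (v, j)
    restarts = 0
    while True:
        path = _walk(graph, rng, max_steps, pair=pair)
        if path is not None:
            return GeneratedSequence(
                sequence="".join(n.subpattern for n in path),
                path=path,
                v_call=v,
                j_call=j,
                n_restarts=restarts,
            )
        restarts += 1
        if restarts > config.max_restarts:
            raise GenerationError(
                f"exceeded max_restarts={config.max_restarts} dead-end "
                f"restarts for gene pair (v_call={v!r}, j_call={j!r})"
            )


def generate_batch(
    graph: LZGraph, n: int, config: GenerationConfig | None = None
) -> list[GeneratedSequence]:
    """n independent draws from one seeded stream; reproducible given
    (seed, n).  Per-draw errors are re-raised annotated with the draw index.
    """
    config = config or GenerationConfig()
    rng = np.random.default_rng(config.seed)
    fn = generate_constrained if config.mode == CONSTRAINED else generate_unconstrained
    out = []
    for i in range(n):
        try:
            out.append(fn(graph, config, rng=rng))
        except GenerationError as exc:
            raise GenerationError(f"draw {i}: {exc}") from exc
    return out
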