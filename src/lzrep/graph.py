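"""LZGraph construction: directed weighted graphs over LZ-76 subpatterns.

An LZGraph of a repertoire is the triplet (V, E, W): nodes are (optionally
position-annotated) LZ-76 subpatterns, edges connect consecutive subpatterns
along each sequence's decomposition path, and the weight of edge (i, j) is
the number of observed i→j transitions divided by the total number of
transition events leaving i — so the out-edge weights of every non-sink node
form a probability distribution.

Three node-encoding schemes are supported:

``naive``
    Bare subpatterns.  Cycles occur naturally (the same subpattern can recur
    at different positions), so this variant is suited to whole-repertoire
    feature extraction (eigencentrality), not probabilistic inference.
``ndp`` (nucleotide double positional)
    Subpattern + reading frame + absolute 1-based start position, rendered
    ``{subpattern}{frame}_{position}`` with frame = (position − 1) mod 3.
    Nucleotide scope only.
``aap`` (amino-acid positional)
    Subpattern + absolute 1-based start position, rendered
    ``{subpattern}_{position}`` (e.g. ``LF_7``: "LF" starting at position 7).

Positional annotation makes start positions strictly increase along every
path, so ndp/aap graphs are DAGs by construction.

Beyond (V, E, W) the graph records, per sequence path, the first node
(``init_counts`` — normalising gives the initial-state distribution P(X0))
and the last node (``term_counts`` — normalising gives the termination mass
Ψ used by the conditional stopping rule), and optionally a gene layer: per
edge, joint (v_call, j_call) usage counts of the sequences that contributed
the transition, plus marginal V/J frequencies for constrained generation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .decomposition import Decomposition, lz76_decompose
from .errors import SchemeError
from .repertoire import NT_ALPHABET, NUCLEOTIDE, Repertoire, as_repertoire

NAIVE = "naive"
NDP = "ndp"
AAP = "aap"
SCHEMES = (NAIVE, NDP, AAP)

POSITIONAL_SCHEMES = (NDP, AAP)


@dataclass(frozen=True)
class NodeKey:
    """A graph node: a subpattern plus scheme-dependent positional fields."""

    subpattern: str
    scheme: str
    reading_frame: int | None = None  # ndp only, in {0, 1, 2}
    position: int | None = None  # ndp and aap, 1-based start index

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise SchemeError(f"unknown scheme {self.scheme!r}")
        if self.scheme == NAIVE and (
            self.reading_frame is not None or self.position is not None
        ):
            raise ValueError("naive keys carry no positional fields")
        if self.scheme == NDP and (self.reading_frame is None or self.position is None):
            raise ValueError("ndp keys need reading_frame and position")
        if self.scheme == AAP and (
            self.position is None or self.reading_frame is not None
        ):
            raise ValueError("aap keys need position only")

    def render(self) -> str:
        if self.scheme == NAIVE:
            return self.subpattern
        if self.scheme == NDP:
            return f"{self.subpattern}{self.reading_frame}_{self.position}"
        return f"{self.subpattern}_{self.position}"

    def __str__(self) -> str:
        return self.render()


def parse_node_key(rendered: str, scheme: str) -> NodeKey:
    """Invert :meth:`NodeKey.render` for a given scheme."""
    if scheme == NAIVE:
        return NodeKey(rendered, NAIVE)
    head, _, pos = rendered.rpartition("_")
    if not head or not pos:
        raise ValueError(f"cannot parse node key {rendered!r} as {scheme}")
    if scheme == NDP:
        return NodeKey(head[:-1], NDP, reading_frame=int(head[-1]), position=int(pos))
    return NodeKey(head, AAP, position=int(pos))


def encode_path(decomposition: Decomposition, scheme: str) -> list[NodeKey]:
    """Map an ordered decomposition to its node path under a scheme.

    Each subpattern's position is the 1-based index of its first character
    in the source sequence; for ndp the reading frame is (position − 1) mod 3.
    """
    if scheme not in SCHEMES:
        raise SchemeError(f"unknown scheme {scheme!r}")
    if scheme == NDP and (set(decomposition.source) - NT_ALPHABET):
        raise SchemeError(
            "the ndp scheme requires nucleotide sequences; got characters "
            f"outside {{A,C,G,T}} in {decomposition.source!r}"
        )
    path = []
    for sub, pos in zip(decomposition.subpatterns, decomposition.start_positions):
        if scheme == NAIVE:
            path.append(NodeKey(sub, NAIVE))
        elif scheme == NDP:
            path.append(NodeKey(sub, NDP, reading_frame=(pos - 1) % 3, position=pos))
        else:
            path.append(NodeKey(sub, AAP, position=pos))
    return path


class LZGraph:
    """A fitted LZGraph: weighted transitions plus initial/terminal statistics.

    Instances are built via :func:`build_graph` (or empty-initialised and
    populated by the deserialiser); they are static after construction.
    """

    def __init__(self, scheme: str, *, with_genes: bool = False) -> None:
        if scheme not in SCHEMES:
            raise SchemeError(f"unknown scheme {scheme!r}")
        self.scheme = scheme
        self.with_genes = with_genes
        self._g = nx.DiGraph()
        self.init_counts: Counter[NodeKey] = Counter()
        self.term_counts: Counter[NodeKey] = Counter()
        self.n_sequences = 0
        self.v_frequencies: Counter[str] = Counter()
        self.j_frequencies: Counter[str] = Counter()
        self._terminal_reach: dict[NodeKey, frozenset[NodeKey]] = {}

    # -- construction ----------------------------------------------------

    def _insert_path(
        self, path: Sequence[NodeKey], v_call: str | None, j_call: str | None
    ) -> None:
        g = self._g
        for node in path:
            if node not in g:
                g.add_node(node)
        self.init_counts[path[0]] += 1
        self.term_counts[path[-1]] += 1
        self.n_sequences += 1
        if self.with_genes:
            self.v_frequencies[v_call] += 1
            self.j_frequencies[j_call] += 1
        for u, v in zip(path, path[1:]):
            data = g.get_edge_data(u, v)
            if data is None:
                data = {"count": 0}
                if self.with_genes:
                    data["gene_usage"] = Counter()
                g.add_edge(u, v, **data)
            data = g[u][v]
            data["count"] += 1
            if self.with_genes:
                data["gene_usage"][(v_call, j_call)] += 1

    def _finalise(self) -> None:
        """Recompute edge weights as count / total outgoing events."""
        for node in self._g.nodes:
            total = sum(d["count"] for _, _, d in self._g.out_edges(node, data=True))
            for _, succ, d in self._g.out_edges(node, data=True):
                d["weight"] = d["count"] / total
        self._terminal_reach.clear()

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self):
        return self._g.nodes

    @property
    def edges(self):
        return self._g.edges

    def node_and_edge_counts(self) -> tuple[int, int]:
        """Cardinalities (|V|, |E|)."""
        return self._g.number_of_nodes(), self._g.number_of_edges()

    def has_edge(self, u: NodeKey, v: NodeKey) -> bool:
        return self._g.has_edge(u, v)

    def edge_count(self, u: NodeKey, v: NodeKey) -> int:
        return self._g[u][v]["count"]

    def weight(self, u: NodeKey, v: NodeKey) -> float:
        return self._g[u][v]["weight"]

    def gene_usage(self, u: NodeKey, v: NodeKey) -> Counter:
        if not self.with_genes:
            raise SchemeError("graph was built without the gene layer")
        return self._g[u][v]["gene_usage"]

    def successors(self, node: NodeKey) -> list[NodeKey]:
        return list(self._g.successors(node))

    def out_degree(self, node: NodeKey) -> int:
        """Number of distinct successors (immediate alternatives)."""
        return self._g.out_degree(node)

    def initial_probability(self, node: NodeKey) -> float:
        """P(X0): marginal probability of starting a path at ``node``."""
        return self.init_counts.get(node, 0) / self.n_sequences

    def psi(self, node: NodeKey) -> float:
        """Ψ: fraction of observed paths that terminated at ``node``."""
        return self.term_counts.get(node, 0) / self.n_sequences

    # -- DAG / reachability ----------------------------------------------

    def check_dag(self) -> tuple[bool, list | None]:
        """Whether a topological order exists; if not, one witness cycle."""
        if nx.is_directed_acyclic_graph(self._g):
            return True, None
        cycle = nx.find_cycle(self._g)
        return False, [u for u, _ in cycle]

    def reachable_terminals(self, node: NodeKey) -> frozenset[NodeKey]:
        """Terminal nodes strictly reachable from ``node`` (node excluded).

        Cached: graphs are static after construction.
        """
        cached = self._terminal_reach.get(node)
        if cached is None:
            desc = nx.descendants(self._g, node)
            cached = frozenset(t for t in self.term_counts if t in desc and t != node)
            self._terminal_reach[node] = cached
        return cached

    def terminal_stop_probability(self, node: NodeKey) -> float:
        """PT: probability of stopping at a terminal node given it was reached.

        PT(T) = Ψ(T) / (Ψ(T) + Σ_{x ∈ U} Ψ(x)) with U the other terminal
        nodes reachable from T; 1 when U is empty (unconditional stop).
        """
        if node not in self.term_counts:
            raise ValueError(f"{node} is not a terminal node of this graph")
        others = self.reachable_terminals(node)
        if not others:
            return 1.0
        psi_t = self.psi(node)
        return psi_t / (psi_t + sum(self.psi(x) for x in others))

    # -- equality ---------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LZGraph):
            return NotImplemented
        if (
            self.scheme != other.scheme
            or self.with_genes != other.with_genes
            or self.n_sequences != other.n_sequences
            or self.init_counts != other.init_counts
            or self.term_counts != other.term_counts
            or self.v_frequencies != other.v_frequencies
            or self.j_frequencies != other.j_frequencies
        ):
            return False
        if set(self._g.nodes) != set(other._g.nodes):
            return False
        if set(self._g.edges) != set(other._g.edges):
            return False
        for u, v, d in self._g.edges(data=True):
            od = other._g[u][v]
            if d["count"] != od["count"] or d["weight"] != od["weight"]:
                return False
            if self.with_genes and d["gene_usage"] != od["gene_usage"]:
                return False
        return True

    def __repr__(self) -> str:
        n, e = self.node_and_edge_counts()
        return (
            f"<LZGraph scheme={self.scheme} nodes={n} edges={e} "
            f"sequences={self.n_sequences} genes={self.with_genes}>"
        )


def build_graph(
    repertoire: "Repertoire | Iterable[str | tuple]",
    scheme: str = AAP,
    *,
    with_genes: bool = False,
    unique: bool = False,
) -> LZGraph:
    """Construct an LZGraph from a repertoire.

    Every record contributes one path (read-level semantics): repeated
    identical sequences each add to counts.  With ``unique=True`` the
    repertoire is first collapsed to its distinct sequences (the semantics
    used by the K1000 diversity index).

    ``with_genes`` requires every record to carry both v_call and j_call and
    populates the per-edge joint gene-usage layer plus marginal frequencies.
    """
    rep = as_repertoire(repertoire)
    if scheme == NDP and rep.scope != NUCLEOTIDE:
        raise SchemeError("the ndp scheme requires a nucleotide repertoire")
    if with_genes:
        missing = [r.sequence for r in rep.records if not r.has_genes]
        if missing:
            raise ValueError(
                "with_genes requires v_call and j_call on every record; "
                f"missing for {len(missing)} record(s), e.g. {missing[:3]}"
            )
    graph = LZGraph(scheme, with_genes=with_genes)
    if unique:
        records = [(s, None, None) for s in rep.unique_sequences()]
        if with_genes:
            # keep the first-annotated record per unique sequence
            first = {}
            for r in rep.records:
                first.setdefault(r.sequence, (r.v_call, r.j_call))
            records = [(s, *first[s]) for s in rep.unique_sequences()]
    else:
        records = [(r.sequence, r.v_call, r.j_call) for r in rep.records]
    for seq, v, j in records:
        path = encode_path(lz76_decompose(seq), scheme)
        graph._insert_path(path, v, j)
    graph._finalise()
    return graph
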