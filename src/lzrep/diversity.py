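"""K1000: a subsampling, abundance-free repertoire diversity index.

Classic alpha-diversity measures (richness, Shannon, Simpson, Hill numbers)
characterise the clonal abundance distribution and ignore how *similar* the
unique sequences are to each other.  The K index instead measures the
information capacity of the repertoire's sequence structure: the number of
nodes in an LZGraph constructed from k randomly sampled unique sequences,
averaged over repeated sampling procedures (k=1000 and 50 repeats by
default).  Because sampling is over the set of unique sequences, the index
is invariant to the clonal abundance distribution by construction.

Repertoires with fewer than k unique sequences cannot support the index
directly; the advised fallback is to lower k to the closest available
number of unique sequences, which this implementation applies only when
explicitly requested (with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .graph import AAP, NDP, LZGraph, build_graph
from .repertoire import NUCLEOTIDE, Repertoire, as_repertoire


@dataclass(frozen=True)
class DiversityResult:
    """Per-repeat node counts and their mean (the K_k index)."""

    k: int
    repeats: int
    per_repeat_node_counts: tuple[int, ...]
    seed: int
    requested_k: int | None = None  # set when the fallback lowered k

    @property
    def index_value(self) -> float:
        return float(np.mean(self.per_repeat_node_counts))


def k_diversity(
    repertoire: "Repertoire | list[str]",
    k: int = 1000,
    repeats: int = 50,
    scheme: str | None = None,
    seed: int = 0,
    *,
    fallback: bool = False,
) -> DiversityResult:
    """The K_k diversity index of a repertoire (K1000 at the default k).

    Deduplicates to unique sequences, then ``repeats`` times samples k of
    them without replacement, builds an LZGraph (ndp for nucleotides, aap
    for amino acids unless overridden) and records its node count.  The
    index is the mean count.  Unique sequences are taken in sorted order,
    so the result depends only on the unique-sequence *set* and the seed —
    never on record order or clonal abundances.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    rep = as_repertoire(repertoire)
    unique = rep.unique_sequences()
    requested_k = None
    if len(unique) < k:
        if not fallback:
            raise ValueError(
                f"repertoire has only {len(unique)} unique sequences, fewer "
                f"than k={k}; the K index cannot be computed directly — "
                "select the closest available number of unique sequences "
                "(pass fallback=True to lower k automatically)"
            )
        requested_k = k
        k = len(unique)
        warnings.warn(
            f"lowering k from {requested_k} to the available {k} unique "
            "sequences",
            stacklevel=2,
        )
    if scheme is None:
        scheme = NDP if rep.scope == NUCLEOTIDE else AAP
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(repeats):
        idx = rng.choice(len(unique), size=k, replace=False)
        sample = [unique[i] for i in idx]
        g = build_graph(
            Repertoire.from_sequences(sample, scope=rep.scope), scheme
        )
        counts.append(g.node_and_edge_counts()[0])
    return DiversityResult(
        k=k,
        repeats=repeats,
        per_repeat_node_counts=tuple(counts),
        seed=seed,
        requested_k=requested_k,
    )
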