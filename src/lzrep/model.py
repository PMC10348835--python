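"""Model/Results facade over the LZGraph machinery.

`LZGraphModel` is constructed from a repertoire (or a rearrangement
DataFrame) and a node-encoding scheme; `fit()` estimates the graph — the
initial-state distribution, the transition weight matrix, the termination
mass and (optionally) the per-edge gene-usage layer — and returns an
:class:`LZGraphResults` carrying the fitted graph together with the
downstream analyses: generation probability, sequence simulation,
centrality and diversity statistics, and plotting.

Example
-------
>>> from lzrep import synth_repertoire, LZGraphModel
>>> rep = synth_repertoire(n_sequences=300, n_unique=150, seed=7)
>>> res = LZGraphModel(rep, scheme="aap").fit()
>>> res.pgen(rep.records[0].sequence).log10_probability  # doctest: +SKIP
-7.3...
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .bow import BowDictionary, BowVector, build_bow_dictionary, encode_bow
from .centrality import (
    CentralityVector,
    GeneUsageMatrix,
    VariationCurve,
    eigencentrality_features,
    gene_variation,
    lz_centrality,
    variation_curve,
)
from .diversity import DiversityResult, k_diversity
from .generation import (
    CONSTRAINED,
    UNCONSTRAINED,
    GeneratedSequence,
    GenerationConfig,
    generate_batch,
)
from .graph import AAP, NDP, LZGraph, build_graph
from .pgen import PgenResult, lzpgen, lzpgen_batch
from .repertoire import AMINO_ACID, NUCLEOTIDE, Repertoire, as_repertoire


class LZGraphModel:
    """An LZ-76 subpattern transition model for one repertoire.

    Parameters
    ----------
    repertoire
        A :class:`~lzrep.repertoire.Repertoire` (or a plain sequence list).
    scheme
        Node encoding: ``"aap"`` (amino-acid positional, default for
        amino-acid scope), ``"ndp"`` (nucleotide double positional, default
        for nucleotide scope) or ``"naive"``.
    with_genes
        Estimate the per-edge joint (V, J) usage layer; requires annotated
        records and enables constrained generation and gene-variation
        analyses on the results object.
    """

    def __init__(
        self,
        repertoire: "Repertoire | Iterable[str | tuple]",
        scheme: str | None = None,
        *,
        with_genes: bool = False,
    ) -> None:
        self.repertoire = as_repertoire(repertoire)
        if scheme is None:
            scheme = NDP if self.repertoire.scope == NUCLEOTIDE else AAP
        self.scheme = scheme
        self.with_genes = with_genes

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        scope: str = AMINO_ACID,
        scheme: str | None = None,
        *,
        column_map: Mapping[str, str] | None = None,
        with_genes: bool = False,
    ) -> "LZGraphModel":
        """Build a model from an AIRR-style rearrangement DataFrame."""
        if column_map:
            df = df.rename(columns=dict(column_map))
        seq_col = "junction" if scope == NUCLEOTIDE else "junction_aa"
        if seq_col not in df.columns:
            raise ValueError(f"required column {seq_col!r} missing")
        has_genes = {"v_call", "j_call"} <= set(df.columns)
        items: list = []
        for _, row in df.iterrows():
            seq = row[seq_col]
            if not isinstance(seq, str) or not seq:
                continue
            if has_genes and isinstance(row["v_call"], str) and isinstance(row["j_call"], str):
                items.append((seq, row["v_call"], row["j_call"]))
            else:
                items.append(seq)
        rep = Repertoire.from_sequences(items, scope=scope)
        return cls(rep, scheme=scheme, with_genes=with_genes)

    def fit(self) -> "LZGraphResults":
        """Estimate the graph from the repertoire's decomposition paths."""
        graph = build_graph(
            self.repertoire, self.scheme, with_genes=self.with_genes
        )
        return LZGraphResults(self, graph)


class LZGraphResults:
    """A fitted LZGraph with its downstream analyses."""

    def __init__(self, model: LZGraphModel, graph: LZGraph) -> None:
        self.model = model
        self.graph = graph

    # -- descriptive ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.node_and_edge_counts()[0]

    @property
    def n_edges(self) -> int:
        return self.graph.node_and_edge_counts()[1]

    def summary(self) -> str:
        """Plain-text fit summary."""
        rep = self.model.repertoire
        n_unique = len(rep.unique_sequences())
        rows = [
            ("Scheme", self.graph.scheme),
            ("Scope", rep.scope),
            ("Sequences (depth)", rep.depth),
            ("Unique sequences", n_unique),
            ("Nodes |V|", self.n_nodes),
            ("Edges |E|", self.n_edges),
            ("Initial states", len(self.graph.init_counts)),
            ("Terminal states", len(self.graph.term_counts)),
            ("Gene layer", "yes" if self.graph.with_genes else "no"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["LZGraph model fit", "=" * (width + 24)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    # -- generation probability -------------------------------------------

    def pgen(self, sequence: str, **kwargs) -> PgenResult:
        return lzpgen(self.graph, sequence, **kwargs)

    def pgen_batch(self, sequences: Iterable[str], **kwargs) -> pd.DataFrame:
        """LZPgen for many sequences as a tidy DataFrame."""
        results = lzpgen_batch(self.graph, list(sequences), **kwargs)
        return pd.DataFrame(
            [
                {
                    "sequence": r.sequence,
                    "pgen": r.probability,
                    "log10_pgen": r.log10_probability,
                    "n_imputed": r.n_imputed,
                }
                if r is not None
                else {"sequence": None, "pgen": np.nan, "log10_pgen": np.nan, "n_imputed": -1}
                for r in results
            ]
        )

    # -- simulation --------------------------------------------------------

    def generate(
        self,
        n: int,
        mode: str = UNCONSTRAINED,
        seed: int = 0,
        **kwargs,
    ) -> list[GeneratedSequence]:
        config = GenerationConfig(mode=mode, seed=seed, **kwargs)
        return generate_batch(self.graph, n, config)

    def generate_frame(self, n: int, mode: str = UNCONSTRAINED, seed: int = 0) -> pd.DataFrame:
        gen = self.generate(n, mode=mode, seed=seed)
        return pd.DataFrame(
            {
                "sequence": [g.sequence for g in gen],
                "v_call": [g.v_call for g in gen],
                "j_call": [g.j_call for g in gen],
                "n_restarts": [g.n_restarts for g in gen],
            }
        )

    # -- per-sequence diagnostics -----------------------------------------

    def variation_curve(self, sequence: str) -> VariationCurve:
        return variation_curve(self.graph, sequence)

    def lz_centrality(self, sequence: str) -> float:
        return lz_centrality(self.graph, sequence)

    def gene_variation(
        self, sequence: str, alpha: float = 50.0
    ) -> tuple[GeneUsageMatrix, GeneUsageMatrix]:
        return gene_variation(self.graph, sequence, alpha)

    # -- repertoire-level features ----------------------------------------

    def eigencentrality(
        self, vocabulary: "BowDictionary | list[str] | None" = None, **kwargs
    ) -> CentralityVector:
        return eigencentrality_features(self.graph, vocabulary, **kwargs)

    def bow(self, dictionary: BowDictionary | None = None) -> BowVector:
        if dictionary is None:
            dictionary = build_bow_dictionary([self.model.repertoire])
        return encode_bow(self.model.repertoire, dictionary)

    def k_diversity(
        self, k: int = 1000, repeats: int = 50, seed: int = 0, **kwargs
    ) -> DiversityResult:
        return k_diversity(
            self.model.repertoire,
            k=k,
            repeats=repeats,
            scheme=self.model.scheme if self.model.scheme != "naive" else None,
            seed=seed,
            **kwargs,
        )

    # -- plotting ----------------------------------------------------------

    def plot_variation_curve(self, sequence: str, ax=None):
        from .plotting import plot_variation_curve

        return plot_variation_curve(self.variation_curve(sequence), ax=ax)

    def plot_gene_variation(self, sequence: str, alpha: float = 50.0, axes=None):
        from .plotting import plot_gene_variation

        v, j = self.gene_variation(sequence, alpha)
        return plot_gene_variation(v, j, axes=axes)
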