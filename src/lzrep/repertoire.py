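"""Sequence records and repertoires.

A *repertoire* is an ordered collection of productive CDR3 sequences, each
optionally annotated with the V and J allele calls of its flanking germline
segments and a read (duplicate) count.  Sequences are either nucleotide
(``A C G T``) or amino-acid (20-letter) strings; the scope is declared at the
repertoire level and every record must respect it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import AlphabetError

logger = logging.getLogger(__name__)

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino_acid"

NT_ALPHABET = frozenset("ACGT")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ALPHABETS = {NUCLEOTIDE: NT_ALPHABET, AMINO_ACID: AA_ALPHABET}


def alphabet_for(scope: str) -> frozenset[str]:
    try:
        return _ALPHABETS[scope]
    except KeyError:
        raise ValueError(
            f"unknown scope {scope!r}; expected {NUCLEOTIDE!r} or {AMINO_ACID!r}"
        ) from None


def validate_sequence(sequence: str, scope: str) -> str:
    """Uppercase and validate a sequence against the scope's alphabet.

    Raises :class:`AlphabetError` naming the first offending position
    (1-based) for out-of-alphabet characters, including ambiguity codes
    (``N``, ``X``, ``*``), and for empty input.
    """
    if not sequence:
        raise AlphabetError("empty sequence")
    seq = sequence.upper()
    alphabet = alphabet_for(scope)
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise AlphabetError(
                f"character {ch!r} at position {i + 1} of {seq!r} is not in "
                f"the {scope} alphabet"
            )
    return seq


def infer_scope(sequences: Iterable[str]) -> str:
    """Guess nucleotide vs amino-acid scope from sequence content."""
    for seq in sequences:
        if set(seq.upper()) - NT_ALPHABET:
            return AMINO_ACID
    return NUCLEOTIDE


@dataclass(frozen=True)
class SequenceRecord:
    """One CDR3 sequence with optional gene annotations.

    ``v_call``/``j_call`` must either both be present or both be ``None``;
    gene-annotated graphs require both flanks.
    """

    sequence: str
    v_call: str | None = None
    j_call: str | None = None
    duplicate_count: int = 1

    def __post_init__(self) -> None:
        if (self.v_call is None) != (self.j_call is None):
            raise ValueError(
                f"record {self.sequence!r}: v_call and j_call must be "
                "both present or both absent"
            )
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be a positive integer")

    @property
    def has_genes(self) -> bool:
        return self.v_call is not None


@dataclass
class Repertoire:
    """An ordered collection of :class:`SequenceRecord` with a declared scope."""

    records: list[SequenceRecord]
    scope: str = AMINO_ACID
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a repertoire must contain at least one record")
        alphabet_for(self.scope)  # validate scope name

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[str | tuple],
        scope: str | None = None,
        *,
        permissive: bool = False,
    ) -> "Repertoire":
        """Build a repertoire from plain strings or ``(seq, v_call, j_call)`` tuples.

        In permissive mode, records failing alphabet validation are dropped
        with a logged warning instead of raising.
        """
        items = list(sequences)
        raw = [it if isinstance(it, str) else it[0] for it in items]
        if scope is None:
            scope = infer_scope(raw)
        records = []
        for it in items:
            if isinstance(it, str):
                seq, v, j = it, None, None
            else:
                seq, v, j = it[0], it[1], it[2]
            try:
                seq = validate_sequence(seq, scope)
            except AlphabetError as exc:
                if permissive:
                    logger.warning("dropping invalid sequence: %s", exc)
                    warnings.warn(str(exc), stacklevel=2)
                    continue
                raise
            records.append(SequenceRecord(seq, v_call=v, j_call=j))
        return cls(records=records, scope=scope)

    @property
    def depth(self) -> int:
        """Repertoire depth: the number of sequence records."""
        return len(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def unique_sequences(self) -> list[str]:
        """Distinct sequences in lexicographic order (abundance-free view)."""
        return sorted(set(r.sequence for r in self.records))

    @property
    def has_genes(self) -> bool:
        return all(r.has_genes for r in self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self):
        import pandas as pd

        col = "junction" if self.scope == NUCLEOTIDE else "junction_aa"
        return pd.DataFrame(
            {
                col: [r.sequence for r in self.records],
                "v_call": [r.v_call for r in self.records],
                "j_call": [r.j_call for r in self.records],
                "duplicate_count": [r.duplicate_count for r in self.records],
            }
        )


def as_repertoire(
    data: "Repertoire | Iterable[str | tuple]", scope: str | None = None
) -> Repertoire:
    """Coerce loose inputs (string lists, tuple lists) into a Repertoire."""
    if isinstance(data, Repertoire):
        return data
    return Repertoire.from_sequences(data, scope=scope)
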