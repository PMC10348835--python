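"""Bag-of-words (BOW) encoding of repertoires over LZ-76 subpatterns.

A BOW dictionary is the union of subpatterns observed across one or more
repertoires, in first-observation order (so feature vectors are reproducible
byte-for-byte).  A repertoire is encoded as the frequency of each dictionary
token across the decompositions of all its sequences, normalised by the
repertoire depth N; subpatterns absent from the dictionary are ignored
(out-of-vocabulary rule), with the ignored count reported for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .decomposition import lz76_decompose
from .repertoire import Repertoire, as_repertoire


@dataclass(frozen=True)
class BowDictionary:
    """Ordered unique subpattern vocabulary."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("BOW dictionary tokens must be unique")
        if not self.tokens:
            raise ValueError("BOW dictionary is empty")

    @property
    def token_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.token_index


@dataclass
class BowVector:
    """Depth-normalised token frequencies aligned to a :class:`BowDictionary`."""

    dictionary: BowDictionary
    values: np.ndarray
    depth: int
    n_ignored: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.dictionary),):
            raise ValueError("vector length must match dictionary size")
        if (self.values < 0).any():
            raise ValueError("BOW values must be nonnegative")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.dictionary.tokens, self.values.tolist()))


def build_bow_dictionary(
    repertoires: "Iterable[Repertoire | Iterable[str]]",
) -> BowDictionary:
    """Union of subpatterns over all sequences, in first-observed order."""
    reps = [as_repertoire(r) for r in repertoires]
    if not reps:
        raise ValueError("at least one repertoire is required")
    tokens: dict[str, None] = {}
    for rep in reps:
        for seq in rep.sequences():
            for sub in lz76_decompose(seq).subpatterns:
                tokens.setdefault(sub, None)
    return BowDictionary(tuple(tokens))


def encode_bow(
    repertoire: "Repertoire | Iterable[str]", dictionary: BowDictionary
) -> BowVector:
    """Encode a repertoire as depth-normalised dictionary-token frequencies.

    Out-of-vocabulary subpatterns are silently skipped; their total count is
    available on the returned vector as ``n_ignored``.
    """
    rep = as_repertoire(repertoire)
    index = dictionary.token_index
    counts = np.zeros(len(dictionary), dtype=float)
    ignored = 0
    for seq in rep.sequences():
        for sub in lz76_decompose(seq).subpatterns:
            i = index.get(sub)
            if i is None:
                ignored += 1
            else:
                counts[i] += 1
    return BowVector(
        dictionary=dictionary,
        values=counts / rep.depth,
        depth=rep.depth,
        n_ignored=ignored,
    )
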