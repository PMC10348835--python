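"""LZ-76 subpattern decomposition.

The 1976 Lempel–Ziv procedure greedily scans a string with a growing window
and emits each window content the first time it has not been seen before.
The number of emitted subpatterns is the sequence's Lempel–Ziv complexity, a
practical estimator of its entropy rate / Kolmogorov complexity.

Two subtleties matter for repertoire graphs:

* **Ordering.**  The classic procedure returns a *set* of subpatterns; graph
  construction needs the subpatterns in emission order, together with the
  start position of each.  :func:`lz76_decompose` returns the ordered list
  (and retains the raw set).
* **The trailing remainder.**  When the scan reaches the end of the string
  while the current window duplicates an already-known subpattern, the
  leftover symbols cannot form a novel subpattern.  They are appended to the
  last emitted subpattern so that concatenating the ordered subpatterns
  always reproduces the input exactly (losslessness).  The merged token — not
  the raw one — is what enters BOW dictionaries and graph nodes, so the two
  vocabularies coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AlphabetError


@dataclass(frozen=True)
class Decomposition:
    """The ordered LZ-76 decomposition of one sequence.

    ``subpatterns`` concatenate to ``source`` exactly.  ``raw_dictionary``
    is the set a literal run of the classic procedure would return;
    ``merged_tail`` records whether the trailing-remainder merge fired, in
    which case the final subpattern differs from the raw tokens.
    """

    source: str
    subpatterns: tuple[str, ...]
    raw_dictionary: frozenset[str]
    merged_tail: bool

    def __post_init__(self) -> None:
        if "".join(self.subpatterns) != self.source:
            raise ValueError("decomposition is not lossless")

    def __len__(self) -> int:
        return len(self.subpatterns)

    @property
    def start_positions(self) -> tuple[int, ...]:
        """1-based start index of each subpattern within the source."""
        positions, pos = [], 1
        for sub in self.subpatterns:
            positions.append(pos)
            pos += len(sub)
        return tuple(positions)


def _validate(sequence: str, alphabet: frozenset[str] | None) -> None:
    if not sequence:
        raise AlphabetError("cannot decompose an empty sequence")
    if alphabet is not None:
        for i, ch in enumerate(sequence):
            if ch not in alphabet:
                raise AlphabetError(
                    f"character {ch!r} at position {i + 1} is not in the "
                    "declared alphabet"
                )


def lz76_decompose(
    sequence: str, alphabet: frozenset[str] | None = None
) -> Decomposition:
    """Greedy LZ-76 scan returning the ordered, lossless decomposition.

    A sliding window starting at ``ind`` grows by one symbol while its
    content is already known; the first novel content is emitted and the
    window restarts just past it.  If the scan ends mid-window (the leftover
    duplicates a known subpattern), the remainder is merged into the last
    emitted subpattern and ``merged_tail`` is set.

    The scan advances ``ind + inc`` monotonically, so the whole decomposition
    is O(L) window moves for a length-L sequence.
    """
    _validate(sequence, alphabet)
    n = len(sequence)
    seen: set[str] = set()
    ordered: list[str] = []
    ind, inc = 0, 1
    while ind + inc <= n:
        sub = sequence[ind : ind + inc]
        if ind + inc == n and sub not in seen:
            seen.add(sub)
            ordered.append(sub)
            ind = n
            break
        if sub in seen:
            inc += 1
        else:
            seen.add(sub)
            ordered.append(sub)
            ind += inc
            inc = 1
    merged = ind < n
    if merged:
        # trailing remainder duplicates a known subpattern: fold it into the
        # last emitted one to keep the decomposition lossless
        remainder = sequence[ind:]
        if ordered:
            ordered[-1] += remainder
        else:  # cannot happen: the very first window is always novel
            ordered.append(remainder)
    return Decomposition(
        source=sequence,
        subpatterns=tuple(ordered),
        raw_dictionary=frozenset(seen),
        merged_tail=merged,
    )


def lz76_complexity(sequence: str, alphabet: frozenset[str] | None = None) -> int:
    """Number of subpatterns in the ordered decomposition (LZ complexity)."""
    return len(lz76_decompose(sequence, alphabet).subpatterns)
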