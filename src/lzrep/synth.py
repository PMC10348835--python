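"""Synthetic CDR3 repertoire generator.

Emulates the structure V(D)J recombination imposes on CDR3s: a small pool
of conserved 5' motifs contributed by the V segment (nearly all TCRB CDR3
amino-acid sequences start with "CAS"), a variable junctional middle, and a
small pool of conserved 3' motifs contributed by the J segment.  V allele
labels are drawn consistently with the chosen 5' motif and J alleles with
the 3' motif, so gene-constrained analyses see realistic motif–allele
coupling.  Clone sizes follow a Zipf-like distribution when replicating
``n_unique`` distinct sequences to ``n_sequences`` records.

Everything is deterministic for a fixed seed, making the generator the
fixture factory for the whole test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .repertoire import (
    AA_ALPHABET,
    AMINO_ACID,
    NT_ALPHABET,
    Repertoire,
    SequenceRecord,
)

_AA_V_POOL: dict[str, tuple[str, ...]] = {
    "CAS": ("TRBV5-1*01", "TRBV19*01", "TRBV6-5*01"),
    "CASS": ("TRBV7-9*01", "TRBV28*01"),
    "CSA": ("TRBV20-1*01",),
}
_AA_J_POOL: dict[str, tuple[str, ...]] = {
    "EQYF": ("TRBJ2-7*01",),
    "EQFF": ("TRBJ2-1*01",),
    "YGYTF": ("TRBJ1-2*01",),
    "NTEAFF": ("TRBJ1-1*01",),
}
_NT_V_POOL: dict[str, tuple[str, ...]] = {
    "TGTGCCAGCAGT": ("TRBV5-1*01", "TRBV19*01"),
    "TGCAGTGCT": ("TRBV20-1*01",),
}
_NT_J_POOL: dict[str, tuple[str, ...]] = {
    "GAGCAGTACTTC": ("TRBJ2-7*01",),
    "TATGGCTACACCTTC": ("TRBJ1-2*01",),
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic repertoire.

    ``length_range`` is inclusive; in nucleotide scope only in-frame
    (divisible-by-3) lengths are emitted, mirroring productive
    rearrangements.  Motif pools map each conserved flank to the allele
    names it may be annotated with.
    """

    n_sequences: int = 1000
    n_unique: int = 500
    scope: str = AMINO_ACID
    length_range: tuple[int, int] | None = None
    five_prime_pool: Mapping[str, Sequence[str]] | None = None
    three_prime_pool: Mapping[str, Sequence[str]] | None = None
    seed: int = 0

    def resolved(self) -> "SynthConfig":
        """Fill scope-dependent defaults; validate feasibility."""
        length_range = self.length_range or (
            (12, 18) if self.scope == AMINO_ACID else (36, 54)
        )
        five = dict(
            self.five_prime_pool
            or (_AA_V_POOL if self.scope == AMINO_ACID else _NT_V_POOL)
        )
        three = dict(
            self.three_prime_pool
            or (_AA_J_POOL if self.scope == AMINO_ACID else _NT_J_POOL)
        )
        cfg = SynthConfig(
            n_sequences=self.n_sequences,
            n_unique=self.n_unique,
            scope=self.scope,
            length_range=length_range,
            five_prime_pool=five,
            three_prime_pool=three,
            seed=self.seed,
        )
        if cfg.n_unique < 1 or cfg.n_sequences < cfg.n_unique:
            raise ValueError("need 1 <= n_unique <= n_sequences")
        if not five or not three:
            raise ValueError("motif pools must be non-empty")
        lo, hi = length_range
        min_needed = max(len(m) for m in five) + max(len(m) for m in three)
        if hi < min_needed:
            raise ValueError(
                f"length range {length_range} is shorter than the longest "
                f"5'+3' motif combination ({min_needed})"
            )
        return cfg


def synth_repertoire(config: SynthConfig | None = None, **kwargs) -> Repertoire:
    """Generate a deterministic synthetic repertoire from a config.

    Keyword arguments are a shorthand for constructing the config, e.g.
    ``synth_repertoire(n_sequences=200, n_unique=100, seed=7)``.
    """
    if config is None:
        config = SynthConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword arguments, not both")
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    alphabet = sorted(AA_ALPHABET if cfg.scope == AMINO_ACID else NT_ALPHABET)
    lo, hi = cfg.length_range  # type: ignore[misc]
    lengths = [
        L
        for L in range(lo, hi + 1)
        if cfg.scope == AMINO_ACID or L % 3 == 0
    ]
    five = sorted(cfg.five_prime_pool)  # type: ignore[arg-type]
    three = sorted(cfg.three_prime_pool)  # type: ignore[arg-type]

    uniques: dict[str, tuple[str, str]] = {}
    attempts = 0
    while len(uniques) < cfg.n_unique:
        attempts += 1
        if attempts > 100 * cfg.n_unique:
            raise ValueError(
                "could not draw enough distinct sequences; widen the length "
                "range or shrink n_unique"
            )
        m5 = five[rng.integers(len(five))]
        m3 = three[rng.integers(len(three))]
        feasible = [L for L in lengths if L >= len(m5) + len(m3)]
        if not feasible:
            continue
        L = feasible[rng.integers(len(feasible))]
        middle = "".join(
            alphabet[i] for i in rng.integers(len(alphabet), size=L - len(m5) - len(m3))
        )
        seq = m5 + middle + m3
        if seq in uniques:
            continue
        v = cfg.five_prime_pool[m5][rng.integers(len(cfg.five_prime_pool[m5]))]  # type: ignore[index]
        j = cfg.three_prime_pool[m3][rng.integers(len(cfg.three_prime_pool[m3]))]  # type: ignore[index]
        uniques[seq] = (v, j)

    seqs = list(uniques)
    # Zipf-like clone sizes: every unique sequence appears at least once
    extra = cfg.n_sequences - cfg.n_unique
    weights = 1.0 / np.arange(1, len(seqs) + 1)
    weights /= weights.sum()
    extra_idx = rng.choice(len(seqs), size=extra, replace=True, p=weights)
    counts = np.bincount(extra_idx, minlength=len(seqs)) + 1
    records = []
    for seq, count in zip(seqs, counts):
        v, j = uniques[seq]
        records.extend(
            SequenceRecord(seq, v_call=v, j_call=j) for _ in range(count)
        )
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return Repertoire(
        records=records,
        scope=cfg.scope,
        metadata={"source": "synthetic", "seed": cfg.seed},
    )
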