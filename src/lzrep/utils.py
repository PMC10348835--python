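"""Small numeric utilities shared across analyses."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import jensenshannon


def sequence_space_size(alphabet_size: int, length: int) -> int:
    """Number of possible sequences of a given length over an alphabet.

    E.g. the theoretical upper bound on length-15 amino-acid CDR3s is
    ``sequence_space_size(20, 15)`` ≈ 3.3e19 — dwarfing the ~1e10–1e11
    unique TCRs in a human body.
    """
    if alphabet_size < 1 or length < 0:
        raise ValueError("alphabet_size must be >= 1 and length >= 0")
    return alphabet_size**length


def expected_null_significant(n_tests: int, alpha: float = 0.05) -> float:
    """Expected count of significant results among n true-null tests."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    return n_tests * alpha


def pgen_jensen_shannon(
    p_values, q_values, *, bins: int = 50, log10: bool = True
) -> float:
    """Jensen–Shannon divergence between two Pgen value distributions.

    Histograms both samples (on the log10 scale by default, where Pgen
    distributions are roughly unimodal) over shared bin edges and returns
    the JS divergence (base 2) of the two empirical distributions.
    """
    p = np.asarray([x for x in p_values if x > 0], dtype=float)
    q = np.asarray([x for x in q_values if x > 0], dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("both samples need at least one positive value")
    if log10:
        p, q = np.log10(p), np.log10(q)
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    hp, _ = np.histogram(p, bins=edges)
    hq, _ = np.histogram(q, bins=edges)
    return float(jensenshannon(hp, hq, base=2) ** 2)
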