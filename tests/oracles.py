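"""Independent reference implementations used only as test oracles.

Everything here is written directly from first principles (plain dicts and
Counters over strings), deliberately sharing no code with the package, so
agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict


def literal_lz76_set(sequence: str) -> set[str]:
    """Literal transcription of the classic sliding-window pseudocode.

    Returns the *set* of subpatterns (the raw dictionary), including the
    end-of-sequence special case that admits a novel final window.
    """
    sub_strings: set[str] = set()
    n = len(sequence)
    ind = 0  # sliding window start position
    inc = 1  # sliding window size
    while True:
        if ind + inc > n:
            break
        if ind + inc == n and sequence[ind : ind + inc] not in sub_strings:
            sub_str = sequence[ind : ind + inc]
            sub_strings = sub_strings | {sub_str}
            break
        else:
            sub_str = sequence[ind : ind + inc]
        if sub_str in sub_strings:
            inc = inc + 1
        else:
            sub_strings = sub_strings | {sub_str}
            ind = ind + inc
            inc = 1
    return sub_strings


def oracle_decompose(seq: str) -> list[tuple[str, int]]:
    """Ordered (subpattern, 1-based start) pairs, trailing remainder merged
    into the last emitted subpattern."""
    seen: set[str] = set()
    out: list[tuple[str, int]] = []
    i = 0
    while i < len(seq):
        j = i + 1
        while j <= len(seq) and seq[i:j] in seen:
            j += 1
        if j > len(seq):
            sub, pos = out[-1]
            out[-1] = (sub + seq[i:], pos)
            break
        seen.add(seq[i:j])
        out.append((seq[i:j], i + 1))
        i = j
    return out


def oracle_path(seq: str, scheme: str) -> list[str]:
    """Rendered node-key path of a sequence under a scheme."""
    toks = oracle_decompose(seq)
    if scheme == "aap":
        return [f"{s}_{p}" for s, p in toks]
    if scheme == "ndp":
        return [f"{s}{(p - 1) % 3}_{p}" for s, p in toks]
    return [s for s, _ in toks]


class CountModel:
    """Raw transition counts of a repertoire, built with plain Counters."""

    def __init__(self, sequences: list[str], scheme: str) -> None:
        self.n = len(sequences)
        self.paths = [oracle_path(s, scheme) for s in sequences]
        self.init: Counter[str] = Counter(p[0] for p in self.paths)
        self.term: Counter[str] = Counter(p[-1] for p in self.paths)
        self.trans: Counter[tuple[str, str]] = Counter(
            (u, v) for p in self.paths for u, v in zip(p, p[1:])
        )
        self.out_total: Counter[str] = Counter(
            u for p in self.paths for u in p[:-1]
        )
        self.succ: dict[str, set[str]] = defaultdict(set)
        for u, v in self.trans:
            self.succ[u].add(v)

    def weight(self, u: str, v: str) -> float:
        return self.trans[(u, v)] / self.out_total[u]

    def reachable(self, node: str) -> set[str]:
        seen, stack = set(), [node]
        while stack:
            for v in self.succ.get(stack.pop(), ()):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    def stop_prob(self, node: str) -> float:
        others = {t for t in self.term if t in self.reachable(node) and t != node}
        if not others:
            return 1.0
        psi = self.term[node] / self.n
        return psi / (psi + sum(self.term[x] / self.n for x in others))


def brute_force_pgen(sequences: list[str], query: str, scheme: str) -> float:
    """Path product of counts ratios, with geometric-mean imputation."""
    m = CountModel(sequences, scheme)
    qpath = oracle_path(query, scheme)
    factors: list[float | None] = []
    p0 = m.init.get(qpath[0], 0) / m.n
    factors.append(p0 if p0 > 0 else None)
    present = []
    for u, v in zip(qpath, qpath[1:]):
        if m.trans.get((u, v), 0) > 0:
            w = m.weight(u, v)
            factors.append(w)
            present.append(w)
        else:
            factors.append(None)
    if all(f is not None for f in factors):
        return math.prod(factors)  # type: ignore[arg-type]
    if not present:
        return 0.0
    gm = math.exp(sum(math.log(w) for w in present) / len(present))
    return math.prod(gm if f is None else f for f in factors)


def enumerate_path_distribution(
    sequences: list[str], scheme: str
) -> dict[tuple[str, ...], float]:
    """Exact sampling distribution over root-to-terminal paths.

    Multiplies the initial-state probability, edge weights, and the
    conditional stop/continue probabilities at each terminal node along the
    path.  Only valid on acyclic (positional) schemes.
    """
    m = CountModel(sequences, scheme)
    dist: dict[tuple[str, ...], float] = {}

    def rec(node: str, prob: float, path: tuple[str, ...]) -> None:
        p_stop = m.stop_prob(node) if node in m.term else 0.0
        if node in m.term and p_stop > 0:
            dist[path] = dist.get(path, 0.0) + prob * p_stop
        cont = prob * (1.0 - p_stop)
        if cont <= 0:
            return
        for v in sorted(m.succ.get(node, ())):
            rec(v, cont * m.weight(node, v), path + (v,))

    for s0, c in m.init.items():
        rec(s0, c / m.n, (s0,))
    total = sum(dist.values())
    assert abs(total - 1.0) < 1e-9, f"enumeration mass {total}"
    return dist
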