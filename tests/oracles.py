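"""Independent oracles used by the test suite.

These deliberately avoid the implementation's code paths: the alignment
oracle is a memoised recursion over explicit alignment moves (validated
against true exhaustive enumeration of every alignment at tiny lengths),
and the chimera oracle enumerates all parent-combination sequences.
"""

from __future__ import annotations

import itertools

# doubled integer scores so that 0.5 gap extensions stay exact:
# nucleotide match +5 / mismatch -4, gap open 10 / extend 0.5
MATCH = 10
MISMATCH = -8
GAP_OPEN = -20  # charged at the first position of a gap
GAP_EXT = -1  # each subsequent position


def local_align_oracle(a: str, b: str) -> tuple[int, frozenset[int]]:
    """Best local alignment score (doubled ints) and the set of identity
    counts achievable by score-optimal alignments."""
    memo: dict[tuple[int, int, str], tuple[int, frozenset[int]]] = {}
    la, lb = len(a), len(b)

    def f(i: int, j: int, prev: str) -> tuple[int, frozenset[int]]:
        key = (i, j, prev)
        if key in memo:
            return memo[key]
        options: list[tuple[int, frozenset[int]]] = [(0, frozenset([0]))]  # stop here
        if i < la and j < lb:
            step = MATCH if a[i] == b[j] else MISMATCH
            ident = 1 if a[i] == b[j] else 0
            score, ids = f(i + 1, j + 1, "M")
            options.append((step + score, frozenset(c + ident for c in ids)))
        if i < la:  # consume a[i] against a gap
            cost = GAP_EXT if prev == "A" else GAP_OPEN
            score, ids = f(i + 1, j, "A")
            options.append((cost + score, ids))
        if j < lb:
            cost = GAP_EXT if prev == "B" else GAP_OPEN
            score, ids = f(i, j + 1, "B")
            options.append((cost + score, ids))
        best = max(s for s, _ in options)
        idset = frozenset().union(*(ids for s, ids in options if s == best))
        memo[key] = (best, idset)
        return memo[key]

    best = 0
    idset: frozenset[int] = frozenset([0])
    for i in range(la + 1):
        for j in range(lb + 1):
            score, ids = f(i, j, "S")
            if score > best:
                best, idset = score, ids
            elif score == best:
                idset = idset | ids
    return best, idset


def enumerate_all_alignments(a: str, b: str) -> tuple[int, frozenset[int]]:
    """Truly exhaustive: walk every alignment path of every substring pair.

    Exponential; only usable for very short sequences.  Validates
    ``local_align_oracle``.
    """
    best = 0
    ids_at_best: set[int] = {0}

    def walk(i: int, j: int, prev: str, score: int, ident: int) -> None:
        nonlocal best, ids_at_best
        if score > best:
            best, ids_at_best = score, {ident}
        elif score == best:
            ids_at_best.add(ident)
        if i < len(a) and j < len(b):
            step = MATCH if a[i] == b[j] else MISMATCH
            walk(i + 1, j + 1, "M", score + step, ident + (1 if a[i] == b[j] else 0))
        if i < len(a):
            walk(i + 1, j, "A", score + (GAP_EXT if prev == "A" else GAP_OPEN), ident)
        if j < len(b):
            walk(i, j + 1, "B", score + (GAP_EXT if prev == "B" else GAP_OPEN), ident)

    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            walk(i, j, "S", 0, 0)
    return best, frozenset(ids_at_best)


def all_combination_sequences(p1: str, p2: str) -> dict[str, tuple[int, ...]]:
    """All 2**k sequences matching one parent at every variable site.

    Returns sequence -> per-site parent pattern (1/2).  The two all-ones /
    all-twos patterns are the parents themselves.
    """
    assert len(p1) == len(p2)
    sites = [i for i, (x, y) in enumerate(zip(p1, p2)) if x != y]
    out: dict[str, tuple[int, ...]] = {}
    for pattern in itertools.product((1, 2), repeat=len(sites)):
        seq = list(p1)
        for site, choice in zip(sites, pattern):
            seq[site] = p1[site] if choice == 1 else p2[site]
        out["".join(seq)] = pattern
    return out
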