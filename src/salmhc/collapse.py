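"""Dereplication of merged reads into abundance-ranked unique variants."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["CollapsedVariant", "collapse_reads", "select_candidates"]

DEFAULT_TOP_N = 5
DEFAULT_MIN_FRACTION = 0.01


@dataclass(frozen=True)
class CollapsedVariant:
    residues: str
    count: int
    rank: int
    fraction: float


def collapse_reads(merged_reads: Iterable) -> list[CollapsedVariant]:
    """Collapse by exact sequence identity (qualities ignored) and rank.

    Deterministic order: count descending, then sequence lexicographic.
    """
    seqs = [getattr(r, "residues", r) for r in merged_reads]
    counts = Counter(seqs)
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedVariant(seq, n, rank, n / total)
        for rank, (seq, n) in enumerate(ordered, start=1)
    ]


def select_candidates(
    variants: Sequence[CollapsedVariant],
    top_n: int = DEFAULT_TOP_N,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> list[CollapsedVariant]:
    """The top ``top_n`` variants whose read fraction reaches ``min_fraction``.

    The default floor of 1% sits at the low end of the observed top-variant
    fractions so that true alleles disadvantaged by primer efficiency (a
    ~4k-read allele next to an ~19k-read one) are retained.
    """
    return [v for v in variants[:top_n] if v.fraction >= min_fraction]
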