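"""Overlap-merging of read pairs into full-length amplicon sequences.

The second mate is reverse-complemented and every candidate relative
placement of the two reads is scored by mismatch density inside the
overlap; the lowest-density placement wins (ties go to the longest
overlap).  The scan is substitution-only — no indel-aware alignment — and
also covers "outie" placements where the amplicon is shorter than the read
length, in which case the merged output excludes any overhang.

At disagreeing overlap positions the consensus takes the base with the
higher Phred score; agreeing bases get the max of the two scores,
disagreeing the absolute difference with a floor of 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import SequenceRecord, reverse_complement

__all__ = ["MergedRead", "MergeFailure", "merge_pair"]

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_DENSITY = 0.25
# a failed best placement this long looks like a real-but-noisy overlap
# ("too_divergent"); anything shorter is indistinguishable from no overlap
_DIVERGENT_MIN_OVERLAP = 25


@dataclass(frozen=True)
class MergedRead:
    residues: str
    qualities: tuple[int, ...]
    overlap_len: int
    mismatches_in_overlap: int
    source_pair_id: str


@dataclass(frozen=True)
class MergeFailure:
    reason: str  # no_overlap | too_divergent
    source_pair_id: str


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _match_profile(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Matches between x and y at every relative offset, via correlation.

    Index ``k`` corresponds to offset ``o = k - (len(y) - 1)`` of y's start
    relative to x's start.  N is *not* treated specially here; callers with
    N-containing reads use the slow path.
    """
    total = np.zeros(x.shape[0] + y.shape[0] - 1, dtype=np.float64)
    for base in b"ACGT":
        xa = (x == base).astype(np.float64)
        ya = (y == base).astype(np.float64)
        total += np.correlate(xa, ya, mode="full")
    return total


def _overlap_bounds(o: int, l1: int, l2: int) -> tuple[int, int]:
    """Overlap window [start, stop) in r1 coordinates for offset ``o``."""
    start = max(0, o)
    stop = min(l1, l2 + o)
    return start, stop


def merge_pair(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_density: float = DEFAULT_MAX_MISMATCH_DENSITY,
) -> MergedRead | MergeFailure:
    """Merge one read pair, or return a categorised failure."""
    if not r1.residues or not r2.residues:
        raise ValueError("merge_pair requires nonempty mates")
    a2 = reverse_complement(r2.residues)
    q2 = tuple(reversed(r2.qualities)) if r2.qualities is not None else (40,) * len(a2)
    q1 = r1.qualities if r1.qualities is not None else (40,) * len(r1.residues)
    l1, l2 = len(r1.residues), len(a2)

    has_n = "N" in r1.residues or "N" in a2
    x, y = _encode(r1.residues), _encode(a2)

    best: tuple[float, int, int, int] | None = None  # density, -overlap, o, mismatches
    if not has_n:
        matches = _match_profile(x, y)
        for k in range(matches.shape[0]):
            o = k - (l2 - 1)
            start, stop = _overlap_bounds(o, l1, l2)
            ov = stop - start
            if ov < min_overlap:
                continue
            mism = ov - int(round(matches[k]))
            density = mism / ov
            cand = (density, -ov, o, mism)
            if best is None or cand[:2] < best[:2]:
                best = cand
    else:
        for o in range(-(l2 - min_overlap), l1 - min_overlap + 1):
            start, stop = _overlap_bounds(o, l1, l2)
            ov = stop - start
            if ov < min_overlap:
                continue
            seg1 = x[start:stop]
            seg2 = y[start - o : stop - o]
            mism = int(np.count_nonzero((seg1 != seg2) & (seg1 != ord("N")) & (seg2 != ord("N"))))
            density = mism / ov
            cand = (density, -ov, o, mism)
            if best is None or cand[:2] < best[:2]:
                best = cand

    if best is None:
        return MergeFailure("no_overlap", r1.id)
    density, neg_ov, o, mism = best
    if density > max_mismatch_density:
        reason = "too_divergent" if -neg_ov >= _DIVERGENT_MIN_OVERLAP else "no_overlap"
        return MergeFailure(reason, r1.id)

    start, stop = _overlap_bounds(o, l1, l2)
    cons_res: list[str] = []
    cons_q: list[int] = []
    if o >= 0:
        cons_res.append(r1.residues[:o])
        cons_q.extend(q1[:o])
    for i in range(start, stop):
        b1, b2 = r1.residues[i], a2[i - o]
        s1, s2 = q1[i], q2[i - o]
        if b1 == b2:
            cons_res.append(b1)
            cons_q.append(max(s1, s2))
        elif b1 == "N":
            cons_res.append(b2)
            cons_q.append(s2)
        elif b2 == "N":
            cons_res.append(b1)
            cons_q.append(s1)
        else:
            cons_res.append(b1 if s1 >= s2 else b2)
            cons_q.append(max(abs(s1 - s2), 2))
    if o >= 0 and l2 + o > l1:  # r2 extends past r1's end
        cons_res.append(a2[l1 - o :])
        cons_q.extend(q2[l1 - o :])
    residues = "".join(cons_res)
    return MergedRead(
        residues=residues,
        qualities=tuple(cons_q),
        overlap_len=stop - start,
        mismatches_in_overlap=mism,
        source_pair_id=r1.id,
    )
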