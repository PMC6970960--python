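"""Quality/adapter trimming and exact-match primer demultiplexing.

First-PCR primers sit at the very start of each mate by construction of the
library prep, so demultiplexing is an anchored exact prefix match with zero
mismatches allowed — one substitution inside the primer leaves the pair
unassigned.  Assigned pairs have the primer bases (and qualities) stripped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_io import PrimerScheme, SequenceRecord

__all__ = ["TrimResult", "DemuxBucket", "DemuxResult", "quality_trim", "demultiplex_by_primer"]

DEFAULT_Q = 20
DEFAULT_MIN_LEN = 100
_WINDOW = 4
_MIN_ADAPTER_MATCH = 8


@dataclass
class TrimResult:
    pair: tuple[SequenceRecord, SequenceRecord] | None
    rejected: bool
    reason: str | None = None


@dataclass
class DemuxBucket:
    gene: str
    forward_label: str
    pairs: list[tuple[SequenceRecord, SequenceRecord]] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return len(self.pairs)


@dataclass
class DemuxResult:
    buckets: list[DemuxBucket]
    unassigned: list[tuple[SequenceRecord, SequenceRecord]]
    n_input: int

    @property
    def n_assigned(self) -> int:
        return sum(b.n_assigned for b in self.buckets)

    @property
    def n_unassigned(self) -> int:
        return len(self.unassigned)


def _trim_read(
    read: SequenceRecord, q_threshold: int, adapters: tuple[str, ...]
) -> SequenceRecord | None:
    quals = read.qualities
    if quals is None:
        raise ValueError(f"read {read.id!r}: quality trimming requires qualities")
    cut = len(quals)
    for i in range(len(quals)):
        window = quals[i : i + _WINDOW]
        if sum(window) / len(window) < q_threshold:
            # keep leading bases of the failing window that are individually fine
            cut = i
            while cut < len(quals) and quals[cut] >= q_threshold:
                cut += 1
            break
    if cut == 0:
        return None
    trimmed = read.slice(0, cut)
    # remove a 3' suffix that is exactly a prefix (>= 8 nt) of a configured adapter
    best = 0
    for adapter in adapters:
        limit = min(len(adapter), len(trimmed.residues) - 1)
        for k in range(limit, _MIN_ADAPTER_MATCH - 1, -1):
            if trimmed.residues.endswith(adapter[:k]):
                best = max(best, k)
                break
    if best:
        trimmed = trimmed.slice(0, len(trimmed.residues) - best)
    return trimmed


def quality_trim(
    pair: tuple[SequenceRecord, SequenceRecord],
    q_threshold: int = DEFAULT_Q,
    min_len: int = DEFAULT_MIN_LEN,
    adapters: tuple[str, ...] = (),
) -> TrimResult:
    """Trim the 3' end where a sliding window-4 mean quality drops below
    ``q_threshold``, strip adapter read-through, reject short survivors."""
    r1, r2 = pair
    t1 = _trim_read(r1, q_threshold, adapters)
    t2 = _trim_read(r2, q_threshold, adapters)
    if t1 is None or t2 is None or len(t1.residues) < min_len or len(t2.residues) < min_len:
        return TrimResult(None, True, "too_short_after_trim")
    return TrimResult((t1, t2), False)


def demultiplex_by_primer(
    pairs: list[tuple[SequenceRecord, SequenceRecord]], scheme: PrimerScheme
) -> DemuxResult:
    """Assign each pair to (gene, forward label) by exact anchored primer match.

    R1 must begin exactly with the forward primer and R2 exactly with the
    gene's reverse primer; both primers are stripped from the assigned pair.
    Every pair lands in exactly one bucket or in ``unassigned``.
    """
    scheme.validate()
    buckets = {key: DemuxBucket(*key) for key in scheme.buckets()}
    unassigned: list[tuple[SequenceRecord, SequenceRecord]] = []
    targets = [
        (gene, lab, fwd, scheme.reverses[gene][1])
        for gene, lab in scheme.buckets()
        for l2, fwd in scheme.forwards[gene]
        if l2 == lab
    ]
    for r1, r2 in pairs:
        for gene, lab, fwd, rev in targets:
            if r1.residues.startswith(fwd) and r2.residues.startswith(rev):
                buckets[(gene, lab)].pairs.append((r1.slice(len(fwd)), r2.slice(len(rev))))
                break
        else:
            unassigned.append((r1, r2))
    return DemuxResult(list(buckets.values()), unassigned, len(pairs))
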